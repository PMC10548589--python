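"""Published summary statistics of the motivating cross-sectional survey.

The package was motivated by a survey of 5810 Colombian workers relating
depressive symptoms to five psychoactive-substance outcomes whose marginal
prevalences span 1.8% to 96.1%.  The subject-level records are
confidential, but the published per-outcome summary tables — crude and
age-group-adjusted prevalence ratios, standard errors (log scale) and 95%
CIs for every model in the comparison battery — are public numbers and are
bundled here as machine-readable inputs.  They drive the worked examples,
the table-reconstruction fixtures and the acceptance checks.

All standard errors are on the natural-log scale (verified: point *
exp(+-z se) reproduces the printed CI limits).  ``None`` marks entries the
survey could not produce (the log-binomial fit did not converge at 96.1%
prevalence).
"""

from __future__ import annotations

OUTCOMES = ("cocaine", "marijuana", "cigarette", "alcohol", "risk")

N_SUBJECTS = 5810

#: marginal outcome prevalence (proportion)
PREVALENCE = {
    "cocaine": 0.018,
    "marijuana": 0.096,
    "cigarette": 0.213,
    "alcohol": 0.857,
    "risk": 0.961,
}

#: crude (unadjusted) estimates: PR with its SE/CI, the NB-model SE, and the OR
CRUDE = {
    "cocaine": {"pr": 3.294, "se": 0.7126, "ci": (0.815, 13.316),
                "nb_se": 0.7168, "or": 3.337, "or_se": 0.717},
    "marijuana": {"pr": 3.493, "se": 0.2999, "ci": (1.940, 6.287),
                  "nb_se": 0.3091, "or": 3.771, "or_se": 0.309},
    "cigarette": {"pr": 2.593, "se": 0.1897, "ci": (1.788, 3.760),
                  "nb_se": 0.2073, "or": 3.045, "or_se": 0.208},
    "alcohol": {"pr": 1.255, "se": 0.0356, "ci": (1.171, 1.346),
                "nb_se": 0.0849, "or": 2.940, "or_se": 0.121},
    "risk": {"pr": 1.086, "se": 0.0180, "ci": (1.048, 1.125),
             "nb_se": 0.0769, "or": 3.560, "or_se": 0.180},
}

#: age-group-adjusted estimates per outcome: the Mantel-Haenszel reference
#: and each regression model (model-based and robust-variance standard
#: errors).  ``None`` = not produced (non-convergence).
ADJUSTED = {
    "cocaine": {
        "mh": {"pr": 2.913, "se": 0.7570, "ci": (0.786, 12.845)},
        "nlb": {"pr": 2.931, "se": 0.7185, "robust_se": 0.7144,
                "robust_ci": (0.723, 11.889), "bic": -43857.1},
        "poisson": {"pr": 2.928, "se": 0.7161, "robust_se": 0.7152,
                    "bic": -43787.03},
        "binomial": {"pr": 2.925, "se": 0.7128, "robust_se": 0.7160,
                     "bic": -43602.83},
        "logistic_or": {"or": 2.965, "se": 0.7184, "robust_se": 0.7198},
    },
    "marijuana": {
        "mh": {"pr": 3.407, "se": 0.3121, "ci": (1.848, 6.281)},
        "nlb": {"pr": 3.444, "se": 0.3245, "robust_se": 0.3154,
                "robust_ci": (1.856, 6.391), "bic": -45899.8},
        "poisson": {"pr": 3.440, "se": 0.3198, "robust_se": 0.3159,
                    "bic": -45541.37},
        "binomial": {"pr": 3.435, "se": 0.3151, "robust_se": 0.3164,
                     "bic": -44534.91},
        "logistic_or": {"or": 3.702, "se": 0.3246, "robust_se": 0.3255},
    },
    "cigarette": {
        "mh": {"pr": 2.209, "se": 0.1913, "ci": (1.518, 3.214)},
        "nlb": {"pr": 2.175, "se": 0.2091, "robust_se": 0.1919,
                "robust_ci": (1.493, 3.167), "bic": -36500.12},
        "poisson": {"pr": 2.197, "se": 0.1991, "robust_se": 0.1901,
                    "bic": -35956.34},
        "binomial": {"pr": 2.225, "se": 0.1885, "robust_se": 0.1878,
                     "bic": -34252.81},
        "logistic_or": {"or": 2.536, "se": 0.2105, "robust_se": 0.2127},
    },
    "alcohol": {
        "mh": {"pr": 1.241, "se": 0.0361, "ci": (1.157, 1.332)},
        "nlb": {"pr": 1.243, "se": 0.0872, "robust_se": 0.0360,
                "robust_ci": (1.158, 1.334), "bic": -45293.58},
        "poisson": {"pr": 1.242, "se": 0.0668, "robust_se": 0.0359,
                    "bic": -44885.75},
        "binomial": {"pr": 1.238, "se": 0.0449, "robust_se": 0.0450,
                     "bic": -41961.72},
        "logistic_or": {"or": 2.810, "se": 0.1260, "robust_se": 0.1248},
    },
    "risk": {
        "mh": {"pr": 1.086, "se": 0.0185, "ci": (1.047, 1.126)},
        "nlb": {"pr": 1.086, "se": 0.0793, "robust_se": 0.0186,
                "robust_ci": (1.047, 1.127), "bic": -47709.15},
        "poisson": {"pr": 1.086, "se": 0.0576, "robust_se": 0.0186,
                    "bic": -47583.75},
        "binomial": None,  # log-binomial fit did not converge
        "logistic_or": {"or": 3.462, "se": 0.1857, "robust_se": 0.1825},
    },
}
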