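"""Synthetic cross-sectional cohorts with a log-link outcome model.

The generator emulates the structure of a workforce survey of psychoactive
substance use (n = 5810; ages 18-56 with mean 28.2 and SD 7.1, grouped as
<=25 / 26-29 / 30-34 / >=35 with shares 41.9/24.0/14.0/20.2%; a binary
"depression" exposure; binary outcomes spanning prevalences from 1.8% to
96.1%).  Each subject draws

* an age group from the configured shares, then a continuous age from the
  study-wide truncated normal restricted to the group's interval;
* exposure from a Bernoulli whose log-odds depend on age group (this
  age-exposure association is what induces confounding);
* each outcome from Bernoulli(mu) with ``mu = exp(b0 + b1 * exposure +
  age_effect[group] + frailty)`` — exactly the log-link model the fitting
  code assumes, so true prevalence ratios are known (``PR = exp(b1)``).

Intercepts are calibrated analytically so the marginal outcome prevalence
hits its target; configurations whose implied mu would exceed 1 at any
covariate support point are refused before any draw.  The optional
mean-one log-normal frailty induces extra-binomial variation for
overdispersion experiments (off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq

from .errors import PrevRatioError, ValidationError
from .glm import ModelSpec, SubjectData, Term, build_design, fit_glm
from .robust import sandwich
from .glm import extract_effect

__all__ = [
    "AGE_GROUP_LABELS",
    "OutcomeSpec",
    "GeneratorConfig",
    "generate",
    "recovery_experiment",
    "load_preset",
    "preset_names",
]

AGE_GROUP_LABELS = ("<=25", "26-29", "30-34", ">=35")
_AGE_EDGES = (18.0, 26.0, 30.0, 35.0, 56.0)  # group g spans [edge_g, edge_{g+1})


@dataclass(frozen=True)
class OutcomeSpec:
    """One binary outcome of the generating model."""

    label: str
    target_prevalence: float
    pr: float  # true exposed/unexposed prevalence ratio, exp(b1)
    age_log_effects: tuple = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValidationError(f"{self.label}: target prevalence must be in (0,1)")
        if self.pr <= 0:
            raise ValidationError(f"{self.label}: pr must be > 0")
        if len(self.age_log_effects) != 4 or self.age_log_effects[0] != 0:
            raise ValidationError(
                f"{self.label}: age_log_effects must have 4 entries, first 0 (reference)")


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 5810
    seed: int = 0
    exposure_prevalence: float = 0.30
    exposure_age_logodds: tuple = (0.0, 0.0, 0.0, 0.0)
    age_shares: tuple = (0.419, 0.240, 0.140, 0.202)
    age_mean: float = 28.2
    age_sd: float = 7.1
    outcomes: tuple = ()
    overdispersion_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not 0 < self.exposure_prevalence < 1:
            raise ValidationError("exposure_prevalence must be in (0,1)")
        total = sum(self.age_shares)
        if len(self.age_shares) != 4 or abs(total - 1) > 0.01:
            raise ValidationError("age_shares must be 4 proportions summing to 1")
        if total != 1.0:  # published shares carry printed rounding (e.g. sum 1.001)
            object.__setattr__(self, "age_shares",
                               tuple(s / total for s in self.age_shares))
        if self.overdispersion_sd < 0:
            raise ValidationError("overdispersion_sd must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        age = d.get("age", {})
        outs = tuple(
            OutcomeSpec(o["label"], float(o["target_prevalence"]), float(o["pr"]),
                        tuple(float(v) for v in o.get("age_log_effects",
                                                      (0, 0, 0, 0))))
            for o in d.get("outcomes", ()))
        return cls(
            n=int(d.get("n", 5810)),
            seed=int(d.get("seed", 0)),
            exposure_prevalence=float(d.get("exposure_prevalence", 0.30)),
            exposure_age_logodds=tuple(
                float(v) for v in d.get("exposure_age_logodds", (0, 0, 0, 0))),
            age_shares=tuple(float(v) for v in age.get("shares",
                                                       (0.419, 0.240, 0.140, 0.202))),
            age_mean=float(age.get("mean", 28.2)),
            age_sd=float(age.get("sd", 7.1)),
            outcomes=outs,
            overdispersion_sd=float(d.get("overdispersion_sd", 0.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _exposure_probs(cfg: GeneratorConfig) -> np.ndarray:
    """Per-age-group exposure probabilities hitting the target marginal."""
    off = np.asarray(cfg.exposure_age_logodds, float)
    shares = np.asarray(cfg.age_shares, float)

    def marginal(c):
        return float(shares @ (1 / (1 + np.exp(-(c + off))))) - cfg.exposure_prevalence

    c = brentq(marginal, -30, 30)
    return 1 / (1 + np.exp(-(c + off)))


def _outcome_intercept(cfg: GeneratorConfig, out: OutcomeSpec,
                       p_exp: np.ndarray) -> float:
    """Calibrate b0 so the marginal prevalence equals the target, then
    verify mu <= 1 at every (age group, exposure) support point."""
    shares = np.asarray(cfg.age_shares, float)
    ag = np.asarray(out.age_log_effects, float)
    b1 = math.log(out.pr)
    k = 0.0
    for g in range(4):
        for e in (0, 1):
            w = shares[g] * (p_exp[g] if e else 1 - p_exp[g])
            k += w * math.exp(b1 * e + ag[g])
    b0 = math.log(out.target_prevalence / k)
    mu_max = math.exp(b0 + max(b1, 0.0) + float(ag.max()))
    if mu_max > 1.0 + 1e-12:
        raise ValidationError(
            f"outcome {out.label!r}: implied probability {mu_max:.4f} > 1 at the "
            "maximal support point (highest-risk age group, exposed); reduce pr, "
            "age effects, or the target prevalence")
    return b0


def generate(config: GeneratorConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw one cohort. Identical config + seed gives a byte-identical frame.

    Columns: ``age`` (years, continuous), ``age_group`` (four labels),
    ``exposure`` (0/1), then one 0/1 column per configured outcome.
    """
    if not config.outcomes:
        raise ValidationError("config has no outcomes")
    p_exp = _exposure_probs(config)
    intercepts = {o.label: _outcome_intercept(config, o, p_exp)
                  for o in config.outcomes}  # validates before any draw

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    group = rng.choice(4, size=n, p=np.asarray(config.age_shares, float))

    # age: study-wide truncated normal, restricted to the group's interval
    lo = np.asarray(_AGE_EDGES[:-1], float)[group]
    hi = np.asarray(_AGE_EDGES[1:], float)[group]
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    age = config.age_mean + config.age_sd * stats.norm.ppf(u)

    exposure = (rng.uniform(size=n) < p_exp[group]).astype(int)

    frame = pd.DataFrame({
        "age": age,
        "age_group": pd.Categorical.from_codes(group, list(AGE_GROUP_LABELS)),
        "exposure": exposure,
    })
    if config.overdispersion_sd > 0:
        s = config.overdispersion_sd
        frailty = rng.normal(-0.5 * s * s, s, size=n)  # mean-one on natural scale
    else:
        frailty = np.zeros(n)
    for out in config.outcomes:
        eta = (intercepts[out.label] + math.log(out.pr) * exposure
               + np.asarray(out.age_log_effects, float)[group] + frailty)
        mu = np.minimum(np.exp(eta), 1.0)  # frailty only can push past 1
        frame[out.label] = (rng.uniform(size=n) < mu).astype(int)
    return frame


def recovery_experiment(
    config: GeneratorConfig,
    n_replicates: int,
    models: Sequence[str] = ("negative_log_binomial", "log_poisson",
                             "log_binomial"),
    *,
    outcome: Optional[str] = None,
    adjust: Optional[bool] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Repeated-sampling check: bias, spread, robust-CI coverage, and
    non-convergence rate of each model's PR estimate against the known truth.

    A master seed (``config.seed``) deterministically spawns one seed per
    replicate.  Non-converged replicates are counted in ``nonconverge_rate``
    and excluded from the moment/coverage summaries (which report the
    number of converged fits they use).
    """
    if not config.outcomes:
        raise ValidationError("config has no outcomes")
    out = (config.outcomes[0] if outcome is None
           else next(o for o in config.outcomes if o.label == outcome))
    true_pr = out.pr
    if adjust is None:
        adjust = (any(e != 0 for e in out.age_log_effects)
                  or any(e != 0 for e in config.exposure_age_logodds))
    terms = (Term("age_group", "categorical", reference=AGE_GROUP_LABELS[0],
                  levels=AGE_GROUP_LABELS),) if adjust else ()

    child_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in np.random.SeedSequence(config.seed).spawn(n_replicates)]
    results = {m: {"pr": [], "cover": [], "fail": 0} for m in models}
    for seed in child_seeds:
        frame = generate(config, seed=seed)
        data = SubjectData(frame, outcome=out.label, exposure="exposure")
        y, X, names = build_design(data, ModelSpec("log_poisson", terms))
        for m in models:
            try:
                fit = fit_glm(y, X, m, names=names)
            except PrevRatioError:  # degenerate replicate (e.g. empty cell)
                results[m]["fail"] += 1
                continue
            if fit.converged != "yes":
                results[m]["fail"] += 1
                continue
            try:
                cov = sandwich(fit, y, X).matrix
            except PrevRatioError:
                results[m]["fail"] += 1
                continue
            est = extract_effect(fit, "exposure", cov=cov, level=level)
            results[m]["pr"].append(est.point)
            results[m]["cover"].append(est.ci_low <= true_pr <= est.ci_high)
    rows = []
    for m in models:
        r = results[m]
        prs = np.asarray(r["pr"], float)
        rows.append({
            "model": m,
            "true_pr": true_pr,
            "n_replicates": n_replicates,
            "n_converged": len(prs),
            "mean_pr": float(prs.mean()) if len(prs) else math.nan,
            "sd_pr": float(prs.std(ddof=1)) if len(prs) > 1 else math.nan,
            "coverage": float(np.mean(r["cover"])) if len(prs) else math.nan,
            "nonconverge_rate": r["fail"] / n_replicates,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def preset_names() -> list:
    root = resources.files("prevratio").joinpath("presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> GeneratorConfig:
    """Load a bundled generator configuration by name."""
    root = resources.files("prevratio").joinpath("presets")
    path = root.joinpath(f"{name}.yaml")
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}")
    return GeneratorConfig.from_dict(yaml.safe_load(text))
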