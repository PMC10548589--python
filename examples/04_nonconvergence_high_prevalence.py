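"""Log-binomial boundary failure at very high prevalence.

At 96.1% outcome prevalence the exposed-cell probability sits a hair below
1.  Adjusting for numeric age, the log-binomial likelihood pushes fitted
probabilities onto the mu < 1 boundary and cannot reach a stationary
point; the Poisson and negative log-binomial fits (whose means are
unconstrained) complete and give valid robust inference.
"""

from prevratio import (ModelSpec, SubjectData, Term, build_design,
                       effect_with_robust, fit_glm)
from prevratio.simulate import generate, load_preset

frame = generate(load_preset("study"))
data = SubjectData(frame, outcome="risk", exposure="exposure")
y, X, names = build_design(data, ModelSpec("log_binomial", (Term("age"),)))

for family in ("log_binomial", "log_poisson", "negative_log_binomial"):
    fit = fit_glm(y, X, family, names=names)
    if fit.converged != "yes":
        print(f"{family:24s} No converge ({fit.converged})")
    else:
        est = effect_with_robust(fit, y, X, "exposure")
        print(f"{family:24s} PR {est.point:.3f} "
              f"({est.ci_low:.3f}, {est.ci_high:.3f})  robust se {est.se_log:.4f}")
# The true PR in this cohort is 1.0585 — the largest effect a log-link
# Bernoulli model can carry at this prevalence and exposure share.
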