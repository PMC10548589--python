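"""Precision, confounding and OR-bias metrics, and the multi-model report.

Three scale-free percentages quantify how a regression model's adjusted
prevalence ratio compares with the Mantel-Haenszel reference:

* PR precision: ``|PR_MH - PR_model| / PR_model * 100``
* confounding ("confusion") percentage: signed relative change from the
  crude PR to the adjusted PR, ``(PR_crude - PR_adj) / PR_adj * 100``
* SE precision: ``|SE_MH - SE_model| / SE_model * 100`` on the log-scale
  standard errors.

The inherent OR bias is the factor ``(1 - p2) / (1 - p1)`` by which the
odds ratio overstates the prevalence ratio; it grows with prevalence and
is the motivation for PR models over logistic regression in
cross-sectional data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedEstimateError, ValidationError
from .glm import (ModelSpec, SubjectData, Term, bic as bic_of, build_design,
                  extract_effect, fit_glm, resolve_family)
from .robust import sandwich
from .tables import (ContingencyTable2x2, EffectEstimate, StratifiedTables,
                     crude_or, crude_pr, mh_pr)

__all__ = [
    "inherent_or_bias",
    "precision_pr",
    "confusion_pct",
    "se_precision",
    "ComparisonRow",
    "ComparisonReport",
    "compare_models",
    "data_to_table",
    "MODEL_LABELS",
]

MODEL_LABELS = {
    "negative_log_binomial": "Negative Log-Binomial model",
    "log_poisson": "Cox/Poisson model",
    "cox_constant_time": "Cox/Poisson model",
    "log_binomial": "Binomial regression",
    "logistic": "Logistic regression",
}


def inherent_or_bias(p1: float, p2: float) -> tuple[float, float]:
    """Bias factor (1-p2)/(1-p1) of OR relative to PR, and as a percentage.

    OR = PR * factor identically; the factor exceeds 1 whenever p1 > p2.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValidationError("p1 and p2 must lie strictly inside (0, 1)")
    factor = (1 - p2) / (1 - p1)
    return factor, (factor - 1.0) * 100.0


def precision_pr(pr_mh: float, pr_model: float) -> float:
    """Absolute relative difference of the MH PR from a model PR, in %."""
    if pr_model <= 0:
        raise ValidationError("pr_model must be > 0")
    return abs(pr_mh - pr_model) / pr_model * 100.0


def confusion_pct(pr_crude: float, pr_adjusted: float) -> float:
    """Signed confounding percentage: (crude - adjusted)/adjusted * 100."""
    if pr_adjusted <= 0:
        raise ValidationError("pr_adjusted must be > 0")
    return (pr_crude - pr_adjusted) / pr_adjusted * 100.0


def se_precision(se_mh: float, se_model: float) -> float:
    """Absolute relative difference of the MH SE from a model SE, in %."""
    if se_model <= 0:
        raise ValidationError("se_model must be > 0")
    return abs(se_mh - se_model) / se_model * 100.0


# ---------------------------------------------------------------------------
# Multi-model comparison report
# ---------------------------------------------------------------------------


@dataclass
class ComparisonRow:
    model_label: str
    estimate: Optional[EffectEstimate]
    confusion_pct: Optional[float] = None
    se_precision_pct: Optional[float] = None
    bic: Optional[float] = None
    convergence: str = "yes"
    is_reference: bool = False


@dataclass
class ComparisonReport:
    outcome_label: str
    prevalence: float
    rows: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must be in (0, 1)")

    @property
    def reference_row(self) -> Optional[ComparisonRow]:
        refs = [r for r in self.rows if r.is_reference]
        return refs[0] if refs else None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            e = r.estimate
            recs.append({
                "outcome": self.outcome_label,
                "model": r.model_label,
                "measure": e.measure if e else "",
                "point": e.point if e else np.nan,
                "confusion_pct": np.nan if r.confusion_pct is None else r.confusion_pct,
                "se_log": e.se_log if e else np.nan,
                "ci_low": e.ci_low if e else np.nan,
                "ci_high": e.ci_high if e else np.nan,
                "se_precision_pct": (np.nan if r.se_precision_pct is None
                                     else r.se_precision_pct),
                "bic": np.nan if r.bic is None else r.bic,
                "convergence": r.convergence,
            })
        return pd.DataFrame.from_records(recs)

    def to_text(self) -> str:
        df = self.to_frame().drop(columns=["outcome"]).copy()
        for col in ("point", "ci_low", "ci_high"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
        df["se_log"] = df["se_log"].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
        for col in ("confusion_pct", "se_precision_pct", "bic"):
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        df.loc[df["convergence"] != "yes", "point"] = "No converge"
        head = f"Outcome: {self.outcome_label} (prevalence = {self.prevalence * 100:.1f}%)"
        return head + "\n" + df.to_string(index=False)


def data_to_table(data: SubjectData) -> ContingencyTable2x2:
    """Collapse subject-level data to the exposure-by-outcome 2x2 table."""
    df = data.frame
    e = df[data.exposure].to_numpy()
    y = df[data.outcome].to_numpy()
    return ContingencyTable2x2(
        a=int(((e == 1) & (y == 1)).sum()), b=int(((e == 1) & (y == 0)).sum()),
        c=int(((e == 0) & (y == 1)).sum()), d=int(((e == 0) & (y == 0)).sum()),
    )


def _strata_from(data: SubjectData, column: str) -> StratifiedTables:
    df = data.frame
    strata = []
    for label, sub in df.groupby(column, sort=True, observed=True):
        strata.append((str(label),
                       data_to_table(SubjectData(sub, data.outcome, data.exposure))))
    return StratifiedTables(strata)


def compare_models(
    data: SubjectData,
    adjustment: Optional[Term] = None,
    models: Sequence[str] = ("negative_log_binomial", "log_poisson",
                             "log_binomial", "logistic"),
    *,
    outcome_label: Optional[str] = None,
    robust: bool = True,
    robust_scaling: str = "stata",
    level: float = 0.95,
) -> ComparisonReport:
    """Fit the requested model battery and lay out the comparison report.

    Rows: crude PR, the MH reference (when ``adjustment`` is categorical),
    then each model adjusted for ``adjustment`` — model-based and (when
    ``robust``) sandwich-variance variants.  Confounding percentages compare
    each adjusted PR with the crude PR; SE precision compares each robust
    SE with the MH SE.  Non-converged fits appear as rows with status
    "No converge" semantics rather than being dropped.
    """
    df = data.frame
    prevalence = float(df[data.outcome].mean())
    report = ComparisonReport(outcome_label or data.outcome, prevalence)
    table = data_to_table(data)

    try:
        crude = crude_pr(table, level)
        report.rows.append(ComparisonRow("PR Crude", crude))
    except UndefinedEstimateError:
        crude = None
        report.rows.append(ComparisonRow("PR Crude", None, convergence="undefined"))

    mh_est = None
    if adjustment is not None and adjustment.kind == "categorical":
        try:
            mh_est = mh_pr(_strata_from(data, adjustment.name), level)
            report.rows.append(ComparisonRow(
                "PR MH (adjusted)", mh_est,
                confusion_pct=(None if crude is None else
                               confusion_pct(crude.point, mh_est.point)),
                is_reference=True))
        except UndefinedEstimateError:
            report.rows.append(ComparisonRow("PR MH (adjusted)", None,
                                             convergence="undefined"))

    terms = () if adjustment is None else (adjustment,)
    for fam_name in models:
        label_core = MODEL_LABELS[fam_name]
        spec = ModelSpec(fam_name, terms)
        y, X, names = build_design(data, spec)
        fit = fit_glm(y, X, fam_name, names=names)
        measure_prefix = "OR" if resolve_family(fam_name) == "logistic" else "PR"
        variants = [("model_based", f"{measure_prefix} {label_core}")]
        if robust:
            variants.append(("robust", f"{measure_prefix} Robust {label_core}"))
        for variance, label in variants:
            if fit.converged != "yes":
                report.rows.append(ComparisonRow(label, None,
                                                 convergence=fit.converged))
                continue
            cov = (sandwich(fit, y, X, scaling=robust_scaling).matrix
                   if variance == "robust" else None)
            est = extract_effect(fit, data.exposure, cov=cov, level=level)
            is_pr = est.measure == "PR"
            row = ComparisonRow(
                label, est,
                confusion_pct=(confusion_pct(crude.point, est.point)
                               if (is_pr and crude is not None) else None),
                se_precision_pct=(se_precision(mh_est.se_log, est.se_log)
                                  if (is_pr and mh_est is not None and
                                      variance == "robust") else None),
                bic=(bic_of(fit) if variance == "robust" or not robust else None),
                convergence=fit.converged)
            report.rows.append(row)
    return report
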