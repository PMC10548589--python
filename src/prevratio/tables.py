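"""Crude and Mantel-Haenszel estimation of prevalence ratios from 2x2 tables.

Table orientation is fixed throughout the package: rows are exposure
(exposed first), columns are outcome (case first)::

                 case   non-case
    exposed       a        b        n1 = a + b
    unexposed     c        d        n0 = c + d

so ``p1 = a / n1`` is the prevalence among the exposed and ``p2 = c / n0``
among the unexposed.  The prevalence ratio is ``PR = p1 / p2`` and the odds
ratio ``OR = (a d) / (b c) = PR * (1 - p2) / (1 - p1)``.

Also provided: exhaustive reconstruction of integer 2x2 tables from printed
summary statistics (total n, outcome prevalence, PR, log-scale SE), which
makes published worked examples testable when the subject-level data are
confidential.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import NoConsistentTableError, UndefinedEstimateError, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "StratifiedTables",
    "EffectEstimate",
    "wald_ci",
    "crude_pr",
    "crude_or",
    "mh_pr",
    "reconstruct_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 exposure-by-outcome table (exposed/case first)."""

    a: int  # exposed cases
    b: int  # exposed non-cases
    c: int  # unexposed cases
    d: int  # unexposed non-cases

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"cell {name}={v!r} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n0(self) -> int:
        return self.c + self.d

    @property
    def n(self) -> int:
        return self.n1 + self.n0

    @property
    def p1(self) -> float:
        if self.n1 == 0:
            raise UndefinedEstimateError("no exposed subjects (a + b = 0)")
        return self.a / self.n1

    @property
    def p2(self) -> float:
        if self.n0 == 0:
            raise UndefinedEstimateError("no unexposed subjects (c + d = 0)")
        return self.c / self.n0

@dataclass(frozen=True)
class StratifiedTables:
    """Ordered collection of labelled 2x2 strata for MH pooling."""

    strata: Sequence[tuple[str, ContingencyTable2x2]]

    def __post_init__(self) -> None:
        if len(self.strata) < 1:
            raise ValidationError("at least one stratum required")
        labels = [lab for lab, _ in self.strata]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"stratum labels not unique: {labels}")

    def __iter__(self):
        return iter(self.strata)

    def __len__(self) -> int:
        return len(self.strata)


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio effect measure (PR or OR) with log-scale SE and Wald CI."""

    measure: str  # "PR" or "OR"
    point: float
    se_log: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    z: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.z is None:
            object.__setattr__(self, "z", stats.norm.ppf(0.5 + self.level / 2))
        if not self.point > 0:
            raise ValidationError(f"point estimate must be positive, got {self.point}")
        if self.se_log < 0:
            raise ValidationError(f"se_log must be non-negative, got {self.se_log}")


def wald_ci(point: float, se_log: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for a ratio, symmetric on the log scale.

    Uses the exact normal quantile (1.959964... at 95%), not 1.96.
    """
    if not point > 0:
        raise ValidationError("point must be > 0")
    if se_log < 0:
        raise ValidationError("se_log must be >= 0")
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * se_log
    return point * math.exp(-half), point * math.exp(half)


def _estimate(measure: str, point: float, se_log: float, level: float) -> EffectEstimate:
    lo, hi = wald_ci(point, se_log, level)
    return EffectEstimate(measure, point, se_log, lo, hi, level)


def crude_pr(
    table: ContingencyTable2x2, level: float = 0.95, correction: float = 0.0
) -> EffectEstimate:
    """Crude prevalence ratio p1/p2 with the delta-method log-scale SE.

    ``se_log = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))``.  A zero cell among
    {a, c} makes the estimate (or its SE) undefined and raises
    :class:`UndefinedEstimateError`; ``correction`` adds the classical +0.5
    to every cell first (off by default).
    """
    a, b, c, d = (x + correction for x in (table.a, table.b, table.c, table.d))
    n1, n0 = a + b, c + d
    if n1 == 0 or n0 == 0:
        raise UndefinedEstimateError("empty exposure arm: a+b and c+d must both be > 0")
    if c == 0:
        raise UndefinedEstimateError("zero unexposed cases (c = 0): PR undefined/infinite")
    if a == 0:
        raise UndefinedEstimateError("zero exposed cases (a = 0): log-PR undefined")
    point = (a / n1) / (c / n0)
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    return _estimate("PR", point, se, level)


def crude_or(
    table: ContingencyTable2x2, level: float = 0.95, correction: float = 0.0
) -> EffectEstimate:
    """Crude odds ratio (a d)/(b c) with SE sqrt(1/a + 1/b + 1/c + 1/d)."""
    cells = {"a": table.a, "b": table.b, "c": table.c, "d": table.d}
    zero = [k for k, v in cells.items() if v + correction == 0]
    if zero:
        raise UndefinedEstimateError(
            f"zero cell(s) {', '.join(zero)}: OR estimate/SE undefined"
        )
    a, b, c, d = (cells[k] + correction for k in "abcd")
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return _estimate("OR", point, se, level)


def mh_pr(strata: StratifiedTables | Iterable, level: float = 0.95) -> EffectEstimate:
    """Mantel-Haenszel pooled prevalence ratio across strata.

    Point estimate::

        PR_MH = sum_i(a_i * n0_i / n_i) / sum_i(c_i * n1_i / n_i)

    Variance of ln PR_MH by the Greenland-Robins (1985) estimator::

        Var = sum_i[(m1_i n1_i n0_i - a_i c_i n_i) / n_i^2] / (R * S)

    with ``m1_i = a_i + c_i`` the stratum case total, ``R`` and ``S`` the MH
    numerator and denominator sums.  On a single stratum this reduces
    exactly to :func:`crude_pr`.
    """
    if not isinstance(strata, StratifiedTables):
        strata = StratifiedTables(list(strata))
    R = S = V = 0.0
    for _, t in strata:
        n = t.n
        if n == 0:
            continue
        R += t.a * t.n0 / n
        S += t.c * t.n1 / n
        m1 = t.a + t.c
        V += (m1 * t.n1 * t.n0 - t.a * t.c * n) / n**2
    if R <= 0 or S <= 0:
        raise UndefinedEstimateError(
            f"MH sums degenerate (numerator={R:g}, denominator={S:g})"
        )
    point = R / S
    se = math.sqrt(V / (R * S))
    return _estimate("PR", point, se, level)


# ---------------------------------------------------------------------------
# Reconstruction of integer tables from printed summary statistics
# ---------------------------------------------------------------------------


def _decimals_of(x: float, cap: int = 8) -> int:
    """Number of decimals in the shortest decimal representation of ``x``."""
    s = repr(float(x))
    if "e" in s or "E" in s:
        return cap
    if "." not in s:
        return 0
    return min(len(s.split(".")[1].rstrip("0")), cap)


def _round(x, nd):
    # numpy round is round-half-even, matching printed statistical output
    return np.round(x, nd)


def reconstruct_table(
    n: int,
    outcome_prevalence: float,
    pr: float,
    se_log: float,
    or_hint: float | None = None,
    *,
    tol_units: float = 0.5,
    level: float = 0.95,
    max_misses: int = 3,
) -> list[ContingencyTable2x2]:
    """Exhaustively search integer 2x2 tables consistent with printed summaries.

    Finds every table with total ``n`` whose case total reproduces the printed
    ``outcome_prevalence``, whose crude PR and log-scale SE round (half-even,
    at each input's printed number of decimals) to the supplied values, and —
    if ``or_hint`` is given — whose crude OR rounds to it as well.  Results
    are ordered by (a, b).  An empty search raises
    :class:`NoConsistentTableError` whose message lists the nearest misses.

    ``tol_units`` is the matching half-width in units of each input's last
    printed digit: the default 0.5 means exact half-even printed rounding;
    larger values (e.g. 2 or 4) admit tables within that many final-digit
    units, which is needed for published rows whose printed statistics are
    not mutually consistent (rounded inputs, design-weighted prevalences,
    or per-outcome non-response).
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if not 0 < outcome_prevalence < 1:
        raise ValidationError("outcome_prevalence must be in (0, 1)")
    if n * outcome_prevalence < 1:
        raise ValidationError("n * prevalence < 1: no cases representable")

    if tol_units < 0.5:
        raise ValidationError("tol_units must be >= 0.5 (0.5 = printed rounding)")
    prev_nd = _decimals_of(outcome_prevalence)
    pr_nd = _decimals_of(pr)
    se_nd = _decimals_of(se_log)
    or_nd = _decimals_of(or_hint) if or_hint is not None else None

    def _match(values, target, nd):
        if tol_units == 0.5:
            return _round(values, nd) == round(target, nd)
        return np.abs(np.asarray(values) - target) <= tol_units * 10.0 ** (-nd) + 1e-12

    # case totals m whose prevalence prints as the given value
    ms = [m for m in range(1, n) if _match(m / n, outcome_prevalence, prev_nd)]
    if not ms:
        raise NoConsistentTableError(
            f"no integer case total in 1..{n - 1} prints prevalence {outcome_prevalence}"
        )

    hits: list[tuple[int, int, ContingencyTable2x2]] = []
    best: list[tuple[float, ContingencyTable2x2]] = []
    n1_all = np.arange(1, n)  # exposed totals
    for m in ms:
        for a in range(1, m):  # need a >= 1 and c = m - a >= 1
            c = m - a
            n1 = n1_all[(n1_all >= a) & (n - n1_all >= c)]
            n0 = n - n1
            with np.errstate(divide="ignore", invalid="ignore"):
                prs = (a / n1) / (c / n0)
                ses = np.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
            ok = _match(prs, pr, pr_nd) & _match(ses, se_log, se_nd)
            if or_hint is not None:
                b_ = n1 - a
                d_ = n0 - c
                with np.errstate(divide="ignore", invalid="ignore"):
                    ors = np.where((b_ > 0) & (d_ > 0), (a * d_) / (b_ * c), np.nan)
                ok &= _match(ors, or_hint, or_nd)
            for n1v in n1[ok]:
                t = ContingencyTable2x2(a, int(n1v) - a, c, n - int(n1v) - c)
                hits.append((t.a, t.b, t))
            if not hits:
                # track nearest misses by relative distance on (PR, SE)
                dist = np.abs(np.log(prs / pr)) + np.abs(ses - se_log) / max(se_log, 1e-12)
                j = int(np.argmin(dist))
                t = ContingencyTable2x2(a, int(n1[j]) - a, c, n - int(n1[j]) - c)
                best.append((float(dist[j]), t))

    if hits:
        hits.sort(key=lambda h: (h[0], h[1]))
        return [t for _, _, t in hits]

    best.sort(key=lambda x: x[0])
    near = [t for _, t in best[:max_misses]]
    lines = []
    for t in near:
        e = crude_pr(t)
        lines.append(f"  (a={t.a}, b={t.b}, c={t.c}, d={t.d}): PR={e.point:.4f}, se_log={e.se_log:.4f}")
    raise NoConsistentTableError(
        "no consistent table for "
        f"(n={n}, prevalence={outcome_prevalence}, PR={pr}, se_log={se_log}"
        + (f", OR={or_hint}" if or_hint is not None else "")
        + ")\nnearest misses:\n" + "\n".join(lines),
        nearest=near,
    )
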