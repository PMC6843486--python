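"""Dose-response and group-comparison statistics for viability assays.

Two tools: a four-parameter logistic (4PL) fit whose midpoint is the IC50,
and one-way ANOVA followed by the Student-Newman-Keuls (SNK) stepdown
multiple-comparison procedure on the studentized range distribution.

The 4PL model for an inhibitory response is

    v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

with dose d > 0, hill > 0, so viability falls from ``top`` toward
``bottom`` and equals their midpoint at d = ic50.  Fitting is done on log
dose with a deterministic multi-start over candidate IC50 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseSeries",
    "IC50Result",
    "GroupComparison",
    "FitError",
    "DegenerateVarianceError",
    "four_pl",
    "fit_4pl",
    "anova_newman_keuls",
]


class FitError(RuntimeError):
    """The dose-response fit did not converge or the data are degenerate."""


class DegenerateVarianceError(ValueError):
    """All groups have zero within-group variance; the studentized range
    statistic is undefined."""


@dataclass
class DoseResponseSeries:
    dose: np.ndarray  # uM
    viability: np.ndarray  # % of control
    replicate_id: str = "exp1"

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.dose.shape != self.viability.shape:
            raise ValueError("dose and viability must be the same length")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_uM": self.dose, "viability_pct": self.viability,
             "replicate": self.replicate_id}
        )


@dataclass
class IC50Result:
    ic50: float  # uM
    hill: float
    top: float
    bottom: float
    confidence_half_width: float  # uM, ~95%
    residual_ss: float = float("nan")


def four_pl(dose, ic50, hill, top, bottom):
    """Inhibitory four-parameter logistic curve."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def _4pl_logp(logd, log_ic50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logd - log_ic50)))


def fit_4pl(series: DoseResponseSeries) -> IC50Result:
    """Least-squares 4PL fit on log dose with deterministic multi-start.

    Raises :class:`FitError` when no start converges or when the response
    increases with dose (an inhibition curve cannot describe it).
    """
    d = series.dose
    v = series.viability
    if len(np.unique(d)) < 4:
        raise FitError("need at least 4 distinct dose levels for a 4PL fit")
    # mean response per dose, for the monotonicity sanity check
    order = np.argsort(d)
    rho = stats.spearmanr(d, v).statistic
    if rho > 0.5:
        raise FitError(
            "viability increases with dose; not an inhibition curve "
            "(fit with a negative-hill model instead)"
        )
    logd = np.log(d)
    top0, bot0 = float(np.max(v)), float(np.min(v))
    if top0 - bot0 < 1e-12:
        raise FitError("flat response: IC50 undefined")

    starts = sorted(set(np.log(np.unique(d))) | {float(np.mean(logd))})
    best = None
    for l0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _4pl_logp,
                logd,
                v,
                p0=[l0, 1.0, top0, bot0],
                bounds=([logd.min() - 12, 0.05, bot0 - 50, bot0 - 50],
                        [logd.max() + 12, 10.0, top0 + 50, top0 + 50]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((v - _4pl_logp(logd, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt, pcov)
    if best is None:
        raise FitError("4PL fit failed to converge from every start")
    ss, popt, pcov = best
    log_ic50, hill, top, bottom = (float(x) for x in popt)
    if bottom >= top:
        raise FitError("fitted bottom >= top; response is not a decreasing 4PL")
    ic50 = float(np.exp(log_ic50))
    se_log = float(np.sqrt(max(pcov[0, 0], 0.0)))
    return IC50Result(
        ic50=ic50,
        hill=hill,
        top=top,
        bottom=bottom,
        confidence_half_width=1.96 * ic50 * se_log,
        residual_ss=ss,
    )


@dataclass
class GroupComparison:
    labels: list
    means: np.ndarray
    sems: np.ndarray
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    alpha: float
    significant: dict = field(default_factory=dict)  # frozenset{a,b} -> bool
    trace: list = field(default_factory=list)  # (pair, stretch, q, crit, tested, sig)

    def stars(self, a, b) -> str:
        """Significance marker for a pair under the usual convention."""
        if not self.significant.get(frozenset((a, b)), False):
            return "ns"
        return "*"


@lru_cache(maxsize=512)
def _q_crit(alpha: float, stretch: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, stretch, df))


def anova_newman_keuls(groups, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA plus SNK stepdown pairwise comparisons.

    Parameters
    ----------
    groups : mapping label -> 1-D observations, or sequence of arrays.

    Notes
    -----
    The SNK procedure orders the group means and tests ranges from widest
    stretch downward against studentized-range critical values whose
    stretch parameter shrinks with the range.  A pair inside a
    non-significant range is declared non-significant without being tested
    (stepdown containment rule).  Unequal group sizes are handled with the
    harmonic mean of the two sizes compared.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(data))]
    k = len(data)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(g) for g in data])
    if np.any(ns < 2):
        raise ValueError("every group needs at least 2 observations")
    means = np.array([g.mean() for g in data])
    sems = np.array([g.std(ddof=1) / np.sqrt(len(g)) for g in data])
    df_within = int(ns.sum() - k)
    sse = float(sum(((g - g.mean()) ** 2).sum() for g in data))
    mse = sse / df_within
    if mse <= 0:
        raise DegenerateVarianceError("zero within-group variance in all groups")
    f_stat, p_val = stats.f_oneway(*data)

    order = np.argsort(means)  # ascending rank of group means
    rank_of = {int(g): r for r, g in enumerate(order)}
    significant: dict = {}
    trace: list = []
    # stepdown: widest stretch first; containment via blocked rank intervals
    blocked: list[tuple[int, int]] = []  # rank intervals declared homogeneous
    for stretch in range(k, 1, -1):
        for lo in range(0, k - stretch + 1):
            hi = lo + stretch - 1
            gi, gj = int(order[lo]), int(order[hi])
            pair = frozenset((labels[gi], labels[gj]))
            contained = any(lo >= b0 and hi <= b1 for b0, b1 in blocked)
            if contained:
                significant[pair] = False
                trace.append((tuple(sorted(pair)), stretch, np.nan, np.nan,
                              False, False))
                continue
            n_h = 2.0 / (1.0 / ns[gi] + 1.0 / ns[gj])
            q = abs(means[gj] - means[gi]) / np.sqrt(mse / n_h)
            crit = _q_crit(alpha, stretch, df_within)
            sig = bool(q >= crit)
            significant[pair] = sig
            trace.append((tuple(sorted(pair)), stretch, float(q), crit, True, sig))
            if not sig:
                blocked.append((lo, hi))
    return GroupComparison(
        labels=labels,
        means=means,
        sems=sems,
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=df_within,
        p_value=float(p_val),
        alpha=alpha,
        significant=significant,
        trace=trace,
    )
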