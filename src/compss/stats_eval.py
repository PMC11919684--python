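"""Statistics for calibrating and evaluating selection metrics.

AUC-ROC is computed through the rank-sum identity AUC = U / (n1 * n0): the
probability that a random active sequence outscores a random inactive one,
ties counting one half.  Fisher's exact test is two-tailed in the
probability-mass sense (sum over tables as or less probable than the one
observed), the convention mainstream statistical software uses.  The
percentile threshold implements "top p-th percentile" calibration: the
cutoff is the order statistic such that at most p% of the calibration
scores lie at or above it (lower-value interpolation, the stringent
reading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LabeledScores:
    """Paired (score, active) observations for one metric."""

    ids: tuple[str, ...]
    scores: tuple[float, ...]
    labels: tuple[int, ...]
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ids, scores and labels must have equal length")
        if any(np.isnan(self.scores)):
            raise ValueError("missing scores are not allowed")
        if set(self.labels) - {0, 1}:
            raise ValueError("labels must be 0/1")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = filter pass/fail, columns = active/inactive."""

    a: int  # pass & active
    b: int  # pass & inactive
    c: int  # fail & active
    d: int  # fail & inactive

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def auc_roc(labeled: LabeledScores) -> float:
    """AUC via the rank-sum identity; orientation applied first."""
    y = np.asarray(labeled.labels)
    s = np.asarray(labeled.scores, dtype=float)
    if not labeled.higher_is_better:
        s = -s
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(s)  # mid-ranks: ties contribute 1/2 per pair
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def spearman(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation; None for constant input."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if len(set(x)) == 1 or len(set(y)) == 1:
        return None
    rho = stats.spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p (probability-mass definition)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def enrichment(table: ContingencyTable2x2) -> dict[str, float]:
    """Active fractions of pass/fail rows and their ratio."""
    pass_rate = table.a / (table.a + table.b)
    fail_rate = table.c / (table.c + table.d)
    return {
        "pass_active_fraction": pass_rate,
        "fail_active_fraction": fail_rate,
        "ratio": pass_rate / fail_rate if fail_rate > 0 else math.inf,
        "percent_higher": 100.0 * (pass_rate / fail_rate - 1.0)
        if fail_rate > 0 else math.inf,
    }


def percentile_threshold(scores: Sequence[float], percentile: float,
                         direction: str = "top") -> float:
    """Cutoff so that the top ``percentile`` percent lie at or above it.

    Lower-value order-statistic convention: with n scores the cutoff is the
    ceil(n*p/100)-th largest, guaranteeing at most p% of the calibration
    scores pass.  direction="bottom" mirrors (at most p% at or below).
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    n = len(scores)
    k = math.ceil(n * percentile / 100.0)  # how many may pass
    ordered = sorted(scores, reverse=(direction == "top"))
    if direction not in {"top", "bottom"}:
        raise ValueError(f"unknown direction {direction!r}")
    return float(ordered[k - 1])


@dataclass(frozen=True)
class QuadrantReport:
    median_a: float
    median_b: float
    #: keyed "lower_left", "lower_right", "upper_left", "upper_right"
    counts: dict
    active_fraction: dict
    spearman_within: dict
    overall_spearman: float | None


def quadrant_analysis(scores_a: Sequence[float], scores_b: Sequence[float],
                      labels: Sequence[int]) -> QuadrantReport:
    """Median split of the (a, b) score plane with per-quadrant statistics.

    Points exactly on a median boundary go to the upper/right quadrant.
    Axis a is horizontal (left/right split), axis b vertical (lower/upper).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("inputs must have equal length")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    right = a >= med_a
    upper = b >= med_b
    quads = {
        "lower_left": ~right & ~upper, "lower_right": right & ~upper,
        "upper_left": ~right & upper, "upper_right": right & upper,
    }
    counts, rates, rhos = {}, {}, {}
    for name, mask in quads.items():
        n = int(mask.sum())
        counts[name] = n
        rates[name] = float(y[mask].mean()) if n else float("nan")
        rhos[name] = (spearman(a[mask].tolist(), b[mask].tolist())
                      if n >= 3 else None)
    return QuadrantReport(median_a=med_a, median_b=med_b, counts=counts,
                          active_fraction=rates, spearman_within=rhos,
                          overall_spearman=spearman(a.tolist(), b.tolist()))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test (statistic, p).

    Exact null distribution for small samples without ties; tie-corrected
    normal approximation with continuity correction otherwise.
    """
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def welch_t_test(x: Sequence[float], y: Sequence[float],
                 alternative: str = "two-sided") -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test (statistic, p)."""
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
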