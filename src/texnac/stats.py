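"""Group-comparison and mono-parametric discrimination statistics.

The dichotomy throughout is non-response (NR, the positive class) versus
any response (PR + CR).  The module provides:

* Wilcoxon rank-sum (two-sided, midranks, tie-corrected normal
  approximation with continuity correction);
* the D'Agostino–Pearson K² omnibus normality test;
* the mid-P variant of Fisher's exact test on 2×2 tables, which gives
  half weight to the observed table and is less conservative than the
  classical exact test — the two-sided p doubles the smaller one-sided
  mid-P (capped at 1);
* empirical ROC analysis with trapezoidal AUC (identical to the
  Mann-Whitney statistic U/(n₁n₂)), a Youden-index cut-off, and a
  normal-approximation test of AUC = 0.5;
* a DeLong-style paired comparison of two AUCs measured on the same
  patients.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "RocResult",
    "wilcoxon_ranksum",
    "dagostino_pearson",
    "fisher_midp",
    "roc",
    "compare_auc",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = feature present/absent, columns = NR / PR+CR."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table total must be positive")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class RocResult:
    auc: float
    p_vs_half: float
    cutoff: float
    se: float  # %, sensitivity at the Youden cut-off
    sp: float  # %, specificity at the Youden cut-off
    curve_points: np.ndarray  # (k, 2) of (1 - Sp, Se) fractions
    direction: str  # "high" → high scores indicate NR, "low" → low scores do
    flags: tuple[str, ...] = ()


def wilcoxon_ranksum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test (midranks, tie-corrected, continuity)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        ranks = sps.rankdata(pooled)
        return TestResult(float(ranks[: x.size].sum()), 1.0,
                          "wilcoxon_ranksum", ("all_values_identical",))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # rank-sum of x
    return TestResult(w, float(res.pvalue), "wilcoxon_ranksum")


def dagostino_pearson(x) -> TestResult:
    """D'Agostino-Pearson K² omnibus normality test (chi-square, 2 df)."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("D'Agostino-Pearson needs n >= 8")
    k2, p = sps.normaltest(x)
    return TestResult(float(k2), float(p), "dagostino_pearson")


def fisher_midp(t: ContingencyTable2x2) -> TestResult:
    """Two-sided mid-P Fisher exact test by hypergeometric enumeration.

    One-sided mid-P in each tail = P(more extreme) + ½·P(observed); the
    two-sided p doubles the smaller tail, capped at 1.  A zero margin
    makes every table equally (un)informative: p = 1 with a flag.
    """
    a = int(t.a)
    row1, row2 = t.a + t.b, t.c + t.d
    col1 = t.a + t.c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return TestResult(float(a), 1.0, "fisher_midp", ("zero_margin",))
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = float(pmf[support == a][0])
    p_lower = float(pmf[support < a].sum()) + 0.5 * p_obs
    p_upper = float(pmf[support > a].sum()) + 0.5 * p_obs
    p = min(1.0, 2.0 * min(p_lower, p_upper))
    return TestResult(float(a), p, "fisher_midp")


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (ties count 1/2)."""
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def roc(scores, labels, direction: str = "auto") -> RocResult:
    """Empirical ROC of a score for detecting the positive class.

    ``labels`` are booleans (True = NR).  With ``direction="auto"`` the
    orientation is chosen so the AUC is >= 0.5 and recorded in the
    result.  The cut-off maximizes the Youden index J = Se + Sp − 1; on
    ties the cut-off with the higher sensitivity wins.  The returned
    convention is "predict NR when score >= cutoff" for direction
    "high" and "<= cutoff" for direction "low".  ``p_vs_half`` is the
    two-sided Mann-Whitney test of AUC = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1D of equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    flags: list[str] = []
    if direction == "auto":
        direction = "high" if _auc_mann_whitney(pos, neg) >= 0.5 else "low"
        flags.append(f"auto_direction:{direction}")
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'auto', 'high' or 'low'")
    oriented = s if direction == "high" else -s

    auc = _auc_mann_whitney(oriented[y], oriented[~y])
    res = sps.mannwhitneyu(oriented[y], oriented[~y], alternative="two-sided",
                           method="asymptotic", use_continuity=True)

    # empirical curve: predict positive when oriented score >= threshold
    thresholds = np.unique(oriented)[::-1]
    se = np.array([(oriented[y] >= thr).mean() for thr in thresholds])
    sp = np.array([(oriented[~y] < thr).mean() for thr in thresholds])
    j = se + sp - 1.0
    best = np.flatnonzero(j == j.max())
    best = best[np.argmax(se[best])]  # ties → higher sensitivity
    cutoff = thresholds[best] if direction == "high" else -thresholds[best]

    curve = np.column_stack([np.concatenate([[0.0], 1 - sp, [1.0]]),
                             np.concatenate([[0.0], se, [1.0]])])
    return RocResult(
        auc=auc,
        p_vs_half=float(res.pvalue),
        cutoff=float(cutoff),
        se=float(se[best] * 100),
        sp=float(sp[best] * 100),
        curve_points=curve,
        direction=direction,
        flags=tuple(flags),
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def compare_auc(scores_a, scores_b, labels) -> TestResult:
    """Paired DeLong-style test of AUC(a) = AUC(b) on the same patients."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValueError("score vectors and labels must share one shape (paired design)")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    v10a, v01a = _placements(sa[y], sa[~y])
    v10b, v01b = _placements(sb[y], sb[~y])
    auc_a, auc_b = v10a.mean(), v10b.mean()
    d10 = v10a - v10b
    d01 = (1 - v01a) - (1 - v01b)
    n1, n0 = v10a.size, v01a.size
    var = 0.0
    if n1 > 1:
        var += d10.var(ddof=1) / n1
    if n0 > 1:
        var += d01.var(ddof=1) / n0
    diff = float(auc_a - auc_b)
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
        return TestResult(diff, p, "delong_paired", ("zero_variance",))
    z = diff / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(diff, min(p, 1.0), "delong_paired")
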