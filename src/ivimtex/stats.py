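"""ROI summary statistics and group comparisons.

Covers the statistical toolkit used to compare parametric maps across
lesion classes: coefficient of variation of an ROI, Kruskal–Wallis with a
Tukey–Kramer post-hoc on mean ranks, the Wilcoxon signed-rank test for
paired model comparisons, and ROC analysis with a Youden-index cutoff and
bootstrap confidence interval for the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = [
    "RoiSummary",
    "RocResult",
    "roi_cv",
    "roi_summary",
    "kruskal_wallis",
    "tukey_kramer_ranks",
    "wilcoxon_signed_rank",
    "roc_analysis",
]


@dataclass(frozen=True)
class RoiSummary:
    mean: float
    sd: float
    cv_percent: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float  # percent, at cutoff
    specificity: float
    accuracy: float
    f1: float


def roi_cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD × 100 / mean (percent).

    Undefined (nan) when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >=2 values")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(np.std(v, ddof=1) * 100.0 / m)


def roi_summary(values: Sequence[float]) -> RoiSummary:
    v = np.asarray(values, dtype=float)
    return RoiSummary(float(v.mean()), float(np.std(v, ddof=1)), roi_cv(v))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) with chi-square p on g−1 df."""
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need >=3 values in total")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrs)
    return float(h), float(p)


def tukey_kramer_ranks(
    groups: Sequence[Sequence[float]],
) -> dict[tuple[int, int], float]:
    """Tukey–Kramer multiple comparison of mean ranks (unequal n).

    Pools all observations, ranks them (average ranks on ties), and
    compares group mean ranks with studentized-range critical values —
    the standard nonparametric post-hoc after a Kruskal–Wallis test.
    Returns family-wise adjusted p-values keyed by group-index pairs.
    """
    if len(groups) < 3:
        raise ValueError("need >=3 groups (use kruskal_wallis for 2)")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    sizes = [a.size for a in arrs]
    splits = np.cumsum(sizes)[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]

    # tie-corrected variance of ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n_total ** 3 - n_total)
    s2 = n_total * (n_total + 1) / 12.0 * tie

    k = len(groups)
    out: dict[tuple[int, int], float] = {}
    for a, b in combinations(range(k), 2):
        se = np.sqrt(s2 * 0.5 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            out[(a, b)] = 1.0
            continue
        q = abs(mean_ranks[a] - mean_ranks[b]) / se
        out[(a, b)] = float(scipy.stats.studentized_range.sf(q, k, np.inf))
    return out


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the exact null distribution is used up
    to n = 25 and a tie/continuity-corrected normal approximation above.
    All-zero differences are degenerate (returns (nan, nan)).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return float("nan"), float("nan")
    if d.size < 5:
        raise ValueError("need >=5 nonzero differences")
    method = "exact" if d.size <= 25 else "approx"
    stat, p = scipy.stats.wilcoxon(d, method=method, correction=(method == "approx"))
    return float(stat), float(p)


def _metrics_at_cutoff(scores, labels, cutoff):
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return sens, spec, acc, f1


def _auc_mannwhitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney statistic (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = scipy.stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    *,
    n_boot: int = 2000,
    ci: float = 0.95,
    seed: int | None = None,
) -> RocResult:
    """ROC analysis with a Youden-optimal cutoff.

    AUC is the Mann–Whitney U statistic scaled to [0, 1] (tied scores
    count one half). The cutoff maximizes sensitivity + specificity − 1;
    ties are resolved toward higher specificity. The AUC confidence
    interval is a stratified percentile bootstrap.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    auc = _auc_mannwhitney(s, y)

    # candidate cutoffs: each observed score (prediction rule: score >= c)
    best = None
    for c in np.unique(s):
        sens, spec, acc, f1 = _metrics_at_cutoff(s, y, c)
        youden = sens + spec - 1.0
        key = (youden, spec)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, acc, f1)
    _, cutoff, sens, spec, acc, f1 = best

    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(y == 1)[0]
    neg_idx = np.nonzero(y == 0)[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bi = np.concatenate([
            rng.choice(pos_idx, pos_idx.size, replace=True),
            rng.choice(neg_idx, neg_idx.size, replace=True),
        ])
        boots[i] = _auc_mannwhitney(s[bi], y[bi])
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    lo, hi = min(lo, auc), max(hi, auc)

    return RocResult(auc, float(lo), float(hi), float(cutoff),
                     sens * 100, spec * 100, acc * 100, f1 * 100)
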