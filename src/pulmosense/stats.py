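"""Normality-gated paired comparison of admission vs discharge markers.

Both groups are first tested for normality with the Shapiro–Wilk test; if
both pass (p > alpha) a two-tailed paired t-test is used, otherwise the
two-tailed Wilcoxon signed-rank test. For n <= 25 pairs the signed-rank
null distribution is computed exactly (dynamic programming over the 2^n
sign assignments, zero differences dropped per Wilcoxon's rule, tied
absolute differences mid-ranked); larger samples fall back to the normal
approximation. p < alpha (default 0.05) is flagged significant.

The normality gate is applied to the two groups rather than to the paired
differences — a deliberate, documented convention of this pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst


@dataclass
class PairedTestResult:
    test_name: str              # "paired-t" | "wilcoxon-signed-rank"
    n_pairs: int
    statistic: float
    p_value: float
    normality_p: tuple          # Shapiro-Wilk p per group
    significant: bool
    alpha: float = 0.05
    warning: str = ""

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("need at least one pair")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")


def signed_rank_exact(diffs: np.ndarray) -> tuple:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; ties among |d| receive mid-ranks. Returns
    ``(W, p)`` with W = min(W+, W-) and p from the exact sign-flip null
    (every difference independently signed with probability 1/2), computed
    by convolution over doubled ranks so mid-ranks stay integral.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = sst.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    ranks2 = np.round(2 * ranks).astype(int)      # mid-ranks -> integers
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    counts /= 2.0 ** n
    w2 = int(round(2 * w))
    p_low = counts[:w2 + 1].sum()
    p_high = counts[w2:].sum()
    p = min(1.0, 2.0 * min(p_low, p_high))
    return w, float(p)


def compare_paired(values_a, values_b, alpha: float = 0.05) -> PairedTestResult:
    """Compare two paired groups with the normality-gated test scheme.

    Raises ``ValueError("insufficient pairs")`` for fewer than three pairs.
    Identical groups (all differences zero) yield p = 1 with a warning
    rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired groups must have equal length")
    if len(a) < 3:
        raise ValueError("insufficient pairs")
    n = len(a)
    diffs = b - a

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0                 # degenerate: certainly not normal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(sst.shapiro(x).pvalue)

    p_norm = (_shapiro_p(a), _shapiro_p(b))
    use_t = p_norm[0] > alpha and p_norm[1] > alpha

    if np.all(diffs == 0):
        return PairedTestResult(
            test_name="paired-t" if use_t else "wilcoxon-signed-rank",
            n_pairs=n, statistic=0.0, p_value=1.0, normality_p=p_norm,
            significant=False, alpha=alpha,
            warning="all paired differences are zero")

    if use_t:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # constant differences -> t = inf
            res = sst.ttest_rel(b, a)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "paired-t"
    else:
        name = "wilcoxon-signed-rank"
        if n <= 25:
            stat, p = signed_rank_exact(diffs)
        else:
            res = sst.wilcoxon(b, a, zero_method="wilcox", method="approx")
            stat, p = float(res.statistic), float(res.pvalue)
    return PairedTestResult(test_name=name, n_pairs=n, statistic=stat,
                            p_value=p, normality_p=p_norm,
                            significant=bool(p < alpha), alpha=alpha)


def summarize_feature(values) -> tuple:
    """``(mean, sd, n)`` with sample sd (n−1 denominator).

    A single value has undefined spread; it is reported as sd = 0.0 (the
    accompanying n = 1 flags the degeneracy).
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return mean, sd, len(x)
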