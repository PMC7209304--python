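"""Paired window comparisons and ST–EEG correlation statistics.

The workhorse is an exact two-sided Wilcoxon signed-rank test suitable for
very small paired samples (n <= 25): zero differences are discarded
(Wilcoxon's classical rule), tied magnitudes receive mid-ranks, and the null
distribution of the positive-rank sum W is obtained by exact enumeration of
all 2^n sign assignments (realised as a convolution over rank values, which
is the same distribution at polynomial cost).  At n = 6 the smallest
attainable two-sided p is 2/2^6 = 0.03125, so significance at alpha = 0.05
requires all six animals to move in the same direction.

Correlations between per-animal ST elevation and relative band-power change
(X - B)/B use the standard Pearson product-moment coefficient with a
t-distributed two-sided p (n - 2 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as st

from .spectral_analysis import AnimalSummary

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "CohortResult",
    "relative_change",
    "wilcoxon_signed_rank_exact",
    "pearson_corr",
    "summarize_cohort",
]


@dataclass
class PairedTestResult:
    band: str
    window_pair: tuple[str, str]
    n_pairs: int
    w: float | None
    p_two_sided: float
    direction: int  # sign of the median paired difference
    measure: str = "median_band_power"

    def __post_init__(self) -> None:
        if not 0 < self.p_two_sided <= 1:
            raise ValueError(f"p must lie in (0, 1], got {self.p_two_sided}")


@dataclass
class CorrelationResult:
    band: str
    window: str  # H1, D1 or D2 — the X in (X - B)/B
    r: float
    p_two_sided: float
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.r) and not -1 - 1e-12 <= self.r <= 1 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")


@dataclass
class CohortResult:
    group: str
    paired_tests: list[PairedTestResult] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    alpha: float = 0.05

    def significant(self) -> list[PairedTestResult]:
        return [t for t in self.paired_tests if t.p_two_sided <= self.alpha]

    def find_test(self, band: str, pair: tuple[str, str], measure: str = "median_band_power"):
        for t in self.paired_tests:
            if t.band == band and t.window_pair == pair and t.measure == measure:
                return t
        return None

    def find_correlation(self, band: str, window: str):
        for c in self.correlations:
            if c.band == band and c.window == window:
                return c
        return None


def relative_change(x: float, b: float) -> float | None:
    """Fractional change (x - b) / b versus baseline; undefined when b <= 0."""
    if b is None or x is None or not b > 0:
        return None
    return (x - b) / b


def _exact_w_distribution(doubled_ranks: Sequence[int]) -> np.ndarray:
    """PMF (unnormalised counts) of the positive-rank sum over 2^n sign flips.

    Ranks are passed doubled so mid-ranks are integers; index k of the result
    counts sign assignments with doubled W = k.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def wilcoxon_signed_rank_exact(pairs: Iterable[tuple[float, float]]) -> PairedTestResult:
    """Exact two-sided Wilcoxon signed-rank test on (before, after) pairs.

    Differences ``after - before`` equal to zero are dropped; at least two
    nonzero differences are required.  W is the sum of ranks (mid-ranks for
    ties) of the positive differences; the two-sided p sums, over the exact
    sign-flip distribution, the probability of outcomes at least as far from
    the null centre sum/2 as the observed W.  If every difference is zero
    the test is degenerate: p = 1 and W is reported as None.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (before, after) tuples")
    d = arr[:, 1] - arr[:, 0]
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    nz = d[d != 0]
    n_all = arr.shape[0]
    if nz.size == 0:
        return PairedTestResult("", ("", ""), n_all, None, 1.0, 0)
    if nz.size < 2:
        # a single informative pair carries no exact two-sided evidence below 1
        return PairedTestResult("", ("", ""), n_all, float(nz.size if nz[0] > 0 else 0), 1.0, int(np.sign(nz[0])))
    if nz.size > 25:
        raise ValueError(f"exact enumeration limited to n <= 25 nonzero differences, got {nz.size}")

    ranks = st.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    doubled = np.round(2 * ranks).astype(int)
    counts = _exact_w_distribution(doubled)
    total = counts.sum()
    s = counts.size - 1  # doubled total rank sum
    w2 = int(round(2 * w_plus))
    # distribution symmetric about s/2: two-sided p = P(|W2 - s/2| >= |w2 - s/2|)
    dev = abs(w2 - s / 2.0)
    support = np.arange(counts.size)
    p = float(counts[np.abs(support - s / 2.0) >= dev - 1e-9].sum() / total)
    p = min(1.0, p)
    direction = int(np.sign(np.median(nz)))
    return PairedTestResult("", ("", ""), n_all, w_plus, p, direction)


def pearson_corr(xs: Sequence[float], ys: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Requires n >= 3 and nonzero variance in both variables (otherwise the
    correlation is undefined and ``ValueError`` is raised).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = st.pearsonr(x, y)
    return CorrelationResult("", "", float(res.statistic), float(res.pvalue), int(x.size))


_PAIRS = (("B", "H1"), ("B", "D1"), ("B", "D2"))
_CHANGE_WINDOWS = ("H1", "D1", "D2")


def summarize_cohort(
    summaries: Sequence[AnimalSummary],
    bands: Sequence[str] = ("delta", "theta", "alpha", "beta"),
    alpha: float = 0.05,
    st_windows: Sequence[str] = ("H1", "D1"),
) -> CohortResult:
    """All pairwise window tests and ST–power correlations for one group.

    For every band plus "total": exact Wilcoxon tests of baseline versus H1,
    D1 and D2 on median band power; the same window pairs on median peak
    frequency (bands only); and for each X in {H1, D1, D2} the Pearson
    correlation between (X - B)/B and the animal's peak ST elevation over
    ``st_windows`` (the day-1 windows by default).  Animals with absent
    values are dropped pairwise and the effective n recorded.  Correlations
    with undefined variance (e.g. a control group with zero ST elevation
    everywhere) are skipped.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least 2 animals")
    group = summaries[0].group
    result = CohortResult(group=group, alpha=alpha)

    def band_value(s: AnimalSummary, window: str, band: str):
        if band == "total":
            return s.total_median_power.get(window)
        return s.median_band_power.get(window, {}).get(band)

    for band in list(bands) + ["total"]:
        for b_name, x_name in _PAIRS:
            pairs = []
            for s in summaries:
                b_val = band_value(s, b_name, band)
                x_val = band_value(s, x_name, band)
                if b_val is not None and x_val is not None:
                    pairs.append((b_val, x_val))
            if len(pairs) >= 2:
                t = wilcoxon_signed_rank_exact(pairs)
                t.band, t.window_pair, t.measure = band, (b_name, x_name), "median_band_power"
                result.paired_tests.append(t)

    for band in bands:
        for b_name, x_name in _PAIRS:
            pairs = []
            for s in summaries:
                b_val = s.median_peak_freq_hz.get(b_name, {}).get(band)
                x_val = s.median_peak_freq_hz.get(x_name, {}).get(band)
                if b_val is not None and x_val is not None:
                    pairs.append((b_val, x_val))
            if len(pairs) >= 2:
                t = wilcoxon_signed_rank_exact(pairs)
                t.band, t.window_pair, t.measure = band, (b_name, x_name), "median_peak_frequency"
                result.paired_tests.append(t)

    def peak_st(s: AnimalSummary):
        vals = [s.peak_st_mv.get(w) for w in st_windows]
        vals = [v for v in vals if v is not None]
        return max(vals) if vals else None

    for band in list(bands) + ["total"]:
        for x_name in _CHANGE_WINDOWS:
            xs, ys = [], []
            for s in summaries:
                st_val = peak_st(s)
                change = relative_change(band_value(s, x_name, band), band_value(s, "B", band))
                if st_val is not None and change is not None:
                    xs.append(st_val)
                    ys.append(change)
            if len(xs) >= 3 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
                c = pearson_corr(xs, ys)
                c.band, c.window = band, x_name
                result.correlations.append(c)
    return result
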