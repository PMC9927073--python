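"""Nonparametric group comparisons.

Three metrics compare the empirical distributions of waveform-derived
parameters between contexts (brainstem regions I..VII, diagnosis groups,
sexes, dB levels):

* the 1-Wasserstein / Earth Mover's Distance (EMD) between empirical
  distributions — in one dimension, the area between the two CDFs;
* a bootstrap two-sample Kolmogorov-Smirnov protocol for unequal group
  sizes: the number of measurements of the smaller set is drawn from the
  larger set 100 times (subsampling without replacement by default) and the
  median KS p-value is reported;
* the two-sided Wilcoxon rank-sum (Mann-Whitney) test.

Pairwise results are arranged in strict lower-triangular comparison
matrices; p-value cells are star-coded ``**`` for p < 0.01 and ``*`` for
p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_N_BOOT = 100
STAR_LEVELS = (0.05, 0.01)


@dataclass(frozen=True)
class Histogram:
    """Normalized frequency histogram over fixed bin edges."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if len(counts) != len(edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("histogram must contain mass")

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized to sum to 1."""
        return self.counts / self.counts.sum()

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def make_histogram(samples, bins="fd") -> Histogram:
    """Histogram with Freedman-Diaconis bins by default."""
    counts, edges = np.histogram(np.asarray(samples, dtype=float), bins=bins)
    return Histogram(bin_edges=edges, counts=counts)


def shared_histograms(x, y, bins="fd"):
    """Two histograms on one bin grid chosen from the pooled samples."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    edges = np.histogram_bin_edges(pooled, bins=bins)
    return (
        Histogram(edges, np.histogram(x, bins=edges)[0]),
        Histogram(edges, np.histogram(y, bins=edges)[0]),
    )


def emd(x, y) -> float:
    """Earth Mover's (1-Wasserstein) distance between empirical distributions.

    Accepts raw samples (binless, the default analysis path) or
    :class:`Histogram` objects (bin centers weighted by frequencies).
    """
    if isinstance(x, Histogram) and isinstance(y, Histogram):
        return float(
            stats.wasserstein_distance(
                x.centers, y.centers, x.frequencies, y.frequencies
            )
        )
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("EMD requires nonempty inputs")
    return float(stats.wasserstein_distance(x, y))


def normalized_emd(values) -> np.ndarray:
    """Divide a matrix of EMD values by its maximum entry (all-zero or
    all-NaN matrices are returned unchanged)."""
    v = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vmax = np.nanmax(v) if np.any(np.isfinite(v)) else 0.0
    if not np.isfinite(vmax) or vmax == 0.0:
        return v.copy()
    return v / vmax


def bootstrap_ks(a, b, n_boot: int = DEFAULT_N_BOOT, seed=None,
                 with_replacement: bool = False):
    """Bootstrap two-sample KS for unequal sample sizes.

    The number of measurements of the smaller set is drawn from the larger
    set ``n_boot`` times (without replacement by default) and a two-sided
    two-sample KS test against the smaller set is run each time.  Returns
    ``(median_p, p_values)``.  Samples are canonically sorted before seeded
    drawing, so the result does not depend on input element order.  Equal
    sizes fall back to one plain KS test (with a warning when n_boot > 1
    was requested).
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("bootstrap_ks requires nonempty inputs")
    if a.size == b.size:
        if n_boot > 1:
            warnings.warn("equal sample sizes: plain KS test, n_boot ignored")
        p = float(stats.ks_2samp(a, b).pvalue)
        return p, np.array([p])
    larger, smaller = (a, b) if a.size > b.size else (b, a)
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_boot)
    for i in range(n_boot):
        draw = rng.choice(larger, size=smaller.size, replace=with_replacement)
        pvals[i] = stats.ks_2samp(draw, smaller).pvalue
    return float(np.median(pvals)), pvals


def ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for small untied samples, continuity-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("ranksum requires nonempty inputs")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _stars(p: float, levels=STAR_LEVELS) -> str:
    if p < levels[1]:
        return "**"
    if p < levels[0]:
        return "*"
    return ""


@dataclass(frozen=True)
class ComparisonMatrix:
    """Strict lower-triangular pairwise comparison matrix.

    ``values[i, j]`` is defined for i > j only (NaN elsewhere); ``stars``
    carries the significance coding for p-value metrics ('' for EMD).
    """

    labels: tuple
    values: np.ndarray
    stars: np.ndarray
    metric: str

    def cell(self, row_label, col_label) -> float:
        i = self.labels.index(row_label)
        j = self.labels.index(col_label)
        if i <= j:
            raise KeyError("strict lower triangle: need row after column")
        return float(self.values[i, j])


def comparison_matrix(
    groups: dict,
    metric: str = "emd_normalized",
    seed=None,
    n_boot: int = DEFAULT_N_BOOT,
    star_levels=STAR_LEVELS,
) -> ComparisonMatrix:
    """Pairwise comparison of labelled sample sets.

    metric : {"emd_normalized", "ks_median_p", "ranksum_p"}
    """
    if metric not in ("emd_normalized", "ks_median_p", "ranksum_p"):
        raise ValueError(f"unknown metric {metric!r}")
    labels = tuple(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 samples")
    k = len(labels)
    values = np.full((k, k), np.nan)
    stars = np.full((k, k), "", dtype=object)
    rng = np.random.default_rng(seed)
    for i in range(1, k):
        for j in range(i):
            x, y = arrays[labels[i]], arrays[labels[j]]
            if metric == "emd_normalized":
                values[i, j] = emd(x, y)
            elif metric == "ks_median_p":
                sub_seed = int(rng.integers(2**31))
                values[i, j], _ = bootstrap_ks(x, y, n_boot=n_boot, seed=sub_seed)
                stars[i, j] = _stars(values[i, j], star_levels)
            else:
                values[i, j] = ranksum(x, y)
                stars[i, j] = _stars(values[i, j], star_levels)
    if metric == "emd_normalized":
        values = normalized_emd(values)
    return ComparisonMatrix(labels=labels, values=values, stars=stars, metric=metric)


__all__ = [
    "Histogram",
    "ComparisonMatrix",
    "make_histogram",
    "shared_histograms",
    "emd",
    "normalized_emd",
    "bootstrap_ks",
    "ranksum",
    "comparison_matrix",
    "DEFAULT_N_BOOT",
    "STAR_LEVELS",
]
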