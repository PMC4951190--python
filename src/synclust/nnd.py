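"""Nearest-neighbor-distance analysis with a segment-wise reshuffling null.

The classical check for input clustering: pool, over all segments, the
distance of every positive spine to its nearest positive neighbor on
the same segment, and compare the pooled median against a Monte-Carlo
null in which the recorded number of inputs is reassigned uniformly at
random over the recorded spine positions, independently within each
segment.  A z-test on the median against the null mean/SD gives the
significance; the per-bin difference curve localizes where the data
deviate (clustered maps pile up mass at short distances).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spinemap import SpineDataset

logger = logging.getLogger(__name__)

DEFAULT_BIN_UM = 1.0
DEFAULT_MAX_UM = 50.0


def _bin_edges(bin_um: float = DEFAULT_BIN_UM, max_um: float = DEFAULT_MAX_UM) -> np.ndarray:
    """Right-open 1 µm bins over [0, 50) µm by default."""
    return np.arange(0.0, max_um + bin_um, bin_um)


@dataclass
class NNDResult:
    """Pooled nearest-neighbor distances of positive spines."""

    distances: np.ndarray
    median: float
    histogram: np.ndarray
    bin_edges: np.ndarray

    @property
    def fractions(self) -> np.ndarray:
        total = self.histogram.sum()
        if total == 0:
            return np.zeros_like(self.histogram, dtype=float)
        return self.histogram / total


@dataclass
class NullDistribution:
    """Reshuffling null of the pooled NND median and histogram."""

    n_iter: int
    medians: np.ndarray
    mean_median: float
    sd_median: float
    mean_histogram: np.ndarray  # per-iteration fractions, averaged
    bin_edges: np.ndarray


@dataclass
class MedianZTest:
    """z-test of an observed median against the reshuffling null."""

    z: float
    p: float
    percentile: float  # empirical percentile of the observed median in the null


def _nnd_of_sorted(p: np.ndarray) -> np.ndarray:
    """Per-point nearest-neighbor distance of sorted 1D positions (len >= 2)."""
    gaps = np.diff(p)
    left = np.concatenate(([np.inf], gaps))
    right = np.concatenate((gaps, [np.inf]))
    return np.minimum(left, right)


def nearest_neighbor_distances(
    ds: SpineDataset, bin_um: float = DEFAULT_BIN_UM, max_um: float = DEFAULT_MAX_UM
) -> NNDResult:
    """Distance of each positive spine to its nearest positive neighbor.

    Distances never cross segment boundaries; segments with fewer than
    two positives contribute none.  An empty result (with a warning) is
    returned when no segment has two or more positives.
    """
    edges = _bin_edges(bin_um, max_um)
    pooled = []
    for seg in ds.sorted_segments():
        p = np.sort(seg.positive_positions)
        if p.size >= 2:
            pooled.append(_nnd_of_sorted(p))
    if not pooled:
        warnings.warn("no segment has two or more positive spines; empty NND result")
        return NNDResult(np.array([]), float("nan"), np.zeros(len(edges) - 1, dtype=int), edges)
    d = np.concatenate(pooled)
    hist, _ = np.histogram(d, bins=edges)
    return NNDResult(d, float(np.median(d)), hist, edges)


def reshuffle_null(
    ds: SpineDataset,
    n_iter: int = 1000,
    seed: int = 0,
    bin_um: float = DEFAULT_BIN_UM,
    max_um: float = DEFAULT_MAX_UM,
) -> NullDistribution:
    """Monte-Carlo null: reassign each segment's input count over its spines.

    Every iteration draws, independently per segment, a uniformly
    random subset of spine positions of the same size as the segment's
    recorded positive count, then pools the NND distances across
    segments exactly as for the data.  Randomness derives from one
    master seed through per-segment substreams (segments processed in
    sorted key order), so results are reproducible and independent of
    input ordering.
    """
    edges = _bin_edges(bin_um, max_um)
    nbins = len(edges) - 1
    master = np.random.SeedSequence(seed)
    per_iter: list[list[np.ndarray]] = [[] for _ in range(n_iter)]
    segments = ds.sorted_segments()
    children = master.spawn(len(segments))
    for seg, child in zip(segments, children):
        k = seg.n_positive
        if k < 2:
            continue  # a relocated single mark still yields no distance
        rng = np.random.default_rng(child)
        N = seg.n_spines
        # k smallest of N uniform ranks = uniform k-subset, per iteration
        ranks = rng.random((n_iter, N)).argpartition(k - 1, axis=1)[:, :k]
        sel = np.sort(np.take(seg.positions, ranks), axis=1)
        gaps = np.diff(sel, axis=1)
        left = np.concatenate((np.full((n_iter, 1), np.inf), gaps), axis=1)
        right = np.concatenate((gaps, np.full((n_iter, 1), np.inf)), axis=1)
        nnd = np.minimum(left, right)
        assert nnd.shape[1] == k  # reshuffle preserves the positive count
        for it in range(n_iter):
            per_iter[it].append(nnd[it])
    medians = np.empty(n_iter)
    hist_sum = np.zeros(nbins)
    for it in range(n_iter):
        if per_iter[it]:
            d = np.concatenate(per_iter[it])
            medians[it] = np.median(d)
            h, _ = np.histogram(d, bins=edges)
            total = h.sum()
            if total:
                hist_sum += h / total
        else:
            medians[it] = np.nan
    sd = float(np.std(medians, ddof=1)) if n_iter > 1 else 0.0
    return NullDistribution(
        n_iter=n_iter,
        medians=medians,
        mean_median=float(np.mean(medians)),
        sd_median=sd,
        mean_histogram=hist_sum / n_iter,
        bin_edges=edges,
    )


def median_z_test(observed: float, null: NullDistribution) -> MedianZTest:
    """Two-sided z-test of the observed median against the null median.

    ``z = (observed - mean) / sd`` with a normal two-sided p; the
    empirical percentile of the observed value among the null medians
    is reported alongside.  A zero null SD yields NaN (undefined test).
    """
    pct = float(np.mean(null.medians <= observed) * 100.0)
    if not np.isfinite(null.sd_median) or null.sd_median == 0:
        warnings.warn("null SD of the median is zero; z-test undefined")
        return MedianZTest(float("nan"), float("nan"), pct)
    z = (observed - null.mean_median) / null.sd_median
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MedianZTest(float(z), p, pct)


def histogram_difference(data: NNDResult, null: NullDistribution) -> np.ndarray:
    """Per-bin difference of normalized histograms (data − null mean)."""
    if data.bin_edges.shape != null.bin_edges.shape or not np.allclose(
        data.bin_edges, null.bin_edges
    ):
        raise ValueError("data and null histograms use different binning")
    return data.fractions - null.mean_histogram


@dataclass
class SomaDistanceNull:
    """Reshuffling null of positive-spine soma distances."""

    observed: np.ndarray
    bin_edges: np.ndarray
    observed_fractions: np.ndarray
    null_mean_fractions: np.ndarray
    all_spine_fractions: np.ndarray
    n_iter: int


def soma_distance_null(
    ds: SpineDataset, n_iter: int = 1000, seed: int = 0, bin_um: float = 10.0
) -> SomaDistanceNull:
    """Null distribution of positive-spine soma distances by reshuffling.

    Marks are reassigned per segment exactly as in :func:`reshuffle_null`
    and the soma distances of the relocated positives pooled.  Segments
    without soma-distance information are skipped with a warning.
    """
    segs = []
    for seg in ds.sorted_segments():
        soma = seg.effective_soma_distances()
        if soma is None:
            warnings.warn(f"segment {seg.key} has no soma distances; skipped")
            continue
        segs.append((seg, soma))
    if not segs:
        raise ValueError("no segment provides soma distances")
    all_d = np.concatenate([soma for _, soma in segs])
    obs = np.concatenate([soma[seg.marks] for seg, soma in segs])
    hi = float(np.ceil(all_d.max() / bin_um) * bin_um) if all_d.size else bin_um
    edges = np.arange(0.0, hi + bin_um, bin_um)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(segs))
    hist_sum = np.zeros(len(edges) - 1)
    pools: list[list[np.ndarray]] = [[] for _ in range(n_iter)]
    for (seg, soma), child in zip(segs, children):
        k = seg.n_positive
        if k == 0:
            continue
        rng = np.random.default_rng(child)
        ranks = rng.random((n_iter, seg.n_spines)).argpartition(k - 1, axis=1)[:, :k]
        vals = np.take(soma, ranks)
        for it in range(n_iter):
            pools[it].append(vals[it])
    for it in range(n_iter):
        if pools[it]:
            d = np.concatenate(pools[it])
            h, _ = np.histogram(d, bins=edges)
            if h.sum():
                hist_sum += h / h.sum()
    obs_h, _ = np.histogram(obs, bins=edges)
    all_h, _ = np.histogram(all_d, bins=edges)
    return SomaDistanceNull(
        observed=obs,
        bin_edges=edges,
        observed_fractions=obs_h / obs_h.sum() if obs_h.sum() else obs_h.astype(float),
        null_mean_fractions=hist_sum / n_iter,
        all_spine_fractions=all_h / all_h.sum() if all_h.sum() else all_h.astype(float),
        n_iter=n_iter,
    )
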