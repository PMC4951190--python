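"""Combinatorial cluster analysis of marked spine maps.

The analysis asks: given a dendritic segment with ``N`` spines of which
``n`` carry a specific input, how unlikely is the observed aggregation
of inputs under random assignment of the ``n`` marks to the ``N``
spines?  It proceeds in five steps:

1. *Ensemble detection* — maximal groups of positive spines in which
   consecutive positives are within the nearest-neighbor criterion
   ``Δ_crit`` (:func:`find_ensembles`).
2. *Specific ensemble likelihood (SEL)* — the exact combinatorial
   probability that an ensemble of a given type ``(l_M, m, l_g)``
   occurs anywhere on the segment
   (:func:`specific_ensemble_likelihood`).  For each anchor spine
   ``d_i`` the window ``[d_i, d_i + l_M]`` is censused; the number of
   qualifying assignments is ``C(M_i-2, m-2) · C(N-M_i-g_i-h_i, n-m)``
   (both window-edge spines carry an input, the flanking gaps of length
   ``l_g`` are input-free, and the remaining ``n-m`` inputs sit outside
   window and gaps), normalized by ``C(N, n)``.
3. *Cluster classification* — ensembles with at least ``min_inputs``
   inputs and SEL at or below the threshold (default 1%) that do not
   span the whole segment (:func:`classify_ensembles`).
4. *Overall cluster likelihood (OCL)* — for a classified cluster, the
   summed SEL over all ensemble types at least as unlikely
   (:func:`overall_cluster_likelihood`).
5. *Segment-count test* — binomial tail probability of observing at
   least ``c`` cluster-bearing segments among ``S`` analyzed segments
   given the per-segment bound ``OCL_max``
   (:func:`segment_cluster_test`).

All likelihoods are computed in exact integer arithmetic and returned
as :class:`fractions.Fraction`; the anchored sum of step 2 is an
inclusion count, so it upper-bounds (and for ``n = m`` equals) the
exact event probability, which :func:`brute_force_sel` enumerates
directly on small instances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats

from .spinemap import SpineSegment

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleType",
    "Ensemble",
    "ClusterCriteria",
    "ClusterCall",
    "SegmentClusterTest",
    "ComputationTooLargeError",
    "find_ensembles",
    "window_census",
    "arrangement_count",
    "placement_count",
    "specific_arrangement_likelihood",
    "specific_ensemble_likelihood",
    "classify_ensembles",
    "overall_cluster_likelihood",
    "segment_cluster_test",
    "segment_count_pvalue",
    "brute_force_sel",
]


class ComputationTooLargeError(RuntimeError):
    """Exhaustive enumeration was requested on an instance that is too big."""


@dataclass(frozen=True)
class EnsembleType:
    """Abstract ensemble descriptor: length ``l_M``, input count ``m``, gap ``l_g``.

    ``l_M`` is the window length in µm (or lattice units), ``m`` the
    number of positive spines inside it (``m ≥ 2``; the two window
    edges are always occupied), and ``l_g`` the flanking gap length,
    equal to the nearest-neighbor criterion ``Δ_crit``.
    """

    l_M: float
    m: int
    l_g: float

    def __post_init__(self) -> None:
        if self.l_M < 0:
            raise ValueError("l_M must be nonnegative")
        if self.m < 2:
            raise ValueError("an ensemble type needs m >= 2 inputs")
        if self.l_g <= 0:
            raise ValueError("gap length must be positive")


@dataclass(frozen=True)
class Ensemble:
    """A realized run of positive spines on a segment.

    ``first_index``/``last_index`` are the indices of the first and
    last positive member (both marks are True by construction); ``M``
    counts all spines within the realized span, ``m`` the positive
    ones, and ``g``/``h`` the spines in the leading/trailing gap
    intervals of length ``Δ_crit``.
    """

    segment: SpineSegment = field(repr=False)
    first_index: int
    last_index: int
    M: int
    m: int
    span_um: float
    g: int
    h: int

    @property
    def is_singleton(self) -> bool:
        return self.m == 1


@dataclass(frozen=True)
class ClusterCriteria:
    """Decision parameters of the five-step analysis (defaults as published)."""

    delta_crit: float = 10.0          # µm, nearest-neighbor criterion
    sel_threshold: float = 0.01       # SEL at or below this may be a cluster
    min_inputs: int = 3               # minimum positives for cluster candidacy
    min_segment_length: float = 20.0  # µm, eligibility for the segment test
    alpha_segments: float = 0.001     # significance level of the segment test
    gap_boundary: str = "open"        # 'open' or 'closed' gap census intervals

    def __post_init__(self) -> None:
        if not 0 < self.sel_threshold < 1:
            raise ValueError("sel_threshold must lie in (0, 1)")
        if self.min_inputs < 2:
            raise ValueError("min_inputs must be >= 2")
        if self.gap_boundary not in ("open", "closed"):
            raise ValueError("gap_boundary must be 'open' or 'closed'")


@dataclass
class ClusterCall:
    """An ensemble together with its likelihood scores and cluster flag."""

    ensemble: Ensemble
    sel: Fraction
    is_cluster: bool
    ocl: Fraction | None = None


@dataclass
class SegmentClusterTest:
    """Result of the binomial segment-count test.

    ``sorted_ocl`` holds, ascending, the best (smallest) OCL of each
    cluster-bearing eligible segment; ``p_values[c-1]`` is the tail
    probability of at least ``c`` cluster segments among ``S`` at bound
    ``OCL_max(c) = sorted_ocl[c-1]``; ``c_significant`` is the largest
    ``c`` with ``p < alpha``.
    """

    S: int
    sorted_ocl: list[float]
    p_values: list[float]
    c_significant: int
    alpha: float


# ---------------------------------------------------------------------------
# censuses and counting primitives
# ---------------------------------------------------------------------------

def _comb0(x: int, k: int) -> int:
    """Binomial coefficient that is zero outside the triangle."""
    if k < 0 or x < 0 or x < k:
        return 0
    return comb(x, k)


def window_census(
    seg: SpineSegment,
    anchor_index: int,
    l_M: float,
    l_g: float,
    gap_boundary: str = "open",
) -> tuple[int, int, int]:
    """Census ``(M_i, g_i, h_i)`` for the window anchored at spine ``anchor_index``.

    ``M_i`` counts spines in the closed window ``[d_i, d_i + l_M]``.
    With the default ``open`` convention the gap censuses count spines
    in the open intervals ``(d_i - l_g, d_i)`` and
    ``(d_i + l_M, d_i + l_M + l_g)``, so a spine is never attributed to
    both the window and a gap; ``closed`` additionally includes the far
    gap boundary.  Gaps truncated by the segment ends count only the
    spines that exist.
    """
    pos = seg.positions
    n = pos.size
    if not 0 <= anchor_index < n:
        raise IndexError(f"anchor index {anchor_index} out of range for {n} spines")
    d = pos[anchor_index]
    lo = int(np.searchsorted(pos, d, side="left"))
    hi = int(np.searchsorted(pos, d + l_M, side="right"))
    m_count = hi - lo
    t0 = d + l_M
    if gap_boundary == "open":
        g = lo - int(np.searchsorted(pos, d - l_g, side="right"))
        h = int(np.searchsorted(pos, t0 + l_g, side="left")) - hi
    elif gap_boundary == "closed":
        g = lo - int(np.searchsorted(pos, d - l_g, side="left"))
        h = int(np.searchsorted(pos, t0 + l_g, side="right")) - hi
    else:
        raise ValueError("gap_boundary must be 'open' or 'closed'")
    return m_count, g, h


def _all_window_censuses(
    pos: np.ndarray, l_M: float, l_g: float, gap_boundary: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ``(M_i, g_i, h_i)`` over every anchor of a position array."""
    lo = np.searchsorted(pos, pos, side="left")
    hi = np.searchsorted(pos, pos + l_M, side="right")
    if gap_boundary == "open":
        g = lo - np.searchsorted(pos, pos - l_g, side="right")
        h = np.searchsorted(pos, pos + l_M + l_g, side="left") - hi
    else:
        g = lo - np.searchsorted(pos, pos - l_g, side="left")
        h = np.searchsorted(pos, pos + l_M + l_g, side="right") - hi
    return hi - lo, g, h


def arrangement_count(M: int, m: int) -> int:
    """Ways to arrange ``m`` inputs on ``M`` window spines with both edges fixed.

    Returns ``C(M-2, m-2)`` (0 when ``m > M``): the first and last
    window spines must carry an input to delimit the ensemble, leaving
    ``m-2`` inputs for the ``M-2`` interior spines.
    """
    if M < 2 or m < 2:
        raise ValueError("arrangement_count requires M >= 2 and m >= 2")
    if m > M:
        return 0
    return comb(M - 2, m - 2)


def placement_count(N: int, M: int) -> int:
    """Placements of an ``M``-spine window on a uniform ``N``-spine lattice.

    ``N - M + 1``, counting end placements whose leading or trailing
    gap is truncated by the segment boundary; 0 when ``M > N``.
    """
    if M < 1 or N < 1:
        raise ValueError("placement_count requires N >= 1 and M >= 1")
    if M > N:
        return 0
    return N - M + 1


# ---------------------------------------------------------------------------
# ensemble detection (step 1)
# ---------------------------------------------------------------------------

def find_ensembles(
    seg: SpineSegment, delta_crit: float = 10.0, gap_boundary: str = "open"
) -> list[Ensemble]:
    """Maximal groups of positive spines with consecutive spacing ≤ ``delta_crit``.

    Singleton positives are returned as degenerate ensembles (``m = 1``,
    reported but excluded from cluster candidacy downstream).
    """
    pos = seg.positions
    pidx = np.flatnonzero(seg.marks)
    ensembles: list[Ensemble] = []
    if pidx.size == 0:
        return ensembles
    ppos = pos[pidx]
    breaks = np.flatnonzero(np.diff(ppos) > delta_crit)
    bounds = np.concatenate(([0], breaks + 1, [pidx.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        first, last = int(pidx[a]), int(pidx[b - 1])
        span = float(pos[last] - pos[first])
        lo = int(np.searchsorted(pos, pos[first], side="left"))
        hi = int(np.searchsorted(pos, pos[last], side="right"))
        _, g, h = window_census(seg, first, span, delta_crit, gap_boundary)
        ensembles.append(
            Ensemble(
                segment=seg,
                first_index=first,
                last_index=last,
                M=hi - lo,
                m=int(b - a),
                span_um=span,
                g=g,
                h=h,
            )
        )
    return ensembles


# ---------------------------------------------------------------------------
# specific ensemble likelihood (step 2)
# ---------------------------------------------------------------------------

def _arrangement_numerator(
    pos: np.ndarray, n: int, m: int, l_M: float, l_g: float, gap_boundary: str
) -> int:
    """Integer numerator of the anchored sum for exactly ``m`` window inputs."""
    N = pos.size
    M, g, h = _all_window_censuses(pos, l_M, l_g, gap_boundary)
    total = 0
    for Mi, gi, hi in zip(M.tolist(), g.tolist(), h.tolist()):
        if Mi < m:
            continue  # window cannot host the ensemble; term vanishes
        total += comb(Mi - 2, m - 2) * _comb0(N - Mi - gi - hi, n - m)
    return total


def _check_args(seg: SpineSegment, n: int, etype: EnsembleType) -> None:
    N = seg.n_spines
    if n > N:
        raise ValueError(f"n={n} inputs cannot exceed N={N} spines")
    if etype.m > n:
        raise ValueError(f"ensemble inputs m={etype.m} cannot exceed n={n}")


def specific_arrangement_likelihood(
    seg: SpineSegment, n: int, etype: EnsembleType, gap_boundary: str = "open"
) -> Fraction:
    """Exact-rational likelihood that exactly ``m`` of ``n`` inputs form the ensemble.

    Anchored sum over all spine positions of
    ``C(M_i - 2, m - 2) · C(N - M_i - g_i - h_i, n - m)`` divided by
    ``C(N, n)``; windows holding fewer than ``m`` spines contribute
    nothing.  The sum counts anchored realizations, so it is an upper
    bound on the probability of the union over anchors (exact when
    realizations at distinct anchors cannot co-occur, e.g. ``n = m``).
    """
    _check_args(seg, n, etype)
    num = _arrangement_numerator(seg.positions, n, etype.m, etype.l_M, etype.l_g, gap_boundary)
    return Fraction(num, comb(seg.n_spines, n))


def specific_ensemble_likelihood(
    seg: SpineSegment, n: int, etype: EnsembleType, gap_boundary: str = "open"
) -> Fraction:
    """SEL: summed arrangement likelihood over all input counts fitting the type.

    ``SEL = Σ_{i=m..min(n, M_max)} p(l_M, i, l_g)`` where ``M_max`` is
    the largest window census over anchors for this ``l_M``.  Returns 1
    for degenerate segments (fewer than 3 spines or fewer than 2
    inputs), which carry no ensemble structure.
    """
    N = seg.n_spines
    if N < 3 or n < 2:
        logger.debug("degenerate segment (N=%d, n=%d): SEL = 1 by convention", N, n)
        return Fraction(1)
    _check_args(seg, n, etype)
    pos = seg.positions
    M, _, _ = _all_window_censuses(pos, etype.l_M, etype.l_g, gap_boundary)
    upper = min(n, int(M.max()))
    total = 0
    for i in range(etype.m, upper + 1):
        total += _arrangement_numerator(pos, n, i, etype.l_M, etype.l_g, gap_boundary)
    return Fraction(total, comb(N, n))


# ---------------------------------------------------------------------------
# classification (step 3)
# ---------------------------------------------------------------------------

def _is_whole_segment(seg: SpineSegment, ens: Ensemble, n: int, l_g: float) -> bool:
    # an ensemble of all inputs covering (nearly) the whole segment is not a
    # cluster: seg_span >= l_M >= seg_span - 2*l_g and m == n
    return ens.m == n and seg.span >= ens.span_um >= seg.span - 2 * l_g


def classify_ensembles(
    seg: SpineSegment,
    ensembles: list[Ensemble] | None = None,
    criteria: ClusterCriteria = ClusterCriteria(),
    compute_ocl: bool = True,
) -> list[ClusterCall]:
    """Score every non-singleton ensemble and flag clusters.

    A cluster is an ensemble with ``SEL ≤ sel_threshold``, at least
    ``min_inputs`` inputs, and not encompassing the whole segment.
    When ``compute_ocl`` is set, the OCL (step 4) is evaluated for each
    cluster.
    """
    if ensembles is None:
        ensembles = find_ensembles(seg, criteria.delta_crit, criteria.gap_boundary)
    n = seg.n_positive
    calls: list[ClusterCall] = []
    for ens in ensembles:
        if ens.m < 2:
            continue
        etype = EnsembleType(ens.span_um, ens.m, criteria.delta_crit)
        sel = specific_ensemble_likelihood(seg, n, etype, criteria.gap_boundary)
        is_cluster = (
            sel <= criteria.sel_threshold
            and ens.m >= criteria.min_inputs
            and not _is_whole_segment(seg, ens, n, criteria.delta_crit)
        )
        ocl = None
        if is_cluster and compute_ocl:
            ocl = overall_cluster_likelihood(seg, n, etype, criteria)
        calls.append(ClusterCall(ensemble=ens, sel=sel, is_cluster=is_cluster, ocl=ocl))
    return calls


# ---------------------------------------------------------------------------
# overall cluster likelihood (step 4)
# ---------------------------------------------------------------------------

def _candidate_lengths(pos: np.ndarray, starred_l_M: float) -> np.ndarray:
    """Candidate window lengths: the distinct positive pairwise spine spans."""
    spans = (pos[None, :] - pos[:, None])[np.triu_indices(pos.size, k=1)]
    cands = np.unique(spans[spans > 0])
    if not np.any(np.isclose(cands, starred_l_M)):
        cands = np.sort(np.append(cands, starred_l_M))
    return cands


def _tight_type_likelihood(
    pos: np.ndarray, n: int, l_M: float, m: int, l_g: float, gap_boundary: str
) -> Fraction:
    """Anchored likelihood restricted to windows realizing length ``l_M`` tightly.

    Sums, over anchors whose window ``[d_i, d_i + l_M]`` ends exactly
    on a spine, the assignments with at least ``m`` positives inside
    (edges occupied, gaps clean).  Tight windows attribute every spine
    set to the single window length it realizes, which is what lets the
    overall cluster likelihood count each set once.
    """
    N = pos.size
    M, g, h = _all_window_censuses(pos, l_M, l_g, gap_boundary)
    hi = np.searchsorted(pos, pos + l_M, side="right")
    last = pos[np.clip(hi - 1, 0, N - 1)]
    tight = np.isclose(last, pos + l_M, rtol=0.0, atol=1e-9)
    num = 0
    upper = min(n, int(M.max()))
    for i in range(N):
        if not tight[i] or M[i] < m:
            continue
        for mp in range(m, min(upper, int(M[i])) + 1):
            num += comb(int(M[i]) - 2, mp - 2) * _comb0(int(N - M[i] - g[i] - h[i]), n - mp)
    return Fraction(num, comb(N, n))


def overall_cluster_likelihood(
    seg: SpineSegment,
    n: int,
    starred: EnsembleType,
    criteria: ClusterCriteria = ClusterCriteria(),
) -> Fraction:
    """OCL: likelihood of *any* ensemble type at least as unlikely as ``starred``.

    Candidate window lengths are the distinct pairwise spine spans
    (capped at ``(m-1)·l_g``: an ensemble of ``m`` inputs with
    consecutive spacing ≤ ``l_g`` cannot span more).  For each
    candidate length the δ-selector picks the smallest input count
    ``m`` whose SEL drops to or below ``SEL(starred)``; the length then
    contributes the likelihood of its *tight* realizations — windows
    ending exactly on a spine.  A spine set realizes the type
    definition for every length from its own span upward; attributing
    it to that tight span alone is how "any set of spines which
    satisfies the ensemble definitions for more than one ``l_M`` is
    only counted once" is enforced.  The result is a union bound on
    (hence at least) the probability that the segment carries any
    ensemble as unlikely as the starred one; on uniform lattices every
    interior window is tight and the sum reduces to the plain SEL
    terms.

    Raises ``ValueError`` if the starred type is unattainable on the
    segment (zero SEL).
    """
    pos = seg.positions
    l_g = starred.l_g
    gap_boundary = criteria.gap_boundary
    sel_star = specific_ensemble_likelihood(seg, n, starred, gap_boundary)
    if sel_star == 0:
        raise ValueError("starred ensemble type is not attainable on this segment")
    total = Fraction(0)
    for l_M in _candidate_lengths(pos, starred.l_M):
        l_M = float(l_M)
        chosen = None
        for m in range(2, n + 1):
            if l_M > (m - 1) * l_g * (1 + 1e-12):
                continue  # not realizable as an m-input ensemble
            fsel = specific_ensemble_likelihood(
                seg, n, EnsembleType(l_M, m, l_g), gap_boundary
            )
            if fsel <= sel_star:
                chosen = m  # smallest qualifying m: SEL(l_M, m-1) > SEL*
                break
        if chosen is None:
            continue
        total += _tight_type_likelihood(pos, n, l_M, chosen, l_g, gap_boundary)
    return total


# ---------------------------------------------------------------------------
# segment-count binomial test (step 5)
# ---------------------------------------------------------------------------

def segment_count_pvalue(c: int, S: int, ocl_max: float) -> float:
    """Tail probability of ≥ ``c`` cluster segments among ``S`` at rate ``ocl_max``."""
    if c <= 0:
        return 1.0
    return float(stats.binom.sf(c - 1, S, ocl_max))


def segment_cluster_test(
    calls_per_segment: list[tuple[SpineSegment, list[ClusterCall]]],
    criteria: ClusterCriteria = ClusterCriteria(),
) -> SegmentClusterTest:
    """Binomial test of the number of cluster-bearing segments.

    Only segments with span at or above ``min_segment_length`` are
    eligible.  Each cluster-bearing segment contributes its smallest
    OCL; values are sorted ascending and ``P(c, OCL_max(c))`` computed
    for every ``c``.
    """
    eligible = [
        (seg, calls)
        for seg, calls in calls_per_segment
        if seg.span >= criteria.min_segment_length
    ]
    S = len(eligible)
    seg_ocls: list[float] = []
    for seg, calls in eligible:
        ocls = [c.ocl for c in calls if c.is_cluster and c.ocl is not None]
        if ocls:
            seg_ocls.append(float(min(ocls)))
    seg_ocls.sort()
    p_values = [segment_count_pvalue(c, S, seg_ocls[c - 1]) for c in range(1, len(seg_ocls) + 1)]
    c_significant = 0
    for c, p in enumerate(p_values, start=1):
        if p < criteria.alpha_segments:
            c_significant = c
    return SegmentClusterTest(
        S=S,
        sorted_ocl=seg_ocls,
        p_values=p_values,
        c_significant=c_significant,
        alpha=criteria.alpha_segments,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

MAX_BRUTE_FORCE = 10**7


def brute_force_sel(
    seg: SpineSegment,
    n: int,
    etype: EnsembleType,
    gap_boundary: str = "open",
    exact_m: bool = False,
) -> Fraction:
    """Exact probability of the ensemble-type event by full enumeration.

    Enumerates all ``C(N, n)`` assignments of ``n`` inputs to the
    segment's spines and returns the fraction in which the type occurs:
    some anchor window ``[d_i, d_i + l_M]`` has both edge spines
    positive, at least ``m`` positives inside (exactly ``m`` when
    ``exact_m``), and input-free flanking gaps.  This is the
    probability of the *union* of the anchored realizations whose
    inclusion count the anchored sum of the specific ensemble
    likelihood adds up, hence always a lower bound on it.
    """
    N = seg.n_spines
    _check_args(seg, n, etype)
    total = comb(N, n)
    if total > MAX_BRUTE_FORCE:
        raise ComputationTooLargeError(
            f"C({N},{n})={total} assignments; use the combinatorial path instead"
        )
    pos = seg.positions
    m = etype.m
    # windows and gaps are fixed by geometry; precompute per anchor
    lo = np.searchsorted(pos, pos, side="left")
    hi = np.searchsorted(pos, pos + etype.l_M, side="right")
    if gap_boundary == "open":
        glo = np.searchsorted(pos, pos - etype.l_g, side="right")
        thi = np.searchsorted(pos, pos + etype.l_M + etype.l_g, side="left")
    else:
        glo = np.searchsorted(pos, pos - etype.l_g, side="left")
        thi = np.searchsorted(pos, pos + etype.l_M + etype.l_g, side="right")
    count = 0
    for combo in itertools.combinations(range(N), n):
        cset = set(combo)
        for i in combo:
            a, b = lo[i], hi[i]
            if b - a < m:
                continue
            if a not in cset or (b - 1) not in cset:
                continue  # window edges must be occupied
            inside = sum(1 for j in combo if a <= j < b)
            if (inside != m) if exact_m else (inside < m):
                continue
            if any(glo[i] <= j < a for j in combo):
                continue  # leading gap must be input-free
            if any(b <= j < thi[i] for j in combo):
                continue  # trailing gap must be input-free
            count += 1
            break
    return Fraction(count, total)
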