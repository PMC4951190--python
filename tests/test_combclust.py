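from fractions import Fraction

import numpy as np
import pytest

from synclust import (
    ClusterCriteria,
    EnsembleType,
    SpineSegment,
    arrangement_count,
    brute_force_sel,
    classify_ensembles,
    find_ensembles,
    overall_cluster_likelihood,
    placement_count,
    segment_cluster_test,
    specific_arrangement_likelihood,
    specific_ensemble_likelihood,
    window_census,
)
from synclust.combclust import ComputationTooLargeError, segment_count_pvalue

from conftest import unit_lattice


# ---------------------------------------------------------------------------
# ensemble detection
# ---------------------------------------------------------------------------

def test_find_ensembles_worked_example(worked_example_segment):
    ens = find_ensembles(worked_example_segment, delta_crit=2.0)
    singles = [e for e in ens if e.is_singleton]
    groups = [e for e in ens if not e.is_singleton]
    assert len(singles) == 1 and singles[0].first_index == 3
    (g,) = groups
    assert (g.first_index, g.last_index) == (10, 15)
    assert (g.M, g.m, g.span_um) == (6, 4, 5.0)
    assert (g.g, g.h) == (1, 1)


def test_find_ensembles_edge_cases(lattice):
    assert find_ensembles(unit_lattice(10), 2.0) == []
    seg = unit_lattice(8, range(8))
    (e,) = find_ensembles(seg, 1.0)
    assert e.m == 8 and e.M == 8


def test_ensemble_edges_are_positive_and_spacing_holds(lattice):
    rng = np.random.default_rng(4)
    for _ in range(50):
        pos = np.sort(rng.uniform(0, 40, 30))
        marks = rng.random(30) < 0.2
        seg = SpineSegment("c", "s", pos, marks)
        for e in find_ensembles(seg, 5.0):
            assert seg.marks[e.first_index] and seg.marks[e.last_index]
            ppos = pos[(pos >= pos[e.first_index]) & (pos <= pos[e.last_index]) & marks]
            assert np.all(np.diff(ppos) <= 5.0 + 1e-12)
            # no positive spine inside either flanking gap
            lead = (pos > pos[e.first_index] - 5.0) & (pos < pos[e.first_index])
            trail = (pos > pos[e.last_index]) & (pos < pos[e.last_index] + 5.0)
            assert not marks[lead].any() and not marks[trail].any()


# ---------------------------------------------------------------------------
# censuses and counts
# ---------------------------------------------------------------------------

def test_window_census_interior_anchor(worked_example_segment):
    M, g, h = window_census(worked_example_segment, 10, l_M=5.0, l_g=2.0)
    assert (M, g, h) == (6, 1, 1)
    assert 30 - M - g - h == 22


def test_window_census_truncation(worked_example_segment):
    M, g, h = window_census(worked_example_segment, 0, l_M=5.0, l_g=2.0)
    assert g == 0  # leading gap truncated at the segment start
    M, g, h = window_census(worked_example_segment, 0, l_M=100.0, l_g=2.0)
    assert M == 30 and h == 0
    with pytest.raises(IndexError):
        window_census(worked_example_segment, 30, 5.0, 2.0)


def test_window_census_closed_boundary(worked_example_segment):
    M, g, h = window_census(worked_example_segment, 10, 5.0, 2.0, gap_boundary="closed")
    assert (M, g, h) == (6, 2, 2)


@pytest.mark.parametrize(
    "M, m, expected", [(6, 4, 6), (5, 2, 1), (9, 2, 1), (5, 7, 0)]
)
def test_arrangement_count(M, m, expected):
    assert arrangement_count(M, m) == expected


@pytest.mark.parametrize("N, M, expected", [(30, 6, 25), (7, 7, 1), (6, 7, 0)])
def test_placement_count(N, M, expected):
    assert placement_count(N, M) == expected


# ---------------------------------------------------------------------------
# specific ensemble likelihood
# ---------------------------------------------------------------------------

def test_arrangement_likelihood_adjacent_pairs(lattice):
    # 15 two-input assignments on 6 spines; 5 give an adjacent pair
    seg = unit_lattice(6)
    p = specific_arrangement_likelihood(seg, 2, EnsembleType(1.0, 2, 1.0))
    assert p == Fraction(5, 15)


def test_arrangement_likelihood_all_positive_certain(lattice):
    seg = unit_lattice(5)
    assert specific_arrangement_likelihood(seg, 5, EnsembleType(10.0, 5, 1.0)) == 1


def test_sel_single_term_and_monotone_in_m(worked_example_segment):
    # when m equals min(n, M_max) the sum has one term
    t = EnsembleType(5.0, 4, 2.0)
    etype_top = EnsembleType(5.0, 5, 2.0)
    sel_top = specific_ensemble_likelihood(worked_example_segment, 5, etype_top)
    p_top = specific_arrangement_likelihood(worked_example_segment, 5, etype_top)
    # M_max for l_M=5 on the unit lattice is 6, but only n=5 inputs exist
    assert sel_top == p_top
    prev = None
    for m in (2, 3, 4, 5):
        sel = specific_ensemble_likelihood(worked_example_segment, 5, EnsembleType(5.0, m, 2.0))
        if prev is not None:
            assert sel <= prev
        prev = sel


def test_sel_is_exact_rational(worked_example_segment):
    sel = specific_ensemble_likelihood(worked_example_segment, 5, EnsembleType(5.0, 4, 2.0))
    assert isinstance(sel, Fraction)
    assert sel == Fraction(5, 203)


def test_sel_argument_errors(lattice):
    seg = unit_lattice(6)
    with pytest.raises(ValueError):
        specific_arrangement_likelihood(seg, 7, EnsembleType(1.0, 2, 1.0))
    with pytest.raises(ValueError):
        specific_ensemble_likelihood(seg, 3, EnsembleType(1.0, 4, 1.0))


def test_degenerate_segment_convention():
    seg = SpineSegment("c", "s", [0.0, 1.0], [True, False])
    assert specific_ensemble_likelihood(seg, 1, EnsembleType(1.0, 2, 1.0)) == 1
    assert [c for c in classify_ensembles(seg) if c.is_cluster] == []


# ---------------------------------------------------------------------------
# oracle relations
# ---------------------------------------------------------------------------

def test_brute_force_matches_derived_pair_fraction(lattice):
    seg = unit_lattice(6)
    assert brute_force_sel(seg, 2, EnsembleType(1.0, 2, 1.0)) == Fraction(1, 3)


def test_brute_force_full_assignment(lattice):
    seg = unit_lattice(5, range(5))
    assert brute_force_sel(seg, 5, EnsembleType(4.0, 5, 1.0)) == 1
    assert brute_force_sel(seg, 5, EnsembleType(1.0, 5, 1.0)) == 0


def test_brute_force_resource_guard():
    seg = unit_lattice(60)
    with pytest.raises(ComputationTooLargeError):
        brute_force_sel(seg, 10, EnsembleType(5.0, 3, 2.0))


def test_sel_upper_bounds_brute_force(worked_example_segment):
    t = EnsembleType(5.0, 4, 2.0)
    sel = specific_ensemble_likelihood(worked_example_segment, 5, t)
    bf = brute_force_sel(worked_example_segment, 5, t)
    assert bf <= sel <= bf * Fraction(21, 20)  # documented union-bound slack


def test_pair_sel_equals_within_criterion_probability(lattice):
    # with unit gap criterion, the two-input SEL at full window length
    # equals the chance the two inputs are neighbors (distance <= 1)
    for N in (5, 8, 12):
        seg = unit_lattice(N)
        sel = specific_ensemble_likelihood(seg, 2, EnsembleType(float(N - 1), 2, 1.0))
        adjacent = Fraction(N - 1, N * (N - 1) // 2)
        assert sel == adjacent


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classification_rules(lattice):
    # tight triple on a long segment: unlikely, >= 3 inputs -> cluster
    seg = unit_lattice(40, [10, 11, 12])
    crit = ClusterCriteria(delta_crit=2.0)
    calls = classify_ensembles(seg, criteria=crit)
    (call,) = calls
    assert call.ensemble.m == 3 and call.sel <= Fraction(1, 100)
    assert call.is_cluster and call.ocl is not None


def test_min_inputs_rule(lattice):
    # an adjacent pair can be arbitrarily unlikely but never a cluster
    seg = unit_lattice(200, [50, 51])
    crit = ClusterCriteria(delta_crit=1.0)
    (call,) = classify_ensembles(seg, criteria=crit)
    assert call.sel <= Fraction(1, 100) and not call.is_cluster


def test_whole_segment_exclusion(lattice):
    # all inputs spanning (almost) the whole segment are not a cluster
    seg = unit_lattice(10, [0, 3, 6, 9])
    crit = ClusterCriteria(delta_crit=4.0, sel_threshold=0.999999)
    (call,) = classify_ensembles(seg, criteria=crit)
    assert call.ensemble.m == 4 and not call.is_cluster


# ---------------------------------------------------------------------------
# overall cluster likelihood
# ---------------------------------------------------------------------------

def test_ocl_at_least_starred_sel_on_lattice(lattice):
    seg = unit_lattice(40, [10, 11, 12])
    crit = ClusterCriteria(delta_crit=2.0)
    (call,) = classify_ensembles(seg, criteria=crit)
    assert call.ocl >= call.sel


def test_ocl_unattainable_type_raises(lattice):
    seg = unit_lattice(10, [2, 3, 4])
    with pytest.raises(ValueError, match="not attainable"):
        overall_cluster_likelihood(seg, 3, EnsembleType(0.5, 3, 2.0))


def test_ocl_upper_bounds_event_probability(lattice):
    """OCL >= exhaustively enumerated P(any ensemble at least as unlikely)."""
    from itertools import combinations

    crit = ClusterCriteria(delta_crit=2.0)
    seg = unit_lattice(10, [3, 4, 5])
    n = 3
    (call,) = classify_ensembles(seg, criteria=crit)
    sel_star = call.sel
    starred = EnsembleType(call.ensemble.span_um, call.ensemble.m, crit.delta_crit)
    ocl = overall_cluster_likelihood(seg, n, starred, crit)
    hits = 0
    combos = list(combinations(range(10), n))
    for combo in combos:
        marks = np.zeros(10, dtype=bool)
        marks[list(combo)] = True
        s2 = seg.with_marks(marks)
        sels = [
            specific_ensemble_likelihood(
                s2, n, EnsembleType(e.span_um, e.m, crit.delta_crit)
            )
            for e in find_ensembles(s2, crit.delta_crit)
            if e.m >= 2
        ]
        if any(s <= sel_star for s in sels):
            hits += 1
    assert Fraction(hits, len(combos)) <= ocl


def test_cluster_call_rate_respects_ocl_bound():
    """Superuniformity: P(any cluster with OCL <= u) <= u on random marks."""
    rng = np.random.default_rng(0)
    crit = ClusterCriteria()
    u = 0.02
    hits = 0
    n_seg = 300
    for i in range(n_seg):
        pos = np.sort(rng.uniform(0, 60, 50))
        marks = np.zeros(50, dtype=bool)
        marks[rng.choice(50, 5, replace=False)] = True
        seg = SpineSegment("c", f"s{i}", pos, marks)
        calls = [c for c in classify_ensembles(seg, criteria=crit) if c.is_cluster]
        if calls and float(min(c.ocl for c in calls)) <= u:
            hits += 1
    # one-sided binomial check at 3 SD above u
    assert hits / n_seg <= u + 3 * np.sqrt(u * (1 - u) / n_seg)


# ---------------------------------------------------------------------------
# segment-count binomial test
# ---------------------------------------------------------------------------

def test_segment_count_pvalue_closed_form():
    assert segment_count_pvalue(0, 40, 0.5) == 1.0
    assert segment_count_pvalue(1, 40, 0.001) == pytest.approx(1 - 0.999**40, abs=1e-12)


def test_segment_count_pvalue_monotone_in_c():
    rng = np.random.default_rng(2)
    for _ in range(20):
        S = int(rng.integers(5, 60))
        p = float(rng.uniform(0, 0.3))
        vals = [segment_count_pvalue(c, S, p) for c in range(S + 1)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_segment_cluster_test_filters_and_sorts(lattice):
    crit = ClusterCriteria(delta_crit=2.0)
    long_seg = unit_lattice(40, [10, 11, 12])
    short = SpineSegment("c", "short", np.arange(10.0), np.zeros(10, dtype=bool))
    calls_long = classify_ensembles(long_seg, criteria=crit)
    res = segment_cluster_test(
        [(long_seg, calls_long), (short, [])], criteria=crit
    )
    assert res.S == 1  # the 9 µm segment is not eligible
    assert len(res.sorted_ocl) == 1
    assert res.p_values[0] == pytest.approx(
        segment_count_pvalue(1, 1, res.sorted_ocl[0])
    )


def test_segment_cluster_test_empty():
    res = segment_cluster_test([])
    assert res.S == 0 and res.sorted_ocl == [] and res.c_significant == 0
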