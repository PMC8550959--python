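"""Decile health indices, ANOVA/Tukey comparisons, health surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import persnet as pn
from persnet import health as hm
from persnet.types import FeatureMatrix, NetworkPartition, Relation, RelationGraph


def _phen(n, rng=None, const=None):
    """Minimal character-only phenotype (one subscale per scale)."""
    rng = rng or np.random.default_rng(0)
    if const is not None:
        vals = np.full((n, 3), float(const))
    else:
        vals = rng.random((n, 3)) * 10
    return FeatureMatrix(vals, [f"s{i}" for i in range(n)],
                         ["SD1", "CO1", "ST1"], "phenotype",
                         {"SD1": "SD", "CO1": "CO", "ST1": "ST"})


def decile_oracle(scores, tail):
    """Sorting oracle for the strict-quantile decile flags."""
    import math
    n = len(scores)
    k = math.ceil(0.1 * n)
    order = np.argsort(scores, kind="stable")
    flags = np.zeros(n, dtype=bool)
    s = np.sort(scores)
    if tail == "top":
        cut = s[n - k - 1] if n - k - 1 >= 0 else -np.inf
        flags = scores > cut
    else:
        cut = s[k] if k < n else np.inf
        flags = scores < cut
    return flags


def test_twenty_distinct_subjects_flag_exactly_the_two_lowest_sums(rng):
    phen = _phen(20, rng)
    h = pn.compute_indices(phen)
    assert h.ill_flag.sum() == 2
    order = np.argsort(h.sum_score)
    assert set(np.flatnonzero(h.ill_flag)) == set(order[:2])
    assert h.well_flag.sum() == 2
    order_w = np.argsort(h.product_score)
    assert set(np.flatnonzero(h.well_flag)) == set(order_w[-2:])


def test_all_ties_cohort_flags_nobody():
    h = pn.compute_indices(_phen(30, const=4.0))
    assert h.well_flag.sum() == 0
    assert h.ill_flag.sum() == 0


def test_unique_maximum_subject_is_well_flagged(rng):
    phen = _phen(25, rng)
    phen.values[7] = 99.0
    h = pn.compute_indices(phen)
    assert h.well_flag[7]


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.integers(0, 10_000), st.integers(5, 60), st.booleans())
def test_decile_flags_match_the_sorting_oracle(seed, n, with_ties):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 8 if with_ties else 10_000, size=n).astype(float)
    from persnet.health import _decile_flags
    for tail in ("top", "bottom"):
        flags, _ = _decile_flags(scores, tail)
        np.testing.assert_array_equal(flags, decile_oracle(scores, tail))
        assert flags.sum() <= np.ceil(0.1 * n)


def test_missing_scale_metadata_is_a_configuration_error(rng):
    phen = _phen(10, rng)
    phen.feature_scales = None
    with pytest.raises(ValueError, match="metadata"):
        pn.compute_indices(phen)


def test_flag_overlap_is_reported_not_resolved(rng):
    h = pn.compute_indices(_phen(40, rng))
    assert 0.0 <= h.overlap_fraction <= 1.0


def test_set_probability_is_the_flagged_fraction(rng):
    phen = _phen(10, rng)
    h = pn.compute_indices(phen)
    h.well_flag = np.array([True] * 9 + [False])
    h.ill_flag = np.zeros(10, dtype=bool)
    b = pn.Bicluster("C_9_1", "character", [f"s{i}" for i in range(10)],
                     ["SD1"], np.ones(10), np.ones(1), 9, 1)
    pw, pi = pn.set_health_probability(b, h)
    assert pw == pytest.approx(0.9)
    assert pi == 0.0


def test_set_probability_is_invariant_to_subject_ordering(rng):
    phen = _phen(30, rng)
    h = pn.compute_indices(phen)
    ids = [f"s{i}" for i in range(0, 30, 2)]
    b1 = pn.Bicluster("C_9_1", "character", ids, ["SD1"],
                      np.ones(len(ids)), np.ones(1), 9, 1)
    b2 = pn.Bicluster("C_9_2", "character", ids[::-1], ["SD1"],
                      np.ones(len(ids)), np.ones(1), 9, 2)
    assert pn.set_health_probability(b1, h) == pn.set_health_probability(b2, h)


def test_anova_micro_example_matches_hand_computation():
    """Groups {1,2,3},{2,3,4},{7,8,9}: SSB=62 (df 2), SSW=6 (df 6), F=31."""
    f, dfb, dfw, p, zero = pn.anova_oneway([[1, 2, 3], [2, 3, 4], [7, 8, 9]])
    assert f == pytest.approx(31.0, rel=1e-12)
    assert (dfb, dfw) == (2, 6)
    assert not zero


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_anova_agrees_with_scipy_reference(seed):
    rng = np.random.default_rng(seed)
    groups = [rng.random(int(rng.integers(3, 12))) for _ in range(3)]
    f, dfb, dfw, p, _ = pn.anova_oneway(groups)
    ref = sps.f_oneway(*groups)
    assert f == pytest.approx(float(ref.statistic), rel=1e-9)
    assert p == pytest.approx(float(ref.pvalue), rel=1e-9)


def test_zero_within_variance_is_flagged_with_infinite_f():
    f, _, _, p, zero = pn.anova_oneway([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
    assert np.isinf(f) and zero and p == 0.0


def _partitioned_sets(rng, n=60):
    universe = [f"s{i}" for i in range(n)]
    phen = _phen(n, rng)
    blocks = [universe[0:20], universe[20:40], universe[40:60]]
    bics = []
    for i, blk in enumerate(blocks):
        for copy in range(2):
            bics.append(pn.Bicluster(
                f"C_{copy + 8}_{i + 1}", "character", blk, ["SD1"],
                np.ones(len(blk)), np.ones(1), copy + 8, i + 1))
    sc = pn.SetCollection(bics, universe, "character")
    part = NetworkPartition(k=3, set_networks={
        b.id: int(b.id.split("_")[2]) for b in bics})
    part.subject_networks = {s: i // 20 + 1 for i, s in enumerate(universe)}
    return phen, sc, part


def test_network_comparison_reports_anova_and_tukey(rng):
    phen, sc, part = _partitioned_sets(rng)
    h = pn.compute_indices(phen)
    comp = pn.compare_networks(part, h, [sc], outcome="well", level="sets")
    assert comp.df_between == 2
    assert comp.f_statistic >= 0
    assert set(comp.group_ns.values()) == {2}
    assert len(comp.tukey_pvalues) == 3
    comp_s = pn.compare_networks(part, h, [sc], outcome="ill", level="subjects")
    assert comp_s.level == "subjects"


def test_networks_with_single_set_are_dropped_with_warning(rng):
    phen, sc, part = _partitioned_sets(rng)
    h = pn.compute_indices(phen)
    small = pn.SetCollection(sc.biclusters[:3], sc.subject_universe, "character")
    part2 = NetworkPartition(k=3, set_networks={
        b.id: i + 1 for i, b in enumerate(small.biclusters)})
    part2.subject_networks = part.subject_networks
    with pytest.raises(ValueError):
        pn.compare_networks(part2, h, [small], outcome="well", level="sets")


def _surface_graph(rng):
    n = 80
    universe = [f"s{i}" for i in range(n)]
    phen = _phen(n, rng)
    h = pn.compute_indices(phen)
    # two disjoint cliques: (c0,c1)x(t0,t1) on subjects 0..39,
    # (c2,c3)x(t2,t3) on subjects 40..79
    def bic(prefix, i, subj, domain):
        return pn.Bicluster(f"{prefix}_9_{i + 1}", domain, subj, ["SD1"],
                            np.ones(len(subj)), np.ones(1), 9, i + 1)
    c_sets = [bic("C", 0, universe[0:25], "character"),
              bic("C", 1, universe[10:35], "character"),
              bic("C", 2, universe[40:65], "character"),
              bic("C", 3, universe[50:75], "character")]
    t_sets = [bic("T", 0, universe[0:30], "temperament"),
              bic("T", 1, universe[5:35], "temperament"),
              bic("T", 2, universe[40:70], "temperament"),
              bic("T", 3, universe[45:75], "temperament")]
    A = pn.SetCollection(c_sets, universe, "character")
    B = pn.SetCollection(t_sets, universe, "temperament")
    rels = []
    for i, a in enumerate(c_sets):
        for j, b in enumerate(t_sets):
            same = (i < 2) == (j < 2)
            ov = len(set(a.subject_ids) & set(b.subject_ids))
            rels.append(Relation(a.id, b.id, ov, a.n_subjects, b.n_subjects,
                                 n, 1e-20 if same else 1.0, 1.0, 1.0, 1.0,
                                 same))
    return RelationGraph(rels, A, B, 0.05, "bh", 199, 5e-3, 0), h


def test_surface_orders_cliques_into_contiguous_blocks(rng):
    g, h = _surface_graph(rng)
    M, rows, cols = pn.health_surface(g, h)
    assert M.shape == (4, 4)
    assert {rows.index("C_9_1"), rows.index("C_9_2")} in ({0, 1}, {2, 3})
    assert {cols.index("T_9_1"), cols.index("T_9_2")} in ({0, 1}, {2, 3})
    # significant cells carry probabilities; cross-clique cells are absent
    assert np.isnan(M).sum() == 8


def test_surface_singleton_relation(rng):
    g, h = _surface_graph(rng)
    keep = [r for r in g.relations if r.source == "C_9_1" and r.target == "T_9_1"]
    keep[0].significant = True
    g1 = RelationGraph(keep, g.source_collection, g.target_collection,
                       0.05, "bh", 199, 5e-3, 0)
    M, rows, cols = pn.health_surface(g1, h)
    assert M.shape == (1, 1)
    inter = (set(g.source_collection.get("C_9_1").subject_ids)
             & set(g.target_collection.get("T_9_1").subject_ids))
    idx = {s: i for i, s in enumerate(h.subject_ids)}
    expected = np.mean([h.well_flag[idx[s]] for s in inter])
    assert M[0, 0] == pytest.approx(expected)


def test_surface_saturated_cell_is_one(rng):
    g, h = _surface_graph(rng)
    h.well_flag = np.ones(len(h.subject_ids), dtype=bool)
    M, _, _ = pn.health_surface(g, h)
    assert np.nanmax(M) == 1.0 and np.nanmin(M) == 1.0


def test_surface_requires_significant_relations(rng):
    g, h = _surface_graph(rng)
    for r in g.relations:
        r.significant = False
    with pytest.raises(ValueError):
        pn.health_surface(g, h)
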