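"""Ancestry PCs, genotype/environment sets, network association, variance."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import persnet as pn
from persnet import integrate as ig
from persnet.types import FeatureMatrix, NetworkPartition


def _unstructured_genotype(rng, n=500, p=200):
    maf = rng.uniform(0.1, 0.5, size=p)
    vals = rng.binomial(2, np.tile(maf, (n, 1))).astype(float)
    return FeatureMatrix(vals, [f"s{i}" for i in range(n)],
                         [f"rs{j}" for j in range(p)], "genotype")


def test_unstructured_genotype_shows_no_stratification(rng):
    gen = _unstructured_genotype(rng)
    strata = pn.compute_ancestry_pcs(gen, n_pcs=3, seed=0)
    assert strata.explained_variance_ratio[0] < 5.0 / 200
    # k-means on pure noise gives a small but nonzero silhouette
    assert silhouette_score(strata.pc_scores, strata.stratum_labels) < 0.3


def test_planted_populations_are_recovered_by_pc_strata():
    cfg = pn.CohortConfig(n_subjects=600, n_snps=300, structure_strength=0.3,
                          seed=17)
    _, gen, _, truth = pn.generate_cohort(cfg)
    strata = pn.compute_ancestry_pcs(gen, n_pcs=3, seed=0)
    ari = adjusted_rand_score(truth.population_labels, strata.stratum_labels)
    assert ari >= 0.9


def test_zero_pcs_is_a_single_stratum_passthrough(rng):
    gen = _unstructured_genotype(rng, n=50, p=30)
    strata = pn.compute_ancestry_pcs(gen, n_pcs=0)
    assert set(strata.stratum_labels) == {0}
    assert strata.pc_scores.shape == (50, 0)


def test_excessive_missingness_raises_listing_snps(rng):
    gen = _unstructured_genotype(rng, n=50, p=10)
    gen.values[:30, 3] = np.nan
    with pytest.raises(ValueError, match="rs3"):
        pn.compute_ancestry_pcs(gen)


def test_two_planted_environment_blocks_are_recovered(rng):
    n = 800
    vals = rng.binomial(3, np.full((n, 12), 0.25)).astype(float)
    blocks = [(np.arange(0, 200), [0, 1, 2, 3]),
              (np.arange(300, 500), [6, 7, 8, 9])]
    for subj, feats in blocks:
        vals[np.ix_(subj, feats)] = rng.binomial(
            3, 0.85, size=(len(subj), len(feats)))
    env = FeatureMatrix(vals, [f"s{i}" for i in range(n)],
                        [f"env{j}" for j in range(12)], "environment")
    sc = pn.derive_feature_sets(env, k_range=range(2, 7), seed=0)
    for subj, _ in blocks:
        pl = {f"s{i}" for i in subj}
        best = max(len(pl & set(b.subject_ids)) / len(pl | set(b.subject_ids))
                   for b in sc.biclusters)
        assert best >= 0.8


def test_constant_environment_column_is_never_a_sole_feature(rng):
    n = 300
    vals = rng.binomial(3, np.full((n, 8), 0.3)).astype(float)
    vals[:, 5] = 2.0  # constant exposure
    vals[np.ix_(np.arange(0, 100), [0, 1])] = 3.0
    env = FeatureMatrix(vals, [f"s{i}" for i in range(n)],
                        [f"env{j}" for j in range(8)], "environment")
    sc = pn.derive_feature_sets(env, k_range=range(2, 6), seed=0)
    for b in sc.biclusters:
        assert b.feature_ids != ["env5"]


def test_phenotype_domain_is_rejected(small_cohort):
    with pytest.raises(ValueError, match="domain"):
        pn.derive_feature_sets(small_cohort[0])


def _exact_partition(universe, k=3):
    per = len(universe) // k
    part = NetworkPartition(k=k, set_networks={})
    part.subject_networks = {
        s: (i // per + 1 if i < per * k else None)
        for i, s in enumerate(universe)}
    part.ordered_by_wellbeing = True
    return part


def _collection_from_blocks(blocks, universe, domain, prefix):
    bics = []
    for i, subj in enumerate(blocks):
        bics.append(pn.Bicluster(
            f"{prefix}_9_{i + 1}", domain, list(subj), [f"f{i}"],
            np.ones(len(subj)), np.ones(1), 9, i + 1))
    return pn.SetCollection(bics, universe, domain)


def test_set_equal_to_network_pool_attains_the_minimum_pvalue():
    universe = [f"s{i}" for i in range(60)]
    part = _exact_partition(universe, k=3)
    blocks = [universe[0:20], universe[20:40], universe[40:60]]
    sc = _collection_from_blocks(blocks, universe, "genotype", "G")
    assoc = pn.associate_sets_with_networks(sc, part, alpha=0.05,
                                            n_perm=199, perm_alpha=5e-3,
                                            seed=0)
    from persnet.relations import overlap_pvalue
    expected = overlap_pvalue(20, 20, 20, 60)
    assert assoc.p_values["G_9_1"][1] == pytest.approx(expected, rel=1e-12)
    assert assoc.flags["G_9_1"] == {1}
    assert assoc.flags["G_9_2"] == {2}


def test_background_set_associates_with_no_network(rng):
    universe = [f"s{i}" for i in range(300)]
    part = _exact_partition(universe, k=3)
    random_block = [universe[i] for i in rng.choice(300, 60, replace=False)]
    sc = _collection_from_blocks([universe[0:100], random_block], universe,
                                 "genotype", "G")
    assoc = pn.associate_sets_with_networks(sc, part, alpha=0.05,
                                            n_perm=199, perm_alpha=5e-3,
                                            seed=0)
    assert assoc.flags["G_9_2"] == set()


def test_association_is_invariant_to_subject_reordering(rng):
    universe = [f"s{i}" for i in range(90)]
    part = _exact_partition(universe, k=3)
    block = universe[0:30]
    a = _collection_from_blocks([block], universe, "genotype", "G")
    b = _collection_from_blocks([block[::-1]], universe, "genotype", "G")
    ka = pn.associate_sets_with_networks(a, part, n_perm=199, perm_alpha=5e-3)
    kb = pn.associate_sets_with_networks(b, part, n_perm=199, perm_alpha=5e-3)
    assert ka.p_values == kb.p_values


def test_planted_snp_sets_associate_with_their_own_network(small_cohort,
                                                           small_full_result):
    phen, gen, env, truth = small_cohort
    res = small_full_result
    sids = phen.subject_ids
    correct = total = 0
    for ps in truth.sets_in_domain("genotype"):
        pl = set(sids[i] for i in ps.subject_idx)
        best = max(res.genotype_sets.biclusters,
                   key=lambda b: len(pl & set(b.subject_ids))
                   / len(pl | set(b.subject_ids)))
        truth_net_label = {s: l for s, l in
                           zip(sids, truth.subject_network_labels)}
        # the partition's labels are a permutation of the truth labels;
        # map via the majority truth label of the recovered network
        flags = res.snp_association.flags[best.id]
        total += 1
        if len(flags) == 1:
            g = next(iter(flags))
            members = [s for s, lab in res.partition.subject_networks.items()
                       if lab == g]
            truth_votes = [truth_net_label[s] for s in members
                           if truth_net_label[s] is not None]
            if truth_votes and np.bincount(truth_votes).argmax() == ps.network:
                correct += 1
    assert total == 6
    assert correct >= 5


def _wiring_fixture():
    """Truth-derived collections exercising the direct/indirect logic."""
    universe = [f"s{i}" for i in range(120)]
    part = _exact_partition(universe, k=3)  # pools of 40
    phen_sets = _collection_from_blocks(
        [universe[0:40], universe[40:80], universe[80:120]],
        universe, "character", "C")
    part.set_networks = {b.id: i + 1
                         for i, b in enumerate(phen_sets.biclusters)}
    snp_sets = _collection_from_blocks(
        [universe[0:30], universe[40:70], universe[80:110]],
        universe, "genotype", "G")
    env_sets = _collection_from_blocks(
        [universe[0:25],          # direct + indirect (overlaps C and G of net 1)
         universe[30:40],         # direct-only (in pool 1, outside G_9_1)
         universe[95:110]],       # inside pool 3 and G_9_3
        universe, "environment", "E")
    return universe, part, phen_sets, snp_sets, env_sets


def test_env_wiring_classification_follows_the_overlap_chains():
    universe, part, phen_sets, snp_sets, env_sets = _wiring_fixture()
    snp_assoc = pn.associate_sets_with_networks(
        snp_sets, part, alpha=0.05, n_perm=199, perm_alpha=5e-3, seed=0)
    report = pn.env_associations(
        env_sets, snp_sets, [phen_sets], part, snp_assoc,
        alpha=0.05, n_perm=199, perm_alpha=5e-3, seed=0)
    assert report.classify("E_9_1") == "both"
    assert report.classify("E_9_2") == "direct"
    assert 1 in report.direct["E_9_1"]
    assert 1 in report.indirect["E_9_1"]
    assert report.indirect["E_9_2"] == set()
    assert any(m[0] == "G_9_1" for m in report.mediators["E_9_1"])


def test_direct_only_truth_wiring_has_no_indirect_flags():
    universe, part, phen_sets, snp_sets, env_sets = _wiring_fixture()
    direct_only = pn.SetCollection([env_sets.biclusters[1]], universe,
                                   "environment")
    snp_assoc = pn.associate_sets_with_networks(
        snp_sets, part, alpha=0.05, n_perm=199, perm_alpha=5e-3, seed=0)
    report = pn.env_associations(
        direct_only, snp_sets, [phen_sets], part, snp_assoc,
        alpha=0.05, n_perm=199, perm_alpha=5e-3, seed=0)
    assert report.n_direct == 1 and report.n_indirect == 0 and report.n_both == 0


def _variance_fixture(p_flags=(0.1, 0.2, 0.3), n=300, seed=0):
    rng = np.random.default_rng(seed)
    universe = [f"s{i}" for i in range(n)]
    part = _exact_partition(universe, k=3)
    per = n // 3
    blocks = [universe[0:per], universe[per:2 * per], universe[2 * per:3 * per]]
    sc = _collection_from_blocks(blocks, universe, "genotype", "G")
    flags = np.zeros(n, dtype=bool)
    for g, pf in enumerate(p_flags):
        idx = np.arange(g * per, (g + 1) * per)
        flags[idx[:int(round(pf * per))]] = True
    h = pn.HealthIndices(universe, np.zeros(n), np.zeros(n),
                         flags, flags.copy(), 0.0, 0.0)
    return part, sc, h, rng


def test_noiseless_linear_outcome_gives_unit_cv_r2():
    part, sc, h, _ = _variance_fixture()
    rep = pn.variance_explained(part, sc, sc, h, outcome="well", folds=10,
                                seed=0)
    assert rep.r2_genotype >= 0.999
    assert rep.r2_joint >= 0.999


def _null_variance_fixture(seed, n=300, n_sets=6):
    """Sets drawn at random (unaligned with networks), random flags."""
    rng = np.random.default_rng(seed)
    universe = [f"s{i}" for i in range(n)]
    part = _exact_partition(universe, k=3)
    blocks = [[universe[i] for i in rng.choice(n, 80, replace=False)]
              for _ in range(n_sets)]
    sc = _collection_from_blocks(blocks, universe, "genotype", "G")
    flags = rng.random(n) < 0.2
    h = pn.HealthIndices(universe, np.zeros(n), np.zeros(n),
                         flags, flags.copy(), 0.0, 0.0)
    return part, sc, h


def test_null_predictors_explain_nothing():
    r2s = []
    for seed in range(20):
        part, sc, h = _null_variance_fixture(seed)
        rep = pn.variance_explained(part, sc, sc, h, outcome="well",
                                    folds=5, seed=seed)
        r2s.append(rep.r2_genotype)
    assert np.mean(r2s) <= 0.05


def test_joint_model_is_no_worse_than_either_single_model(small_full_result):
    for outcome in ("well", "ill"):
        rep = small_full_result.variance[outcome]
        assert rep.r2_joint >= max(rep.r2_genotype, rep.r2_environment) - 0.05


def test_subjects_outside_all_sets_are_imputed_and_flagged():
    part, sc, h, _ = _variance_fixture()
    smaller = pn.SetCollection(sc.biclusters[:2], sc.subject_universe,
                               "genotype")
    rep = pn.variance_explained(part, smaller, sc, h, outcome="well",
                                folds=5, seed=0)
    assert rep.n_imputed["genotype"] > 0


def test_too_few_subjects_for_folds_raises():
    part, sc, h, _ = _variance_fixture(n=30)
    with pytest.raises(ValueError, match="subjects"):
        pn.variance_explained(part, sc, sc, h, folds=10)


def test_stratified_permutation_controls_a_planted_confound():
    """With two ancestry groups of different set prevalence, unstratified
    permutation finds spurious network association; stratified does not."""
    rng = np.random.default_rng(5)
    n = 400
    universe = [f"s{i}" for i in range(n)]
    pop = np.repeat([0, 1], n // 2)
    # network pools follow ancestry; a 'SNP set' also follows ancestry but
    # has no within-population association
    part = NetworkPartition(k=2, set_networks={})
    part.subject_networks = {}
    for i, s in enumerate(universe):
        if pop[i] == 0:
            part.subject_networks[s] = 1 if rng.random() < 0.8 else 2
        else:
            part.subject_networks[s] = 2 if rng.random() < 0.8 else 1
    members = [s for i, s in enumerate(universe)
               if rng.random() < (0.7 if pop[i] == 0 else 0.2)]
    sc = _collection_from_blocks([members], universe, "genotype", "G")
    strata = pn.AncestryStrata(universe, np.zeros((n, 1)), pop, np.zeros(1))
    un = pn.associate_sets_with_networks(sc, part, None, alpha=0.05,
                                         n_perm=499, perm_alpha=2.1e-2, seed=0)
    st_ = pn.associate_sets_with_networks(sc, part, strata, alpha=0.05,
                                          n_perm=499, perm_alpha=2.1e-2, seed=0)
    assert un.p_empirical["G_9_1"][1] <= 0.021       # confounded: spurious
    assert st_.p_empirical["G_9_1"][1] > 0.021       # stratified: controlled
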