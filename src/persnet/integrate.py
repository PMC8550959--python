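"""Genotype and environment set collections, their association with the
phenotypic networks, ancestry stratification, and variance explained.

Genotype and environment matrices are biclustered exactly like the
phenotype domains (NMF over the nonnegative dosage / coded-environment
matrix).  A derived set associates with a phenotypic network when its
subjects are enriched in the network's subject pool (hypergeometric test
with BH correction, plus a permutation test stratified within ancestry
strata when those are supplied).  Environmental sets may relate to a
network directly (overlapping its temperament/character sets) or
indirectly (overlapping a network-associated SNP set — a set-theoretic
gene-environment chain, not a causal mediation estimand).

Variance explained follows the linear-benchmark recipe: the outcome is
the network index (1..k ordered by mean well-being), each subject's
genotype (environment) predictor is the mean set-level health probability
of the genotype (environment) sets containing the subject, and three OLS
models (genotype-only, environment-only, joint) are scored by mean
out-of-fold R^2 over stratified k-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import StratifiedKFold

from . import nmf
from .health import set_health_probability
from .relations import overlap_pvalue, relate_collections
from .types import (
    AncestryStrata,
    FeatureMatrix,
    HealthIndices,
    NetworkPartition,
    RelationGraph,
    SetCollection,
    VarianceReport,
)


def compute_ancestry_pcs(
    gen: FeatureMatrix,
    n_pcs: int = 3,
    n_strata: int = 3,
    seed: int = 0,
    max_missing: float = 0.2,
) -> AncestryStrata:
    """Leading PCs of the standardized dosage matrix, plus k-means strata.

    SNPs missing in more than ``max_missing`` of subjects are an error
    (listed).  Missing dosages are mean-imputed before centering.
    ``n_pcs=0`` is the no-adjustment pass-through: a single stratum.
    """
    X = gen.values.copy()
    miss_frac = np.isnan(X).mean(axis=0)
    bad = np.flatnonzero(miss_frac > max_missing)
    if bad.size:
        names = [gen.feature_ids[j] for j in bad[:10]]
        raise ValueError(f"{bad.size} SNPs exceed {max_missing:.0%} missingness: {names}")
    if n_pcs == 0:
        n = gen.n_subjects
        return AncestryStrata(list(gen.subject_ids), np.zeros((n, 0)),
                              np.zeros(n, dtype=int), np.zeros(0))
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean, X)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    km = KMeans(n_clusters=n_strata, random_state=seed, n_init=10)
    labels = km.fit_predict(scores)
    return AncestryStrata(list(gen.subject_ids), scores, labels,
                          pca.explained_variance_ratio_)


def derive_feature_sets(
    X: FeatureMatrix,
    k_range: Iterable[int] = range(2, 9),
    seed: int = 0,
    subject_policy="otsu",
    feature_policy=("relmax", 0.5),
    max_subject_frac: float = 0.34,
) -> SetCollection:
    """Bicluster a genotype or environment matrix into a set collection.

    Delegates to the NMF accumulation path with domain-appropriate
    defaults; set ids follow the ``E_rank_index`` / ``G_rank_index``
    convention.
    """
    if X.domain not in ("genotype", "environment"):
        raise ValueError(f"unexpected domain {X.domain!r}")
    return nmf.accumulate_sets(
        X, k_range, seed=seed,
        subject_policy=subject_policy,
        feature_policy=feature_policy,
        max_subject_frac=max_subject_frac,
    )


@dataclass
class NetworkAssociation:
    """Association flags of one set collection against the networks."""

    domain: str
    flags: dict[str, set[int]]            # set id -> associated networks
    p_values: dict[str, dict[int, float]]  # set id -> network -> hypergeom p
    q_values: dict[str, dict[int, float]]
    p_empirical: dict[str, dict[int, float]]
    contingency: np.ndarray                # (n_sets associated, k) counts

    def associated_sets(self, network: Optional[int] = None) -> list[str]:
        if network is None:
            return [s for s, gs in self.flags.items() if gs]
        return [s for s, gs in self.flags.items() if network in gs]


def associate_sets_with_networks(
    sc: SetCollection,
    p: NetworkPartition,
    strata: Optional[AncestryStrata] = None,
    alpha: float = 0.05,
    n_perm: int = 1999,
    perm_alpha: Optional[float] = None,
    seed: int = 0,
) -> NetworkAssociation:
    """Test every set for subject-overlap enrichment in each network pool.

    The universe is the whole cohort; one margin is the network's assigned
    subjects, the other the set's members.  Hypergeometric p-values are BH
    corrected across the set x network grid; significance additionally
    requires a permutation p (subject labels shuffled, within ancestry
    strata when given) at or below ``perm_alpha``.  A set may associate
    with several networks.
    """
    if not p.subject_networks:
        raise ValueError("partition has no subject assignments")
    if perm_alpha is None:
        perm_alpha = max(5e-4, 1.0 / (1.0 + n_perm))
    universe = sc.subject_universe
    N = len(universe)
    strata_arr = None
    if strata is not None:
        if strata.subject_ids != universe:
            raise ValueError("strata indexed over a different cohort")
        strata_arr = np.asarray(strata.stratum_labels)
    net_ind = np.zeros((p.k, N), dtype=bool)
    for i, s in enumerate(universe):
        g = p.subject_networks.get(s)
        if g is not None:
            net_ind[g - 1, i] = True
    M = sc.membership_matrix()
    sizes = M.sum(axis=1)
    net_sizes = net_ind.sum(axis=1)
    obs = (M.astype(np.float32) @ net_ind.T.astype(np.float32)).astype(np.int64)

    pvals = np.ones_like(obs, dtype=float)
    for i in range(obs.shape[0]):
        for g in range(p.k):
            pvals[i, g] = overlap_pvalue(int(obs[i, g]), int(sizes[i]),
                                         int(net_sizes[g]), N)
    qvals = stats.false_discovery_control(pvals.ravel(), method="bh").reshape(pvals.shape)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    Mf = M.astype(np.float32)
    netf = net_ind.astype(np.float32)
    for _ in range(n_perm):
        if strata_arr is None:
            perm = rng.permutation(N)
        else:
            perm = np.arange(N)
            for gstr in np.unique(strata_arr):
                idx = np.flatnonzero(strata_arr == gstr)
                perm[idx] = idx[rng.permutation(len(idx))]
        ov = (Mf @ netf[:, perm].T).astype(np.int64)
        exceed += ov >= obs
    p_emp = (1.0 + exceed) / (1.0 + n_perm)

    flags: dict[str, set[int]] = {}
    pv: dict[str, dict[int, float]] = {}
    qv: dict[str, dict[int, float]] = {}
    pe: dict[str, dict[int, float]] = {}
    for i, b in enumerate(sc.biclusters):
        flags[b.id] = {
            g + 1 for g in range(p.k)
            if qvals[i, g] <= alpha and p_emp[i, g] <= perm_alpha
        }
        pv[b.id] = {g + 1: float(pvals[i, g]) for g in range(p.k)}
        qv[b.id] = {g + 1: float(qvals[i, g]) for g in range(p.k)}
        pe[b.id] = {g + 1: float(p_emp[i, g]) for g in range(p.k)}
    contingency = np.zeros((len(sc), p.k), dtype=int)
    for i, b in enumerate(sc.biclusters):
        for g in flags[b.id]:
            contingency[i, g - 1] = 1
    return NetworkAssociation(sc.domain, flags, pv, qv, pe, contingency)


@dataclass
class EnvAssociationReport:
    """Direct / indirect / both classification of environment sets."""

    direct: dict[str, set[int]]
    indirect: dict[str, set[int]]
    mediators: dict[str, list[tuple[str, int]]]  # env set -> [(snp set, network)]
    n_direct: int = field(init=False)
    n_indirect: int = field(init=False)
    n_both: int = field(init=False)

    def __post_init__(self) -> None:
        d = {e for e, gs in self.direct.items() if gs}
        i = {e for e, gs in self.indirect.items() if gs}
        self.n_direct = len(d - i)
        self.n_indirect = len(i - d)
        self.n_both = len(d & i)

    def classify(self, env_id: str) -> str:
        d = bool(self.direct.get(env_id))
        i = bool(self.indirect.get(env_id))
        return {(True, True): "both", (True, False): "direct",
                (False, True): "indirect", (False, False): "none"}[(d, i)]


def env_associations(
    env: SetCollection,
    snp: SetCollection,
    phen_collections: Sequence[SetCollection],
    p: NetworkPartition,
    snp_assoc: NetworkAssociation,
    alpha: float = 0.05,
    n_perm: int = 1999,
    perm_alpha: Optional[float] = None,
    seed: int = 0,
    strata: Optional[AncestryStrata] = None,
) -> EnvAssociationReport:
    """Classify environment sets as directly and/or indirectly networked.

    Direct: the environment set significantly overlaps a temperament or
    character set assigned to the network.  Indirect: it significantly
    overlaps a SNP set that itself associates with the network.  Both
    relations use the dual (analytic + permutation) criterion.
    """
    strata_arr = np.asarray(strata.stratum_labels) if strata is not None else None
    direct: dict[str, set[int]] = {b.id: set() for b in env.biclusters}
    indirect: dict[str, set[int]] = {b.id: set() for b in env.biclusters}
    mediators: dict[str, list[tuple[str, int]]] = {b.id: [] for b in env.biclusters}

    for sc in phen_collections:
        g = relate_collections(env, sc, alpha=alpha, n_perm=n_perm,
                               perm_alpha=perm_alpha, seed=seed, strata=strata_arr)
        for r in g.significant:
            net = p.set_networks.get(r.target)
            if net is not None:
                direct[r.source].add(net)

    g = relate_collections(env, snp, alpha=alpha, n_perm=n_perm,
                           perm_alpha=perm_alpha, seed=seed, strata=strata_arr)
    for r in g.significant:
        for net in snp_assoc.flags.get(r.target, set()):
            indirect[r.source].add(net)
            mediators[r.source].append((r.target, net))
    return EnvAssociationReport(direct=direct, indirect=indirect, mediators=mediators)


def _subject_predictor(
    sc: SetCollection,
    h: HealthIndices,
    outcome: str,
    subjects: Sequence[str],
) -> tuple[np.ndarray, int]:
    """Mean set-level health probability over the sets containing each
    subject; subjects in no set get the grand mean (count returned)."""
    probs = []
    for b in sc.biclusters:
        pw, pi = set_health_probability(b, h)
        probs.append(pw if outcome == "well" else pi)
    probs = np.asarray(probs)
    M = sc.membership_matrix()
    sidx = {s: i for i, s in enumerate(sc.subject_universe)}
    cols = np.array([sidx[s] for s in subjects])
    counts = M[:, cols].sum(axis=0)
    sums = probs @ M[:, cols]
    with np.errstate(invalid="ignore"):
        x = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_missing = int(np.isnan(x).sum())
    if n_missing:
        grand = np.nanmean(x) if np.isfinite(np.nanmean(x)) else 0.0
        x = np.where(np.isnan(x), grand, x)
    return x, n_missing


def variance_explained(
    p: NetworkPartition,
    snp: SetCollection,
    env: SetCollection,
    h: HealthIndices,
    outcome: str = "ill",
    folds: int = 10,
    seed: int = 0,
) -> VarianceReport:
    """Cross-validated R^2 of genotype-only / environment-only / joint OLS.

    The outcome y is the subject's network index (requires a partition
    ordered by well-being, so 1 < 2 < 3 is meaningful); unassigned
    subjects are excluded.  Folds are stratified by network.
    """
    if not p.ordered_by_wellbeing:
        warnings.warn("partition not ordered by well-being; y ordering is arbitrary")
    subjects = [s for s, g in p.subject_networks.items() if g is not None]
    if len(subjects) < folds * 5:
        raise ValueError(f"need >= {folds * 5} assigned subjects, got {len(subjects)}")
    y = np.array([p.subject_networks[s] for s in subjects], dtype=float)
    x_gen, miss_gen = _subject_predictor(snp, h, outcome, subjects)
    x_env, miss_env = _subject_predictor(env, h, outcome, subjects)
    X = {"genotype": x_gen[:, None], "environment": x_env[:, None],
         "joint": np.column_stack([x_gen, x_env])}
    fold_r2: dict[str, list[float]] = {m: [] for m in X}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    for train, test in skf.split(np.zeros(len(y)), y.astype(int)):
        for m, Xm in X.items():
            model = LinearRegression().fit(Xm[train], y[train])
            fold_r2[m].append(float(r2_score(y[test], model.predict(Xm[test]))))
    return VarianceReport(
        outcome=outcome,
        r2_genotype=float(np.mean(fold_r2["genotype"])),
        r2_environment=float(np.mean(fold_r2["environment"])),
        r2_joint=float(np.mean(fold_r2["joint"])),
        fold_r2=fold_r2, folds=folds, seed=seed,
        n_imputed={"genotype": miss_gen, "environment": miss_env},
    )
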