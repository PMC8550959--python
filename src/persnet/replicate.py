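"""End-to-end pipeline orchestration and cross-cohort replication.

:func:`run_pipeline` chains biclustering -> relations -> network
partitioning -> health indices -> genotype/environment integration on one
cohort, with every random stage seeded from a single seed sequence so a
rerun reproduces the result exactly.

Replication compares a discovery run against an independently analysed
second cohort.  Subjects differ between cohorts, so discovery and
replication sets are matched by their shared FEATURES (subscales / SNP
ids intersected by name): similarity is the hypergeometric enrichment of
shared features, and a greedy best-first one-to-one matcher (optimal
assignment available) pairs sets below a significance threshold.  A
discovery relation replicates when both endpoint sets are matched and the
corresponding replication pair is itself significant.  The matched
fraction is calibrated by permuting the replication collection's feature
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import health as health_mod
from . import integrate as integrate_mod
from . import networks as networks_mod
from . import nmf
from . import relations as relations_mod
from .relations import overlap_pvalue
from .types import (
    FeatureMatrix,
    HealthComparison,
    HealthIndices,
    NetworkPartition,
    RelationGraph,
    SetCollection,
    TEMPERAMENT_SCALES,
    VarianceReport,
)


@dataclass
class PipelineConfig:
    """Every stage's parameters, with the defaults the pipeline runs at."""

    k_min_phenotype: int = 2
    k_max_phenotype: int = 8
    k_min_genotype: int = 2
    k_max_genotype: int = 8
    k_min_environment: int = 2
    k_max_environment: int = 10
    rank_selection: str = "all"      # "all" accumulates every rank; "stability"
    n_consensus_runs: int = 10       # restricts to consensus-stable ranks
    subject_policy: str = "otsu"     # or "relmax:<frac>"
    feature_policy: str = "relmax:0.5"
    max_subject_frac: float = 0.34
    alpha: float = 0.05
    correction: str = "bh"
    n_perm: int = 1999
    perm_alpha: Optional[float] = None  # None: max(5e-4, add-one floor)
    k_networks: int = 3
    min_membership: float = 0.5
    folds: int = 10
    ancestry_pcs: int = 0            # 0 disables ancestry stratification
    n_strata: int = 3
    seed: int = 0


@dataclass
class PipelineResult:
    """Everything one cohort's analysis produced, plus the seeds used."""

    config: PipelineConfig
    temperament_sets: SetCollection
    character_sets: SetCollection
    relation_graph: RelationGraph
    partition: NetworkPartition
    health: HealthIndices
    comparisons: dict[str, HealthComparison]
    genotype_sets: Optional[SetCollection] = None
    environment_sets: Optional[SetCollection] = None
    snp_association: Optional[integrate_mod.NetworkAssociation] = None
    env_report: Optional[integrate_mod.EnvAssociationReport] = None
    variance: dict[str, VarianceReport] = field(default_factory=dict)
    strata: Optional[object] = None
    stage_seeds: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict:
        s = {
            "n_temperament_sets": len(self.temperament_sets),
            "n_character_sets": len(self.character_sets),
            "n_significant_relations": len(self.relation_graph.significant),
            "network_sizes": self.partition.network_sizes(),
            "unassigned_fraction": self.partition.unassigned_fraction,
        }
        if self.genotype_sets is not None:
            s["n_genotype_sets"] = len(self.genotype_sets)
        if self.environment_sets is not None:
            s["n_environment_sets"] = len(self.environment_sets)
        if self.env_report is not None:
            s["env_direct"] = self.env_report.n_direct
            s["env_indirect"] = self.env_report.n_indirect
            s["env_both"] = self.env_report.n_both
        return s


def split_phenotype(phen: FeatureMatrix) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split a phenotype matrix into temperament and character matrices."""
    if phen.feature_scales is None:
        raise ValueError("phenotype matrix lacks scale metadata")
    temp = [f for f in phen.feature_ids
            if phen.feature_scales.get(f) in TEMPERAMENT_SCALES]
    char = [f for f in phen.feature_ids
            if phen.feature_scales.get(f) not in TEMPERAMENT_SCALES]
    if not temp or not char:
        raise ValueError("phenotype matrix must contain both temperament and "
                         "character subscales")
    return (phen.subset_features(temp, "temperament"),
            phen.subset_features(char, "character"))


def parse_policy(spec: str):
    """Parse a policy string: ``"otsu"`` or ``"relmax:<frac>"``."""
    if spec == "otsu":
        return "otsu"
    if spec.startswith("relmax:"):
        return ("relmax", float(spec.split(":", 1)[1]))
    raise ValueError(f"unknown threshold policy {spec!r}")


def _derive(X: FeatureMatrix, k_min: int, k_max: int, cfg: PipelineConfig,
            seed: int) -> SetCollection:
    k_range = range(k_min, min(k_max, min(X.values.shape) - 1) + 1)
    selection = None
    if cfg.rank_selection == "stability":
        selection = nmf.select_ranks(X, k_range, n_runs=cfg.n_consensus_runs,
                                     seed=seed)
    return nmf.accumulate_sets(
        X, k_range, seed=seed,
        subject_policy=parse_policy(cfg.subject_policy),
        feature_policy=parse_policy(cfg.feature_policy),
        max_subject_frac=cfg.max_subject_frac,
        rank_selection=selection,
    )


def run_pipeline(
    phen: FeatureMatrix,
    gen: Optional[FeatureMatrix] = None,
    env: Optional[FeatureMatrix] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full analysis on one cohort.

    Stages raise with their name attached; rerunning with the same inputs
    and config reproduces the result exactly.
    """
    cfg = config or PipelineConfig()
    ss = np.random.SeedSequence(cfg.seed)
    stage_names = ["temperament", "character", "relations", "partition",
                   "genotype", "environment", "ancestry", "association",
                   "variance"]
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(stage_names, ss.spawn(len(stage_names)))}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    temp_X, char_X = stage("split", split_phenotype, phen)
    temp_sets = stage("temperament", _derive, temp_X, cfg.k_min_phenotype,
                      cfg.k_max_phenotype, cfg, seeds["temperament"])
    char_sets = stage("character", _derive, char_X, cfg.k_min_phenotype,
                      cfg.k_max_phenotype, cfg, seeds["character"])
    graph = stage("relations", relations_mod.relate_collections,
                  char_sets, temp_sets, alpha=cfg.alpha,
                  correction=cfg.correction, n_perm=cfg.n_perm,
                  perm_alpha=cfg.perm_alpha, seed=seeds["relations"])
    M, src_ids, tgt_ids = stage("partition", networks_mod.build_relation_matrix, graph)
    part = stage("partition", networks_mod.partition_networks, M, src_ids,
                 tgt_ids, k=cfg.k_networks, seed=seeds["partition"])
    part = stage("partition", networks_mod.assign_subjects, part,
                 [char_sets, temp_sets], cfg.min_membership)
    health = stage("health", health_mod.compute_indices, phen)
    part = stage("partition", networks_mod.order_networks, part, health)
    networks_mod.partition_disjointness(part, [char_sets, temp_sets])
    comparisons = {
        outcome: stage("health", health_mod.compare_networks, part, health,
                       [char_sets, temp_sets], outcome, "sets")
        for outcome in ("well", "ill")
    }

    result = PipelineResult(
        config=cfg, temperament_sets=temp_sets, character_sets=char_sets,
        relation_graph=graph, partition=part, health=health,
        comparisons=comparisons, stage_seeds=seeds,
    )
    if gen is None and env is None:
        return result

    strata = None
    if gen is not None and cfg.ancestry_pcs > 0:
        strata = stage("ancestry", integrate_mod.compute_ancestry_pcs, gen,
                       cfg.ancestry_pcs, cfg.n_strata, seeds["ancestry"])
        result.strata = strata
    if gen is not None:
        result.genotype_sets = stage(
            "genotype", integrate_mod.derive_feature_sets, gen,
            range(cfg.k_min_genotype, cfg.k_max_genotype + 1),
            seed=seeds["genotype"], max_subject_frac=cfg.max_subject_frac)
        result.snp_association = stage(
            "association", integrate_mod.associate_sets_with_networks,
            result.genotype_sets, part, strata, cfg.alpha, cfg.n_perm,
            cfg.perm_alpha, seeds["association"])
    if env is not None:
        result.environment_sets = stage(
            "environment", integrate_mod.derive_feature_sets, env,
            range(cfg.k_min_environment, cfg.k_max_environment + 1),
            seed=seeds["environment"], max_subject_frac=cfg.max_subject_frac)
    if gen is not None and env is not None:
        result.env_report = stage(
            "association", integrate_mod.env_associations,
            result.environment_sets, result.genotype_sets,
            [char_sets, temp_sets], part, result.snp_association,
            cfg.alpha, cfg.n_perm, cfg.perm_alpha, seeds["association"],
            strata)
        for outcome in ("well", "ill"):
            result.variance[outcome] = stage(
                "variance", integrate_mod.variance_explained, part,
                result.genotype_sets, result.environment_sets, health,
                outcome, cfg.folds, seeds["variance"])
    return result


# ---------------------------------------------------------------------------
# cross-cohort matching
# ---------------------------------------------------------------------------

def _feature_sets(sc: SetCollection, universe: set[str]) -> dict[str, set[str]]:
    return {b.id: set(b.feature_ids) & universe for b in sc.biclusters}


def _pair_pvalues(disc_feats: dict[str, set[str]],
                  repl_feats: dict[str, set[str]],
                  n_universe: int) -> list[tuple[float, str, str]]:
    out = []
    for d, fd in disc_feats.items():
        if not fd:
            continue
        for r, fr in repl_feats.items():
            if not fr:
                continue
            if fd == fr:
                # identical signatures always match: enrichment of a
                # near-universal feature set is bounded away from zero
                # even against its own copy
                p = 0.0
            else:
                p = overlap_pvalue(len(fd & fr), len(fd), len(fr), n_universe)
            out.append((p, d, r))
    return out


def _greedy_match(pairs: list[tuple[float, str, str]],
                  threshold: float) -> dict[str, tuple[str, float]]:
    match: dict[str, tuple[str, float]] = {}
    used: set[str] = set()
    for p, d, r in sorted(pairs):
        if p > threshold:
            break
        if d not in match and r not in used:
            match[d] = (r, p)
            used.add(r)
    return match


def _assignment_match(pairs: list[tuple[float, str, str]],
                      threshold: float) -> dict[str, tuple[str, float]]:
    ds = sorted({d for _, d, _ in pairs})
    rs = sorted({r for _, _, r in pairs})
    cost = np.zeros((len(ds), len(rs)))
    pmat = np.ones((len(ds), len(rs)))
    di = {d: i for i, d in enumerate(ds)}
    ri = {r: j for j, r in enumerate(rs)}
    for p, d, r in pairs:
        pmat[di[d], ri[r]] = p
        cost[di[d], ri[r]] = -min(300.0, -np.log10(max(p, 1e-300)))
    rows, cols = linear_sum_assignment(cost)
    return {ds[i]: (rs[j], float(pmat[i, j]))
            for i, j in zip(rows, cols) if pmat[i, j] <= threshold}


def match_collections(
    disc: SetCollection,
    repl: SetCollection,
    threshold: float = 0.05,
    method: str = "greedy",
) -> tuple[dict[str, tuple[str, float]], float]:
    """Match discovery sets to replication sets by shared features.

    Returns the match map (discovery id -> (replication id, p)) and the
    matched fraction over ALL discovery sets.  The feature universe is the
    intersection-free union of both collections' feature namespaces
    restricted to features both cohorts could observe; an empty shared
    namespace is an error.
    """
    disc_universe = {f for b in disc.biclusters for f in b.feature_ids}
    repl_universe = {f for b in repl.biclusters for f in b.feature_ids}
    shared = disc_universe | repl_universe
    if not (disc_universe & repl_universe):
        raise ValueError("collections share no features")
    disc_feats = _feature_sets(disc, shared)
    repl_feats = _feature_sets(repl, shared)
    pairs = _pair_pvalues(disc_feats, repl_feats, len(shared))
    if method == "greedy":
        match = _greedy_match(pairs, threshold)
    elif method == "assignment":
        match = _assignment_match(pairs, threshold)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    fraction = len(match) / len(disc) if len(disc) else 0.0
    return match, fraction


def match_relations(
    disc_graph: RelationGraph,
    repl_graph: RelationGraph,
    source_map: dict[str, tuple[str, float]],
    target_map: dict[str, tuple[str, float]],
) -> float:
    """Fraction of significant discovery relations replicated.

    A discovery relation is matched iff both endpoint sets are matched and
    the corresponding replication pair is significant in the replication
    graph.
    """
    disc_sig = disc_graph.significant
    if not disc_sig:
        return 0.0
    repl_sig = {(r.source, r.target) for r in repl_graph.significant}
    matched = 0
    for r in disc_sig:
        if r.source in source_map and r.target in target_map:
            pair = (source_map[r.source][0], target_map[r.target][0])
            if pair in repl_sig:
                matched += 1
    return matched / len(disc_sig)


def replication_permutation_test(
    observed_fraction: float,
    disc: SetCollection,
    repl: SetCollection,
    n_perm: int = 199,
    seed: int = 0,
    threshold: float = 0.05,
    method: str = "greedy",
) -> float:
    """Empirical p of a matched fraction under feature-label permutation.

    The replication collection's feature labels are globally permuted
    ``n_perm`` times, the matched fraction recomputed each time, and
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    disc_universe = {f for b in disc.biclusters for f in b.feature_ids}
    repl_universe = {f for b in repl.biclusters for f in b.feature_ids}
    shared = sorted(disc_universe | repl_universe)
    fidx = {f: i for i, f in enumerate(shared)}
    disc_feats = _feature_sets(disc, set(shared))
    repl_idx = {b.id: np.array([fidx[f] for f in b.feature_ids], dtype=int)
                for b in repl.biclusters}
    rng = np.random.default_rng(seed)
    exceed = 0
    n_shared = len(shared)
    matcher = _greedy_match if method == "greedy" else _assignment_match
    for _ in range(n_perm):
        perm = rng.permutation(n_shared)
        repl_feats = {rid: {shared[perm[i]] for i in idx}
                      for rid, idx in repl_idx.items()}
        pairs = _pair_pvalues(disc_feats, repl_feats, n_shared)
        frac = len(matcher(pairs, threshold)) / len(disc) if len(disc) else 0.0
        if frac >= observed_fraction:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_perm)
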