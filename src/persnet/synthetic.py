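"""Synthetic genotype-phenotype-environment cohorts with planted structure.

The generator emulates the statistical structure the pipeline assumes: a
cohort whose subjects fall into three (configurable) networks plus a
background fraction; within each network, planted biclusters over
temperament subscales, character subscales, SNPs, and environmental
variables co-occur in overlapping subject blocks.  Phenotype scores are a
truncated-normal nonnegative baseline plus an additive mean shift of
``effect_size`` on planted cells; genotype backgrounds are Hardy-Weinberg
draws at a uniform MAF, with planted blocks shifted toward the minor
allele; environment variables are ordinal 0..3 exposures with elevated
prevalence on planted cells.

Two random streams are separated: the *structure* stream (from
``config.seed``) fixes the feature-side layout — planted feature sets,
disjointness sharing, allele frequencies, environment wiring — while the
*subject* stream (``subject_seed``, defaulting to the structure seed)
draws the subjects and their data.  Two cohorts generated from the same
config but different ``subject_seed`` therefore share one ground truth
over a common feature namespace: twin cohorts for replication studies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .types import (
    CHARACTER_SCALES,
    FeatureMatrix,
    SizingError,
    TEMPERAMENT_SCALES,
)

DOMAINS = ("temperament", "character", "genotype", "environment")


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 2000
    temperament_subscales: int = 16
    character_subscales: int = 13
    n_snps: int = 1000
    n_env_vars: int = 15
    n_networks: int = 3
    sets_per_domain_per_network: dict = field(default_factory=lambda: {
        "temperament": 1, "character": 1, "genotype": 2, "environment": 2,
    })
    disjointness: float = 0.9
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 1.0
    missing_rate: float = 0.0
    unassigned_fraction: float = 0.05
    maf_range: tuple = (0.05, 0.5)
    structure_strength: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_subjects, self.temperament_subscales,
                  self.character_subscales, self.n_snps, self.n_env_vars,
                  self.n_networks)
        if any(c < 1 for c in counts):
            raise SizingError("all counts must be positive")
        for frac in (self.disjointness, self.missing_rate, self.unassigned_fraction):
            if not (0.0 <= frac <= 1.0):
                raise SizingError(f"fraction {frac} outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SizingError(f"maf_range {self.maf_range} outside (0, 0.5]")
        for dom in DOMAINS:
            if self.sets_per_domain_per_network.get(dom, 0) < 1:
                raise SizingError(f"need >= 1 planted set per network for {dom}")
        # every network needs a nonempty feature pool
        sizes = {"temperament": self.temperament_subscales,
                 "character": self.character_subscales,
                 "genotype": self.n_snps, "environment": self.n_env_vars}
        for dom, n_feat in sizes.items():
            if n_feat < 2 * self.n_networks:
                raise SizingError(
                    f"{dom}: {n_feat} features cannot host {self.n_networks} "
                    "networks (need >= 2 per network)")


@dataclass
class PlantedSet:
    """One planted bicluster with its ground-truth indices."""

    id: str
    domain: str
    subject_idx: list[int]
    feature_idx: list[int]
    network: int
    wiring: str = "direct"  # environment sets: direct | indirect | both

    def validate(self, n_subjects: int, n_features: int) -> None:
        if not self.subject_idx or not self.feature_idx:
            raise ValueError(f"planted set {self.id} has an empty axis")
        if max(self.subject_idx) >= n_subjects or max(self.feature_idx) >= n_features:
            raise ValueError(f"planted set {self.id} indices out of bounds")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: planted sets and subject labels."""

    planted_sets: list[PlantedSet]
    subject_network_labels: list[Optional[int]]
    config: CohortConfig
    population_labels: Optional[list[int]] = None

    def sets_in_domain(self, domain: str) -> list[PlantedSet]:
        return [s for s in self.planted_sets if s.domain == domain]

    def network_feature_sets(self, domain: str) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for s in self.sets_in_domain(domain):
            out.setdefault(s.network, set()).update(s.feature_idx)
        return out

    def shared_feature_fraction(self, domain: str) -> float:
        """Fraction of planted features of a domain used by >= 2 networks."""
        nets = self.network_feature_sets(domain)
        all_feats: dict[int, int] = {}
        for feats in nets.values():
            for f in feats:
                all_feats[f] = all_feats.get(f, 0) + 1
        if not all_feats:
            return 0.0
        return sum(1 for c in all_feats.values() if c > 1) / len(all_feats)


def _scale_feature_ids(n: int, scales: tuple[str, ...]) -> tuple[list[str], dict[str, str]]:
    """Distribute n subscales round-robin over named scales (NS1, NS2, ...)."""
    per = [n // len(scales) + (1 if i < n % len(scales) else 0)
           for i in range(len(scales))]
    ids, meta = [], {}
    for scale, cnt in zip(scales, per):
        for j in range(cnt):
            fid = f"{scale}{j + 1}"
            ids.append(fid)
            meta[fid] = scale
    return ids, meta


def _plant_features(rng: np.random.Generator, n_features: int, n_networks: int,
                    sets_per_network: int, disjointness: float) -> list[tuple[int, list[int]]]:
    """Choose planted feature index sets per network with a disjointness dial.

    Features are partitioned into per-network pools, and each pool is
    split (disjointly) among the network's planted sets, so sets are
    distinguishable by their feature signatures both across and within
    networks.  Each set then borrows a fraction (1 - disjointness) of
    its size in extra features from other networks' pools.  The borrow
    sequence is drawn before the dial is applied, so for a fixed seed
    the fraction of planted features shared between networks is exactly
    monotone non-increasing in ``disjointness`` (and zero at 1).
    """
    pool_order = rng.permutation(n_features)
    pools = np.array_split(pool_order, n_networks)
    out: list[tuple[int, list[int]]] = []
    for g in range(n_networks):
        own = pools[g]
        others = np.concatenate([pools[h] for h in range(n_networks) if h != g])
        chunks = np.array_split(rng.permutation(own), sets_per_network)
        for base in chunks:
            size = len(base)
            if size < 1:
                raise SizingError(
                    f"feature pool of {len(own)} cannot host {sets_per_network} sets")
            borrow_seq = rng.choice(others, size=min(size, len(others)),
                                    replace=False)
            n_borrow = int(round((1.0 - disjointness) * size))
            feats = np.concatenate([base, borrow_seq[:n_borrow]])
            out.append((g + 1, sorted(set(int(f) for f in feats))))
    return out


def generate_cohort(
    config: CohortConfig,
    subject_seed: Optional[int] = None,
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix, SyntheticTruth]:
    """Generate (phenotype, genotype, environment, truth) for one cohort."""
    config.validate()
    struct_rng = np.random.default_rng(config.seed)
    data_rng = np.random.default_rng(
        config.seed + 1_000_003 if subject_seed is None else subject_seed
    )
    n = config.n_subjects
    k = config.n_networks
    spd = config.sets_per_domain_per_network

    # ---- feature namespaces -------------------------------------------------
    temp_ids, temp_meta = _scale_feature_ids(config.temperament_subscales,
                                             TEMPERAMENT_SCALES)
    char_ids, char_meta = _scale_feature_ids(config.character_subscales,
                                             CHARACTER_SCALES)
    phen_ids = temp_ids + char_ids
    phen_meta = {**temp_meta, **char_meta}
    snp_ids = [f"rs{100000 + j}" for j in range(config.n_snps)]
    env_ids = [f"env{j + 1}" for j in range(config.n_env_vars)]

    # ---- structure stream: planted feature sets, MAFs, wiring ---------------
    feat_sets = {
        "temperament": _plant_features(struct_rng, config.temperament_subscales,
                                       k, spd["temperament"], config.disjointness),
        "character": _plant_features(struct_rng, config.character_subscales,
                                     k, spd["character"], config.disjointness),
        "genotype": _plant_features(struct_rng, config.n_snps,
                                    k, spd["genotype"], config.disjointness),
        "environment": _plant_features(struct_rng, config.n_env_vars,
                                       k, spd["environment"], config.disjointness),
    }
    maf = struct_rng.uniform(config.maf_range[0], config.maf_range[1],
                             size=config.n_snps)
    wiring_cycle = ("direct", "indirect", "both")
    env_wiring = [wiring_cycle[i % 3] for i in range(k * spd["environment"])]

    # optional latent ancestry: per-population allele frequency shifts
    pop_shift = None
    if config.structure_strength > 0:
        pop_shift = struct_rng.normal(0.0, config.structure_strength,
                                      size=(3, config.n_snps))

    # ---- subject stream: network pools and blocks ---------------------------
    order = data_rng.permutation(n)
    n_unassigned = int(round(config.unassigned_fraction * n))
    background = order[:n_unassigned]
    pools = np.array_split(order[n_unassigned:], k)
    labels: list[Optional[int]] = [None] * n
    for g, pool in enumerate(pools, start=1):
        for s in pool:
            labels[s] = g

    def block(pool_part: np.ndarray, frac: float) -> list[int]:
        size = max(2, int(round(frac * len(pool_part))))
        return sorted(int(s) for s in
                      data_rng.choice(pool_part, size=min(size, len(pool_part)),
                                      replace=False))

    bg_shares = np.array_split(background, k)
    planted: list[PlantedSet] = []
    counter = {d: 0 for d in DOMAINS}
    for g in range(1, k + 1):
        pool = pools[g - 1]
        # Subject layout per network: phenotype blocks each cover ~85% of
        # the pool (so network labels are recoverable from phenotype alone);
        # a reserved slice R is excluded from SNP blocks and hosts
        # direct-only environment sets; SNP blocks span the rest of the
        # pool plus a share of the background, whose env co-occurrence
        # realizes indirect (gene-environment) wiring.
        reserve = np.array(block(pool, 0.25))
        non_reserve = pool[~np.isin(pool, reserve)]
        bg_share = bg_shares[g - 1]
        phen_sets_g: list[PlantedSet] = []
        for domain in ("temperament", "character"):
            for net, feats in feat_sets[domain]:
                if net != g:
                    continue
                counter[domain] += 1
                ps = PlantedSet(
                    id=f"true_{domain[0].upper()}{counter[domain]}",
                    domain=domain, subject_idx=block(pool, 0.85),
                    feature_idx=feats, network=g)
                planted.append(ps)
                phen_sets_g.append(ps)
        # every labeled subject carries phenotype signal in >= 1 domain:
        # pool members missed by all phenotype blocks join one at random
        covered = set()
        for ps in phen_sets_g:
            covered.update(ps.subject_idx)
        for s in pool:
            if int(s) not in covered:
                ps = phen_sets_g[int(data_rng.integers(len(phen_sets_g)))]
                ps.subject_idx = sorted(ps.subject_idx + [int(s)])
        snp_blocks: list[list[int]] = []
        for net, feats in feat_sets["genotype"]:
            if net != g:
                continue
            counter["genotype"] += 1
            sb = sorted(set(block(non_reserve, 0.85)) | set(block(bg_share, 0.8)))
            snp_blocks.append(sb)
            planted.append(PlantedSet(
                id=f"true_G{counter['genotype']}", domain="genotype",
                subject_idx=sb, feature_idx=feats, network=g))
        env_sets_g = [(net, feats) for net, feats in feat_sets["environment"] if net == g]
        for i, (net, feats) in enumerate(env_sets_g):
            counter["environment"] += 1
            wiring = env_wiring[counter["environment"] - 1]
            snp_b = np.array(snp_blocks[i % len(snp_blocks)])
            if wiring == "direct":
                subj = block(reserve, 0.8)
            elif wiring == "indirect":
                region = snp_b[np.isin(snp_b, bg_share)]
                subj = block(region, 0.9) if len(region) >= 2 else block(bg_share, 0.8)
            else:  # both
                subj = block(snp_b[np.isin(snp_b, non_reserve)], 0.15)
            planted.append(PlantedSet(
                id=f"true_E{counter['environment']}", domain="environment",
                subject_idx=subj, feature_idx=feats, network=g, wiring=wiring))

    # ---- phenotype matrix ---------------------------------------------------
    shift = np.zeros((n, len(phen_ids)))
    char_offset = len(temp_ids)
    for ps in planted:
        if ps.domain == "temperament":
            shift[np.ix_(ps.subject_idx, ps.feature_idx)] += config.effect_size
        elif ps.domain == "character":
            shift[np.ix_(ps.subject_idx,
                         [f + char_offset for f in ps.feature_idx])] += config.effect_size
    phen_vals = np.clip(
        data_rng.normal(config.baseline_mean + shift, config.noise_sd), 0.0, None
    )

    # ---- genotype matrix ----------------------------------------------------
    freq = np.tile(maf, (n, 1))
    if pop_shift is not None:
        pop_labels = data_rng.integers(0, 3, size=n)
        freq = np.clip(freq + pop_shift[pop_labels], 0.01, 0.99)
    else:
        pop_labels = None
    for ps in planted:
        if ps.domain == "genotype":
            sub = np.ix_(ps.subject_idx, ps.feature_idx)
            freq[sub] = np.clip(freq[sub] + 0.2 * config.effect_size, None, 0.95)
    gen_vals = data_rng.binomial(2, freq).astype(float)

    # ---- environment matrix (ordinal 0..3: graded exposures) ----------------
    env_p = np.full((n, config.n_env_vars), 0.25)
    for ps in planted:
        if ps.domain == "environment":
            env_p[np.ix_(ps.subject_idx, ps.feature_idx)] = 0.85
    env_vals = data_rng.binomial(3, env_p).astype(float)

    # ---- missingness (MCAR) -------------------------------------------------
    if config.missing_rate > 0:
        for vals in (phen_vals, gen_vals, env_vals):
            miss = data_rng.random(vals.shape) < config.missing_rate
            vals[miss] = np.nan

    subj_ids = [f"S{i + 1:05d}" for i in range(n)]
    phenotype = FeatureMatrix(phen_vals, subj_ids, phen_ids, "phenotype", phen_meta)
    genotype = FeatureMatrix(gen_vals, subj_ids, snp_ids, "genotype")
    environment = FeatureMatrix(env_vals, subj_ids, env_ids, "environment")
    truth = SyntheticTruth(
        planted_sets=planted, subject_network_labels=labels, config=config,
        population_labels=[int(x) for x in pop_labels] if pop_labels is not None else None,
    )
    sizes = {"temperament": len(temp_ids), "character": len(char_ids),
             "genotype": config.n_snps, "environment": config.n_env_vars}
    for ps in planted:
        ps.validate(n, sizes[ps.domain])
    return phenotype, genotype, environment, truth


# ---------------------------------------------------------------------------
# truth serialization: a documented JSON schema (structured text)
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    """Write ground truth as JSON: {config, subject_network_labels,
    population_labels, planted_sets: [{id, domain, subject_idx, feature_idx,
    network, wiring}]}."""
    doc = {
        "config": asdict(truth.config),
        "subject_network_labels": truth.subject_network_labels,
        "population_labels": truth.population_labels,
        "planted_sets": [asdict(s) for s in truth.planted_sets],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SyntheticTruth:
    """Read ground truth written by :func:`write_truth` (lossless)."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"malformed truth file {path}: line {e.lineno}, "
                             f"column {e.colno}: {e.msg}") from e
    try:
        cfg_raw = dict(doc["config"])
        cfg_raw["maf_range"] = tuple(cfg_raw["maf_range"])
        config = CohortConfig(**cfg_raw)
        planted = [PlantedSet(**s) for s in doc["planted_sets"]]
        labels = doc["subject_network_labels"]
        pop = doc.get("population_labels")
    except (KeyError, TypeError) as e:
        raise ValueError(f"malformed truth file {path}: {e}") from e
    return SyntheticTruth(planted_sets=planted, subject_network_labels=labels,
                          config=config, population_labels=pop)
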