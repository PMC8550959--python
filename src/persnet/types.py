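"""Shared containers for the set-network pipeline.

The pipeline moves data through a small number of shapes: a subjects x
features matrix (:class:`FeatureMatrix`), biclusters of subjects and
features (:class:`Bicluster` grouped in :class:`SetCollection`), pairwise
shared-subject relations (:class:`Relation` in :class:`RelationGraph`),
and a partition of sets and subjects into near-disjoint networks
(:class:`NetworkPartition`).  Everything downstream (health indices,
variance decomposition, replication matching) consumes these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PHENOTYPE_SCALES = ("NS", "HA", "RD", "PS", "SD", "CO", "ST")
TEMPERAMENT_SCALES = ("NS", "HA", "RD", "PS")
CHARACTER_SCALES = ("SD", "CO", "ST")

#: single-letter prefix used in set ids, per domain
DOMAIN_PREFIX = {
    "temperament": "T",
    "character": "C",
    "phenotype": "P",
    "genotype": "G",
    "environment": "E",
}


class SizingError(ValueError):
    """A requested dimension (rank, set count, block size) is infeasible."""


@dataclass
class FeatureMatrix:
    """Subjects x features numeric matrix with domain metadata.

    Missing cells are ``NaN``.  Genotype matrices hold additive minor/alt
    allele dosages in {0, 1, 2}; phenotype and environment matrices hold
    nonnegative scores.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_ids: list[str]
    domain: str
    feature_scales: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = list(self.subject_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        n, p = self.values.shape
        if n != len(self.subject_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_ids)} features"
            )
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def validate_nonnegative(self) -> None:
        """Raise with the offending cell if any observed entry is negative."""
        neg = np.argwhere(np.nan_to_num(self.values, nan=0.0) < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative value at subject {self.subject_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}: {self.values[i, j]}"
            )

    def validate_genotype(self) -> None:
        v = self.values
        obs = v[~np.isnan(v)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"genotype dosage outside {{0,1,2}}: {bad}")

    def scale_columns(self, scale: str) -> np.ndarray:
        """Column indices belonging to one named scale (e.g. ``"SD"``)."""
        if self.feature_scales is None:
            raise ValueError("feature matrix has no scale metadata")
        return np.array(
            [j for j, f in enumerate(self.feature_ids) if self.feature_scales.get(f) == scale],
            dtype=int,
        )

    def subset_features(self, feature_ids: Sequence[str], domain: Optional[str] = None) -> "FeatureMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        scales = None
        if self.feature_scales is not None:
            scales = {f: self.feature_scales[f] for f in feature_ids}
        return FeatureMatrix(
            self.values[:, idx], self.subject_ids, list(feature_ids),
            domain or self.domain, scales,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_ids)
        df.index.name = "subject"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, domain: str,
                   feature_scales: Optional[dict[str, str]] = None) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index],
                   [str(c) for c in df.columns], domain, feature_scales)


@dataclass
class Bicluster:
    """One set: a subject subset plus a feature subset with weights.

    Ids follow the ``<prefix>_<rank>_<factor>`` convention, e.g. ``C_14_7``
    is the 7th factor of the rank-14 factorization of the character matrix.
    """

    id: str
    domain: str
    subject_ids: list[str]
    feature_ids: list[str]
    subject_weights: np.ndarray
    feature_weights: np.ndarray
    rank: int
    factor_index: int

    def __post_init__(self) -> None:
        if not self.subject_ids or not self.feature_ids:
            raise ValueError(f"bicluster {self.id} has an empty axis")
        self.subject_weights = np.asarray(self.subject_weights, dtype=float)
        self.feature_weights = np.asarray(self.feature_weights, dtype=float)
        if len(self.subject_weights) != len(self.subject_ids):
            raise ValueError("subject weights length mismatch")
        if len(self.feature_weights) != len(self.feature_ids):
            raise ValueError("feature weights length mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class SetCollection:
    """All biclusters extracted from one domain, over one cohort."""

    biclusters: list[Bicluster]
    subject_universe: list[str]
    domain: str
    ranks_used: list[int] = field(default_factory=list)
    cophenetic: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [b.id for b in self.biclusters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate bicluster ids in collection")
        universe = set(self.subject_universe)
        for b in self.biclusters:
            missing = set(b.subject_ids) - universe
            if missing:
                raise ValueError(f"bicluster {b.id} references unknown subjects {sorted(missing)[:3]}")
        for v in self.cophenetic.values():
            if not (-1.0 - 1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"cophenetic value {v} outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.biclusters)

    @property
    def ids(self) -> list[str]:
        return [b.id for b in self.biclusters]

    @property
    def cohort_size(self) -> int:
        return len(self.subject_universe)

    def get(self, set_id: str) -> Bicluster:
        for b in self.biclusters:
            if b.id == set_id:
                return b
        raise KeyError(set_id)

    def membership_matrix(self) -> np.ndarray:
        """(n_sets, cohort_size) boolean indicator of subject membership."""
        index = {s: i for i, s in enumerate(self.subject_universe)}
        M = np.zeros((len(self.biclusters), len(self.subject_universe)), dtype=bool)
        for r, b in enumerate(self.biclusters):
            M[r, [index[s] for s in b.subject_ids]] = True
        return M

    def weight_matrix(self) -> np.ndarray:
        """(n_sets, cohort_size) membership weights, max-normalized per set."""
        index = {s: i for i, s in enumerate(self.subject_universe)}
        W = np.zeros((len(self.biclusters), len(self.subject_universe)))
        for r, b in enumerate(self.biclusters):
            w = b.subject_weights
            top = w.max() if w.size and w.max() > 0 else 1.0
            W[r, [index[s] for s in b.subject_ids]] = w / top
        return W

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.biclusters:
            rows.append({
                "id": b.id, "domain": b.domain, "rank": b.rank,
                "factor": b.factor_index,
                "subjects": ";".join(b.subject_ids),
                "features": ";".join(b.feature_ids),
                "subject_weights": ";".join(f"{w:.6g}" for w in b.subject_weights),
                "feature_weights": ";".join(f"{w:.6g}" for w in b.feature_weights),
            })
        return pd.DataFrame(rows, columns=["id", "domain", "rank", "factor",
                                           "subjects", "features",
                                           "subject_weights", "feature_weights"])


@dataclass
class ProfileAssignment:
    """Deep clustering of sets into profiles (e.g. 5 character profiles)."""

    labels: dict[str, int]
    centroids: np.ndarray
    feature_ids: list[str]


@dataclass
class Relation:
    """A significant (or tested) pair of sets sharing subjects."""

    source: str
    target: str
    overlap: int
    n_source: int
    n_target: int
    cohort_size: int
    p_hypergeom: float
    p_fisher: float
    p_empirical: float
    q_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.overlap <= min(self.n_source, self.n_target)):
            raise ValueError("overlap exceeds a margin")
        for p in (self.p_hypergeom, self.p_fisher, self.p_empirical):
            if not (0.0 <= p <= 1.0 + 1e-12):
                raise ValueError(f"p-value {p} outside [0, 1]")


@dataclass
class RelationGraph:
    """All tested pairs between a source and a target collection."""

    relations: list[Relation]
    source_collection: SetCollection
    target_collection: SetCollection
    alpha: float
    correction: str
    n_perm: int
    perm_alpha: float
    seed: int

    def __post_init__(self) -> None:
        pairs = [(r.source, r.target) for r in self.relations]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (source, target) relation pairs")

    @property
    def significant(self) -> list[Relation]:
        return [r for r in self.relations if r.significant]

    def to_frame(self, significant_only: bool = False) -> pd.DataFrame:
        rels = self.significant if significant_only else self.relations
        return pd.DataFrame(
            [{
                "source": r.source, "target": r.target, "overlap": r.overlap,
                "n_source": r.n_source, "n_target": r.n_target,
                "p_hypergeom": r.p_hypergeom, "p_fisher": r.p_fisher,
                "p_empirical": r.p_empirical, "q_value": r.q_value,
                "significant": r.significant,
            } for r in rels],
            columns=["source", "target", "overlap", "n_source", "n_target",
                     "p_hypergeom", "p_fisher", "p_empirical", "q_value",
                     "significant"],
        )


@dataclass
class NetworkPartition:
    """Assignment of sets and subjects into k near-disjoint networks.

    Network labels are 1..k.  After :func:`persnet.networks.order_networks`
    the labels are ordered by ascending mean well-being of their assigned
    subjects (1 = lowest well-being).  Subject label ``None`` = unassigned.
    """

    k: int
    set_networks: dict[str, int]
    subject_networks: dict[str, Optional[int]] = field(default_factory=dict)
    ordered_by_wellbeing: bool = False
    unassigned_fraction: float = float("nan")
    disjointness: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, g in self.set_networks.items():
            if not (1 <= g <= self.k):
                raise ValueError(f"set {sid} has label {g} outside 1..{self.k}")

    def network_subjects(self, g: int) -> list[str]:
        return [s for s, lab in self.subject_networks.items() if lab == g]

    def network_sizes(self) -> dict[int, int]:
        sizes = {g: 0 for g in range(1, self.k + 1)}
        for lab in self.subject_networks.values():
            if lab is not None:
                sizes[lab] += 1
        return sizes


@dataclass
class HealthIndices:
    """Decile-based well-being and ill-being flags per subject.

    Well-being is the top decile of the product of the three character
    scale totals (SD x CO x ST); ill-being is the bottom decile of the sum
    SD + CO.  Flags use the strict-quantile rule: only scores strictly
    beyond the k-th order-statistic cutpoint are flagged, so an all-ties
    cohort flags nobody.
    """

    subject_ids: list[str]
    product_score: np.ndarray
    sum_score: np.ndarray
    well_flag: np.ndarray
    ill_flag: np.ndarray
    well_cutpoint: float
    ill_cutpoint: float

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for arr in (self.product_score, self.sum_score, self.well_flag, self.ill_flag):
            if len(arr) != n:
                raise ValueError("health index arrays must match subject count")

    @property
    def overlap_fraction(self) -> float:
        """Fraction of subjects flagged for both well- and ill-being."""
        n = len(self.subject_ids)
        return float((self.well_flag & self.ill_flag).sum() / n) if n else 0.0

    def flags(self, outcome: str) -> np.ndarray:
        if outcome == "well":
            return self.well_flag
        if outcome == "ill":
            return self.ill_flag
        raise ValueError(f"unknown outcome {outcome!r} (use 'well' or 'ill')")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject_ids,
            "product_score": self.product_score,
            "sum_score": self.sum_score,
            "well_flag": self.well_flag.astype(int),
            "ill_flag": self.ill_flag.astype(int),
        })


@dataclass
class HealthComparison:
    """One-way ANOVA + Tukey HSD across networks on health probabilities."""

    outcome: str
    level: str
    group_means: dict[int, float]
    group_sds: dict[int, float]
    group_ns: dict[int, int]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey_pvalues: dict[tuple[int, int], float]
    zero_within_variance: bool = False


@dataclass
class AncestryStrata:
    """Leading genotype principal components and derived strata."""

    subject_ids: list[str]
    pc_scores: np.ndarray
    stratum_labels: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.pc_scores).all():
            raise ValueError("PC scores must be finite")
        if len(self.stratum_labels) != len(self.subject_ids):
            raise ValueError("stratum labels must cover all subjects")


@dataclass
class VarianceReport:
    """Cross-validated R^2 of genotype / environment / joint OLS models."""

    outcome: str
    r2_genotype: float
    r2_environment: float
    r2_joint: float
    fold_r2: dict[str, list[float]]
    folds: int
    seed: int
    n_imputed: dict[str, int] = field(default_factory=dict)
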