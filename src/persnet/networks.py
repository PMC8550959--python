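"""Partition the bipartite temperament-character relation graph into
near-disjoint networks and assign subjects.

The significant relations form a weighted source x target matrix (default
weight: -log10 hypergeometric p, capped).  NMF of that matrix at rank k
(default 3) gives each source and target set a maximal factor = network.
Subjects inherit the network holding the weighted plurality of their set
memberships; subjects in no set, or whose majority network holds no more
than half their total membership weight, stay unassigned.  Networks are
finally renamed 1..k by ascending mean well-being of their subjects.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import nmf
from .types import (
    HealthIndices,
    NetworkPartition,
    RelationGraph,
    SetCollection,
    SizingError,
)


def build_relation_matrix(
    g: RelationGraph,
    weighting: str = "neglog10",
    cap: float = 300.0,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Significant relations as a (source sets x target sets) weight matrix.

    Weight options: ``"neglog10"`` (-log10 of the hypergeometric p, capped
    at ``cap``), ``"overlap"`` (shared-subject count), ``"binary"``.
    Nonsignificant pairs are zero.
    """
    src_ids = g.source_collection.ids
    tgt_ids = g.target_collection.ids
    si = {s: i for i, s in enumerate(src_ids)}
    ti = {t: i for i, t in enumerate(tgt_ids)}
    M = np.zeros((len(src_ids), len(tgt_ids)))
    for r in g.significant:
        if weighting == "neglog10":
            w = cap if r.p_hypergeom <= 10.0 ** (-cap) else min(cap, -np.log10(r.p_hypergeom))
        elif weighting == "overlap":
            w = float(r.overlap)
        elif weighting == "binary":
            w = 1.0
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        M[si[r.source], ti[r.target]] = w
    if not M.any():
        raise ValueError("no significant relations: nothing to partition")
    return M, src_ids, tgt_ids


def partition_networks(
    M: np.ndarray,
    src_ids: Sequence[str],
    tgt_ids: Sequence[str],
    k: int = 3,
    seed: int = 0,
) -> NetworkPartition:
    """NMF of the relation matrix at rank k; each set joins its maximal factor.

    Labels come out as provisional 1..k; use :func:`order_networks` to
    rename them by mean well-being once subjects are assigned.  Sets with
    no significant relation (all-zero row/column) take part in no
    network: they are left unlabeled so they cannot pull their subjects
    toward an arbitrary factor.
    """
    M = np.asarray(M, dtype=float)
    if (M < 0).any():
        raise ValueError("relation matrix must be nonnegative")
    if k < 2:
        raise SizingError("need k >= 2 networks")
    if k > min(M.shape):
        raise SizingError(f"k={k} exceeds relation matrix rank bound {min(M.shape)}")
    fp = nmf.factorize(M, k, seed=seed, init="nndsvd")
    set_networks: dict[str, int] = {}
    for i, s in enumerate(src_ids):
        if M[i].any():
            set_networks[s] = int(np.argmax(fp.W[i]) + 1)
    for j, t in enumerate(tgt_ids):
        if M[:, j].any():
            set_networks[t] = int(np.argmax(fp.H[:, j]) + 1)
    return NetworkPartition(k=k, set_networks=set_networks)


def assign_subjects(
    p: NetworkPartition,
    collections: Sequence[SetCollection],
    min_membership: float = 0.5,
    min_support_frac: float = 0.25,
) -> NetworkPartition:
    """Assign each subject to the weighted plurality network of its sets.

    A subject's membership weight in a network is the sum of its
    (max-normalized) loadings over the network's sets, across all given
    collections.  Assignment requires (a) the majority network to hold
    strictly more than ``min_membership`` of the subject's total weight,
    and (b) the total weight to exceed ``min_support_frac`` times the
    median total weight of all in-set subjects.  The default quarter of
    the median corresponds to about half of one domain's typical
    cross-rank membership streak (set copies accumulate over ranks, and
    membership spans two phenotype domains): a scale-free threshold of
    significant association that keeps subjects brushed by one or two
    stray sets out of the networks without dropping genuine members
    captured in a single domain.  Otherwise the subject is unassigned.
    Ties break toward larger total weight, then the lower network index.
    """
    universe = collections[0].subject_universe
    for sc in collections[1:]:
        if sc.subject_universe != universe:
            raise ValueError("collections indexed over different cohorts")
    n = len(universe)
    weight = np.zeros((n, p.k))
    for sc in collections:
        W = sc.weight_matrix()
        for r, b in enumerate(sc.biclusters):
            g = p.set_networks.get(b.id)
            if g is not None:
                weight[:, g - 1] += W[r]
    totals = weight.sum(axis=1)
    in_set = totals > 0
    support_floor = (min_support_frac * float(np.median(totals[in_set]))
                     if in_set.any() else 0.0)
    subject_networks: dict[str, Optional[int]] = {}
    for i, s in enumerate(universe):
        if totals[i] <= 0 or totals[i] <= support_floor:
            subject_networks[s] = None
            continue
        best = int(np.argmax(weight[i]))  # argmax takes the lowest index on ties
        if weight[i, best] / totals[i] > min_membership:
            subject_networks[s] = best + 1
        else:
            subject_networks[s] = None
    p.subject_networks = subject_networks
    p.unassigned_fraction = sum(v is None for v in subject_networks.values()) / n
    return p


def order_networks(p: NetworkPartition, health: HealthIndices) -> NetworkPartition:
    """Rename networks 1..k by ascending mean well-being of their subjects.

    The renaming is a permutation of 1..k, so it is invariant to the
    arbitrary ordering of the NMF factors.  Networks with no assigned
    subjects sort first (mean taken as -inf).
    """
    if not p.subject_networks:
        raise ValueError("assign subjects before ordering networks")
    widx = {s: i for i, s in enumerate(health.subject_ids)}
    means = {}
    for g in range(1, p.k + 1):
        members = [widx[s] for s in p.network_subjects(g) if s in widx]
        means[g] = float(np.mean(health.well_flag[members])) if members else -np.inf
    order = sorted(range(1, p.k + 1), key=lambda g: (means[g], g))
    remap = {old: new + 1 for new, old in enumerate(order)}
    p.set_networks = {s: remap[g] for s, g in p.set_networks.items()}
    p.subject_networks = {
        s: (remap[g] if g is not None else None) for s, g in p.subject_networks.items()
    }
    p.ordered_by_wellbeing = True
    return p


def disjointness_stats(
    network_members: dict[str, set[int]],
    collections: Sequence[SetCollection],
    k: int,
) -> dict[str, dict[tuple[int, int], dict[str, float]]]:
    """Pairwise percentage of sets and subjects shared between networks.

    ``network_members`` maps set id -> set of network labels (a single
    label for a hard partition; possibly several for association flags).
    For each domain and each network pair (g, h), the shared-set
    percentage is 100 x |sets in both| / |sets in the domain associated
    with any network|, and likewise for subjects via set membership.
    """
    out: dict[str, dict[tuple[int, int], dict[str, float]]] = {}
    for sc in collections:
        set_nets = {b.id: network_members.get(b.id, set()) for b in sc.biclusters}
        assoc_sets = [sid for sid, gs in set_nets.items() if gs]
        subj_nets: dict[str, set[int]] = {}
        for b in sc.biclusters:
            for s in b.subject_ids:
                subj_nets.setdefault(s, set()).update(set_nets[b.id])
        assoc_subj = [s for s, gs in subj_nets.items() if gs]
        pairs: dict[tuple[int, int], dict[str, float]] = {}
        for g in range(1, k + 1):
            for h in range(g + 1, k + 1):
                shared_sets = sum(1 for sid in assoc_sets
                                  if {g, h} <= set_nets[sid])
                shared_subj = sum(1 for s in assoc_subj if {g, h} <= subj_nets[s])
                pairs[(g, h)] = {
                    "sets_pct": 100.0 * shared_sets / len(assoc_sets) if assoc_sets else 0.0,
                    "subjects_pct": 100.0 * shared_subj / len(assoc_subj) if assoc_subj else 0.0,
                }
        out[sc.domain] = pairs
    return out


def partition_disjointness(
    p: NetworkPartition, collections: Sequence[SetCollection]
) -> dict:
    """Disjointness of a hard partition (sets single-labeled; subjects may
    sit in sets of several networks)."""
    members = {sid: {g} for sid, g in p.set_networks.items()}
    stats = disjointness_stats(members, collections, p.k)
    p.disjointness = {
        dom: {f"{g}-{h}": v for (g, h), v in pairs.items()}
        for dom, pairs in stats.items()
    }
    return p.disjointness
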