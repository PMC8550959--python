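"""Well-being and ill-being indices, network health comparisons, surfaces.

The two indices follow the character-scale convention: ill-being is the
bottom decile of the sum of the Self-directedness and Cooperativeness
scale totals; well-being is the top decile of the product of all three
character scale totals (SD x CO x ST).  Scale totals are the sums of the
scale's subscale columns.  Decile flags use a strict-quantile rule: with
k = ceil(0.1 n), the cutpoint is the (k+1)-th extreme order statistic and
only scores strictly beyond it are flagged — distinct scores flag exactly
k subjects, an all-ties cohort flags nobody, and ties at the boundary
flag fewer than k (never more).
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .relations import overlap_pvalue
from .types import (
    Bicluster,
    CHARACTER_SCALES,
    FeatureMatrix,
    HealthComparison,
    HealthIndices,
    NetworkPartition,
    RelationGraph,
    SetCollection,
)


def _scale_total(phen: FeatureMatrix, scale: str) -> np.ndarray:
    cols = phen.scale_columns(scale)
    if cols.size == 0:
        raise ValueError(f"phenotype matrix has no {scale} subscale columns")
    block = phen.values[:, cols]
    # mean-impute missing subscale cells so a sparse NA cannot zero a total
    col_means = np.nanmean(block, axis=0)
    block = np.where(np.isnan(block), col_means, block)
    return block.sum(axis=1)


def _decile_flags(scores: np.ndarray, tail: str) -> tuple[np.ndarray, float]:
    """Strict-quantile decile flags; returns (flags, cutpoint)."""
    n = len(scores)
    k = math.ceil(0.1 * n)
    s = np.sort(scores)
    if tail == "top":
        cut = s[n - k - 1] if n - k - 1 >= 0 else -np.inf
        return scores > cut, float(cut)
    cut = s[k] if k < n else np.inf
    return scores < cut, float(cut)


def compute_indices(phen: FeatureMatrix) -> HealthIndices:
    """Decile well-being / ill-being flags from the character scale totals."""
    if phen.feature_scales is None:
        raise ValueError("phenotype matrix lacks scale metadata (need SD/CO/ST)")
    totals = {sc: _scale_total(phen, sc) for sc in CHARACTER_SCALES}
    product = totals["SD"] * totals["CO"] * totals["ST"]
    total_sum = totals["SD"] + totals["CO"]
    well, well_cut = _decile_flags(product, "top")
    ill, ill_cut = _decile_flags(total_sum, "bottom")
    return HealthIndices(
        subject_ids=list(phen.subject_ids),
        product_score=product, sum_score=total_sum,
        well_flag=well, ill_flag=ill,
        well_cutpoint=well_cut, ill_cutpoint=ill_cut,
    )


def set_health_probability(s: Bicluster, h: HealthIndices) -> tuple[float, float]:
    """Fraction of a set's members flagged for well-being and ill-being."""
    idx = {sid: i for i, sid in enumerate(h.subject_ids)}
    members = [idx[x] for x in s.subject_ids]
    if not members:
        raise ValueError(f"set {s.id} is empty")
    return (float(h.well_flag[members].mean()), float(h.ill_flag[members].mean()))


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, int, int, float, bool]:
    """Textbook one-way ANOVA: (F, df_between, df_within, p, zero_within).

    With zero within-group variance the F statistic is infinite; it is
    reported as computed (inf) with the degenerate case flagged.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    ns = [len(g) for g in groups]
    if any(n < 1 for n in ns) or len(groups) < 2:
        raise ValueError("need >= 2 nonempty groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups))
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = sum(ns) - len(groups)
    if dfw <= 0:
        raise ValueError("no within-group degrees of freedom")
    msw = ssw / dfw
    if msw == 0.0:
        return float("inf"), dfb, dfw, 0.0, True
    f = (ssb / dfb) / msw
    p = float(stats.f.sf(f, dfb, dfw))
    return float(f), dfb, dfw, p, False


def compare_networks(
    p: NetworkPartition,
    h: HealthIndices,
    collections: Sequence[SetCollection],
    outcome: str = "well",
    level: str = "sets",
) -> HealthComparison:
    """ANOVA + Tukey HSD of health probabilities across networks.

    ``level="sets"`` compares the set-level flagged fractions of each
    network's member sets; ``level="subjects"`` compares the subject flags
    directly.  Networks contributing fewer than 2 observations are dropped
    with a warning.
    """
    if outcome not in ("well", "ill"):
        raise ValueError("outcome must be 'well' or 'ill'")
    groups: dict[int, list[float]] = {g: [] for g in range(1, p.k + 1)}
    if level == "sets":
        for sc in collections:
            for b in sc.biclusters:
                g = p.set_networks.get(b.id)
                if g is None:
                    continue
                pw, pi = set_health_probability(b, h)
                groups[g].append(pw if outcome == "well" else pi)
    elif level == "subjects":
        flags = h.flags(outcome)
        idx = {sid: i for i, sid in enumerate(h.subject_ids)}
        for s, g in p.subject_networks.items():
            if g is not None:
                groups[g].append(float(flags[idx[s]]))
    else:
        raise ValueError("level must be 'sets' or 'subjects'")

    kept = {g: np.asarray(v) for g, v in groups.items() if len(v) >= 2}
    dropped = set(groups) - set(kept)
    if dropped:
        warnings.warn(f"networks {sorted(dropped)} dropped (<2 observations)")
    if len(kept) < 2:
        raise ValueError("fewer than 2 networks with >= 2 observations")
    labels = sorted(kept)
    f, dfb, dfw, pval, zero_var = anova_oneway([kept[g] for g in labels])
    tukey: dict[tuple[int, int], float] = {}
    if not zero_var:
        res = stats.tukey_hsd(*[kept[g] for g in labels])
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                tukey[(labels[a], labels[b])] = float(res.pvalue[a, b])
    else:
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                tukey[(labels[a], labels[b])] = 0.0
    return HealthComparison(
        outcome=outcome, level=level,
        group_means={g: float(kept[g].mean()) for g in labels},
        group_sds={g: float(kept[g].std(ddof=1)) for g in labels},
        group_ns={g: int(len(kept[g])) for g in labels},
        f_statistic=f, df_between=dfb, df_within=dfw, p_value=pval,
        tukey_pvalues=tukey, zero_within_variance=zero_var,
    )


def _cluster_order(sc_sets: list[Bicluster], cohort_size: int) -> list[int]:
    """Order sets by average-linkage clustering of -log10 overlap p."""
    m = len(sc_sets)
    if m <= 2:
        return list(range(m))
    members = [set(b.subject_ids) for b in sc_sets]
    sim = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ov = len(members[i] & members[j])
            pv = overlap_pvalue(ov, len(members[i]), len(members[j]), cohort_size)
            sim[i, j] = sim[j, i] = min(300.0, -np.log10(max(pv, 1e-300)))
    dist = sim.max() - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return [int(i) for i in leaves_list(Z)]


def health_surface(
    g: RelationGraph,
    h: HealthIndices,
    outcome: str = "well",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Ordered matrix of per-relation health probabilities.

    Rows are the source (character) sets and columns the target
    (temperament) sets participating in significant relations, both
    ordered by average-linkage clustering of their pairwise shared-subject
    enrichment.  Each significant cell holds the flagged fraction of the
    relation's subject intersection; non-significant cells are NaN
    (absent — interpolation is a rendering concern).
    """
    sig = g.significant
    if not sig:
        raise ValueError("graph has no significant relations")
    src_ids = sorted({r.source for r in sig})
    tgt_ids = sorted({r.target for r in sig})
    src_sets = [g.source_collection.get(s) for s in src_ids]
    tgt_sets = [g.target_collection.get(t) for t in tgt_ids]
    N = g.source_collection.cohort_size
    row_order = _cluster_order(src_sets, N)
    col_order = _cluster_order(tgt_sets, N)
    rows = [src_ids[i] for i in row_order]
    cols = [tgt_ids[j] for j in col_order]
    ri = {s: i for i, s in enumerate(rows)}
    ci = {t: j for j, t in enumerate(cols)}
    flags = h.flags(outcome)
    idx = {sid: i for i, sid in enumerate(h.subject_ids)}
    M = np.full((len(rows), len(cols)), np.nan)
    src_members = {b.id: set(b.subject_ids) for b in src_sets}
    tgt_members = {b.id: set(b.subject_ids) for b in tgt_sets}
    for r in sig:
        inter = src_members[r.source] & tgt_members[r.target]
        if inter:
            M[ri[r.source], ci[r.target]] = float(
                np.mean([flags[idx[s]] for s in inter])
            )
    return M, rows, cols
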