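"""Shared-subject relations between two set collections.

Each pair (source set, target set) is scored by the exact upper-tail
hypergeometric probability of its subject overlap, a two-sided Fisher
exact p, and an empirical permutation p obtained by permuting subject
identities (whole sets preserved).  A relation is called significant only
when the analytic test survives the configured multiplicity correction AND
the permutation p clears the empirical threshold — the dual criterion the
analysis reports for every association.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .types import Relation, RelationGraph, SetCollection


def overlap_pvalue(overlap: int, n_source: int, n_target: int, cohort_size: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= overlap).

    X is the overlap of a random ``n_target``-subset with a fixed
    ``n_source``-subset of a cohort.  The tail is summed in log space so
    extreme tails (p ~ 1e-300) keep full relative accuracy.
    """
    overlap, n_source, n_target, cohort_size = map(int, (overlap, n_source, n_target, cohort_size))
    if min(overlap, n_source, n_target, cohort_size) < 0:
        raise ValueError("counts must be nonnegative")
    if n_source > cohort_size or n_target > cohort_size:
        raise ValueError("set larger than cohort")
    if overlap > min(n_source, n_target):
        raise ValueError(f"overlap {overlap} exceeds min margin {min(n_source, n_target)}")
    lo = max(overlap, n_source + n_target - cohort_size)
    hi = min(n_source, n_target)
    if lo > hi:
        return 1.0 if overlap <= max(0, n_source + n_target - cohort_size) else 0.0
    support = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(support, cohort_size, n_source, n_target)
    return float(min(1.0, np.exp(logsumexp(logp))))


def fisher_pvalue(table, exact_max_n: int = 1000) -> float:
    """Two-sided Fisher exact probability of a 2x2 count table.

    The two-sided p is the sum of probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.  Tables up to ``exact_max_n`` total count are summed in
    exact rational arithmetic (so ties are handled exactly); larger
    tables fall back to scipy's implementation.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be nonnegative integers")
    a, b = int(round(t[0, 0])), int(round(t[0, 1]))
    c, d = int(round(t[1, 0])), int(round(t[1, 1]))
    n = a + b + c + d
    if n == 0:
        return 1.0
    if n > exact_max_n:
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    from fractions import Fraction
    from math import comb

    # all tables with these margins share the denominator C(n, c1), so
    # probability comparisons reduce to exact integer comparisons
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    nums = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    num_obs = nums[a - lo]
    return float(min(1, Fraction(sum(m for m in nums if m <= num_obs), denom)))


def _overlap_counts(A_ind: np.ndarray, B_ind: np.ndarray) -> np.ndarray:
    return (A_ind.astype(np.float32) @ B_ind.astype(np.float32).T).astype(np.int64)


def _permute_within_strata(rng: np.random.Generator, n: int,
                           strata: Optional[np.ndarray]) -> np.ndarray:
    if strata is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for g in np.unique(strata):
        idx = np.flatnonzero(strata == g)
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


def permutation_null(
    A: SetCollection,
    B: SetCollection,
    n_perm: int = 1999,
    seed: int = 0,
    strata: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Empirical upper-tail p of every pairwise overlap, by permutation.

    Subject identities on B's side are permuted as whole sets (set sizes
    preserved) ``n_perm`` times; p = (1 + #{perm >= observed}) / (1 + n_perm)
    with the add-one correction, so p can never be 0.  With ``strata``
    given, permutation is restricted to within-stratum swaps.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    if A.subject_universe != B.subject_universe:
        raise ValueError("collections must share one cohort")
    A_ind = A.membership_matrix().astype(np.float32)
    B_ind = B.membership_matrix().astype(np.float32)
    observed = (A_ind @ B_ind.T).astype(np.int64)
    rng = np.random.default_rng(seed)
    n = A_ind.shape[1]
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = _permute_within_strata(rng, n, strata)
        ov = (A_ind @ B_ind[:, perm].T).astype(np.int64)
        exceed += ov >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def relate_collections(
    A: SetCollection,
    B: SetCollection,
    alpha: float = 0.05,
    correction: str = "bh",
    n_perm: int = 1999,
    perm_alpha: Optional[float] = None,
    seed: int = 0,
    strata: Optional[np.ndarray] = None,
    min_overlap: int = 0,
) -> RelationGraph:
    """Test all source x target pairs for shared-subject enrichment.

    ``correction`` is ``"bh"`` (Benjamini-Hochberg FDR over all pairs, the
    default) or ``"raw"`` (compare the uncorrected hypergeometric p with
    ``alpha``, e.g. alpha = 1e-5).  Significance additionally requires the
    empirical permutation p <= ``perm_alpha``.  When ``perm_alpha`` is
    None it defaults to max(5e-4, 1/(1+n_perm)): the 5e-4 working
    threshold, never tighter than the add-one floor the permutation count
    can attain (with the default 1999 permutations the floor IS 5e-4).
    """
    if A.subject_universe != B.subject_universe:
        raise ValueError("collections are indexed over different cohorts")
    if correction not in ("bh", "raw"):
        raise ValueError(f"unknown correction {correction!r}")
    if perm_alpha is None:
        perm_alpha = max(5e-4, 1.0 / (1.0 + n_perm))
    elif n_perm < 1.0 / perm_alpha - 1:
        warnings.warn(
            f"n_perm={n_perm} cannot attain permutation threshold {perm_alpha}"
        )
    N = A.cohort_size
    A_ind = A.membership_matrix()
    B_ind = B.membership_matrix()
    sizes_a = A_ind.sum(axis=1)
    sizes_b = B_ind.sum(axis=1)
    overlaps = _overlap_counts(A_ind, B_ind)

    p_hyper = np.ones_like(overlaps, dtype=float)
    p_fish = np.ones_like(overlaps, dtype=float)
    for i in range(overlaps.shape[0]):
        for j in range(overlaps.shape[1]):
            ov, na, nb = int(overlaps[i, j]), int(sizes_a[i]), int(sizes_b[j])
            p_hyper[i, j] = overlap_pvalue(ov, na, nb, N)
            p_fish[i, j] = fisher_pvalue(
                [[ov, na - ov], [nb - ov, N - na - nb + ov]]
            )
    if correction == "bh":
        q = stats.false_discovery_control(p_hyper.ravel(), method="bh").reshape(p_hyper.shape)
    else:
        q = p_hyper.copy()
    p_emp = permutation_null(A, B, n_perm=n_perm, seed=seed, strata=strata)

    relations = []
    for i, a in enumerate(A.biclusters):
        for j, b in enumerate(B.biclusters):
            sig = bool(
                q[i, j] <= alpha
                and p_emp[i, j] <= perm_alpha
                and overlaps[i, j] >= max(min_overlap, 1)
            )
            relations.append(Relation(
                source=a.id, target=b.id, overlap=int(overlaps[i, j]),
                n_source=int(sizes_a[i]), n_target=int(sizes_b[j]),
                cohort_size=N, p_hypergeom=float(p_hyper[i, j]),
                p_fisher=float(p_fish[i, j]), p_empirical=float(p_emp[i, j]),
                q_value=float(q[i, j]), significant=sig,
            ))
    relations.sort(key=lambda r: (r.p_hypergeom, r.source, r.target))
    return RelationGraph(
        relations=relations, source_collection=A, target_collection=B,
        alpha=alpha, correction=correction, n_perm=n_perm,
        perm_alpha=perm_alpha, seed=seed,
    )
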