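"""Nonnegative matrix factorization biclustering with consensus rank selection.

The factorizer uses multiplicative updates on the Frobenius objective with a
0/1 observation mask, so missing cells never contribute to the objective or
the updates.  Initialization is either deterministic NNDSVD (for the
reproducible extraction path) or seeded random uniform (for the stochastic
consensus runs that rank selection needs).

Rank selection follows consensus-clustering practice: for each candidate
rank k, several random-start factorizations produce a subject x subject
consensus matrix (fraction of runs in which two subjects share a dominant
factor); the cophenetic correlation between consensus dissimilarity and its
average-linkage hierarchical clustering scores the stability of k.  Ranks
within a margin of the best cophenetic value are retained, and biclusters
are additionally accumulated across the whole rank range so that fine
structure at several granularities survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .types import (
    Bicluster,
    DOMAIN_PREFIX,
    FeatureMatrix,
    ProfileAssignment,
    SetCollection,
    SizingError,
)

_EPS = 1e-10


@dataclass
class FactorPair:
    """One NMF solution: nonnegative W (subjects x k) and H (k x features)."""

    W: np.ndarray
    H: np.ndarray
    k: int
    objective_trace: list[float]
    seed: int
    init: str

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("factor entries must be nonnegative")

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def _nndsvd(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization (zeros kept, no random fill).

    Singular vector signs are canonicalized (largest-magnitude entry of each
    left vector made positive) so the init — and hence the whole
    deterministic path — is equivariant under subject permutation.
    """
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(min(k, len(S))):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    n, p = X.shape
    W = np.zeros((n, k))
    H = np.zeros((k, p))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        nup, nvp, nun, nvn = map(np.linalg.norm, (up, vp, un, vn))
        if nup * nvp >= nun * nvn:
            sigma, a, b = nup * nvp, up / max(nup, _EPS), vp / max(nvp, _EPS)
        else:
            sigma, a, b = nun * nvn, un / max(nun, _EPS), vn / max(nvn, _EPS)
        W[:, j] = np.sqrt(S[j] * sigma) * a
        H[j] = np.sqrt(S[j] * sigma) * b
    return W, H


def factorize(
    X: FeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: str = "nndsvd",
) -> FactorPair:
    """Factorize a nonnegative matrix at rank ``k`` by multiplicative updates.

    Missing (NaN) cells are excluded from both the objective and the
    updates via a 0/1 mask.  The Frobenius objective over observed cells is
    recorded at every iteration and is non-increasing (up to numerical
    epsilon).  Stops when the relative objective change drops below ``tol``.
    """
    A = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValueError("input must be 2-D")
    n, p = A.shape
    if not (1 <= k <= min(n, p)):
        raise SizingError(f"rank {k} outside 1..{min(n, p)} for a {n}x{p} matrix")
    mask = ~np.isnan(A)
    neg = np.argwhere(np.where(mask, A, 0.0) < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(f"negative input at cell ({i}, {j}): {A[i, j]}")
    Xf = np.where(mask, A, 0.0)

    if not Xf.any():  # identically zero input
        return FactorPair(np.zeros((n, k)), np.zeros((k, p)), k, [0.0], seed, init)

    if init == "nndsvd":
        W, H = _nndsvd(Xf, k)
        # NNDSVD leaves exact zeros which multiplicative updates can never
        # move; nudge them so every factor stays live.
        tiny = Xf[mask].mean() * 1e-6
        W[W < tiny] = tiny
        H[H < tiny] = tiny
    elif init == "kmeans":
        # subject-cluster indicator init: targets block structure that the
        # Frobenius-optimal dense solutions tend to merge
        from sklearn.cluster import KMeans

        imputed = np.where(mask, A, Xf[mask].mean())
        km = KMeans(n_clusters=k, random_state=seed % (2**31), n_init=10)
        labels = km.fit_predict(imputed)
        tiny = Xf[mask].mean() * 1e-4
        W = np.full((n, k), tiny)
        W[np.arange(n), labels] = 1.0
        H = np.maximum(km.cluster_centers_, tiny)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(Xf[mask].mean() / k)
        W = rng.uniform(_EPS, scale, size=(n, k))
        H = rng.uniform(_EPS, scale, size=(k, p))
    else:
        raise ValueError(f"unknown init {init!r}")

    full = mask.all()
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H
        R = WH if full else mask * WH
        H *= (W.T @ Xf) / (W.T @ R + _EPS)
        WH = W @ H
        R = WH if full else mask * WH
        W *= (Xf @ H.T) / (R @ H.T + _EPS)
        WH = W @ H
        obj = float(np.linalg.norm(np.where(mask, A - WH, 0.0)))
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, _EPS):
            break
        prev = obj
    return FactorPair(W, H, k, trace, seed, init)


def _dominant_labels(fp: FactorPair) -> np.ndarray:
    return np.argmax(fp.W, axis=1)


def _otsu_mask(col: np.ndarray) -> np.ndarray:
    """Bimodal split of a loading column: maximize between-class variance.

    Exact Otsu threshold over the sorted values.  A (near-)constant column
    has no split and retains everyone.
    """
    x = np.sort(col)
    n = len(x)
    if n < 2 or x[-1] - x[0] <= 1e-12 * max(x[-1], 1.0):
        return np.ones(n, dtype=bool)
    csum = np.cumsum(x)
    total = csum[-1]
    idx = np.arange(1, n)  # split after position idx-1
    mean_lo = csum[:-1] / idx
    mean_hi = (total - csum[:-1]) / (n - idx)
    between = idx * (n - idx) * (mean_hi - mean_lo) ** 2
    cut = x[int(np.argmax(between))]  # largest value of the low class
    return col > cut


def threshold_mask(col: np.ndarray, policy, robust_top: int = 5) -> np.ndarray:
    """Apply a membership threshold policy to one loading column.

    ``policy`` is ``("relmax", frac)`` — keep loadings >= frac times the
    reference loading (mean of the ``robust_top`` largest; the plain max
    when ``robust_top=1``) — or ``"otsu"``, the parameter-free bimodal
    split.
    """
    if policy == "otsu":
        return _otsu_mask(col)
    kind, frac = policy
    if kind != "relmax":
        raise ValueError(f"unknown threshold policy {policy!r}")
    top = min(max(1, robust_top), len(col))
    ref = float(np.sort(col)[-top:].mean())
    return col >= frac * ref


def consensus_matrix(labels: Sequence[np.ndarray]) -> np.ndarray:
    """Fraction of runs in which each subject pair shares a dominant factor."""
    n = len(labels[0])
    C = np.zeros((n, n))
    for lab in labels:
        C += (lab[:, None] == lab[None, :])
    C /= len(labels)
    return C


def cophenetic_correlation(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity 1 - C.

    A degenerate consensus (all pairs always or never co-clustered
    identically, i.e. zero-variance dissimilarity) is reported as 1.0 with
    a warning: the clustering is perfectly stable.
    """
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    cond = squareform(D, checks=False)
    if cond.size == 0 or np.allclose(cond, cond[0]):
        warnings.warn("degenerate consensus matrix; cophenetic reported as 1.0")
        return 1.0
    Z = linkage(cond, method="average")
    c, _ = cophenet(Z, cond)
    return float(c)


@dataclass
class RankSelection:
    """Output of :func:`select_ranks`."""

    retained: list[int]
    consensus: dict[int, np.ndarray]
    cophenetic: dict[int, float]
    seeds: dict[int, list[int]] = field(default_factory=dict)


def select_ranks(
    X: FeatureMatrix | np.ndarray,
    k_range: Iterable[int],
    n_runs: int = 10,
    seed: int = 0,
    max_iter: int = 150,
    stability_margin: float = 0.02,
) -> RankSelection:
    """Score candidate ranks by consensus stability.

    For each k, ``n_runs`` random-start factorizations give a consensus
    matrix; its cophenetic correlation scores the stability of rank k.
    Ranks whose cophenetic value is within ``stability_margin`` of the best
    are retained.  All run seeds are logged.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise SizingError("empty rank range")
    if n_runs < 2:
        raise SizingError("need at least 2 consensus runs")
    ss = np.random.SeedSequence(seed)
    consensus: dict[int, np.ndarray] = {}
    coph: dict[int, float] = {}
    seeds: dict[int, list[int]] = {}
    for k in ks:
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
        labels = [
            _dominant_labels(factorize(X, k, seed=s, max_iter=max_iter, init="random"))
            for s in run_seeds
        ]
        C = consensus_matrix(labels)
        consensus[k] = C
        coph[k] = cophenetic_correlation(C)
        seeds[k] = run_seeds
    best = max(coph.values())
    retained = [k for k in ks if coph[k] >= best - stability_margin]
    return RankSelection(retained, consensus, coph, seeds)


def extract_biclusters(
    fp: FactorPair,
    subject_ids: Sequence[str],
    feature_ids: Sequence[str],
    domain: str,
    subject_policy="otsu",
    feature_policy=("relmax", 0.5),
    max_subject_frac: float = 1.0,
    values: Optional[np.ndarray] = None,
    min_contrast: float = 0.0,
    warn_empty: bool = True,
) -> list[Bicluster]:
    """One candidate bicluster per factor, by loading thresholds.

    Membership policies (see :func:`threshold_mask`): the default subject
    policy is the parameter-free bimodal (Otsu) split of the loading
    column, which adapts to the loading spread instead of clipping the
    block tail against an outlier maximum; ``("relmax", 0.5)`` is the
    fixed relative-max alternative.  Features default to relative-max 0.5
    on the rows of H (feature weights are few and crisp).  Factors whose
    subject membership exceeds ``max_subject_frac`` of the cohort are
    dropped: near-uniform factors describe the cohort-wide baseline, not
    a subgroup.  When the data ``values`` are given, factors whose
    members are not distinctively HIGH on the factor's own features
    (mean contrast over non-members <= ``min_contrast``) are dropped:
    additive NMF also produces noise-floor factors whose "members" are
    simply the low scorers, and those are not biclusters.  Empty factors
    are dropped; an all-empty result triggers a warning.
    """
    prefix = DOMAIN_PREFIX.get(domain, domain[:1].upper())
    out: list[Bicluster] = []
    n = len(subject_ids)
    for j in range(fp.k):
        wcol, hrow = fp.W[:, j], fp.H[j]
        wmax, hmax = wcol.max(), hrow.max()
        if wmax <= 0 or hmax <= 0:
            continue
        smask = threshold_mask(wcol, subject_policy)
        fmask = threshold_mask(hrow, feature_policy, robust_top=1)
        if not smask.any() or not fmask.any():
            continue
        if smask.sum() > max_subject_frac * n:
            continue
        if values is not None and smask.sum() < n:
            sub = values[np.ix_(smask, fmask)]
            rest = values[np.ix_(~smask, fmask)]
            contrast = np.nanmean(sub) - np.nanmean(rest)
            if not contrast > min_contrast:
                continue
        out.append(Bicluster(
            id=f"{prefix}_{fp.k}_{j + 1}",
            domain=domain,
            subject_ids=[subject_ids[i] for i in np.flatnonzero(smask)],
            feature_ids=[feature_ids[i] for i in np.flatnonzero(fmask)],
            subject_weights=wcol[smask],
            feature_weights=hrow[fmask],
            rank=fp.k,
            factor_index=j + 1,
        ))
    if not out and warn_empty:
        warnings.warn("bicluster extraction produced an empty collection")
    return out


def accumulate_sets(
    X: FeatureMatrix,
    k_range: Iterable[int],
    seed: int = 0,
    subject_policy="otsu",
    feature_policy=("relmax", 0.5),
    max_subject_frac: float = 0.34,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: str = "kmeans",
    rank_selection: Optional[RankSelection] = None,
) -> SetCollection:
    """Extract and pool biclusters across a rank range (one domain).

    A deterministic seeded path (k-means indicator init by default, which
    targets block structure; NNDSVD available) is used at every rank so
    the collection is reproducible.  When a :class:`RankSelection` is given its cophenetic
    values are recorded and extraction is restricted to the retained ranks;
    otherwise every rank in ``k_range`` contributes sets.
    """
    ks = sorted(set(int(k) for k in k_range))
    if rank_selection is not None:
        ks = [k for k in ks if k in rank_selection.retained]
    sets: list[Bicluster] = []
    for k in ks:
        fp = factorize(X, k, seed=seed, max_iter=max_iter, tol=tol, init=init)
        sets.extend(extract_biclusters(
            fp, X.subject_ids, X.feature_ids, X.domain,
            subject_policy, feature_policy, max_subject_frac,
            values=X.values, warn_empty=False,
        ))
    if not sets:
        warnings.warn(f"no biclusters extracted from {X.domain} over ranks {ks}")
    return SetCollection(
        biclusters=sets,
        subject_universe=list(X.subject_ids),
        domain=X.domain,
        ranks_used=ks,
        cophenetic=dict(rank_selection.cophenetic) if rank_selection else {},
    )


def cluster_profiles(sc: SetCollection, n_profiles: int, seed: int = 0) -> ProfileAssignment:
    """Group sets into deep profiles by factorizing their feature centroids.

    The set x feature centroid matrix (per-set feature weights normalized
    to sum 1, zero elsewhere) is itself NMF-factorized at rank
    ``n_profiles``; each set joins its maximal profile factor.
    """
    if n_profiles < 1 or n_profiles > len(sc):
        raise SizingError(f"{n_profiles} profiles requested for {len(sc)} sets")
    universe = sorted({f for b in sc.biclusters for f in b.feature_ids})
    fidx = {f: j for j, f in enumerate(universe)}
    M = np.zeros((len(sc), len(universe)))
    for i, b in enumerate(sc.biclusters):
        w = b.feature_weights
        total = w.sum() if w.sum() > 0 else 1.0
        for f, wf in zip(b.feature_ids, w):
            M[i, fidx[f]] = wf / total
    fp = factorize(M, n_profiles, seed=seed, init="nndsvd")
    labels = {b.id: int(np.argmax(fp.W[i]) + 1) for i, b in enumerate(sc.biclusters)}
    return ProfileAssignment(labels=labels, centroids=fp.H, feature_ids=universe)
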