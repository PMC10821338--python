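"""Alpha/beta diversity and spatial pattern statistics.

Shannon diversity, Wilcoxon rank-sum group comparison, Bray–Curtis
dissimilarity, non-metric multidimensional scaling (NMDS), analysis of
similarities (ANOSIM) and distance–decay regression of community similarity
against latitudinal separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .io_core import OtuTable
from .pairwise import PairwiseMatrix, align


def shannon(counts) -> float:
    """Shannon diversity H = −Σ p_i ln p_i, in nats.

    Zero-count taxa contribute nothing; an all-zero vector is an error.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: OtuTable) -> pd.Series:
    """Shannon index for each sample of an OTU table."""
    return pd.Series(
        {s: shannon(row) for s, row in zip(table.sample_ids, table.matrix)},
        name="shannon",
    )


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Returns ``(U, p)`` where U is the statistic for sample ``a``.  Uses the
    exact distribution for small tie-free samples and the tie-corrected
    normal approximation otherwise (scipy's ``method="auto"``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input sample")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bray_curtis(table: OtuTable) -> PairwiseMatrix:
    """Bray–Curtis dissimilarity BC(x,y) = Σ|x−y| / Σ(x+y) between samples."""
    m = table.matrix.astype(float)
    totals = m.sum(axis=1)
    if (totals == 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-sum samples: {empty}")
    d = squareform(pdist(m, metric="braycurtis"))
    return PairwiseMatrix(table.sample_ids, d, kind="dissimilarity")


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # samples × k
    stress: float  # Kruskal stress-1 of the best configuration


def nmds(
    dist: PairwiseMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmdsResult:
    """Non-metric MDS ordination of a dissimilarity matrix.

    Runs ``n_restarts − 1`` random starts plus one start initialised from
    principal-coordinates analysis, and returns the lowest-stress
    configuration (Kruskal stress-1).  Deterministic given ``seed``.
    """
    n = dist.n_samples
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    d = dist.values

    def _run(n_init: int, init=None):
        import warnings as _warnings

        mds = MDS(
            n_components=k,
            metric=False,
            n_init=1 if init is not None else n_init,
            max_iter=max_iter,
            eps=tol,
            dissimilarity="precomputed",
            random_state=seed,
            normalized_stress=True,
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            coords = mds.fit_transform(d, init=init)
        return coords, float(mds.stress_)

    candidates = []
    if n_restarts > 1:
        candidates.append(_run(n_restarts - 1))
    # one start from classical (principal-coordinates) scaling
    from skbio.stats.ordination import pcoa

    pc = pcoa(d, number_of_dimensions=min(k, n - 1), method="eigh")
    init = np.zeros((n, k))
    avail = pc.samples.to_numpy()[:, : min(k, pc.samples.shape[1])]
    init[:, : avail.shape[1]] = avail
    candidates.append(_run(1, init=init))

    coords, stress = min(candidates, key=lambda c: c[1])
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return NmdsResult(pd.DataFrame(coords, index=dist.sample_ids, columns=cols), stress)


@dataclass
class AnosimResult:
    r: float
    p: float
    n_perm: int


def anosim(
    dist: PairwiseMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities (Clarke's R) with a permutation test.

    R = (mean between-group rank − mean within-group rank) / (M/2) over the
    ranked condensed dissimilarities, M = n(n−1)/2 and average ranks on ties;
    R ∈ [−1, 1].  p is the add-one permutation estimator
    (1 + #{R_perm ≥ R_obs}) / (1 + n_perm) under random relabelling.
    """
    labels = np.asarray(pd.Series(groups).reindex(dist.sample_ids))
    if pd.isna(labels).any():
        missing = [s for s, l in zip(dist.sample_ids, labels) if pd.isna(l)]
        raise ValueError(f"samples without a group label: {missing}")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    ranks = stats.rankdata(dist.condensed())
    n = dist.n_samples
    iu, ju = np.triu_indices(n, k=1)
    denom = (n * (n - 1) / 2) / 2.0  # M/2

    codes = pd.factorize(labels)[0]

    def _r(c):
        within = c[iu] == c[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = _r(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _r(perm) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(float(r_obs), float(p), n_perm)


@dataclass
class DistanceDecayFit:
    """Least-squares fit of community similarity against Δlatitude."""

    slope: float
    intercept: float
    spearman_rho: float
    spearman_p: float
    r_squared: float
    n_pairs: int
    mantel_p: float | None = None  # permutation p acknowledging pair non-independence


def distance_decay(
    similarity,
    delta_latitude,
    n_perm: int | None = None,
    seed: int = 0,
) -> DistanceDecayFit:
    """Distance–decay regression of similarity (1 − Bray–Curtis) on Δlatitude.

    Accepts either two equal-length pair vectors (condensed upper triangles)
    or two :class:`PairwiseMatrix` objects.  Reports the ordinary
    least-squares slope/intercept and r², Spearman's ρ with its naive p, and
    — when ``n_perm`` is given and matrices were supplied — a Mantel-style
    permutation p that respects the non-independence of sample pairs.
    """
    mantel_p = None
    if isinstance(similarity, PairwiseMatrix) and isinstance(delta_latitude, PairwiseMatrix):
        sim_m, dlat_m = align(similarity, delta_latitude)
        sim = sim_m.condensed()
        dlat = dlat_m.condensed()
        if n_perm:
            from .drivers import mantel

            res = mantel(sim_m, dlat_m, method="spearman", n_perm=n_perm, seed=seed, tail="two-sided")
            mantel_p = res.p
    else:
        sim = np.asarray(similarity, dtype=float)
        dlat = np.asarray(delta_latitude, dtype=float)
        if sim.shape != dlat.shape:
            raise ValueError("similarity and delta_latitude lengths differ")
    if sim.size < 3:
        raise ValueError("distance-decay needs at least 3 pairs")

    ls = stats.linregress(dlat, sim)
    if np.ptp(sim) == 0 or np.ptp(dlat) == 0:
        rho, rho_p = 0.0, 1.0
        r2 = 0.0 if np.ptp(sim) == 0 else ls.rvalue**2
        if np.ptp(sim) == 0:
            # flat response: slope 0 regardless of predictor
            return DistanceDecayFit(0.0, float(sim.mean()), rho, rho_p, 0.0, sim.size, mantel_p)
    else:
        sp = stats.spearmanr(dlat, sim)
        rho, rho_p = float(sp.statistic), float(sp.pvalue)
        r2 = float(ls.rvalue**2)
    return DistanceDecayFit(
        float(ls.slope), float(ls.intercept), rho, rho_p, float(r2), int(sim.size), mantel_p
    )
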