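"""Phylogenetic and taxonomic null models of community assembly.

The core inference chain:

1. βMNTD — abundance-weighted beta mean nearest taxon distance between every
   pair of communities, from patristic (tip-to-tip branch length) distances.
2. βNTI — the z-score of observed βMNTD against a null distribution obtained
   by shuffling taxon positions on the phylogeny (taxa shuffle).  |βNTI| > 2
   signals deterministic selection: heterogeneous (> 2, divergent filtering)
   or homogeneous (< −2, uniform filtering).
3. RCbray — for pairs not under selection, the Bray–Curtis-based Raup–Crick
   index locates the observed dissimilarity within a null ensemble of
   communities assembled probabilistically from the metacommunity (species
   membership weighted by occupancy, individuals by relative abundance),
   rescaled to [−1, 1].  RCbray > 0.95 → dispersal limitation,
   < −0.95 → homogenizing dispersal, otherwise drift.
4. Relative contributions of the five processes across sample pairs, overall,
   per stratum, and per latitudinal-difference bin, plus detection of the
   spatial scale at which dominance switches from stochastic to deterministic.

βMNTD for all pairs is computed by one matrix product per (null) distance
matrix: with F the samples × OTUs relative-abundance matrix and M[s, i] the
distance from taxon i to its nearest taxon present in sample s,
βMNTD = 0.5·(F·Mᵀ + (F·Mᵀ)ᵀ).  One taxa-shuffle permutation per null
replicate is shared by all pairs (the classic community-matrix
randomisation), so the whole null distribution costs n_null matrix products.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .io_core import OtuTable
from .pairwise import PairwiseMatrix, align

logger = logging.getLogger(__name__)

# the five assembly processes
HETEROGENEOUS_SELECTION = "heterogeneous_selection"
HOMOGENEOUS_SELECTION = "homogeneous_selection"
DISPERSAL_LIMITATION = "dispersal_limitation"
HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
DRIFT = "drift"
PROCESSES = (
    HETEROGENEOUS_SELECTION,
    HOMOGENEOUS_SELECTION,
    DISPERSAL_LIMITATION,
    HOMOGENIZING_DISPERSAL,
    DRIFT,
)
DETERMINISTIC = frozenset({HETEROGENEOUS_SELECTION, HOMOGENEOUS_SELECTION})
STOCHASTIC = frozenset({DISPERSAL_LIMITATION, HOMOGENIZING_DISPERSAL, DRIFT})

BNTI_THRESHOLD = 2.0
RCBRAY_THRESHOLD = 0.95


@dataclass
class PhyloDistances:
    """Patristic distances d_ij between OTUs (tips of the phylogeny)."""

    otu_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.otu_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match otu_ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("patristic distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("patristic distance diagonal must be zero")
        self._index = {o: i for i, o in enumerate(self.otu_ids)}

    def restrict(self, otu_ids) -> "PhyloDistances":
        otu_ids = [str(o) for o in otu_ids]
        missing = sorted(set(otu_ids) - set(self._index))
        if missing:
            raise KeyError(f"OTUs absent from the phylogeny: {missing}")
        idx = np.array([self._index[o] for o in otu_ids])
        return PhyloDistances(otu_ids, self.d[np.ix_(idx, idx)])


@dataclass
class NullModelConfig:
    """Controls for the βNTI and RCbray null distributions."""

    n_null: int = 999
    seed: int = 0
    randomization: str = "taxa_shuffle"
    abundance_weighted: bool = True

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.randomization != "taxa_shuffle":
            raise ValueError(f"unknown randomization {self.randomization!r}")


def patristic_distances(tree: TreeNode, otu_ids=None) -> PhyloDistances:
    """Tip-to-tip branch-length (patristic) distances of a rooted tree.

    If ``otu_ids`` is given the matrix is restricted/reordered to those tips;
    ids not found in the tree raise an error listing the symmetric
    difference.
    """
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("tree tips are not uniquely labeled")
    dm = tree.tip_tip_distances()
    pd_all = PhyloDistances(list(dm.ids), dm.data)
    if otu_ids is None:
        return pd_all
    want, have = set(map(str, otu_ids)), set(pd_all.otu_ids)
    if want - have:
        raise KeyError(
            f"id mismatch between table and tree; missing from tree: "
            f"{sorted(want - have)}; extra tips: {sorted(have - want)}"
        )
    return pd_all.restrict(otu_ids)


# ---------------------------------------------------------------------------
# βMNTD / βNTI
# ---------------------------------------------------------------------------

def beta_mntd(abund_a, abund_b, distances: PhyloDistances, abundance_weighted: bool = True) -> float:
    """βMNTD between two communities.

    ``abund_a``/``abund_b`` are relative-abundance vectors aligned with
    ``distances.otu_ids`` (each summing to 1 over its present OTUs).  For
    each OTU in one community the patristic distance to its nearest taxon in
    the other community is averaged, weighting by relative abundance
    (``abundance_weighted=True``) or uniformly over the community's richness:

    βMNTD = 0.5·[ Σ_{i∈A} f_iA · min_{j∈B} d_ij + Σ_{j∈B} f_jB · min_{i∈A} d_ij ]
    """
    fa = np.asarray(abund_a, dtype=float)
    fb = np.asarray(abund_b, dtype=float)
    if fa.shape != (len(distances.otu_ids),) or fb.shape != fa.shape:
        raise ValueError("abundance vectors must align with distances.otu_ids")
    pa, pb = fa > 0, fb > 0
    if not pa.any() or not pb.any():
        raise ValueError("empty community")
    if not abundance_weighted:
        fa = pa / pa.sum()
        fb = pb / pb.sum()
    d = distances.d
    min_a_to_b = d[np.ix_(pa, pb)].min(axis=1)
    min_b_to_a = d[np.ix_(pb, pa)].min(axis=1)
    return float(0.5 * (fa[pa] @ min_a_to_b + fb[pb] @ min_b_to_a))


def _beta_mntd_all_pairs(F: np.ndarray, present: np.ndarray, d: np.ndarray) -> np.ndarray:
    """βMNTD for all sample pairs given aligned abundances and distances.

    ``F``: samples × OTUs weights (rows sum to 1), ``present``: boolean mask,
    ``d``: OTU × OTU distances.  Returns the symmetric samples × samples
    matrix.
    """
    s = F.shape[0]
    m = np.empty((s, F.shape[1]))
    for k in range(s):
        m[k] = d[:, present[k]].min(axis=1)
    g = F @ m.T  # g[a, b] = Σ_i f_ai · min_{j∈b} d_ij
    return 0.5 * (g + g.T)


def beta_mntd_matrix(
    table: OtuTable, distances: PhyloDistances, abundance_weighted: bool = True
) -> PairwiseMatrix:
    """Observed βMNTD between every pair of samples."""
    dsub = distances.restrict(table.otu_ids)
    F = table.relative_abundance()
    present = F > 0
    if not abundance_weighted:
        F = present / present.sum(axis=1, keepdims=True)
    vals = _beta_mntd_all_pairs(F, present, dsub.d)
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(table.sample_ids, vals, kind="dissimilarity")


def bnti_matrix(
    table: OtuTable, distances: PhyloDistances, config: NullModelConfig | None = None
) -> PairwiseMatrix:
    """βNTI for every sample pair.

    βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null, where each of the
    ``config.n_null`` replicates shuffles taxon identities uniformly at
    random on the patristic distance matrix while holding the community
    matrix fixed.  Pairs whose null distribution is degenerate (sd = 0, e.g.
    identical compositions, where shared taxa pin βMNTD at zero in every
    replicate) are returned as NaN with a warning.  Deterministic given
    ``config.seed``.
    """
    config = config or NullModelConfig()
    dsub = distances.restrict(table.otu_ids)
    F = table.relative_abundance()
    present = F > 0
    if not config.abundance_weighted:
        F = present / present.sum(axis=1, keepdims=True)
    d = dsub.d
    n_otus = d.shape[0]
    s = F.shape[0]

    obs = _beta_mntd_all_pairs(F, present, d)

    rng = np.random.default_rng(config.seed)
    # running moments over null replicates
    total = np.zeros((s, s))
    total_sq = np.zeros((s, s))
    for _ in range(config.n_null):
        perm = rng.permutation(n_otus)
        null = _beta_mntd_all_pairs(F, present, d[np.ix_(perm, perm)])
        total += null
        total_sq += null * null
    mean = total / config.n_null
    if config.n_null > 1:
        var = (total_sq - config.n_null * mean * mean) / (config.n_null - 1)
        var = np.maximum(var, 0.0)
        sd = np.sqrt(var)
    else:
        sd = np.zeros((s, s))

    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - mean) / sd
    iu = np.triu_indices(s, k=1)
    degenerate = int((sd[iu] == 0).sum())
    if degenerate:
        warnings.warn(
            f"{degenerate} sample pairs have a degenerate (sd=0) βMNTD null "
            "distribution; their βNTI is undefined (NaN)"
        )
    bnti[sd == 0] = np.nan
    np.fill_diagonal(bnti, 0.0)
    bnti = 0.5 * (bnti + bnti.T)  # symmetrise exactly against fp noise
    return PairwiseMatrix(table.sample_ids, bnti, kind="bnti")


# ---------------------------------------------------------------------------
# RCbray
# ---------------------------------------------------------------------------

def _null_communities(
    richness: int,
    total: int,
    occupancy: np.ndarray,
    meta_abund: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assemble ``n_null`` null communities (n_null × OTUs integer counts).

    Each null community preserves the observed richness and total abundance:
    ``richness`` species are drawn without replacement with probability
    proportional to metacommunity occupancy (Gumbel top-k), each receives one
    individual, and the remaining ``total − richness`` individuals are
    assigned multinomially with probability proportional to metacommunity
    relative abundance over the drawn species.
    """
    n = occupancy.size
    if richness > (occupancy > 0).sum():
        raise ValueError("sample richness exceeds species pool size")
    log_w = np.full(n, -np.inf)
    np.log(occupancy, out=log_w, where=occupancy > 0)
    keys = log_w + rng.gumbel(size=(n_null, n))
    top = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    member = np.zeros((n_null, n), dtype=bool)
    np.put_along_axis(member, top, True, axis=1)

    counts = member.astype(np.int64)
    extra = total - richness
    if extra > 0:
        pv = meta_abund * member
        pv /= pv.sum(axis=1, keepdims=True)
        counts += rng.multinomial(extra, pv)
    return counts


def rc_bray_matrix(table: OtuTable, config: NullModelConfig | None = None) -> PairwiseMatrix:
    """Bray–Curtis-based Raup–Crick index for every sample pair.

    RCbray = 2·[ (#{BC_null < BC_obs} + ½·#{BC_null = BC_obs}) / n_null − ½ ],
    in [−1, 1].  One ensemble of ``n_null`` null communities is assembled per
    sample (per-sample seed substreams, so results do not depend on pair
    evaluation order); replicate k of a pair compares the two samples' k-th
    null communities, which are mutually independent.
    """
    config = config or NullModelConfig()
    counts = table.matrix
    s, n = counts.shape
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("samples with zero total counts")
    occupancy = (counts > 0).mean(axis=0)
    meta_abund = counts.sum(axis=0).astype(float)
    meta_abund /= meta_abund.sum()

    seeds = np.random.SeedSequence(config.seed).spawn(s)
    nulls = np.empty((s, config.n_null, n), dtype=np.int64)
    for k in range(s):
        rng = np.random.default_rng(seeds[k])
        nulls[k] = _null_communities(
            int((counts[k] > 0).sum()), int(totals[k]), occupancy, meta_abund,
            config.n_null, rng,
        )

    rc = np.zeros((s, s))
    for a in range(s):
        for b in range(a + 1, s):
            obs = np.abs(counts[a] - counts[b]).sum() / (totals[a] + totals[b])
            diff = np.abs(nulls[a] - nulls[b]).sum(axis=1)
            bc_null = diff / (totals[a] + totals[b])
            less = (bc_null < obs - 1e-12).sum()
            equal = (np.abs(bc_null - obs) <= 1e-12).sum()
            rc[a, b] = rc[b, a] = 2.0 * ((less + 0.5 * equal) / config.n_null - 0.5)
    return PairwiseMatrix(table.sample_ids, rc, kind="rcbray")


# ---------------------------------------------------------------------------
# classification and contributions
# ---------------------------------------------------------------------------

def classify_pair(bnti: float, rcbray: float) -> str:
    """Assign one sample pair to one of the five assembly processes.

    Boundary convention: βNTI exactly ±2 falls to the stochastic branch;
    RCbray exactly ±0.95 is drift (strict inequalities throughout).
    """
    if np.isnan(bnti):
        raise ValueError("undefined βNTI")
    if bnti > BNTI_THRESHOLD:
        return HETEROGENEOUS_SELECTION
    if bnti < -BNTI_THRESHOLD:
        return HOMOGENEOUS_SELECTION
    if np.isnan(rcbray):
        raise ValueError("undefined RCbray for a stochastic-branch pair")
    if rcbray > RCBRAY_THRESHOLD:
        return DISPERSAL_LIMITATION
    if rcbray < -RCBRAY_THRESHOLD:
        return HOMOGENIZING_DISPERSAL
    return DRIFT


def classify_processes(bnti: PairwiseMatrix, rcbray: PairwiseMatrix) -> pd.DataFrame:
    """Per-pair process classification.

    Returns a DataFrame with one row per sample pair (i < j) and columns
    ``sample_i, sample_j, bnti, rcbray, label``.  Pairs with undefined βNTI
    are excluded with a warning.
    """
    bnti_m, rc_m = align(bnti, rcbray)
    pairs = bnti_m.pair_ids()
    b = bnti_m.condensed()
    r = rc_m.condensed()
    rows = []
    skipped = 0
    for (si, sj), bv, rv in zip(pairs, b, r):
        if np.isnan(bv):
            skipped += 1
            continue
        rows.append((si, sj, bv, rv, classify_pair(bv, rv)))
    if skipped:
        warnings.warn(f"excluded {skipped} pairs with undefined βNTI")
    if not rows:
        raise ValueError("no classifiable pairs")
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "bnti", "rcbray", "label"])


def process_contributions(classification: pd.DataFrame, strata=None) -> pd.DataFrame:
    """Percentage of sample pairs assigned to each process, per stratum.

    ``strata`` is an optional per-pair label sequence aligned with the
    classification rows; without it a single stratum ``"all"`` is reported.
    All five processes appear as columns (zeros included) plus ``n_pairs``.
    """
    labels = classification["label"]
    if strata is None:
        strata = pd.Series(["all"] * len(labels), index=labels.index)
    else:
        strata = pd.Series(list(strata), index=labels.index)
    out = {}
    for stratum, idx in strata.groupby(strata).groups.items():
        sub = labels.loc[idx]
        if len(sub) == 0:
            warnings.warn(f"stratum {stratum!r} has no classified pairs; omitted")
            continue
        pct = sub.value_counts().reindex(PROCESSES, fill_value=0) / len(sub) * 100.0
        row = pct.to_dict()
        row["n_pairs"] = len(sub)
        out[stratum] = row
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "stratum"
    return df[list(PROCESSES) + ["n_pairs"]]


def _pair_values(classification: pd.DataFrame, matrix: PairwiseMatrix) -> np.ndarray:
    return np.array(
        [matrix[si, sj] for si, sj in zip(classification["sample_i"], classification["sample_j"])]
    )


def binned_contributions(
    classification: pd.DataFrame,
    delta_lat: PairwiseMatrix,
    bin_edges,
) -> pd.DataFrame:
    """Process contributions stratified by latitudinal-difference bin.

    Pairs fall in half-open bins [e_k, e_{k+1}); the last bin is closed.  A
    pair outside every bin is an error suggesting wider edges.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    dlat = _pair_values(classification, delta_lat)
    out_of_range = (dlat < edges[0]) | (dlat > edges[-1])
    if out_of_range.any():
        raise ValueError(
            f"{out_of_range.sum()} pairs fall outside bins "
            f"[{edges[0]}, {edges[-1]}]; extend the bin edges"
        )
    idx = np.digitize(dlat, edges, right=False) - 1
    idx = np.minimum(idx, len(edges) - 2)  # close the last bin on the right
    strata = [f"{edges[k]:g}-{edges[k + 1]:g}" for k in idx]
    df = process_contributions(classification, strata)
    order = [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
    return df.reindex([b for b in order if b in df.index])


@dataclass
class ScaleRegression:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n_pairs: int
    mantel_p: float | None = None


def bnti_scale_regression(
    bnti: PairwiseMatrix,
    delta_lat: PairwiseMatrix,
    n_perm: int | None = None,
    seed: int = 0,
) -> ScaleRegression:
    """Ordinary least squares of βNTI on latitudinal difference over pairs.

    Reports slope, intercept, r², the naive regression p, and (optionally)
    a Mantel-permutation p that accounts for pair non-independence.
    """
    b_m, d_m = align(bnti, delta_lat)
    b = b_m.condensed()
    d = d_m.condensed()
    ok = ~np.isnan(b)
    b, d = b[ok], d[ok]
    if b.size < 3:
        raise ValueError("need at least 3 pairs with defined βNTI")
    if np.ptp(d) == 0:
        raise ValueError("zero variance in latitudinal differences")
    ls = stats.linregress(d, b)
    mantel_p = None
    if n_perm:
        from .drivers import mantel

        mantel_p = mantel(b_m, d_m, method="pearson", n_perm=n_perm, seed=seed, tail="two-sided").p
    return ScaleRegression(
        float(ls.slope), float(ls.intercept), float(ls.rvalue**2), float(ls.pvalue),
        int(b.size), mantel_p,
    )


@dataclass
class ThresholdScan:
    """Per-bin stochastic/deterministic dominance used in threshold detection."""

    bins: pd.DataFrame  # columns: lo, hi, n_pairs, pct_deterministic, dominant, included
    threshold: float | None


def dominant_process_threshold(
    classification: pd.DataFrame,
    delta_lat: PairwiseMatrix,
    bin_width: float = 2.0,
    min_pairs: int = 5,
    full_scan: bool = False,
):
    """Latitudinal-difference scale at which dominance switches from
    stochastic to deterministic processes.

    Pairs are pooled into consecutive [k·w, (k+1)·w) bins; per bin, pairs are
    collapsed to deterministic (selection) vs stochastic (dispersal + drift).
    A bin is deterministic-dominant when deterministic pairs are a strict
    majority (a 50/50 tie counts as stochastic).  The detected threshold is
    the left edge of the first bin of the final unbroken deterministic-
    dominant run, provided at least one stochastic-dominant bin precedes it;
    ``None`` if dominance never switches.  Bins with fewer than ``min_pairs``
    pairs are flagged and excluded from the scan.

    Returns the threshold, or a :class:`ThresholdScan` when
    ``full_scan=True``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dlat = _pair_values(classification, delta_lat)
    det = classification["label"].isin(DETERMINISTIC).to_numpy()
    k = np.floor(dlat / bin_width).astype(int)
    n_bins = int(k.max()) + 1
    rows = []
    for b in range(n_bins):
        mask = k == b
        n = int(mask.sum())
        pct_det = float(det[mask].mean() * 100.0) if n else np.nan
        rows.append(
            {
                "lo": b * bin_width,
                "hi": (b + 1) * bin_width,
                "n_pairs": n,
                "pct_deterministic": pct_det,
                "dominant": ("deterministic" if n and pct_det > 50.0 else "stochastic"),
                "included": n >= min_pairs,
            }
        )
    bins = pd.DataFrame(rows)
    scan = bins[bins["included"]].reset_index(drop=True)
    threshold: float | None = None
    if len(scan) >= 2:
        dom = (scan["dominant"] == "deterministic").to_numpy()
        if dom[-1] and not dom.all():
            # first bin of the unbroken deterministic tail
            i = len(dom) - 1
            while i > 0 and dom[i - 1]:
                i -= 1
            if not dom[:i].all():  # a stochastic bin precedes the tail
                threshold = float(scan["lo"].iloc[i])
    excluded = int((~bins["included"]).sum())
    if excluded:
        logger.info("threshold scan: %d bins below min_pairs=%d excluded", excluded, min_pairs)
    if full_scan:
        return ThresholdScan(bins, threshold)
    return threshold
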