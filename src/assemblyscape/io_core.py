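"""Input handling: OTU tables, metadata, trophic annotations, filtering,
rarefaction and trophic-group sub-datasets.

The on-disk dialect is the QIIME-classic one: a tab-separated OTU table whose
first header cell is ``#OTU ID`` with OTUs as rows and samples as columns
(a ``orientation`` flag transposes), a newick tree over OTU ids, and plain TSV
for per-sample metadata and the OTU → trophic-group annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

TROPHIC_GROUPS = ("autotroph", "heterotroph", "mixotroph", "parasite")
#: OTUs that could not be attributed to a trophic group
UNKNOWN_GROUP = "unknown"
HABITATS = ("water", "sediment")

METADATA_COLUMNS = (
    "sample_id",
    "latitude",
    "longitude",
    "temperature",
    "salinity",
    "habitat",
    "ecoregion",
)


@dataclass
class OtuTable:
    """Integer abundance matrix, samples × OTUs.

    ``counts`` is a pandas DataFrame indexed by sample id with OTU-id columns;
    cells are non-negative integers (sequence tag counts).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("OTU counts must be integers")
            self.counts = df.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.index]

    @property
    def otu_ids(self) -> list[str]:
        return [str(o) for o in self.counts.columns]

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances f_i (rows sum to 1)."""
        m = self.matrix.astype(float)
        totals = m.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            empty = [s for s, t in zip(self.sample_ids, totals.ravel()) if t == 0]
            raise ValueError(f"samples with zero total counts: {empty}")
        return m / totals

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)].copy())

    def select_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[:, list(otu_ids)].copy())

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        return OtuTable(self.counts.loc[:, keep].copy())

    def equals(self, other: "OtuTable") -> bool:
        return self.counts.equals(other.counts)


@dataclass
class TrophicAnnotation:
    """Mapping OTU id → trophic group (autotroph/heterotroph/mixotroph/
    parasite/unknown)."""

    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = set(TROPHIC_GROUPS) | {UNKNOWN_GROUP}
        bad = {g for g in self.groups.values() if g not in allowed}
        if bad:
            raise ValueError(f"unknown trophic groups: {sorted(bad)}")

    def group_of(self, otu_id: str) -> str:
        return self.groups.get(otu_id, UNKNOWN_GROUP)

    def otus_in(self, group: str) -> list[str]:
        return [o for o, g in self.groups.items() if g == group]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a tab-separated OTU table.

    Parameters
    ----------
    orientation
        ``"otus_as_rows"`` (QIIME-classic, default) or ``"samples_as_rows"``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ids in {path}: {dups}")
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    bad = np.argwhere(~(np.isfinite(arr) & (arr == np.round(arr)) & (arr >= 0)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-integer or negative count at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if orientation == "otus_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return OtuTable(df.astype(np.int64))


def write_otu_table(table: OtuTable, path, orientation: str = "otus_as_rows") -> None:
    df = table.counts
    if orientation == "otus_as_rows":
        df.T.to_csv(path, sep="\t", index_label="#OTU ID")
    elif orientation == "samples_as_rows":
        df.to_csv(path, sep="\t", index_label="sample_id")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata; validates coordinates and habitat labels."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    df = df.set_index("sample_id")
    validate_metadata(df)
    return df


def validate_metadata(df: pd.DataFrame) -> None:
    if not df["latitude"].between(-90, 90).all():
        raise ValueError("latitude outside [-90, 90]")
    if not ((df["longitude"] > -180) & (df["longitude"] <= 180)).all():
        raise ValueError("longitude outside (-180, 180]")
    bad = set(df["habitat"].unique()) - set(HABITATS)
    if bad:
        raise ValueError(f"habitat must be one of {HABITATS}, got {sorted(bad)}")


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path) -> TrophicAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("annotation needs columns otu_id and trophic_group")
    otu_col, grp_col = df.columns[:2]
    if df[otu_col].duplicated().any():
        dups = df[otu_col][df[otu_col].duplicated()].tolist()
        raise ValueError(f"duplicate OTU ids in annotation: {dups}")
    return TrophicAnnotation(
        dict(zip(df[otu_col], df[grp_col].str.strip().str.lower()))
    )


def write_annotation(annotation: TrophicAnnotation, path) -> None:
    pd.DataFrame(
        {"otu_id": list(annotation.groups), "trophic_group": list(annotation.groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("tree has duplicate tip labels")
    return tree


# ---------------------------------------------------------------------------
# filtering / rarefaction / trophic splitting
# ---------------------------------------------------------------------------

def filter_otus(
    table: OtuTable,
    min_total_tags: int = 2,
    exclude_ids=None,
) -> OtuTable:
    """Drop OTUs below a total-tag threshold and any caller-flagged ids.

    ``min_total_tags=2`` reproduces the convention of excluding singleton
    OTUs ("fewer than two tags"); ``exclude_ids`` carries non-target taxa
    (metazoans etc.) identified upstream — taxonomy strings are not parsed
    here.
    """
    if min_total_tags < 0:
        raise ValueError("min_total_tags must be >= 0")
    totals = table.otu_totals()
    keep = totals >= min_total_tags
    if exclude_ids is not None:
        excl = set(map(str, exclude_ids))
        keep &= ~table.counts.columns.isin(excl)
    if not keep.any():
        raise ValueError("filter removed all OTUs")
    return OtuTable(table.counts.loc[:, keep].copy())


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to ``depth`` tags without replacement.

    Uses a multivariate hypergeometric draw per sample.  Samples whose total
    falls below ``depth`` are dropped (logged); an error is raised if none
    remain.  Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    kept = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if not kept:
        raise ValueError(f"all samples have fewer than {depth} tags")
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    out = np.empty((len(kept), table.counts.shape[1]), dtype=np.int64)
    sub = table.counts.loc[kept]
    for i, (_, row) in enumerate(sub.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    return OtuTable(pd.DataFrame(out, index=kept, columns=table.counts.columns))


def split_by_trophic(
    table: OtuTable,
    annotation: TrophicAnnotation,
    group_depth: int,
    min_group_tags: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, OtuTable], dict[str, list[str]]]:
    """Extract and renormalise one sub-table per trophic group.

    For each of the four named groups the table is restricted to that group's
    OTUs; samples whose group total falls below ``min_group_tags`` (default:
    ``group_depth``, i.e. a sample must support the group's rarefaction
    depth) are excluded, and the remainder rarefied to ``group_depth``.
    ``unknown`` OTUs appear in no group table.

    Returns
    -------
    tables, excluded
        ``tables[group]`` is the rarefied sub-table (empty DataFrame if the
        group has no OTUs); ``excluded[group]`` lists the samples dropped
        from that group's analyses.
    """
    if group_depth < 1:
        raise ValueError("group_depth must be >= 1")
    if min_group_tags is None:
        min_group_tags = group_depth
    ss = np.random.SeedSequence(seed)
    child_seeds = {g: s for g, s in zip(TROPHIC_GROUPS, ss.spawn(len(TROPHIC_GROUPS)))}
    tables: dict[str, OtuTable] = {}
    excluded: dict[str, list[str]] = {}
    for group in TROPHIC_GROUPS:
        otus = [o for o in table.otu_ids if annotation.group_of(o) == group]
        if not otus:
            warnings.warn(f"trophic group {group!r} has no OTUs in the table")
            tables[group] = OtuTable(
                pd.DataFrame(
                    np.empty((0, 0), dtype=np.int64),
                    index=pd.Index([], dtype=object),
                    columns=pd.Index([], dtype=object),
                )
            )
            excluded[group] = list(table.sample_ids)
            continue
        sub = table.select_otus(otus)
        totals = sub.sample_totals()
        low = totals.index[totals < min_group_tags].tolist()
        keep = totals.index[totals >= min_group_tags].tolist()
        excluded[group] = low
        if not keep:
            warnings.warn(f"no samples meet min_group_tags for group {group!r}")
            tables[group] = OtuTable(sub.counts.iloc[:0].copy())
            continue
        sub = sub.select_samples(keep)
        grp_seed = int(child_seeds[group].generate_state(1, dtype=np.uint32)[0] % (2**31))
        tables[group] = rarefy(sub, group_depth, grp_seed)
    return tables, excluded
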