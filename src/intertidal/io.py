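"""Readers, writers and validation for the three standard inputs.

The pipeline consumes a site-by-OTU count table (TSV, OTUs in rows by the
common amplicon convention), a rooted newick phylogeny over the OTUs, and a
per-sample metadata table (TSV). Everything downstream works on the aligned
triple produced by :func:`align_inputs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "AlignmentError",
    "OtuTable",
    "HABITATS",
    "SIZE_FRACTIONS",
    "SEASONS",
    "ENV_VARIABLES",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "align_inputs",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_table",
]


class FormatError(ValueError):
    """An input file violates the format contract."""


class AlignmentError(ValueError):
    """Table, tree and metadata cannot be reconciled."""


HABITATS = ("water", "sediment")
SIZE_FRACTIONS = ("micro", "nano", "none")
SEASONS = ("spring", "summer")

#: Environmental measurement columns recognised in metadata. Any subset may
#: be present; values may be missing (NA) per sample.
ENV_VARIABLES = (
    "salinity", "pH", "NOx", "PO4", "Si", "water_content", "grain_size",
    "chl_a", "bacteria", "As", "Cd", "Co", "Cr", "Cu", "Fe", "Mn", "Ni",
    "Pb", "Se", "Zn", "env_driver",
)

_REQUIRED_META = ("habitat", "season", "latitude", "longitude")


@dataclass(frozen=True)
class OtuTable:
    """Samples-by-OTUs count matrix.

    ``data`` is a pandas DataFrame with sample identifiers as the index and
    OTU identifiers as the columns; every cell is a non-negative integer.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample identifiers in OTU table")
        if df.columns.has_duplicates:
            raise FormatError("duplicate OTU identifiers in OTU table")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                bad = np.argwhere(~np.isfinite(vals) | (vals != np.floor(vals)))
                r, c = bad[0]
                raise FormatError(
                    f"non-integer count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
                )
            object.__setattr__(self, "data", df.astype(np.int64))
            vals = self.data.to_numpy()
        if np.any(vals < 0):
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select(self, samples=None, otus=None) -> "OtuTable":
        df = self.data
        if samples is not None:
            df = df.loc[list(samples)]
        if otus is not None:
            df = df[list(otus)]
        return OtuTable(df)

    def drop_empty(self) -> "OtuTable":
        """Drop all-zero samples and OTUs (warn-and-drop policy)."""
        df = self.data
        zero_samples = df.index[df.sum(axis=1) == 0]
        zero_otus = df.columns[df.sum(axis=0) == 0]
        if len(zero_samples):
            logger.warning("dropping %d all-zero sample(s): %s",
                           len(zero_samples), ", ".join(map(str, zero_samples)))
        if len(zero_otus):
            logger.warning("dropping %d all-zero OTU(s)", len(zero_otus))
        if len(zero_samples) or len(zero_otus):
            df = df.drop(index=zero_samples, columns=zero_otus)
        return OtuTable(df)


def read_otu_table(path, samples_in_rows: bool = False) -> OtuTable:
    """Read an OTU count table from TSV.

    The on-disk dialect puts OTUs in rows and samples in columns (first
    column = OTU identifiers, header row = sample identifiers); pass
    ``samples_in_rows=True`` for the transposed layout.
    """
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise FormatError(f"empty OTU table file {path}")
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate column name(s) in OTU table: {dupes}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#")
    if not samples_in_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise FormatError(
                f"non-numeric count in OTU {col!r}, sample {bad[0]!r}"
                if samples_in_rows else
                f"non-numeric count in sample {bad[0]!r}, OTU {col!r}"
            )
    return OtuTable(df).drop_empty()


def write_otu_table(table: OtuTable, path) -> None:
    """Write a TSV with OTUs in rows (inverse of :func:`read_otu_table`)."""
    out = table.data.T
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    """Read a single rooted newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"unparseable newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate tip label(s) in tree: {dupes}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        logger.warning("%d branch(es) had no length; set to 0", n_missing)
    return tree


def tree_from_newick(newick: str) -> TreeNode:
    """Parse a newick string (same validation as :func:`read_tree`)."""
    try:
        tree = TreeNode.read(StringIO(newick), format="newick")
    except Exception as exc:
        raise FormatError(f"unparseable newick: {exc}") from exc
    return _validate_tree(tree)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the per-sample metadata TSV.

    Returns a DataFrame indexed by ``sample_id`` with categorical columns
    (habitat, size_fraction, season, site), coordinates, and any subset of
    the environmental variables in :data:`ENV_VARIABLES`.
    """
    df = pd.read_csv(path, sep="\t", header=0, comment="#")
    if "sample_id" not in df.columns:
        raise FormatError("metadata must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    for col in _REQUIRED_META:
        if col not in df.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    if "size_fraction" not in df.columns:
        df = df.copy()
        df["size_fraction"] = "none"
    bad = set(df["habitat"]) - set(HABITATS)
    if bad:
        raise FormatError(f"unknown habitat value(s) {sorted(bad)}; expected {HABITATS}")
    bad = set(df["season"]) - set(SEASONS)
    if bad:
        raise FormatError(f"unknown season value(s) {sorted(bad)}; expected {SEASONS}")
    bad = set(df["size_fraction"]) - set(SIZE_FRACTIONS)
    if bad:
        raise FormatError(
            f"unknown size_fraction value(s) {sorted(bad)}; expected {SIZE_FRACTIONS}")
    lat = df["latitude"].astype(float)
    lon = df["longitude"].astype(float)
    if ((lat < -90) | (lat > 90)).any():
        raise FormatError("latitude out of range [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise FormatError("longitude out of range [-180, 180]")
    water = df["habitat"] == "water"
    if (df.loc[water, "size_fraction"] == "none").any():
        raise FormatError("water samples must carry a size fraction (micro/nano)")
    if (df.loc[~water, "size_fraction"] != "none").any():
        raise FormatError("sediment samples must have size_fraction = none")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def align_inputs(table: OtuTable, tree: TreeNode, meta: pd.DataFrame):
    """Restrict the triple to shared samples and tree-covered OTUs.

    Samples are intersected between table and metadata (table order kept);
    OTUs absent from the tree are dropped; the tree is sheared to the OTUs
    present in the table. Idempotent. Raises :class:`AlignmentError` if
    fewer than 2 samples or 3 OTUs survive.
    """
    meta_samples = set(meta.index)
    samples = [s for s in table.sample_ids if s in meta_samples]
    n_drop_tab = table.n_samples - len(samples)
    n_drop_meta = len(meta_samples) - len(samples)
    if n_drop_tab or n_drop_meta:
        logger.warning("align: dropped %d table sample(s) and %d metadata row(s) "
                       "not shared", n_drop_tab, n_drop_meta)
    tips = {t.name for t in tree.tips()}
    otus = [o for o in table.otu_ids if o in tips]
    if len(otus) < table.n_otus:
        logger.warning("align: dropped %d OTU(s) absent from the tree",
                       table.n_otus - len(otus))
    if len(samples) < 2:
        raise AlignmentError(
            f"only {len(samples)} sample(s) shared between table and metadata")
    if len(otus) < 3:
        raise AlignmentError(f"only {len(otus)} OTU(s) shared between table and tree")
    aligned = table.select(samples=samples, otus=otus).drop_empty()
    if aligned.n_samples < 2:
        raise AlignmentError("fewer than 2 non-empty samples after alignment")
    sheared = tree.shear(aligned.otu_ids) if len(tips) > aligned.n_otus else tree
    sheared.prune()
    return aligned, sheared, meta.loc[aligned.sample_ids]


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment="#",
                     float_precision="round_trip")
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path, header_lines=()) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "id"
    _write_with_header(df, path, header_lines, float_format="%.17g")


def write_table(df: pd.DataFrame, path, header_lines=(), index=True) -> None:
    """Write a result table as TSV, with optional ``#``-prefixed header lines."""
    _write_with_header(df, path, header_lines, index=index)


def _write_with_header(df, path, header_lines, float_format=None, index=True):
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format=float_format, index=index)
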