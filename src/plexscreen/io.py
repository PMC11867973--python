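"""On-disk formats and shared domain models.

Everything downstream of the simulator speaks through the types defined
here: sparse count matrices in the 10x triplet convention (MatrixMarket
``matrix.mtx`` plus ``features.tsv``/``barcodes.tsv``), the plate map CSV
that is the single source of the well → treatment mapping, tab-separated
GMT gene-set collections, and a gene annotation table used to restrict
DEG counting to protein-coding genes.

Gene symbols are matched case-insensitively and stored upper-cased,
because gene sets and annotations routinely come from mixed sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("plexscreen")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class ConfigError(ValueError):
    """A configuration value is missing or inconsistent."""


def log_stage(stage: str, **counts) -> None:
    """Report input/output entity counts for a pipeline stage at info level."""
    payload = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("%s: %s", stage, payload)


# ---------------------------------------------------------------------------
# Sparse count matrices (features x cells)
# ---------------------------------------------------------------------------

@dataclass
class CountMatrixHandle:
    """Sparse integer count matrix, features (rows) x cell barcodes (columns).

    Invariants: counts are nonnegative integers; ``feature_ids`` and
    ``barcode_ids`` are unique and match the matrix dimensions.
    """

    counts: sp.csr_matrix
    feature_ids: list
    barcode_ids: list

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.feature_ids = list(self.feature_ids)
        self.barcode_ids = list(self.barcode_ids)
        n_feat, n_bc = self.counts.shape
        if len(self.feature_ids) != n_feat:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {n_feat} matrix rows")
        if len(self.barcode_ids) != n_bc:
            raise ValidationError(
                f"{len(self.barcode_ids)} barcode ids for {n_bc} matrix columns")
        if len(set(self.feature_ids)) != n_feat:
            raise ValidationError("feature ids are not unique")
        if len(set(self.barcode_ids)) != n_bc:
            raise ValidationError("barcode ids are not unique")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer counts")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_features(self, index) -> "CountMatrixHandle":
        index = np.asarray(index)
        return CountMatrixHandle(self.counts[index, :],
                                 [self.feature_ids[i] for i in index],
                                 self.barcode_ids)

    def subset_barcodes(self, index) -> "CountMatrixHandle":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrixHandle(self.counts[:, index],
                                 self.feature_ids,
                                 [self.barcode_ids[i] for i in index])

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


def _read_id_column(path) -> list:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountMatrixHandle:
    """Read a 10x-style triplet directory (1-based MatrixMarket indices)."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # malformed header, out-of-range indices, ...
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size:
        if np.any(mat.data < 0):
            raise FormatError(f"{matrix_path}: negative entries")
        if not np.allclose(mat.data, np.round(mat.data)):
            raise FormatError(f"{matrix_path}: non-integer entries")
        if mat.row.max() >= mat.shape[0] or mat.col.max() >= mat.shape[1]:
            raise FormatError(f"{matrix_path}: entry index exceeds declared dimensions")
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    if len(features) != mat.shape[0] or len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"id lists ({len(features)} features, {len(barcodes)} barcodes) do not "
            f"match matrix dimensions {mat.shape}")
    try:
        return CountMatrixHandle(mat.tocsr(), features, barcodes)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_counts_mtx(handle: CountMatrixHandle, out_dir) -> dict:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``; inverse of
    :func:`read_counts_mtx`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    coo = handle.counts.tocoo()
    coo.data = coo.data.astype(np.int64)
    scipy.io.mmwrite(str(paths["matrix"]), coo, field="integer")
    paths["features"].write_text("".join(f"{f}\n" for f in handle.feature_ids))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in handle.barcode_ids))
    return paths


# ---------------------------------------------------------------------------
# Plate map
# ---------------------------------------------------------------------------

PLATE_MAP_COLUMNS = ["well", "row_tag", "col_tag", "model", "drug", "moa",
                     "concentration", "unit", "replicate", "is_control"]

DEFAULT_ROW_TAGS = tuple(f"R{i}" for i in range(1, 9))
DEFAULT_COL_TAGS = tuple(f"C{i}" for i in range(1, 13))


@dataclass
class PlateMap:
    """Well → (row tag, column tag, model, drug, MOA, concentration, replicate).

    Invariants: (row_tag, col_tag) pairs unique; row tags drawn from a family
    of at most 8, column tags from a family of at most 12; at least one
    control well per model.
    """

    wells: pd.DataFrame
    _pair_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        df = self.wells.reset_index(drop=True)
        missing = set(PLATE_MAP_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"plate map missing columns: {sorted(missing)}")
        if df.empty:
            raise ValidationError("plate map has no wells")
        pairs = list(zip(df["row_tag"], df["col_tag"]))
        if len(set(pairs)) != len(pairs):
            dup = pd.Series(pairs)[pd.Series(pairs).duplicated()].iloc[0]
            raise ValidationError(f"duplicate (row_tag, col_tag) pair {dup}")
        if df["row_tag"].nunique() > 8:
            raise ValidationError("more than 8 distinct row tags")
        if df["col_tag"].nunique() > 12:
            raise ValidationError("more than 12 distinct column tags")
        df["is_control"] = df["is_control"].astype(bool)
        df["replicate"] = df["replicate"].astype(int)
        df["concentration"] = df["concentration"].astype(float)
        for model, grp in df.groupby("model"):
            if not grp["is_control"].any():
                raise ValidationError(f"model {model!r} has no control well")
        self.wells = df
        self._pair_index = {p: i for i, p in enumerate(pairs)}

    def __len__(self) -> int:
        return len(self.wells)

    @property
    def row_tags(self) -> list:
        return sorted(self.wells["row_tag"].unique())

    @property
    def col_tags(self) -> list:
        return sorted(self.wells["col_tag"].unique())

    def lookup(self, row_tag: str, col_tag: str):
        """Return the well record for a tag pair, or None if unused."""
        idx = self._pair_index.get((row_tag, col_tag))
        if idx is None:
            return None
        return self.wells.iloc[idx]

    def write_csv(self, path) -> None:
        self.wells[PLATE_MAP_COLUMNS].to_csv(path, index=False)


def read_plate_map(csv_path, row_tag_universe=DEFAULT_ROW_TAGS,
                   col_tag_universe=DEFAULT_COL_TAGS) -> PlateMap:
    """Read a plate-map CSV with the fixed header and enforce invariants.

    ``row_tag_universe``/``col_tag_universe`` define the admissible tag ids
    (pass None to accept any labels, subject to the 8/12 family-size caps).
    """
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{csv_path}: empty plate map") from exc
    if list(df.columns) != PLATE_MAP_COLUMNS:
        raise FormatError(
            f"{csv_path}: expected header {PLATE_MAP_COLUMNS}, got {list(df.columns)}")
    if row_tag_universe is not None:
        unknown = set(df["row_tag"]) - set(row_tag_universe)
        if unknown:
            raise ValidationError(f"unknown row tag ids: {sorted(unknown)}")
    if col_tag_universe is not None:
        unknown = set(df["col_tag"]) - set(col_tag_universe)
        if unknown:
            raise ValidationError(f"unknown column tag ids: {sorted(unknown)}")
    return PlateMap(df)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """symbol → biotype table; symbols unique after upper-casing."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        if "symbol" not in df.columns or "biotype" not in df.columns:
            raise ValidationError("annotation needs 'symbol' and 'biotype' columns")
        df["symbol"] = df["symbol"].astype(str).str.upper()
        if df["symbol"].duplicated().any():
            dup = df.loc[df["symbol"].duplicated(), "symbol"].iloc[0]
            raise ValidationError(f"duplicate gene symbol after upper-casing: {dup}")
        self.table = df.set_index("symbol", drop=False)

    def biotype_of(self, symbol: str):
        row = self.table["biotype"].get(str(symbol).upper())
        return row

    def protein_coding(self) -> set:
        return set(self.table.index[self.table["biotype"] == "protein_coding"])


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(df)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets (upper-cased, deduplicated, order-preserving)."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, genes in self.sets.items():
            seen, out = set(), []
            for g in genes:
                g = str(g).upper()
                if not g:
                    raise ValidationError(f"empty gene symbol in set {name!r}")
                if g not in seen:
                    seen.add(g)
                    out.append(g)
            clean[name] = out
        self.sets = clean
        self.descriptions = {n: self.descriptions.get(n, "") for n in clean}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list:
        return list(self.sets)

    def filter_by_size(self, min_size: int, max_size: int) -> "GeneSetCollection":
        keep = {n: g for n, g in self.sets.items() if min_size <= len(g) <= max_size}
        return GeneSetCollection(keep, {n: self.descriptions[n] for n in keep})


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, genes...)."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return cfg
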