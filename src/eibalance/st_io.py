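"""Readers/writers for the on-disk formats the pipeline touches.

Count matrices use the 10x triplet dialect: a Matrix Market coordinate
integer file (``matrix.mtx``/``.mtx.gz``) stored genes x spots on disk,
plus ``barcodes.tsv`` and ``features.tsv``. In memory everything is
spot-major (spots x genes). Spot metadata travels as a tissue-position
CSV; gene sets as GMT.
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "SpotTable",
    "GeneSetCollection",
    "FormatError",
    "REGION_VOCAB",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_positions",
    "write_positions",
]

REGION_VOCAB = ("CA1", "CA3", "DG", "other", "unassigned")


class FormatError(ValueError):
    """Malformed on-disk data (dimension mismatch, bad field, duplicate key)."""


def _dedup(names: list[str]) -> list[str]:
    """Make identifiers unique by suffixing repeats with .1, .2, ... (stable)."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        k = seen.get(name, 0)
        out.append(name if k == 0 else f"{name}.{k}")
        seen[name] = k + 1
    return out


@dataclass
class CountMatrix:
    """Sparse UMI counts, spots x genes, with unique spot/gene identifiers."""

    counts: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = [str(b) for b in self.barcodes]
        self.genes = [str(g) for g in self.genes]
        self.validate()
        if not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)

    def validate(self) -> None:
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes are not unique")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("gene identifiers are not unique")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise FormatError("counts contain negative entries")
            if not np.issubdtype(data.dtype, np.integer) and not np.all(
                data == np.rint(data)
            ):
                raise FormatError("counts contain non-integral entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def subset_spots(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            self.counts[idx], [self.barcodes[i] for i in idx], list(self.genes)
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            self.counts[:, idx], list(self.barcodes), [self.genes[i] for i in idx]
        )


_SPOT_COLUMNS = ["barcode", "row", "col", "in_tissue", "sample", "group", "region"]


@dataclass
class SpotTable:
    """Per-spot metadata: array coordinates, sample/group label, region call."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _SPOT_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"SpotTable missing columns: {missing}")
        self.table = self.table[_SPOT_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t.duplicated(subset=["sample", "barcode"]).any():
            raise FormatError("(sample, barcode) pairs are not unique")
        bad = set(t["region"].unique()) - set(REGION_VOCAB)
        if bad:
            raise FormatError(f"region labels outside vocabulary: {sorted(bad)}")
        if not t["in_tissue"].isin([0, 1, True, False]).all():
            raise FormatError("in_tissue must be 0/1")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def barcodes(self) -> list[str]:
        return self.table["barcode"].tolist()

    def with_regions(self, regions: pd.Series) -> "SpotTable":
        """Return a copy with ``region`` set from a barcode-indexed Series."""
        t = self.table.copy()
        mapped = t["barcode"].map(regions)
        t.loc[mapped.notna(), "region"] = mapped[mapped.notna()]
        return SpotTable(t)

    def hippocampal_mask(self) -> np.ndarray:
        return self.table["region"].isin(["CA1", "CA3", "DG"]).to_numpy()


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (synapse signatures, region markers)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def _locate(directory: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        p = directory / (stem + suffix)
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def read_count_matrix(directory_path) -> CountMatrix:
    """Read a 10x-style triplet directory into a spots x genes CountMatrix.

    The Matrix Market header dimensions decide orientation: a genes x spots
    file (the 10x convention) is transposed on read. Gene symbols come from
    the second column of features.tsv when present; collisions are suffixed
    ``.1``, ``.2``, ...
    """
    directory = Path(directory_path)
    mtx_path = _locate(directory, "matrix.mtx")
    bc_path = _locate(directory, "barcodes.tsv")
    ft_path = _locate(directory, "features.tsv")

    with _open_text(bc_path) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_text(ft_path) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    genes = [r[1] if len(r) > 1 else r[0] for r in feat_rows]
    genes = _dedup(genes)

    mat = sp.coo_matrix(mmread(str(mtx_path)))
    n_genes, n_spots = len(genes), len(barcodes)
    if mat.shape == (n_genes, n_spots):
        counts = mat.T.tocsr()  # genes x spots on disk -> transpose
    elif mat.shape == (n_spots, n_genes):
        counts = mat.tocsr()
    else:
        raise FormatError(
            f"matrix.mtx header declares {mat.shape}, but found "
            f"{n_spots} barcodes and {n_genes} features"
        )
    return CountMatrix(counts, barcodes, genes)


def write_count_matrix(cm: CountMatrix, directory_path) -> None:
    """Write a CountMatrix as matrix.mtx + barcodes.tsv + features.tsv.

    The matrix is stored genes x spots (10x convention) with an integer
    Matrix Market field, so `read_count_matrix` round-trips it exactly.
    """
    cm.validate()
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(
        str(directory / "matrix.mtx"),
        sp.coo_matrix(cm.counts.T),
        field="integer",
        symmetry="general",
    )
    with open(directory / "barcodes.tsv", "w", encoding="utf-8") as fh:
        for b in cm.barcodes:
            fh.write(b + "\n")
    with open(directory / "features.tsv", "w", encoding="utf-8") as fh:
        for g in cm.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are dropped with a warning; lines with
    fewer than three fields raise FormatError with the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >=3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(
                    f"GMT set {name!r}: dropped {len(genes) - len(unique)} "
                    "duplicate gene(s)",
                    stacklevel=2,
                )
            if not unique:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_positions(path, sample: str = "sample0", group: str = "NA") -> SpotTable:
    """Read a tissue-position CSV (barcode,in_tissue,row,col; extras ignored)."""
    df = pd.read_csv(path)
    required = ["barcode", "in_tissue", "row", "col"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"positions CSV missing columns: {missing}")
    if df["barcode"].duplicated().any():
        dup = df["barcode"][df["barcode"].duplicated()].iloc[0]
        raise FormatError(f"duplicate barcode in positions file: {dup!r}")
    if not df["in_tissue"].isin([0, 1]).all():
        bad = df.loc[~df["in_tissue"].isin([0, 1]), "in_tissue"].iloc[0]
        raise FormatError(f"in_tissue must be 0/1, found {bad!r}")
    out = pd.DataFrame(
        {
            "barcode": df["barcode"].astype(str),
            "row": df["row"].astype(int),
            "col": df["col"].astype(int),
            "in_tissue": df["in_tissue"].astype(int),
            "sample": df["sample"].astype(str) if "sample" in df.columns else sample,
            "group": df["group"].astype(str) if "group" in df.columns else group,
            "region": "unassigned",
        }
    )
    return SpotTable(out)


def write_positions(st: SpotTable, path) -> None:
    """Write positions CSV with sample/group carried as extra columns."""
    cols = ["barcode", "in_tissue", "row", "col", "sample", "group"]
    st.table[cols].to_csv(path, index=False)
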