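"""Spot/gene quality control and library-size log-normalization."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .st_io import CountMatrix

__all__ = ["NormMatrix", "EmptyResultError", "qc_spots", "qc_genes", "lognormalize"]


class EmptyResultError(ValueError):
    """A filter removed everything; thresholds need loosening."""


@dataclass
class NormMatrix:
    """Dense spots x genes log-normalized expression.

    value = ln(1 + count * scale_factor / spot_total), so proportional
    count vectors normalize identically (capture-size removal).
    """

    values: np.ndarray
    barcodes: list[str]
    genes: list[str]
    scale_factor: float = 1e4
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("values shape does not match barcodes/genes")
        if self.values.size and self.values.min() < 0:
            raise ValueError("normalized values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def subset_spots(self, mask) -> "NormMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormMatrix(self.values[idx], [self.barcodes[i] for i in idx],
                          list(self.genes), self.scale_factor, dict(self.provenance))


def _mito_mask(genes: list[str]) -> np.ndarray:
    return np.array([g.lower().startswith("mt-") for g in genes])


def qc_spots(cm: CountMatrix, min_features: int = 100,
             max_mito: float = 0.2) -> CountMatrix:
    """Keep spots with >= min_features detected genes and mitochondrial
    count fraction <= max_mito (genes with an ``mt-`` prefix, any case)."""
    if min_features < 0:
        raise ValueError("min_features must be >= 0")
    if not 0 <= max_mito <= 1:
        raise ValueError("max_mito must be in [0, 1]")
    counts = cm.counts
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    mito = _mito_mask(cm.genes)
    mito_counts = np.asarray(counts[:, mito].sum(axis=1)).ravel() if mito.any() \
        else np.zeros(len(cm.barcodes))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = (detected >= min_features) & (frac <= max_mito)
    if not keep.any():
        raise EmptyResultError(
            "spot QC removed every spot; lower min_features or raise max_mito"
        )
    return cm.subset_spots(keep)


def qc_genes(cm: CountMatrix, min_spots: int = 3) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_spots`` spots."""
    if min_spots < 0:
        raise ValueError("min_spots must be >= 0")
    detected = np.asarray((cm.counts > 0).sum(axis=0)).ravel()
    return cm.subset_genes(detected >= min_spots)


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormMatrix:
    """ln(1 + count * scale_factor / spot_total) per entry."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(cm.counts.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"spot {cm.barcodes[zero[0]]!r} has zero total counts; run QC first"
        )
    dense = cm.counts.toarray().astype(float)
    values = np.log1p(dense * scale_factor / totals[:, None])
    return NormMatrix(values, list(cm.barcodes), list(cm.genes), scale_factor,
                      provenance={"scale_factor": scale_factor})
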