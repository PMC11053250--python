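"""Marker-score assignment of spots to hippocampal subregions.

Each spot gets, per region, the mean across that region's marker genes of
the gene-wise z-score (gene centered/scaled across spots); the spot is
assigned to the argmax region when the best score clears a threshold,
otherwise to "other". This automates what is usually a manual
cluster-to-anatomy curation step.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import NormMatrix
from .st_io import GeneSetCollection, SpotTable

__all__ = ["MissingMarkersError", "marker_score", "assign_regions",
           "REGION_ORDER"]

#: fixed priority for argmax ties
REGION_ORDER = ("CA1", "CA3", "DG")


class MissingMarkersError(ValueError):
    """A marker set has no gene present in the matrix."""


def marker_score(nm: NormMatrix, markers: GeneSetCollection,
                 region_names=REGION_ORDER) -> pd.DataFrame:
    """Per-spot per-region marker z-score table (index = barcodes).

    Zero-variance genes contribute 0 to every spot's score.
    """
    gene_idx = nm.gene_index()
    mean = nm.values.mean(axis=0)
    sd = nm.values.std(axis=0)
    scores = {}
    for region in region_names:
        genes = markers[region]
        present = [gene_idx[g] for g in genes if g in gene_idx]
        if not present:
            raise MissingMarkersError(
                f"marker set {region!r}: none of {genes} present in matrix"
            )
        cols = np.array(present)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (nm.values[:, cols] - mean[cols]) / sd[cols]
        z[:, sd[cols] == 0] = 0.0
        scores[region] = z.mean(axis=1)
    return pd.DataFrame(scores, index=pd.Index(nm.barcodes, name="barcode"))


def assign_regions(scores: pd.DataFrame, threshold: float = 0.25,
                   spots: SpotTable | None = None):
    """Argmax region per spot, "other" below threshold.

    Ties resolve by the fixed order CA1 > CA3 > DG. When ``spots`` is
    given, returns a SpotTable with the region column filled; otherwise a
    barcode-indexed Series of labels.
    """
    ordered = [r for r in REGION_ORDER if r in scores.columns]
    mat = scores[ordered].to_numpy()
    best = mat.argmax(axis=1)  # first max -> CA1 > CA3 > DG priority
    labels = np.where(mat[np.arange(len(mat)), best] >= threshold,
                      np.array(ordered, dtype=object)[best], "other")
    series = pd.Series(labels, index=scores.index, name="region")
    if spots is None:
        return series
    return spots.with_regions(series)
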