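"""Spot-level differential expression screen and candidate prioritization.

Two-group Wilcoxon rank-sum per gene on log-normalized hippocampal spots,
BH-FDR adjustment, fold changes on de-logged normalized means, the
discovery gates |FC| >= 1.25 with Padj < 0.05 (top tier at FC >= 1.5),
and Spearman spatial similarity of each gene's expression with the
glutamatergic synapse score for ranking receptor-like candidates.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import NormMatrix
from .setscore import ScoreMatrix
from .st_io import GeneSetCollection
from .stats import bh_adjust, rank_sum_pvalues

__all__ = ["per_gene_test", "fold_change", "de_table", "spatial_similarity",
           "prioritize_candidates", "DEThresholds"]


class DEThresholds:
    """The discovery gates: |FC| >= fc, Padj < padj; top tier at FC >= top_fc."""

    def __init__(self, fc: float = 1.25, padj: float = 0.05,
                 top_fc: float = 1.5, pseudocount: float = 0.01):
        self.fc, self.padj, self.top_fc, self.pseudocount = fc, padj, top_fc, pseudocount


def _group_masks(groups, affected: str, control: str):
    groups = np.asarray(groups)
    aff, con = groups == affected, groups == control
    if aff.sum() < 2 or con.sum() < 2:
        raise ValueError("both groups need >= 2 spots")
    return aff, con


def per_gene_test(nm: NormMatrix, groups, affected: str, control: str) -> np.ndarray:
    """Two-sided Mann-Whitney p per gene (constant genes get p = 1)."""
    aff, con = _group_masks(groups, affected, control)
    values = nm.values[aff | con]
    return rank_sum_pvalues(values, aff[aff | con])


def fold_change(nm: NormMatrix, groups, affected: str, control: str,
                pseudocount: float = 0.01):
    """fc = (mean de-logged normalized expr, affected + c) / (control + c).

    Returns (fc, abs_fc, direction) arrays; abs_fc = max(fc, 1/fc).
    """
    aff, con = _group_masks(groups, affected, control)
    delog = np.expm1(nm.values)
    m_aff = delog[aff].mean(axis=0)
    m_con = delog[con].mean(axis=0)
    fc = (m_aff + pseudocount) / (m_con + pseudocount)
    abs_fc = np.maximum(fc, 1.0 / fc)
    direction = np.where(fc >= 1.0, "up", "down")
    return fc, abs_fc, direction


def spatial_similarity(nm: NormMatrix, scores: ScoreMatrix, set_name: str,
                       genes=None) -> pd.Series:
    """Spearman correlation of each gene's per-spot expression with the
    named score column. Constant genes (or a constant score) get 0 with a
    warning."""
    if nm.barcodes != scores.barcodes:
        raise ValueError("NormMatrix and ScoreMatrix barcodes differ")
    if len(nm.barcodes) < 3:
        raise ValueError("need >= 3 spots for a rank correlation")
    gene_idx = nm.gene_index()
    if genes is None:
        genes = list(nm.genes)
    missing = [g for g in genes if g not in gene_idx]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    cols = np.array([gene_idx[g] for g in genes])
    values = nm.values[:, cols]

    score = scores.column(set_name)
    if np.ptp(score) == 0:
        warnings.warn(f"score column {set_name!r} is constant; similarity = 0",
                      stacklevel=2)
        return pd.Series(0.0, index=pd.Index(genes, name="gene"))

    rs = rankdata(score)
    rs = (rs - rs.mean()) / rs.std()
    rv = rankdata(values, axis=0)
    sd = rv.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s); similarity = 0",
                      stacklevel=2)
    sd_safe = np.where(constant, 1.0, sd)
    rv = (rv - rv.mean(axis=0)) / sd_safe
    sim = rv.T @ rs / len(rs)
    sim[constant] = 0.0
    return pd.Series(sim, index=pd.Index(genes, name="gene"))


def de_table(nm: NormMatrix, groups, affected: str, control: str,
             thresholds: DEThresholds | None = None,
             scores: ScoreMatrix | None = None,
             similarity_set: str | None = None) -> pd.DataFrame:
    """Assemble the per-gene DE table, sorted by padj then abs_fc descending.

    When ``scores``/``similarity_set`` are given, the spatial-similarity
    column is filled; otherwise it is NaN.
    """
    th = thresholds or DEThresholds()
    aff, con = _group_masks(groups, affected, control)
    p = per_gene_test(nm, groups, affected, control)
    padj = bh_adjust(p)
    fc, abs_fc, direction = fold_change(nm, groups, affected, control,
                                        th.pseudocount)
    delog = np.expm1(nm.values)
    df = pd.DataFrame({
        "gene": nm.genes,
        "mean_affected": delog[aff].mean(axis=0),
        "mean_control": delog[con].mean(axis=0),
        "fc": fc,
        "abs_fc": abs_fc,
        "p": p,
        "padj": padj,
        "direction": direction,
    })
    df["pass_de"] = (df["abs_fc"] >= th.fc) & (df["padj"] < th.padj)
    df["top_tier"] = df["pass_de"] & (df["abs_fc"] >= th.top_fc)
    if scores is not None and similarity_set is not None:
        df["similarity"] = spatial_similarity(
            nm, scores, similarity_set).reindex(df["gene"]).to_numpy()
    else:
        df["similarity"] = np.nan
    df = df.sort_values(["padj", "abs_fc"], ascending=[True, False],
                        kind="mergesort").reset_index(drop=True)
    return df


def prioritize_candidates(de: pd.DataFrame, sets: GeneSetCollection,
                          set_name: str) -> pd.DataFrame:
    """Top-tier genes belonging to the named set, ranked by spatial
    similarity descending (ties by abs_fc descending). Empty when no gene
    qualifies."""
    members = set(sets[set_name])
    cand = de[de["top_tier"] & de["gene"].isin(members)].copy()
    cand = cand.sort_values(["similarity", "abs_fc"], ascending=[False, False],
                            kind="mergesort").reset_index(drop=True)
    return cand
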