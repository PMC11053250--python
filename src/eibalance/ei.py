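"""Excitatory/inhibitory spot classification and group comparison.

Each hippocampal spot is split at the pooled (both groups together) median
of its glutamatergic and GABAergic synapse scores into high/low levels;
the 2x2 of levels defines four categories: high-glut/low-GABA spots are
excitatory, low-glut/high-GABA inhibitory, and the two agreeing cells are
mixed. Group differences are tested with two-sided Mann-Whitney on the
scores and a two-proportion chi-square on the high-glutamatergic and
excitatory fractions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .setscore import ScoreMatrix
from .st_io import SpotTable
from .stats import rank_sum_test, two_proportion_test

__all__ = ["EIClassification", "GroupComparison", "CATEGORIES", "dichotomize",
           "classify_ei", "group_summary"]

CATEGORIES = ("excitatory", "inhibitory", "mixed_high", "mixed_low")


@dataclass
class EIClassification:
    barcodes: list[str]
    glut_level: np.ndarray  # "high"/"low"
    gaba_level: np.ndarray
    ei_call: np.ndarray     # one of CATEGORIES
    glut_median: float
    gaba_median: float

    def __post_init__(self) -> None:
        n = len(self.barcodes)
        for arr in (self.glut_level, self.gaba_level, self.ei_call):
            if len(arr) != n:
                raise ValueError("classification arrays must align with barcodes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": self.barcodes,
            "glut_level": self.glut_level,
            "gaba_level": self.gaba_level,
            "ei_call": self.ei_call,
        })


@dataclass
class GroupComparison:
    """Per-set score tests and per-category proportion summaries."""

    set_stats: pd.DataFrame       # set, per-group medians, U, p
    category_table: pd.DataFrame  # group, category, n, proportion
    proportion_tests: pd.DataFrame  # quantity, per-group k/n/prop, chi2, p
    groups: list[str] = field(default_factory=list)


def dichotomize(scores: ScoreMatrix, set_name: str) -> tuple[np.ndarray, float]:
    """High/low level per spot at the pooled median; ties at the median
    go low (strict >)."""
    col = scores.column(set_name)
    if col.size < 2:
        raise ValueError("need >= 2 spots to median-split")
    med = float(np.median(col))
    levels = np.where(col > med, "high", "low")
    return levels, med


def classify_ei(glut_levels, gaba_levels, barcodes=None,
                glut_median: float = np.nan,
                gaba_median: float = np.nan) -> EIClassification:
    glut = np.asarray(glut_levels)
    gaba = np.asarray(gaba_levels)
    if glut.shape != gaba.shape:
        raise ValueError("glut and gaba level arrays differ in length")
    hi_g, hi_b = glut == "high", gaba == "high"
    call = np.empty(glut.shape, dtype=object)
    call[hi_g & ~hi_b] = "excitatory"
    call[~hi_g & hi_b] = "inhibitory"
    call[hi_g & hi_b] = "mixed_high"
    call[~hi_g & ~hi_b] = "mixed_low"
    if barcodes is None:
        barcodes = [f"spot{i}" for i in range(len(glut))]
    return EIClassification(list(barcodes), glut, gaba, call,
                            glut_median, gaba_median)


def group_summary(cls: EIClassification, spots: SpotTable,
                  scores: ScoreMatrix) -> GroupComparison:
    """Group-wise score tests, category proportions, and proportion tests.

    ``spots`` supplies the group label per barcode; only barcodes present
    in the classification are summarized.
    """
    groups_by_bc = spots.table.set_index("barcode")["group"]
    group = pd.Series(cls.barcodes).map(groups_by_bc)
    if group.isna().any():
        missing = cls.barcodes[int(np.flatnonzero(group.isna())[0])]
        raise ValueError(f"barcode {missing!r} missing from SpotTable")
    group = group.to_numpy()
    group_names = sorted(set(group))
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups for a comparison")
    for g in group_names:
        if (group == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 spots")

    bc_pos = {b: i for i, b in enumerate(scores.barcodes)}
    rows = np.array([bc_pos[b] for b in cls.barcodes])

    set_rows = []
    for name in scores.set_names:
        col = scores.scores[:, scores.set_names.index(name)][rows]
        rec = {"set": name}
        for g in group_names:
            rec[f"median_{g}"] = float(np.median(col[group == g]))
        u, p = rank_sum_test(col[group == group_names[0]],
                             col[group == group_names[1]])
        rec["U"], rec["p"] = u, p
        set_rows.append(rec)

    cat_rows = []
    for g in group_names:
        calls = cls.ei_call[group == g]
        n_g = len(calls)
        for cat in CATEGORIES:
            n_cat = int((calls == cat).sum())
            cat_rows.append({"group": g, "category": cat, "n": n_cat,
                             "proportion": n_cat / n_g})

    prop_rows = []
    for label, indicator in (("high_glut", cls.glut_level == "high"),
                             ("high_gaba", cls.gaba_level == "high"),
                             ("excitatory", cls.ei_call == "excitatory")):
        ks, ns = [], []
        rec = {"quantity": label}
        for g in group_names:
            k = int(indicator[group == g].sum())
            n_g = int((group == g).sum())
            ks.append(k)
            ns.append(n_g)
            rec[f"k_{g}"], rec[f"n_{g}"] = k, n_g
            rec[f"prop_{g}"] = k / n_g
        chi2, p = two_proportion_test(ks[0], ns[0], ks[1], ns[1])
        rec["chi2"], rec["p"] = chi2, p
        prop_rows.append(rec)

    return GroupComparison(pd.DataFrame(set_rows), pd.DataFrame(cat_rows),
                           pd.DataFrame(prop_rows), group_names)
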