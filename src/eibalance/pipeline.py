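"""Schema-validated configuration and single-call orchestration.

Stages: simulate (or load) -> spot/gene QC -> log-normalize -> marker-based
region assignment -> per-spot synapse-set scoring on hippocampal spots ->
median-split E/I classification + group statistics -> DE screen + spatial
similarity -> candidate ranking. ``analyze_dataset`` runs everything in
memory; ``run_pipeline`` adds dataset generation/loading and writes TSV
result tables plus a JSON manifest recording the seed, every threshold,
and the spot/gene counts at each stage. Two runs with the same config and
seed are byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .descreen import DEThresholds, de_table, prioritize_candidates
from .ei import classify_ei, dichotomize, group_summary
from .preprocess import lognormalize, qc_genes, qc_spots
from .regions import assign_regions, marker_score
from .setscore import SetScoreParams, score_sets
from .simulate import GABA_SET, GLUT_SET, SimConfig, generate_dataset, write_dataset
from .st_io import (CountMatrix, GeneSetCollection, SpotTable,
                    read_count_matrix, read_gmt, read_positions)

__all__ = ["PipelineConfig", "ConfigSchemaError", "load_config",
           "analyze_dataset", "run_pipeline"]

log = logging.getLogger("eibalance")

_FLOAT_FMT = "%.10g"


class ConfigSchemaError(ValueError):
    """Configuration rejected by the schema (unknown key, bad value)."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    enabled: bool = True
    n_spots_per_sample: int = 1000
    n_genes: int = 1000
    hippocampal_fraction: float = 0.35
    marker_fold: float = 4.0
    marker_baseline_frac: float = 0.1
    glut_set_size: int = 30
    gaba_set_size: int = 30
    effect_glut: float = 1.5
    effect_gaba: float = 1.0
    receptor_boost: float = 2.0
    glut_program_cv: float = 0.0
    gaba_program_cv: float = 0.3
    baseline_mean: float = 0.5
    dispersion: float = 0.3
    libsize_cv: float = 0.3
    mito_fraction_mean: float = 0.05
    n_de_spike: int = 0
    de_spike_fold: float = 2.0


class SampleSpec(_Strict):
    name: str
    counts_dir: str
    positions: str
    group: str


class DataSection(_Strict):
    samples: list[SampleSpec]
    gene_sets: str  # GMT with synapse signatures and region markers


class QCSection(_Strict):
    min_features: int = 100
    max_mito: float = 0.2
    min_spots: int = 3


class NormSection(_Strict):
    scale_factor: float = 1e4


class RegionSection(_Strict):
    threshold: float = 0.25


class ScoreSection(_Strict):
    tau: float = 1.0
    es_mode: str = "diff"
    ecdf_mode: str = "ecdf"
    glut_set: str = GLUT_SET
    gaba_set: str = GABA_SET


class DESection(_Strict):
    fc_threshold: float = 1.25
    padj_threshold: float = 0.05
    top_fc: float = 1.5
    pseudocount: float = 0.01


class PipelineConfig(_Strict):
    seed: int = 7
    outdir: str = "eibalance_out"
    affected_group: str = "DSS"
    control_group: str = "CON"
    simulate: SimulateSection = SimulateSection()
    data: DataSection | None = None
    qc: QCSection = QCSection()
    norm: NormSection = NormSection()
    regions: RegionSection = RegionSection()
    score: ScoreSection = ScoreSection()
    de: DESection = DESection()

    def sim_config(self) -> SimConfig:
        fields = self.simulate.model_dump()
        fields.pop("enabled")
        return SimConfig(**fields, seed=self.seed,
                         groups=(self.control_group, self.affected_group),
                         affected_group=self.affected_group)


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigSchemaError(str(exc)) from exc


def _load_samples(data: DataSection):
    """Stack per-sample triplet matrices/positions into one dataset."""
    import scipy.sparse as sp

    mats, tables = [], []
    genes = None
    for spec in data.samples:
        cm = read_count_matrix(spec.counts_dir)
        if genes is None:
            genes = cm.genes
        elif cm.genes != genes:
            raise ValueError(f"sample {spec.name!r}: gene list differs")
        st = read_positions(spec.positions, sample=spec.name, group=spec.group)
        if st.barcodes != cm.barcodes:
            raise ValueError(f"sample {spec.name!r}: barcodes differ between "
                             "matrix and positions")
        mats.append(cm.counts)
        tables.append(st.table)
    cm = CountMatrix(sp.vstack(mats),
                     [b for t in tables for b in t["barcode"]], genes)
    st = SpotTable(pd.concat(tables, ignore_index=True))
    sets = read_gmt(data.gene_sets)
    return cm, st, sets


def analyze_dataset(cm: CountMatrix, spots: SpotTable, sets: GeneSetCollection,
                    cfg: PipelineConfig) -> dict:
    """Run QC -> normalize -> regions -> scores -> E/I -> DE, in memory."""
    stages: dict = {"input": {"n_spots": len(cm.barcodes),
                              "n_genes": len(cm.genes)}}

    log.info("stage qc")
    cm_qc = qc_spots(cm, cfg.qc.min_features, cfg.qc.max_mito)
    cm_qc = qc_genes(cm_qc, cfg.qc.min_spots)
    keep = pd.Series(spots.table["barcode"]).isin(cm_qc.barcodes).to_numpy()
    spots = SpotTable(spots.table[keep].reset_index(drop=True))
    stages["qc"] = {"n_spots": len(cm_qc.barcodes), "n_genes": len(cm_qc.genes),
                    "min_features": cfg.qc.min_features,
                    "max_mito": cfg.qc.max_mito, "min_spots": cfg.qc.min_spots}

    log.info("stage normalize")
    nm = lognormalize(cm_qc, cfg.norm.scale_factor)

    log.info("stage regions")
    region_scores = marker_score(nm, sets)
    spots = assign_regions(region_scores, cfg.regions.threshold, spots)
    hip_mask = spots.hippocampal_mask()
    stages["regions"] = {
        "threshold": cfg.regions.threshold,
        "hippocampal_spots_per_sample":
            spots.table.loc[hip_mask].groupby("sample").size().to_dict(),
    }
    if not hip_mask.any():
        raise RuntimeError("no hippocampal spots assigned; cannot continue")

    log.info("stage setscore")
    nm_hip = nm.subset_spots(hip_mask)
    spots_hip = SpotTable(spots.table[hip_mask].reset_index(drop=True))
    params = SetScoreParams(cfg.score.tau, cfg.score.es_mode, cfg.score.ecdf_mode)
    synapse_sets = GeneSetCollection(
        {cfg.score.glut_set: sets[cfg.score.glut_set],
         cfg.score.gaba_set: sets[cfg.score.gaba_set]})
    sm = score_sets(nm_hip, synapse_sets, params)
    stages["setscore"] = {"set_sizes_used": sm.set_sizes_used,
                          "params": asdict(params)}

    log.info("stage ei")
    glut_levels, glut_med = dichotomize(sm, cfg.score.glut_set)
    gaba_levels, gaba_med = dichotomize(sm, cfg.score.gaba_set)
    cls = classify_ei(glut_levels, gaba_levels, sm.barcodes, glut_med, gaba_med)
    comparison = group_summary(cls, spots_hip, sm)
    stages["ei"] = {"glut_median": glut_med, "gaba_median": gaba_med}

    log.info("stage de")
    th = DEThresholds(cfg.de.fc_threshold, cfg.de.padj_threshold,
                      cfg.de.top_fc, cfg.de.pseudocount)
    groups = spots_hip.table["group"].to_numpy()
    de = de_table(nm_hip, groups, cfg.affected_group, cfg.control_group,
                  th, scores=sm, similarity_set=cfg.score.glut_set)
    candidates = prioritize_candidates(de, sets, cfg.score.glut_set)
    stages["de"] = {
        "thresholds": {"fc": th.fc, "padj": th.padj, "top_fc": th.top_fc,
                       "pseudocount": th.pseudocount},
        "n_pass_de": int(de["pass_de"].sum()),
        "n_top_tier": int(de["top_tier"].sum()),
        "n_candidates": len(candidates),
    }

    return {
        "counts": cm_qc, "spots": spots, "spots_hip": spots_hip, "norm": nm,
        "norm_hip": nm_hip, "region_scores": region_scores, "scores": sm,
        "classification": cls, "comparison": comparison, "de": de,
        "candidates": candidates, "stages": stages,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate/load, analyze, and write result tables + manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate/load")
    gt = None
    if cfg.simulate.enabled:
        cm, spots, sets, gt = generate_dataset(cfg.sim_config())
        write_dataset(cm, spots, sets, gt, out / "dataset")
    elif cfg.data is not None:
        cm, spots, sets = _load_samples(cfg.data)
    else:
        raise ConfigSchemaError("either simulate.enabled or data must be set")

    bundle = analyze_dataset(cm, spots, sets, cfg)
    bundle["ground_truth"] = gt
    bundle["outdir"] = out

    # outdir is where the manifest itself lives; recording it would make
    # otherwise-identical runs differ
    manifest = {"version": __version__, "seed": cfg.seed,
                "config": cfg.model_dump(exclude={"outdir"}),
                "stages": bundle["stages"]}
    bundle["manifest"] = manifest

    spots_df = bundle["spots"].table
    spots_df.to_csv(out / "regions.tsv", sep="\t", index=False)
    sm = bundle["scores"]
    pd.DataFrame(sm.scores, columns=sm.set_names).assign(
        barcode=sm.barcodes)[["barcode", *sm.set_names]].to_csv(
        out / "scores.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    cls_df = bundle["classification"].to_frame().merge(
        bundle["spots_hip"].table[["barcode", "sample", "group", "region"]],
        on="barcode")
    cls_df.to_csv(out / "ei_classification.tsv", sep="\t", index=False)
    comparison = bundle["comparison"]
    comparison.set_stats.to_csv(out / "ei_set_stats.tsv", sep="\t",
                                index=False, float_format=_FLOAT_FMT)
    comparison.category_table.to_csv(out / "ei_summary.tsv", sep="\t",
                                     index=False, float_format=_FLOAT_FMT)
    comparison.proportion_tests.to_csv(out / "ei_proportion_tests.tsv",
                                       sep="\t", index=False,
                                       float_format=_FLOAT_FMT)
    bundle["de"].to_csv(out / "de_table.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)
    bundle["candidates"].to_csv(out / "candidates.tsv", sep="\t", index=False,
                                float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return bundle
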