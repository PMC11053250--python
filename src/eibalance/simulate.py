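"""Two-condition Visium-like count simulator with hippocampal band geometry.

Emulates the study design the pipeline targets: one control-like and one
colitis-like brain section of ~1000 spots each, a contiguous hippocampal
band (~350 spots/sample, inside [300, 400]) split into CA1/CA3/DG strips
with region-specific markers, negative-binomial UMI counts with spot
library-size variation and a small mitochondrial fraction, and a
multiplicative condition effect that inflates a glutamatergic synapse
signature in affected hippocampal spots while a GABAergic signature stays
at baseline. A designated receptor-like gene (Grm1) carries an extra boost
so its spatial pattern tracks the glutamatergic signature, mirroring the
candidate-gene logic the downstream screen is meant to recover.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .st_io import CountMatrix, GeneSetCollection, SpotTable, write_count_matrix, \
    write_gmt, write_positions

__all__ = ["SimConfig", "GroundTruth", "ConfigError", "default_config",
           "generate_dataset", "write_dataset", "substream"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Mouse-style gene symbols for the signature and marker sets. The first three
# genes of each region marker set are the CA1/CA3/DG cluster markers the
# analysis is anchored on; the remainder are plausible companions. These are
# synthetic stand-in sets, not curated pathway annotations.
GLUT_GENES = [
    "Grm1", "Shank3", "Grik4", "Grin1", "Grin2a", "Grin2b", "Gria1", "Gria2",
    "Gria3", "Grik2", "Grm5", "Dlg4", "Dlgap1", "Camk2a", "Slc17a7", "Slc17a6",
    "Nlgn1", "Nrxn1", "Syt1", "Stx1a", "Snap25", "Vamp2", "Homer1", "Shank1",
    "Shank2", "Epha4", "Ppp3ca", "Prkca", "Plcb1", "Itpr1",
]
GABA_GENES = [
    "Gabra1", "Gabra2", "Gabrb1", "Gabrb2", "Gabrb3", "Gabrg2", "Gabra5",
    "Gad1", "Gad2", "Slc32a1", "Slc6a1", "Gphn", "Nlgn2", "Gabbr1", "Gabbr2",
    "Pvalb", "Sst", "Vip", "Npy", "Cnr1", "Erbb4", "Lhx6", "Arx", "Dlx1",
    "Dlx2", "Slc6a11", "Abat", "Aldh5a1", "Trak2", "Plcl1",
]
MARKER_GENES = {
    "CA1": ["Itpka", "Fibcd1", "Spink8", "Wfs1", "Pou3f1", "Mpped1", "Nr3c2",
            "Klk8", "Satb2", "Gpr161"],
    "CA3": ["Cabp7", "Homer3", "Hs3st4", "Bok", "Slit2", "Cdh24", "Npy2r",
            "Chgb", "Coch", "Prss12"],
    "DG": ["C1ql2", "Fam163b", "Dsp", "Prox1", "Dock10", "Trpc6", "Stra6",
           "Rasgrp1", "Pdzd2", "Plk5"],
}
MITO_GENES = ["mt-Nd1", "mt-Nd2", "mt-Nd3", "mt-Nd4", "mt-Nd5", "mt-Co1",
              "mt-Co2", "mt-Co3", "mt-Atp6", "mt-Cytb"]

GLUT_SET = "Glutamatergic_synapse"
GABA_SET = "GABAergic_synapse"


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from a single pipeline seed.

    Keeps stages decoupled: changing how many draws one stage makes never
    perturbs another stage's stream.
    """
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag]))


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the packaged study conditions."""

    n_spots_per_sample: int = 1000
    n_genes: int = 1000
    hippocampal_fraction: float = 0.35
    #: region -> (first_row, last_row) inclusive; derived from
    #: hippocampal_fraction when None
    region_layout: dict | None = None
    marker_fold: float = 4.0
    #: marker genes are subfield-enriched: outside every band their baseline
    #: is baseline_mean * marker_baseline_frac (hippocampal subfield markers
    #: are close to background elsewhere in real sections)
    marker_baseline_frac: float = 0.1
    glut_set_size: int = 30
    gaba_set_size: int = 30
    #: multiplicative condition effect on glutamatergic-set genes in
    #: hippocampal spots of the affected group
    effect_glut: float = 1.5
    effect_gaba: float = 1.0
    #: extra fold on the receptor-like gene (first glutamatergic gene, Grm1)
    #: in affected hippocampal spots, on top of effect_glut
    receptor_boost: float = 2.0
    #: per-spot lognormal activity factor (CV) applied to all genes of the
    #: corresponding synapse program, emulating spot-to-spot variation in
    #: neuronal content; GABAergic signal is patchy in real sections
    #: (interneurons are sparse and scattered), so its default CV is larger
    glut_program_cv: float = 0.0
    gaba_program_cv: float = 0.3
    baseline_mean: float = 0.5
    dispersion: float = 0.3  # NB variance = mu + dispersion * mu^2
    libsize_cv: float = 0.3
    mito_fraction_mean: float = 0.05
    n_de_spike: int = 0
    de_spike_fold: float = 2.0
    groups: tuple = ("CON", "DSS")
    affected_group: str = "DSS"
    seed: int = 7

    def grid(self) -> tuple[int, int]:
        n_rows = max(3, round(math.sqrt(self.n_spots_per_sample / 1.6)))
        n_cols = math.ceil(self.n_spots_per_sample / n_rows)
        return n_rows, n_cols

    def layout(self) -> dict:
        """Resolved region row-bands (inclusive), disjoint and contiguous."""
        if self.region_layout is not None:
            return self.region_layout
        n_rows, _ = self.grid()
        n_hip = max(3, round(self.hippocampal_fraction * n_rows))
        n_hip = min(n_hip, n_rows)
        start = (n_rows - n_hip) // 2
        sizes = [n_hip // 3 + (1 if i < n_hip % 3 else 0) for i in range(3)]
        bands, lo = {}, start
        for region, size in zip(("CA1", "CA3", "DG"), sizes):
            bands[region] = (lo, lo + size - 1)
            lo += size
        return bands

    def validate(self) -> None:
        if self.effect_glut <= 0 or self.effect_gaba <= 0:
            raise ConfigError("effect sizes must be > 0")
        if self.receptor_boost <= 0 or self.de_spike_fold <= 0:
            raise ConfigError("fold parameters must be > 0")
        if not 0 < self.hippocampal_fraction < 1:
            raise ConfigError("hippocampal_fraction must be in (0, 1)")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigError("baseline_mean and dispersion must be > 0")
        if not 0 < self.marker_baseline_frac <= 1:
            raise ConfigError("marker_baseline_frac must be in (0, 1]")
        if self.libsize_cv < 0 or not 0 <= self.mito_fraction_mean < 1:
            raise ConfigError("invalid libsize_cv or mito_fraction_mean")
        if self.glut_program_cv < 0 or self.gaba_program_cv < 0:
            raise ConfigError("program CVs must be >= 0")
        n_special = (self.glut_set_size + self.gaba_set_size
                     + sum(len(v) for v in MARKER_GENES.values())
                     + len(MITO_GENES) + self.n_de_spike)
        if n_special >= self.n_genes:
            raise ConfigError(
                f"gene sets ({n_special} special genes) exceed n_genes={self.n_genes}"
            )
        bands = self.layout()
        if set(bands) != {"CA1", "CA3", "DG"}:
            raise ConfigError("region_layout must define CA1, CA3 and DG")
        rows: set[int] = set()
        for lo, hi in bands.values():
            band = set(range(lo, hi + 1))
            if not band or band & rows:
                raise ConfigError("region bands must be non-empty and disjoint")
            rows |= band
        if len(self.groups) != 2 or self.affected_group not in self.groups:
            raise ConfigError("need exactly two groups incl. affected_group")


@dataclass
class GroundTruth:
    """True per-spot regions and per-gene effects emitted by the generator."""

    spots: pd.DataFrame  # barcode, sample, group, region
    genes: pd.DataFrame  # gene, in_glut, in_gaba, marker_region, is_mito,
                         # is_spike, true_fold
    config: SimConfig = field(repr=False, default=None)


def default_config() -> SimConfig:
    """The packaged default study conditions (two samples, ~350 hip spots each)."""
    return SimConfig()


def _extend(names: list[str], size: int, stem: str) -> list[str]:
    if size <= len(names):
        return names[:size]
    return names + [f"{stem}{i:02d}" for i in range(len(names) + 1, size + 1)]


def _build_genes(config: SimConfig):
    glut = _extend(GLUT_GENES, config.glut_set_size, "Glut")
    gaba = _extend(GABA_GENES, config.gaba_set_size, "Gaba")
    markers = {r: list(g) for r, g in MARKER_GENES.items()}
    special = glut + gaba + sum(markers.values(), []) + MITO_GENES
    n_filler = config.n_genes - len(special)
    filler = [f"Gene{i:04d}" for i in range(1, n_filler + 1)]
    spikes = filler[:config.n_de_spike]
    genes = special + filler
    return genes, glut, gaba, markers, spikes


def generate_dataset(config: SimConfig):
    """Simulate both samples; deterministic given ``config.seed``.

    Returns ``(CountMatrix, SpotTable, GeneSetCollection, GroundTruth)``.
    """
    config.validate()
    genes, glut, gaba, markers, spikes = _build_genes(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = config.n_genes
    bands = config.layout()
    n_rows, n_cols = config.grid()

    # per-gene baseline means; mitochondrial genes elevated to hit the
    # expected mitochondrial fraction
    base = np.full(n_genes, config.baseline_mean)
    mito_idx = np.array([gene_idx[g] for g in MITO_GENES])
    non_mito_total = config.baseline_mean * (n_genes - len(MITO_GENES))
    if config.mito_fraction_mean > 0:
        base[mito_idx] = (
            config.mito_fraction_mean / (1 - config.mito_fraction_mean)
            * non_mito_total / len(MITO_GENES)
        )

    glut_idx = np.array([gene_idx[g] for g in glut])
    gaba_idx = np.array([gene_idx[g] for g in gaba])
    spike_idx = np.array([gene_idx[g] for g in spikes], dtype=int)
    receptor = glut[0]

    rng_lib = substream(config.seed, "libsize")
    rng_counts = substream(config.seed, "counts")
    rng_prog = substream(config.seed, "program")

    def _lognormal_factors(rng, cv: float, n: int) -> np.ndarray:
        if cv <= 0:
            return np.ones(n)
        sigma = math.sqrt(math.log(1 + cv**2))
        return rng.lognormal(-sigma**2 / 2, sigma, n)

    all_counts, bc, spot_rows = [], [], []
    for sample_i, group in enumerate(config.groups):
        sample = group
        # row-major grid, truncated to n_spots
        rows = np.repeat(np.arange(n_rows), n_cols)[: config.n_spots_per_sample]
        cols = np.tile(np.arange(n_cols), n_rows)[: config.n_spots_per_sample]
        region = np.full(config.n_spots_per_sample, "other", dtype=object)
        for r, (lo, hi) in bands.items():
            region[(rows >= lo) & (rows <= hi)] = r
        hip = np.isin(region, ["CA1", "CA3", "DG"])

        mult = np.ones((config.n_spots_per_sample, n_genes))
        for r, names in markers.items():
            idx = np.array([gene_idx[g] for g in names])
            mult[:, idx] *= config.marker_baseline_frac
            mult[np.ix_(region == r, idx)] *= (config.marker_fold
                                               / config.marker_baseline_frac)
        if group == config.affected_group:
            mult[np.ix_(hip, glut_idx)] *= config.effect_glut
            mult[np.ix_(hip, gaba_idx)] *= config.effect_gaba
            mult[hip, gene_idx[receptor]] *= config.receptor_boost
            if spike_idx.size:
                mult[np.ix_(hip, spike_idx)] *= config.de_spike_fold

        # spot-level synaptic-program activity (neuronal content variation)
        n_spots = config.n_spots_per_sample
        mult[:, glut_idx] *= _lognormal_factors(
            rng_prog, config.glut_program_cv, n_spots)[:, None]
        mult[:, gaba_idx] *= _lognormal_factors(
            rng_prog, config.gaba_program_cv, n_spots)[:, None]

        if config.libsize_cv > 0:
            sigma = math.sqrt(math.log(1 + config.libsize_cv**2))
            lib = rng_lib.lognormal(-sigma**2 / 2, sigma,
                                    config.n_spots_per_sample)
        else:
            lib = np.ones(config.n_spots_per_sample)

        mean = base[None, :] * mult * lib[:, None]
        r_nb = 1.0 / config.dispersion
        counts = rng_counts.negative_binomial(r_nb, r_nb / (r_nb + mean))
        all_counts.append(sp.csr_matrix(counts))

        barcodes = [f"{sample}-{i:04d}" for i in range(config.n_spots_per_sample)]
        bc.extend(barcodes)
        spot_rows.append(pd.DataFrame({
            "barcode": barcodes, "row": rows, "col": cols, "in_tissue": 1,
            "sample": sample, "group": group, "region": "unassigned",
            "_true_region": region,
        }))

    spot_df = pd.concat(spot_rows, ignore_index=True)
    cm = CountMatrix(sp.vstack(all_counts), bc, genes)
    st = SpotTable(spot_df.drop(columns="_true_region"))

    sets = GeneSetCollection(
        {GLUT_SET: glut, GABA_SET: gaba, **{r: markers[r] for r in ("CA1", "CA3", "DG")}},
        {GLUT_SET: "glutamatergic synapse signature",
         GABA_SET: "GABAergic synapse signature",
         "CA1": "CA1 markers", "CA3": "CA3 markers", "DG": "DG markers"},
    )

    true_fold = np.ones(n_genes)
    true_fold[glut_idx] *= config.effect_glut
    true_fold[gaba_idx] *= config.effect_gaba
    true_fold[gene_idx[receptor]] *= config.receptor_boost
    if spike_idx.size:
        true_fold[spike_idx] *= config.de_spike_fold
    marker_region = np.full(n_genes, "", dtype=object)
    for r, names in markers.items():
        marker_region[[gene_idx[g] for g in names]] = r
    gene_df = pd.DataFrame({
        "gene": genes,
        "in_glut": np.isin(np.arange(n_genes), glut_idx),
        "in_gaba": np.isin(np.arange(n_genes), gaba_idx),
        "marker_region": marker_region,
        "is_mito": np.isin(np.arange(n_genes), mito_idx),
        "is_spike": np.isin(np.arange(n_genes), spike_idx),
        "true_fold": true_fold,
    })
    gt = GroundTruth(
        spots=spot_df.drop(columns="region")
        .rename(columns={"_true_region": "region"})[
            ["barcode", "sample", "group", "region"]].copy(),
        genes=gene_df,
        config=replace(config),
    )
    return cm, st, sets, gt


def write_dataset(cm: CountMatrix, st: SpotTable, sets: GeneSetCollection,
                  gt: GroundTruth, outdir) -> None:
    """Persist a generated dataset: triplet matrix, positions CSV, GMT,
    and ground-truth sidecar TSVs."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(cm, out / "matrix")
    write_positions(st, out / "positions.csv")
    write_gmt(sets, out / "gene_sets.gmt")
    gt.spots.to_csv(out / "ground_truth_spots.tsv", sep="\t", index=False)
    gt.genes.to_csv(out / "ground_truth_genes.tsv", sep="\t", index=False)
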