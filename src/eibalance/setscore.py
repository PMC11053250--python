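"""Per-spot gene-set variation scores, built from first principles.

The statistic is the rank-based single-sample enrichment score used for
the glutamatergic/GABAergic synapse signatures: for each gene an
expression-level statistic is computed across spots (an averaged-tie ECDF
by default, optionally a Gaussian-kernel CDF estimate); within each spot
genes are ordered by that statistic and a Kolmogorov-Smirnov-like random
walk compares the weighted distribution of set genes against the uniform
distribution of the complement. The enrichment score is either the sum of
the walk's largest positive and negative deviations ("diff", the default)
or the single deviation of maximal magnitude ("maxabs").

Stages are exposed separately (``ecdf_transform``, ``spot_rank_stat``,
``random_walk_es``) so each can be checked against independent oracles;
``score_sets`` composes them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .preprocess import NormMatrix
from .st_io import GeneSetCollection

__all__ = ["SetScoreParams", "ScoreMatrix", "SetScoreError", "ecdf_transform",
           "spot_rank_stat", "random_walk_es", "score_sets", "permutation_null"]


class SetScoreError(ValueError):
    """Degenerate scoring input (empty set, set covering every gene, ...)."""


@dataclass(frozen=True)
class SetScoreParams:
    tau: float = 1.0            # walk weight exponent on |N/2 - rank|
    es_mode: str = "diff"       # "diff" (max + min deviation) or "maxabs"
    ecdf_mode: str = "ecdf"     # "ecdf" or "gaussian-kernel" (bandwidth sd/4)

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise SetScoreError("tau must be >= 0")
        if self.es_mode not in ("diff", "maxabs"):
            raise SetScoreError(f"unknown es_mode {self.es_mode!r}")
        if self.ecdf_mode not in ("ecdf", "gaussian-kernel"):
            raise SetScoreError(f"unknown ecdf_mode {self.ecdf_mode!r}")


@dataclass
class ScoreMatrix:
    """Spots x gene-sets enrichment scores."""

    scores: np.ndarray
    barcodes: list[str]
    set_names: list[str]
    params: SetScoreParams = field(default_factory=SetScoreParams)
    set_sizes_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.barcodes), len(self.set_names)):
            raise ValueError("scores shape does not match barcodes/set names")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def column(self, set_name: str) -> np.ndarray:
        try:
            j = self.set_names.index(set_name)
        except ValueError:
            raise KeyError(f"unknown gene set {set_name!r}") from None
        return self.scores[:, j]


def ecdf_transform(nm, params: SetScoreParams | None = None) -> np.ndarray:
    """Stage 1: per-gene expression-level statistic across spots.

    Default mode: averaged-tie rank of each spot among all spots for the
    gene, divided by the number of spots (values in (0, 1]). Kernel mode:
    Gaussian CDF estimate with bandwidth = gene sd / 4; zero-variance
    genes fall back to 0.5 everywhere.
    """
    params = params or SetScoreParams()
    values = nm.values if isinstance(nm, NormMatrix) else np.asarray(nm, float)
    n_spots = values.shape[0]
    if n_spots < 2:
        raise SetScoreError("need >= 2 spots to rank expression across spots")
    if params.ecdf_mode == "ecdf":
        return rankdata(values, axis=0) / n_spots
    out = np.empty_like(values, dtype=float)
    sd = values.std(axis=0)
    for j in range(values.shape[1]):  # per-gene kernel CDF
        if sd[j] == 0:
            out[:, j] = 0.5
            continue
        h = sd[j] / 4
        diffs = (values[:, j][:, None] - values[:, j][None, :]) / h
        out[:, j] = norm.cdf(diffs).mean(axis=1)
    return out


def spot_rank_stat(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stage 2: per-spot gene ordering and rank weights.

    Genes are ordered by the stage-1 statistic descending, ties broken by
    gene index ascending. Returns ``(order, rank_weights)`` where
    ``order[s]`` lists gene indices from rank 1 to N for spot ``s`` and
    ``rank_weights[r-1] = |N/2 - r|`` (identical for every spot).
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    n_genes = e.shape[1]
    order = np.argsort(-e, axis=1, kind="stable")
    ranks = np.arange(1, n_genes + 1)
    return order, np.abs(n_genes / 2 - ranks)


def _es_from_walk(nu: np.ndarray, es_mode: str) -> np.ndarray:
    """Reduce walk trajectories (rows) to enrichment scores.

    The walk starts at 0, so the 0 state participates in both extrema of
    "diff" mode: ES = max(nu, 0) + min(nu, 0).
    """
    if es_mode == "diff":
        return np.maximum(nu.max(axis=-1), 0) + np.minimum(nu.min(axis=-1), 0)
    idx = np.abs(nu).argmax(axis=-1)
    return np.take_along_axis(nu, idx[..., None], axis=-1)[..., 0]


def _walk(in_set: np.ndarray, rank_weights: np.ndarray, tau: float) -> np.ndarray:
    """Walk trajectories for boolean in-set indicators in rank order.

    ``in_set`` may be 1-D (one spot) or 2-D (spots x genes-in-rank-order).
    """
    in_set = np.atleast_2d(in_set)
    n_genes = in_set.shape[1]
    m = in_set.sum(axis=1)
    if np.any(m == 0):
        raise SetScoreError("gene set has no member in the matrix")
    if np.any(m == n_genes):
        raise SetScoreError("gene set covers every gene; walk undefined")
    w = np.abs(rank_weights) ** tau
    num = np.cumsum(np.where(in_set, w[None, :], 0.0), axis=1)
    den = num[:, -1].copy()
    # all in-set weights zero (possible at tau>0 when every set gene sits at
    # weight 0): fall back to the unweighted in-set step function
    flat = den == 0
    if flat.any():
        cnt = np.cumsum(in_set[flat], axis=1)
        num[flat] = cnt
        den[flat] = m[flat]
    inside = num / den[:, None]
    outside = np.cumsum(~in_set, axis=1) / (n_genes - m)[:, None]
    return inside - outside


def random_walk_es(order: np.ndarray, rank_weights: np.ndarray,
                   set_mask: np.ndarray,
                   params: SetScoreParams | None = None) -> float:
    """Stage 3 for a single spot: weighted KS walk enrichment score.

    ``order`` is the spot's gene ranking (gene indices, best first),
    ``rank_weights`` the per-rank weights, ``set_mask`` a boolean gene
    membership vector.
    """
    params = params or SetScoreParams()
    set_mask = np.asarray(set_mask, dtype=bool)
    in_set = set_mask[np.asarray(order)]
    nu = _walk(in_set, np.asarray(rank_weights, float), params.tau)
    return float(_es_from_walk(nu, params.es_mode)[0])


def score_sets(nm: NormMatrix, sets: GeneSetCollection,
               params: SetScoreParams | None = None) -> ScoreMatrix:
    """Compose the three stages for every spot and every gene set."""
    params = params or SetScoreParams()
    e = ecdf_transform(nm, params)
    order, rank_weights = spot_rank_stat(e)
    gene_idx = nm.gene_index()
    n_genes = len(nm.genes)

    cols, sizes = [], {}
    for name in sets.names():
        present = [gene_idx[g] for g in sets[name] if g in gene_idx]
        if not present:
            raise SetScoreError(f"gene set {name!r} has no gene in the matrix")
        if len(present) == n_genes:
            raise SetScoreError(f"gene set {name!r} covers every gene")
        mask = np.zeros(n_genes, dtype=bool)
        mask[present] = True
        nu = _walk(mask[order], rank_weights, params.tau)
        cols.append(_es_from_walk(nu, params.es_mode))
        sizes[name] = len(present)
    return ScoreMatrix(np.column_stack(cols), list(nm.barcodes), sets.names(),
                       params, sizes)


def permutation_null(nm: NormMatrix, set_size: int, n_perm: int, seed: int,
                     params: SetScoreParams | None = None) -> np.ndarray:
    """Null ES sample: scores of ``n_perm`` random gene sets of ``set_size``.

    Returns an (n_perm, n_spots) array; seeded and reproducible.
    """
    params = params or SetScoreParams()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_genes = len(nm.genes)
    if not 1 <= set_size < n_genes:
        raise SetScoreError("set_size must satisfy 1 <= set_size < n_genes")
    e = ecdf_transform(nm, params)
    order, rank_weights = spot_rank_stat(e)
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, len(nm.barcodes)))
    for k in range(n_perm):
        mask = np.zeros(n_genes, dtype=bool)
        mask[rng.choice(n_genes, size=set_size, replace=False)] = True
        nu = _walk(mask[order], rank_weights, params.tau)
        out[k] = _es_from_walk(nu, params.es_mode)
    return out
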