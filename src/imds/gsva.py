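"""Single-sample gene-set enrichment scoring.

The engine converts a genes x samples log2 expression matrix into a
signatures x samples enrichment-score (ES) matrix in three steps:

1. per-gene Gaussian kernel CDF across samples (bandwidth = sd/4),
2. per-sample ranking of genes by decreasing statistic and a symmetric
   rank statistic |p/2 - rank|,
3. a weighted Kolmogorov-Smirnov-like random walk per signature, with
   ES = max positive deviation minus the magnitude of the max negative
   deviation ("max-diff" mode), so every score lies in [-1, 1].

Scores are cohort-relative: the kernel CDF is fit across the samples in
the call, so train/validation cohorts must either be scored jointly or
treated as deliberately separate scoring universes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import json

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data import ExpressionMatrix
from .signatures import SignatureLibrary

logger = logging.getLogger(__name__)

MIN_SAMPLES_KCDF = 3
DEFAULT_MIN_SET_SIZE = 5
DEFAULT_MAX_SET_SIZE = 500


@dataclass
class ESMatrix:
    """Signatures x samples enrichment scores plus the parameter record."""

    scores: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def signature_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def write(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="signature")
        sidecar = Path(path).with_suffix(Path(path).suffix + ".params.json")
        sidecar.write_text(json.dumps(self.params, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "ESMatrix":
        scores = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".params.json")
        params = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(scores, params)


# ---------------------------------------------------------------------------
# Step 1: kernel CDF
# ---------------------------------------------------------------------------

def kcdf_transform(x: np.ndarray, min_samples: int = MIN_SAMPLES_KCDF) -> np.ndarray:
    """Gaussian kernel CDF statistic per gene across samples.

    z[i, j] = (1/n) * sum_k Phi((x[i, j] - x[i, k]) / h_i) with bandwidth
    h_i = s_i / 4 (sample sd, ddof=1).  Zero-variance genes are mapped to
    the uninformative constant 0.5 with a warning.  Location and positive
    scale changes of a gene's row leave its z row unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-d genes x samples array")
    n = x.shape[1]
    if n < min_samples:
        raise ValueError(f"kernel CDF estimation requires >= {min_samples} samples, got {n}")
    s = x.std(axis=1, ddof=1)
    zero_var = s == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s) assigned constant 0.5",
            stacklevel=2,
        )
    h = np.where(zero_var, 1.0, s / 4.0)
    z = np.empty_like(x)
    # chunk over genes to bound the (chunk, n, n) pairwise-difference tensor
    chunk = max(1, int(4_000_000 // max(n * n, 1)))
    for i0 in range(0, x.shape[0], chunk):
        xi = x[i0 : i0 + chunk]
        d = (xi[:, :, None] - xi[:, None, :]) / h[i0 : i0 + chunk, None, None]
        z[i0 : i0 + chunk] = ndtr(d).mean(axis=2)
    z[zero_var] = 0.5
    return z


# ---------------------------------------------------------------------------
# Step 2: symmetric rank statistic
# ---------------------------------------------------------------------------

def gene_ranking(z: np.ndarray) -> np.ndarray:
    """Per-sample gene order by decreasing statistic (stable on ties).

    Returns an integer array ``order`` of the same shape where
    ``order[k, j]`` is the gene index at rank k+1 in sample j.
    """
    return np.argsort(-np.asarray(z, dtype=float), axis=0, kind="stable")


def rank_statistic(z: np.ndarray) -> np.ndarray:
    """Symmetric rank statistic r[i, j] = |p/2 - rank_ij| per sample.

    Ranks run 1..p by decreasing z within each sample; ties break by gene
    index (stable), so ES may differ at machine precision from other tie
    conventions.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("rank statistic requires finite input")
    p, n = z.shape
    order = gene_ranking(z)
    ranks = np.empty((p, n), dtype=np.int64)
    cols = np.arange(n)[None, :]
    ranks[order, cols] = np.arange(1, p + 1)[:, None]
    return np.abs(p / 2.0 - ranks)


# ---------------------------------------------------------------------------
# Step 3: weighted random walk
# ---------------------------------------------------------------------------

def walk_es(
    r_sample: np.ndarray,
    order_sample: np.ndarray,
    geneset: Iterable[int],
    tau: float = 1.0,
) -> float:
    """Enrichment score for one signature in one sample.

    Walk over genes in rank order; in-set steps are weighted by the rank
    statistic to the power ``tau`` (normalized over the set), out-of-set
    steps by 1/(p - m).  ES = max positive excursion + min negative
    excursion of the running sum.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    order_sample = np.asarray(order_sample)
    p = r_sample.size
    idx = np.fromiter(geneset, dtype=np.int64)
    m = idx.size
    if m == 0 or m >= p:
        raise ValueError(f"gene set size must satisfy 1 <= m < p, got m={m}, p={p}")
    inset = np.zeros(p, dtype=bool)
    inset[idx] = True
    inset_sorted = inset[order_sample]
    w = np.where(inset_sorted, r_sample[order_sample] ** tau, 0.0)
    wsum = w.sum()
    steps = np.where(inset_sorted, w / wsum, -1.0 / (p - m))
    nu = np.cumsum(steps)
    return float(max(nu.max(), 0.0) + min(nu.min(), 0.0))


# ---------------------------------------------------------------------------
# Full scoring
# ---------------------------------------------------------------------------

def gsva_scores(
    expr: ExpressionMatrix,
    lib: SignatureLibrary,
    tau: float = 1.0,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> ESMatrix:
    """Score every signature in every sample.

    Signature gene sets are intersected with the expression matrix's gene
    universe first; signatures falling outside [min_size, max_size] after
    intersection are dropped with a warning.  Deterministic for fixed
    input.
    """
    x = expr.values.to_numpy(dtype=float)
    p = x.shape[0]
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}

    kept_ids: list[str] = []
    gene_sets: list[np.ndarray] = []
    for sig in lib:
        idx = np.array(
            sorted(gene_index[g] for g in sig.genes if g in gene_index),
            dtype=np.int64,
        )
        if idx.size < min_size or idx.size > max_size or idx.size >= p:
            warnings.warn(
                f"signature {sig.id!r} dropped: {idx.size} genes in universe "
                f"outside [{min_size}, {min(max_size, p - 1)}]",
                stacklevel=2,
            )
            continue
        kept_ids.append(sig.id)
        gene_sets.append(idx)
    if not kept_ids:
        raise ValueError("no signature survives intersection with the gene universe")

    z = kcdf_transform(x)
    order = gene_ranking(z)
    r = rank_statistic(z)

    m = len(kept_ids)
    membership = np.zeros((m, p), dtype=bool)
    for row, idx in enumerate(gene_sets):
        membership[row, idx] = True
    sizes = membership.sum(axis=1)

    n = x.shape[1]
    es = np.empty((m, n))
    for j in range(n):
        o = order[:, j]
        r_sorted = r[o, j] ** tau
        mem_sorted = membership[:, o]
        w = mem_sorted * r_sorted[None, :]
        inc = w / w.sum(axis=1, keepdims=True)
        dec = (~mem_sorted) / (p - sizes)[:, None]
        nu = np.cumsum(inc - dec, axis=1)
        es[:, j] = np.maximum(nu.max(axis=1), 0.0) + np.minimum(nu.min(axis=1), 0.0)

    scores = pd.DataFrame(es, index=kept_ids, columns=expr.sample_ids)
    params = {
        "kernel": "gaussian",
        "bandwidth": "sd/4",
        "tau": tau,
        "es_mode": "max-diff",
        "min_set_size": min_size,
        "max_set_size": max_size,
        "n_genes": int(p),
        "n_samples": int(n),
    }
    return ESMatrix(scores, params)
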