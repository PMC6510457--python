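"""Gene-signature library: GMT I/O, validation, auditing and derivation.

A signature is a named set of gene symbols with an optional direction
(UP/DOWN).  Libraries are ordered, id-unique collections.  The standard
curation rules are: symbols uppercased and deduplicated at load, mixed
signatures split into single-direction halves, and signatures with fewer
than five genes discarded.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 5

UP = "UP"
DOWN = "DOWN"


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set.

    ``genes`` preserves first-seen order (stored as a tuple) but compares
    as a set for overlap purposes.  ``direction`` is UP, DOWN or None;
    ``gene_directions`` optionally annotates per-gene direction for mixed
    signatures awaiting a split.
    """

    id: str
    genes: tuple[str, ...]
    description: str = ""
    direction: str | None = None
    gene_directions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("signature id must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.id!r} has no genes")
        if any(not g for g in self.genes):
            raise ValueError(f"signature {self.id!r} contains empty gene symbols")
        if self.direction is not None and self.direction not in (UP, DOWN):
            raise ValueError(f"direction must be UP or DOWN, got {self.direction!r}")

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def _normalize_genes(
    genes: Iterable[str], alias_map: Mapping[str, str] | None = None
) -> tuple[str, ...]:
    """Uppercase, apply optional alias remapping, deduplicate keeping order."""
    seen: dict[str, None] = {}
    for g in genes:
        g = g.strip().upper()
        if not g:
            continue
        if alias_map:
            g = alias_map.get(g, g).upper()
        seen.setdefault(g, None)
    return tuple(seen)


def make_signature(
    sig_id: str,
    genes: Iterable[str],
    description: str = "",
    direction: str | None = None,
    alias_map: Mapping[str, str] | None = None,
    gene_directions: Mapping[str, str] | None = None,
) -> GeneSignature:
    """Construct a signature with symbol normalization applied."""
    norm = _normalize_genes(genes, alias_map)
    if direction is None:
        direction = infer_direction(sig_id)
    gd = None
    if gene_directions is not None:
        gd = {k.strip().upper(): v for k, v in gene_directions.items()}
    return GeneSignature(
        id=sig_id, genes=norm, description=description, direction=direction,
        gene_directions=gd,
    )


def infer_direction(sig_id: str) -> str | None:
    """Infer UP/DOWN from an id suffix like ``Tcell.activated.HS.IVS.UP``."""
    tail = sig_id.rsplit(".", 1)[-1].rsplit("_", 1)[-1].upper()
    if tail in (UP, DOWN):
        return tail
    return None


class SignatureLibrary:
    """Ordered collection of :class:`GeneSignature` with unique ids."""

    def __init__(self, signatures: Iterable[GeneSignature] = ()) -> None:
        self._signatures: list[GeneSignature] = []
        self._by_id: dict[str, GeneSignature] = {}
        for sig in signatures:
            self.add(sig)

    def add(self, sig: GeneSignature) -> None:
        if sig.id in self._by_id:
            raise ValueError(f"duplicate signature id: {sig.id!r}")
        self._signatures.append(sig)
        self._by_id[sig.id] = sig

    def __len__(self) -> int:
        return len(self._signatures)

    def __iter__(self) -> Iterator[GeneSignature]:
        return iter(self._signatures)

    def __contains__(self, sig_id: str) -> bool:
        return sig_id in self._by_id

    def __getitem__(self, sig_id: str) -> GeneSignature:
        return self._by_id[sig_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureLibrary):
            return NotImplemented
        return self._signatures == other._signatures

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self._signatures]

    def subset(self, ids: Iterable[str]) -> "SignatureLibrary":
        return SignatureLibrary(self._by_id[i] for i in ids)

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for sig in self._signatures:
            out |= sig.gene_set
        return out

    def membership(self, gene_order: list[str]) -> np.ndarray:
        """Boolean signatures x genes matrix against a fixed gene order."""
        index = {g: i for i, g in enumerate(gene_order)}
        mat = np.zeros((len(self), len(gene_order)), dtype=bool)
        for row, sig in enumerate(self._signatures):
            for g in sig.genes:
                j = index.get(g)
                if j is not None:
                    mat[row, j] = True
        return mat


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> SignatureLibrary:
    """Read a GMT file (tab-separated: id, description, genes...).

    Gene symbols are uppercased and deduplicated; line order is preserved.
    Raises on duplicate ids and on lines with fewer than three fields.
    """
    lib = SignatureLibrary()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            sig_id, description = fields[0].strip(), fields[1]
            if sig_id in lib:
                raise ValueError(f"{path}: duplicate signature id {sig_id!r}")
            sig = make_signature(sig_id, fields[2:], description=description,
                                 alias_map=alias_map)
            lib.add(sig)
    return lib


def write_gmt(lib: SignatureLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in lib:
            fh.write("\t".join([sig.id, sig.description, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# Curation rules
# ---------------------------------------------------------------------------

def filter_min_genes(
    lib: SignatureLibrary, min_genes: int = DEFAULT_MIN_GENES
) -> SignatureLibrary:
    """Drop signatures with fewer than ``min_genes`` genes (order preserved)."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    kept, removed = [], []
    for sig in lib:
        (kept if len(sig) >= min_genes else removed).append(sig)
    if removed:
        logger.info(
            "filter_min_genes removed %d signature(s): %s",
            len(removed), ", ".join(s.id for s in removed),
        )
    return SignatureLibrary(kept)


def split_directions(
    lib: SignatureLibrary, min_genes: int = DEFAULT_MIN_GENES
) -> SignatureLibrary:
    """Split mixed signatures into single-direction UP/DOWN halves.

    Already single-direction signatures pass through unchanged.  The
    minimum-size filter is re-applied to the split halves.
    """
    out = SignatureLibrary()
    for sig in lib:
        if sig.direction is not None:
            out.add(sig)
            continue
        if sig.gene_directions is None:
            raise ValueError(
                f"signature {sig.id!r} has no direction information to split on"
            )
        for direction in (UP, DOWN):
            genes = tuple(
                g for g in sig.genes
                if sig.gene_directions.get(g, "").upper() == direction
            )
            if len(genes) < min_genes:
                if genes:
                    logger.info(
                        "split_directions dropped %s.%s (%d genes < %d)",
                        sig.id, direction, len(genes), min_genes,
                    )
                continue
            out.add(GeneSignature(
                id=f"{sig.id}.{direction}", genes=genes,
                description=sig.description, direction=direction,
            ))
    return out


# ---------------------------------------------------------------------------
# Signature derivation from differential expression
# ---------------------------------------------------------------------------

def derive_signature_from_de(
    expr: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    case: str,
    control: str,
    sig_id: str = "derived",
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    min_genes: int = DEFAULT_MIN_GENES,
) -> tuple[GeneSignature | None, GeneSignature | None]:
    """Derive an (UP, DOWN) signature pair from a two-group comparison.

    Per-gene pooled-variance t-tests on log2 values; UP keeps genes with
    log2 fold change >= log2(fc_threshold) and BH-FDR < fdr_threshold,
    DOWN the mirror image.  Either element is None when fewer than
    ``min_genes`` genes qualify.
    """
    groups = pd.Series(groups)
    case_ids = groups.index[groups == case]
    ctrl_ids = groups.index[groups == control]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(case_ids)} {case!r} "
            f"and {len(ctrl_ids)} {control!r}"
        )
    a = expr.values[case_ids].to_numpy(float)
    b = expr.values[ctrl_ids].to_numpy(float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.nan_to_num(p, nan=1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    log2_fc = math.log2(fc_threshold)
    genes = np.asarray(expr.gene_ids)
    up_genes = genes[(lfc >= log2_fc) & (p_adj < fdr_threshold)]
    dn_genes = genes[(lfc <= -log2_fc) & (p_adj < fdr_threshold)]

    def _build(symbols: np.ndarray, direction: str) -> GeneSignature | None:
        if len(symbols) < min_genes:
            return None
        return make_signature(f"{sig_id}.{direction}", symbols, direction=direction)

    return _build(up_genes, UP), _build(dn_genes, DOWN)


# ---------------------------------------------------------------------------
# Overlap audit
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    n_signatures: int
    n_pairs: int
    threshold: float
    method: str
    pairs_over: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_over(self) -> int:
        return len(self.pairs_over)


def overlap_fraction(a: frozenset[str], b: frozenset[str], method: str = "min") -> float:
    """Pairwise gene-overlap fraction.

    ``min``: |A n B| / min(|A|, |B|) — flags containment, the redundancy
    that would bias an additive score.  ``jaccard``: |A n B| / |A u B|.
    """
    inter = len(a & b)
    if method == "min":
        denom = min(len(a), len(b))
    elif method == "jaccard":
        denom = len(a | b)
    else:
        raise ValueError(f"unknown overlap method {method!r}")
    return inter / denom if denom else 0.0


def overlap_summary(
    lib: SignatureLibrary, threshold: float = 0.20, method: str = "min"
) -> OverlapSummary:
    """Audit all unordered signature pairs for gene overlap >= threshold."""
    sigs = list(lib)
    if len(sigs) < 2:
        raise ValueError("overlap audit requires a library of >= 2 signatures")
    pairs_over = []
    for sa, sb in itertools.combinations(sigs, 2):
        frac = overlap_fraction(sa.gene_set, sb.gene_set, method=method)
        if frac >= threshold:
            pairs_over.append((sa.id, sb.id, frac))
    m = len(sigs)
    return OverlapSummary(
        n_signatures=m,
        n_pairs=m * (m - 1) // 2,
        threshold=threshold,
        method=method,
        pairs_over=pairs_over,
    )
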