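"""Hierarchical clustering of ES matrices and signature-signature correlation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .gsva import ESMatrix
from .signatures import SignatureLibrary

VALID_LINKAGES = ("complete", "average", "ward")


@dataclass
class ClusterResult:
    """Sample-side agglomerative tree plus flat labels at a k cut."""

    linkage: np.ndarray
    sample_ids: list[str]
    labels: pd.Series  # flat cluster label per sample at the requested cut
    k: int
    metric: str
    method: str

    def composition(self, annotations: pd.DataFrame) -> pd.DataFrame:
        """Counts of each annotation combination per flat cluster."""
        ann = annotations.loc[self.sample_ids].copy()
        ann["cluster"] = self.labels.values
        cols = [c for c in ("disease", "group", "timepoint") if c in ann.columns]
        return ann.groupby(["cluster", *cols], observed=True).size().rename("count").reset_index()

    def to_newick(self) -> str:
        """Serialize the linkage tree in newick format with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def _recurse(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            left = _recurse(node.get_left())
            right = _recurse(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return _recurse(tree) + ";"


def hcluster(
    es: ESMatrix,
    signature_subset: Iterable[str] | None = None,
    metric: str = "euclidean",
    method: str = "complete",
    k: int = 2,
) -> ClusterResult:
    """Cluster samples on the ES rows of a signature subset.

    Euclidean distances over the selected signature rows, agglomerative
    linkage (default complete), flat labels from a k-way cut.
    Deterministic for fixed input.
    """
    if method not in VALID_LINKAGES:
        raise ValueError(f"linkage must be one of {VALID_LINKAGES}")
    if signature_subset is None:
        subset = list(es.scores.index)
    else:
        subset = list(signature_subset)
    if not subset:
        raise ValueError("signature subset must be non-empty")
    missing = [s for s in subset if s not in es.scores.index]
    if missing:
        raise KeyError(f"signature id(s) absent from ES matrix: {missing}")
    data = es.scores.loc[subset].to_numpy(float).T  # samples x signatures
    if data.shape[0] < 2:
        raise ValueError("clustering requires >= 2 samples")
    dists = pdist(data, metric=metric)
    linkage = hierarchy.linkage(dists, method=method)
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=es.sample_ids, name="cluster")
    return ClusterResult(
        linkage=linkage, sample_ids=list(es.sample_ids), labels=labels,
        k=k, metric=metric, method=method,
    )


def cluster_purity(
    cluster_labels: Mapping[str, int] | pd.Series,
    labeling: Mapping[str, str] | pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Majority label and purity per cluster, plus overall weighted purity."""
    cluster_labels = pd.Series(cluster_labels)
    labeling = pd.Series(labeling)
    missing = cluster_labels.index.difference(labeling.index)
    if len(missing):
        raise ValueError(f"labeling does not cover samples: {list(missing)[:5]}")
    rows = []
    total_majority = 0
    for cl, members in cluster_labels.groupby(cluster_labels):
        labs = labeling[members.index]
        counts = labs.value_counts()
        majority = counts.index[0]
        rows.append(
            {
                "cluster": cl,
                "size": len(labs),
                "majority_label": majority,
                "purity": counts.iloc[0] / len(labs),
            }
        )
        total_majority += int(counts.iloc[0])
    table = pd.DataFrame(rows).set_index("cluster")
    overall = total_majority / len(cluster_labels)
    return table, overall


def signature_correlations(
    es: ESMatrix,
    set_a: Iterable[str],
    set_b: Iterable[str],
    lib: SignatureLibrary | None = None,
    sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of ES rows for every (A, B) signature pair.

    Returns one row per pair with r, the two-sided p-value from the t
    transform (unadjusted), and the gene-overlap count from the library
    when provided.  Zero-variance rows yield missing r with a warning.
    """
    set_a, set_b = list(set_a), list(set_b)
    cols = list(sample_ids) if sample_ids is not None else list(es.scores.columns)
    if len(cols) < 3:
        raise ValueError("correlation requires >= 3 samples")
    for sid in (*set_a, *set_b):
        if sid not in es.scores.index:
            raise KeyError(f"signature id absent from ES matrix: {sid!r}")
    rows = []
    for sa in set_a:
        va = es.scores.loc[sa, cols].to_numpy(float)
        for sb in set_b:
            vb = es.scores.loc[sb, cols].to_numpy(float)
            if np.std(va) == 0 or np.std(vb) == 0:
                warnings.warn(
                    f"zero-variance ES row in pair ({sa!r}, {sb!r}); r undefined",
                    stacklevel=2,
                )
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(va, vb)
            n_overlap = None
            if lib is not None:
                n_overlap = len(lib[sa].gene_set & lib[sb].gene_set)
            rows.append(
                {"signature_a": sa, "signature_b": sb, "r": r, "p": p,
                 "n_samples": len(cols), "n_overlap_genes": n_overlap}
            )
    return pd.DataFrame(rows)
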