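"""Differential enrichment between sample groups and set comparisons.

Per-signature two-group contrasts on enrichment scores (pooled-variance t,
or paired t when subject ids are supplied), Benjamini-Hochberg adjustment
across the signatures of the comparison, and the dual-threshold selection
rule: |delta ES| >= min_delta AND significance <= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VALID_DIRECTIONS = ("up", "down", "both")


@dataclass(frozen=True)
class SelectionCriteria:
    """Dual-threshold rule for calling a signature differentially enriched.

    Both boundaries are inclusive: delta exactly at ``min_delta`` and
    significance exactly at ``alpha`` pass.  ``use_adjusted`` switches the
    significance column between BH-adjusted (default) and raw p-values;
    the choice is recorded in all outputs.
    """

    min_delta: float = 0.2
    alpha: float = 0.05
    adjust: str = "fdr_bh"
    direction: str = "both"
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(f"direction must be one of {VALID_DIRECTIONS}")


@dataclass
class DifferentialResult:
    """Per-signature contrast table for one two-group comparison.

    ``table`` columns: delta (mean ES A - mean ES B), t, p_raw, p_adj,
    direction ('up'/'down'), selected (filled by :func:`select_enriched`).
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    paired: bool = False
    criteria: SelectionCriteria | None = None

    @property
    def signature_ids(self) -> list[str]:
        return list(self.table.index)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="signature")


def compare_groups(
    es_scores: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    paired: bool = False,
    subjects: Mapping[str, str] | pd.Series | None = None,
) -> DifferentialResult:
    """Per-signature t contrast of group A vs group B enrichment scores.

    ``labels`` maps sample id -> group label; only samples labeled
    ``group_a`` or ``group_b`` enter the test.  When ``paired`` is true,
    ``subjects`` must map sample ids to subject ids and a paired t-test is
    run over subjects present in both groups.  BH adjustment is applied
    across the signatures of this single comparison.
    """
    labels = pd.Series(labels)
    for g in (group_a, group_b):
        if g not in set(labels.values):
            raise ValueError(f"unknown or empty group label {g!r}")
    ids_a = [s for s in es_scores.columns if labels.get(s) == group_a]
    ids_b = [s for s in es_scores.columns if labels.get(s) == group_b]

    if paired:
        if subjects is None:
            raise ValueError("paired comparison requires subject ids")
        subjects = pd.Series(subjects)
        subj_a = {subjects[s]: s for s in ids_a}
        subj_b = {subjects[s]: s for s in ids_b}
        common = sorted(set(subj_a) & set(subj_b))
        if len(common) < 2:
            raise ValueError(f"paired comparison requires >= 2 subject pairs, got {len(common)}")
        a = es_scores[[subj_a[c] for c in common]].to_numpy(float)
        b = es_scores[[subj_b[c] for c in common]].to_numpy(float)
        t, p = stats.ttest_rel(a, b, axis=1)
    else:
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValueError(
                f"need >= 2 samples per group, got {len(ids_a)} {group_a!r} "
                f"and {len(ids_b)} {group_b!r}"
            )
        a = es_scores[ids_a].to_numpy(float)
        b = es_scores[ids_b].to_numpy(float)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)

    delta = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "delta": delta,
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "direction": np.where(delta >= 0, "up", "down"),
            "selected": False,
        },
        index=es_scores.index,
    )
    return DifferentialResult(table, group_a=group_a, group_b=group_b, paired=paired)


def select_enriched(
    res: DifferentialResult, crit: SelectionCriteria | None = None
) -> list[str]:
    """Signature ids passing the dual threshold, in table order.

    Also fills the ``selected`` column of ``res.table`` and records the
    criteria on the result.
    """
    crit = crit or SelectionCriteria()
    tab = res.table
    sig_col = tab["p_adj"] if crit.use_adjusted else tab["p_raw"]
    mask = (tab["delta"].abs() >= crit.min_delta) & (sig_col <= crit.alpha)
    if crit.direction == "up":
        mask &= tab["delta"] > 0
    elif crit.direction == "down":
        mask &= tab["delta"] < 0
    res.table["selected"] = mask
    res.criteria = crit
    return list(tab.index[mask])


class VennCounts(NamedTuple):
    only_a: int
    shared: int
    only_b: int
    members_only_a: list[str]
    members_shared: list[str]
    members_only_b: list[str]


def venn_counts(set_a: Iterable[str], set_b: Iterable[str]) -> VennCounts:
    """Two-way set partition: exclusive-to-A, shared, exclusive-to-B."""
    sa, sb = set(set_a), set(set_b)
    return VennCounts(
        only_a=len(sa - sb),
        shared=len(sa & sb),
        only_b=len(sb - sa),
        members_only_a=sorted(sa - sb),
        members_shared=sorted(sa & sb),
        members_only_b=sorted(sb - sa),
    )
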