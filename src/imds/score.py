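"""Composite molecular disease-activity score and responder classification.

The per-sample score is the sum of enrichment scores over a selected set
of disease-associated upregulated signatures, centered so the healthy
reference samples average zero.  A sample scoring below the configured
cutoff is called responder-like; at or above it, nonresponder-like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gsva import ESMatrix

RESPONDER = "responder-like"
NONRESPONDER = "nonresponder-like"


@dataclass(frozen=True)
class ScoreConfig:
    """Configuration of the activity score.

    ``threshold`` is a cohort- and signature-set-specific operating point
    (the published one is 32); :func:`choose_threshold` is the recommended
    path on new data.  At the exact threshold the nonresponder-like class
    is assigned.
    """

    signature_ids: tuple[str, ...]
    nhv_ids: tuple[str, ...]
    threshold: float = 32.0

    def __post_init__(self) -> None:
        if len(self.signature_ids) == 0:
            raise ValueError("signature set must be non-empty")
        if len(self.nhv_ids) == 0:
            raise ValueError("healthy reference sample set must be non-empty")


@dataclass
class IMDSResult:
    """Per-sample scores, predicted classes and cohort metrics."""

    scores: pd.Series
    offset: float
    config: ScoreConfig
    predicted: pd.Series | None = None
    metrics: dict = field(default_factory=dict)

    def write(self, score_path: str | Path, metrics_path: str | Path | None = None) -> None:
        out = pd.DataFrame({"score": self.scores})
        if self.predicted is not None:
            out["predicted_class"] = self.predicted
        out.to_csv(score_path, sep="\t", index_label="sample")
        if metrics_path is not None:
            Path(metrics_path).write_text(json.dumps(self.metrics, indent=2, sort_keys=True))


def compute_imds(es: ESMatrix, cfg: ScoreConfig) -> IMDSResult:
    """Score every sample: signature-ES sum minus the healthy-reference mean.

    score_j = sum_{s in signature set} ES[s, j]
              - mean_{h in healthy refs} sum_{s} ES[s, h]

    so the mean score over the healthy reference ids is zero by
    construction.
    """
    missing_sigs = [s for s in cfg.signature_ids if s not in es.scores.index]
    if missing_sigs:
        raise KeyError(f"signature id(s) absent from ES matrix: {missing_sigs}")
    missing_nhv = [h for h in cfg.nhv_ids if h not in es.scores.columns]
    if missing_nhv:
        raise KeyError(f"healthy reference sample(s) absent from ES matrix: {missing_nhv}")
    sums = es.scores.loc[list(cfg.signature_ids)].sum(axis=0)
    offset = float(sums[list(cfg.nhv_ids)].mean())
    return IMDSResult(scores=sums - offset, offset=offset, config=cfg)


def classify(result: IMDSResult, cfg: ScoreConfig | None = None) -> pd.Series:
    """Assign classes: score < threshold -> responder-like, else nonresponder-like."""
    cfg = cfg or result.config
    predicted = pd.Series(
        np.where(result.scores < cfg.threshold, RESPONDER, NONRESPONDER),
        index=result.scores.index,
    )
    result.predicted = predicted
    result.config = cfg
    return predicted


def confusion_metrics(
    predicted: Mapping[str, str] | pd.Series,
    clinical_labels: Mapping[str, str] | pd.Series,
) -> dict:
    """Sensitivity/specificity of predicted classes vs clinical R/NR labels.

    Orientation: sensitivity = fraction of clinical responders called
    responder-like; specificity = fraction of clinical non-responders
    called nonresponder-like.  The confusion counts are returned so the
    opposite reading is checkable.
    """
    predicted = pd.Series(predicted)
    clinical = pd.Series(clinical_labels)
    bad = set(clinical.unique()) - {"R", "NR"}
    if bad:
        raise ValueError(f"clinical labels must be R or NR, got {sorted(bad)}")
    common = clinical.index.intersection(predicted.index)
    clinical = clinical[common]
    pred = predicted[common]
    r_mask = clinical == "R"
    nr_mask = clinical == "NR"
    tp = int(((pred == RESPONDER) & r_mask).sum())       # R called responder-like
    fn = int(((pred == NONRESPONDER) & r_mask).sum())
    tn = int(((pred == NONRESPONDER) & nr_mask).sum())   # NR called nonresponder-like
    fp = int(((pred == RESPONDER) & nr_mask).sum())
    n_r, n_nr = int(r_mask.sum()), int(nr_mask.sum())
    return {
        "sensitivity": tp / n_r if n_r else float("nan"),
        "specificity": tn / n_nr if n_nr else float("nan"),
        "n_responders": n_r,
        "n_nonresponders": n_nr,
        "r_called_responder": tp,
        "r_called_nonresponder": fn,
        "nr_called_nonresponder": tn,
        "nr_called_responder": fp,
    }


def _evaluate_threshold(
    scores: np.ndarray, is_r: np.ndarray, threshold: float
) -> tuple[float, float]:
    pred_r = scores < threshold
    sens = (pred_r & is_r).sum() / max(is_r.sum(), 1)
    spec = (~pred_r & ~is_r).sum() / max((~is_r).sum(), 1)
    return float(sens), float(spec)


def threshold_scan(
    scores: Mapping[str, float] | pd.Series,
    labels: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Sensitivity/specificity at every candidate cutoff.

    Candidates are the midpoints between consecutive sorted unique scores
    plus guards one unit below the minimum and above the maximum.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels)
    common = scores.index.intersection(labels.index)
    sc = scores[common].to_numpy(float)
    is_r = (labels[common] == "R").to_numpy()
    uniq = np.unique(sc)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    rows = []
    for thr in candidates:
        sens, spec = _evaluate_threshold(sc, is_r, thr)
        rows.append({"threshold": float(thr), "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


def choose_threshold(
    scores: Mapping[str, float] | pd.Series,
    labels: Mapping[str, str] | pd.Series,
    criterion: str = "max_specificity_first",
) -> float:
    """Pick a score cutoff from labeled samples.

    ``max_specificity_first`` maximizes sensitivity subject to perfect
    specificity (no non-responder called responder-like); ``youden``
    maximizes sensitivity + specificity - 1.  Ties break toward the
    lowest qualifying threshold; deterministic.
    """
    labels = pd.Series(labels)
    present = set(labels.unique())
    if not {"R", "NR"} <= present:
        raise ValueError(f"both R and NR labels required, got {sorted(present)}")
    scan = threshold_scan(scores, labels)
    if criterion == "max_specificity_first":
        perfect = scan[scan["specificity"] == 1.0]
        best_sens = perfect["sensitivity"].max()
        return float(perfect[perfect["sensitivity"] == best_sens]["threshold"].iloc[0])
    if criterion == "youden":
        youden = scan["sensitivity"] + scan["specificity"] - 1.0
        return float(scan["threshold"][youden.idxmax()])
    raise ValueError(f"unknown criterion {criterion!r}")
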