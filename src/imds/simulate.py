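"""Synthetic expression cohorts with planted signature effects.

The generator emits log2-scale expression for a healthy-volunteer arm and
two disease arms, each with responder/non-responder patients sampled at
baseline and post-treatment.  Truly dysregulated signatures are shifted
additively in patient samples: non-responders more than responders at
baseline, responders reverting to healthy post-treatment, non-responders
unchanged.  Everything is reproducible from the seed (numpy PCG64 via
``numpy.random.default_rng``; the RNG algorithm is part of the contract so
fixtures stay stable across releases).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .signatures import GeneSignature, SignatureLibrary

DISEASES = ("CD", "UC")
PATIENT_CELLS = (("R", "BL"), ("R", "PT"), ("NR", "BL"), ("NR", "PT"))


@dataclass(frozen=True)
class SignatureSpec:
    """One signature to plant: its size and whether/where it is dysregulated."""

    size: int
    dysregulated: bool = False
    shared: bool = True  # shifted in both diseases; else CD only


@dataclass
class CohortDesign:
    """Generative design for a synthetic cohort.

    Effect sizes are additive log2 shifts applied to the genes of
    dysregulated signatures: ``delta_r``/``delta_nr`` at baseline,
    ``delta_r_pt`` (default 0: reversion to healthy) and ``delta_nr_pt``
    (default equal to ``delta_nr``: no change) post-treatment.
    """

    n_genes: int = 2000
    n_per_group: int = 12
    signatures: list[SignatureSpec] = field(default_factory=list)
    delta_r: float = 1.2
    delta_nr: float = 2.0
    delta_r_pt: float = 0.0
    delta_nr_pt: float | None = None
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_nr_pt is None:
            self.delta_nr_pt = self.delta_nr
        self.validate()

    def validate(self) -> None:
        if not (self.delta_nr >= self.delta_r >= 0):
            raise ValueError("effect sizes must satisfy delta_nr >= delta_r >= 0")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 samples per group cell")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for spec in self.signatures:
            if spec.size < 1:
                raise ValueError("signature size must be >= 1")
            if spec.size > self.n_genes:
                raise ValueError(
                    f"signature size {spec.size} exceeds n_genes={self.n_genes}"
                )

    @property
    def true_shared_count(self) -> int:
        return sum(1 for s in self.signatures if s.dysregulated and s.shared)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["signatures"] = [asdict(s) for s in self.signatures]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortDesign":
        payload = json.loads(Path(path).read_text())
        payload["signatures"] = [SignatureSpec(**s) for s in payload["signatures"]]
        return cls(**payload)


@dataclass
class GroundTruth:
    """What was planted: dysregulated signature ids and per-gene shifts."""

    true_ids: list[str]
    shared_ids: list[str]
    sample_classes: pd.DataFrame  # same as the emitted annotations
    gene_shifts: dict[str, list[str]]  # signature id -> its gene list


def default_design(seed: int = 0) -> CohortDesign:
    """Canonical test-fixture design: 10 true + 90 null signatures of size 20."""
    specs = [SignatureSpec(size=20, dysregulated=True, shared=True) for _ in range(10)]
    specs += [SignatureSpec(size=20, dysregulated=False) for _ in range(90)]
    return CohortDesign(
        n_genes=2000, n_per_group=12, signatures=specs,
        delta_r=1.2, delta_nr=2.0, delta_r_pt=0.0, delta_nr_pt=None,
        noise_sd=0.5, seed=seed,
    )


def _sample_frame(design: CohortDesign) -> pd.DataFrame:
    """Sample annotation table for the design (NHV + 2 diseases x R/NR x BL/PT)."""
    rows = []
    for i in range(design.n_per_group):
        rows.append(("NHV_%02d" % (i + 1), "none", "NHV", "BL", "NHV_%02d" % (i + 1)))
    for disease in DISEASES:
        for group, _ in (("R", None), ("NR", None)):
            for i in range(design.n_per_group):
                subject = f"{disease}_{group}_{i + 1:02d}"
                for tp in ("BL", "PT"):
                    rows.append((f"{subject}_{tp}", disease, group, tp, subject))
    frame = pd.DataFrame(
        rows, columns=["sample", "disease", "group", "timepoint", "subject"]
    ).set_index("sample")
    return frame


def _planted_delta(design: CohortDesign, group: str, timepoint: str) -> float:
    if group == "R":
        return design.delta_r if timepoint == "BL" else design.delta_r_pt
    if group == "NR":
        return design.delta_nr if timepoint == "BL" else float(design.delta_nr_pt)
    return 0.0


def simulate_cohort(
    design: CohortDesign,
) -> tuple[ExpressionMatrix, SignatureLibrary, GroundTruth]:
    """Generate (expression, signature library, ground truth) from a design.

    Signature gene sets are drawn without replacement within each
    signature; when total capacity allows, signatures are mutually
    disjoint (a single permutation of the gene universe is sliced), else
    each is drawn independently.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    genes = [f"G{i + 1:05d}" for i in range(design.n_genes)]
    annotations = _sample_frame(design)
    samples = list(annotations.index)
    n = len(samples)

    gene_means = rng.normal(design.baseline_mean, design.baseline_sd, size=design.n_genes)
    values = rng.normal(0.0, design.noise_sd, size=(design.n_genes, n)) + gene_means[:, None]

    total_size = sum(s.size for s in design.signatures)
    if total_size <= design.n_genes:
        perm = rng.permutation(design.n_genes)
        slices, cursor = [], 0
        for spec in design.signatures:
            slices.append(perm[cursor : cursor + spec.size])
            cursor += spec.size
    else:
        slices = [
            rng.choice(design.n_genes, size=spec.size, replace=False)
            for spec in design.signatures
        ]

    lib = SignatureLibrary()
    true_ids, shared_ids = [], []
    gene_shifts: dict[str, list[str]] = {}
    for k, (spec, idx) in enumerate(zip(design.signatures, slices), start=1):
        sig_genes = tuple(genes[i] for i in idx)
        kind = "true" if spec.dysregulated else "null"
        sig_id = f"sig{k:03d}.{kind}.sim.HS.IVS.UP"
        lib.add(GeneSignature(id=sig_id, genes=sig_genes,
                              description=f"synthetic {kind} signature", direction="UP"))
        if spec.dysregulated:
            true_ids.append(sig_id)
            if spec.shared:
                shared_ids.append(sig_id)
            gene_shifts[sig_id] = list(sig_genes)
            target_diseases = DISEASES if spec.shared else ("CD",)
            for j, sample in enumerate(samples):
                ann = annotations.loc[sample]
                if ann["disease"] not in target_diseases:
                    continue
                delta = _planted_delta(design, ann["group"], ann["timepoint"])
                if delta:
                    values[idx, j] += delta

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), annotations
    )
    truth = GroundTruth(
        true_ids=true_ids,
        shared_ids=shared_ids,
        sample_classes=annotations.copy(),
        gene_shifts=gene_shifts,
    )
    return expr, lib, truth
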