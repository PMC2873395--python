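"""Simulation of two-group RT-qPCR Cq studies with known ground truth.

A study is described by a list of gene plans (baseline Cq, tumour-group
log2 shift, gene-specific intra-group noise, panel role) and a study
configuration (group sizes, technical noise, replication, detection
ceiling).  The measured Cq of replicate r of gene i in sample s is

    Cq_isr = base_i − shift_i·[s is tumour] + u_s + p_plate(s) + e_is + ε_isr

with u_s ~ N(0, sample_shift_sd²) a sample-wide technical shift (pipetting,
input amount), p ~ N(0, plate_shift_sd²) a per-plate run effect, e_is ~
N(0, intra_sd_i²) the gene's biological variation drawn once per
sample x gene, and ε ~ N(0, replicate_sd²) the replicate pipetting noise.
All noise is Normal on the Cq (log2) scale, where qPCR data are inherently
linear.  A positive ``group_shift_log2`` (log2 fold-change up-regulation in
tumours) lowers the tumour Cq by that many cycles.  Values at or above the
detection ceiling are emitted as undetected — the instrument's
"Undetermined" — never truncated to the ceiling.

Plates are assigned round-robin over samples for balance; identical
(config, seed) pairs produce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cq_data import AssayPanel, CqDataset, SampleSheet
from .efficiency import DilutionSeries
from .errors import ConfigurationError


@dataclass
class GenePlan:
    """Ground-truth description of one simulated assay."""

    assay_id: str
    base_cq: float
    group_shift_log2: float = 0.0
    intra_sd: float = 0.0
    role: str = "reference_candidate"
    rna_class: str = "miRNA"

    def validate(self) -> None:
        if self.base_cq <= 0:
            raise ConfigurationError(f"{self.assay_id}: base_cq must be > 0")
        if self.intra_sd < 0:
            raise ConfigurationError(f"{self.assay_id}: intra_sd must be >= 0")


@dataclass
class StudyConfig:
    """Two-group study design and noise model parameters (cycles)."""

    gene_plans: list[GenePlan]
    n_tumour: int = 35
    n_normal: int = 39
    sample_shift_sd: float = 0.5
    replicate_sd: float = 0.15
    n_replicates: int = 3
    detection_ceiling: float = 40.0
    n_plates: int = 1
    plate_shift_sd: float = 0.0
    seed: int = 0
    tumour_label: str = "tumour"
    normal_label: str = "normal"

    def validate(self) -> None:
        if not self.gene_plans:
            raise ConfigurationError("gene_plans: must contain at least one gene")
        ids = [p.assay_id for p in self.gene_plans]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("gene_plans: assay_ids must be unique")
        for plan in self.gene_plans:
            plan.validate()
        if self.n_tumour < 2 or self.n_normal < 2:
            raise ConfigurationError("n_tumour/n_normal: each group needs >= 2 samples")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates: must be >= 1")
        if self.n_plates < 1:
            raise ConfigurationError("n_plates: must be >= 1")
        for name in ("sample_shift_sd", "replicate_sd", "plate_shift_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.detection_ceiling <= 0:
            raise ConfigurationError("detection_ceiling: must be > 0")


@dataclass
class SimulatedStudy:
    """A simulated dataset together with its per-gene ground truth.

    ``truth`` is indexed by assay_id with columns base_cq, group_shift_log2,
    intra_sd, role and instability_score (intra_sd + |shift|; sorting by it
    gives the expected stability ordering, most stable first).
    """

    dataset: CqDataset
    truth: pd.DataFrame
    config: StudyConfig = field(repr=False, default=None)


def simulate_study(config: StudyConfig) -> SimulatedStudy:
    """Draw a complete replicate-level Cq study from the model above."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    plans = config.gene_plans
    n_genes = len(plans)
    n_samples = config.n_tumour + config.n_normal
    sample_ids = [f"T{i + 1:03d}" for i in range(config.n_tumour)] + [
        f"N{i + 1:03d}" for i in range(config.n_normal)
    ]
    is_tumour = np.array([1.0] * config.n_tumour + [0.0] * config.n_normal)
    plate_of_sample = np.arange(n_samples) % config.n_plates

    base = np.array([p.base_cq for p in plans])
    shift = np.array([p.group_shift_log2 for p in plans])
    intra = np.array([p.intra_sd for p in plans])

    u = rng.normal(0.0, config.sample_shift_sd, size=n_samples)
    p_plate = rng.normal(0.0, config.plate_shift_sd, size=config.n_plates)
    e = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * intra[:, None]
    eps = rng.normal(
        0.0, config.replicate_sd, size=(n_genes, n_samples, config.n_replicates)
    )

    mean_cq = (
        base[:, None]
        - shift[:, None] * is_tumour[None, :]
        + u[None, :]
        + p_plate[plate_of_sample][None, :]
        + e
    )
    cq = mean_cq[:, :, None] + eps
    cq = np.where(cq >= config.detection_ceiling, np.nan, cq)

    gene_idx, sample_idx, rep_idx = np.meshgrid(
        np.arange(n_genes), np.arange(n_samples), np.arange(config.n_replicates),
        indexing="ij",
    )
    measurements = pd.DataFrame(
        {
            "sample_id": np.array(sample_ids)[sample_idx.ravel()],
            "assay_id": np.array([p.assay_id for p in plans])[gene_idx.ravel()],
            "replicate": rep_idx.ravel() + 1,
            "plate_id": np.array(
                [f"plate{p + 1}" for p in range(config.n_plates)]
            )[plate_of_sample[sample_idx.ravel()]],
            "cq": cq.ravel(),
        }
    )

    samples = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": [config.tumour_label] * config.n_tumour
                + [config.normal_label] * config.n_normal,
            }
        )
    )
    panel = AssayPanel(
        pd.DataFrame(
            {
                "assay_id": [p.assay_id for p in plans],
                "rna_class": [p.rna_class for p in plans],
                "role": [p.role for p in plans],
            }
        )
    )
    dataset = CqDataset(measurements, samples, panel)

    truth = pd.DataFrame(
        {
            "assay_id": [p.assay_id for p in plans],
            "base_cq": base,
            "group_shift_log2": shift,
            "intra_sd": intra,
            "role": [p.role for p in plans],
        }
    ).set_index("assay_id")
    truth["instability_score"] = truth["intra_sd"] + truth["group_shift_log2"].abs()
    return SimulatedStudy(dataset=dataset, truth=truth, config=config)


def make_dilution_series(
    amplification_factor: float,
    n_points: int = 6,
    step: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_cq: float = 20.0,
    assay_id: str = "assay",
) -> DilutionSeries:
    """Standard-curve input: a serial dilution measured with optional noise.

    Each ``step``-fold dilution raises Cq by log(step)/log(amplification
    factor) cycles (3.3219 for 10-fold steps at perfect doubling).  The most
    concentrated point sits at log10 input 0 with ``base_cq``.
    """
    if amplification_factor <= 1:
        raise ConfigurationError("amplification_factor: must be > 1")
    if n_points < 3:
        raise ConfigurationError("n_points: a dilution series needs >= 3 points")
    if step <= 1:
        raise ConfigurationError("step: fold dilution must be > 1")
    rng = np.random.default_rng(seed)
    log10_input = -np.arange(n_points) * np.log10(step)
    slope = -1.0 / np.log10(amplification_factor)  # cycles per log10 input
    cq = base_cq + slope * log10_input + rng.normal(0.0, noise_sd, size=n_points)
    return DilutionSeries(assay_id=assay_id, log10_input=log10_input, cq=cq)


def default_gene_plans() -> list[GenePlan]:
    """The default simulated panel: eight reference candidates spanning the
    stability spectrum and four dysregulated targets (two up, two down).

    Baselines follow typical colorectal-tissue Cq levels for these assays;
    the planted target shifts are +2, +3, −1 and −1 log2 units.
    """
    return [
        GenePlan("miR-16", 23.6, 0.0, 0.25),
        GenePlan("miR-345", 27.4, 0.0, 0.30),
        GenePlan("miR-425", 27.5, 0.0, 0.35),
        GenePlan("miR-26a", 23.6, 0.0, 0.40),
        GenePlan("miR-454", 30.1, 0.0, 0.45),
        GenePlan("let-7a", 28.3, 0.0, 0.60),
        GenePlan("RNU48", 26.3, 0.0, 0.90, rna_class="snoRNA"),
        GenePlan("Z30", 31.2, 0.0, 1.20, rna_class="snoRNA"),
        GenePlan("miR-21", 24.8, 2.0, 0.8, role="target"),
        GenePlan("miR-31", 29.4, 3.0, 0.8, role="target"),
        GenePlan("miR-143", 23.0, -1.0, 0.8, role="target"),
        GenePlan("miR-145", 24.8, -1.0, 0.8, role="target"),
    ]


def default_study_config(seed: int = 0) -> StudyConfig:
    """The default two-group study: 35 tumour vs 39 normal samples,
    triplicates, sample-wide technical shift 0.5 cycles, replicate noise
    0.15 cycles, detection ceiling 40."""
    return StudyConfig(gene_plans=default_gene_plans(), seed=seed)


def planted_recovery_config(seed: int = 0) -> StudyConfig:
    """A planted-truth panel for stability-recovery checks: two stable genes
    (intra_sd 0.2, no shift) among six unstable ones, 20 + 20 samples.

    Every unstable gene is both noisy (intra_sd 1.2) and dysregulated
    (|shift| 1.5 log2), with shifts balanced between up and down so the
    panel-average group contrast — the baseline both stability models work
    against — stays at zero, keeping the planted stable pair the
    model-true optimum.
    """
    plans = [
        GenePlan("stable-1", 24.0, 0.0, 0.2),
        GenePlan("stable-2", 27.0, 0.0, 0.2),
        GenePlan("unstable-u1", 25.0, 1.5, 1.2),
        GenePlan("unstable-u2", 26.0, 1.5, 1.2),
        GenePlan("unstable-u3", 28.0, 1.5, 1.2),
        GenePlan("unstable-d1", 29.0, -1.5, 1.2),
        GenePlan("unstable-d2", 25.5, -1.5, 1.2),
        GenePlan("unstable-d3", 26.5, -1.5, 1.2),
    ]
    return StudyConfig(
        gene_plans=plans, n_tumour=20, n_normal=20, sample_shift_sd=0.5,
        replicate_sd=0.15, seed=seed,
    )
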