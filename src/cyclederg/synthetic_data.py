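"""Synthetic input generators with known ground truth.

Every downstream stage (gene-set deregulation, survival, differential
expression, dose-response, qPCR) gets a no-download test surface here.  All
generators are pure functions of (config, seed): identical seeds give
bit-identical output.  Ground truth is returned alongside the data so
recovery tests are self-contained.

Expression is modelled as log2-normal noise around a cohort baseline with a
configurable log2 up- or down-shift injected into a designated gene set;
all downstream statistics are median/rank-based, so the exact law is not
load-bearing.  Survival times are exponential with hazard
``baseline_hazard * exp(beta * covariate)`` and independent uniform
censoring on (0, max_follow_up).

Seed splitting: a master seed expands to per-stage child seeds through
:func:`child_seeds`, which draws 31-bit integers from
``numpy.random.default_rng(master)`` in a fixed stage order, so each stage
is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import DataValidationError, ExpressionDataset, GeneSet, SurvivalRecord, SurvivalTable

__all__ = [
    "PanCancerSimConfig",
    "SurvivalSimConfig",
    "TreatmentSimConfig",
    "child_seeds",
    "simulate_pancancer",
    "simulate_survival",
    "simulate_treatment_microarray",
    "simulate_dose_response",
    "simulate_qpcr",
]

STAGE_ORDER = ("pancancer", "survival", "treatment", "doseresponse", "qpcr")


def child_seeds(master_seed: int) -> dict[str, int]:
    """Expand one master seed into a per-stage seed for every generator stage."""
    rng = np.random.default_rng(master_seed)
    draws = rng.integers(0, 2**31 - 1, size=len(STAGE_ORDER))
    return {stage: int(s) for stage, s in zip(STAGE_ORDER, draws)}


# ---------------------------------------------------------------------------
# pan-cancer cohorts

@dataclass
class PanCancerSimConfig:
    """Multi-cohort expression matrices with a set-level log2 up-shift.

    ``delta`` may be a single float (same shift in every cohort) or a
    sequence of per-cohort shifts of length ``n_cohorts``.
    """

    n_cohorts: int = 24
    genes_per_matrix: int = 2000
    samples_per_cohort: int = 100
    set_size: int = 200
    delta: float | Sequence[float] = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def deltas(self) -> np.ndarray:
        d = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if d.size == 1:
            d = np.repeat(d, self.n_cohorts)
        if d.size != self.n_cohorts:
            raise DataValidationError(
                f"delta has {d.size} entries for {self.n_cohorts} cohorts"
            )
        return d

    def validate(self) -> None:
        if self.set_size >= self.genes_per_matrix:
            raise DataValidationError("set_size must be < genes_per_matrix")
        if self.samples_per_cohort < 2:
            raise DataValidationError("samples_per_cohort must be >= 2")
        if self.baseline_sd <= 0:
            raise DataValidationError("baseline_sd must be > 0")
        if self.n_cohorts < 1:
            raise DataValidationError("n_cohorts must be >= 1")
        self.deltas()


def simulate_pancancer(
    config: PanCancerSimConfig,
) -> tuple[ExpressionDataset, dict[str, float], GeneSet]:
    """Simulate per-cohort expression with a known set-level shift.

    Set genes are drawn Normal(baseline_mean + delta_c, baseline_sd) in
    cohort ``c``; all other genes Normal(baseline_mean, baseline_sd).
    Returns the dataset, the per-cohort true delta, and the shifted set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    deltas = config.deltas()
    gene_ids = [f"G{i:05d}" for i in range(config.genes_per_matrix)]
    set_members = frozenset(gene_ids[: config.set_size])
    gene_set = GeneSet("SIM_SET", "simulated shifted gene set", set_members)

    cohort_labels = [f"C{c:02d}" for c in range(config.n_cohorts)]
    blocks = []
    sample_ids: list[str] = []
    cohort_of: dict[str, str] = {}
    for c, (label, d) in enumerate(zip(cohort_labels, deltas)):
        block = rng.normal(
            config.baseline_mean,
            config.baseline_sd,
            size=(config.genes_per_matrix, config.samples_per_cohort),
        )
        block[: config.set_size, :] += d
        blocks.append(block)
        for j in range(config.samples_per_cohort):
            sid = f"{label}_S{j:03d}"
            sample_ids.append(sid)
            cohort_of[sid] = label
    values = np.hstack(blocks)
    dataset = ExpressionDataset(gene_ids, sample_ids, values, cohort_of)
    truth = {label: float(d) for label, d in zip(cohort_labels, deltas)}
    return dataset, truth, gene_set


# ---------------------------------------------------------------------------
# survival

@dataclass
class SurvivalSimConfig:
    """Exponential proportional-hazards survival with uniform censoring."""

    n_patients: int = 500
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    log_hazard_ratio: float = 0.0  # beta, per unit of covariate
    censor_rate: float = 0.3
    max_follow_up: float = 3000.0  # days
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise DataValidationError("baseline_hazard must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise DataValidationError("censor_rate must be in [0, 1)")
        if self.n_patients < 1:
            raise DataValidationError("n_patients must be >= 1")
        if self.max_follow_up <= 0:
            raise DataValidationError("max_follow_up must be > 0")


def simulate_survival(
    expression_values: Sequence[float], config: SurvivalSimConfig
) -> SurvivalTable:
    """Simulate time-to-event records whose hazard depends on one covariate.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hazard_ratio * covariate)``.  A fraction
    ``censor_rate`` of patients receives an independent censoring time
    uniform on (0, max_follow_up); everyone is administratively censored at
    ``max_follow_up``.
    """
    config.validate()
    cov = np.asarray(expression_values, dtype=float)
    if cov.ndim != 1 or cov.size != config.n_patients:
        raise DataValidationError(
            f"expected {config.n_patients} covariate values, got {cov.size}"
        )
    rng = np.random.default_rng(config.seed)
    hazard = config.baseline_hazard * np.exp(config.log_hazard_ratio * cov)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.full(config.n_patients, config.max_follow_up)
    censored_mask = rng.random(config.n_patients) < config.censor_rate
    censor_time[censored_mask] = rng.uniform(
        0.0, config.max_follow_up, size=int(censored_mask.sum())
    )
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    records = [
        SurvivalRecord(f"P{i:04d}", float(t), bool(e), float(c))
        for i, (t, e, c) in enumerate(zip(time, event, cov))
    ]
    return SurvivalTable(records)


# ---------------------------------------------------------------------------
# treated/control microarray

@dataclass
class TreatmentSimConfig:
    """Triplicate treated/control arrays with dose-dependent set down-shift.

    ``shifts`` maps each non-control condition to the log2 shift applied to
    the target set (non-increasing across the dose escalation, e.g.
    0 > -1 > -2 means deeper knock-down at higher dose).
    """

    n_genes: int = 2000
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("control", "IC25", "IC50", "IC75")
    shifts: tuple[float, ...] = (0.0, -0.5, -1.0, -2.0)  # aligned with conditions
    target_set_size: int = 100
    baseline_mean: float = 8.0
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise DataValidationError("n_replicates must be >= 2")
        if len(self.shifts) != len(self.conditions):
            raise DataValidationError("one shift per condition required")
        diffs = np.diff(self.shifts)
        if np.any(diffs > 0):
            raise DataValidationError(
                "shifts must be monotone non-increasing across conditions"
            )
        if self.target_set_size >= self.n_genes:
            raise DataValidationError("target_set_size must be < n_genes")
        if self.noise_sd < 0:
            raise DataValidationError("noise_sd must be >= 0")


def simulate_treatment_microarray(
    config: TreatmentSimConfig,
) -> tuple[ExpressionDataset, GeneSet]:
    """Simulate log2 arrays where target-set genes shift down per condition.

    Cohort label of each sample is its condition; replicate noise is i.i.d.
    Normal(0, noise_sd).  Returns the dataset and the shifted target set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    target = frozenset(gene_ids[: config.target_set_size])
    gene_set = GeneSet("TARGET", "simulated drug-target gene set", target)
    # per-gene baseline shared across all arrays
    baseline = rng.normal(config.baseline_mean, 1.0, size=config.n_genes)
    cols = []
    sample_ids: list[str] = []
    cohort_of: dict[str, str] = {}
    for cond, shift in zip(config.conditions, config.shifts):
        for r in range(config.n_replicates):
            col = baseline + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            col[: config.target_set_size] += shift
            cols.append(col)
            sid = f"{cond}_R{r + 1}"
            sample_ids.append(sid)
            cohort_of[sid] = cond
    values = np.column_stack(cols)
    return ExpressionDataset(gene_ids, sample_ids, values, cohort_of), gene_set


# ---------------------------------------------------------------------------
# dose-response and qPCR

def _four_pl(dose: np.ndarray, bottom: float, top: float, hill: float, ec50: float):
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def simulate_dose_response(
    params: tuple[float, float, float, float],
    doses: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate viability (% of control) on a 4PL curve plus Gaussian noise.

    ``params`` is (bottom, top, hill, ec50) with top > bottom and ec50 > 0;
    ``doses`` are concentrations in µM, all positive.  Each dose gets
    ``n_replicates`` wells with independent noise, mirroring the replicate
    design of a plate-based viability assay.
    """
    bottom, top, hill, ec50 = params
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise DataValidationError("doses must be positive")
    if top <= bottom:
        raise DataValidationError("top must exceed bottom")
    if ec50 <= 0:
        raise DataValidationError("ec50 must be > 0")
    if n_replicates < 1:
        raise DataValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    all_doses = np.repeat(doses, n_replicates)
    viability = _four_pl(all_doses, bottom, top, hill, ec50)
    if noise_sd > 0:
        viability = viability + rng.normal(0.0, noise_sd, size=all_doses.size)
    return pd.DataFrame({"dose_uM": all_doses, "viability_pct": viability})


def simulate_qpcr(
    true_folds: dict[str, float],
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR CT table for given true expression fold changes.

    Lower expression means later amplification, so the treated target CT is
    ``control_ct - log2(fold) + noise``; the reference gene CT is constant
    up to the same noise in both arms.  Columns: group, gene, replicate,
    ct_target, ct_reference.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise DataValidationError("fold changes must be > 0")
    if base_ct <= 0 or reference_ct <= 0:
        raise DataValidationError("CT values must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, fold in true_folds.items():
        for group in ("control", "treated"):
            shift = 0.0 if group == "control" else -np.log2(fold)
            for r in range(n_replicates):
                ct_t = base_ct + shift + rng.normal(0.0, noise_sd)
                ct_ref = reference_ct + rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "group": group,
                        "gene": gene,
                        "replicate": r + 1,
                        "ct_target": ct_t,
                        "ct_reference": ct_ref,
                    }
                )
    return pd.DataFrame(rows)
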