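"""Synthetic Ct data with the structure low-density miRNA cards produce.

The generator works on the cycle (log2) scale, where qPCR measurement noise
is approximately normal and a linear fold-change f maps to an additive Ct
shift of −log2(|f|) (down-regulation, written f = −2 for a halving, shifts Ct
*up* by log2 2 = 1 cycle):

    Ct(i, j, r) = B_i + L_j + s_i * [j in case group] + eps_ijr

with assay baseline B_i ~ Uniform(baseline_ct_range), per-sample loading
shift L_j ~ Normal(0, loading_sd), technical noise
eps ~ Normal(0, noise_sd), and s_i the planted shift (0 for null assays).
Endogenous-control wells use a fixed baseline and no group effect, but the
same loading and noise model, so normalization has to cope with their noise.
Wells at or beyond the detection limit are censored to non-detected; that is
the only dropout mechanism.

Defaults mirror a two-card discovery design: 667 target assays, 8
endogenous-control wells, 10 case + 10 control samples, single wells.  A
companion constructor mirrors the validation design: 15 targets + 1 control
assay in technical triplicate on 21 + 25 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ASSAY_LEVEL, REPLICATE_LEVEL, CtMatrix, DataError, PanelDef, SampleSheet

__all__ = [
    "SynthConfig",
    "SimulatedDataset",
    "generate_dataset",
    "generate_validation_dataset",
    "validation_config",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study-design and noise parameters of the Ct simulator.

    Fold-changes are linear and signed: 2.0 doubles expression in the case
    group, −2.0 halves it; |f| must be >= 1 (1.0 = null).  All SDs and Ct
    values are in cycles.
    """

    n_assays: int = 667
    n_case: int = 10
    n_control: int = 10
    n_planted: int = 0
    planted_fold_changes: Sequence[float] = (2.0,)
    baseline_ct_range: tuple[float, float] = (22.0, 35.0)
    loading_sd: float = 0.5
    noise_sd: float = 0.4
    ec_ct: float = 20.0
    n_ec_assays: int = 8
    lod_ct: float = 40.0
    replicates: int = 1
    seed: int = 0
    case_group: str = "endometriosis"
    control_group: str = "control"

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise DataError("both groups need at least one sample")
        if self.n_assays < 1 or self.n_ec_assays < 1 or self.replicates < 1:
            raise DataError("n_assays, n_ec_assays and replicates must be >= 1")
        if self.n_planted > self.n_assays:
            raise DataError("cannot plant more differential assays than assays")
        if self.loading_sd < 0 or self.noise_sd < 0:
            raise DataError("noise SDs must be non-negative")
        if any(abs(f) < 1.0 or f == 0 for f in self.planted_fold_changes):
            raise DataError("planted fold-changes must have |f| >= 1")
        lo, hi = self.baseline_ct_range
        if not lo <= hi:
            raise DataError("baseline_ct_range must be (low, high)")


def _ct_shift(fold_change: float) -> float:
    """Additive Ct shift produced by a signed linear fold-change."""
    if fold_change > 0:
        return -float(np.log2(fold_change))
    return float(np.log2(-fold_change))


@dataclass
class SimulatedDataset:
    """Generated inputs plus the ground truth used to plant them."""

    ct: CtMatrix
    sheet: SampleSheet
    panel: PanelDef
    truth: pd.DataFrame  # columns: assay, fold_change (signed linear; 1.0 = null)


def generate_dataset(cfg: SynthConfig) -> SimulatedDataset:
    """Simulate one card run under ``cfg``; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)

    targets = [f"mir-{i + 1:04d}" for i in range(cfg.n_assays)]
    if cfg.n_ec_assays == 1:
        ec_assays = ["RNU6B"]
    else:
        ec_assays = [f"MammU6-{k + 1}" for k in range(cfg.n_ec_assays)]
    assays = targets + ec_assays

    case_ids = [f"case_{i + 1:02d}" for i in range(cfg.n_case)]
    ctrl_ids = [f"ctrl_{i + 1:02d}" for i in range(cfg.n_control)]
    samples = case_ids + ctrl_ids
    is_case = np.array([1.0] * cfg.n_case + [0.0] * cfg.n_control)

    lo, hi = cfg.baseline_ct_range
    baseline = np.concatenate(
        [rng.uniform(lo, hi, size=cfg.n_assays),
         np.full(cfg.n_ec_assays, cfg.ec_ct)]
    )

    fold = np.ones(cfg.n_assays)
    if cfg.n_planted:
        planted_idx = rng.choice(cfg.n_assays, size=cfg.n_planted, replace=False)
        fcs = list(cfg.planted_fold_changes)
        fold[planted_idx] = [fcs[k % len(fcs)] for k in range(cfg.n_planted)]
    shift = np.concatenate(
        [[_ct_shift(f) for f in fold], np.zeros(cfg.n_ec_assays)]
    )

    loading = rng.normal(0.0, cfg.loading_sd, size=len(samples))

    n_rows = len(assays) * cfg.replicates
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_rows, len(samples)))
    base = (
        np.repeat(baseline, cfg.replicates)[:, None]
        + loading[None, :]
        + np.repeat(shift, cfg.replicates)[:, None] * is_case[None, :]
    )
    ct_values = base + noise

    idx = pd.MultiIndex.from_arrays(
        [
            np.repeat(assays, cfg.replicates),
            np.tile(np.arange(1, cfg.replicates + 1), len(assays)),
        ],
        names=[ASSAY_LEVEL, REPLICATE_LEVEL],
    )
    ct = CtMatrix(pd.DataFrame(ct_values, index=idx, columns=samples)).censor(cfg.lod_ct)

    groups = {s: cfg.case_group for s in case_ids}
    groups.update({s: cfg.control_group for s in ctrl_ids})
    sheet = SampleSheet.from_groups(groups, calibrator=ctrl_ids[0])

    panel = PanelDef(assays=assays, endogenous_controls=ec_assays,
                     replicates=cfg.replicates)
    truth = pd.DataFrame({"assay": targets, "fold_change": fold})
    return SimulatedDataset(ct=ct, sheet=sheet, panel=panel, truth=truth)


def validation_config(**overrides) -> SynthConfig:
    """A :class:`SynthConfig` mirroring the validation-card design.

    15 target assays plus one endogenous-control assay (RNU6B), 3 technical
    replicates per assay, 21 case + 25 control samples; other fields keep the
    discovery defaults and can be overridden.
    """
    base = SynthConfig(
        n_assays=15, n_case=21, n_control=25, replicates=3, n_ec_assays=1
    )
    return replace(base, **overrides)


def generate_validation_dataset(cfg: SynthConfig | None = None, **overrides) -> SimulatedDataset:
    """Simulate a validation-card run (see :func:`validation_config`)."""
    return generate_dataset(cfg if cfg is not None else validation_config(**overrides))
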