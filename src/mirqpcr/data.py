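"""Core containers for low-density-array qPCR data.

A run is described by three objects: a :class:`CtMatrix` of raw cycle-threshold
values (assay wells x samples, with explicit non-detection), a
:class:`SampleSheet` assigning each sample to a study group and designating the
calibrator, and a :class:`PanelDef` naming the assays, the endogenous-control
wells used for normalization, and the technical replicate count.

Non-detected wells ("Undetermined" in vendor exports, or Ct at/after the last
cycle) are represented as NaN throughout; they are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Ct at or above this cycle number is treated as non-detected (40-cycle runs).
DEFAULT_LOD_CT = 40.0

#: Case-insensitive cell tokens interpreted as "no amplification reported".
NONDETECT_TOKENS = frozenset({"undetermined", "nd", "na", "n/a", ""})

ASSAY_LEVEL = "assay"
REPLICATE_LEVEL = "replicate"


class DataError(ValueError):
    """Raised when inputs violate the data model (hard errors)."""


class InputValidationError(DataError):
    """Raised by :func:`validate_inputs` with the full list of violations."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid inputs:\n" + "\n".join(f"- {v}" for v in self.violations)
        )


def _check_unique(ids: Iterable, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise DataError(f"duplicate {what} ids: {dupes}")
    return ids


@dataclass
class CtMatrix:
    """Raw Ct values, one row per (assay, replicate) well, one column per sample.

    ``values`` is indexed by a two-level MultiIndex (assay, replicate) and holds
    floats; NaN marks a non-detected well.  Every (assay, sample, replicate)
    cell is present.  Replicate numbers start at 1.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df.index, pd.MultiIndex) or df.index.nlevels != 2:
            raise DataError("CtMatrix index must be a (assay, replicate) MultiIndex")
        df.index = df.index.set_names([ASSAY_LEVEL, REPLICATE_LEVEL])
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise DataError(f"duplicate (assay, replicate) wells: {dupes[:5]}")
        _check_unique(df.columns, "sample")
        self.values = df.astype(float)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_wide(cls, frame: pd.DataFrame, lod_ct: float = DEFAULT_LOD_CT) -> "CtMatrix":
        """Build from an assay x sample table (single replicate per assay)."""
        idx = pd.MultiIndex.from_arrays(
            [frame.index, np.ones(len(frame), dtype=int)],
            names=[ASSAY_LEVEL, REPLICATE_LEVEL],
        )
        return cls(pd.DataFrame(frame.to_numpy(dtype=float), index=idx,
                                columns=frame.columns)).censor(lod_ct)

    # -- basic views -------------------------------------------------------

    @property
    def assays(self) -> list:
        seen: dict = {}
        for a in self.values.index.get_level_values(ASSAY_LEVEL):
            seen.setdefault(a, None)
        return list(seen)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def max_replicates(self) -> int:
        return int(self.values.groupby(level=ASSAY_LEVEL, sort=False).size().max())

    def assay_values(self) -> pd.DataFrame:
        """Assay x sample view; requires one replicate row per assay."""
        if self.max_replicates > 1:
            raise DataError(
                "matrix holds technical replicates; aggregate_replicates() first"
            )
        out = self.values.copy()
        out.index = out.index.get_level_values(ASSAY_LEVEL)
        return out

    # -- transforms --------------------------------------------------------

    def censor(self, lod_ct: float = DEFAULT_LOD_CT) -> "CtMatrix":
        """Coerce Ct values at or above the detection cutoff to non-detected.

        Idempotent: re-censoring at the same cutoff is a no-op.
        """
        vals = self.values.where(self.values < lod_ct)
        vals = vals.where(vals > 0)  # nonpositive Ct is physically meaningless
        return CtMatrix(vals)

    def to_long(self) -> pd.DataFrame:
        """Tidy (assay, sample, replicate, ct) frame; nd rows have NaN ct."""
        long = self.values.stack(future_stack=True).rename("ct").reset_index()
        long.columns = [ASSAY_LEVEL, REPLICATE_LEVEL, "sample", "ct"]
        return long[[ASSAY_LEVEL, "sample", REPLICATE_LEVEL, "ct"]]

    def equals(self, other: "CtMatrix") -> bool:
        a, b = self.values.sort_index(), other.values.sort_index()
        return a.columns.equals(b.columns) and a.index.equals(b.index) and bool(
            ((a == b) | (a.isna() & b.isna())).all().all()
        )


@dataclass
class SampleSheet:
    """Sample-to-group assignment plus the calibrator designation.

    ``table`` has columns ``sample_id``, ``group`` and boolean ``calibrator``;
    exactly one sample is the calibrator and every group is non-empty.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "group", "calibrator"}
        missing = required - set(t.columns)
        if missing:
            raise DataError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(t["sample_id"], "sample")
        if t["group"].isna().any() or (t["group"].astype(str) == "").any():
            raise DataError("sample sheet has empty group labels")
        ncal = int(t["calibrator"].astype(bool).sum())
        if ncal != 1:
            raise DataError(f"exactly one calibrator sample required, found {ncal}")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_groups(cls, groups: dict, calibrator: str) -> "SampleSheet":
        """Build from ``{sample_id: group}`` plus the calibrator sample id."""
        rows = pd.DataFrame(
            {"sample_id": list(groups), "group": list(groups.values())}
        )
        rows["calibrator"] = rows["sample_id"] == calibrator
        return cls(rows)

    @property
    def samples(self) -> list:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> pd.Series:
        """Series mapping sample_id -> group label."""
        return self.table.set_index("sample_id")["group"]

    @property
    def group_names(self) -> list:
        seen: dict = {}
        for g in self.table["group"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def calibrator(self) -> str:
        return self.table.loc[self.table["calibrator"].astype(bool), "sample_id"].iloc[0]

    def group_samples(self, group: str) -> list:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])


@dataclass
class PanelDef:
    """Assay panel: target + endogenous-control assay ids, replicate count."""

    assays: list
    endogenous_controls: list
    replicates: int = 1

    def __post_init__(self) -> None:
        self.assays = _check_unique(self.assays, "assay")
        self.endogenous_controls = list(self.endogenous_controls)
        if not self.endogenous_controls:
            raise DataError("panel needs at least one endogenous-control assay")
        stray = set(self.endogenous_controls) - set(self.assays)
        if stray:
            raise DataError(
                f"endogenous controls not in panel assay list: {sorted(stray)}"
            )
        if self.replicates < 1:
            raise DataError("replicates must be >= 1")

    @property
    def targets(self) -> list:
        ec = set(self.endogenous_controls)
        return [a for a in self.assays if a not in ec]


@dataclass
class Dataset:
    """A cross-validated bundle of the three inputs, ready for the pipeline."""

    ct: CtMatrix
    sheet: SampleSheet
    panel: PanelDef


def input_violations(ct: CtMatrix, sheet: SampleSheet, panel: PanelDef) -> list[str]:
    """Cross-check the three inputs; return human-readable violations.

    A missing endogenous control in the Ct matrix is *not* returned here — it
    makes normalization impossible and is always a hard error
    (see :func:`validate_inputs`).
    """
    v: list[str] = []
    ct_samples, sheet_samples = set(ct.samples), set(sheet.samples)
    for s in sorted(sheet_samples - ct_samples):
        v.append(f"sample sheet sample {s!r} absent from Ct matrix")
    for s in sorted(ct_samples - sheet_samples):
        v.append(f"Ct matrix sample {s!r} absent from sample sheet")
    ct_assays = set(ct.assays)
    for a in sorted(set(panel.assays) - ct_assays):
        v.append(f"panel assay {a!r} absent from Ct matrix")
    for a in sorted(ct_assays - set(panel.assays)):
        v.append(f"Ct matrix assay {a!r} not in panel definition")
    if ct.max_replicates > panel.replicates:
        v.append(
            f"Ct matrix has up to {ct.max_replicates} replicates per assay; "
            f"panel declares {panel.replicates}"
        )
    return v


def validate_inputs(ct: CtMatrix, sheet: SampleSheet, panel: PanelDef) -> Dataset:
    """Join the three inputs into a :class:`Dataset`, or raise.

    Raises :class:`DataError` immediately when no endogenous-control assay is
    present in the Ct matrix (normalization impossible), and
    :class:`InputValidationError` listing every other cross-reference
    violation.
    """
    present_ec = [a for a in panel.endogenous_controls if a in set(ct.assays)]
    if not present_ec:
        raise DataError(
            "no endogenous-control assay present in the Ct matrix: "
            f"{panel.endogenous_controls}"
        )
    violations = input_violations(ct, sheet, panel)
    if violations:
        raise InputValidationError(violations)
    return Dataset(ct=ct, sheet=sheet, panel=panel)
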