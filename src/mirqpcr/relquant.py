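"""Relative quantification: replicate aggregation, dCt, ddCt and RQ.

The comparative-Ct model assumes perfect doubling per PCR cycle:

* dCt(i, j)  = Ct(i, j) − reference Ct of sample j, where the reference is the
  aggregate of the detected endogenous-control wells in that sample;
* ddCt(i, j) = dCt(i, j) − dCt(i, calibrator);
* RQ(i, j)   = 2^−ddCt(i, j), so the calibrator sample has RQ 1 for every
  assay detected in it.

dCt normalization removes per-sample loading differences (adding a constant
to every Ct of a sample leaves its dCt unchanged); ddCt expresses abundance
relative to a designated calibrator sample.  Non-detected wells stay missing
at every stage.

The two stages are exposed as scikit-learn transformers operating on
samples x assays frames (NaN = non-detected), with thin assay x sample
functions on top matching the field's table orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ASSAY_LEVEL, CtMatrix, DataError, PanelDef, SampleSheet

__all__ = [
    "aggregate_replicates",
    "delta_ct",
    "delta_delta_ct",
    "RQResult",
    "DeltaCtTransformer",
    "RelativeQuantityTransformer",
]


def aggregate_replicates(ct: CtMatrix, panel: PanelDef, method: str = "mean") -> CtMatrix:
    """Collapse technical replicates to one Ct per (assay, sample).

    The aggregate is the ``method`` ('mean' or 'median') of the *detected*
    replicates; a cell is non-detected only when every replicate is.  With a
    single replicate per assay this is the identity.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown replicate aggregation {method!r}")
    grouped = ct.values.groupby(level=ASSAY_LEVEL, sort=False)
    agg = grouped.mean() if method == "mean" else grouped.median()
    agg.index = pd.MultiIndex.from_arrays(
        [agg.index, np.ones(len(agg), dtype=int)]
    )
    return CtMatrix(agg)


def _as_X(frame: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(frame, pd.DataFrame):
        raise TypeError("expected a pandas DataFrame")
    return frame


class DeltaCtTransformer(TransformerMixin, BaseEstimator):
    """Normalize Ct to the endogenous control within each sample.

    Parameters
    ----------
    endogenous_controls : list of assay ids used as the reference signal.
    aggregate : 'mean' or 'median' of the detected control wells per sample.
    drop_controls : drop the control columns from the output (default); the
        controls' own dCt carries no information beyond their spread.

    Input/output are samples x assays frames; NaN cells propagate.
    """

    def __init__(self, endogenous_controls=(), aggregate: str = "mean",
                 drop_controls: bool = True):
        self.endogenous_controls = endogenous_controls
        self.aggregate = aggregate
        self.drop_controls = drop_controls

    def fit(self, X, y=None):
        X = _as_X(X)
        ecs = [a for a in self.endogenous_controls if a in X.columns]
        if not ecs:
            raise DataError(
                f"no endogenous-control assay among the input columns: "
                f"{list(self.endogenous_controls)}"
            )
        if self.aggregate not in ("mean", "median"):
            raise ValueError(f"unknown control aggregation {self.aggregate!r}")
        self.control_assays_ = ecs
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_X(X)
        ec = X[self.control_assays_]
        ref = ec.mean(axis=1) if self.aggregate == "mean" else ec.median(axis=1)
        missing = ref.index[ref.isna()].tolist()
        if missing:
            raise DataError(
                f"no detected endogenous-control well in sample(s) {missing}"
            )
        self.reference_ct_ = ref
        out = X.sub(ref, axis=0)
        if self.drop_controls:
            out = out.drop(columns=self.control_assays_)
        return out


class RelativeQuantityTransformer(TransformerMixin, BaseEstimator):
    """Turn dCt into relative quantities 2^−ddCt against a calibrator.

    ``calibrator`` names the reference sample (policy 'sample'); policy
    'control-mean' instead anchors each assay at the mean dCt of the control
    group, which requires group labels ``y`` at fit time plus
    ``control_group``.  Assays non-detected in the calibrator have undefined
    ddCt; they are dropped and listed in ``undefined_assays_``.
    """

    def __init__(self, calibrator=None, policy: str = "sample",
                 control_group=None):
        self.calibrator = calibrator
        self.policy = policy
        self.control_group = control_group

    def fit(self, X, y=None):
        X = _as_X(X)
        if self.policy == "sample":
            if self.calibrator is None:
                raise ValueError("policy 'sample' needs a calibrator sample id")
            if self.calibrator not in X.index:
                raise DataError(f"calibrator sample {self.calibrator!r} not in data")
            ref = X.loc[self.calibrator]
        elif self.policy == "control-mean":
            if y is None or self.control_group is None:
                raise ValueError(
                    "policy 'control-mean' needs y labels and control_group"
                )
            mask = np.asarray(y) == self.control_group
            if mask.sum() == 0:
                raise DataError(f"no samples in control group {self.control_group!r}")
            ref = X.loc[np.asarray(X.index)[mask]].mean(axis=0)
        else:
            raise ValueError(f"unknown calibrator policy {self.policy!r}")
        self.reference_dct_ = ref
        self.undefined_assays_ = [a for a in X.columns if pd.isna(ref[a])]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def delta_delta_ct(self, X) -> pd.DataFrame:
        X = _as_X(X)
        keep = [a for a in X.columns if a not in set(self.undefined_assays_)]
        return X[keep].sub(self.reference_dct_[keep], axis=1)

    def transform(self, X) -> pd.DataFrame:
        return 2.0 ** (-self.delta_delta_ct(X))


# ---------------------------------------------------------------------------
# assay x sample convenience wrappers


def delta_ct(ct: CtMatrix, panel: PanelDef, aggregate: str = "mean",
             drop_controls: bool = True) -> pd.DataFrame:
    """dCt matrix (assay rows x sample columns) against the panel's controls.

    Replicates must already be aggregated.  Raises :class:`DataError` naming
    the sample when a sample has no detected control well.
    """
    X = ct.assay_values().T
    tr = DeltaCtTransformer(
        endogenous_controls=panel.endogenous_controls,
        aggregate=aggregate,
        drop_controls=drop_controls,
    )
    return tr.fit_transform(X).T


@dataclass
class RQResult:
    """ddCt and RQ grids (assay x sample) plus assays undefined in the calibrator."""

    delta_delta_ct: pd.DataFrame
    rq: pd.DataFrame
    undefined_assays: list


def delta_delta_ct(dct: pd.DataFrame, sheet: SampleSheet,
                   policy: str = "sample", control_group=None) -> RQResult:
    """ddCt and RQ from an assay x sample dCt frame and the sample sheet."""
    X = dct.T
    tr = RelativeQuantityTransformer(
        calibrator=sheet.calibrator if policy == "sample" else None,
        policy=policy,
        control_group=control_group,
    )
    y = sheet.groups.reindex(X.index).to_numpy() if policy == "control-mean" else None
    tr.fit(X, y)
    return RQResult(
        delta_delta_ct=tr.delta_delta_ct(X).T,
        rq=tr.transform(X).T,
        undefined_assays=tr.undefined_assays_,
    )
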