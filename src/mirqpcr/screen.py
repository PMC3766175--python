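"""Discovery screen: group statistics, signed fold-changes, Welch test, triage.

For every assay that survives the retention rule, the screen compares the two
study groups on relative quantities (RQ = 2^−ddCt):

* descriptive statistics per group — n, mean, SD (n−1), coefficient of
  variation (%), max/min ratio, median;
* the ratio of group means and of group medians (case over control),
  expressed as *signed* fold-changes: a ratio r becomes r when r >= 1 and
  −1/r otherwise, so 2-fold up and 2-fold down sit symmetrically at ±2;
* a two-sided Welch t-test (unequal-variance approximation);
* the composite differential-expression call — an assay is flagged when at
  least one of p <= 0.1, |mean fold-change| >= 2, |median fold-change| >= 2
  holds (a deliberately permissive union, because intra-group variability on
  low-density cards is high);
* a confidence tier (top / medium / low) from the detection-strength flags.

The heavy lifting lives in :class:`DifferentialExpressionScreen`, a
scikit-learn estimator over samples x assays RQ frames; :func:`run_screen`
drives the whole stage from raw Ct values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data import CtMatrix, DataError, PanelDef, SampleSheet
from .flags import flag_summary, retention_filter
from .relquant import aggregate_replicates, delta_ct, delta_delta_ct

__all__ = [
    "signed_fold_change",
    "welch_t",
    "de_call",
    "confidence_tier",
    "group_stats",
    "DifferentialExpressionScreen",
    "run_screen",
    "ScreenResult",
    "TIER_ORDER",
]

TIER_ORDER = {"top": 0, "medium": 1, "low": 2}


def signed_fold_change(ratio: float) -> float:
    """Express a positive expression ratio as a signed fold-change.

    Returns ``ratio`` when ratio >= 1, else ``−1/ratio``; thus a halving maps
    to −2 and |result| >= 1 always.  The representation is antisymmetric
    under inverting the ratio: sfc(1/r) = −sfc(r) for r != 1.
    """
    if not math.isfinite(ratio) or ratio <= 0:
        raise DataError(f"fold-change ratio must be positive and finite, got {ratio!r}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, Welch–Satterthwaite df, p).

    Degenerate spreads follow a documented convention: when both groups have
    zero variance, p is 1 for equal means and 0 otherwise (df is NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("Welch test needs at least two values per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, float("nan"), 1.0
        t = math.inf if x.mean() > y.mean() else -math.inf
        return t, float("nan"), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def de_call(p: float, mean_fc: float, median_fc: float,
            p_threshold: float = 0.1, fc_threshold: float = 2.0) -> bool:
    """Composite differential-expression rule (union of three prerequisites)."""
    return bool(
        p <= p_threshold
        or abs(mean_fc) >= fc_threshold
        or abs(median_fc) >= fc_threshold
    )


def confidence_tier(assay_flags: pd.DataFrame) -> str:
    """Triage one assay from its per-group good/low flag counts.

    ``assay_flags`` is indexed by group with columns including ``good`` and
    ``low``.  Any *low* flag in any sample demotes the assay to 'low';
    otherwise at least one *good* flag in every group earns 'top'; everything
    else (including good flags in only some groups, a case the tier scheme
    leaves open) is 'medium'.
    """
    if (assay_flags["low"] > 0).any():
        return "low"
    if (assay_flags["good"] >= 1).all():
        return "top"
    return "medium"


def group_stats(rq: pd.DataFrame, sheet: SampleSheet, min_n: int = 2) -> pd.DataFrame:
    """Descriptive statistics per (assay, group) over detected RQ values.

    Returns a frame indexed by (assay, group) with columns n, mean, sd, cv,
    maxmin_r, median.  Assays with fewer than ``min_n`` detected values in
    any group are dropped (their SD is undefined).
    """
    rows = []
    for group in sheet.group_names:
        cols = [s for s in sheet.group_samples(group) if s in rq.columns]
        sub = rq[cols]
        stats_df = pd.DataFrame(
            {
                "n": sub.notna().sum(axis=1),
                "mean": sub.mean(axis=1),
                "sd": sub.std(axis=1, ddof=1),
                "median": sub.median(axis=1),
                "maxmin_r": sub.max(axis=1) / sub.min(axis=1),
            }
        )
        stats_df["cv"] = 100.0 * stats_df["sd"] / stats_df["mean"]
        stats_df["group"] = group
        rows.append(stats_df)
    out = pd.concat(rows)
    out.index.name = "assay"
    out = out.reset_index().set_index(["assay", "group"])
    enough = (out["n"].unstack("group") >= min_n).all(axis=1)
    out = out[out.index.get_level_values("assay").map(enough)]
    return out[["n", "mean", "sd", "cv", "maxmin_r", "median"]]


class DifferentialExpressionScreen(BaseEstimator):
    """Per-assay two-group comparison on relative quantities.

    Parameters
    ----------
    case_group, control_group : labels in ``y``; fold-changes are case over
        control.  When None, the first / second distinct label in ``y`` order.
    p_threshold, fc_threshold : thresholds of the composite DE rule.
    test_scale : 'rq' runs the Welch test on linear RQ values (Table-style
        magnitudes); 'log' runs it on log2 RQ = −ddCt, where qPCR noise is
        closer to normal.
    min_group_n : minimum detected values per group (statistics undefined
        below 2).

    After ``fit(X, y)`` (X: samples x assays RQ frame, NaN = missing),
    ``results_`` holds one row per testable assay and ``excluded_`` maps
    dropped assays to the reason.
    """

    def __init__(self, case_group=None, control_group=None,
                 p_threshold: float = 0.1, fc_threshold: float = 2.0,
                 test_scale: str = "rq", min_group_n: int = 2):
        self.case_group = case_group
        self.control_group = control_group
        self.p_threshold = p_threshold
        self.fc_threshold = fc_threshold
        self.test_scale = test_scale
        self.min_group_n = min_group_n

    def _resolve_groups(self, y) -> tuple:
        labels = list(dict.fromkeys(np.asarray(y, dtype=object)))
        if len(labels) != 2:
            raise DataError(f"screen needs exactly two groups, got {labels}")
        case = self.case_group if self.case_group is not None else labels[0]
        control = (
            self.control_group if self.control_group is not None else
            next(l for l in labels if l != case)
        )
        if case not in labels or control not in labels or case == control:
            raise DataError(
                f"groups ({case!r}, {control!r}) do not match labels {labels}"
            )
        return case, control

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x assays DataFrame of RQ values")
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise DataError("y must have one group label per sample (row of X)")
        if self.test_scale not in ("rq", "log"):
            raise ValueError(f"unknown test scale {self.test_scale!r}")
        case, control = self._resolve_groups(y)
        self.case_group_, self.control_group_ = case, control
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        rows, excluded = [], {}
        for assay in X.columns:
            xs = X.loc[y == case, assay].dropna().to_numpy(dtype=float)
            ys = X.loc[y == control, assay].dropna().to_numpy(dtype=float)
            if len(xs) < self.min_group_n or len(ys) < self.min_group_n:
                excluded[assay] = (
                    f"fewer than {self.min_group_n} detected values in a group "
                    f"(case {len(xs)}, control {len(ys)})"
                )
                continue
            row = {"assay": assay}
            for tag, v in (("case", xs), ("control", ys)):
                mean, sd = v.mean(), v.std(ddof=1)
                row.update(
                    {
                        f"n_{tag}": len(v),
                        f"mean_{tag}": mean,
                        f"sd_{tag}": sd,
                        f"cv_{tag}": 100.0 * sd / mean,
                        f"maxmin_r_{tag}": v.max() / v.min(),
                        f"median_{tag}": np.median(v),
                    }
                )
            mean_ratio = row["mean_case"] / row["mean_control"]
            median_ratio = row["median_case"] / row["median_control"]
            if self.test_scale == "rq":
                t, df, p = welch_t(xs, ys)
            else:
                t, df, p = welch_t(np.log2(xs), np.log2(ys))
            mean_fc = signed_fold_change(mean_ratio)
            median_fc = signed_fold_change(median_ratio)
            row.update(
                {
                    "mean_ratio": mean_ratio,
                    "median_ratio": median_ratio,
                    "mean_fc": mean_fc,
                    "median_fc": median_fc,
                    "t_welch": t,
                    "df_welch": df,
                    "p_welch": p,
                    "de_call": de_call(p, mean_fc, median_fc,
                                       self.p_threshold, self.fc_threshold),
                }
            )
            rows.append(row)
        self.results_ = pd.DataFrame(rows)
        self.excluded_ = excluded
        return self


@dataclass
class ScreenResult:
    """Everything the discovery stage produces."""

    records: pd.DataFrame
    flag_summary: pd.DataFrame
    retained: list
    excluded: dict = field(default_factory=dict)


def run_screen(
    ct: CtMatrix,
    sheet: SampleSheet,
    panel: PanelDef,
    case_group=None,
    control_group=None,
    p_threshold: float = 0.1,
    fc_threshold: float = 2.0,
    quartile: float = 0.25,
    min_detected: int = 2,
    test_scale: str = "rq",
    replicate_method: str = "mean",
    ec_aggregate: str = "mean",
    calibrator_policy: str = "sample",
    quartile_population: str = "within-sample",
) -> ScreenResult:
    """Full discovery stage from raw Ct values.

    Pipeline: aggregate replicates -> dCt against the endogenous controls ->
    strength flags -> retention (>= ``min_detected`` detected samples per
    group) -> ddCt/RQ against the calibrator -> per-assay statistics, signed
    fold-changes, Welch p, DE call -> confidence tier.  Records are sorted by
    tier, then p, then assay id; exclusions (with reasons) are logged in the
    result.
    """
    agg = aggregate_replicates(ct, panel, method=replicate_method)
    dct = delta_ct(agg, panel, aggregate=ec_aggregate)
    fs = flag_summary(dct, sheet, q=quartile, population=quartile_population)
    retained = retention_filter(fs, min_detected=min_detected)
    excluded = {
        a: f"detected in fewer than {min_detected} samples of a group"
        for a in dct.index
        if a not in set(retained)
    }
    if not retained:
        return ScreenResult(pd.DataFrame(), fs, [], excluded)

    rqres = delta_delta_ct(
        dct.loc[retained], sheet, policy=calibrator_policy,
        control_group=control_group,
    )
    for a in rqres.undefined_assays:
        excluded[a] = "not detected in the calibrator sample (ddCt undefined)"

    est = DifferentialExpressionScreen(
        case_group=case_group,
        control_group=control_group,
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
        test_scale=test_scale,
        min_group_n=min_detected,
    )
    X = rqres.rq.T
    est.fit(X, sheet.groups.reindex(X.index).to_numpy(dtype=object))
    excluded.update(est.excluded_)
    records = est.results_

    if len(records):
        tiers = {
            a: confidence_tier(fs.xs(a, level="assay"))
            for a in records["assay"]
        }
        records = records.assign(tier=records["assay"].map(tiers))
        records = records.sort_values(
            by=["tier", "p_welch", "assay"],
            key=lambda col: col.map(TIER_ORDER) if col.name == "tier" else col,
        ).reset_index(drop=True)
    return ScreenResult(records, fs, retained, excluded)
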