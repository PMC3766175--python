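"""Detection/strength flags: values, nd, good, normal, low.

Each sample's detected assays are ranked by dCt.  Assays in the strongest
quartile (lowest dCt, i.e. most abundant) are flagged *good*, the weakest
quartile (highest dCt) *low*, the middle half *normal*.  Per assay and study
group, the summary counts how many samples detected the assay (*values* vs
*nd*) and how many of those fell in each strength band.  These counts drive
the retention rule and the confidence triage of the screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SampleSheet

__all__ = ["classify_sample", "flag_summary", "retention_filter", "FLAG_COLUMNS"]

FLAG_COLUMNS = ["values", "nd", "good", "normal", "low"]

#: Samples with fewer detected assays than this cannot support quartiles.
MIN_ASSAYS_FOR_QUARTILES = 4


def classify_sample(dct_sample: pd.Series, q: float = 0.25) -> pd.Series:
    """Label each detected assay of one sample good / normal / low by dCt quartile.

    Thresholds are the ``q`` and ``1−q`` quantiles (linear interpolation
    between order statistics) of the sample's detected dCt values, boundary
    inclusive on both sides.  Degenerate cases are conservative: fewer than
    four detected assays, or coinciding quartile thresholds (heavy ties),
    label everything normal.  Non-detected entries are dropped.
    """
    if not 0 < q < 0.5:
        raise ValueError("quartile fraction q must be in (0, 0.5)")
    v = dct_sample.dropna()
    labels = pd.Series("normal", index=v.index, dtype=object)
    if len(v) < MIN_ASSAYS_FOR_QUARTILES:
        return labels
    lo, hi = np.quantile(v.to_numpy(), [q, 1.0 - q])
    if lo == hi:
        return labels
    labels[v <= lo] = "good"
    labels[v >= hi] = "low"
    return labels


def flag_summary(dct: pd.DataFrame, sheet: SampleSheet, q: float = 0.25,
                 population: str = "within-sample") -> pd.DataFrame:
    """Per-assay, per-group flag counts from an assay x sample dCt frame.

    ``population`` selects the quartile reference set: 'within-sample' ranks a
    sample's detected assays against each other (strength relative to the rest
    of that sample's miRNA complement, the default); 'within-assay' ranks an
    assay's detected samples against each other.

    Returns a frame indexed by (assay, group) with columns
    ``values, nd, good, normal, low`` satisfying values + nd = group size and
    good + normal + low = values.
    """
    if population == "within-sample":
        labelled = {s: classify_sample(dct[s], q=q) for s in dct.columns}
        labels = pd.DataFrame(labelled).reindex(index=dct.index, columns=dct.columns)
    elif population == "within-assay":
        labels = pd.DataFrame(
            {a: classify_sample(dct.loc[a], q=q) for a in dct.index}
        ).T.reindex(index=dct.index, columns=dct.columns)
    else:
        raise ValueError(f"unknown quartile population {population!r}")

    rows = []
    for group in sheet.group_names:
        cols = [s for s in sheet.group_samples(group) if s in dct.columns]
        sub = labels[cols]
        counts = pd.DataFrame(
            {
                "values": sub.notna().sum(axis=1),
                "good": (sub == "good").sum(axis=1),
                "normal": (sub == "normal").sum(axis=1),
                "low": (sub == "low").sum(axis=1),
            }
        )
        counts["nd"] = len(cols) - counts["values"]
        counts["group"] = group
        rows.append(counts)
    out = pd.concat(rows)
    out.index.name = "assay"
    out = out.reset_index().set_index(["assay", "group"])
    return out[FLAG_COLUMNS].astype(int)


def retention_filter(summary: pd.DataFrame, min_detected: int = 2) -> list:
    """Assays detectable in at least ``min_detected`` samples of *every* group.

    This is the screen's inclusion rule: with fewer than two detected samples
    in a group no spread, hence no test statistic, can be formed.
    """
    detected = summary["values"].unstack("group")
    keep = (detected >= min_detected).all(axis=1)
    order = {a: i for i, a in enumerate(detected.index)}
    return sorted(keep.index[keep], key=order.get)
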