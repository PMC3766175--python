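"""Small bundled reference tables.

``discovery_panel_summary.tsv`` holds published discovery-stage summary
statistics for a 15-miRNA endometriosis candidate panel measured on TaqMan
low-density cards (10 endometriosis vs 10 control samples): per-group mean
RQ, SD, CV (%), max/min ratio, plus the ratio of group means and medians
(endometriosis over control) and the corresponding signed fold-changes as
printed.  It supports worked examples of the signed fold-change convention;
it is a summary table, not raw Ct data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_discovery_panel_summary"]


def load_discovery_panel_summary() -> pd.DataFrame:
    """Published per-group summary statistics for the 15-miRNA candidate panel.

    Columns: ``mirna``; ``mean/sd/cv/maxmin_r`` suffixed ``_endo`` (the
    endometriosis group) and ``_ctrl``; ``mean_ratio`` and ``median_ratio``
    (endo over control); printed signed ``mean_fc`` / ``median_fc``.
    """
    ref = resources.files(__package__) / "discovery_panel_summary.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
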