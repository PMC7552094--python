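"""Hub classification and group comparison of hub presence.

A region is a hub for a subject and metric when its nodal value strictly
exceeds 1.5 times that subject's whole-brain mean of the metric.  Hub
presence/absence is then compared region-by-region between groups with a
two-sided Fisher exact test; raw p-values are reported alongside
FDR-adjusted ones (across regions, within metric), since exploratory reports
often quote the uncorrected values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group_stats import fdr_bh, fisher_exact_2x2

__all__ = ["HUB_FACTOR", "classify_hubs", "hub_flag_table",
           "compare_hub_presence", "HubTable"]

#: multiple of the whole-brain mean above which a region counts as a hub
HUB_FACTOR = 1.5


def classify_hubs(metric_row) -> np.ndarray:
    """Boolean hub flags for one subject: value > 1.5 x whole-brain mean."""
    v = np.asarray(metric_row, dtype=float)
    if v.size == 0:
        raise ValueError("empty metric vector")
    return v > HUB_FACTOR * v.mean()


def hub_flag_table(metric_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-subject hub flags (subjects x regions boolean DataFrame)."""
    flags = np.vstack([classify_hubs(row) for row in metric_matrix.to_numpy()])
    return pd.DataFrame(flags, index=metric_matrix.index,
                        columns=metric_matrix.columns)


@dataclass
class HubTable:
    """Per-region hub-presence comparison between groups for one metric.

    ``table`` columns: region, n_hub_controls, n_hub_patients, n_controls,
    n_patients, direction ("patient"/"control"/"none": which group carries
    the higher hub frequency), p_raw, p_fdr.
    """

    metric_name: str
    table: pd.DataFrame
    alpha: float = 0.05

    def significant(self, corrected: bool = True) -> pd.DataFrame:
        col = "p_fdr" if corrected else "p_raw"
        return self.table[self.table[col] < self.alpha]


def compare_hub_presence(hub_flags: pd.DataFrame, controls: list[str],
                         patients: list[str], metric_name: str = "metric",
                         alpha: float = 0.05) -> HubTable:
    """Fisher-exact comparison of per-region hub frequency between groups."""
    if not len(controls) or not len(patients):
        raise ValueError("both groups must be non-empty")
    ctrl = hub_flags.loc[list(controls)].to_numpy()
    pat = hub_flags.loc[list(patients)].to_numpy()
    n_c, n_p = len(controls), len(patients)
    rows = []
    for r, region in enumerate(hub_flags.columns):
        hc = int(ctrl[:, r].sum())
        hp = int(pat[:, r].sum())
        p = fisher_exact_2x2([[hc, n_c - hc], [hp, n_p - hp]])
        freq_c, freq_p = hc / n_c, hp / n_p
        direction = ("patient" if freq_p > freq_c
                     else "control" if freq_c > freq_p else "none")
        rows.append((region, hc, hp, n_c, n_p, direction, p))
    table = pd.DataFrame(rows, columns=[
        "region", "n_hub_controls", "n_hub_patients", "n_controls",
        "n_patients", "direction", "p_raw"])
    table["p_fdr"] = fdr_bh(table["p_raw"].to_numpy(), alpha)[0]
    return HubTable(metric_name=metric_name, table=table, alpha=alpha)
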