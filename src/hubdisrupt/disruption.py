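"""Hub-disruption index: regression of nodal-metric differences on the
control-mean nodal profile.

For a nodal metric with control-mean profile <LM>_C over N regions, the
subject-wise disruption index k_S of subject S is the OLS slope of
``LM_S - <LM>_C`` against ``<LM>_C`` across regions; the group-wise index k
replaces LM_S with the patient-group mean profile.  A nonzero k signals a
systematic reorganization of nodal topology: k < 0 means regions that are
strong in controls are relatively weakened in patients (and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DisruptionResult",
    "control_mean_profile",
    "subject_disruption",
    "group_disruption",
    "subject_disruption_table",
]


@dataclass
class DisruptionResult:
    """Fitted disruption-index regression(s) for one metric.

    ``mode`` is "group_wise" (one slope for the patient group, with a
    two-sided t-test p-value on N-2 degrees of freedom) or "subject_wise"
    (one slope per subject in controls + patients).
    """

    metric_name: str
    mode: str
    k: float | None = None
    k0: float | None = None
    p_slope: float | None = None
    per_subject_k: dict[str, float] = field(default_factory=dict)
    per_subject_k0: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None

    def per_subject_series(self) -> pd.Series:
        return pd.Series(self.per_subject_k, name=f"k_{self.metric_name}")


def control_mean_profile(metric_matrix: pd.DataFrame,
                         controls: list[str]) -> np.ndarray:
    """Per-region arithmetic mean of the metric over control subjects."""
    if len(controls) < 2:
        raise ValueError("need at least 2 controls for a mean profile")
    return metric_matrix.loc[list(controls)].to_numpy().mean(axis=0)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Closed-form simple OLS: slope, intercept, residuals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 regions")
    xc = x - x.mean()
    sxx = (xc ** 2).sum()
    if sxx == 0:
        raise ValueError("control profile is constant: disruption slope undefined")
    slope = (xc * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    return float(slope), float(intercept), resid


def subject_disruption(metric_row: np.ndarray, control_profile: np.ndarray
                       ) -> tuple[float, float, np.ndarray]:
    """Subject-wise disruption index.

    OLS of y = metric_row - control_profile on x = control_profile over all
    regions; returns (slope k, intercept k0, residuals).
    """
    x = np.asarray(control_profile, dtype=float)
    y = np.asarray(metric_row, dtype=float) - x
    return _ols_line(x, y)


def group_disruption(metric_matrix: pd.DataFrame, controls: list[str],
                     patients: list[str], metric_name: str = "metric"
                     ) -> DisruptionResult:
    """Group-wise disruption index with slope significance.

    Regresses (patient mean profile - control mean profile) on the control
    mean profile; p_slope is the two-sided t-test on the OLS slope with
    N - 2 degrees of freedom.
    """
    if not len(controls) or not len(patients):
        raise ValueError("both groups must be non-empty")
    ctrl = control_mean_profile(metric_matrix, controls)
    pat = metric_matrix.loc[list(patients)].to_numpy().mean(axis=0)
    k, k0, resid = _ols_line(ctrl, pat - ctrl)
    n = ctrl.size
    df = n - 2
    sxx = ((ctrl - ctrl.mean()) ** 2).sum()
    s2 = (resid ** 2).sum() / df
    se = np.sqrt(s2 / sxx)
    if se == 0:
        p = 1.0 if k == 0 else 0.0
    else:
        t = k / se
        p = float(2 * stats.t.sf(abs(t), df))
    return DisruptionResult(metric_name=metric_name, mode="group_wise",
                            k=k, k0=k0, p_slope=p, residuals=resid)


def subject_disruption_table(metric_matrix: pd.DataFrame, controls: list[str],
                             patients: list[str], metric_name: str = "metric",
                             leave_one_out: bool = False) -> DisruptionResult:
    """Subject-wise disruption indices for every subject (controls + patients).

    By default each control is regressed against the full control mean,
    exactly as the subject-wise definition subtracts the complete control-mean
    profile for all subjects; with ``leave_one_out`` a control's own row is
    excluded from the reference mean.
    """
    if not len(controls) or not len(patients):
        raise ValueError("both groups must be non-empty")
    profile = control_mean_profile(metric_matrix, controls)
    res = DisruptionResult(metric_name=metric_name, mode="subject_wise")
    control_set = set(controls)
    for sid in list(controls) + list(patients):
        ref = profile
        if leave_one_out and sid in control_set:
            others = [c for c in controls if c != sid]
            ref = control_mean_profile(metric_matrix, others)
        k, k0, _ = subject_disruption(metric_matrix.loc[sid].to_numpy(), ref)
        res.per_subject_k[sid] = k
        res.per_subject_k0[sid] = k0
    return res
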