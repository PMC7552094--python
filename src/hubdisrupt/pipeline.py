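"""End-to-end analysis: thresholding, metrics, group comparisons, disruption
indices, hub analysis, clinical associations and ROC discrimination.

The report layout mirrors a connectome group study's results: global-metric
comparisons, region-wise local comparisons (FDR across regions within each
metric), group- and subject-wise disruption indices, hub presence by group,
age/sex-adjusted clinical associations, and ROC tables for global measures /
disruption indices and for local measures ordered by AUC.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome_io import (CohortTable, Connectome, read_cohort,
                            read_connectome)
from .disruption import group_disruption, subject_disruption_table
from .graph_metrics import (GLOBAL_METRICS, LOCAL_METRICS, MetricTable,
                            compute_metric_table)
from .group_stats import (clinical_association, fdr_bh, mann_whitney,
                          median_pct_effect, roc_logistic)
from .hub_analysis import compare_hub_presence, hub_flag_table

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Pipeline settings; defaults reproduce the published procedure
    (10% sparsity, FDR alpha 0.05, patients as the ROC positive class)."""

    sparsity: float = 0.10
    alpha: float = 0.05
    mw_method: str = "auto"
    leave_one_out: bool = False
    roc_local_top_k: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.sparsity <= 1:
            raise ValueError(f"sparsity must be in (0, 1], got {self.sparsity}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class AnalysisReport:
    """All result tables of one pipeline run (see module docstring)."""

    config: AnalysisConfig
    metrics: MetricTable
    global_comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    local_comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    disruption_group: pd.DataFrame = field(default_factory=pd.DataFrame)
    disruption_subject: pd.DataFrame = field(default_factory=pd.DataFrame)
    disruption_comparison: pd.DataFrame = field(default_factory=pd.DataFrame)
    hubs: pd.DataFrame = field(default_factory=pd.DataFrame)
    associations: pd.DataFrame = field(default_factory=pd.DataFrame)
    roc_global: pd.DataFrame = field(default_factory=pd.DataFrame)
    roc_local: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: dict = field(default_factory=dict)

    def significant_local(self, metric: str) -> list[str]:
        t = self.local_comparisons
        sel = t[(t["metric"] == metric) & (t["p_fdr"] < self.config.alpha)]
        return sel["region"].tolist()


def _safe_effect(pat_vals: np.ndarray, ctl_vals: np.ndarray) -> float:
    try:
        return median_pct_effect(pat_vals, ctl_vals)
    except ValueError:
        return float("nan")


def _compare_groups(values: pd.Series | pd.DataFrame, controls, patients,
                    mw_method: str) -> list[dict]:
    """Mann-Whitney + median-percent effect for one or many columns."""
    if isinstance(values, pd.Series):
        values = values.to_frame()
    out = []
    for col in values.columns:
        x = values.loc[list(patients), col].to_numpy()
        y = values.loc[list(controls), col].to_numpy()
        u, p = mann_whitney(x, y, method=mw_method)
        out.append({"name": col, "U": u, "p_raw": p,
                    "effect_size_pct": _safe_effect(x, y)})
    return out


def run_pipeline(connectomes: list[Connectome], cohort: CohortTable,
                 config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full group analysis and return the report."""
    config = config or AnalysisConfig()
    connectomes = sorted(connectomes, key=lambda c: c.subject_id)
    ids = {c.subject_id for c in connectomes}
    expected = set(cohort.table["subject_id"])
    if ids != expected:
        raise ValueError(
            f"cohort/connectome mismatch: missing {sorted(expected - ids)}, "
            f"extra {sorted(ids - expected)}")
    controls, patients = cohort.controls, cohort.patients
    if not controls or not patients:
        raise ValueError("both groups must be present in the cohort")

    logger.info("stage metrics: %d subjects, sparsity %.3f",
                len(connectomes), config.sparsity)
    metrics = compute_metric_table(connectomes, config.sparsity)
    report = AnalysisReport(config=config, metrics=metrics)

    # --- global metric comparisons (FDR family: the global metrics) -------
    glob = pd.DataFrame(metrics.global_)
    rows = _compare_groups(glob, controls, patients, config.mw_method)
    gdf = pd.DataFrame(rows).rename(columns={"name": "metric"})
    gdf["p_fdr"] = fdr_bh(gdf["p_raw"].to_numpy(), config.alpha)[0]
    report.global_comparisons = gdf

    # --- local metric comparisons (FDR across regions within metric) -----
    local_rows = []
    for metric in LOCAL_METRICS:
        rows = _compare_groups(metrics.local[metric], controls, patients,
                               config.mw_method)
        df = pd.DataFrame(rows).rename(columns={"name": "region"})
        df.insert(0, "metric", metric)
        df["p_fdr"] = fdr_bh(df["p_raw"].to_numpy(), config.alpha)[0]
        local_rows.append(df)
    report.local_comparisons = pd.concat(local_rows, ignore_index=True)

    # --- disruption indices ----------------------------------------------
    logger.info("stage disruption")
    grows, srows, crows = [], [], []
    subject_k = {}
    for metric in LOCAL_METRICS:
        mat = metrics.local[metric]
        g = group_disruption(mat, controls, patients, metric_name=metric)
        grows.append({"metric": metric, "k": g.k, "k0": g.k0,
                      "p_slope": g.p_slope})
        s = subject_disruption_table(mat, controls, patients,
                                     metric_name=metric,
                                     leave_one_out=config.leave_one_out)
        ks = s.per_subject_series()
        subject_k[metric] = ks
        for sid, kval in s.per_subject_k.items():
            srows.append({"metric": metric, "subject_id": sid, "k": kval,
                          "k0": s.per_subject_k0[sid],
                          "group": "control" if sid in set(controls)
                          else "patient"})
        x = ks.loc[list(patients)].to_numpy()
        y = ks.loc[list(controls)].to_numpy()
        u, p = mann_whitney(x, y, method=config.mw_method)
        crows.append({"metric": metric, "U": u, "p_raw": p,
                      "effect_size_pct": _safe_effect(x, y)})
    report.disruption_group = pd.DataFrame(grows)
    report.disruption_group["p_fdr"] = fdr_bh(
        report.disruption_group["p_slope"].to_numpy(), config.alpha)[0]
    report.disruption_subject = pd.DataFrame(srows)
    cdf = pd.DataFrame(crows)
    cdf["p_fdr"] = fdr_bh(cdf["p_raw"].to_numpy(), config.alpha)[0]
    report.disruption_comparison = cdf

    # --- hub analysis -----------------------------------------------------
    logger.info("stage hubs")
    hub_frames = []
    for metric in LOCAL_METRICS:
        flags = hub_flag_table(metrics.local[metric])
        ht = compare_hub_presence(flags, controls, patients,
                                  metric_name=metric, alpha=config.alpha)
        t = ht.table.copy()
        t.insert(0, "metric", metric)
        hub_frames.append(t)
    report.hubs = pd.concat(hub_frames, ignore_index=True)

    # --- clinical associations (age/sex adjusted) ------------------------
    tab = cohort.table.set_index("subject_id")
    order = [c.subject_id for c in connectomes]
    age = tab.loc[order, "age"].to_numpy(dtype=float)
    sex = tab.loc[order, "sex"].to_numpy()
    arows = []
    for clin in cohort.clinical_columns:
        cvals = tab.loc[order, clin].to_numpy(dtype=float)
        # local metrics: FDR across regions within (metric, clinical)
        for metric in LOCAL_METRICS:
            mat = metrics.local[metric].loc[order]
            batch = []
            for region in mat.columns:
                try:
                    r = clinical_association(
                        mat[region].to_numpy(), cvals, age, sex,
                        metric_name=metric, clinical_name=clin, region=region)
                except ValueError:
                    continue
                batch.append({"clinical": clin, "metric": metric,
                              "region": region, "beta": r.beta,
                              "cohens_f2": r.cohens_f2, "p_raw": r.p_raw,
                              "n": r.n_complete, "family": f"local:{metric}"})
            arows.extend(batch)
        # global metrics: FDR across the global metrics, per clinical score
        for metric in GLOBAL_METRICS:
            vals = metrics.global_[metric].loc[order].to_numpy()
            try:
                r = clinical_association(vals, cvals, age, sex,
                                         metric_name=metric,
                                         clinical_name=clin, region="global")
            except ValueError:
                continue
            arows.append({"clinical": clin, "metric": metric,
                          "region": "global", "beta": r.beta,
                          "cohens_f2": r.cohens_f2, "p_raw": r.p_raw,
                          "n": r.n_complete, "family": "global"})
        # disruption indices: their own FDR family, per clinical score
        for metric in LOCAL_METRICS:
            vals = subject_k[metric].loc[order].to_numpy()
            try:
                r = clinical_association(vals, cvals, age, sex,
                                         metric_name=f"k_{metric}",
                                         clinical_name=clin, region="global")
            except ValueError:
                continue
            arows.append({"clinical": clin, "metric": f"k_{metric}",
                          "region": "global", "beta": r.beta,
                          "cohens_f2": r.cohens_f2, "p_raw": r.p_raw,
                          "n": r.n_complete, "family": "disruption"})
    adf = pd.DataFrame(arows)
    if len(adf):
        adf["p_fdr"] = np.nan
        for (_, _), idx in adf.groupby(["clinical", "family"]).groups.items():
            adj, _ = fdr_bh(adf.loc[idx, "p_raw"].to_numpy(), config.alpha)
            adf.loc[idx, "p_fdr"] = adj
    report.associations = adf

    # --- ROC discrimination ----------------------------------------------
    logger.info("stage roc")
    labels01 = np.array([0 if sid in set(controls) else 1 for sid in order])
    roc_rows = []
    for metric in GLOBAL_METRICS:
        r = roc_logistic(metrics.global_[metric].loc[order].to_numpy(),
                         labels01, name=metric)
        roc_rows.append(dataclasses.asdict(r))
    for metric in LOCAL_METRICS:
        r = roc_logistic(subject_k[metric].loc[order].to_numpy(), labels01,
                         name=f"k_{metric}")
        roc_rows.append(dataclasses.asdict(r))
    rg = pd.DataFrame(roc_rows).sort_values("auc", ascending=False,
                                            kind="stable")
    report.roc_global = rg.reset_index(drop=True)

    lrows = []
    for metric in LOCAL_METRICS:
        mat = metrics.local[metric].loc[order]
        for region in mat.columns:
            r = roc_logistic(mat[region].to_numpy(), labels01, name=metric)
            d = dataclasses.asdict(r)
            d["region"] = region
            lrows.append(d)
    rl = pd.DataFrame(lrows).sort_values("auc", ascending=False, kind="stable")
    report.roc_local = rl.reset_index(drop=True)

    wdigest = hashlib.sha256()
    for c in connectomes:
        wdigest.update(np.ascontiguousarray(c.weights).tobytes())
    report.metadata = {
        "version": __version__,
        "n_controls": len(controls),
        "n_patients": len(patients),
        "n_regions": connectomes[0].n_regions,
        "sparsity": config.sparsity,
        "alpha": config.alpha,
        "input_sha256": wdigest.hexdigest(),
    }
    return report


def load_dataset(directory: str | Path
                 ) -> tuple[list[Connectome], CohortTable]:
    """Load a dataset directory (cohort.csv, labels.txt, one matrix per
    subject as <subject_id>.tsv/.csv/.mtx).  Subject file order on disk is
    irrelevant: subjects are taken from the cohort table."""
    directory = Path(directory)
    cohort = read_cohort(directory / "cohort.csv")
    labels_path = directory / "labels.txt"
    connectomes = []
    for sid in cohort.table["subject_id"]:
        for ext in ("tsv", "csv", "mtx"):
            p = directory / f"{sid}.{ext}"
            if p.exists():
                connectomes.append(read_connectome(p, labels_path,
                                                   subject_id=sid))
                break
        else:
            raise FileNotFoundError(f"no matrix file for subject {sid!r} "
                                    f"in {directory}")
    return connectomes, cohort


def write_report(report: AnalysisReport, outdir: str | Path) -> Path:
    """Write every report table as CSV plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "global_comparisons": report.global_comparisons,
        "local_comparisons": report.local_comparisons,
        "disruption_group": report.disruption_group,
        "disruption_subject": report.disruption_subject,
        "disruption_comparison": report.disruption_comparison,
        "hubs": report.hubs,
        "associations": report.associations,
        "roc_global": report.roc_global,
        "roc_local": report.roc_local,
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    report.metrics.to_tidy().to_csv(outdir / "metrics_tidy.csv", index=False)
    summary = {
        "metadata": report.metadata,
        "significant_local": {
            m: report.significant_local(m) for m in LOCAL_METRICS},
        "disruption_group": report.disruption_group.to_dict("records"),
        "top_local_auc": report.roc_local.head(
            report.config.roc_local_top_k)[
                ["region", "predictor", "auc"]].to_dict("records"),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True) + "\n")
    return outdir
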