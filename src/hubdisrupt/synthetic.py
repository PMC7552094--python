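"""Synthetic cohorts of structural connectomes with known planted effects.

The generator emulates the statistical structure a glaucoma-vs-control
connectome study assumes: two groups (15 controls, 23 patients by default)
over an 84-region Desikan-style parcellation; a multiplicative group effect
on edges incident to a small set of affected (occipital/paracentral) regions;
a planted subject-wise disruption slope on the nodal-strength profile;
subject-level multiplicative edge noise; and clinical covariates (RNFL, GCL,
VFI, IOP) with a planted negative metric-RNFL association.  It produces
connectomes, not diffusion data: tractography, parcellation and their error
modes are outside its scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome_io import (Connectome, CohortTable, write_cohort,
                            write_connectome, write_labels)
from .graph_metrics import threshold_sparsity

__all__ = ["SimulationConfig", "desikan84_labels", "make_base_connectome",
           "simulate_cohort", "simulate_disruption_profiles", "write_dataset"]

_DESIKAN_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]
_SUBCORTICAL = [
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala",
    "accumbens", "cerebellum-cortex",
]


def desikan84_labels() -> list[str]:
    """84 region labels: 34 Desikan cortical + 8 subcortical per hemisphere."""
    labels = []
    for hemi in ("L", "R"):
        labels += [f"{hemi}-{r}" for r in _DESIKAN_CORTICAL]
        labels += [f"{hemi}-{r}" for r in _SUBCORTICAL]
    return labels


def _default_affected() -> tuple[str, ...]:
    # the occipital / paracentral targets a glaucoma cohort is expected to hit
    return ("L-lateraloccipital", "L-pericalcarine", "R-lingual",
            "R-paracentral")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions the analysis is designed for:
    15 controls vs 23 patients, 84 regions, a ~30% multiplicative group
    effect on edges of 4 affected regions, a planted strength-disruption
    slope of 0.16, 20% coefficient-of-variation edge noise, and RNFL thinning
    of 8 um per SD of the designated region's strength.
    """

    n_controls: int = 15
    n_patients: int = 23
    n_regions: int = 84
    affected_regions: tuple[str, ...] = field(default_factory=_default_affected)
    edge_amplification: float = 1.3
    global_slope: float = 0.16
    subject_noise_cv: float = 0.2
    clinical_beta: float = -8.0   # um RNFL per SD of the designated metric
    clinical_noise_sd: float = 6.0
    seed: int = 0
    # base-connectome geometry
    distance_decay: float = 0.6   # edge-probability decay length (unit cube)
    weight_mu: float = 3.0        # log-scale mean of log-normal weights
    weight_sigma: float = 0.9     # log-scale sd of log-normal weights
    sparsity: float = 0.10        # density at which connectedness is required
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if self.edge_amplification <= 0:
            raise ValueError("edge_amplification must be > 0")
        if self.subject_noise_cv < 0:
            raise ValueError("subject_noise_cv must be >= 0")
        labels = self.region_labels()
        missing = set(self.affected_regions) - set(labels)
        if missing:
            raise ValueError(f"affected regions not in parcellation: {missing}")

    def region_labels(self) -> list[str]:
        if self.n_regions == 84:
            return desikan84_labels()
        return [f"region{i:03d}" for i in range(self.n_regions)]

    def affected_indices(self) -> np.ndarray:
        labels = self.region_labels()
        return np.array([labels.index(r) for r in self.affected_regions],
                        dtype=int)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "affected_regions" in data:
            data["affected_regions"] = tuple(data["affected_regions"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["affected_regions"] = list(data["affected_regions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _connected_at_sparsity(w: np.ndarray, sparsity: float,
                           labels: list[str]) -> bool:
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix
    tc = threshold_sparsity(Connectome("_base", w, labels), sparsity)
    n_comp, _ = connected_components(csr_matrix(tc.weights), directed=False)
    return n_comp == 1


def make_base_connectome(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> Connectome:
    """Deterministic (seeded) group-level base connectome.

    Regions are placed uniformly in the unit cube; edges appear with
    probability exp(-d / decay) and carry log-normal weights attenuated with
    distance, mimicking the short-range bias of streamline counts.  The
    matrix is regenerated (bounded retries) until the graph thresholded at
    ``config.sparsity`` is connected.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_regions
    labels = config.region_labels()
    for _ in range(config.max_retries):
        pos = rng.uniform(size=(n, 3))
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        prob = np.exp(-d / config.distance_decay)
        iu = np.triu_indices(n, k=1)
        mask = rng.uniform(size=len(iu[0])) < prob[iu]
        raw = rng.lognormal(config.weight_mu, config.weight_sigma,
                            size=len(iu[0]))
        vals = np.where(mask, raw * np.exp(-d[iu] / (2 * config.distance_decay)),
                        0.0)
        w = np.zeros((n, n))
        w[iu] = vals
        w += w.T
        density = np.count_nonzero(vals) / len(vals)
        if density >= max(0.2, 2 * config.sparsity) and \
                _connected_at_sparsity(w, config.sparsity, labels):
            return Connectome("base", w, labels)
    raise RuntimeError(
        f"could not generate a connected base connectome in "
        f"{config.max_retries} attempts")


def _scale_to_target_strength(w: np.ndarray, target: np.ndarray,
                              iters: int = 60, tol: float = 1e-10) -> np.ndarray:
    """Symmetric region-wise rescaling so row sums match ``target`` (IPF)."""
    out = w.copy()
    for _ in range(iters):
        cur = out.sum(axis=1)
        ratio = np.where(cur > 0, target / cur, 1.0)
        out *= np.sqrt(np.outer(ratio, ratio))
        if np.max(np.abs(out.sum(axis=1) - target) /
                  np.maximum(target, 1e-12)) < tol:
            break
    return out


def _patient_base(base: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Patient-group expected connectome: amplified affected-region edges plus
    a region-wise rescaling that plants the strength-disruption slope.

    Amplification multiplies every edge incident to an affected region.  The
    rescaling then tilts the expected strength profile so its OLS disruption
    slope against the control profile equals ``global_slope``, while keeping
    the amplification-driven deviations from the fitted line intact.
    """
    amp = config.edge_amplification
    s = config.global_slope
    if amp == 1.0 and s == 0.0:
        return base.copy()
    n = base.shape[0]
    affected = config.affected_indices()
    factor = np.ones(n)
    factor[affected] = amp
    w_amp = base * np.maximum.outer(factor, factor)
    m = base.sum(axis=1)
    m_amp = w_amp.sum(axis=1)
    xc = m - m.mean()
    y = m_amp - m
    s_amp = float((xc * (y - y.mean())).sum() / (xc ** 2).sum())
    target = m_amp + (s - s_amp) * m
    if np.any(target <= 0):
        raise ValueError("planted slope drives a region's strength negative; "
                         "reduce |global_slope|")
    return _scale_to_target_strength(w_amp, target)


def _symmetric_lognormal_noise(n: int, sigma: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative edge noise, symmetric, ones on the diagonal."""
    iu = np.triu_indices(n, k=1)
    e = np.ones((n, n))
    vals = rng.lognormal(-sigma ** 2 / 2, sigma, size=len(iu[0]))
    e[iu] = vals
    e.T[iu] = vals
    return e


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[list[Connectome], CohortTable]:
    """Simulate connectomes and the cohort table for one study replicate.

    Controls are the base connectome under subject-level multiplicative edge
    noise; patients additionally carry the amplified/tilted patient base.
    With ``edge_amplification == 1`` and ``global_slope == 0`` the two groups
    are exchangeable (null construction).  RNFL is linear in the designated
    region's nodal strength with slope ``clinical_beta`` per SD plus noise;
    VFI and GCL are correlated noisy transforms of RNFL.
    """
    rng = np.random.default_rng(config.seed)
    base = make_base_connectome(config, rng)
    labels = base.region_labels
    w_patient = _patient_base(base.weights, config)
    sigma = float(np.sqrt(np.log1p(config.subject_noise_cv ** 2)))
    n = config.n_regions

    connectomes: list[Connectome] = []
    rows = []
    designated = config.affected_indices()[0]
    for group, count, w_group in (("control", config.n_controls, base.weights),
                                  ("patient", config.n_patients, w_patient)):
        for i in range(count):
            sid = f"{'ctl' if group == 'control' else 'pat'}{i + 1:02d}"
            noise = _symmetric_lognormal_noise(n, sigma, rng) \
                if sigma > 0 else 1.0
            w = w_group * noise
            connectomes.append(Connectome(sid, w, labels))
            rows.append({"subject_id": sid, "group": group,
                         "age": float(np.round(rng.uniform(50, 76), 1)),
                         "sex": "M" if rng.uniform() < 0.5 else "F"})
    strengths = np.array([c.weights[designated].sum() for c in connectomes])
    z = (strengths - strengths.mean()) / strengths.std()
    rnfl = 85.0 + config.clinical_beta * z + \
        config.clinical_noise_sd * rng.normal(size=len(rows))
    vfi = np.clip(60.0 + 0.45 * (rnfl - 70.0) + 8.0 * rng.normal(size=len(rows)),
                  0.0, 100.0)
    gcl = 15.0 + 0.55 * rnfl + 3.0 * rng.normal(size=len(rows))
    iop = np.array([rng.normal(19, 4) if r["group"] == "patient"
                    else rng.normal(15, 2) for r in rows])
    table = pd.DataFrame(rows)
    table["VFI"] = np.round(vfi, 1)
    table["RNFL"] = np.round(rnfl, 1)
    table["GCL"] = np.round(gcl, 1)
    table["IOP"] = np.round(iop, 1)
    return connectomes, CohortTable(table, clinical_columns=["VFI", "RNFL",
                                                             "GCL", "IOP"])


def simulate_disruption_profiles(n_controls: int = 15, n_patients: int = 23,
                                 n_regions: int = 84, slope: float = 0.16,
                                 noise_sd: float = 0.5,
                                 control_noise_sd: float | None = None,
                                 rng: np.random.Generator | int | None = None
                                 ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Nodal-metric profiles with an exactly planted disruption slope.

    The control-mean profile is uniform on [1, 10]; control rows are the
    profile plus homoscedastic Gaussian noise (sd ``control_noise_sd``,
    defaulting to ``noise_sd``) and patient rows are (1 + slope) x profile
    plus noise of sd ``noise_sd``, so the expected subject-wise OLS slope of
    every patient equals ``slope``.  Used for calibration and
    parameter-recovery studies at the metric level, bypassing graph
    construction.  With ``control_noise_sd = 0`` the empirical control mean
    equals the population profile, which makes the group-wise slope test's
    nominal level exact; with noisy controls the shared control-mean noise
    enters both regression axes and biases the index slightly negative
    (regression to the mean), mirroring the behaviour of the index on real
    finite control samples.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if control_noise_sd is None:
        control_noise_sd = noise_sd
    profile = rng.uniform(1.0, 10.0, size=n_regions)
    controls = [f"ctl{i + 1:02d}" for i in range(n_controls)]
    patients = [f"pat{i + 1:02d}" for i in range(n_patients)]
    rows = np.empty((n_controls + n_patients, n_regions))
    rows[:n_controls] = profile + rng.normal(0, 1.0, (n_controls, n_regions)) \
        * control_noise_sd
    rows[n_controls:] = (1.0 + slope) * profile + \
        rng.normal(0, noise_sd, (n_patients, n_regions))
    df = pd.DataFrame(rows, index=controls + patients)
    return df, controls, patients


def write_dataset(config: SimulationConfig, outdir: str | Path,
                  fmt: str = "tsv") -> Path:
    """Simulate a cohort and write it in the formats ``connectome_io`` reads:
    one matrix per subject, ``labels.txt`` and ``cohort.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    connectomes, cohort = simulate_cohort(config)
    write_labels(connectomes[0].region_labels, outdir / "labels.txt")
    for c in connectomes:
        write_connectome(c, outdir / f"{c.subject_id}.{fmt}", format=fmt)
    write_cohort(cohort, outdir / "cohort.csv")
    config.to_yaml(outdir / "config.yaml")
    return outdir
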