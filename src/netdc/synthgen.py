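"""Synthetic two-group resting-state BOLD cohorts with planted hub effects.

The generator emulates the statistical structure that a voxel-wise
degree-centrality (DC) analysis assumes: every gray-matter voxel loads on a
small set of band-limited latent network signals, so voxels sharing a
network correlate while voxels in different networks do not.  A contiguous
"hub" region additionally loads on *every* network with coupling ``a``;
those voxels therefore correlate (weakly) with the whole gray matter and
their binarized degree is governed by how ``a`` places the hub-to-network
correlation relative to the DC threshold.  Patients receive an extra
additive coupling ``group_effect_delta``, raising hub DC in the patient
group — the recoverable ground truth for every downstream stage.

On top of the network signal each voxel carries white noise, a random
linear drift, and a shared set of nuisance series (stand-ins for motion /
CSF confounds) with random per-voxel weights; the nuisance series are
returned so the preprocessing stage can regress them back out.

Randomness: one root ``numpy.random.SeedSequence`` is spawned per subject
by counter, so a subject's data depend only on the cohort seed and the
subject's position, not on cohort size elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .errors import ConfigurationError
from .images import BoldSeries, default_affine

PATIENT, CONTROL = "patient", "control"


@dataclass
class LatentNetworkModel:
    """Latent-network signal model for one cohort.

    Parameters
    ----------
    n_networks:
        Number of independent band-limited latent signals; the gray matter is
        partitioned into that many contiguous regions, one network each.
    within_loading:
        Loading of a voxel on its own region's network (signal units).
    hub_coupling:
        Baseline additive loading of hub voxels on *all* networks.
    group_effect_delta:
        Additive increase of ``hub_coupling`` in the patient group; 0 gives
        an exchangeable null cohort.
    hub_gain_sd:
        SD of a per-subject random deviation of the hub coupling; creates
        between-subject hub-strength variation that clinical scores can be
        coupled to.
    noise_sd:
        White-noise SD per voxel (must be > 0).
    drift_slope_sd:
        SD of the per-voxel linear drift slope (signal units per scan).
    band:
        Passband (Hz) of the latent signals; defaults to the analysis band.
    n_nuisance:
        Number of shared nuisance series per subject.
    nuisance_weight_sd:
        SD of the random per-voxel nuisance weights.
    """

    n_networks: int = 5
    within_loading: float = 1.0
    hub_coupling: float = 0.15
    group_effect_delta: float = 0.0
    hub_gain_sd: float = 0.05
    noise_sd: float = 1.0
    drift_slope_sd: float = 0.02
    band: tuple[float, float] = (0.01, 0.08)
    n_nuisance: int = 3
    nuisance_weight_sd: float = 0.3

    def validate(self) -> None:
        if self.n_networks < 1:
            raise ConfigurationError(f"n_networks must be >= 1, got {self.n_networks}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not (0 <= self.band[0] < self.band[1]):
            raise ConfigurationError(f"band must satisfy 0 <= low < high, got {self.band}")
        if self.hub_gain_sd < 0 or self.drift_slope_sd < 0:
            raise ConfigurationError("hub_gain_sd and drift_slope_sd must be >= 0")


def strong_effect_model(**overrides) -> "LatentNetworkModel":
    """The documented *strong* planted-effect condition.

    ``delta = 1.6`` on a 0.15 baseline places the hub-to-network
    correlation of controls (~0.10) well below the DC threshold of 0.25
    and that of patients (~0.35) well above it, so hub degree separates
    the groups decisively — the regime recovery tests are run in.
    """
    params = dict(hub_coupling=0.15, group_effect_delta=1.6, hub_gain_sd=0.05)
    params.update(overrides)
    return LatentNetworkModel(**params)


def coupling_model(**overrides) -> "LatentNetworkModel":
    """Condition for clinical-correlation recovery.

    The hub coupling (0.5, with reduced noise) puts the hub-to-network
    correlation right at the DC threshold, where degree is most sensitive
    to the per-subject coupling deviation while staying on the monotone
    flank of the (saturating) degree response; ``hub_gain_sd = 0.25`` then
    drives recoverable between-subject DC variation that clinical scores
    can be coupled to via ``CovariateModel.moca_coupling`` /
    ``sledai_coupling``.
    """
    params = dict(hub_coupling=0.5, group_effect_delta=0.0, hub_gain_sd=0.25,
                  noise_sd=0.6)
    params.update(overrides)
    return LatentNetworkModel(**params)


#: Default clinical-score distributions: truncated normals with published-range
#: means/SDs per group, (mean_patient, mean_control, sd_patient, sd_control, lo, hi).
DEFAULT_SCORE_MODEL = {
    "age": (29.17, 27.02, 9.23, 5.25, 15.0, 50.0),
    "education": (12.32, 12.98, 2.62, 2.49, 0.0, 22.0),
    "SLEDAI": (13.23, float("nan"), 7.12, float("nan"), 0.0, 40.0),
    "MoCA": (26.72, 28.49, 1.25, 1.14, 0.0, 30.0),
    "BDI": (10.04, 6.40, 2.78, 2.10, 0.0, 63.0),
}


@dataclass
class CovariateModel:
    """Distributions for phenotype / clinical columns.

    ``male_fraction`` mirrors the roughly 1:4 male:female case mix the
    pipeline is calibrated against.  ``moca_coupling`` / ``sledai_coupling``
    add ``coupling * u_i`` score points to a subject whose hub-gain deviation
    is ``u_i`` (in SD units), so association recovery is testable; both
    default to 0 (no coupling).
    """

    male_fraction: float = 0.21
    score_model: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_MODEL))
    moca_coupling: float = 0.0
    sledai_coupling: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.male_fraction <= 1):
            raise ConfigurationError(
                f"male_fraction must lie in [0, 1], got {self.male_fraction}"
            )


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort (a pure function of its fields)."""

    n_per_group: int = 15
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_timepoints: int = 240
    tr: float = 2.0
    rng_seed: int = 0
    spacing_mm: float = 3.0
    model: LatentNetworkModel = field(default_factory=LatentNetworkModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.n_timepoints <= 10:
            raise ConfigurationError(
                f"n_timepoints must exceed 10 (volume dropping must leave data), got {self.n_timepoints}"
            )
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3D with sides >= 4, got {self.grid_shape}")
        if max(self.grid_shape) > 24:
            raise ConfigurationError(
                f"grid_shape sides must be <= 24 for desk-scale runs, got {self.grid_shape}"
            )
        if self.tr <= 0:
            raise ConfigurationError(f"tr must be > 0, got {self.tr}")
        nyquist = 0.5 / self.tr
        if self.model.band[1] > nyquist:
            raise ConfigurationError(
                f"model.band upper edge {self.model.band[1]} exceeds Nyquist {nyquist}"
            )
        self.model.validate()
        self.covariates.validate()


@dataclass
class Cohort:
    """Generated cohort bundle: images, phenotypes and ground truth."""

    series: list            # list[BoldSeries], patients first then controls
    nuisance: list          # list[np.ndarray], (T, n_nuisance) per subject
    table: pd.DataFrame     # one row per subject, same order as ``series``
    gray_mask: np.ndarray   # 3D bool
    hub_mask: np.ndarray    # 3D bool, subset of gray_mask
    affine: np.ndarray
    spec: CohortSpec


# ---------------------------------------------------------------------------
# geometry helpers

def default_gray_mask(grid_shape) -> np.ndarray:
    """Centered ellipsoid occupying roughly a third of the grid volume."""
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = 0.42 * shape
    ijk = np.indices(grid_shape, dtype=float)
    dist2 = sum(((ijk[d] - center[d]) / semi[d]) ** 2 for d in range(3))
    return dist2 <= 1.0


def default_hub_mask(grid_shape, gray_mask: np.ndarray, radius: float = 2.5) -> np.ndarray:
    """Small sphere offset from the mask centre; intersected with gray matter."""
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1) / 2.0 + 0.15 * shape  # off-centre so the hub is asymmetric
    center = np.minimum(center, shape - 1)
    ijk = np.indices(grid_shape, dtype=float)
    dist2 = sum((ijk[d] - center[d]) ** 2 for d in range(3))
    hub = (dist2 <= radius**2) & gray_mask
    if not hub.any():
        # tiny grids: fall back to a sphere at the gray-matter centroid
        centroid = np.array(np.nonzero(gray_mask)).mean(axis=1)
        dist2 = sum((ijk[d] - centroid[d]) ** 2 for d in range(3))
        hub = (dist2 <= radius**2) & gray_mask
    return hub


def partition_networks(gray_mask: np.ndarray, n_networks: int) -> np.ndarray:
    """Assign each in-mask voxel (C scan order) to one of ``n_networks`` slabs.

    Returns an int array of length n_voxels with labels 0..K-1; contiguous
    chunks of the scan order give spatially coherent slab-like regions.
    """
    n_vox = int(gray_mask.sum())
    return np.minimum((np.arange(n_vox) * n_networks) // n_vox, n_networks - 1)


# ---------------------------------------------------------------------------
# signal generation

def bandlimited_signals(rng: np.random.Generator, n: int, n_timepoints: int,
                        tr: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian signals band-passed to ``band`` (Hz).

    White noise is filtered with a zero-phase Butterworth (order 5) and each
    series rescaled to SD 1, so the analysis passband carries all the power.
    """
    white = rng.standard_normal((n, n_timepoints))
    fs = 1.0 / tr
    low, high = band
    if low <= 0:
        sos = sps.butter(5, high, btype="lowpass", output="sos", fs=fs)
    else:
        sos = sps.butter(5, [low, high], btype="bandpass", output="sos", fs=fs)
    out = sps.sosfiltfilt(sos, white, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _nuisance_series(rng: np.random.Generator, n_series: int, n_timepoints: int) -> np.ndarray:
    """Slow AR(1) confound series (T, n_series), SD 1."""
    eps = rng.standard_normal((n_timepoints, n_series))
    out = np.empty_like(eps)
    out[0] = eps[0]
    for t in range(1, n_timepoints):
        out[t] = 0.9 * out[t - 1] + np.sqrt(1 - 0.9**2) * eps[t]
    return out / out.std(axis=0, keepdims=True)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_clinical_scores(spec: CohortSpec, groups, hub_gains,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Sample phenotype/clinical columns for the given subjects.

    ``hub_gains`` are the per-subject hub-coupling deviations in SD units;
    when a coupling is configured the corresponding score receives
    ``coupling * u_i`` extra points (negative coupling gives lower scores to
    stronger-hub subjects), making correlation recovery testable.
    """
    cov = spec.covariates
    cov.validate()
    groups = np.asarray(groups)
    hub_gains = np.asarray(hub_gains, dtype=float)
    n = len(groups)
    is_patient = groups == PATIENT

    out = {}
    out["sex"] = np.where(rng.random(n) < cov.male_fraction, "M", "F")
    for name, (mp, mc, sp_, sc, lo, hi) in cov.score_model.items():
        vals = np.full(n, np.nan)
        if np.isfinite(mp) and is_patient.any():
            vals[is_patient] = _truncnorm(rng, mp, sp_, lo, hi, int(is_patient.sum()))
        if np.isfinite(mc) and (~is_patient).any():
            vals[~is_patient] = _truncnorm(rng, mc, sc, lo, hi, int((~is_patient).sum()))
        if name == "MoCA" and cov.moca_coupling != 0:
            vals = np.clip(vals + cov.moca_coupling * hub_gains, lo, hi)
        if name == "SLEDAI" and cov.sledai_coupling != 0:
            vals = np.clip(vals + cov.sledai_coupling * hub_gains, lo, hi)
        out[name] = vals
    return pd.DataFrame(out)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full two-group cohort; deterministic given ``spec``.

    Subjects are ordered patients first (``sub-P01`` ...) then controls
    (``sub-C01`` ...).  Returns the 4D series, per-subject nuisance series,
    the phenotype table, the gray-matter mask and the ground-truth hub mask.
    """
    spec.validate()
    model = spec.model
    shape = tuple(spec.grid_shape)
    gray = default_gray_mask(shape)
    hub = default_hub_mask(shape, gray)
    if not hub.any():
        raise ConfigurationError("hub_mask is empty for this grid_shape")
    if (hub & ~gray).any():
        raise ConfigurationError("hub_mask extends outside the gray-matter mask")

    affine = default_affine(spec.spacing_mm, shape)
    flat_idx = np.flatnonzero(gray.ravel())
    n_vox = flat_idx.size
    region = partition_networks(gray, model.n_networks)
    hub_in_mask = hub.ravel()[flat_idx]  # bool per in-mask voxel

    # base loading matrix (V, K): each voxel loads on its region's network
    loadings = np.zeros((n_vox, model.n_networks))
    loadings[np.arange(n_vox), region] = model.within_loading

    n_sub = 2 * spec.n_per_group
    groups = np.array([PATIENT] * spec.n_per_group + [CONTROL] * spec.n_per_group)
    subject_ids = [f"sub-P{i+1:02d}" for i in range(spec.n_per_group)] + \
                  [f"sub-C{i+1:02d}" for i in range(spec.n_per_group)]

    root = np.random.SeedSequence(spec.rng_seed)
    children = root.spawn(n_sub + 1)  # one stream per subject + one for phenotypes

    t_axis = np.arange(spec.n_timepoints, dtype=float)
    t_centered = t_axis - t_axis.mean()

    series_list, nuisance_list, hub_gains = [], [], np.zeros(n_sub)
    for i in range(n_sub):
        rng = np.random.default_rng(children[i])
        latents = bandlimited_signals(rng, model.n_networks, spec.n_timepoints,
                                      spec.tr, model.band)
        u_i = rng.standard_normal()
        hub_gains[i] = u_i
        a_i = model.hub_coupling + model.hub_gain_sd * u_i
        if groups[i] == PATIENT:
            a_i += model.group_effect_delta

        sub_loadings = loadings.copy()
        sub_loadings[hub_in_mask, :] += a_i

        x = sub_loadings @ latents                                    # (V, T)
        x += model.noise_sd * rng.standard_normal((n_vox, spec.n_timepoints))
        slopes = model.drift_slope_sd * rng.standard_normal(n_vox)
        x += slopes[:, None] * t_centered[None, :]
        nuis = _nuisance_series(rng, model.n_nuisance, spec.n_timepoints)  # (T, M)
        weights = model.nuisance_weight_sd * rng.standard_normal((n_vox, model.n_nuisance))
        x += weights @ nuis.T

        data = np.zeros(shape + (spec.n_timepoints,))
        data.reshape(-1, spec.n_timepoints)[flat_idx] = x
        series_list.append(BoldSeries(data=data, affine=affine, tr=spec.tr))
        nuisance_list.append(nuis)

    pheno_rng = np.random.default_rng(children[n_sub])
    scores = sample_clinical_scores(spec, groups, hub_gains, pheno_rng)
    table = pd.DataFrame({"subject_id": subject_ids, "group": groups})
    table = pd.concat([table, scores], axis=1)
    table["hub_gain"] = hub_gains   # ground-truth column for recovery tests
    table["include_flag"] = True

    return Cohort(series=series_list, nuisance=nuisance_list, table=table,
                  gray_mask=gray, hub_mask=hub, affine=affine, spec=spec)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a cohort to disk (NIfTI volumes, TSV phenotypes, JSON sidecar)."""
    import dataclasses
    import json
    from pathlib import Path

    from . import io as ndio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths, nuisance_paths = [], []
    for sid, series, nuis in zip(cohort.table["subject_id"], cohort.series, cohort.nuisance):
        p = out / f"{sid}_bold.nii.gz"
        ndio.write_volume(p, series.data, series.affine)
        np.savetxt(out / f"{sid}_nuisance.txt", nuis, fmt="%.8g")
        # stored relative to the phenotype table so the cohort is relocatable
        paths.append(p.name)
        nuisance_paths.append(f"{sid}_nuisance.txt")
    ndio.write_volume(out / "gray_mask.nii.gz", cohort.gray_mask.astype(float), cohort.affine)
    ndio.write_volume(out / "hub_truth.nii.gz", cohort.hub_mask.astype(float), cohort.affine)
    table = cohort.table.copy()
    table["image_path"] = paths
    table["nuisance_path"] = nuisance_paths
    ndio.write_phenotype_table(out / "phenotype.tsv", table)

    spec_dict = dataclasses.asdict(cohort.spec)
    (out / "cohort_spec.json").write_text(json.dumps(spec_dict, indent=2, default=str) + "\n")
    return {
        "phenotype": str(out / "phenotype.tsv"),
        "gray_mask": str(out / "gray_mask.nii.gz"),
        "hub_truth": str(out / "hub_truth.nii.gz"),
        "spec": str(out / "cohort_spec.json"),
    }
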