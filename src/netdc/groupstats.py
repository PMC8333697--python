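"""Voxel-wise group inference with cluster-level FDR, plus demographics
summary tests.

The voxel-wise model is an ordinary least-squares GLM per voxel with an
intercept, a patient/control indicator (+1 patient, 0 control) and
covariates (age, sex, education by default); the reported statistic is
the t of the group coefficient with df = n - rank(design).

Cluster-level FDR is realized as a permutation procedure: supra-threshold
voxels (two-sided p < voxel_p, split by the sign of t) are grouped into
connected components (default 26-neighborhood); each observed cluster's
uncorrected p is the add-one proportion of group-label permutations whose
maximum same-sign cluster extent reaches the observed extent; Benjamini-
Hochberg is then applied across observed clusters at level q.  Only the
group labels are permuted — covariates stay attached to their subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .images import VolumeMap, world_coordinates

SEX_TO_COVARIATE = {"F": 0.0, "M": 1.0}  # documented coding: F=0, M=1
DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclass
class DesignMatrix:
    """Subjects-by-predictors design for the voxel-wise GLM.

    Column 0 is the intercept, column 1 the group indicator; remaining
    columns are covariates.  Row order matches the map list.
    """

    matrix: np.ndarray
    columns: list
    group_col: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise InputError("design matrix must be 2D")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            bad = _dependent_columns(self.matrix, self.columns)
            raise InputError(f"design matrix is rank deficient; collinear columns: {bad}")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


def _dependent_columns(matrix: np.ndarray, names) -> list:
    from scipy.linalg import qr

    _, r, piv = qr(matrix, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol] or list(names)


def make_design(table: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> DesignMatrix:
    """Build the default design from a phenotype table.

    Group is coded +1 for patients, 0 for controls; sex is converted with
    the documented F=0 / M=1 coding.
    """
    group = np.asarray(table["group"])
    indicator = np.where(group == "patient", 1.0, 0.0)
    if indicator.sum() < 2 or (1 - indicator).sum() < 2:
        raise InputError("need at least 2 subjects per group")
    cols = [np.ones(len(table)), indicator]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov == "sex":
            vals = np.array([SEX_TO_COVARIATE[s] for s in table["sex"]])
        else:
            vals = np.asarray(table[cov], dtype=np.float64)
            if np.isnan(vals).any():
                raise InputError(f"covariate '{cov}' has missing values")
        if np.ptp(vals) == 0:
            # constant covariate (e.g. a single-sex small cohort) is absorbed
            # by the intercept; keeping it would make the design singular
            logging.getLogger("netdc").warning(
                "covariate '%s' is constant; dropped from the design", cov)
            continue
        cols.append(vals)
        names.append(cov)
    return DesignMatrix(matrix=np.column_stack(cols), columns=names)


# ---------------------------------------------------------------------------
# voxel-wise GLM

def _stack_maps(maps) -> tuple[np.ndarray, np.ndarray, VolumeMap]:
    """Stack subject maps to (n, V) over the common finite-value mask."""
    first = maps[0]
    for m in maps[1:]:
        if m.grid_shape != first.grid_shape or not np.allclose(m.affine, first.affine):
            raise InputError("subject maps do not share a grid")
    stack = np.stack([m.data for m in maps])          # (n, x, y, z)
    mask = np.all(np.isfinite(stack), axis=0)
    y = stack[:, mask]
    return y, mask, first


def _glm_t(y: np.ndarray, x: np.ndarray, group_col: int) -> tuple[np.ndarray, int]:
    """Vectorized OLS t-statistics of one coefficient over V voxels.

    y: (n, V), x: (n, p) full rank.  Returns (t of shape (V,), df).
    """
    n, p = x.shape
    df = n - p
    if df <= 0:
        raise InputError(f"non-positive degrees of freedom: n={n}, p={p}")
    pinv = np.linalg.pinv(x)
    beta = pinv @ y                                   # (p, V)
    resid = y - x @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    gg = np.linalg.inv(x.T @ x)[group_col, group_col]
    sigma2 = rss / df
    se = np.sqrt(sigma2 * gg)
    # numerically zero residuals (e.g., identical maps in both groups) mean
    # an undefined t; report 0 rather than round-off noise
    zero_resid = rss <= 1e-12 * np.einsum("ij,ij->j", y, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((se > 0) & ~zero_resid, beta[group_col] / se, 0.0)
    return t, df


def voxelwise_glm_ttest(maps, design: DesignMatrix) -> tuple[VolumeMap, int]:
    """Covariate-adjusted two-sample t-map (group coefficient t per voxel)."""
    y, mask, first = _stack_maps(maps)
    if design.n_subjects != len(maps):
        raise InputError(
            f"design has {design.n_subjects} rows but {len(maps)} maps were given"
        )
    t, df = _glm_t(y, design.matrix, design.group_col)
    out = np.full(first.grid_shape, np.nan)
    out[mask] = t
    return VolumeMap(data=out, affine=first.affine.copy(), kind="t_stat"), df


# ---------------------------------------------------------------------------
# clusters

def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise InputError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def t_critical(voxel_p: float, df: int) -> float:
    """Two-sided |t| threshold matching a voxel-level p."""
    if not (0 < voxel_p < 1):
        raise InputError(f"voxel_p must lie in (0, 1), got {voxel_p}")
    if df <= 0:
        raise InputError(f"df must be positive, got {df}")
    return float(stats.t.isf(voxel_p / 2.0, df))


def _label_signed(t_data: np.ndarray, t_crit: float, structure: np.ndarray):
    """Connected components of supra-threshold voxels, split by sign.

    Yields (sign, labeled_array, n_components) for sign in (+1, -1).
    """
    finite = np.nan_to_num(t_data, nan=0.0)
    for sign in (1, -1):
        supra = (sign * finite) > t_crit
        labeled, n = ndimage.label(supra, structure=structure)
        yield sign, labeled, n


def form_clusters(t_map: VolumeMap, df: int, voxel_p: float = 0.001,
                  connectivity: int = 26):
    """Label supra-threshold clusters deterministically.

    Returns ``(labels, clusters)``: a 3D int array (0 = background) and a
    list of dicts with id, sign, extent and min linear voxel index.
    Labels are assigned in descending extent order, ties broken by the
    smallest linear voxel index.
    """
    structure = _structure(connectivity)
    t_crit = t_critical(voxel_p, df)
    raw = []
    for sign, labeled, n in _label_signed(t_map.data, t_crit, structure):
        for comp in range(1, n + 1):
            where = labeled == comp
            flat = np.flatnonzero(where.ravel())
            raw.append({"sign": sign, "extent": int(flat.size),
                        "min_index": int(flat[0]), "voxels": where})
    raw.sort(key=lambda c: (-c["extent"], c["min_index"]))
    labels = np.zeros(t_map.grid_shape, dtype=np.int32)
    clusters = []
    for cid, c in enumerate(raw, start=1):
        labels[c["voxels"]] = cid
        clusters.append({"id": cid, "sign": c["sign"], "extent": c["extent"],
                         "min_index": c["min_index"]})
    return labels, clusters


def _max_extent_by_sign(t_data: np.ndarray, t_crit: float, structure: np.ndarray) -> dict:
    out = {}
    for sign, labeled, n in _label_signed(t_data, t_crit, structure):
        if n == 0:
            out[sign] = 0
        else:
            counts = np.bincount(labeled.ravel())[1:]
            out[sign] = int(counts.max())
    return out


@dataclass
class ClusterReport:
    """Supra-threshold clusters with permutation/BH cluster-level inference."""

    clusters: list = field(default_factory=list)
    forming_threshold: float = 0.001
    connectivity: int = 26
    df: int = 0
    n_permutations: int = 0
    q: float = 0.05

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.get("significant")]

    def to_frame(self) -> pd.DataFrame:
        cols = ["id", "sign", "extent", "peak_t", "peak_x_mm", "peak_y_mm",
                "peak_z_mm", "p_uncorrected", "p_fdr", "significant"]
        if not self.clusters:
            return pd.DataFrame(columns=cols)
        rows = []
        for c in self.clusters:
            px, py, pz = c["peak_world"]
            rows.append([c["id"], c["sign"], c["extent"], c["peak_t"], px, py, pz,
                         c["p_uncorrected"], c["p_fdr"], c["significant"]])
        return pd.DataFrame(rows, columns=cols)


def peak_world_coordinates(labels: np.ndarray, t_map: VolumeMap, affine: np.ndarray) -> dict:
    """Per-cluster peak |t| voxel mapped to world mm.

    Ties resolve to the smallest linear voxel index.  Returns
    ``{cluster_id: (peak_t, (x, y, z) mm, voxel_index)}``.
    """
    out = {}
    abs_t = np.abs(np.nan_to_num(t_map.data, nan=0.0)).ravel()
    t_flat = t_map.data.ravel()
    lab_flat = labels.ravel()
    for cid in np.unique(labels[labels > 0]):
        flat = np.flatnonzero(lab_flat == cid)
        peak_flat = flat[np.argmax(abs_t[flat])]  # argmax returns first max: tie rule
        ijk = np.unravel_index(peak_flat, labels.shape)
        world = world_coordinates(affine, ijk)
        out[int(cid)] = (float(t_flat[peak_flat]), tuple(np.asarray(world, dtype=float)),
                         tuple(int(v) for v in ijk))
    return out


def cluster_fdr(maps, design: DesignMatrix, *, voxel_p: float = 0.001,
                q: float = 0.05, connectivity: int = 26,
                n_permutations: int = 1000, rng=None,
                scheme: str = "labels") -> tuple[VolumeMap, np.ndarray, ClusterReport]:
    """Voxel-wise GLM + cluster formation + permutation cluster-level FDR.

    Returns ``(t_map, labels, report)``.  Each observed cluster's
    uncorrected p is (b + 1)/(B + 1) where b counts permutations whose
    maximum same-sign cluster extent >= the observed extent; BH-adjusted
    p-values are compared against ``q``.

    ``scheme='labels'`` (default) permutes the group indicator, keeping
    covariates attached to subjects; ``scheme='freedman_lane'`` permutes
    the residuals of the reduced (covariates-only) model instead — a
    non-default option that respects covariate structure under the null.
    """
    if scheme not in ("labels", "freedman_lane"):
        raise InputError(f"unknown permutation scheme '{scheme}'")
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1 (0 makes inference impossible)")
    rng = np.random.default_rng(rng)
    y, mask, first = _stack_maps(maps)
    x = design.matrix
    t_vals, df = _glm_t(y, x, design.group_col)
    t_data = np.full(first.grid_shape, np.nan)
    t_data[mask] = t_vals
    t_map = VolumeMap(data=t_data, affine=first.affine.copy(), kind="t_stat")

    labels, clusters = form_clusters(t_map, df, voxel_p, connectivity)
    report = ClusterReport(forming_threshold=voxel_p, connectivity=connectivity,
                           df=df, n_permutations=n_permutations, q=q)
    if not clusters:
        return t_map, labels, report

    structure = _structure(connectivity)
    t_crit = t_critical(voxel_p, df)
    group_vals = x[:, design.group_col].copy()
    if scheme == "freedman_lane":
        reduced = np.delete(x, design.group_col, axis=1)
        gamma = np.linalg.pinv(reduced) @ y
        fitted_reduced = reduced @ gamma
        resid_reduced = y - fitted_reduced
    exceed = {c["id"]: 0 for c in clusters}
    tmp = np.zeros(first.grid_shape)
    for _ in range(n_permutations):
        if scheme == "labels":
            xp = x.copy()
            xp[:, design.group_col] = rng.permutation(group_vals)
            tp, _df = _glm_t(y, xp, design.group_col)
        else:
            perm = rng.permutation(x.shape[0])
            y_star = fitted_reduced + resid_reduced[perm]
            tp, _df = _glm_t(y_star, x, design.group_col)
        tmp[mask] = tp
        max_ext = _max_extent_by_sign(np.where(mask, tmp, 0.0), t_crit, structure)
        for c in clusters:
            if max_ext[c["sign"]] >= c["extent"]:
                exceed[c["id"]] += 1

    p_unc = np.array([(exceed[c["id"]] + 1) / (n_permutations + 1) for c in clusters])
    _, p_fdr, _, _ = multipletests(p_unc, method="fdr_bh")
    peaks = peak_world_coordinates(labels, t_map, first.affine)
    for c, pu, pf in zip(clusters, p_unc, p_fdr):
        peak_t, world, ijk = peaks[c["id"]]
        c.update(peak_t=peak_t, peak_world=world, peak_voxel=ijk,
                 p_uncorrected=float(pu), p_fdr=float(pf),
                 significant=bool(pf < q))
    report.clusters = clusters
    return t_map, labels, report


# ---------------------------------------------------------------------------
# demographics / summary-statistic tests

def two_sample_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sample t from (mean, sd, n) summaries.

    Returns ``(t, two_sided_p, df)`` with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0, df
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def chi_square_counts(table_2x2, correction: bool = True):
    """2x2 chi-square with Yates continuity correction (the sex test)."""
    table_2x2 = np.asarray(table_2x2, dtype=float)
    if table_2x2.shape != (2, 2):
        raise InputError(f"expected a 2x2 table, got shape {table_2x2.shape}")
    chi2, p, _, _ = stats.chi2_contingency(table_2x2, correction=correction)
    return float(chi2), float(p)


def ks_normality(values) -> tuple[float, bool]:
    """Kolmogorov-Smirnov check against a fitted normal; True = looks normal."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3 or values.std() == 0:
        return 1.0, True
    _, p = stats.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
    return float(p), bool(p > 0.05)


def summary_stat_tests(table: pd.DataFrame,
                       continuous=("age", "education", "MoCA", "BDI")) -> pd.DataFrame:
    """Group-comparison report for the phenotype table.

    Pooled-variance two-sample t for continuous variables (computed from
    the raw columns via their summaries, so the same code path serves
    printed mean/sd/n tables), Yates-corrected chi-square for sex, and a
    KS normality flag per continuous variable.
    """
    groups = np.asarray(table["group"])
    pat = table[groups == "patient"]
    ctl = table[groups == "control"]
    if len(pat) < 2 or len(ctl) < 2:
        raise InputError("each group needs n >= 2")
    rows = []
    for var in continuous:
        a = np.asarray(pat[var], dtype=float)
        b = np.asarray(ctl[var], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        t, p, df = two_sample_t_from_summary(a.mean(), a.std(ddof=1), len(a),
                                             b.mean(), b.std(ddof=1), len(b))
        _, normal = ks_normality(np.concatenate([a - a.mean(), b - b.mean()]))
        rows.append({"variable": var, "test": "two_sample_t", "statistic": t,
                     "p": p, "df": df, "normal": normal})
    sex_tab = np.array([
        [(pat["sex"] == "M").sum(), (pat["sex"] == "F").sum()],
        [(ctl["sex"] == "M").sum(), (ctl["sex"] == "F").sum()],
    ])
    chi2, p = chi_square_counts(sex_tab)
    rows.append({"variable": "sex", "test": "chi_square_yates", "statistic": chi2,
                 "p": p, "df": 1, "normal": None})
    return pd.DataFrame(rows)
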