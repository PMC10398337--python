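"""Voxelwise group GLM with cluster-level multiple-comparison correction.

Two correction routes are provided: the Gaussian-random-field (GRF) route
based on estimated map smoothness and the expected-cluster formulae for
excursion sets of smooth Gaussian fields, and a label-permutation route that
serves as its distribution-free oracle.  Positive and negative excursions are
corrected separately (each tail thresholded at voxel_p / 2 when two-tailed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

__all__ = [
    "GroupGlmResult",
    "fit_voxelwise_glm",
    "one_sample_tmap",
    "estimate_smoothness",
    "t_to_z",
    "grf_cluster_correct",
    "permutation_cluster_correct",
    "extract_cluster_table",
    "connectivity_structure",
]

CLUSTER_TABLE_COLUMNS = [
    "cluster_id",
    "n_voxels",
    "peak_stat",
    "peak_x",
    "peak_y",
    "peak_z",
    "sign",
    "p_corrected",
    "label",
]


@dataclass
class GroupGlmResult:
    """Per-voxel group-contrast t statistics from an OLS fit."""

    t_map: np.ndarray  # flat, one entry per in-mask voxel
    df: int
    design_columns: list[str]
    contrast: str
    residuals: np.ndarray  # (n_subjects, V), for smoothness estimation
    design: np.ndarray


def _empty_cluster_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CLUSTER_TABLE_COLUMNS)


def build_design(covariates: pd.DataFrame, patient_label: str = "patient") -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, group, age (centered), sex] from a covariate table.

    The group column codes patient = 1, control = 0, so the contrast is
    patient minus control.
    """
    levels = sorted(covariates["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, found {levels}")
    if patient_label not in levels:
        patient_label = levels[0]
    group = (covariates["group"] == patient_label).to_numpy(dtype=np.float64)
    cols = [np.ones(len(covariates)), group]
    names = ["intercept", "group"]
    for name in ("age", "sex"):
        if name in covariates.columns:
            v = covariates[name].to_numpy(dtype=np.float64)
            if name == "age":
                v = v - v.mean()
            cols.append(v)
            names.append(name)
    return np.column_stack(cols), names


def _check_design(design: np.ndarray, names: list[str]) -> None:
    for j, name in enumerate(names):
        if j > 0 and np.ptp(design[:, j]) == 0:
            raise ValueError(f"design column '{name}' is constant")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the first column that is collinear with its predecessors
        for j in range(1, design.shape[1] + 1):
            if np.linalg.matrix_rank(design[:, :j]) < j:
                raise ValueError(f"design is rank deficient at column '{names[j - 1]}'")
        raise ValueError("design is rank deficient")


def _glm_tmap(maps: np.ndarray, design: np.ndarray, contrast_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS over voxels; returns (t values, residual maps)."""
    n, p = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ maps  # (p, V)
    residuals = maps - design @ beta
    df = n - p
    sigma2 = (residuals**2).sum(axis=0) / df
    c = np.zeros(p)
    c[contrast_index] = 1.0
    var_scale = float(c @ xtx_inv @ c)
    se = np.sqrt(sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (c @ beta) / se, 0.0)
    return t, residuals


def fit_voxelwise_glm(
    maps: np.ndarray,
    covariates: pd.DataFrame,
    design: np.ndarray | None = None,
    design_names: list[str] | None = None,
) -> GroupGlmResult:
    """Two-group GLM per voxel with optional age/sex covariates.

    Parameters
    ----------
    maps : ndarray, shape (n_subjects, V)
        One standardized (or raw) map per subject, flattened over in-mask voxels.
    covariates : DataFrame
        Must contain ``group``; ``age`` and ``sex`` are used when present.
    """
    maps = np.asarray(maps, dtype=np.float64)
    if design is None:
        design, design_names = build_design(covariates)
    assert design_names is not None
    if maps.shape[0] != design.shape[0]:
        raise ValueError("number of maps does not match number of covariate rows")
    counts = covariates["group"].value_counts()
    if counts.min() < 3:
        raise ValueError(f"need >= 3 subjects per group, got {counts.to_dict()}")
    _check_design(design, design_names)
    df = maps.shape[0] - design.shape[1]
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    t, residuals = _glm_tmap(maps, design, contrast_index=design_names.index("group"))
    return GroupGlmResult(
        t_map=t,
        df=df,
        design_columns=design_names,
        contrast="patient - control",
        residuals=residuals,
        design=design,
    )


def one_sample_tmap(maps: np.ndarray, cap: float = 50.0) -> tuple[np.ndarray, int]:
    """Per-voxel one-sample t (mean / SE) with df = n - 1.

    Zero-variance voxels cannot yield a finite t: a zero-mean zero-variance
    voxel returns 0, a nonzero-mean one returns +/- ``cap``.
    """
    maps = np.asarray(maps, dtype=np.float64)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a one-sample t-test")
    mean = maps.mean(axis=0)
    se = maps.std(axis=0, ddof=1) / np.sqrt(n)
    t = np.zeros_like(mean)
    ok = se > 0
    t[ok] = mean[ok] / se[ok]
    t[~ok & (mean != 0)] = np.sign(mean[~ok & (mean != 0)]) * cap
    return t, n - 1


def estimate_smoothness(
    residual_maps: np.ndarray, mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Per-axis FWHM (mm) of the residual spatial autocorrelation.

    Uses the classic normalized-neighbour-difference estimator: for unit-
    variance residual fields, FWHM_i = d_i * sqrt(-2 ln 2 / ln(1 - v_i / 2))
    where v_i is the variance of the first difference along axis i.
    """
    residual_maps = np.asarray(residual_maps, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if residual_maps.ndim != 4:
        raise ValueError("residual_maps must be (n_maps, x, y, z)")
    if residual_maps.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    if not mask.any():
        raise ValueError("mask is empty")
    sd = residual_maps.std(axis=0, ddof=1)
    if np.all(sd[mask] == 0):
        raise ValueError("residuals are flat; smoothness undefined")
    norm = np.zeros_like(residual_maps)
    ok = sd > 0
    norm[:, ok] = residual_maps[:, ok] / sd[ok]

    fwhm = np.empty(3)
    for axis in range(3):
        d = np.diff(norm, axis=axis + 1)
        pair = mask & np.roll(mask, -1, axis=axis)
        pair = np.take(pair, range(d.shape[axis + 1]), axis=axis)
        vals = np.moveaxis(d, axis + 1, 1)[:, np.moveaxis(pair, axis, 0)]
        v = vals.var(ddof=1)
        v = min(v, 1.9999)  # keep the log argument positive
        if v <= 0:
            fwhm[axis] = np.inf
            continue
        arg = 1.0 - v / 2.0
        fwhm[axis] = voxel_size[axis] * np.sqrt(-2.0 * np.log(2.0) / np.log(arg))
    return fwhm


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Convert t to z by matching tail probabilities (sign-preserving)."""
    t = np.asarray(t, dtype=np.float64)
    p_tail = stats.t.sf(np.abs(t), df)
    p_tail = np.clip(p_tail, 1e-300, 1.0)
    return np.sign(t) * stats.norm.isf(p_tail)


def connectivity_structure(connectivity: int = 26) -> np.ndarray:
    """3D binary structuring element for 6-, 18- or 26-neighbour labeling."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _expected_ec_3d(u: float, resels: float) -> float:
    """Expected number of suprathreshold clusters of a unit Gaussian field."""
    return (
        resels
        * (4.0 * np.log(2.0)) ** 1.5
        * (2.0 * np.pi) ** -2
        * (u**2 - 1.0)
        * np.exp(-(u**2) / 2.0)
    )


def grf_cluster_p(
    cluster_size_voxels: int, u: float, n_mask_voxels: int, resels_per_voxel: float
) -> float:
    """Corrected cluster-level p for an excursion above z = u.

    Standard random-field approximation: the number of clusters is Poisson
    with mean E[m]; cluster extent has the exponential tail
    P(N >= k) = exp(-beta k^(2/3)).  Corrected p = 1 - exp(-E[m] P(N >= k)).
    """
    resels = n_mask_voxels * resels_per_voxel
    e_m = max(_expected_ec_3d(u, resels), 1e-300)
    expected_voxels = n_mask_voxels * stats.norm.sf(u)
    e_n = max(expected_voxels / e_m, 1e-300)  # expected voxels per cluster
    beta = (special.gamma(2.5) / e_n) ** (2.0 / 3.0)
    p_tail = np.exp(-beta * cluster_size_voxels ** (2.0 / 3.0))
    return float(-np.expm1(-e_m * p_tail))


def _threshold_label(
    z_map: np.ndarray, u: float, structure: np.ndarray
) -> list[tuple[np.ndarray, int]]:
    """Connected components of {z > u}; returns (component mask, size) pairs."""
    excursion = z_map > u
    labeled, n = ndimage.label(excursion, structure=structure)
    comps = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        comps.append((comp, int(comp.sum())))
    return comps


def extract_cluster_table(
    cluster_masks: list[tuple[np.ndarray, str, float]],
    stat_map: np.ndarray,
    affine: np.ndarray,
    atlas: np.ndarray | None = None,
    atlas_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Build the cluster-report table from component masks.

    Parameters
    ----------
    cluster_masks : list of (3D bool mask, sign, corrected p)
    stat_map : 3D statistic map (peaks located by max |stat| inside each mask)
    affine : voxel-to-world transform for peak coordinates in mm
    """
    rows = []
    for cid, (comp, sign, p_corr) in enumerate(cluster_masks, start=1):
        idx = np.argwhere(comp)
        vals = stat_map[comp]
        peak_local = idx[np.argmax(np.abs(vals))]
        peak_world = affine @ np.append(peak_local, 1.0)
        label = ""
        if atlas is not None:
            code = int(atlas[tuple(peak_local)])
            label = atlas_names.get(code, str(code)) if atlas_names else str(code)
        rows.append(
            {
                "cluster_id": cid,
                "n_voxels": int(comp.sum()),
                "peak_stat": float(stat_map[tuple(peak_local)]),
                "peak_x": float(peak_world[0]),
                "peak_y": float(peak_world[1]),
                "peak_z": float(peak_world[2]),
                "sign": sign,
                "p_corrected": float(p_corr),
                "label": label,
            }
        )
    if not rows:
        return _empty_cluster_table()
    return pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)


def grf_cluster_correct(
    result: GroupGlmResult,
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_size: tuple[float, float, float],
    fwhm_mm: np.ndarray | None = None,
    voxel_p: float = 0.05,
    cluster_p: float = 0.05,
    two_tailed: bool = True,
    connectivity: int = 26,
    atlas: np.ndarray | None = None,
    atlas_names: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """GRF cluster-level correction of a group t map.

    Returns the surviving-cluster table and an integer-labeled cluster mask
    (positive clusters first, in table order).
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must lie in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if fwhm_mm is None:
        res4d = np.zeros((result.residuals.shape[0],) + mask.shape)
        res4d[:, mask] = result.residuals
        fwhm_mm = estimate_smoothness(res4d, mask, voxel_size)
    fwhm_mm = np.asarray(fwhm_mm, dtype=np.float64)
    vs = np.asarray(voxel_size, dtype=np.float64)
    if np.any(fwhm_mm < vs):
        # RFT breaks down below voxel scale; fall back to voxel-sized resels
        fwhm_mm = np.maximum(fwhm_mm, vs)
    resels_per_voxel = float(np.prod(vs / fwhm_mm))

    z_flat = t_to_z(result.t_map, result.df)
    z_map = np.zeros(mask.shape)
    z_map[mask] = z_flat
    stat_map = np.zeros(mask.shape)
    stat_map[mask] = result.t_map

    u = float(stats.norm.isf(voxel_p / 2.0 if two_tailed else voxel_p))
    structure = connectivity_structure(connectivity)
    n_mask = int(mask.sum())

    surviving: list[tuple[np.ndarray, str, float]] = []
    signs = [("+", z_map), ("-", -z_map)] if two_tailed else [("+", z_map)]
    for sign, field in signs:
        for comp, size in _threshold_label(np.where(mask, field, -np.inf), u, structure):
            p_corr = grf_cluster_p(size, u, n_mask, resels_per_voxel)
            if p_corr < cluster_p:
                surviving.append((comp, sign, p_corr))
    surviving.sort(key=lambda item: (-item[0].sum(), item[1]))
    table = extract_cluster_table(surviving, stat_map, affine, atlas, atlas_names)
    labels = np.zeros(mask.shape, dtype=np.int32)
    for cid, (comp, _, _) in enumerate(surviving, start=1):
        labels[comp] = cid
    return table, labels


def permutation_cluster_correct(
    maps: np.ndarray,
    covariates: pd.DataFrame,
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_p: float = 0.05,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    two_tailed: bool = True,
    connectivity: int = 26,
    atlas: np.ndarray | None = None,
    atlas_names: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster correction by permuting group labels (covariates held fixed).

    The null distribution of the maximum suprathreshold cluster size (pooled
    over both tails when two-tailed) calibrates the cluster-size threshold at
    the 1 - cluster_p quantile.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null distribution")
    maps = np.asarray(maps, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    design, names = build_design(covariates)
    _check_design(design, names)
    counts = covariates["group"].value_counts()
    if counts.min() < 2:
        raise ValueError("need >= 2 subjects per group to permute")
    n = maps.shape[0]
    n_distinct = special.comb(n, int(counts.min()), exact=True)
    if n_perm > n_distinct:
        import warnings

        warnings.warn(
            f"n_perm={n_perm} exceeds the {n_distinct} distinct label assignments; capping",
            stacklevel=2,
        )
        n_perm = int(n_distinct)

    gidx = names.index("group")
    df = n - design.shape[1]
    u = float(stats.norm.isf(voxel_p / 2.0 if two_tailed else voxel_p))
    structure = connectivity_structure(connectivity)

    def max_cluster_size(t_flat: np.ndarray) -> tuple[int, list[tuple[np.ndarray, str, int]]]:
        z_flat = t_to_z(t_flat, df)
        z_map = np.full(mask.shape, -np.inf)
        z_map[mask] = z_flat
        comps = []
        for sign, field in ([("+", z_map), ("-", np.where(mask, -z_map, -np.inf))] if two_tailed else [("+", z_map)]):
            for comp, size in _threshold_label(field, u, structure):
                comps.append((comp, sign, size))
        biggest = max((size for _, _, size in comps), default=0)
        return biggest, comps

    t_obs, _ = _glm_tmap(maps, design, gidx)
    _, observed_comps = max_cluster_size(t_obs)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    group_col = design[:, gidx].copy()
    for b in range(n_perm):
        perm = rng.permutation(n)
        design_b = design.copy()
        design_b[:, gidx] = group_col[perm]
        t_b, _ = _glm_tmap(maps, design_b, gidx)
        null_max[b], _ = max_cluster_size(t_b)

    # smallest size whose exceedance probability under the null is < cluster_p
    threshold = np.quantile(null_max, 1.0 - cluster_p, method="higher")
    surviving = []
    for comp, sign, size in observed_comps:
        if size > threshold:
            p_corr = (1 + np.sum(null_max >= size)) / (n_perm + 1)
            surviving.append((comp, sign, float(p_corr)))
    surviving.sort(key=lambda item: (-item[0].sum(), item[1]))

    stat_map = np.zeros(mask.shape)
    stat_map[mask] = t_obs
    table = extract_cluster_table(surviving, stat_map, affine, atlas, atlas_names)
    labels = np.zeros(mask.shape, dtype=np.int32)
    for cid, (comp, _, _) in enumerate(surviving, start=1):
        labels[comp] = cid
    return table, labels
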