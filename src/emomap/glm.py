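"""First- and second-level GLM inference for block-design BOLD runs.

First level: proportional global scaling, optional Gaussian smoothing,
ordinary-least-squares fit of boxcar-convolved-HRF regressors plus a
discrete-cosine high-pass drift basis (128 s cutoff by default), and contrast
t-maps.  Second level: one-sample t across subjects' contrast images with
voxelwise p thresholding and cluster-extent familywise-error control by a
sign-flipping max-cluster-size permutation scheme (exact under the symmetric
null, unlike parametric random-field corrections, and fully reproducible
given a seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .hrf import DEFAULT_HRF, HRF_MODELS, condition_regressor
from .synthetic_data import DesignSpec
from .types import StatMap


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list[str]
    hrf_id: str
    highpass_s: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def n_dct_columns(run_duration_s: float, highpass_s: float) -> int:
    """Number of cosine drift columns for a high-pass cutoff: floor(2T / cutoff)."""
    return int(np.floor(2.0 * run_duration_s / highpass_s))


def dct_basis(n_volumes: int, n_columns: int) -> np.ndarray:
    """Unit-norm discrete-cosine drift regressors (k = 1 .. n_columns)."""
    i = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * i + 1) / (2 * n_volumes))
        for k in range(1, n_columns + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def build_design(design: DesignSpec, hrf_id: str = "double_gamma", highpass_s: float = 128.0) -> DesignMatrix:
    """One convolved-boxcar column per condition with blocks, plus DCT drift
    columns up to the high-pass cutoff and an intercept."""
    if highpass_s <= 2 * design.tr_seconds:
        raise ValueError(f"high-pass cutoff {highpass_s} s must exceed twice the TR")
    hrf_params = HRF_MODELS.get(hrf_id, DEFAULT_HRF)
    if hrf_id not in HRF_MODELS:
        raise ValueError(f"unknown HRF model {hrf_id!r}")
    cols, names = [], []
    for condition in design.condition_names:
        onsets = design.onsets(condition)
        if onsets.size == 0:
            continue
        cols.append(
            condition_regressor(onsets, design.durations(condition), design.n_volumes, design.tr_seconds, hrf_params)
        )
        names.append(condition)
    drift = dct_basis(design.n_volumes, n_dct_columns(design.duration_s, highpass_s))
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"dct_{k + 1:02d}")
    cols.append(np.ones(design.n_volumes))
    names.append("intercept")
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return DesignMatrix(matrix=X, names=names, hrf_id=hrf_id, highpass_s=highpass_s)


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns: those whose removal restores the rank count
        collinear = []
        for j in range(X.shape[1]):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                collinear.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def scale_global(volume: np.ndarray, target: float = 100.0, mask: np.ndarray | None = None) -> np.ndarray:
    """Proportional scaling: multiply each frame so its in-mask mean equals ``target``.

    The default brain mask keeps voxels whose time-averaged intensity exceeds
    one eighth of the global mean (the conventional heuristic for EPI data).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    mean_img = vol.mean(axis=3)
    if mask is None:
        mask = mean_img > mean_img.mean() / 8.0
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty brain mask")
    frame_means = vol[mask].mean(axis=0)
    if np.any(frame_means <= 0):
        raise ValueError("non-positive in-mask frame mean; cannot scale proportionally")
    return vol * (target / frame_means)[None, None, None, :]


def smooth_gaussian(map3d: np.ndarray, fwhm_mm: Sequence[float] | float, affine: np.ndarray) -> np.ndarray:
    """Separable Gaussian smoothing with per-axis FWHM in millimetres.

    Requires a shear-free (diagonal) affine; sigma per axis is
    FWHM / (2 sqrt(2 ln 2)) converted to voxel units.  Zero FWHM is the
    identity.  Uses a constant-zero boundary, so the image sum is conserved
    except for mass smoothed across the array edge.
    """
    affine = np.asarray(affine, dtype=float)
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-8):
        raise ValueError("smoothing requires a shear-free diagonal affine")
    vox = np.abs(np.diag(lin))
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("FWHM must be nonnegative")
    if np.all(fwhm == 0):
        return np.asarray(map3d, dtype=float).copy()
    sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
    return ndimage.gaussian_filter(np.asarray(map3d, dtype=float), sigma=sigma_vox, mode="constant")


# ---------------------------------------------------------------------------
# first level
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSpec:
    """Contrast weights over named regressors, e.g. {"motor_hands": 1} for
    'Hands Movement > Rest' (unnamed regressors get weight 0)."""

    weights: dict[str, float]
    label: str = ""

    def vector(self, names: Sequence[str]) -> np.ndarray:
        unknown = set(self.weights) - set(names)
        if unknown:
            raise ValueError(f"contrast names not in design: {sorted(unknown)}")
        c = np.array([self.weights.get(n, 0.0) for n in names])
        if np.all(c == 0):
            raise ValueError("contrast weights are all zero")
        return c


@dataclass
class FirstLevelFit:
    """OLS result of one run: per-voxel betas, residual variance, and the
    design bookkeeping needed to form contrast t statistics."""

    betas: np.ndarray  # (x, y, z, p)
    resvar: np.ndarray  # (x, y, z)
    df: int
    names: list[str]
    xtx_inv: np.ndarray
    affine: np.ndarray


def fit_first_level(volume: np.ndarray, X: DesignMatrix, affine: np.ndarray) -> FirstLevelFit:
    """Voxelwise ordinary least squares of a 4-D run against a design matrix."""
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    n = vol.shape[3]
    if n != X.n_volumes:
        raise ValueError(f"volume has {n} frames but design has {X.n_volumes} rows")
    _check_full_rank(X.matrix, X.names)
    shape = vol.shape[:3]
    Y = vol.reshape(-1, n).T  # (n, voxels)
    pinv = np.linalg.pinv(X.matrix)
    B = pinv @ Y
    resid = Y - X.matrix @ B
    df = n - X.matrix.shape[1]
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    resvar = (resid**2).sum(axis=0) / df
    # voxels fit exactly (e.g. noiseless synthetic data) leave only rounding
    # error in the residual; clamp those to zero so they are flagged degenerate
    resvar[resvar <= (Y**2).mean(axis=0) * 1e-12] = 0.0
    xtx_inv = np.linalg.inv(X.matrix.T @ X.matrix)
    return FirstLevelFit(
        betas=B.T.reshape(*shape, -1),
        resvar=resvar.reshape(shape),
        df=df,
        names=list(X.names),
        xtx_inv=xtx_inv,
        affine=np.asarray(affine, dtype=float),
    )


def contrast_effect_map(fit: FirstLevelFit, contrast: ContrastSpec) -> StatMap:
    """Contrast image c'beta (the per-subject input to second-level analysis)."""
    c = contrast.vector(fit.names)
    eff = fit.betas @ c
    return StatMap(eff, fit.affine, "beta")


def contrast_tmap(fit: FirstLevelFit, contrast: ContrastSpec) -> StatMap:
    """Voxelwise t = c'beta / sqrt(resvar c'(X'X)^-1 c).

    Voxels with zero estimated residual variance get t = 0 and are flagged in
    ``degenerate_mask`` rather than carrying an infinite statistic.
    """
    c = contrast.vector(fit.names)
    eff = fit.betas @ c
    var_scale = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.resvar * var_scale)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / se
    t[degenerate] = 0.0
    return StatMap(t, fit.affine, "tstat", df=fit.df, degenerate_mask=degenerate)


# ---------------------------------------------------------------------------
# second level
# ---------------------------------------------------------------------------


def _stack_subject_maps(maps: Sequence[StatMap]) -> tuple[np.ndarray, StatMap]:
    if len(maps) < 3:
        raise ValueError("second-level inference needs at least 3 subjects")
    first = maps[0]
    for m in maps[1:]:
        first.require_same_grid(m, "subject contrast maps")
    return np.stack([np.asarray(m.data, dtype=float) for m in maps]), first


def one_sample_t(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t over axis 0; zero-variance entries get t = 0 and a flag."""
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    t[degenerate] = 0.0
    return t, degenerate


def second_level_ttest(contrast_maps: Sequence[StatMap]) -> StatMap:
    """Random-effects group inference: one-sample t across subjects per voxel."""
    stack, first = _stack_subject_maps(contrast_maps)
    t, degenerate = one_sample_t(stack)
    return StatMap(t, first.affine, "tstat", df=stack.shape[0] - 1, degenerate_mask=degenerate)


# ---------------------------------------------------------------------------
# thresholding with permutation cluster correction
# ---------------------------------------------------------------------------


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def max_cluster_size(binary: np.ndarray, connectivity: int = 26) -> int:
    labels, n = ndimage.label(binary, structure=_connectivity_structure(connectivity))
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def t_threshold(voxel_p: float, df: int, tail: str) -> float:
    if not 0 < voxel_p <= 1:
        raise ValueError("voxel_p must lie in (0, 1]")
    if tail == "greater":
        return float(stats.t.isf(voxel_p, df)) if voxel_p < 1 else -np.inf
    if tail == "two-sided":
        return float(stats.t.isf(voxel_p / 2.0, df)) if voxel_p < 1 else -np.inf
    raise ValueError("tail must be 'greater' or 'two-sided'")


def _suprathreshold(t: np.ndarray, tcrit: float, tail: str) -> np.ndarray:
    return (t > tcrit) if tail == "greater" else (np.abs(t) > tcrit)


def signflip_t_stack(stack2d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for every sign-flip at once.

    ``stack2d`` is (n_subjects, n_voxels); ``signs`` is (n_perm, n_subjects)
    of +-1.  Sign flips leave per-voxel second moments unchanged, so the
    permuted variance follows from the permuted mean alone and each
    permutation costs one matrix product.
    """
    n = stack2d.shape[0]
    mean_p = signs @ stack2d / n  # (n_perm, n_vox)
    msq = (stack2d**2).mean(axis=0)  # (n_vox,)
    var_p = np.clip(n * (msq[None, :] - mean_p**2) / (n - 1), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_p / np.sqrt(var_p / n)
    t[var_p == 0] = 0.0
    return t


def signflip_max_cluster_null(
    stack: np.ndarray,
    tcrit: float,
    n_permutations: int,
    rng: np.random.Generator,
    connectivity: int = 26,
    tail: str = "greater",
) -> np.ndarray:
    """Max-cluster-size null distribution under subject sign flipping.

    The identity flip is always included as the first permutation so the
    resulting familywise p-values cannot fall below 1/n_permutations.
    """
    n_sub = stack.shape[0]
    shape = stack.shape[1:]
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_sub))
    signs[0, :] = 1.0
    t_all = signflip_t_stack(stack.reshape(n_sub, -1), signs)
    structure = _connectivity_structure(connectivity)
    out = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        supra = _suprathreshold(t_all[i].reshape(shape), tcrit, tail)
        labels, nlab = ndimage.label(supra, structure=structure)
        out[i] = int(np.bincount(labels.ravel())[1:].max()) if nlab else 0
    return out


def cluster_size_cutoff(null_sizes: np.ndarray, cluster_p: float) -> float:
    """The (1 - cluster_p) quantile of the permutation max-cluster-size null;
    observed clusters must exceed it to survive."""
    return float(np.quantile(np.asarray(null_sizes), 1.0 - cluster_p))


def threshold_cluster(
    tmap: StatMap,
    voxel_p: float,
    cluster_p: float | None = None,
    subject_maps: Sequence[StatMap] | np.ndarray | None = None,
    null_sizes: np.ndarray | None = None,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    tail: str = "greater",
    connectivity: int = 26,
) -> StatMap:
    """Voxelwise p threshold plus optional cluster-extent FWER correction.

    With ``cluster_p`` set, the max-cluster-size null comes either from
    ``null_sizes`` (precomputed) or from sign-flip permutations of
    ``subject_maps`` (the second-level input).  With ``cluster_p`` None only
    the voxel threshold is applied — the single-subject p < 0.05 mode.
    """
    if tmap.kind != "tstat":
        raise ValueError("threshold_cluster expects a tstat map")
    tcrit = t_threshold(voxel_p, tmap.df, tail)
    supra = _suprathreshold(tmap.data, tcrit, tail)
    meta = {
        "voxel_p": voxel_p,
        "cluster_p": cluster_p,
        "tail": tail,
        "connectivity": connectivity,
        "t_critical": tcrit if np.isfinite(tcrit) else None,
        "method": "voxelwise" if cluster_p is None else "signflip_maxcluster_permutation",
    }
    if cluster_p is None:
        return StatMap(supra.astype(np.uint8), tmap.affine, "binary", threshold_meta=meta)
    if cluster_p <= 0.05 and n_permutations < 100 and null_sizes is None:
        raise ValueError("cluster correction at cluster_p <= 0.05 needs at least 100 permutations")
    if null_sizes is None:
        if subject_maps is None:
            raise ValueError("cluster correction needs subject maps or a precomputed null")
        stack = (
            np.asarray(subject_maps, dtype=float)
            if isinstance(subject_maps, np.ndarray)
            else _stack_subject_maps(subject_maps)[0]
        )
        rng = rng if rng is not None else np.random.default_rng(0)
        null_sizes = signflip_max_cluster_null(stack, tcrit, n_permutations, rng, connectivity, tail)
        meta["n_permutations"] = int(n_permutations)
    cutoff = cluster_size_cutoff(null_sizes, cluster_p)
    meta["cluster_size_cutoff"] = cutoff
    structure = _connectivity_structure(connectivity)
    labels, nlab = ndimage.label(supra, structure=structure)
    keep = np.zeros_like(supra)
    if nlab:
        sizes = np.bincount(labels.ravel())
        for lab in range(1, nlab + 1):
            if sizes[lab] > cutoff:
                keep |= labels == lab
    return StatMap(keep.astype(np.uint8), tmap.affine, "binary", threshold_meta=meta)
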