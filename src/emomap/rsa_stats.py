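"""Representational similarity between pixel and voxel body-emotion matrices,
JZS Bayes-factor one-sample t-tests, and ratings contrasts.

The RSA correlates each subject's silhouette-derived (pixel) matrix with the
fMRI-derived (voxel) matrix and tests the coefficients against zero across
subjects.  Bayes factors use the Jeffreys-Zellner-Siow setup: a Cauchy prior
(default scale sqrt(2)/2) on the standardised effect, integrated numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .types import BodyEmotionMatrix, EMOTIONS

DEFAULT_PRIOR_SCALE = float(np.sqrt(2.0) / 2.0)


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BFResult:
    """Classical one-sample t-test alongside the JZS Bayes factor."""

    t: float
    df: int
    p: float
    bf10: float
    prior_scale: float
    n: int

    def __post_init__(self) -> None:
        if self.bf10 <= 0:
            raise ValueError("bf10 must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def jzs_bf10(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS Bayes factor (alternative/null) for a one-sample t statistic.

    Under the null the data density is proportional to
    ``(1 + t^2/df)^(-(df+1)/2)``; under the alternative the standardised
    effect has a Cauchy(0, r) prior, equivalent to integrating the scaled
    density over g with an inverse-gamma(1/2, 1/2) mixing density:

        BF10 = int_0^inf (1 + N g r^2)^(-1/2)
               (1 + t^2 / ((1 + N g r^2) df))^(-(df+1)/2)
               InvGamma(g; 1/2, 1/2) dg
             / (1 + t^2/df)^(-(df+1)/2)

    evaluated by adaptive quadrature.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior scale must be positive")
    df = n - 1
    t = float(t)
    r2 = prior_scale**2

    def log_null() -> float:
        return -(df + 1) / 2.0 * np.log1p(t**2 / df)

    def integrand(g: float) -> float:
        k = 1.0 + n * g * r2
        log_f = (
            -0.5 * np.log(k)
            - (df + 1) / 2.0 * np.log1p(t**2 / (k * df))
            - log_null()
        )
        # inverse-gamma(1/2, 1/2) density: g^(-3/2) exp(-1/(2g)) / sqrt(2 pi)
        log_prior = -1.5 * np.log(g) - 1.0 / (2.0 * g) - 0.5 * np.log(2.0 * np.pi)
        return float(np.exp(log_f + log_prior))

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(val)


def bayes_one_sample(values: np.ndarray, mu0: float = 0.0, prior_scale: float = DEFAULT_PRIOR_SCALE) -> BFResult:
    """One-sample t-test against ``mu0`` with the JZS Bayes factor."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance sample; t-test undefined")
    n = x.size
    t, p = stats.ttest_1samp(x, mu0)
    return BFResult(
        t=float(t), df=n - 1, p=float(p), bf10=jzs_bf10(float(t), n, prior_scale),
        prior_scale=prior_scale, n=n,
    )


# ---------------------------------------------------------------------------
# RSA between pixel and voxel matrices
# ---------------------------------------------------------------------------


@dataclass
class RSAResult:
    per_subject_r: pd.Series
    t: float
    df: int
    p: float
    mode: str
    fisher_z: bool
    excluded: list[str]


def _flat_pair(pix: BodyEmotionMatrix, vox: BodyEmotionMatrix) -> tuple[np.ndarray, np.ndarray]:
    a, b = pix.flat(), vox.flat()
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def _rdm(mat: BodyEmotionMatrix) -> np.ndarray:
    """Lower triangle of the 5x5 emotion dissimilarity (1 - Pearson r of the
    per-segment profiles) matrix for one modality."""
    vals = mat.values.to_numpy(dtype=float)
    ne = vals.shape[0]
    out = []
    for i in range(ne):
        for j in range(i):
            a, b = vals[i], vals[j]
            if a.std() == 0 or b.std() == 0:
                out.append(np.nan)
            else:
                out.append(1.0 - np.corrcoef(a, b)[0, 1])
    return np.asarray(out)


def rsa_voxel_pixel(
    pixel_mats: dict[str, BodyEmotionMatrix],
    voxel_mats: dict[str, BodyEmotionMatrix],
    mode: str = "direct",
    method: str = "pearson",
    fisher_z: bool = True,
) -> RSAResult:
    """Correlate pixel and voxel body-emotion matrices per subject, then test
    the coefficients against zero across subjects.

    ``mode="direct"`` correlates the flattened 5x4 matrices;
    ``mode="rdm"`` first builds a 5x5 emotion-dissimilarity matrix per
    modality and correlates the lower triangles.  Coefficients are
    Fisher-z transformed before the group one-sample t-test unless
    ``fisher_z=False`` (the raw-r variant).
    """
    subjects = sorted(set(pixel_mats) & set(voxel_mats))
    if len(subjects) < 3:
        raise ValueError("need both matrices for at least 3 subjects")
    if mode not in ("direct", "rdm"):
        raise ValueError("mode must be 'direct' or 'rdm'")
    corr = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    rs, excluded = {}, []
    for s in subjects:
        if mode == "direct":
            a, b = _flat_pair(pixel_mats[s], voxel_mats[s])
        else:
            a, b = _rdm(pixel_mats[s]), _rdm(voxel_mats[s])
            keep = np.isfinite(a) & np.isfinite(b)
            a, b = a[keep], b[keep]
        if a.size < 3 or a.std() == 0 or b.std() == 0:
            warnings.warn(f"subject {s}: constant matrix, excluded from RSA", stacklevel=2)
            excluded.append(s)
            continue
        rs[s] = float(corr(a, b)[0])
    if len(rs) < 3:
        raise ValueError("fewer than 3 usable subjects after exclusions")
    r_series = pd.Series(rs, name="r")
    vals = r_series.to_numpy()
    if fisher_z:
        vals = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
    if np.std(vals, ddof=1) == 0:
        # all coefficients identical (e.g. all exactly 1): the one-sample t is
        # degenerate; report an infinite t with p = 0 for a nonzero mean.
        mean = float(np.mean(vals))
        t = float(np.inf) if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
    else:
        t, p = stats.ttest_1samp(vals, 0.0)
    return RSAResult(
        per_subject_r=r_series, t=float(t), df=len(rs) - 1, p=float(p),
        mode=mode, fisher_z=fisher_z, excluded=excluded,
    )


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------


def ratings_contrast(
    table: pd.DataFrame,
    measure: str = "intensity",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> dict[str, BFResult]:
    """Paired emotional-vs-neutral test per emotion on subject-level means.

    For every emotion, each subject contributes (mean emotional rating -
    mean neutral rating); the differences go into a one-sample t-test with
    the JZS Bayes factor.  Subjects missing either arm are dropped with a
    warning.
    """
    if measure not in ("intensity", "vividness"):
        raise ValueError("measure must be 'intensity' or 'vividness'")
    required = {"subject_id", "condition", measure}
    if not required.issubset(table.columns):
        raise ValueError(f"ratings table must have columns {sorted(required)}")
    out = {}
    neutral = table[table["condition"] == "neutral"].groupby("subject_id")[measure].mean()
    for emo in EMOTIONS:
        emot = table[table["condition"] == f"emotional:{emo}"].groupby("subject_id")[measure].mean()
        common = emot.index.intersection(neutral.index)
        dropped = set(emot.index).symmetric_difference(neutral.index)
        if dropped:
            warnings.warn(f"{emo}: subjects {sorted(dropped)} missing a rating arm, dropped", stacklevel=2)
        if len(common) < 2:
            raise ValueError(f"{emo}: need at least 2 subjects with paired ratings")
        diffs = (emot.loc[common] - neutral.loc[common]).to_numpy()
        out[emo] = bayes_one_sample(diffs, prior_scale=prior_scale)
    return out
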