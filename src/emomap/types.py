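"""Core containers shared across the pipeline.

The package works on a fixed voxel grid per analysis: every statistical map
(:class:`StatMap`) carries its data array together with a NIfTI-style affine so
maps from different stages can be checked for grid compatibility before any
voxelwise operation.  Body-emotion matrices (:class:`BodyEmotionMatrix`) hold
the 5 emotions x 4 body segments percentage tables that both the silhouette
(pixel) and the fMRI (voxel) branches of the analysis produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

SEGMENTS: tuple[str, ...] = ("face", "hands", "trunk", "feet")
EMOTIONS: tuple[str, ...] = ("happiness", "sadness", "fear", "anger", "serenity")
MODALITIES: tuple[str, ...] = ("motor", "tactile")

STATMAP_KINDS = ("beta", "tstat", "binary")


@dataclass(frozen=True)
class GridSpec:
    """An isotropic voxel grid with a scaled-identity RAS affine."""

    shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)


def _check_affine_close(a: np.ndarray, b: np.ndarray, atol: float = 1e-6) -> bool:
    return np.allclose(a, b, atol=atol)


@dataclass
class StatMap:
    """A 3-D scalar map (beta, t, or thresholded-binary) on a voxel grid.

    Parameters
    ----------
    data:
        3-D array of map values.
    affine:
        4x4 voxel-to-world matrix (NIfTI convention).
    kind:
        One of ``beta``, ``tstat``, ``binary``.
    df:
        Degrees of freedom; required exactly when ``kind == "tstat"``.
    threshold_meta:
        Provenance of any thresholding applied (voxel p, cluster p, method).
    degenerate_mask:
        Optional boolean array flagging voxels whose statistic was undefined
        (zero residual or between-subject variance) and was set to 0.
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str
    df: int | None = None
    threshold_meta: dict | None = None
    degenerate_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"StatMap data must be 3-D, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.kind not in STATMAP_KINDS:
            raise ValueError(f"kind must be one of {STATMAP_KINDS}, got {self.kind!r}")
        if self.kind == "tstat":
            if self.df is None or int(self.df) < 1:
                raise ValueError("tstat maps require df >= 1")
            self.df = int(self.df)
        elif self.df is not None:
            raise ValueError(f"df is only meaningful for tstat maps (kind={self.kind!r})")
        if self.kind == "binary":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary maps may contain only {0, 1}")
            self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_grid(self, other: "StatMap") -> bool:
        return self.shape == other.shape and _check_affine_close(self.affine, other.affine)

    def require_same_grid(self, other: "StatMap", what: str = "maps") -> None:
        if not self.same_grid(other):
            raise ValueError(f"{what} are not on a common voxel grid")

    def count(self) -> int:
        """Number of nonzero voxels (suprathreshold voxels for binary maps)."""
        return int(np.count_nonzero(self.data))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        """Write the map as NIfTI-1 plus a JSON sidecar with map metadata."""
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        sidecar = {"kind": self.kind, "df": self.df, "threshold_meta": self.threshold_meta}
        stem = path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        (path.parent / f"{stem}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, kind: str | None = None) -> "StatMap":
        path = Path(path)
        img = nib.load(str(path))
        stem = path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        sidecar_path = path.parent / f"{stem}.json"
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        resolved_kind = kind or meta.get("kind", "beta")
        data = np.asarray(img.get_fdata())
        if resolved_kind == "binary":
            data = (data > 0.5).astype(np.uint8)
        return cls(
            data=data,
            affine=img.affine,
            kind=resolved_kind,
            df=meta.get("df"),
            threshold_meta=meta.get("threshold_meta"),
        )


def binary_map(mask: np.ndarray, like: "StatMap | GridSpec", threshold_meta: dict | None = None) -> StatMap:
    """Wrap a boolean voxel array as a binary :class:`StatMap` on an existing grid."""
    affine = like.affine if isinstance(like, (GridSpec,)) else like.affine
    return StatMap(np.asarray(mask, dtype=bool).astype(np.uint8), affine, "binary", threshold_meta=threshold_meta)


@dataclass
class BodyEmotionMatrix:
    """Emotions x body segments percentage matrix (pixels or voxels).

    ``values`` is a DataFrame with emotion rows and segment columns; entries
    are percentages in [0, 100], or NaN where the quantity is undefined
    (e.g. an empty denominator set).
    """

    values: pd.DataFrame
    source: str  # "pixels" | "voxels"
    subject_id: str = "group"

    def __post_init__(self) -> None:
        if self.source not in ("pixels", "voxels"):
            raise ValueError("source must be 'pixels' or 'voxels'")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
            raise ValueError("percentages must lie in [0, 100]")

    @property
    def emotions(self) -> list[str]:
        return list(self.values.index)

    @property
    def segments(self) -> list[str]:
        return list(self.values.columns)

    def flat(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float).ravel()

    @classmethod
    def from_dict(
        cls,
        entries: Mapping[str, Mapping[str, float]],
        source: str,
        subject_id: str = "group",
        emotions: Iterable[str] = EMOTIONS,
        segments: Iterable[str] = SEGMENTS,
    ) -> "BodyEmotionMatrix":
        df = pd.DataFrame(
            [[float(entries[e][s]) for s in segments] for e in emotions],
            index=list(emotions),
            columns=list(segments),
        )
        return cls(values=df, source=source, subject_id=subject_id)


def mean_matrix(mats: list[BodyEmotionMatrix], subject_id: str = "group") -> BodyEmotionMatrix:
    """Element-wise mean of per-subject matrices (NaN entries propagate as NaN-mean)."""
    if not mats:
        raise ValueError("need at least one matrix")
    source = mats[0].source
    stack = np.stack([m.values.to_numpy(dtype=float) for m in mats])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    df = pd.DataFrame(mean, index=mats[0].values.index, columns=mats[0].values.columns)
    return BodyEmotionMatrix(values=df, source=source, subject_id=subject_id)


def round_half_away(x: float | np.ndarray) -> np.ndarray | int:
    """Round half away from zero (the package-wide rule for fraction x count)."""
    arr = np.asarray(x, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    if np.isscalar(x) or arr.ndim == 0:
        return int(out)
    return out.astype(int)
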