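"""Synthetic multi-subject datasets with planted ground truth.

The generator emulates the study conditions of a somatotopy-of-emotion
experiment: 2 s TR block designs (20 s stimulation / 20 s rest localizer
blocks for four body segments in the fixed order hands, feet, face, trunk;
14 s emotional/neutral recall episodes), somatotopically clustered BOLD
activation for 4 body segments x {motor, tactile}, emotion activation maps
with controlled fractional overlap onto those clusters, Gaussian noise plus
low-frequency cosine drift, coloured body silhouettes with specified
per-segment coloured-pixel fractions, and 1-5 intensity/vividness ratings.

Every generator is a pure function of its seed, and in the noiseless limit
all planted voxel and pixel counts are recovered exactly by the downstream
counting operations — which is what makes the whole pipeline testable
without any real scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hrf import DEFAULT_HRF, HRFParams, condition_regressor
from .silhouette import BodyTemplate, Silhouette
from .types import EMOTIONS, GridSpec, MODALITIES, SEGMENTS, StatMap, binary_map, round_half_away

LOCALIZER_SEGMENT_ORDER = ("hands", "feet", "face", "trunk")


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    onset_s: float
    duration_s: float
    condition: str


@dataclass(frozen=True)
class DesignSpec:
    """Block timing for one run: TR, volume count, and condition blocks."""

    tr_seconds: float
    n_volumes: int
    blocks: tuple[Block, ...]
    condition_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        total = self.n_volumes * self.tr_seconds
        prev = -np.inf
        for b in self.blocks:
            if b.onset_s < 0 or b.duration_s <= 0:
                raise ValueError(f"invalid block timing {b}")
            if b.onset_s < prev:
                raise ValueError("blocks must be sorted by onset")
            if b.onset_s + b.duration_s > total + 1e-9:
                raise ValueError(f"block {b} extends beyond the run ({total:.1f} s)")
            if b.condition not in self.condition_names:
                raise ValueError(f"block condition {b.condition!r} not in condition_names")
            prev = b.onset_s

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_seconds

    def onsets(self, condition: str) -> np.ndarray:
        return np.array([b.onset_s for b in self.blocks if b.condition == condition])

    def durations(self, condition: str) -> np.ndarray:
        return np.array([b.duration_s for b in self.blocks if b.condition == condition])

    def to_events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [b.onset_s for b in self.blocks],
                "duration": [b.duration_s for b in self.blocks],
                "condition": [b.condition for b in self.blocks],
            }
        )

    def write_events(self, path: str | Path) -> None:
        """Write blocks as a 3-column tab-delimited events file."""
        self.to_events_frame().to_csv(Path(path), sep="\t", index=False)

    @classmethod
    def from_events(
        cls, path: str | Path, tr_seconds: float, n_volumes: int, condition_names: Sequence[str] | None = None
    ) -> "DesignSpec":
        df = pd.read_csv(Path(path), sep="\t")
        blocks = tuple(
            Block(float(r.onset), float(r.duration), str(r.condition)) for r in df.itertuples(index=False)
        )
        if condition_names is None:
            condition_names = tuple(dict.fromkeys(b.condition for b in blocks))
        return cls(tr_seconds, n_volumes, blocks, tuple(condition_names))


def localizer_design(
    modality: str,
    n_repeats: int = 4,
    block_s: float = 20.0,
    rest_s: float = 20.0,
    tr_seconds: float = 2.0,
) -> DesignSpec:
    """Block localizer: each segment stimulated/moved for 20 s followed by 20 s rest.

    Segments cycle in the fixed order hands, feet, face, trunk, repeated
    ``n_repeats`` times; condition names are ``{modality}_{segment}``.
    """
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    blocks = []
    t = 0.0
    for _ in range(n_repeats):
        for seg in LOCALIZER_SEGMENT_ORDER:
            blocks.append(Block(t, block_s, f"{modality}_{seg}"))
            t += block_s + rest_s
    n_volumes = int(np.ceil(t / tr_seconds))
    names = tuple(f"{modality}_{seg}" for seg in LOCALIZER_SEGMENT_ORDER)
    return DesignSpec(tr_seconds, n_volumes, tuple(blocks), names)


def recall_design(
    rng: np.random.Generator,
    n_episodes_per_emotion: int = 3,
    episode_s: float = 14.0,
    rating_gap_s: float = 8.0,
    tr_seconds: float = 2.0,
    emotions: Sequence[str] = EMOTIONS,
) -> DesignSpec:
    """Emotional-recall run: 14 s episodes, emotional alternated with neutral.

    Emotional episodes (``n_episodes_per_emotion`` per emotion) appear in a
    seeded random order, each followed by a neutral episode; a rating gap
    after every episode models the intensity/vividness response period.
    """
    order = [e for e in emotions for _ in range(n_episodes_per_emotion)]
    order = [order[i] for i in rng.permutation(len(order))]
    blocks = []
    t = 0.0
    for emo in order:
        blocks.append(Block(t, episode_s, emo))
        t += episode_s + rating_gap_s
        blocks.append(Block(t, episode_s, "neutral"))
        t += episode_s + rating_gap_s
    n_volumes = int(np.ceil(t / tr_seconds))
    names = tuple(emotions) + ("neutral",)
    return DesignSpec(tr_seconds, n_volumes, tuple(blocks), names)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _sphere_mask(grid: GridSpec, center: tuple[int, int, int], radius: int) -> np.ndarray:
    idx = np.indices(grid.shape)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def default_roi_centers(grid: GridSpec = GridSpec()) -> dict[tuple[str, str], tuple[int, int, int]]:
    """Eight disjoint spherical ROI centres: 4 segments x {motor, tactile}.

    Motor ROIs sit on one axial plane, tactile ROIs on another, echoing the
    pre/post-central arrangement of motor and somatosensory strips.
    """
    nx, ny, nz = grid.shape
    xs = np.linspace(nx * 0.2, nx * 0.8, 4).astype(int)
    z_motor, z_tactile = int(nz * 0.7), int(nz * 0.3)
    y = ny // 2
    centers = {}
    for seg, x in zip(SEGMENTS, xs):
        centers[(seg, "motor")] = (int(x), y, z_motor)
        centers[(seg, "tactile")] = (int(x), y, z_tactile)
    return centers


@dataclass
class GroundTruth:
    """Planted signal description for one synthetic study.

    ``effect_size`` maps condition names (``motor_hands``, ``happiness`` ...)
    to BOLD block amplitudes in signal units; ``emotion_overlap_fraction``
    maps ``(emotion, segment)`` to the fraction of that segment's mask the
    emotion activates.  ``baseline`` is the constant raw-signal level that
    proportional global scaling normalises away.
    """

    roi_centers: dict[tuple[str, str], tuple[int, int, int]] = field(default_factory=default_roi_centers)
    roi_radius_vox: int = 2
    common_center: tuple[int, int, int] | None = None
    common_radius_vox: int = 3
    modality_bias: float = 0.3
    effect_size: dict[str, float] = field(default_factory=dict)
    emotion_overlap_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    baseline: float = 100.0
    seed: int = 0
    extra_condition_voxels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be nonnegative")
        if self.roi_radius_vox < 1:
            raise ValueError("roi_radius_vox must be a positive integer")
        for key, frac in self.emotion_overlap_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"overlap fraction for {key} must lie in [0, 1]")

    def roi_mask(self, segment: str, modality: str, grid: GridSpec) -> np.ndarray:
        return _sphere_mask(grid, self.roi_centers[(segment, modality)], self.roi_radius_vox)

    def common_mask(self, grid: GridSpec) -> np.ndarray:
        """Whole-body region responding to every localizer condition (emulating
        areas with body-wide receptive fields such as SII / insula)."""
        if self.common_center is None:
            return np.zeros(grid.shape, dtype=bool)
        return _sphere_mask(grid, self.common_center, self.common_radius_vox)

    def validate_rois(self, grid: GridSpec) -> None:
        """Reject ROI layouts where distinct segments share voxels or leave the grid."""
        occupancy = np.zeros(grid.shape, dtype=int)
        for (seg, mod), center in self.roi_centers.items():
            if any(c - self.roi_radius_vox < 0 or c + self.roi_radius_vox >= s for c, s in zip(center, grid.shape)):
                raise ValueError(f"ROI {(seg, mod)} at {center} does not fit inside the grid {grid.shape}")
        for seg in {s for s, _ in self.roi_centers}:
            seg_mask = np.zeros(grid.shape, dtype=bool)
            for (s, mod), _ in self.roi_centers.items():
                if s == seg:
                    seg_mask |= self.roi_mask(s, mod, grid)
            occupancy += seg_mask
        if occupancy.max() > 1:
            raise ValueError("ROIs of distinct body segments overlap")
        common = self.common_mask(grid)
        if common.any():
            if any(c - self.common_radius_vox < 0 or c + self.common_radius_vox >= s
                   for c, s in zip(self.common_center, grid.shape)):
                raise ValueError("whole-body common ROI does not fit inside the grid")
            if (occupancy.astype(bool) & common).any():
                raise ValueError("whole-body common ROI overlaps a segment ROI")

    def true_segment_masks(self, grid: GridSpec) -> dict[str, np.ndarray]:
        """Ground-truth voxel sets per body segment (both modalities' spheres)
        plus the whole-body common region under key ``"whole_body"``."""
        out: dict[str, np.ndarray] = {}
        for seg, mod in self.roi_centers:
            out.setdefault(seg, np.zeros(grid.shape, dtype=bool))
            out[seg] |= self.roi_mask(seg, mod, grid)
        common = self.common_mask(grid)
        if common.any():
            out["whole_body"] = common
        return out

    def condition_mask(self, condition: str, grid: GridSpec) -> np.ndarray | None:
        """Voxel set activated by a condition (sphere for localizer conditions,
        explicitly planted voxels for emotion conditions), or None."""
        if condition in self.extra_condition_voxels:
            mask = np.zeros(grid.shape, dtype=bool)
            mask.flat[self.extra_condition_voxels[condition]] = True
            return mask
        if "_" in condition:
            mod, _, seg = condition.partition("_")
            if (seg, mod) in self.roi_centers:
                mask = self.roi_mask(seg, mod, grid)
                return mask | self.common_mask(grid)
        return None

    def condition_field(self, condition: str, grid: GridSpec) -> np.ndarray | None:
        """Amplitude multiplier field for a condition (None if it drives no voxel).

        Localizer conditions activate their segment sphere at 1 and the
        whole-body common region with a modality-dependent asymmetry: the
        anterior half responds more to movement, the posterior half more to
        touch (amplitudes 1 +- ``modality_bias``), so the common region still
        survives the all-contrasts conjunction while supporting a
        motor-vs-tactile partition.
        """
        if condition in self.extra_condition_voxels:
            field = np.zeros(grid.shape)
            field.flat[self.extra_condition_voxels[condition]] = 1.0
            return field
        if "_" in condition:
            mod, _, seg = condition.partition("_")
            if (seg, mod) in self.roi_centers:
                field = self.roi_mask(seg, mod, grid).astype(float)
                common = self.common_mask(grid)
                if common.any():
                    y = np.indices(grid.shape)[1]
                    anterior = common & (y < self.common_center[1])
                    posterior = common & ~anterior
                    hi, lo = 1.0 + self.modality_bias, 1.0 - self.modality_bias
                    if mod == "motor":
                        field[anterior] = hi
                        field[posterior] = lo
                    else:
                        field[anterior] = lo
                        field[posterior] = hi
                return field
        return None


# Planted overlap fractions per (emotion, body segment): broad felt-body
# patterns (face/trunk-weighted positive emotions and sadness, limb-weighted
# fear/anger, feet weakest overall) at magnitudes comparable to reported
# body-map percentages.  "whole_body" addresses the conjunction region.
DEFAULT_EMOTION_FRACTIONS: dict[tuple[str, str], float] = {
    ("happiness", "face"): 0.25, ("happiness", "hands"): 0.13, ("happiness", "trunk"): 0.13,
    ("happiness", "feet"): 0.08, ("happiness", "whole_body"): 0.08,
    ("sadness", "face"): 0.17, ("sadness", "hands"): 0.08, ("sadness", "trunk"): 0.12,
    ("sadness", "feet"): 0.03, ("sadness", "whole_body"): 0.20,
    ("fear", "face"): 0.05, ("fear", "hands"): 0.10, ("fear", "trunk"): 0.11,
    ("fear", "feet"): 0.07, ("fear", "whole_body"): 0.06,
    ("anger", "face"): 0.13, ("anger", "hands"): 0.09, ("anger", "trunk"): 0.10,
    ("anger", "feet"): 0.04, ("anger", "whole_body"): 0.01,
    ("serenity", "face"): 0.22, ("serenity", "hands"): 0.21, ("serenity", "trunk"): 0.18,
    ("serenity", "feet"): 0.15, ("serenity", "whole_body"): 0.02,
}


def default_common_center(grid: GridSpec) -> tuple[int, int, int]:
    nx, ny, nz = grid.shape
    return (nx // 2, int(ny * 0.25), nz // 2)


def default_ground_truth(grid: GridSpec = GridSpec(), seed: int = 0, **overrides) -> GroundTruth:
    """Study-condition defaults: unit localizer block amplitude on a baseline of
    100 (i.e. ~1% signal change), noise SD 1, mild cosine drift."""
    effects = {f"{mod}_{seg}": 1.0 for mod in MODALITIES for seg in SEGMENTS}
    effects.update({e: 1.0 for e in EMOTIONS})
    effects["neutral"] = 0.0
    truth = GroundTruth(
        roi_centers=default_roi_centers(grid),
        common_center=default_common_center(grid),
        effect_size=effects,
        emotion_overlap_fraction=dict(DEFAULT_EMOTION_FRACTIONS),
        seed=seed,
    )
    return replace(truth, **overrides) if overrides else truth


# ---------------------------------------------------------------------------
# fMRI run simulation
# ---------------------------------------------------------------------------


def simulate_run(
    design: DesignSpec,
    truth: GroundTruth,
    grid: GridSpec = GridSpec(),
    rng: np.random.Generator | None = None,
    hrf_params: HRFParams = DEFAULT_HRF,
) -> np.ndarray:
    """Simulate a 4-D run (x, y, z, t) for one subject.

    Each voxel's time series is the sum over conditions of
    ``beta(condition) * (boxcar * HRF)`` inside that condition's planted
    voxel set, plus slow cosine drift and i.i.d. Gaussian noise, on a
    constant baseline.  Deterministic given the generator state.
    """
    truth.validate_rois(grid)
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    n = design.n_volumes
    nvox = grid.n_voxels
    data = np.zeros((nvox, n))
    for condition in design.condition_names:
        onsets = design.onsets(condition)
        if onsets.size == 0:
            continue
        beta = truth.effect_size.get(condition, 0.0)
        if beta == 0.0:
            continue
        field = truth.condition_field(condition, grid)
        if field is None:
            continue
        reg = condition_regressor(onsets, design.durations(condition), n, design.tr_seconds, hrf_params)
        flat = field.ravel()
        nz = flat != 0
        data[nz, :] += beta * flat[nz, None] * reg[None, :]
    if truth.drift_amplitude > 0:
        i = np.arange(n)
        drift = np.zeros(n)
        for k in (1, 2):
            drift += np.cos(np.pi * k * (2 * i + 1) / (2 * n)) / k
        data += truth.drift_amplitude * drift[None, :]
    if truth.noise_sd > 0:
        data += rng.normal(0.0, truth.noise_sd, size=(nvox, n))
    data += truth.baseline
    return data.reshape(*grid.shape, n)


# ---------------------------------------------------------------------------
# planted emotion maps (option A) and planted emotion voxel sets (option B)
# ---------------------------------------------------------------------------


def _compact_subset(mask: np.ndarray, n_pick: int, anchor: np.ndarray | None = None) -> np.ndarray:
    """Deterministically pick ``n_pick`` voxels/pixels of ``mask`` forming a
    compact blob: the nearest to the mask centroid (or ``anchor``), with a
    lexicographic tie-break."""
    coords = np.argwhere(mask)
    if n_pick > len(coords):
        raise ValueError("requested more elements than the mask contains")
    if anchor is None:
        anchor = coords.mean(axis=0)
    d2 = ((coords - anchor) ** 2).sum(axis=1)
    order = np.lexsort(tuple(coords.T[::-1]) + (d2,))
    picked = coords[order[:n_pick]]
    out = np.zeros_like(mask, dtype=bool)
    out[tuple(picked.T)] = True
    return out


def planted_fraction_mask(mask: np.ndarray, fraction: float, anchor: np.ndarray | None = None) -> np.ndarray:
    """Compact sub-mask containing round(fraction x |mask|) elements.

    Rounding is half-away-from-zero; a positive fraction that rounds to zero
    elements triggers a warning (the planted count is then 0).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    total = int(np.count_nonzero(mask))
    n_pick = round_half_away(fraction * total)
    if fraction > 0 and n_pick < 1:
        warnings.warn(
            f"fraction {fraction} of {total} elements rounds to zero; planting nothing", stacklevel=2
        )
        n_pick = 0
    return _compact_subset(mask, n_pick, anchor)


def _as_bool_mask(m) -> np.ndarray:
    return (m.data if isinstance(m, StatMap) else np.asarray(m)).astype(bool)


def simulate_emotion_maps(
    truth: GroundTruth,
    masks: Mapping[str, "StatMap | np.ndarray"],
    grid: GridSpec = GridSpec(),
    rng: np.random.Generator | None = None,
    n_outside: int = 30,
    fractions: Mapping[tuple[str, str], float] | None = None,
) -> dict[str, StatMap]:
    """Plant binary suprathreshold emotion maps with exact per-segment overlap.

    For each emotion, its map intersects each segment mask in exactly
    ``round(fraction x |mask|)`` voxels (a compact blob inside the mask) and
    additionally contains ``n_outside`` voxels placed outside all masks.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 1)
    fractions = dict(fractions) if fractions is not None else truth.emotion_overlap_fraction
    seg_masks = {s: _as_bool_mask(masks[s]) for s in masks}
    if any(m.sum() == 0 for m in seg_masks.values()):
        raise ValueError("segment masks must be nonempty")
    union = np.zeros(grid.shape, dtype=bool)
    for m in seg_masks.values():
        union |= m
    outside = ~union
    out: dict[str, StatMap] = {}
    for emotion in EMOTIONS:
        emo = np.zeros(grid.shape, dtype=bool)
        for seg, m in seg_masks.items():
            frac = fractions.get((emotion, seg), 0.0)
            emo |= planted_fraction_mask(m, frac)
        if n_outside > 0:
            free = np.argwhere(outside)
            anchor = free[rng.integers(len(free))]
            emo |= _compact_subset(outside, n_outside, anchor)
        out[emotion] = binary_map(emo, grid)
    return out


def plant_emotion_voxels(
    truth: GroundTruth,
    masks: Mapping[str, "StatMap | np.ndarray"] | None = None,
    grid: GridSpec = GridSpec(),
    fractions: Mapping[tuple[str, str], float] | None = None,
) -> GroundTruth:
    """Ground truth with each emotion's voxel set (the exact fractional
    overlap blobs, by default inside the true segment regions) planted as
    beta carriers, so a full GLM run of the recall design produces
    activation at precisely those voxels."""
    fractions = dict(fractions) if fractions is not None else truth.emotion_overlap_fraction
    seg_masks = {k: _as_bool_mask(v) for k, v in (masks or truth.true_segment_masks(grid)).items()}
    extra = dict(truth.extra_condition_voxels)
    for emotion in EMOTIONS:
        emo = np.zeros(grid.shape, dtype=bool)
        for seg in seg_masks:
            frac = fractions.get((emotion, seg), 0.0)
            emo |= planted_fraction_mask(seg_masks[seg], frac)
        extra[emotion] = np.flatnonzero(emo.ravel())
    return replace(truth, extra_condition_voxels=extra)


# ---------------------------------------------------------------------------
# silhouettes
# ---------------------------------------------------------------------------


def simulate_silhouette(
    per_segment_fraction_act: Mapping[str, float],
    per_segment_fraction_deact: Mapping[str, float] | None,
    template: BodyTemplate,
    rng: np.random.Generator | None = None,
    allow_overlap: bool = False,
    **meta,
) -> Silhouette:
    """Colour exact per-segment pixel fractions on the body template.

    Within each segment, ``round(fraction x segment_pixel_count)`` pixels are
    set in the corresponding channel: activation fills a band growing from
    the segment's top in row-major order, deactivation a band growing from
    the bottom, so the channels are disjoint whenever the two fractions sum
    to at most 1 (the default contract; with ``allow_overlap`` both bands
    grow from the top and may intersect).
    """
    per_segment_fraction_deact = per_segment_fraction_deact or {}
    act = np.zeros(template.shape, dtype=np.uint8)
    deact = np.zeros(template.shape, dtype=np.uint8)
    for seg in SEGMENTS:
        fa = float(per_segment_fraction_act.get(seg, 0.0))
        fd = float(per_segment_fraction_deact.get(seg, 0.0))
        if not (0.0 <= fa <= 1.0 and 0.0 <= fd <= 1.0):
            raise ValueError(f"fractions for {seg} must lie in [0, 1]")
        if not allow_overlap and fa + fd > 1.0 + 1e-12:
            raise ValueError(f"activation+deactivation fractions exceed 1 for segment {seg}")
        coords = np.argwhere(template.segment_mask(seg))  # already row-major sorted
        total = len(coords)
        for frac, channel, from_top in ((fa, act, True), (fd, deact, allow_overlap)):
            n_pick = round_half_away(frac * total)
            if frac > 0 and n_pick < 1:
                warnings.warn(
                    f"fraction {frac} of {total} pixels rounds to zero; planting nothing", stacklevel=2
                )
                continue
            picked = coords[:n_pick] if from_top else coords[total - n_pick :]
            channel[tuple(picked.T)] = 1
    if not allow_overlap and np.any(act & deact):  # only possible if rounding collides
        raise ValueError("activation and deactivation channels overlap under the disjoint flag")
    return Silhouette(activation=act, deactivation=deact, registered=True, **meta)


def render_scan(
    s: Silhouette,
    template: BodyTemplate,
    shift: tuple[float, float] = (0.0, 0.0),
    angle_deg: float = 0.0,
    scale: float = 1.0,
    body_gray: float = 0.82,
) -> np.ndarray:
    """Render a silhouette as a scanned colour page, optionally displaced.

    The page shows the body filled light grey, activation pixels pure red,
    deactivation pixels pure blue, on white paper, transformed by a 2-D
    similarity (``shift`` = (rows, cols) translation, rotation about the page
    centre, isotropic scale) to emulate imperfect scanner placement.
    """
    from skimage.transform import SimilarityTransform, warp

    h, w = template.shape
    page = np.ones((h, w, 3), dtype=float)
    body = template.body_mask.astype(bool)
    for c in range(3):
        page[:, :, c][body] = body_gray
    page[:, :, 0][s.activation.astype(bool)] = 1.0
    page[:, :, 1][s.activation.astype(bool)] = 0.0
    page[:, :, 2][s.activation.astype(bool)] = 0.0
    page[:, :, 0][s.deactivation.astype(bool)] = 0.0
    page[:, :, 1][s.deactivation.astype(bool)] = 0.0
    page[:, :, 2][s.deactivation.astype(bool)] = 1.0
    if shift == (0.0, 0.0) and angle_deg == 0.0 and scale == 1.0:
        return page
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x=col, y=row)
    fwd = (
        SimilarityTransform(translation=-center)
        + SimilarityTransform(rotation=np.deg2rad(angle_deg), scale=scale)
        + SimilarityTransform(translation=center)
        + SimilarityTransform(translation=(shift[1], shift[0]))
    )
    # scan(y) = page(fwd^-1(y)): pass the inverse map output->input to warp
    scan = warp(page, fwd.inverse, order=0, cval=1.0, preserve_range=True)
    return scan


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------


def simulate_ratings(
    rng: np.random.Generator,
    n_episodes_per_emotion: int = 3,
    effect: float = 2.0,
    sd: float = 0.8,
    neutral_mean: float = 2.0,
    subject_id: str = "sub-01",
    emotions: Sequence[str] = EMOTIONS,
) -> pd.DataFrame:
    """Integer 1-5 intensity and vividness ratings for one subject's episodes.

    Emotional episodes score ``neutral_mean + effect`` on average, their
    neutral counterparts ``neutral_mean``; draws are Gaussian, rounded and
    clipped to the 1-5 scale (a warning flags means outside the scale).
    """
    if n_episodes_per_emotion <= 0:
        raise ValueError("need at least one episode per emotion")
    if sd <= 0:
        raise ValueError("rating sd must be positive")
    for m in (neutral_mean, neutral_mean + effect):
        if not 1.0 <= m <= 5.0:
            warnings.warn(f"rating mean {m} lies outside the 1-5 scale; values will clip", stacklevel=2)
    rows = []
    episode = 0
    for emo in emotions:
        for _ in range(n_episodes_per_emotion):
            for cond, mu in ((f"emotional:{emo}", neutral_mean + effect), ("neutral", neutral_mean)):
                episode += 1
                vals = rng.normal(mu, sd, size=2)
                vals = np.clip(np.rint(vals), 1, 5).astype(int)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "episode_id": f"ep{episode:03d}",
                        "condition": cond,
                        "intensity": int(vals[0]),
                        "vividness": int(vals[1]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-subject bundles
# ---------------------------------------------------------------------------


@dataclass
class SubjectDataset:
    """Everything the pipeline consumes for one synthetic subject."""

    subject_id: str
    runs: dict[str, tuple[np.ndarray, DesignSpec]]
    silhouettes_pre: dict[str, Silhouette]
    silhouettes_post: dict[str, Silhouette]
    ratings: pd.DataFrame
    grid: GridSpec
    emotion_fractions: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {vol.shape[:3] for vol, _ in self.runs.values()}
        if len(shapes) > 1:
            raise ValueError("all runs of a subject must share one voxel grid")


def jittered_fractions(
    rng: np.random.Generator,
    base: Mapping[tuple[str, str], float],
    jitter_sd: float = 0.05,
) -> dict[tuple[str, str], float]:
    """Per-subject overlap/colouring fractions: planted mean plus clipped Gaussian jitter."""
    return {k: float(np.clip(v + rng.normal(0.0, jitter_sd), 0.0, 1.0)) for k, v in base.items()}


def simulate_subject(
    subject_id: str,
    truth: GroundTruth,
    template: BodyTemplate,
    seed_seq: np.random.SeedSequence,
    grid: GridSpec = GridSpec(),
    pixel_fractions: Mapping[tuple[str, str], float] | None = None,
    subject_jitter_sd: float = 0.08,
    phase_jitter_sd: float = 0.03,
    n_localizer_repeats: int = 4,
    n_episodes_per_emotion: int = 3,
) -> SubjectDataset:
    """Generate one subject: three runs (tactile/motor localizer + recall),
    pre/post silhouettes per emotion, and the ratings table.

    Each subject gets a stable felt-body profile — the group fractions plus a
    subject-level offset (``subject_jitter_sd``) — that drives both pre- and
    post-scan silhouettes (each with smaller phase-level jitter,
    ``phase_jitter_sd``); the same profile is exposed as
    ``emotion_fractions`` so the fMRI branch can plant congruent activation.
    """
    rngs = [np.random.default_rng(s) for s in seed_seq.spawn(7)]
    runs: dict[str, tuple[np.ndarray, DesignSpec]] = {}
    for i, modality in enumerate(MODALITIES):
        design = localizer_design(modality, n_repeats=n_localizer_repeats)
        runs[modality] = (simulate_run(design, truth, grid, rngs[i]), design)
    design_recall = recall_design(rngs[2], n_episodes_per_emotion=n_episodes_per_emotion)
    runs["recall"] = (simulate_run(design_recall, truth, grid, rngs[2]), design_recall)
    base_px = dict(pixel_fractions) if pixel_fractions is not None else truth.emotion_overlap_fraction
    subject_fr = jittered_fractions(rngs[6], base_px, subject_jitter_sd)
    sil_pre, sil_post = {}, {}
    for phase, store, rng in (("pre", sil_pre, rngs[3]), ("post", sil_post, rngs[4])):
        fr = jittered_fractions(rng, subject_fr, phase_jitter_sd)
        for emo in EMOTIONS:
            act = {seg: fr[(emo, seg)] for seg in SEGMENTS}
            store[emo] = simulate_silhouette(
                act, None, template, subject_id=subject_id, phase=phase, emotion=emo
            )
    ratings = simulate_ratings(rngs[5], subject_id=subject_id)
    return SubjectDataset(
        subject_id=subject_id,
        runs=runs,
        silhouettes_pre=sil_pre,
        silhouettes_post=sil_post,
        ratings=ratings,
        grid=grid,
        emotion_fractions=subject_fr,
    )
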