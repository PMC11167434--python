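"""Convergence of emotion activation with sensorimotor masks.

Quantifies how much of the sensorimotor map (whole-body or per body segment)
each emotion's suprathreshold activation reaches, builds per-subject
voxel-based body-emotion matrices ("voxel homunculi"), finds per-emotion
hotspot segments, and tabulates the agreement between self-report (pixel)
and fMRI (voxel) hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .sensorimotor_maps import SegmentMaskSet
from .types import BodyEmotionMatrix, EMOTIONS, SEGMENTS, StatMap, mean_matrix

MISSING = "–"  # rendered for undefined cells (empty denominator)


def mask_emotion(emotion_map: StatMap, mask: StatMap) -> StatMap:
    """Voxelwise AND of a binary emotion map with a binary sensorimotor mask."""
    for m, name in ((emotion_map, "emotion map"), (mask, "mask")):
        if m.kind != "binary":
            raise ValueError(f"{name} must be binary")
    emotion_map.require_same_grid(mask, "emotion map and mask")
    data = (emotion_map.data.astype(bool) & mask.data.astype(bool)).astype(np.uint8)
    return StatMap(data, mask.affine, "binary", threshold_meta=emotion_map.threshold_meta)


def convergence_percent(emotion_map: StatMap, mask: StatMap, mode: str = "mask") -> float | None:
    """Overlap percentage between an emotion map and a sensorimotor mask.

    ``mode="mask"``: 100 x |emotion AND mask| / |mask| (the fraction of the
    sensorimotor map reached by the emotion — the default, which normalises
    per mask so segments of different sizes are comparable).
    ``mode="emotion"``: 100 x |emotion AND mask| / |emotion|.
    Returns None when the denominator set is empty (reported as missing).
    """
    inter = mask_emotion(emotion_map, mask).count()
    if mode == "mask":
        denom = mask.count()
    elif mode == "emotion":
        denom = emotion_map.count()
    else:
        raise ValueError("mode must be 'mask' or 'emotion'")
    if denom == 0:
        return None
    return 100.0 * inter / denom


@dataclass
class ConvergenceTable:
    """Emotions x masks percentage table with undefined cells as NaN."""

    values: pd.DataFrame
    denominator_mode: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
            raise ValueError("convergence percentages must lie in [0, 100]")

    def formatted(self) -> pd.DataFrame:
        """Two-decimal strings with '–' for undefined cells."""
        return self.values.map(lambda v: MISSING if not np.isfinite(v) else f"{v:.2f}")


def convergence_table(
    emotion_maps: Mapping[str, StatMap],
    masks: Mapping[str, StatMap],
    mode: str = "mask",
    provenance: dict | None = None,
) -> ConvergenceTable:
    """Tabulate convergence percentages for every emotion x mask pair."""
    emotions = [e for e in EMOTIONS if e in emotion_maps] or list(emotion_maps)
    rows = {}
    for emo in emotions:
        row = {}
        for name, mask in masks.items():
            masked = mask_emotion(emotion_maps[emo], mask)
            # per-segment tables are undefined when the emotion reaches no voxel
            # of the segment... only an empty *denominator* is undefined;
            # zero overlap is a true 0.00.
            val = convergence_percent(emotion_maps[emo], mask, mode=mode)
            row[name] = np.nan if val is None else val
        rows[emo] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[list(masks)]
    return ConvergenceTable(values=df, denominator_mode=mode, provenance=provenance or {})


def voxel_homunculus(
    per_subject_emotion_maps: Mapping[str, Mapping[str, StatMap]],
    masks: SegmentMaskSet | Mapping[str, StatMap],
) -> tuple[dict[str, BodyEmotionMatrix], BodyEmotionMatrix]:
    """Per-subject voxel body-emotion matrices plus the group mean.

    For each subject and emotion, the entry for a body segment is
    100 x |emotion AND segment mask| / |segment mask| — the voxel analogue of
    the silhouette pixel percentages.
    """
    seg_masks = masks.segment_masks() if isinstance(masks, SegmentMaskSet) else dict(masks)
    missing = [s for s in SEGMENTS if s not in seg_masks]
    if missing:
        raise ValueError(f"missing segment masks: {missing}")
    per_subject: dict[str, BodyEmotionMatrix] = {}
    for subject, emo_maps in per_subject_emotion_maps.items():
        entries = {}
        for emo in EMOTIONS:
            entries[emo] = {}
            for seg in SEGMENTS:
                val = convergence_percent(emo_maps[emo], seg_masks[seg], mode="mask")
                if val is None:
                    raise ValueError(f"segment mask {seg!r} is empty")
                entries[emo][seg] = val
        per_subject[subject] = BodyEmotionMatrix.from_dict(entries, source="voxels", subject_id=subject)
    group = mean_matrix(list(per_subject.values()))
    group.source = "voxels"
    return per_subject, group


def hotspots(matrix: BodyEmotionMatrix, tau: float = 0.0) -> dict[str, set[str]]:
    """Per-emotion hotspot segments: values within tau of the row maximum.

    With the default tau = 0 this is the strict argmax set (ties all
    included); tau = 0.2 admits segments reaching 80% of the row maximum.
    An all-zero row has no hotspot.
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must lie in [0, 1)")
    out: dict[str, set[str]] = {}
    for emo in matrix.emotions:
        row = matrix.values.loc[emo]
        vals = row.to_numpy(dtype=float)
        finite = np.where(np.isfinite(vals), vals, -np.inf)
        rmax = finite.max()
        if not np.isfinite(rmax) or rmax <= 0:
            out[emo] = set()
            continue
        out[emo] = {seg for seg, v in zip(matrix.segments, finite) if v >= (1.0 - tau) * rmax}
    return out


def congruence_table(
    pixel_matrix: BodyEmotionMatrix,
    voxel_matrix: BodyEmotionMatrix,
    tau: float = 0.0,
) -> pd.DataFrame:
    """Hotspot agreement between self-report and fMRI body-emotion matrices.

    Returns a table with one row per emotion and a +/- flag pair
    (self_report, fmri) per body segment, plus a boolean ``agree`` column
    that is True when the two modalities share at least one hotspot segment.
    """
    if list(pixel_matrix.emotions) != list(voxel_matrix.emotions):
        raise ValueError("pixel and voxel matrices must cover the same emotions in order")
    hs_pix = hotspots(pixel_matrix, tau)
    hs_vox = hotspots(voxel_matrix, tau)
    rows = []
    for emo in pixel_matrix.emotions:
        row: dict[str, object] = {"emotion": emo}
        for seg in pixel_matrix.segments:
            row[f"{seg}_self_report"] = "+" if seg in hs_pix[emo] else "-"
            row[f"{seg}_fmri"] = "+" if seg in hs_vox[emo] else "-"
        row["agree"] = bool(hs_pix[emo] & hs_vox[emo])
        rows.append(row)
    return pd.DataFrame(rows).set_index("emotion")
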