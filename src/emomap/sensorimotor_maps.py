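"""Group-level somatotopic sensorimotor maps from localizer contrasts.

Three kinds of masks are built from the 4 body segments x {motor, tactile}
localizer contrasts:

* the *whole-body* map — the minimum-statistic conjunction of all eight
  contrasts versus rest (voxels active for every segment and modality),
* *segment-specific* maps — for each segment, the contrast (segment motor +
  segment tactile) > mean of all other segments' contrasts,
* the *motor / tactile partition* of the whole-body map — voxels more active
  for movement than touch and vice versa.

All thresholding goes through the voxelwise-p + permutation cluster-extent
machinery of :mod:`emomap.glm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .glm import (
    StatMap,
    _connectivity_structure,
    _stack_subject_maps,
    _suprathreshold,
    second_level_ttest,
    signflip_t_stack,
    t_threshold,
    threshold_cluster,
)
from .types import MODALITIES, SEGMENTS
from scipy import ndimage

SubjectMaps = Mapping[tuple[str, str], Sequence[StatMap]]  # (segment, modality) -> per-subject contrast images


@dataclass
class SegmentMaskSet:
    """Binary masks keyed by (segment, modality).

    Segment-specific maps use modality ``"conjunction"`` (motor & tactile
    evidence combined); the whole-body conjunction map and the motor/tactile
    partition are keyed ``("all", "whole_body")``, ``("all", "motor")`` and
    ``("all", "tactile")``.  Segment-specific masks are pairwise disjoint by
    construction (shared voxels go to the segment with the larger t).
    """

    masks: dict[tuple[str, str], StatMap]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        maps = list(self.masks.values())
        for m in maps[1:]:
            maps[0].require_same_grid(m, "segment masks")

    def segment(self, segment: str) -> StatMap:
        return self.masks[(segment, "conjunction")]

    def segment_masks(self) -> dict[str, StatMap]:
        return {s: self.masks[(s, "conjunction")] for s in SEGMENTS if (s, "conjunction") in self.masks}

    @property
    def whole_body(self) -> StatMap:
        return self.masks[("all", "whole_body")]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (seg, mod), m in self.masks.items():
            m.save(outdir / f"{seg}_{mod}.nii.gz")
        import json

        (outdir / "manifest.json").write_text(json.dumps(self.provenance, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# conjunction
# ---------------------------------------------------------------------------


def conjunction(
    tmaps: Sequence[StatMap],
    voxel_p: float,
    cluster_p: float | None = None,
    subject_maps: Sequence[Sequence[StatMap]] | None = None,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    tail: str = "greater",
    connectivity: int = 26,
) -> StatMap:
    """Minimum-statistic conjunction over a set of t-maps (conjunction null).

    The voxelwise minimum t is thresholded at the voxel p; with a cluster p
    the max-cluster-size null is built by sign-flipping each contrast's
    subject maps with the same flips (subjects are the exchangeable units)
    and taking the minimum across contrasts per permutation.  With the
    cluster step disabled the result equals the intersection of the
    individually thresholded maps.
    """
    if len(tmaps) < 2:
        raise ValueError("conjunction needs at least two t-maps")
    first = tmaps[0]
    dfs = set()
    for m in tmaps:
        if m.kind != "tstat":
            raise ValueError("conjunction operates on tstat maps")
        first.require_same_grid(m, "conjunction inputs")
        dfs.add(m.df)
    if len(dfs) > 1:
        raise ValueError(f"conjunction inputs must share one df policy, got {sorted(dfs)}")
    df = dfs.pop()
    min_t = np.min(np.stack([m.data for m in tmaps]), axis=0)
    min_map = StatMap(min_t, first.affine, "tstat", df=df)
    if cluster_p is None:
        out = threshold_cluster(min_map, voxel_p, None, tail=tail, connectivity=connectivity)
        out.threshold_meta["method"] = "min_statistic_conjunction"
        return out
    if subject_maps is None:
        raise ValueError("cluster-corrected conjunction needs per-contrast subject maps")
    rng = rng if rng is not None else np.random.default_rng(0)
    tcrit = t_threshold(voxel_p, df, tail)
    stacks = [_stack_subject_maps(list(sm))[0] for sm in subject_maps]
    n_sub = stacks[0].shape[0]
    shape = stacks[0].shape[1:]
    flat = [s.reshape(n_sub, -1) for s in stacks]
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_sub))
    signs[0, :] = 1.0
    min_t_perm = None
    for s2d in flat:
        t_all = signflip_t_stack(s2d, signs)
        min_t_perm = t_all if min_t_perm is None else np.minimum(min_t_perm, t_all)
    structure = _connectivity_structure(connectivity)
    null_sizes = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        supra = _suprathreshold(min_t_perm[i].reshape(shape), tcrit, tail)
        labels, nlab = ndimage.label(supra, structure=structure)
        null_sizes[i] = int(np.bincount(labels.ravel())[1:].max()) if nlab else 0
    out = threshold_cluster(min_map, voxel_p, cluster_p, null_sizes=null_sizes, tail=tail, connectivity=connectivity)
    out.threshold_meta["method"] = "min_statistic_conjunction+signflip_maxcluster"
    out.threshold_meta["n_permutations"] = int(n_permutations)
    return out


# ---------------------------------------------------------------------------
# segment-specific maps
# ---------------------------------------------------------------------------


def _require_all_contrasts(subject_betas: SubjectMaps) -> int:
    missing = [(s, m) for s in SEGMENTS for m in MODALITIES if (s, m) not in subject_betas]
    if missing:
        raise ValueError(f"missing localizer contrast maps for {missing}")
    n_subjects = {len(v) for v in subject_betas.values()}
    if len(n_subjects) != 1:
        raise ValueError("all contrasts must cover the same subjects")
    return n_subjects.pop()


def segment_contrast_maps(subject_betas: SubjectMaps, target_segment: str) -> list[StatMap]:
    """Per-subject contrast images for 'target (motor & tactile) > all other
    segments (motor & tactile)': mean of the 2 target maps minus mean of the
    6 remaining maps."""
    if target_segment not in SEGMENTS:
        raise ValueError(f"unknown segment {target_segment!r}")
    n_sub = _require_all_contrasts(subject_betas)
    out = []
    for i in range(n_sub):
        target = np.mean([subject_betas[(target_segment, m)][i].data for m in MODALITIES], axis=0)
        others = np.mean(
            [subject_betas[(s, m)][i].data for s in SEGMENTS if s != target_segment for m in MODALITIES], axis=0
        )
        out.append(StatMap(target - others, subject_betas[(target_segment, "motor")][i].affine, "beta"))
    return out


def segment_specific_map(
    target_segment: str,
    subject_betas: SubjectMaps,
    voxel_p: float,
    cluster_p: float | None,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    tail: str = "greater",
    connectivity: int = 26,
) -> tuple[StatMap, StatMap]:
    """Thresholded binary map and the underlying second-level t-map for one
    segment's specific contrast."""
    cmaps = segment_contrast_maps(subject_betas, target_segment)
    tmap = second_level_ttest(cmaps)
    binary = threshold_cluster(
        tmap, voxel_p, cluster_p, subject_maps=cmaps, n_permutations=n_permutations, rng=rng, tail=tail,
        connectivity=connectivity,
    )
    return binary, tmap


def resolve_segment_overlaps(
    binaries: Mapping[str, StatMap], tmaps: Mapping[str, StatMap]
) -> dict[str, StatMap]:
    """Make segment maps pairwise disjoint: a voxel surviving several
    segments' contrasts is assigned to the segment with the larger t."""
    segs = list(binaries)
    first = binaries[segs[0]]
    stack_bin = np.stack([binaries[s].data.astype(bool) for s in segs])
    stack_t = np.stack([tmaps[s].data for s in segs])
    masked_t = np.where(stack_bin, stack_t, -np.inf)
    winner = np.argmax(masked_t, axis=0)
    any_on = stack_bin.any(axis=0)
    out = {}
    for i, s in enumerate(segs):
        data = (any_on & (winner == i) & stack_bin[i]).astype(np.uint8)
        out[s] = StatMap(data, first.affine, "binary", threshold_meta=binaries[s].threshold_meta)
    return out


# ---------------------------------------------------------------------------
# motor / tactile partition
# ---------------------------------------------------------------------------


def motor_minus_tactile_maps(subject_betas: SubjectMaps) -> list[StatMap]:
    """Per-subject (mean motor - mean tactile) contrast images over all segments."""
    n_sub = _require_all_contrasts(subject_betas)
    out = []
    for i in range(n_sub):
        motor = np.mean([subject_betas[(s, "motor")][i].data for s in SEGMENTS], axis=0)
        tactile = np.mean([subject_betas[(s, "tactile")][i].data for s in SEGMENTS], axis=0)
        out.append(StatMap(motor - tactile, subject_betas[(SEGMENTS[0], "motor")][i].affine, "beta"))
    return out


def motor_tactile_partition(
    subject_betas: SubjectMaps,
    whole_body: StatMap,
    voxel_p: float,
    cluster_p: float | None = None,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    connectivity: int = 26,
) -> tuple[StatMap, StatMap]:
    """Split the whole-body map into motor-dominant and tactile-dominant parts.

    Motor voxels survive the one-sided motor>tactile threshold, tactile
    voxels the reversed contrast; both are restricted to the whole-body map,
    and the two outputs are disjoint because the one-sided thresholds cannot
    both be exceeded.
    """
    if voxel_p is None:
        raise ValueError("a voxelwise threshold is required for the partition")
    dmaps = motor_minus_tactile_maps(subject_betas)
    rng = rng if rng is not None else np.random.default_rng(0)
    results = []
    for sign in (1.0, -1.0):
        signed = [StatMap(sign * m.data, m.affine, "beta") for m in dmaps]
        tmap = second_level_ttest(signed)
        thr = threshold_cluster(
            tmap, voxel_p, cluster_p, subject_maps=signed, n_permutations=n_permutations,
            rng=np.random.default_rng(rng.integers(2**31)), tail="greater", connectivity=connectivity,
        )
        restricted = thr.data.astype(bool) & whole_body.data.astype(bool)
        results.append(StatMap(restricted.astype(np.uint8), thr.affine, "binary", threshold_meta=thr.threshold_meta))
    return results[0], results[1]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def build_segment_mask_set(
    subject_betas: SubjectMaps,
    voxel_p: float = 0.001,
    cluster_p: float | None = 0.05,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    connectivity: int = 26,
) -> SegmentMaskSet:
    """Build the full mask set (whole-body conjunction, 4 disjoint segment
    maps, motor/tactile partition) from per-subject localizer contrast images."""
    _require_all_contrasts(subject_betas)
    rng = rng if rng is not None else np.random.default_rng(0)
    tmaps = {key: second_level_ttest(list(maps)) for key, maps in subject_betas.items()}
    whole = conjunction(
        list(tmaps.values()),
        voxel_p,
        cluster_p,
        subject_maps=[list(subject_betas[k]) for k in tmaps],
        n_permutations=n_permutations,
        rng=np.random.default_rng(rng.integers(2**31)),
        connectivity=connectivity,
    )
    seg_bin, seg_t = {}, {}
    for seg in SEGMENTS:
        b, t = segment_specific_map(
            seg, subject_betas, voxel_p, cluster_p, n_permutations,
            rng=np.random.default_rng(rng.integers(2**31)), connectivity=connectivity,
        )
        seg_bin[seg], seg_t[seg] = b, t
    disjoint = resolve_segment_overlaps(seg_bin, seg_t)
    motor, tactile = motor_tactile_partition(
        subject_betas, whole, voxel_p, cluster_p, n_permutations,
        rng=np.random.default_rng(rng.integers(2**31)), connectivity=connectivity,
    )
    masks = {("all", "whole_body"): whole, ("all", "motor"): motor, ("all", "tactile"): tactile}
    for seg in SEGMENTS:
        masks[(seg, "conjunction")] = disjoint[seg]
    provenance = {
        "voxel_p": voxel_p,
        "cluster_p": cluster_p,
        "n_permutations": n_permutations,
        "connectivity": connectivity,
        "contrasts": {
            "whole_body": "conjunction of all segment x modality contrasts vs rest",
            **{seg: f"{seg} motor & tactile > mean of other segments" for seg in SEGMENTS},
            "motor": "motor > tactile within whole-body map",
            "tactile": "tactile > motor within whole-body map",
        },
    }
    return SegmentMaskSet(masks=masks, provenance=provenance)
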