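"""End-to-end orchestration: simulate -> GLM -> masks -> emotion maps ->
convergence -> silhouettes -> RSA, with table/report generation.

:func:`run_pipeline` executes the whole analysis in memory on a synthetic
multi-subject study and writes the report bundle: body-emotion percentage
tables for pixels and voxels, convergence tables against the whole-body and
per-segment sensorimotor maps, hotspot-congruence flags, ratings and
Bayes-factor summaries, the mask volumes, and a JSON provenance manifest.
Two runs with the same config and seed produce identical numeric tables.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .convergence import congruence_table, convergence_table, voxel_homunculus
from .glm import (
    ContrastSpec,
    build_design,
    contrast_effect_map,
    contrast_tmap,
    fit_first_level,
    scale_global,
    smooth_gaussian,
    threshold_cluster,
)
from .rsa_stats import RSAResult, bayes_one_sample, ratings_contrast, rsa_voxel_pixel
from .sensorimotor_maps import SegmentMaskSet, build_segment_mask_set
from .silhouette import body_emotion_matrix, make_body_template
from .synthetic_data import (
    SubjectDataset,
    default_ground_truth,
    jittered_fractions,
    plant_emotion_voxels,
    simulate_emotion_maps,
    simulate_subject,
)
from .types import BodyEmotionMatrix, EMOTIONS, MODALITIES, SEGMENTS, StatMap, mean_matrix

PERCENT_FORMAT = "%.2f"


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(f"[emomap] {msg}", file=sys.stderr)


# ---------------------------------------------------------------------------
# per-subject analysis steps
# ---------------------------------------------------------------------------


def localizer_first_level(
    subject: SubjectDataset, cfg: RunConfig
) -> dict[tuple[str, str], StatMap]:
    """Fit both localizer runs of one subject and return the eight
    segment x modality contrast images (condition vs rest)."""
    out: dict[tuple[str, str], StatMap] = {}
    for modality in MODALITIES:
        vol, design = subject.runs[modality]
        vol = scale_global(vol)
        if cfg.smooth_fwhm_mm > 0:
            vol = np.stack(
                [smooth_gaussian(vol[..., i], cfg.smooth_fwhm_mm, subject.grid.affine) for i in range(vol.shape[3])],
                axis=3,
            )
        X = build_design(design, highpass_s=cfg.highpass_s)
        fit = fit_first_level(vol, X, subject.grid.affine)
        for seg in SEGMENTS:
            c = ContrastSpec({f"{modality}_{seg}": 1.0}, label=f"{modality} {seg} > rest")
            out[(seg, modality)] = contrast_effect_map(fit, c)
    return out


def recall_emotion_maps_glm(subject: SubjectDataset, cfg: RunConfig) -> dict[str, StatMap]:
    """Single-subject emotion > neutral maps from the recall run, thresholded
    at uncorrected p (one-sided by default) without a cluster step."""
    vol, design = subject.runs["recall"]
    vol = scale_global(vol)
    X = build_design(design, highpass_s=cfg.highpass_s)
    fit = fit_first_level(vol, X, subject.grid.affine)
    maps = {}
    for emo in EMOTIONS:
        c = ContrastSpec({emo: 1.0, "neutral": -1.0}, label=f"{emo} recall > neutral recall")
        tmap = contrast_tmap(fit, c)
        maps[emo] = threshold_cluster(tmap, cfg.single_subject_p, None, tail=cfg.tail)
    return maps


def recall_emotion_effects(subject: SubjectDataset, cfg: RunConfig) -> dict[str, StatMap]:
    """Per-subject emotion > neutral contrast images (for group-level maps)."""
    vol, design = subject.runs["recall"]
    vol = scale_global(vol)
    X = build_design(design, highpass_s=cfg.highpass_s)
    fit = fit_first_level(vol, X, subject.grid.affine)
    return {
        emo: contrast_effect_map(fit, ContrastSpec({emo: 1.0, "neutral": -1.0}))
        for emo in EMOTIONS
    }


# ---------------------------------------------------------------------------
# result bundle
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: RunConfig
    masks: SegmentMaskSet
    tables: dict[str, pd.DataFrame]
    pixel_matrices: dict[str, BodyEmotionMatrix]
    voxel_matrices: dict[str, BodyEmotionMatrix]
    rsa: RSAResult
    reliability: tuple[float, float]
    manifest: dict = field(default_factory=dict)


def _bayes_table(mats: list[BodyEmotionMatrix]) -> pd.DataFrame:
    """Bayesian one-sample t-test per emotion x segment cell across subjects."""
    rows = []
    for emo in EMOTIONS:
        for seg in SEGMENTS:
            vals = np.array([m.values.loc[emo, seg] for m in mats], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < 2 or vals.std(ddof=1) == 0:
                rows.append({"emotion": emo, "segment": seg, "n": int(vals.size),
                             "mean_percent": float(vals.mean()) if vals.size else np.nan,
                             "t": np.nan, "p": np.nan, "bf10": np.nan})
                continue
            res = bayes_one_sample(vals)
            rows.append({"emotion": emo, "segment": seg, "n": res.n, "mean_percent": float(vals.mean()),
                         "t": res.t, "p": res.p, "bf10": res.bf10})
    return pd.DataFrame(rows)


def write_tables(tables: dict[str, pd.DataFrame], outdir: Path) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, float_format=PERCENT_FORMAT if name.endswith("percentages") else "%.6g")
        written.append(str(path))
    return written


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig, outdir: str | Path, quiet: bool = False) -> PipelineResult:
    """Run the full synthetic study and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = cfg.grid
    template = make_body_template()
    root_seq = np.random.SeedSequence(cfg.seed)
    subj_seqs = root_seq.spawn(cfg.n_subjects)
    stage_rng = np.random.default_rng(root_seq.spawn(1)[0])

    truth = default_ground_truth(grid, seed=cfg.seed, noise_sd=cfg.noise_sd)
    truth.effect_size = {k: v * cfg.effect_size for k, v in truth.effect_size.items()}
    if cfg.emotion_mode == "glm":
        truth = plant_emotion_voxels(truth, grid=grid)

    _log(f"simulating {cfg.n_subjects} subjects on grid {grid.shape}", quiet)
    subjects: list[SubjectDataset] = []
    subject_betas: dict[tuple[str, str], list[StatMap]] = {(s, m): [] for s in SEGMENTS for m in MODALITIES}
    for i, seq in enumerate(subj_seqs):
        sid = f"sub-{i + 1:02d}"
        subject = simulate_subject(
            sid, truth, template, seq, grid,
            subject_jitter_sd=cfg.subject_jitter_sd, phase_jitter_sd=cfg.phase_jitter_sd,
            n_localizer_repeats=cfg.n_localizer_repeats,
            n_episodes_per_emotion=cfg.n_episodes_per_emotion,
        )
        subjects.append(subject)
        for key, m in localizer_first_level(subject, cfg).items():
            subject_betas[key].append(m)

    _log("building sensorimotor masks (conjunction, segments, motor/tactile partition)", quiet)
    masks = build_segment_mask_set(
        subject_betas, cfg.voxel_p, cfg.cluster_p, cfg.n_permutations,
        rng=np.random.default_rng(stage_rng.integers(2**31)), connectivity=cfg.connectivity,
    )
    seg_masks = masks.segment_masks()
    plant_masks = {**{s: m for s, m in seg_masks.items()}, "whole_body": masks.whole_body}

    _log(f"emotion maps ({cfg.emotion_mode} mode)", quiet)
    per_subject_emotion: dict[str, dict[str, StatMap]] = {}
    if cfg.emotion_mode == "glm":
        for subject in subjects:
            per_subject_emotion[subject.subject_id] = recall_emotion_maps_glm(subject, cfg)
        group_emotion = {}
        emo_effects = {e: [] for e in EMOTIONS}
        for subject in subjects:
            for e, m in recall_emotion_effects(subject, cfg).items():
                emo_effects[e].append(m)
        from .glm import second_level_ttest

        for e in EMOTIONS:
            tmap = second_level_ttest(emo_effects[e])
            group_emotion[e] = threshold_cluster(
                tmap, cfg.voxel_p, cfg.cluster_p, subject_maps=emo_effects[e],
                n_permutations=cfg.n_permutations,
                rng=np.random.default_rng(stage_rng.integers(2**31)), tail=cfg.tail,
                connectivity=cfg.connectivity,
            )
    else:
        for i, subject in enumerate(subjects):
            rng = np.random.default_rng(subj_seqs[i].spawn(1)[0])
            fr = jittered_fractions(rng, subject.emotion_fractions, cfg.voxel_jitter_sd)
            per_subject_emotion[subject.subject_id] = simulate_emotion_maps(
                truth, plant_masks, grid, rng, fractions=fr
            )
        group_emotion = simulate_emotion_maps(
            truth, plant_masks, grid, np.random.default_rng(stage_rng.integers(2**31))
        )

    _log("convergence tables and voxel homunculi", quiet)
    conv_whole = convergence_table(
        group_emotion, {"sensorimotor_map": masks.whole_body}, mode=cfg.denominator_mode,
        provenance=masks.provenance,
    )
    conv_seg = convergence_table(group_emotion, seg_masks, mode=cfg.denominator_mode, provenance=masks.provenance)
    voxel_mats, voxel_group = voxel_homunculus(per_subject_emotion, masks)

    _log("silhouette digitization", quiet)
    pixel_pre = {
        s.subject_id: body_emotion_matrix(s.silhouettes_pre, template, s.subject_id, channel=cfg.channel)
        for s in subjects
    }
    pixel_post = {
        s.subject_id: body_emotion_matrix(s.silhouettes_post, template, s.subject_id, channel=cfg.channel)
        for s in subjects
    }
    from .silhouette import prepost_reliability

    reliability = prepost_reliability(list(pixel_pre.values()), list(pixel_post.values()))
    pixel_group = mean_matrix(list(pixel_post.values()))

    _log("ratings contrasts and RSA", quiet)
    ratings = pd.concat([s.ratings for s in subjects], ignore_index=True)
    bf_int = ratings_contrast(ratings, "intensity")
    bf_viv = ratings_contrast(ratings, "vividness")
    rsa = rsa_voxel_pixel(pixel_post, voxel_mats, mode=cfg.rsa_mode, fisher_z=cfg.rsa_fisher_z)

    tables = {
        "pixel_percentages": pixel_group.values,
        "convergence_wholebody": conv_whole.formatted(),
        "convergence_segments": conv_seg.formatted(),
        "voxel_percentages": voxel_group.values,
        "hotspot_congruence": congruence_table(pixel_group, voxel_group),
        "bayes_pixel_bodyparts": _bayes_table(list(pixel_post.values())),
        "bayes_voxel_bodyparts": _bayes_table(list(voxel_mats.values())),
        "ratings_bayes": pd.DataFrame(
            [
                {"measure": meas, "emotion": emo, "t": r.t, "df": r.df, "p": r.p, "bf10": r.bf10}
                for meas, res in (("intensity", bf_int), ("vividness", bf_viv))
                for emo, r in res.items()
            ]
        ).set_index(["measure", "emotion"]),
        "rsa_summary": pd.DataFrame(
            {
                "statistic": ["mean_r", "t", "df", "p", "n_subjects", "prepost_r", "prepost_p"],
                "value": [
                    float(rsa.per_subject_r.mean()), rsa.t, rsa.df, rsa.p,
                    len(rsa.per_subject_r), reliability[0], reliability[1],
                ],
            }
        ).set_index("statistic"),
        "rsa_per_subject": rsa.per_subject_r.to_frame(),
    }

    written = write_tables(tables, outdir / "tables")
    masks.save(outdir / "masks")
    emodir = outdir / "emotion_maps"
    emodir.mkdir(parents=True, exist_ok=True)
    for e, m in group_emotion.items():
        m.save(emodir / f"group_{e}.nii.gz")

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {
            "simulate": {"n_subjects": cfg.n_subjects, "grid": list(grid.shape)},
            "glm": {"highpass_s": cfg.highpass_s, "smooth_fwhm_mm": cfg.smooth_fwhm_mm},
            "masks": masks.provenance,
            "emotion_maps": {"mode": cfg.emotion_mode, "files": sorted(p.name for p in emodir.glob("*.nii.gz"))},
            "tables": sorted(Path(p).name for p in written),
        },
        "outputs": sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log(f"report written to {outdir}", quiet)
    return PipelineResult(
        config=cfg, masks=masks, tables=tables, pixel_matrices=pixel_post,
        voxel_matrices=voxel_mats, rsa=rsa, reliability=reliability, manifest=manifest,
    )
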