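"""Digitization of coloured body-silhouette self reports.

Participants colour a body silhouette in red where they feel increased bodily
activation during an emotion and in blue where they feel decreased activation.
This module turns a scanned page into quantitative per-segment statistics:

1. register the scan to a standard body template (2-D similarity transform
   maximising Mattes mutual information),
2. code coloured pixels as 1 / uncoloured as 0 inside the body boundary,
3. build activation - deactivation subtraction maps and pixelwise group
   t-maps,
4. compute the percentage of coloured pixels per body segment
   (face / hands / trunk / feet) and the pre- vs post-scan reliability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk
from scipy import stats
from skimage.color import rgb2gray, rgb2hsv
from skimage.draw import disk

from .types import BodyEmotionMatrix, EMOTIONS, SEGMENTS

SEGMENT_LABELS = {"face": 1, "hands": 2, "trunk": 3, "feet": 4}


@dataclass(frozen=True)
class BodyTemplate:
    """Binary body raster with a 4-segment labelling.

    ``segment_labels`` is 0 outside the body and 1..4 (face, hands, trunk,
    feet) inside; the labelled pixels tile the body mask exactly.
    """

    body_mask: np.ndarray
    segment_labels: np.ndarray

    def __post_init__(self) -> None:
        if self.body_mask.shape != self.segment_labels.shape:
            raise ValueError("body mask and segment labels must share one shape")
        inside = self.body_mask.astype(bool)
        if not np.array_equal(self.segment_labels > 0, inside):
            raise ValueError("segment labels must be nonzero exactly inside the body mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.body_mask.shape

    @property
    def pixel_count_inside(self) -> int:
        return int(np.count_nonzero(self.body_mask))

    def segment_mask(self, segment: str) -> np.ndarray:
        return self.segment_labels == SEGMENT_LABELS[segment]

    def segment_counts(self) -> dict[str, int]:
        return {s: int(np.count_nonzero(self.segment_mask(s))) for s in SEGMENTS}


def make_body_template(shape: tuple[int, int] = (220, 100)) -> BodyTemplate:
    """Build the package's standard body template programmatically.

    A stylised front-facing figure: circular head (face district), rectangular
    trunk, two arms (hands district) and two legs (feet district).  Districts
    tile the silhouette, so per-segment pixel counts sum to the body total.
    """
    h, w = shape
    if h < 110 or w < 50:
        raise ValueError("template raster too small for the stylised figure")
    labels = np.zeros(shape, dtype=np.uint8)
    cx = w // 2
    # face: head disk
    rr, cc = disk((int(0.14 * h), cx), int(0.10 * h), shape=shape)
    labels[rr, cc] = SEGMENT_LABELS["face"]
    # trunk: torso rectangle
    r0, r1 = int(0.25 * h), int(0.55 * h)
    c0, c1 = int(0.30 * w), int(0.70 * w)
    labels[r0:r1, c0:c1] = SEGMENT_LABELS["trunk"]
    # hands: two arm columns
    ar0, ar1 = int(0.27 * h), int(0.52 * h)
    aw = max(3, int(0.10 * w))
    labels[ar0:ar1, c0 - aw - 1 : c0 - 1] = SEGMENT_LABELS["hands"]
    labels[ar0:ar1, c1 + 1 : c1 + aw + 1] = SEGMENT_LABELS["hands"]
    # feet: two leg columns
    lr0, lr1 = int(0.55 * h), int(0.92 * h)
    lw = max(3, int(0.16 * w))
    labels[lr0:lr1, cx - lw - 1 : cx - 1] = SEGMENT_LABELS["feet"]
    labels[lr0:lr1, cx + 1 : cx + lw + 1] = SEGMENT_LABELS["feet"]
    return BodyTemplate(body_mask=(labels > 0).astype(np.uint8), segment_labels=labels)


@dataclass
class Silhouette:
    """Binary activation / deactivation rasters for one subject, phase, emotion."""

    activation: np.ndarray
    deactivation: np.ndarray
    registered: bool = True
    subject_id: str = ""
    phase: str = "pre"  # "pre" | "post"
    emotion: str = ""

    def __post_init__(self) -> None:
        self.activation = np.asarray(self.activation).astype(np.uint8)
        self.deactivation = np.asarray(self.deactivation).astype(np.uint8)
        if self.activation.shape != self.deactivation.shape:
            raise ValueError("activation and deactivation rasters must share one shape")
        for name, arr in (("activation", self.activation), ("deactivation", self.deactivation)):
            if not np.all(np.isin(np.unique(arr), (0, 1))):
                raise ValueError(f"{name} raster must be binary")
        if self.phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")


def subtraction_map(s: Silhouette) -> np.ndarray:
    """Activation minus deactivation per pixel, valued in {-1, 0, 1}."""
    return s.activation.astype(np.int8) - s.deactivation.astype(np.int8)


def segment_percentages(
    source: Silhouette | np.ndarray,
    template: BodyTemplate,
    channel: str = "activation",
) -> dict[str, float]:
    """Percentage of coloured pixels per body segment.

    ``channel`` selects what counts as coloured: ``activation`` /
    ``deactivation`` count that raster's 1-pixels; ``subtraction`` counts
    pixels whose activation-minus-deactivation value is +1.
    """
    counts = template.segment_counts()
    if any(c == 0 for c in counts.values()):
        raise ValueError("template has an empty body segment")
    if isinstance(source, Silhouette):
        if channel == "activation":
            raster = source.activation
        elif channel == "deactivation":
            raster = source.deactivation
        elif channel == "subtraction":
            raster = (subtraction_map(source) == 1).astype(np.uint8)
        else:
            raise ValueError(f"unknown channel {channel!r}")
    else:
        raster = (np.asarray(source) == 1).astype(np.uint8)
    out = {}
    for seg in SEGMENTS:
        m = template.segment_mask(seg)
        out[seg] = 100.0 * float(np.count_nonzero(raster[m])) / counts[seg]
    return out


def body_emotion_matrix(
    silhouettes: dict[str, Silhouette],
    template: BodyTemplate,
    subject_id: str = "group",
    channel: str = "activation",
    emotions: Sequence[str] = EMOTIONS,
) -> BodyEmotionMatrix:
    """Assemble the 5 emotions x 4 segments pixel-percentage matrix for one subject."""
    entries = {e: segment_percentages(silhouettes[e], template, channel=channel) for e in emotions}
    return BodyEmotionMatrix.from_dict(entries, source="pixels", subject_id=subject_id, emotions=emotions)


def group_pixel_tmap(rasters: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise one-sample t across subjects of subtraction rasters.

    Returns ``(tmap, degenerate)`` where ``degenerate`` flags pixels with a
    nonzero mean but zero between-subject variance (t undefined; set to 0).
    """
    if len(rasters) < 3:
        raise ValueError("need at least 3 subjects for a group t-map")
    stack = np.stack([np.asarray(r, dtype=float) for r in rasters])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0) & (mean != 0)
    t[sd == 0] = 0.0
    return t, degenerate


def prepost_reliability(
    pre_mats: Sequence[BodyEmotionMatrix], post_mats: Sequence[BodyEmotionMatrix]
) -> tuple[float, float]:
    """Pearson correlation between matched pre- and post-scan percentage vectors.

    Concatenates all (subject x emotion x segment) entries and returns
    ``(r, p)`` with the p-value from the usual t transform of r.
    """
    if len(pre_mats) != len(post_mats) or not pre_mats:
        raise ValueError("pre and post matrix lists must be matched and nonempty")
    pre = np.concatenate([m.flat() for m in pre_mats])
    post = np.concatenate([m.flat() for m in post_mats])
    keep = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[keep], post[keep]
    if pre.std() == 0 or post.std() == 0:
        raise ValueError("zero variance in pre or post percentages; correlation undefined")
    r, p = stats.pearsonr(pre, post)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# colour coding of scanned pages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorRules:
    """HSV windows deciding which scanned pixels count as red/blue colouring.

    Hues are in degrees on the usual colour wheel; pixels below the
    saturation or value floors (grey body fill, white page) are uncoloured.
    """

    red_hue_max_deg: float = 20.0
    red_hue_min_deg: float = 340.0
    blue_hue_range_deg: tuple[float, float] = (200.0, 260.0)
    min_saturation: float = 0.3
    min_value: float = 0.2


DEFAULT_COLOR_RULES = ColorRules()


def code_pixels(
    rgb: np.ndarray,
    template: BodyTemplate,
    rules: ColorRules = DEFAULT_COLOR_RULES,
    registered: bool = True,
    **meta,
) -> Silhouette:
    """Code a registered colour raster into binary activation/deactivation maps.

    Red-dominant pixels (by the HSV rule) become activation 1, blue-dominant
    pixels deactivation 1; anything else, and every pixel outside the body
    boundary, is 0.  The red and blue hue windows are disjoint, so no pixel
    can be both.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an RGB raster")
    if rgb.shape[:2] != template.shape:
        raise ValueError("raster and template shapes differ; register first")
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    hsv = rgb2hsv(rgb[:, :, :3])
    hue_deg = hsv[:, :, 0] * 360.0
    sat_ok = (hsv[:, :, 1] >= rules.min_saturation) & (hsv[:, :, 2] >= rules.min_value)
    red = sat_ok & ((hue_deg < rules.red_hue_max_deg) | (hue_deg > rules.red_hue_min_deg))
    blue = sat_ok & (hue_deg >= rules.blue_hue_range_deg[0]) & (hue_deg <= rules.blue_hue_range_deg[1])
    body = template.body_mask.astype(bool)
    return Silhouette(
        activation=(red & body).astype(np.uint8),
        deactivation=(blue & body).astype(np.uint8),
        registered=registered,
        **meta,
    )


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityParams:
    """2-D similarity transform mapping template coordinates to scan coordinates.

    ``shift_cols`` / ``shift_rows`` are the translation in pixels (array
    column / row axes), ``angle_deg`` the rotation about the template centre,
    ``scale`` the isotropic scale factor.
    """

    shift_cols: float
    shift_rows: float
    angle_deg: float
    scale: float
    final_metric: float = float("nan")


def _scan_foreground(scan: np.ndarray) -> np.ndarray:
    """Ink density of a scanned page: 0 on white paper, positive on the figure."""
    scan = np.asarray(scan, dtype=float)
    if scan.ndim == 3:
        if scan.max() > 1.0:
            scan = scan / 255.0
        gray = rgb2gray(scan[:, :, :3])
    else:
        gray = scan / scan.max() if scan.max() > 1.0 else scan
    return 1.0 - gray


def register_to_template(
    scan: np.ndarray,
    template: BodyTemplate,
    n_histogram_bins: int = 50,
    sampling_fraction: float = 0.5,
    seed: int = 12345,
) -> tuple[np.ndarray, SimilarityParams]:
    """Register a scanned silhouette page to the body template.

    Maximises Mattes mutual information between the template body mask and
    the scan's ink density under a 2-D similarity transform (rotation,
    translation, isotropic scale), then resamples the scan into template
    space with nearest-neighbour interpolation so colours stay crisp.

    Returns the registered raster (same shape as the template) and the
    recovered :class:`SimilarityParams`.  Raises ``RuntimeError`` when the
    scan has no usable foreground or the optimiser fails to improve the
    metric (e.g. a blank page).
    """
    fg = _scan_foreground(scan)
    if np.count_nonzero(fg > 0.05) < 50:
        raise RuntimeError("scan has no usable foreground; cannot register a blank page")

    fixed = sitk.GetImageFromArray(template.body_mask.astype(np.float32))
    moving = sitk.GetImageFromArray(fg.astype(np.float32))

    initial = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Similarity2DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=n_histogram_bins)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(sampling_fraction, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        final = reg.Execute(fixed, moving)
    except RuntimeError as exc:  # optimizer blow-up on degenerate content
        raise RuntimeError(f"registration failed to converge: {exc}") from None
    metric = reg.GetMetricValue()
    if not np.isfinite(metric) or metric > -1e-3:
        raise RuntimeError(f"registration did not converge (final Mattes MI metric {metric:.4g})")

    params = _similarity_params(final, template, metric)

    scan_arr = np.asarray(scan, dtype=float)
    if scan_arr.ndim == 2:
        scan_arr = scan_arr[:, :, None]
    if scan_arr.max() > 1.0:
        scan_arr = scan_arr / 255.0
    channels = []
    for c in range(scan_arr.shape[2]):
        mov_c = sitk.GetImageFromArray(scan_arr[:, :, c].astype(np.float32))
        res = sitk.Resample(mov_c, fixed, final, sitk.sitkNearestNeighbor, 1.0)
        channels.append(sitk.GetArrayFromImage(res))
    registered = np.stack(channels, axis=-1)
    if registered.shape[2] == 1:
        registered = registered[:, :, 0]
    return registered, params


def _similarity_params(transform: sitk.Transform, template: BodyTemplate, metric: float) -> SimilarityParams:
    """Express a fitted transform as translation/rotation/scale about the template centre."""
    sim = sitk.Similarity2DTransform()
    flat = sitk.CompositeTransform(transform).GetBackTransform() if transform.GetName() == "CompositeTransform" else transform
    sim.SetParameters(flat.GetParameters())
    sim.SetFixedParameters(flat.GetFixedParameters())
    h, w = template.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # sitk (x=col, y=row)
    moved = np.array(sim.TransformPoint(tuple(center)))
    shift = moved - center
    return SimilarityParams(
        shift_cols=float(shift[0]),
        shift_rows=float(shift[1]),
        angle_deg=float(np.degrees(sim.GetAngle())),
        scale=float(sim.GetScale()),
        final_metric=float(metric),
    )


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------


def write_silhouette_png(s: Silhouette, path: str | Path) -> None:
    """Write a coded silhouette as 8-bit RGB PNG (R=activation, G=deactivation)."""
    h, w = s.activation.shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:, :, 0] = s.activation * 255
    img[:, :, 1] = s.deactivation * 255
    iio.imwrite(Path(path), img)


def read_silhouette_png(path: str | Path, **meta) -> Silhouette:
    img = iio.imread(Path(path))
    return Silhouette(
        activation=(img[:, :, 0] > 127).astype(np.uint8),
        deactivation=(img[:, :, 1] > 127).astype(np.uint8),
        **meta,
    )


def write_template_png(template: BodyTemplate, path: str | Path) -> None:
    iio.imwrite(Path(path), template.segment_labels.astype(np.uint8))


def read_template_png(path: str | Path) -> BodyTemplate:
    labels = np.asarray(iio.imread(Path(path)))
    if labels.ndim == 3:
        labels = labels[:, :, 0]
    return BodyTemplate(body_mask=(labels > 0).astype(np.uint8), segment_labels=labels.astype(np.uint8))
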