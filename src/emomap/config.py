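"""Run configuration for pipeline executions.

One YAML file (or keyword overrides) controls grid, thresholds, permutation
counts, and analysis-mode switches; invariants are validated on construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .types import GridSpec


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings.

    Thresholds follow the group-analysis convention of voxelwise p < 0.001
    with cluster-level FWER p < 0.05 (permutation-based), and single-subject
    maps thresholded at uncorrected p < 0.05.
    """

    n_subjects: int = 12
    grid_shape: tuple[int, int, int] = (32, 32, 24)
    voxel_size_mm: float = 2.0
    voxel_p: float = 0.001
    cluster_p: float | None = 0.05
    single_subject_p: float = 0.05
    n_permutations: int = 200
    highpass_s: float = 128.0
    smooth_fwhm_mm: float = 0.0
    n_localizer_repeats: int = 4
    n_episodes_per_emotion: int = 3
    one_sided: bool = True
    connectivity: int = 26
    denominator_mode: str = "mask"  # "mask" | "emotion"
    rsa_mode: str = "direct"  # "direct" | "rdm"
    rsa_fisher_z: bool = True
    channel: str = "activation"  # "activation" | "subtraction"
    emotion_mode: str = "planted"  # "planted" (direct binary maps) | "glm" (full recall-run GLM)
    noise_sd: float = 1.0
    effect_size: float = 1.0
    subject_jitter_sd: float = 0.08
    phase_jitter_sd: float = 0.03
    voxel_jitter_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_p", "single_subject_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.cluster_p is not None:
            if not 0.0 < self.cluster_p < 1.0:
                raise ValueError("cluster_p must lie in (0, 1) or be null")
            if self.n_permutations < 100:
                raise ValueError("n_permutations must be >= 100 when cluster correction is enabled")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects for group inference")
        if self.denominator_mode not in ("mask", "emotion"):
            raise ValueError("denominator_mode must be 'mask' or 'emotion'")
        if self.rsa_mode not in ("direct", "rdm"):
            raise ValueError("rsa_mode must be 'direct' or 'rdm'")
        if self.channel not in ("activation", "subtraction"):
            raise ValueError("channel must be 'activation' or 'subtraction'")
        if self.emotion_mode not in ("planted", "glm"):
            raise ValueError("emotion_mode must be 'planted' or 'glm'")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(shape=tuple(self.grid_shape), voxel_size_mm=self.voxel_size_mm)

    @property
    def tail(self) -> str:
        return "greater" if self.one_sided else "two-sided"

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
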