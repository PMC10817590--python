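"""Configuration dataclasses for every pipeline stage.

All stages are driven by plain dataclasses that can be populated from a single
YAML document (see :func:`load_run_config`).  Each class validates its own
invariants on construction and raises :class:`ConfigurationError` otherwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .constants import EYES, LAYERS, QUADRANTS, SEXES
from .errors import ConfigurationError

N_LAYERS = len(LAYERS)


@dataclass(frozen=True)
class CohortConfig:
    """Demographics of a synthetic cohort: two sex-balanced groups of healthy
    adults whose ages follow a truncated normal distribution (years)."""

    n_per_group: int = 49
    age_mean: float = 42.5
    age_sd: float = 16.3
    age_min: float = 19.0
    age_max: float = 74.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if not (self.age_min <= self.age_mean <= self.age_max):
            raise ConfigurationError("need age_min <= age_mean <= age_max")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")


@dataclass(frozen=True)
class VolumeConfig:
    """Geometry and intensity statistics of a synthetic macular OCT cube.

    The en-face grid is ``n_bscan`` slow-axis slices of ``n_ascan`` depth
    profiles (the clinical 512 x 128 macular cube by default); depth is
    ``n_depth`` voxels.  Six neuroretinal layers are delimited by seven
    interface surfaces; inner layers thin towards the fovea.  Per-layer
    reflectivity is a mean level plus a stationary correlated texture field
    plus white noise, all in arbitrary 0-255 reflectivity units.

    Correlation lengths and the foveal radius are expressed in *isotropic*
    en-face pixels, i.e. units of the 128 x 128 grid the texture analysis
    runs on; along the 512-column A-scan axis they are scaled by the grid
    aspect ratio internally.
    """

    n_bscan: int = 128
    n_ascan: int = 512
    n_depth: int = 64
    layer_mean_thickness: Sequence[float] = (6.0, 7.0, 6.0, 6.0, 5.0, 12.0)
    foveal_dip_depth: float = 24.0
    foveal_dip_radius: float = 8.0
    interface_smoothness: float = 12.0
    interface_noise_sd: float = 0.8
    intensity_base: Sequence[float] = (160.0, 110.0, 120.0, 90.0, 130.0, 70.0)
    texture_corr_length: Sequence[float] = (2.0,) * N_LAYERS
    texture_sd: Sequence[float] = (10.0,) * N_LAYERS
    noise_sd: float = 5.0
    #: Optional between-participant heterogeneity of the texture parameters,
    #: shared by a participant's two eyes: log-normal coefficients of
    #: variation for the per-layer texture sd and correlation length, and an
    #: additive normal jitter (reflectivity units) on the per-layer mean
    #: level.  The default cohort is homogeneous (zero values): participant
    #: latents shared across the en-face plane induce long-range feature
    #: correlations that defeat localised effect injection, so heterogeneity
    #: is opt-in.
    texture_sd_cv: float = 0.0
    texture_corr_length_cv: float = 0.0
    intensity_base_jitter: float = 0.0

    def __post_init__(self):
        for name in ("layer_mean_thickness", "intensity_base",
                     "texture_corr_length", "texture_sd"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != N_LAYERS:
                raise ConfigurationError(f"{name} must have {N_LAYERS} entries")
            object.__setattr__(self, name, vals)
        if min(self.layer_mean_thickness) < 1:
            raise ConfigurationError("layer mean thicknesses must be >= 1 voxel")
        if any(s < 0 for s in self.texture_sd) or self.noise_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.interface_noise_sd < 0:
            raise ConfigurationError("interface_noise_sd must be >= 0")
        if min(self.texture_sd_cv, self.texture_corr_length_cv,
               self.intensity_base_jitter) < 0:
            raise ConfigurationError("heterogeneity parameters must be >= 0")
        if self.n_bscan < 1 or self.n_ascan < 1 or self.n_depth < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if self.top_margin < 2.0:
            raise ConfigurationError(
                "layers cannot fit in n_depth: need >= 2 voxels of margin "
                "above and below the retina slab"
            )

    @property
    def total_mean_thickness(self) -> float:
        return float(sum(self.layer_mean_thickness))

    @property
    def top_margin(self) -> float:
        """Depth of the vitreous gap above the first interface."""
        return (self.n_depth - self.total_mean_thickness) / 2.0

    @property
    def aspect(self) -> float:
        """A-scan pixels per isotropic en-face pixel."""
        return self.n_ascan / self.n_bscan


@dataclass(frozen=True)
class EffectSpec:
    """An injected right-vs-left texture difference, restricted to one
    (sex, eye, layer, quadrant) cell.

    ``delta_corr_length`` and ``delta_sd`` are added to the target layer's
    texture parameters inside the target quadrant's en-face footprint of the
    matching eyes only.  Quadrants are named in the post-flip frame, so a Q4
    effect lands in the nasal-inferior region of both an OD and an OS scan.
    Zero deltas are a no-op by construction.
    """

    target_sex: str
    target_eye: str
    target_layer: str
    target_quadrant: str
    delta_corr_length: float = 0.0
    delta_sd: float = 0.0

    def __post_init__(self):
        if self.target_sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.target_sex!r}")
        if self.target_eye not in EYES:
            raise ConfigurationError(f"unknown eye {self.target_eye!r}")
        if self.target_layer not in LAYERS:
            raise ConfigurationError(f"unknown layer {self.target_layer!r}")
        if self.target_quadrant not in QUADRANTS:
            raise ConfigurationError(f"unknown quadrant {self.target_quadrant!r}")


@dataclass(frozen=True)
class GLCMConfig:
    """Grey-level co-occurrence settings: pixel distance, quantization depth,
    and the dialect switches for ambiguous feature definitions."""

    distance: int = 1
    n_levels: int = 16
    #: "per_image" min-max scaling over the valid pixels, or "fixed" to use
    #: ``fixed_range`` for every image.
    quantization: str = "per_image"
    fixed_range: tuple[float, float] = (0.0, 255.0)
    #: Sum Variance is a second moment of the level-sum distribution taken
    #: about Sum Average (the erratum-corrected reading) or, if set to
    #: "sum_entropy", about Sum Entropy as literally printed by Haralick.
    sum_variance_about: str = "sum_average"

    def __post_init__(self):
        if self.distance < 1:
            raise ConfigurationError("distance must be >= 1")
        if self.n_levels < 2:
            raise ConfigurationError("n_levels must be >= 2")
        if self.quantization not in ("per_image", "fixed"):
            raise ConfigurationError("quantization must be per_image or fixed")
        if self.sum_variance_about not in ("sum_average", "sum_entropy"):
            raise ConfigurationError("bad sum_variance_about")


@dataclass(frozen=True)
class StatsConfig:
    """Parameters of the decorrelation / paired-testing stage."""

    alpha: float = 0.05
    sw_level: float = 0.10
    r_threshold: float = 0.5
    storey_lambda: float = 0.5
    storey_t: float = 0.05
    #: If True, re-rank the remaining correlated features after every discard
    #: instead of traversing a single static ranking.
    recompute_after_discard: bool = False
    #: Shapiro-Wilk gate on the raw per-eye samples ("eyes") or on the paired
    #: OD-OS differences ("differences").
    normality_on: str = "eyes"

    def __post_init__(self):
        if not (0 < self.r_threshold < 1):
            raise ConfigurationError("r_threshold must be in (0, 1)")
        if not (0 <= self.storey_lambda < 1):
            raise ConfigurationError("storey_lambda must be in [0, 1)")
        if not (0 < self.alpha < 1) or not (0 < self.sw_level < 1):
            raise ConfigurationError("alpha and sw_level must be in (0, 1)")
        if self.normality_on not in ("eyes", "differences"):
            raise ConfigurationError("normality_on must be eyes or differences")


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    volume: VolumeConfig = field(default_factory=VolumeConfig)
    effects: tuple[EffectSpec, ...] = ()
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    layers: tuple[str, ...] = LAYERS
    seed: int = 0
    write_volumes: bool = False

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple(self.effects))
        object.__setattr__(self, "layers", tuple(self.layers))
        for layer in self.layers:
            if layer not in LAYERS:
                raise ConfigurationError(f"unknown layer {layer!r}")
        if not self.layers:
            raise ConfigurationError("at least one layer required")


def _as_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(cfg: RunConfig) -> str:
    """Stable hex digest of a run configuration, for provenance stamping."""
    canon = yaml.safe_dump(_as_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; missing keys fall back to the
    defaults.  ``effects`` is a list of mappings with EffectSpec fields.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    if "cohort" in doc:
        kwargs["cohort"] = CohortConfig(**doc["cohort"])
    if "volume" in doc:
        kwargs["volume"] = VolumeConfig(**doc["volume"])
    if "glcm" in doc:
        kwargs["glcm"] = GLCMConfig(**doc["glcm"])
    if "stats" in doc:
        kwargs["stats"] = StatsConfig(**doc["stats"])
    if "effects" in doc:
        kwargs["effects"] = tuple(EffectSpec(**e) for e in doc["effects"])
    for key in ("layers", "seed", "write_volumes"):
        if key in doc:
            kwargs[key] = doc[key]
    return RunConfig(**kwargs)
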