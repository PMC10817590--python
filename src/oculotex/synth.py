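"""Synthetic segmented OCT volume generator.

Emulates the data the analysis assumes: per-eye macular cubes with six
neuroretinal layers delimited by seven smooth interface surfaces, radially
symmetric foveal thinning of the inner layers, per-layer stationary
reflectivity texture (Gaussian-smoothed white noise with a configurable
correlation length and standard deviation), and additive white noise.

Interocular texture effects can be injected into one (sex, eye, layer,
quadrant) cell: inside the target quadrant's footprint the layer's texture
field is re-derived *from the same white noise* with the perturbed
parameters, so a zero-delta effect is a bit-exact no-op and voxels outside
the target region are bit-identical to the no-effect dataset.

Every (participant, eye) pair draws from its own RNG substream keyed by
(seed, participant id, eye); adding participants never perturbs existing
ones.
"""

from __future__ import annotations

import zlib
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .cohort import ParticipantRecord
from .config import EffectSpec, VolumeConfig
from .constants import EYES, LAYERS
from .errors import ConfigurationError
from .grid import ISO_SIZE, quadrant_pixel_ranges
from .projection import LayerInterfaces, OCTVolume

N_INNER_LAYERS = 4  # RNFL..INL thin towards the foveal centre

VITREOUS_INTENSITY = 5.0
SUBRETINAL_INTENSITY = 40.0


def eye_rng(seed: int, participant_id: str, eye: str) -> np.random.Generator:
    """Independent RNG substream for one (seed, participant, eye)."""
    key = zlib.crc32(participant_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), key, EYES.index(eye)])
    )


def participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Substream for participant-level latent traits shared by both eyes."""
    key = zlib.crc32(participant_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, 2]))


def participant_texture_params(participant_id: str, vconfig: VolumeConfig,
                               seed: int) -> dict[str, np.ndarray]:
    """Per-layer texture parameters of one participant.

    Real cohorts are heterogeneous: participants differ in reflectivity
    texture, and a participant's two eyes share that individuality.  The
    per-layer texture sd and correlation length get log-normal multipliers
    (so zero population values stay zero) and the mean level an additive
    jitter, all drawn from a participant-keyed substream so both eyes see
    identical traits.
    """
    rng = participant_rng(seed, participant_id)
    n = len(LAYERS)
    sd_mult = np.exp(rng.normal(0.0, vconfig.texture_sd_cv, n)) \
        if vconfig.texture_sd_cv > 0 else np.ones(n)
    cl_mult = np.exp(rng.normal(0.0, vconfig.texture_corr_length_cv, n)) \
        if vconfig.texture_corr_length_cv > 0 else np.ones(n)
    base_jit = rng.normal(0.0, vconfig.intensity_base_jitter, n) \
        if vconfig.intensity_base_jitter > 0 else np.zeros(n)
    return {
        "texture_sd": np.asarray(vconfig.texture_sd) * sd_mult,
        "texture_corr_length": np.asarray(vconfig.texture_corr_length) * cl_mult,
        "intensity_base": np.asarray(vconfig.intensity_base) + base_jit,
    }


def _smooth_standardised(noise: np.ndarray, corr_length: float,
                         aspect: float) -> np.ndarray:
    """Smooth white noise to the given isotropic correlation length and
    standardise to zero mean, unit variance.  Infinite correlation length
    (or a zero-variance result) degenerates to a flat zero field."""
    if not np.isfinite(corr_length):
        return np.zeros_like(noise)
    if corr_length > 0:
        field = gaussian_filter(noise, sigma=(corr_length, corr_length * aspect),
                                mode="reflect", truncate=3.0)
    else:
        field = noise
    sd = field.std()
    if sd == 0:
        return np.zeros_like(field)
    return (field - field.mean()) / sd


def generate_interfaces(vconfig: VolumeConfig,
                        rng: np.random.Generator) -> LayerInterfaces:
    """Generate seven ordered interface surfaces on the en-face grid.

    Layer thicknesses are the configured means plus a smooth perturbation,
    floored at one voxel; the foveal dip then shrinks the four inner layers
    proportionally to their local thickness (down to zero at a deep dip).
    """
    nb, na = vconfig.n_bscan, vconfig.n_ascan
    aspect = vconfig.aspect

    # Interface perturbations are generated on the coarse isotropic grid and
    # replicated along the A-scan axis when the aspect ratio is integral:
    # at the configured smoothness the replication step is far below the
    # correlation length, and filtering the small grid is much cheaper.
    coarse = aspect.is_integer() and aspect > 1

    def field() -> np.ndarray:
        if coarse:
            f = _smooth_standardised(
                rng.standard_normal((nb, na // int(aspect))),
                vconfig.interface_smoothness, 1.0,
            )
            return np.repeat(f, int(aspect), axis=1)
        return _smooth_standardised(
            rng.standard_normal((nb, na)), vconfig.interface_smoothness, aspect
        )

    z0 = vconfig.top_margin + vconfig.interface_noise_sd * field()
    thickness = np.empty((len(LAYERS), nb, na))
    for k, mean_t in enumerate(vconfig.layer_mean_thickness):
        thickness[k] = np.clip(mean_t + vconfig.interface_noise_sd * field(), 1.0, None)

    # Radial Gaussian foveal depression of the inner layers.
    if vconfig.foveal_dip_depth > 0:
        b = np.arange(nb)[:, None]
        a = np.arange(na)[None, :]
        rr2 = (b - (nb - 1) / 2.0) ** 2 + ((a - (na - 1) / 2.0) / aspect) ** 2
        dip = vconfig.foveal_dip_depth * np.exp(
            -rr2 / (2.0 * vconfig.foveal_dip_radius ** 2)
        )
        inner_total = thickness[:N_INNER_LAYERS].sum(axis=0)
        factor = np.clip(1.0 - dip / inner_total, 0.0, 1.0)
        thickness[:N_INNER_LAYERS] *= factor

    z = np.empty((len(LAYERS) + 1, nb, na))
    z[0] = np.clip(z0, 0.0, None)
    np.cumsum(thickness, axis=0, out=z[1:])
    z[1:] += z[0]
    if z[-1].max() > vconfig.n_depth:
        if z[-1].min() > vconfig.n_depth:
            raise ConfigurationError("layers cannot fit in n_depth")
        z = np.minimum(z, vconfig.n_depth)
    return LayerInterfaces(z=z)


def quadrant_footprint(quadrant: str, eye: str,
                       vconfig: VolumeConfig) -> tuple[slice, slice]:
    """En-face footprint of a (post-flip) quadrant in raw volume coordinates.

    Rows index B-scans, columns index A-scans of the *unflipped* scan, so a
    left-eye footprint is the mirror image of the right-eye one along the
    A-scan axis.
    """
    if eye not in EYES:
        raise ConfigurationError(f"unknown eye {eye!r}")
    (r0, r1), (c0, c1) = quadrant_pixel_ranges(quadrant)
    rs = vconfig.n_bscan / ISO_SIZE
    cs = vconfig.n_ascan / ISO_SIZE
    rows = slice(round(r0 * rs), round(r1 * rs))
    cols = slice(round(c0 * cs), round(c1 * cs))
    if eye == "OS":
        cols = slice(vconfig.n_ascan - cols.stop, vconfig.n_ascan - cols.start)
    return rows, cols


def generate_eye_volume(
    participant: ParticipantRecord,
    eye: str,
    vconfig: VolumeConfig,
    effects: Sequence[EffectSpec] = (),
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[OCTVolume, LayerInterfaces]:
    """Generate one segmented synthetic eye scan.

    Voxels of layer L take the value intensity_base[L] plus a depth-constant
    correlated en-face texture field (rescaled to texture_sd[L]) plus
    independent white noise, clipped to [0, 255].  Matching effects replace
    the target layer's field inside the target quadrant footprint with the
    field re-smoothed/re-scaled at the perturbed parameters.

    With ``seed`` given, per-layer texture parameters are the participant's
    own traits (see :func:`participant_texture_params`; identical for a
    participant's two eyes, population values under zero heterogeneity).
    With only ``rng`` given there is no participant key, so population-level
    parameters are used directly.
    """
    if eye not in EYES:
        raise ConfigurationError(f"unknown eye {eye!r}")
    if rng is None:
        if seed is None:
            raise ConfigurationError("either seed or rng must be given")
        rng = eye_rng(seed, participant.participant_id, eye)
    if seed is not None:
        params = participant_texture_params(participant.participant_id,
                                            vconfig, seed)
    else:  # no participant key available: population-level parameters
        params = {
            "texture_sd": np.asarray(vconfig.texture_sd),
            "texture_corr_length": np.asarray(vconfig.texture_corr_length),
            "intensity_base": np.asarray(vconfig.intensity_base),
        }

    interfaces = generate_interfaces(vconfig, rng)
    nb, nd, na = vconfig.n_bscan, vconfig.n_depth, vconfig.n_ascan
    aspect = vconfig.aspect

    fields = np.empty((len(LAYERS) + 2, nb, na), dtype=np.float32)
    fields[0] = VITREOUS_INTENSITY
    fields[-1] = SUBRETINAL_INTENSITY
    for k, layer in enumerate(LAYERS):
        noise = rng.standard_normal((nb, na))
        cl = float(params["texture_corr_length"][k])
        sd = float(params["texture_sd"][k])
        base = float(params["intensity_base"][k])
        layer_field = base + sd * _smooth_standardised(noise, cl, aspect)
        for eff in effects:
            if (eff.target_sex == participant.sex and eff.target_eye == eye
                    and eff.target_layer == layer):
                rows, cols = quadrant_footprint(eff.target_quadrant, eye, vconfig)
                alt = base + (sd + eff.delta_sd) * _smooth_standardised(
                    noise, cl + eff.delta_corr_length, aspect
                )
                layer_field[rows, cols] = alt[rows, cols]
        fields[k + 1] = layer_field

    # Region index per voxel: 0 = vitreous, 1..6 = layers, 7 = below retina.
    depth = np.arange(nd, dtype=np.int16)[None, :, None]
    region = np.zeros((nb, nd, na), dtype=np.int8)
    buf = np.empty((nb, nd, na), dtype=bool)
    for k in range(len(LAYERS) + 1):
        ztop = np.ceil(interfaces.z[k]).astype(np.int16)[:, None, :]
        np.greater_equal(depth, ztop, out=buf)
        region += buf

    b_idx = np.arange(nb)[:, None, None]
    a_idx = np.arange(na)[None, None, :]
    intensity = fields[region, b_idx, a_idx]
    if vconfig.noise_sd > 0:
        intensity = intensity + vconfig.noise_sd * rng.standard_normal(
            (nb, nd, na), dtype=np.float32
        )
    np.clip(intensity, 0.0, 255.0, out=intensity)
    volume = OCTVolume(intensity=intensity, eye=eye,
                       participant_id=participant.participant_id)
    return volume, interfaces


def generate_cohort_volumes(
    cohort: Iterable[ParticipantRecord],
    vconfig: VolumeConfig,
    effects: Sequence[EffectSpec] = (),
    *,
    seed: int,
):
    """Yield (participant, eye, volume, interfaces) for every scan of a
    cohort, both eyes per participant, deterministically under the seed."""
    for participant in cohort:
        for eye in EYES:
            volume, interfaces = generate_eye_volume(
                participant, eye, vconfig, effects, seed=seed
            )
            yield participant, eye, volume, interfaces
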