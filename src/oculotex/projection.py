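"""Per-layer mean value fundus (MVF) projection.

An OCT macular cube is a stack of B-scans; each A-scan is one depth profile.
For a given retinal layer, the MVF image assigns to every en-face position
the depth-wise average of the voxels between the layer's two delimiting
interfaces.  Images are stored with rows = B-scans (superior to inferior)
and columns = A-scans (temporal to nasal for a right eye); left-eye images
are flipped horizontally so the temporal/nasal sides coincide across eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import EYES, LAYERS
from .errors import DataError


@dataclass
class OCTVolume:
    """3-D intensity grid, axes (b-scan, depth, a-scan), values in [0, 255]."""

    intensity: np.ndarray
    eye: str
    participant_id: str

    def __post_init__(self):
        if self.intensity.ndim != 3:
            raise DataError("volume intensity must be 3-D (bscan, depth, ascan)")
        if self.eye not in EYES:
            raise DataError(f"unknown eye {self.eye!r}")
        if not np.all(np.isfinite(self.intensity)):
            raise DataError("volume contains non-finite intensities")

    @property
    def n_bscan(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_ascan(self) -> int:
        return self.intensity.shape[2]


@dataclass
class LayerInterfaces:
    """Seven ordered depth surfaces z[k] (fractional voxels), axes
    (interface, b-scan, a-scan); layer k occupies [z_k, z_{k+1})."""

    z: np.ndarray

    def __post_init__(self):
        if self.z.ndim != 3 or self.z.shape[0] != len(LAYERS) + 1:
            raise DataError("interfaces must have shape (7, n_bscan, n_ascan)")
        if np.any(np.diff(self.z, axis=0) < 0):
            raise DataError("interface surfaces must be ordered z_k <= z_{k+1}")


@dataclass
class MVFImage:
    """2-D en-face mean-reflectivity image for one layer of one eye.

    ``values`` has rows = B-scans, columns = A-scans.  Pixels whose depth
    span is empty (zero layer thickness, e.g. inner layers at the foveal
    centre) are masked invalid and carry NaN, never a silent zero.
    """

    values: np.ndarray
    mask: np.ndarray
    layer: str
    eye: str
    participant_id: str = ""
    flipped: bool = False

    def __post_init__(self):
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise DataError("values and mask must be matching 2-D arrays")


def _depth_cumsum(volume: OCTVolume) -> np.ndarray:
    """Zero-padded cumulative sum of intensities along depth.

    float32 volumes keep a float32 accumulator: depth sums of 0-255 values
    stay far below the 2**24 integer-exactness limit.
    """
    dtype = np.float32 if volume.intensity.dtype == np.float32 else np.float64
    csum = np.cumsum(volume.intensity, axis=1, dtype=dtype)
    return np.concatenate(
        [np.zeros((volume.n_bscan, 1, volume.n_ascan), dtype=dtype), csum],
        axis=1,
    )


def _mvf_from_csum(csum: np.ndarray, volume: OCTVolume,
                   interfaces: LayerInterfaces, layer: str) -> MVFImage:
    k = LAYERS.index(layer)
    ztop = np.ceil(interfaces.z[k]).astype(np.int64)
    zbot = np.ceil(interfaces.z[k + 1]).astype(np.int64)
    top = np.take_along_axis(csum, ztop[:, None, :], axis=1)[:, 0, :]
    bot = np.take_along_axis(csum, zbot[:, None, :], axis=1)[:, 0, :]
    counts = zbot - ztop
    mask = counts > 0
    values = np.full(mask.shape, np.nan)
    np.divide(bot - top, counts, out=values, where=mask)
    return MVFImage(values=values, mask=mask, layer=layer, eye=volume.eye,
                    participant_id=volume.participant_id, flipped=False)


def _check_geometry(volume: OCTVolume, interfaces: LayerInterfaces) -> None:
    z = interfaces.z
    if z.shape[1:] != (volume.n_bscan, volume.n_ascan):
        raise DataError("interfaces and volume must share the en-face grid")
    if z.min() < 0 or z.max() > volume.n_depth:
        raise DataError("interfaces exceed the volume depth range")


def compute_mvf(volume: OCTVolume, interfaces: LayerInterfaces, layer: str) -> MVFImage:
    """Project one layer of a volume to its mean value fundus image.

    The depth span of a pixel is the half-open integer range
    [ceil(z_top), ceil(z_bottom)); no sub-voxel interpolation is applied.
    Empty spans are masked invalid.
    """
    if layer not in LAYERS:
        raise DataError(f"unknown layer {layer!r}")
    _check_geometry(volume, interfaces)
    return _mvf_from_csum(_depth_cumsum(volume), volume, interfaces, layer)


def compute_all_mvfs(volume: OCTVolume, interfaces: LayerInterfaces,
                     layers=LAYERS) -> dict[str, MVFImage]:
    """MVF images for several layers, sharing one depth cumulative sum."""
    for layer in layers:
        if layer not in LAYERS:
            raise DataError(f"unknown layer {layer!r}")
    _check_geometry(volume, interfaces)
    csum = _depth_cumsum(volume)
    return {layer: _mvf_from_csum(csum, volume, interfaces, layer)
            for layer in layers}


def standardise_orientation(mvf: MVFImage) -> MVFImage:
    """Flip left-eye images along the A-scan axis so the temporal side is the
    low-column side for every eye; right-eye images pass through unchanged."""
    if mvf.eye == "OD":
        return replace(mvf, values=mvf.values.copy(), mask=mvf.mask.copy())
    return replace(
        mvf,
        values=mvf.values[:, ::-1].copy(),
        mask=mvf.mask[:, ::-1].copy(),
        flipped=not mvf.flipped,
    )
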