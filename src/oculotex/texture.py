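"""Block-wise grey-level co-occurrence (GLCM) texture features.

Each per-layer mean value fundus image (128 rows x 512 columns) is pooled
4:1 along the A-scan axis to a 128 x 128 isotropic image, quantized to 16
grey levels, and split into a 7 x 7 grid of 18 x 18 blocks whose central row
and column (the fovea) are discarded.  For each of the 36 remaining blocks a
symmetric GLCM is accumulated at distance d = 1 for the orientations 0, 45,
90 and 135 degrees (opposite directions pooled), 21 Haralick-family features
are computed per orientation, the per-block value is the maximum over the
four orientations, and quadrant values are the means of their nine blocks.
This yields 21 features x 6 layers x 4 quadrants = 504 values per eye.

Conventions fixed here (the feature definitions in the literature leave them
open): grey levels are indexed 1..N in the moment-type features, all
logarithms are base 2 with 0*log(0) = 0, Sum Variance is taken about Sum
Average (erratum-corrected Haralick), Difference Variance is the variance of
the level-difference distribution, and features with a degenerate
denominator (Correlation, IMC1, IMC2 on a constant block) are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .config import GLCMConfig
from .constants import FEATURES, LAYERS, QUADRANTS
from .errors import DataError
from .grid import (ISO_SIZE, quadrant_of, retained_tiles,
                   tile_pixel_slices)
from .projection import (MVFImage, compute_all_mvfs,
                         standardise_orientation)

ANGLES = (0, 45, 90, 135)

#: Row/column displacement of the pixel-pair for each orientation (rows grow
#: downward, so 45 degrees points up-right).
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_LN2 = np.log(2.0)


@dataclass
class QuantizedImage:
    """Integer grey levels in [0, n_levels) with the inherited validity mask."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int


@dataclass
class Block:
    tile: tuple[int, int]  # 1-based (row, col) in the 7x7 grid
    quadrant: str
    levels: np.ndarray
    mask: np.ndarray


@dataclass
class BlockGrid:
    blocks: list[Block]
    n_levels: int


@dataclass
class GLCM:
    """Normalised symmetric co-occurrence matrix for one block/orientation.

    ``degenerate`` flags a block with no valid pixel pair at this
    orientation; its P is all zeros and it is excluded downstream.
    """

    P: np.ndarray
    angle: int
    n_pairs: int

    @property
    def degenerate(self) -> bool:
        return self.n_pairs == 0


def downsample(mvf: MVFImage) -> MVFImage:
    """4:1 mean-pool along the A-scan axis to an isotropic 128 x 128 image.

    A pooled pixel is invalid only if all four source pixels are invalid;
    otherwise it is the mean of the valid sources.
    """
    rows, cols = mvf.values.shape
    if rows != ISO_SIZE or cols != 4 * ISO_SIZE:
        raise DataError(f"expected a {ISO_SIZE}x{4 * ISO_SIZE} image, got {rows}x{cols}")
    vals = np.where(mvf.mask, mvf.values, 0.0).reshape(rows, ISO_SIZE, 4)
    counts = mvf.mask.reshape(rows, ISO_SIZE, 4).sum(axis=2)
    mask = counts > 0
    pooled = np.full((rows, ISO_SIZE), np.nan)
    np.divide(vals.sum(axis=2), counts, out=pooled, where=mask)
    return MVFImage(values=pooled, mask=mask, layer=mvf.layer, eye=mvf.eye,
                    participant_id=mvf.participant_id, flipped=mvf.flipped)


def quantize(mvf: MVFImage, n_levels: int = 16, *, mode: str = "per_image",
             fixed_range: tuple[float, float] = (0.0, 255.0)) -> QuantizedImage:
    """Linear equal-width binning of the valid pixels into ``n_levels`` grey
    levels; the maximum maps to level n_levels - 1.  ``mode`` selects the
    binning range: the image's own valid min-max (default) or a fixed range.
    A constant image quantizes to all zeros."""
    valid = mvf.mask
    if not valid.any():
        raise DataError("cannot quantize an all-invalid image")
    v = mvf.values
    if mode == "per_image":
        lo = float(np.nanmin(np.where(valid, v, np.nan)))
        hi = float(np.nanmax(np.where(valid, v, np.nan)))
    elif mode == "fixed":
        lo, hi = map(float, fixed_range)
    else:
        raise DataError(f"unknown quantization mode {mode!r}")
    levels = np.zeros(v.shape, dtype=np.int16)
    if hi > lo:
        scaled = (np.where(valid, v, lo) - lo) / (hi - lo)
        levels = np.clip((scaled * n_levels).astype(np.int16), 0, n_levels - 1)
    return QuantizedImage(levels=levels, mask=valid.copy(), n_levels=n_levels)


def partition_blocks(q: QuantizedImage) -> BlockGrid:
    """Split a 128 x 128 quantized image into the 36 retained 18 x 18 blocks
    (central row/column of the 7 x 7 grid discarded)."""
    if q.levels.shape != (ISO_SIZE, ISO_SIZE):
        raise DataError(f"expected a {ISO_SIZE}x{ISO_SIZE} image")
    blocks = []
    for tile in retained_tiles():
        rs, cs = tile_pixel_slices(tile)
        blocks.append(Block(tile=tile, quadrant=quadrant_of(tile),
                            levels=q.levels[rs, cs], mask=q.mask[rs, cs]))
    return BlockGrid(blocks=blocks, n_levels=q.n_levels)


def _cooccurrence_counts(levels: np.ndarray, mask: np.ndarray, angle: int,
                         distance: int, n_levels: int) -> np.ndarray:
    """Directed co-occurrence counts for one orientation at one distance,
    skipping pairs that touch an invalid pixel."""
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((n_levels, n_levels), dtype=np.int64)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    codes = a[ok].astype(np.int64) * n_levels + b[ok]
    counts = np.bincount(codes, minlength=n_levels * n_levels)
    return counts.reshape(n_levels, n_levels)


def compute_glcm(levels: np.ndarray, angle: int, config: GLCMConfig,
                 mask: Optional[np.ndarray] = None) -> GLCM:
    """Symmetric normalised GLCM of one block at one orientation.

    Opposite directions (angle and angle + 180 degrees) are pooled by adding
    the transposed directed counts, making P symmetric; P then sums to 1
    unless no valid pair exists, in which case the GLCM is flagged
    degenerate.
    """
    if angle not in _OFFSETS:
        raise DataError(f"angle must be one of {ANGLES}")
    levels = np.asarray(levels)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    if levels.max(initial=0) >= config.n_levels:
        raise DataError("levels exceed n_levels")
    counts = _cooccurrence_counts(levels, mask, angle, config.distance,
                                  config.n_levels)
    counts = counts + counts.T
    total = counts.sum()
    P = counts / total if total > 0 else counts.astype(float)
    return GLCM(P=P, angle=angle, n_pairs=int(total) // 2)


class _FeatureEngine:
    """Vectorised evaluation of the 21 features over stacked GLCMs.

    Index-dependent weight matrices are cached per number of grey levels.
    Levels are indexed 1..N; k runs 2..2N for the level-sum marginal and
    0..N-1 for the absolute-difference marginal.
    """

    def __init__(self, n_levels: int):
        N = self.N = n_levels
        I = np.arange(1, N + 1, dtype=float)
        self.I = I
        iv, jv = I[:, None], I[None, :]
        self.w_auto = iv * jv
        diff = iv - jv
        self.w_contrast = diff ** 2
        self.w_absdiff = np.abs(diff)
        self.w_homog = 1.0 / (1.0 + diff ** 2)
        self.w_invdiff = 1.0 / (1.0 + np.abs(diff))
        self.w_idmn = 1.0 / (1.0 + diff ** 2 / N ** 2)
        self.w_idn = 1.0 / (1.0 + np.abs(diff) / N)
        # One-hot selectors mapping P(i, j) onto the p_{x+y} / p_{x-y} bins.
        self.k_sum = np.arange(2, 2 * N + 1, dtype=float)
        self.k_diff = np.arange(0, N, dtype=float)
        isum = (iv + jv).astype(int)
        idiff = np.abs(iv - jv).astype(int)
        self.sel_sum = np.zeros((2 * N - 1, N, N))
        self.sel_diff = np.zeros((N, N, N))
        for i in range(N):
            for j in range(N):
                self.sel_sum[isum[i, j] - 2, i, j] = 1.0
                self.sel_diff[idiff[i, j], i, j] = 1.0

    def __call__(self, P: np.ndarray, config: GLCMConfig) -> dict[str, np.ndarray]:
        """Evaluate all features; P has shape (..., N, N) and each returned
        array has shape P.shape[:-2]."""
        N, I = self.N, self.I

        def total(w):
            return np.tensordot(P, w, axes=([-2, -1], [0, 1]))

        px = P.sum(axis=-1)
        py = P.sum(axis=-2)
        mu_x = (px * I).sum(axis=-1)
        mu_y = (py * I).sum(axis=-1)
        var_x = (px * (I - mu_x[..., None]) ** 2).sum(axis=-1)
        var_y = (py * (I - mu_y[..., None]) ** 2).sum(axis=-1)

        p_sum = np.tensordot(P, self.sel_sum, axes=([-2, -1], [1, 2]))
        p_diff = np.tensordot(P, self.sel_diff, axes=([-2, -1], [1, 2]))

        entropy = -xlogy(P, P).sum(axis=(-2, -1)) / _LN2
        hx = -xlogy(px, px).sum(axis=-1) / _LN2
        hy = -xlogy(py, py).sum(axis=-1) / _LN2
        pxy = px[..., :, None] * py[..., None, :]
        hxy1 = -xlogy(P, pxy).sum(axis=(-2, -1)) / _LN2
        hxy2 = -xlogy(pxy, pxy).sum(axis=(-2, -1)) / _LN2

        autocorr = total(self.w_auto)
        mu_sum = mu_x + mu_y
        dev = self.k_sum - mu_sum[..., None]
        cluster_prom = (p_sum * dev ** 4).sum(axis=-1)
        cluster_shade = (p_sum * dev ** 3).sum(axis=-1)

        sigma = np.sqrt(var_x * var_y)
        with np.errstate(invalid="ignore", divide="ignore"):
            correlation = np.where(sigma > 0,
                                   (autocorr - mu_x * mu_y) / np.where(sigma > 0, sigma, 1.0),
                                   0.0)
        hmax = np.maximum(hx, hy)
        with np.errstate(invalid="ignore", divide="ignore"):
            imc1 = np.where(hmax > 0,
                            (entropy - hxy1) / np.where(hmax > 0, hmax, 1.0),
                            0.0)
        imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0, None))

        sum_avg = (p_sum * self.k_sum).sum(axis=-1)
        sum_entropy = -xlogy(p_sum, p_sum).sum(axis=-1) / _LN2
        sv_about = sum_avg if config.sum_variance_about == "sum_average" else sum_entropy
        sum_var = (p_sum * (self.k_sum - sv_about[..., None]) ** 2).sum(axis=-1)

        mu_d = (p_diff * self.k_diff).sum(axis=-1)
        diff_var = (p_diff * (self.k_diff - mu_d[..., None]) ** 2).sum(axis=-1)
        diff_entropy = -xlogy(p_diff, p_diff).sum(axis=-1) / _LN2

        ssv = (px * (I - mu_x[..., None]) ** 2).sum(axis=-1)

        return {
            "Autocorrelation": autocorr,
            "Cluster Prominence": cluster_prom,
            "Cluster Shade": cluster_shade,
            "Contrast": total(self.w_contrast),
            "Correlation": correlation,
            "Difference Entropy": diff_entropy,
            "Difference Variance": diff_var,
            "Dissimilarity": total(self.w_absdiff),
            "Energy": (P ** 2).sum(axis=(-2, -1)),
            "Entropy": entropy,
            "Homogeneity": total(self.w_homog),
            "IMC1": imc1,
            "IMC2": imc2,
            "Inverse Difference": total(self.w_invdiff),
            "IDMN": total(self.w_idmn),
            "IDN": total(self.w_idn),
            "Maximum Probability": P.max(axis=(-2, -1)),
            "Sum Average": sum_avg,
            "Sum Entropy": sum_entropy,
            "SSV": ssv,
            "Sum Variance": sum_var,
        }


_ENGINES: dict[int, _FeatureEngine] = {}


def _engine(n_levels: int) -> _FeatureEngine:
    if n_levels not in _ENGINES:
        _ENGINES[n_levels] = _FeatureEngine(n_levels)
    return _ENGINES[n_levels]


def glcm_features(glcm: GLCM, config: Optional[GLCMConfig] = None) -> dict[str, float]:
    """The 21 texture features of one normalised GLCM."""
    config = config or GLCMConfig()
    if glcm.degenerate:
        raise DataError("cannot compute features of a degenerate GLCM")
    if abs(glcm.P.sum() - 1.0) > 1e-8:
        raise DataError("GLCM is not normalised")
    out = _engine(glcm.P.shape[-1])(glcm.P, config)
    return {name: float(val) for name, val in out.items()}


def orientation_max(vectors: Sequence[Optional[dict[str, float]]]) -> Optional[dict[str, float]]:
    """Per-feature elementwise maximum over the four orientation vectors.

    ``None`` entries (degenerate orientations) are excluded; if all four are
    degenerate the block has no value and ``None`` is returned.
    """
    present = [v for v in vectors if v is not None]
    if len(vectors) != len(ANGLES):
        raise DataError(f"expected {len(ANGLES)} orientation vectors")
    if not present:
        return None
    return {name: max(v[name] for v in present) for name in FEATURES}


def aggregate_quadrants(block_values: Sequence[Optional[dict[str, float]]],
                        grid: BlockGrid) -> pd.DataFrame:
    """Mean feature value per quadrant over its nine blocks (invalid blocks
    skipped; a quadrant with no valid block is NaN).

    Returns a DataFrame indexed by feature with one column per quadrant.
    """
    if len(block_values) != len(grid.blocks):
        raise DataError("one value vector per block required")
    out = pd.DataFrame(index=list(FEATURES), columns=list(QUADRANTS), dtype=float)
    for quadrant in QUADRANTS:
        vecs = [v for blk, v in zip(grid.blocks, block_values)
                if blk.quadrant == quadrant and v is not None]
        for name in FEATURES:
            out.loc[name, quadrant] = (
                float(np.mean([v[name] for v in vecs])) if vecs else np.nan
            )
    return out


_BLOCK_MAP: Optional[np.ndarray] = None


def _block_map() -> np.ndarray:
    """Retained-block index (0..35) per pixel of the 128 x 128 image, -1 in
    the discarded central band and the unused trailing rows/columns."""
    global _BLOCK_MAP
    if _BLOCK_MAP is None:
        bm = np.full((ISO_SIZE, ISO_SIZE), -1, dtype=np.int64)
        for bi, tile in enumerate(retained_tiles()):
            rs, cs = tile_pixel_slices(tile)
            bm[rs, cs] = bi
        _BLOCK_MAP = bm
    return _BLOCK_MAP


def _glcm_stack(q: QuantizedImage, config: GLCMConfig) -> tuple[np.ndarray, np.ndarray]:
    """Directed-pair accumulation for all 36 blocks and 4 orientations in one
    pass per orientation over the full image (pairs crossing a block border,
    the central band or an invalid pixel are skipped).  Returns the
    normalised symmetric stack P (36, 4, N, N) and a validity flag
    (36, 4)."""
    N = q.n_levels
    bm = _block_map()
    lv, mk = q.levels.astype(np.int64), q.mask
    n_blocks = len(retained_tiles())
    P = np.zeros((n_blocks, len(ANGLES), N, N))
    valid = np.zeros((n_blocks, len(ANGLES)), dtype=bool)
    h = w = ISO_SIZE
    for ai, angle in enumerate(ANGLES):
        dr, dc = _OFFSETS[angle]
        dr, dc = dr * config.distance, dc * config.distance
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = np.s_[r0:r1, c0:c1]
        dst = np.s_[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (bm[src] == bm[dst]) & (bm[src] >= 0) & mk[src] & mk[dst]
        codes = (bm[src][ok] * N + lv[src][ok]) * N + lv[dst][ok]
        counts = np.bincount(codes, minlength=n_blocks * N * N)
        counts = counts.reshape(n_blocks, N, N)
        counts = counts + counts.transpose(0, 2, 1)
        totals = counts.sum(axis=(1, 2))
        valid[:, ai] = totals > 0
        P[:, ai] = counts / np.maximum(totals, 1)[:, None, None]
    return P, valid


def _block_feature_values(grid: BlockGrid, config: GLCMConfig,
                          q: Optional[QuantizedImage] = None) -> list[Optional[dict[str, float]]]:
    """Orientation-maximised feature vector for every block (vectorised over
    the block x angle stack for speed)."""
    n = len(grid.blocks)
    if q is not None:
        P, valid = _glcm_stack(q, config)
    else:
        P = np.zeros((n, len(ANGLES), grid.n_levels, grid.n_levels))
        valid = np.zeros((n, len(ANGLES)), dtype=bool)
        for bi, blk in enumerate(grid.blocks):
            for ai, angle in enumerate(ANGLES):
                counts = _cooccurrence_counts(blk.levels, blk.mask, angle,
                                              config.distance, grid.n_levels)
                counts = counts + counts.T
                total = counts.sum()
                if total > 0:
                    P[bi, ai] = counts / total
                    valid[bi, ai] = True
    feats = _engine(grid.n_levels)(P, config)  # each (n, 4)
    out: list[Optional[dict[str, float]]] = []
    for bi in range(n):
        if not valid[bi].any():
            out.append(None)
            continue
        ok = valid[bi]
        out.append({name: float(feats[name][bi, ok].max()) for name in FEATURES})
    return out


_QUADRANT_OF_BLOCK = np.array(
    [QUADRANTS.index(quadrant_of(t)) for t in retained_tiles()])


def _quadrant_feature_array(q: QuantizedImage, config: GLCMConfig) -> np.ndarray:
    """(21 features x 4 quadrants) array for one quantized image: GLCM
    stack, per-block orientation max, quadrant means (invalid blocks
    skipped)."""
    P, valid = _glcm_stack(q, config)
    feats = _engine(q.n_levels)(P, config)
    F = np.stack([feats[name] for name in FEATURES])  # (21, 36, 4)
    block_ok = valid.any(axis=1)
    Fmax = np.where(valid[None, :, :], F, -np.inf).max(axis=2)  # (21, 36)
    out = np.full((len(FEATURES), len(QUADRANTS)), np.nan)
    for qi in range(len(QUADRANTS)):
        sel = (_QUADRANT_OF_BLOCK == qi) & block_ok
        if sel.any():
            out[:, qi] = Fmax[:, sel].mean(axis=1)
    return out


def mvf_quadrant_features(mvf: MVFImage, config: Optional[GLCMConfig] = None) -> pd.DataFrame:
    """Full texture pipeline for one orientation-standardised MVF image:
    downsample, quantize, block partition, GLCMs, orientation max, quadrant
    means.  Returns features x quadrants."""
    config = config or GLCMConfig()
    ds = downsample(mvf)
    q = quantize(ds, config.n_levels, mode=config.quantization,
                 fixed_range=config.fixed_range)
    values = _quadrant_feature_array(q, config)
    return pd.DataFrame(values, index=list(FEATURES), columns=list(QUADRANTS))


def extract_eye_features(volume, interfaces, participant, *,
                         layers: Sequence[str] = LAYERS,
                         config: Optional[GLCMConfig] = None) -> pd.DataFrame:
    """Tidy feature rows for one eye scan: project each layer, standardise
    orientation, and run the texture pipeline.  504 rows per eye when all
    six layers are analysed."""
    config = config or GLCMConfig()
    mvfs = compute_all_mvfs(volume, interfaces, layers)
    per_layer = []
    for layer in layers:
        mvf = standardise_orientation(mvfs[layer])
        ds = downsample(mvf)
        q = quantize(ds, config.n_levels, mode=config.quantization,
                     fixed_range=config.fixed_range)
        per_layer.append(_quadrant_feature_array(q, config))
    n_l, n_q, n_f = len(layers), len(QUADRANTS), len(FEATURES)
    # Row order: layer, then quadrant, then feature.
    values = np.stack(per_layer).transpose(0, 2, 1).reshape(-1)
    return pd.DataFrame({
        "participant_id": participant.participant_id,
        "sex": participant.sex,
        "age": participant.age,
        "eye": volume.eye,
        "layer": np.repeat(list(layers), n_q * n_f),
        "quadrant": np.tile(np.repeat(list(QUADRANTS), n_f), n_l),
        "feature": np.tile(list(FEATURES), n_l * n_q),
        "value": values,
    })


def extract_features(scans: Iterable, *, layers: Sequence[str] = LAYERS,
                     config: Optional[GLCMConfig] = None) -> pd.DataFrame:
    """Feature table for an iterable of (participant, eye, volume,
    interfaces) scans, e.g. the output of
    :func:`oculotex.synth.generate_cohort_volumes` or
    :func:`oculotex.io.load_dataset`."""
    frames = [
        extract_eye_features(volume, interfaces, participant,
                             layers=layers, config=config)
        for participant, _eye, volume, interfaces in scans
    ]
    if not frames:
        return pd.DataFrame(columns=["participant_id", "sex", "age", "eye",
                                     "layer", "quadrant", "feature", "value"])
    return pd.concat(frames, ignore_index=True)
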