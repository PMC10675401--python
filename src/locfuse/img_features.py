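"""Texture quantitation of protein-channel patches.

Shallow descriptors: 26 Haralick statistics (13 classic statistics, mean and
range over the 4 co-occurrence directions at distance 1 on a 32-gray-level
GLCM), extended across an 8-level Daubechies wavelet decomposition to a
674-dimensional vector (26 original-patch features + 27 per detail band:
26 Haralick statistics of the band-reconstructed image plus the band energy),
and a 256-bin local-binary-pattern histogram.  Patch vectors of one protein
are aggregated by the element-wise mean.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pywt

from .io import FeatureVector

N_GRAY_LEVELS = 32
WAVELET_LEVELS = 8
#: (dr, dc) offsets of the four co-occurrence directions at distance 1.
GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
#: detail orientations in fixed output order
ORIENTATIONS = ("horizontal", "vertical", "diagonal")

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_correlation_1",
    "info_correlation_2",
)


class PatchSizeError(ValueError):
    """Patch too small for the requested operator."""


def quantize_gray(patch: np.ndarray, levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Uniformly bin [min, max] of the patch into integer levels 0..levels-1.

    A constant patch maps entirely to level 0.
    """
    patch = np.asarray(patch, dtype=float)
    lo, hi = patch.min(), patch.max()
    # near-constant patches (e.g. round-off noise in a zeroed wavelet band)
    # are treated as constant rather than amplifying 1e-15 ripples
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        return np.zeros(patch.shape, dtype=np.uint8)
    q = np.floor((patch - lo) / (hi - lo) * levels).astype(np.int64)
    return np.minimum(q, levels - 1).astype(np.uint8)


def glcm(
    quantized: np.ndarray, direction: int, levels: int = N_GRAY_LEVELS
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix at distance 1.

    ``direction`` is one of 0, 45, 90, 135 degrees with the image row axis
    pointing down (so 45 deg pairs a pixel with its upper-right neighbor).
    """
    dr, dc = GLCM_OFFSETS[direction]
    a = quantized
    H, W = a.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    src = a[r0:r1, c0:c1].ravel().astype(np.int64)
    dst = a[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel().astype(np.int64)
    counts = np.bincount(src * levels + dst, minlength=levels * levels).reshape(
        levels, levels
    )
    sym = counts + counts.T
    total = sym.sum()
    return sym / total if total > 0 else sym.astype(float)


def haralick_statistics(p: np.ndarray) -> np.ndarray:
    """The 13 classic Haralick statistics of one normalized symmetric GLCM.

    Degenerate matrices (all mass on one level) yield the analytic values
    ASM=1, entropy=0, contrast=0; correlation-type statistics whose
    denominator vanishes are defined as 0.
    """
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    var_x = ((i - mu_x) ** 2 * px).sum()
    var_y = ((i - mu_y) ** 2 * py).sum()

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    asm = (p**2).sum()
    contrast = (diff**2 * p).sum()
    if var_x > 0 and var_y > 0:
        correlation = ((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y)
    else:
        correlation = 0.0
    variance = ((ii - mu_x) ** 2 * p).sum()
    idm = (p / (1.0 + diff**2)).sum()

    # p_{x+y}(k), k = 0..2*levels-2 and p_{x-y}(k), k = 0..levels-1
    k_sum = (ii + jj).astype(np.int64)
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * levels - 1)
    k_diff = np.abs(diff).astype(np.int64)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=levels)

    ks = np.arange(p_sum.size, dtype=float)
    sum_average = (ks * p_sum).sum()
    sum_variance = ((ks - sum_average) ** 2 * p_sum).sum()

    def _entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    sum_entropy = _entropy(p_sum)
    entropy = _entropy(p)
    kd = np.arange(p_diff.size, dtype=float)
    diff_mean = (kd * p_diff).sum()
    difference_variance = ((kd - diff_mean) ** 2 * p_diff).sum()
    difference_entropy = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    outer = np.outer(px, py)
    mask = (p > 0) & (outer > 0)
    hxy1 = float(-(p[mask] * np.log(outer[mask])).sum())
    pos = outer > 0
    hxy2 = float(-(outer[pos] * np.log(outer[pos])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def haralick26(patch: np.ndarray, levels: int = N_GRAY_LEVELS) -> np.ndarray:
    """Mean and range over the 4 directions of the 13 Haralick statistics.

    *patch* is quantized to ``levels`` gray levels first.  Output layout:
    13 direction means followed by the 13 direction ranges.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 2:
        raise PatchSizeError("haralick26 needs a single-channel patch of size >= 2x2")
    q = quantize_gray(patch, levels)
    per_dir = np.vstack(
        [haralick_statistics(glcm(q, d, levels)) for d in GLCM_OFFSETS]
    )
    return np.concatenate([per_dir.mean(axis=0), per_dir.max(axis=0) - per_dir.min(axis=0)])


def _band_reconstructions(
    patch: np.ndarray, wavelet: str, levels: int
) -> Iterable[tuple[int, str, np.ndarray, float]]:
    """Yield (level, orientation, reconstructed image, band energy) per detail band.

    Level 1 is the finest scale.  The reconstruction inverts the transform
    with every other sub-band zeroed; symmetric signal extension throughout.
    """
    with warnings.catch_warnings():
        # deep decompositions of a 512x512 patch run past the textbook
        # max level; boundary effects are part of the descriptor definition
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(patch, wavelet, level=levels, mode="symmetric")
    # coeffs = [cA_n, (cH_n, cV_n, cD_n), ..., (cH_1, cV_1, cD_1)]
    zeros = [np.zeros_like(coeffs[0])] + [
        tuple(np.zeros_like(b) for b in triple) for triple in coeffs[1:]
    ]
    for level in range(1, levels + 1):
        pos = len(coeffs) - level  # finest triple sits last
        for o_idx, orientation in enumerate(ORIENTATIONS):
            band = coeffs[pos][o_idx]
            energy = float((band**2).mean())
            work = list(zeros)
            triple = [np.zeros_like(b) for b in coeffs[pos]]
            triple[o_idx] = band
            work[pos] = tuple(triple)
            recon = pywt.waverec2(work, wavelet, mode="symmetric")
            yield level, orientation, recon[: patch.shape[0], : patch.shape[1]], energy


def wavelet_haralick(
    patch: np.ndarray, wavelet: str = "db8", levels: int = WAVELET_LEVELS
) -> np.ndarray:
    """Wavelet-domain Haralick descriptor: 26 + 3 * 27 * levels dims (674 at 8 levels).

    26 statistics of the quantized original patch, then for each
    decomposition level (finest first) and detail orientation
    (horizontal, vertical, diagonal): the 26 Haralick statistics of the image
    reconstructed from that band alone, re-quantized to 32 gray levels, plus
    the band energy (mean squared band coefficient), 27 per band.
    """
    if not (wavelet.startswith("db") and wavelet[2:].isdigit()
            and 1 <= int(wavelet[2:]) <= 10):
        raise ValueError(f"unsupported wavelet {wavelet!r}: expected db1..db10")
    patch = np.asarray(patch, dtype=float)
    parts = [haralick26(patch)]
    for _level, _orient, recon, energy in _band_reconstructions(patch, wavelet, levels):
        parts.append(haralick26(recon))
        parts.append([energy])
    return np.concatenate([np.atleast_1d(p) for p in parts])


#: neighbor offsets clockwise from top-left; first neighbor is the high bit
LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp_histogram(patch: np.ndarray) -> np.ndarray:
    """Normalized 256-bin histogram of 8-neighbor local binary patterns.

    For each interior pixel, bit k is 1 iff the k-th neighbor >= center,
    neighbors ordered clockwise from the top-left corner of the 3x3 mask
    (bit 0 is the most significant).  Border pixels are skipped.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.shape[0] < 3 or patch.shape[1] < 3:
        raise PatchSizeError("lbp_histogram needs a patch of at least 3x3")
    center = patch[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for k, (dr, dc) in enumerate(LBP_OFFSETS):
        nb = patch[1 + dr : patch.shape[0] - 1 + dr, 1 + dc : patch.shape[1] - 1 + dc]
        codes = codes | ((nb >= center).astype(np.int64) << (7 - k))
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def aggregate_patches(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Element-wise mean of the per-patch vectors of one operator."""
    if not vectors:
        raise ValueError("no patch vectors to aggregate")
    op = vectors[0].operator_name
    dim = vectors[0].dimension
    pid = vectors[0].protein_id
    for v in vectors:
        if v.operator_name != op or v.dimension != dim:
            raise ValueError(
                f"cannot aggregate {v.operator_name}:{v.dimension} with {op}:{dim}"
            )
    mean = np.mean([v.values for v in vectors], axis=0)
    return FeatureVector(pid, op, mean)
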