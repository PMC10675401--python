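"""IHC preprocessing: quality filtering, stain unmixing, patch extraction.

An RGB immunohistochemistry micrograph is converted to optical density,
linearly unmixed into a DAB (protein) and a haematoxylin (DNA) concentration
plane, quality-filtered against an empirical mean-intensity threshold, and
tiled by a non-overlapping 512x512 sliding window from which the first 15
"effective" (sufficiently stained) patches are kept.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .io import IhcImage

#: Ruifrok-Johnston optical-density stain vectors, columns = (haematoxylin, DAB),
#: rows = (R, G, B); each column unit-normalized.
DEFAULT_STAIN_BASIS = np.array(
    [
        [0.650, 0.269],
        [0.704, 0.568],
        [0.286, 0.778],
    ]
)
DEFAULT_STAIN_BASIS = DEFAULT_STAIN_BASIS / np.linalg.norm(
    DEFAULT_STAIN_BASIS, axis=0, keepdims=True
)

#: Empirical mean-intensity quality threshold on the 0-255 protein plane.
QUALITY_THRESHOLD = 13.0

WINDOW = 512
MAX_PATCHES = 15


class StainBasisError(ValueError):
    """Degenerate or mis-shaped stain basis."""


class ImageSizeError(ValueError):
    """Image or plane too small for the requested window."""


@dataclasses.dataclass(frozen=True)
class StainChannels:
    """Unmixed stain concentration planes, rescaled to [0, 255]."""

    protein: np.ndarray
    dna: np.ndarray
    stain_basis: np.ndarray

    def __post_init__(self) -> None:
        if self.protein.shape != self.dna.shape:
            raise ValueError("protein and dna planes differ in shape")
        if self.protein.min() < 0 or self.dna.min() < 0:
            raise ValueError("concentration planes must be non-negative")


@dataclasses.dataclass(frozen=True)
class Patch:
    """A 512x512 single-channel patch with its top-left origin (row, col)."""

    pixels: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("patch must be a single-channel plane")


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Optical density per channel: OD_c = -log10((I_c + 1) / 256)."""
    return -np.log10((pixels.astype(float) + 1.0) / 256.0)


def _nnls_two_stains(od: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares for a 2-stain basis, vectorized.

    For two variables the NNLS solution is either the unconstrained LS
    solution (when both coefficients are non-negative) or the best of the two
    single-stain fits with the other coefficient clamped at zero.
    """
    flat = od.reshape(-1, 3)
    gram = basis.T @ basis
    rhs = flat @ basis  # (N, 2)
    unconstrained = rhs @ np.linalg.inv(gram).T
    # single-stain fallbacks (coefficient of the other stain fixed at 0)
    c_h = np.clip(rhs[:, 0] / gram[0, 0], 0.0, None)
    c_d = np.clip(rhs[:, 1] / gram[1, 1], 0.0, None)
    out = unconstrained.copy()
    neg = (unconstrained < 0).any(axis=1)
    if np.any(neg):
        # residual^2 = ||od||^2 - 2 c rhs + c^2 g; compare the two edge fits
        res_h = -2 * c_h[neg] * rhs[neg, 0] + c_h[neg] ** 2 * gram[0, 0]
        res_d = -2 * c_d[neg] * rhs[neg, 1] + c_d[neg] ** 2 * gram[1, 1]
        pick_h = res_h <= res_d
        edge = np.zeros((neg.sum(), 2))
        edge[pick_h, 0] = c_h[neg][pick_h]
        edge[~pick_h, 1] = c_d[neg][~pick_h]
        out[neg] = edge
    return out.reshape(od.shape[:2] + (2,))


def unmix_stains(
    image: IhcImage,
    basis: Optional[np.ndarray] = None,
    rescale_percentile: float = 99.0,
) -> StainChannels:
    """Linear spectral separation of the protein (DAB) and DNA (haematoxylin) planes.

    Per pixel the optical density is decomposed as a non-negative combination
    of the two stain vectors; each concentration plane is then rescaled so
    that its ``rescale_percentile`` value maps to 255 (robust to outliers),
    clipping above.
    """
    basis = DEFAULT_STAIN_BASIS if basis is None else np.asarray(basis, dtype=float)
    if basis.shape != (3, 2):
        raise StainBasisError(f"stain basis must be 3x2, got {basis.shape}")
    if np.linalg.matrix_rank(basis) < 2:
        raise StainBasisError("stain basis is singular: stain vectors are collinear")
    conc = _nnls_two_stains(rgb_to_od(image.pixels), basis)

    def rescale(plane: np.ndarray) -> np.ndarray:
        ref = np.percentile(plane, rescale_percentile)
        if ref <= 0:
            return np.zeros_like(plane)
        return np.clip(plane / ref * 255.0, 0.0, 255.0)

    return StainChannels(
        protein=rescale(conc[..., 1]), dna=rescale(conc[..., 0]), stain_basis=basis
    )


def quality_filter(
    image: IhcImage,
    threshold: float = QUALITY_THRESHOLD,
    basis: Optional[np.ndarray] = None,
) -> tuple[bool, float]:
    """Accept an image iff its mean unmixed protein-channel intensity >= *threshold*.

    Returns ``(accepted, mean_protein_intensity)`` on the 0-255 scale.
    Weakly stained slides (including pure-white images, whose optical density
    is ~0 everywhere) fall below the threshold and are rejected.
    """
    channels = unmix_stains(image, basis=basis)
    mean = float(channels.protein.mean())
    return mean >= threshold, mean


def extract_patches(
    channels: StainChannels,
    window: int = WINDOW,
    max_patches: int = MAX_PATCHES,
    effective_threshold: float = QUALITY_THRESHOLD,
) -> tuple[list[Patch], bool]:
    """First *max_patches* effective window patches of the protein plane.

    The plane is tiled by a non-overlapping *window*-stride grid scanned in
    row-major order; remainder margins are discarded.  A patch is "effective"
    iff its mean intensity >= *effective_threshold*.  Returns the patches and
    a shortfall flag (True when fewer than *max_patches* effective patches
    exist).
    """
    plane = channels.protein
    H, W = plane.shape
    if H < window or W < window:
        raise ImageSizeError(
            f"protein plane {H}x{W} smaller than the {window}x{window} window"
        )
    patches: list[Patch] = []
    for r in range(0, H - window + 1, window):
        for c in range(0, W - window + 1, window):
            block = plane[r : r + window, c : c + window]
            if block.mean() >= effective_threshold:
                patches.append(Patch(block.copy(), (r, c)))
                if len(patches) == max_patches:
                    return patches, False
    return patches, True
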