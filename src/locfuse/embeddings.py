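"""Pluggable patch-embedding providers.

The deep-feature slots of the pipeline (two 1024-dimensional layer readouts
of a convolutional network) are served through a provider interface: any
callable object mapping a single-channel patch to a fixed-length vector,
deterministic under its configuration, can be registered.  The default
provider is a small frozen convolutional encoder with seed-initialized
random weights -- a reproducible random-feature embedding, not a trained
network; swap in a pretrained model by registering it under a name.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import FeatureVector


class EmbeddingContractError(ValueError):
    """Provider output does not honour its declared dimension."""


class SeededConvEmbedding:
    """Frozen random-weight convolutional encoder.

    Pipeline: block-mean downsample to 64x64, scale to [0, 1], two strided
    convolution + ReLU stages (16 then 32 random filters), 2x2 average
    pooling, and a fixed random projection with tanh to ``output_dim``
    values.  Identical patch + identical (name, seed, output_dim) always
    yields the identical vector.
    """

    def __init__(self, name: str, seed: int, output_dim: int = 1024):
        self.name = name
        self.output_dim = output_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._w1 = rng.normal(0, 1.0 / 5.0, size=(16, 5, 5))
        self._b1 = rng.normal(0, 0.1, size=16)
        self._w2 = rng.normal(0, 1.0 / (3.0 * 4.0), size=(32, 16, 3, 3))
        self._b2 = rng.normal(0, 0.1, size=32)
        self._proj = rng.normal(0, 1.0, size=(output_dim, 32 * 7 * 7)) / np.sqrt(
            32 * 7 * 7
        )

    @staticmethod
    def _downsample(patch: np.ndarray, out: int = 64) -> np.ndarray:
        H, W = patch.shape
        fr, fc = max(H // out, 1), max(W // out, 1)
        trimmed = patch[: (H // fr) * fr, : (W // fc) * fc]
        pooled = trimmed.reshape(H // fr, fr, W // fc, fc).mean(axis=(1, 3))
        return pooled[:out, :out]

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
        # x: (C_in, H, W); w: (C_out, C_in, kh, kw) or (C_out, kh, kw) for C_in=1
        if w.ndim == 3:
            w = w[:, None, :, :]
        kh, kw = w.shape[2:]
        windows = sliding_window_view(x, (x.shape[0], kh, kw))[0]
        windows = windows[::stride, ::stride]  # (H', W', C_in, kh, kw)
        out = np.tensordot(windows, w, axes=([2, 3, 4], [1, 2, 3]))
        return np.maximum(out + b, 0.0).transpose(2, 0, 1)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        x = self._downsample(np.asarray(patch, dtype=float)) / 255.0
        h = self._conv(x[None], self._w1, self._b1, stride=2)  # (16, 30, 30)
        h = self._conv(h, self._w2, self._b2, stride=2)  # (32, 14, 14)
        pooled = h[:, :14, :14].reshape(32, 7, 2, 7, 2).mean(axis=(2, 4))
        return np.tanh(self._proj @ pooled.ravel())


#: Default providers standing in the two deep-layer readout slots.
PROVIDER_REGISTRY: dict[str, object] = {
    "C3": SeededConvEmbedding("C3", seed=3),
    "GAP": SeededConvEmbedding("GAP", seed=7),
}


def register_provider(provider) -> None:
    if not hasattr(provider, "name") or not hasattr(provider, "output_dim"):
        raise ValueError("provider must expose .name and .output_dim")
    PROVIDER_REGISTRY[provider.name] = provider


def deep_embed(patch: np.ndarray, provider, protein_id: str = "") -> FeatureVector:
    """Embed one patch through *provider* (an object or a registered name)."""
    if isinstance(provider, str):
        try:
            provider = PROVIDER_REGISTRY[provider]
        except KeyError:
            raise KeyError(
                f"no embedding provider named {provider!r}; "
                f"registered: {sorted(PROVIDER_REGISTRY)}"
            ) from None
    values = np.asarray(provider(patch), dtype=float).ravel()
    if values.size != provider.output_dim:
        raise EmbeddingContractError(
            f"provider {provider.name!r} declared {provider.output_dim} dims "
            f"but produced {values.size}"
        )
    return FeatureVector(protein_id, provider.name, values)
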