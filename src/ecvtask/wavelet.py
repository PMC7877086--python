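"""Periodized orthogonal Daubechies wavelet transform (2D, multi-level).

Minimal in-package implementation (no PyWavelets dependency): analysis and
synthesis are exact transposes of each other, so the transform is orthonormal
and round-trips to machine precision.  Coefficients are packed in place,
``[LL | LH; HL | HH]`` recursively, so a transformed image has the same shape
as the input.
"""

from __future__ import annotations

import numpy as np

# Daubechies 4-vanishing-moment ("db4") orthonormal lowpass filter
_DB4_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523,
])
_DB4_HI = _DB4_LO[::-1].copy()
_DB4_HI[1::2] *= -1.0


def _gather_idx(n: int, taps: int) -> np.ndarray:
    return (2 * np.arange(n // 2)[:, None] + np.arange(taps)[None, :]) % n


def _analysis_axis(x: np.ndarray, axis: int) -> np.ndarray:
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    idx = _gather_idx(n, len(_DB4_LO))
    g = x[..., idx]
    out = np.concatenate([g @ _DB4_LO, g @ _DB4_HI], axis=-1)
    return np.moveaxis(out, -1, axis)


def _synthesis_axis(c: np.ndarray, axis: int) -> np.ndarray:
    c = np.moveaxis(c, axis, -1)
    n = c.shape[-1]
    a, d = c[..., : n // 2], c[..., n // 2:]
    idx = _gather_idx(n, len(_DB4_LO))
    x = np.zeros_like(c)
    contrib = a[..., :, None] * _DB4_LO + d[..., :, None] * _DB4_HI
    np.add.at(x, (..., idx), contrib)
    return np.moveaxis(x, -1, axis)


def _check(n: int, levels: int) -> None:
    if n % (1 << levels):
        raise ValueError(f"image side {n} not divisible by 2^{levels}")


def dwt2(img: np.ndarray, levels: int = 3) -> np.ndarray:
    """Multi-level 2D DWT; same-shape packed coefficient array."""
    _check(img.shape[-1], levels)
    _check(img.shape[-2], levels)
    out = np.array(img, dtype=complex if np.iscomplexobj(img) else float)
    ny, nx = img.shape[-2:]
    for _ in range(levels):
        band = out[..., :ny, :nx]
        band = _analysis_axis(band, -1)
        band = _analysis_axis(band, -2)
        out[..., :ny, :nx] = band
        ny //= 2
        nx //= 2
    return out


def idwt2(coeffs: np.ndarray, levels: int = 3) -> np.ndarray:
    """Inverse of :func:`dwt2`."""
    _check(coeffs.shape[-1], levels)
    _check(coeffs.shape[-2], levels)
    out = np.array(coeffs, dtype=complex if np.iscomplexobj(coeffs) else float)
    ny = coeffs.shape[-2] >> (levels - 1)
    nx = coeffs.shape[-1] >> (levels - 1)
    for _ in range(levels):
        band = out[..., :ny, :nx]
        band = _synthesis_axis(band, -2)
        band = _synthesis_axis(band, -1)
        out[..., :ny, :nx] = band
        ny *= 2
        nx *= 2
    return out


def detail_mask(shape: tuple, levels: int = 3) -> np.ndarray:
    """Boolean mask of detail coefficients (everything but the coarsest LL)."""
    mask = np.ones(shape, dtype=bool)
    mask[..., : shape[-2] >> levels, : shape[-1] >> levels] = False
    return mask


def soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    """Complex soft thresholding (magnitude shrinkage)."""
    mag = np.abs(z)
    scale = np.maximum(mag - t, 0.0) / np.maximum(mag, 1e-300)
    return z * scale
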