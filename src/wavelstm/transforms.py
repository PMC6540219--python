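"""Row-wise discrete transforms used to condition feature vectors.

Three alternatives are offered for the feature-conditioning stage placed
between extraction and classification: the single-level Daubechies DWT (which
halves the dimension, keeping the approximation coefficients), and the
orthonormal DCT-II and normalized fast Walsh-Hadamard transforms (which keep
the dimension unchanged).  All are data-independent linear maps, so they are
applied identically to training and test rows — there is nothing to fit.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy.fft import dct as _scipy_dct

from .wavelets import (
    ExtensionMode,
    WaveletFilterPair,
    coefficient_length,
    daubechies_filters,
    dwt_single_level,
)

__all__ = ["dct_transform", "fwht_transform", "reduce_features", "ReductionMethod"]

ReductionMethod = Literal["dwt", "dct", "fwht", "none"]


def dct_transform(signal: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II of a 1-D signal (energy preserving, same length)."""
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a nonempty 1-D vector")
    return _scipy_dct(x, type=2, norm="ortho")


def fwht_transform(signal: np.ndarray) -> np.ndarray:
    """Normalized fast Walsh-Hadamard transform (natural/Hadamard ordering).

    Computes ``H_n x / sqrt(n)`` with the in-place butterfly, so the transform
    is orthonormal and its own inverse.  Requires the length to be a power of
    two (4096 always qualifies).
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a nonempty 1-D vector")
    n = x.size
    if n & (n - 1):
        raise ValueError(f"FWHT requires a power-of-2 length, got {n}")
    y = x.copy()
    h = 1
    while h < n:
        blocks = y.reshape(-1, 2 * h)
        a = blocks[:, :h].copy()
        b = blocks[:, h:]
        blocks[:, :h] = a + b
        blocks[:, h:] = a - b
        h *= 2
    return y / np.sqrt(n)


def reduce_features(
    features: np.ndarray,
    method: ReductionMethod = "dwt",
    *,
    wavelet_order: int = 7,
    extension_mode: ExtensionMode | str = ExtensionMode.SYMMETRIC,
    coefficients: Literal["approximation", "detail"] = "approximation",
) -> np.ndarray:
    """Apply the chosen transform to every row of a feature matrix.

    ``dwt`` returns the approximation-coefficient rows (4096 -> 2054 with the
    default db7), the conditioning step at the heart of the pipeline; the
    ``coefficients="detail"`` flag exposes the highpass half instead.  ``dct``
    and ``fwht`` return full-length transformed rows; ``none`` is the identity.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("features must be a nonempty 2-D matrix")
    if method == "none":
        return X.copy()
    if method == "dct":
        return _scipy_dct(X, type=2, norm="ortho", axis=1)
    if method == "fwht":
        return np.vstack([fwht_transform(row) for row in X])
    if method == "dwt":
        filters = daubechies_filters(wavelet_order)
        out = np.empty((X.shape[0], coefficient_length(X.shape[1], filters.length)))
        for i, row in enumerate(X):
            coeffs = dwt_single_level(row, filters, mode=extension_mode)
            out[i] = coeffs.cA if coefficients == "approximation" else coeffs.cD
        return out
    raise ValueError(f"unknown reduction method {method!r}")
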