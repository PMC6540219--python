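"""Single-level 1-D discrete wavelet transform with Daubechies filter banks.

The decomposition follows the classic two-channel analysis bank: the signal is
extended at both ends by half-point symmetric replication, convolved with the
lowpass and highpass analysis filters, and downsampled by two keeping the
odd-indexed samples of the valid convolution.  For a signal of length ``n`` and
a filter of length ``L`` this yields ``floor((n + L - 1) / 2)`` approximation
(cA) and detail (cD) coefficients each — 2054 from a 4096-long feature vector
with db7.  The synthesis bank (:func:`idwt_single_level`) reconstructs the
signal exactly because the Daubechies banks are orthonormal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "ExtensionMode",
    "WaveletFilterPair",
    "WaveletCoefficients",
    "daubechies_filters",
    "dwt_single_level",
    "idwt_single_level",
]


class ExtensionMode(str, Enum):
    """Boundary handling for filtering a finite signal."""

    SYMMETRIC = "symmetric"  # half-point mirror: ... x1 x0 | x0 x1 ...
    PERIODIC = "periodic"    # wrap-around: ... x_{n-2} x_{n-1} | x0 x1 ...
    ZERO = "zero"            # pad with zeros


# Canonical Daubechies analysis lowpass filters, orders 1-10 (length 2*order),
# normalized so that sum(h) = sqrt(2) and sum(h^2) = 1.  Stored lowest-index
# first; db1 is the Haar pair.
_DAUBECHIES_LOWPASS: dict[int, tuple[float, ...]] = {
    1: (
        0.7071067811865476,
        0.7071067811865476,
    ),
    2: (
        -0.12940952255126037,
        0.2241438680420134,
        0.8365163037378079,
        0.48296291314453416,
    ),
    3: (
        0.03522629188570953,
        -0.08544127388202666,
        -0.13501102001025458,
        0.45987750211849154,
        0.8068915093110925,
        0.33267055295008263,
    ),
    4: (
        -0.010597401785069032,
        0.0328830116668852,
        0.030841381835560764,
        -0.18703481171909309,
        -0.027983769416859854,
        0.6308807679298589,
        0.7148465705529157,
        0.2303778133088965,
    ),
    5: (
        0.0033357252854737712,
        -0.012580751999081999,
        -0.006241490212798274,
        0.07757149384004572,
        -0.032244869584638375,
        -0.24229488706638203,
        0.13842814590132074,
        0.7243085284377729,
        0.6038292697971896,
        0.16010239797419293,
    ),
    6: (
        -0.0010773010853084796,
        0.004777257510945511,
        0.0005538422011614961,
        -0.03158203931748603,
        0.027522865530305727,
        0.09750160558732304,
        -0.12976686756726194,
        -0.22626469396543983,
        0.31525035170919763,
        0.7511339080210954,
        0.49462389039845306,
        0.11154074335010947,
    ),
    7: (
        0.00035371379997452024,
        -0.0018016407040474908,
        0.0004295779729213665,
        0.01255099855609984,
        -0.01657454163066688,
        -0.03802993693501441,
        0.08061260915108308,
        0.07130921926683026,
        -0.22403618499387498,
        -0.14390600392856498,
        0.4697822874051931,
        0.7291320908462351,
        0.3965393194819173,
        0.07785205408500918,
    ),
    8: (
        -0.00011747678412476953,
        0.0006754494064505693,
        -0.00039174037337694705,
        -0.004870352993451574,
        0.008746094047405777,
        0.013981027917398282,
        -0.044088253930794755,
        -0.017369301001807547,
        0.12874742662047847,
        0.0004724845739132828,
        -0.2840155429615469,
        -0.015829105256349306,
        0.5853546836542067,
        0.6756307362972898,
        0.31287159091429995,
        0.05441584224310401,
    ),
    9: (
        3.93473203162716e-05,
        -0.0002519631889427101,
        0.00023038576352319597,
        0.0018476468830562265,
        -0.00428150368246343,
        -0.004723204757751397,
        0.022361662123679096,
        0.00025094711483145197,
        -0.06763282906132997,
        0.03072568147933338,
        0.14854074933810638,
        -0.09684078322297646,
        -0.2932737832791749,
        0.13319738582500756,
        0.6572880780513005,
        0.6048231236901112,
        0.24383467461259034,
        0.038077947363878345,
    ),
    10: (
        -1.3264202894521244e-05,
        9.358867032006959e-05,
        -0.00011646685512928545,
        -0.0006858566949597116,
        0.001992405295185056,
        0.001395351747052901,
        -0.010733175483330575,
        0.0036065535669561697,
        0.033212674059341,
        -0.029457536821875813,
        -0.07139414716639708,
        0.09305736460357235,
        0.12736934033579325,
        -0.19594627437737705,
        -0.24984642432731538,
        0.2811723436605775,
        0.6884590394536035,
        0.5272011889317256,
        0.1881768000776915,
        0.026670057900555554,
    ),
}


@dataclass(frozen=True)
class WaveletFilterPair:
    """Orthonormal analysis filter bank of a Daubechies wavelet.

    ``highpass`` is the quadrature mirror of ``lowpass``:
    ``g[k] = (-1)^k h[L-1-k]``.  Both filters have length
    ``L = 2 * vanishing_moments``.
    """

    lowpass: np.ndarray
    highpass: np.ndarray
    vanishing_moments: int

    @property
    def length(self) -> int:
        return self.lowpass.size

    def __post_init__(self) -> None:
        lo = np.asarray(self.lowpass, dtype=np.float64)
        hi = np.asarray(self.highpass, dtype=np.float64)
        object.__setattr__(self, "lowpass", lo)
        object.__setattr__(self, "highpass", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lowpass/highpass must be 1-D vectors of equal length")
        _validate_orthonormal(lo, hi)


def _validate_orthonormal(lo: np.ndarray, hi: np.ndarray, tol: float = 1e-10) -> None:
    """Check the defining invariants of an orthonormal two-channel bank."""
    if abs(lo.sum() - np.sqrt(2.0)) > tol:
        raise ValueError("lowpass filter does not sum to sqrt(2)")
    if abs(np.dot(lo, lo) - 1.0) > tol:
        raise ValueError("lowpass filter is not unit-norm")
    if abs(hi.sum()) > tol:
        raise ValueError("highpass filter does not sum to 0")
    L = lo.size
    for k in range(1, L // 2):
        if abs(np.dot(lo[: L - 2 * k], lo[2 * k :])) > tol:
            raise ValueError(f"lowpass filter not orthogonal to its shift by {2 * k}")
    if abs(np.dot(lo, hi)) > tol:
        raise ValueError("lowpass and highpass filters are not orthogonal")


def daubechies_filters(vanishing_moments: int) -> WaveletFilterPair:
    """Return the Daubechies analysis filter pair of the given order.

    Parameters
    ----------
    vanishing_moments
        Number of vanishing moments (1-10); the filter length is twice this.
        Order 1 is the Haar wavelet, order 7 (length 14) is the bank used to
        reduce 4096-long feature vectors to 2054 approximation coefficients.
    """
    if vanishing_moments not in _DAUBECHIES_LOWPASS:
        raise ValueError(
            f"unsupported Daubechies order {vanishing_moments!r}; supported: 1-10"
        )
    lo = np.array(_DAUBECHIES_LOWPASS[vanishing_moments], dtype=np.float64)
    # quadrature mirror: alternating-sign time reversal, g[k] = (-1)^(k+1) h[L-1-k]
    hi = lo[::-1].copy()
    hi[0::2] *= -1.0
    return WaveletFilterPair(lowpass=lo, highpass=hi, vanishing_moments=vanishing_moments)


@dataclass
class WaveletCoefficients:
    """One decomposition level: approximation (cA) and detail (cD) halves."""

    cA: np.ndarray
    cD: np.ndarray
    original_length: int
    extension_mode: ExtensionMode = ExtensionMode.SYMMETRIC

    def __post_init__(self) -> None:
        self.cA = np.asarray(self.cA, dtype=np.float64)
        self.cD = np.asarray(self.cD, dtype=np.float64)
        if self.cA.shape != self.cD.shape or self.cA.ndim != 1:
            raise ValueError("cA and cD must be 1-D vectors of equal length")


def _extend(signal: np.ndarray, pad: int, mode: ExtensionMode) -> np.ndarray:
    if mode is ExtensionMode.SYMMETRIC:
        left = signal[:pad][::-1]
        right = signal[::-1][:pad]
        return np.concatenate([left, signal, right])
    if mode is ExtensionMode.PERIODIC:
        left = signal[-pad:]
        right = signal[:pad]
        return np.concatenate([left, signal, right])
    if mode is ExtensionMode.ZERO:
        z = np.zeros(pad, dtype=signal.dtype)
        return np.concatenate([z, signal, z])
    raise ValueError(f"unknown extension mode {mode!r}")


def coefficient_length(signal_length: int, filter_length: int) -> int:
    """Number of cA (= cD) coefficients after one decomposition level."""
    return (signal_length + filter_length - 1) // 2


def dwt_single_level(
    signal: np.ndarray,
    filters: WaveletFilterPair,
    mode: ExtensionMode | str = ExtensionMode.SYMMETRIC,
) -> WaveletCoefficients:
    """One level of the 1-D DWT of ``signal``.

    The signal is extended by ``L - 1`` samples at each end, convolved with
    each analysis filter (valid part only), and downsampled by two keeping the
    odd-indexed convolution outputs (index origin 0).
    """
    mode = ExtensionMode(mode)
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    L = filters.length
    if x.size < L:
        raise ValueError(f"signal length {x.size} shorter than filter length {L}")
    ext = _extend(x, L - 1, mode)
    # np.convolve flips the kernel; analysis filtering correlates with the
    # time-reversed filter, which is exactly convolution with the filter as
    # stored.
    cA = np.convolve(ext, filters.lowpass, mode="valid")[1::2]
    cD = np.convolve(ext, filters.highpass, mode="valid")[1::2]
    return WaveletCoefficients(cA=cA, cD=cD, original_length=x.size, extension_mode=mode)


def idwt_single_level(
    coeffs: WaveletCoefficients, filters: WaveletFilterPair
) -> np.ndarray:
    """Invert :func:`dwt_single_level` (exact for the orthonormal banks).

    Each coefficient stream is upsampled by two, convolved with the synthesis
    filter (the time-reversed analysis filter), the branches summed and the
    result trimmed to the original length.
    """
    L = filters.length
    n = coeffs.original_length
    m = coeffs.cA.size
    if m != coefficient_length(n, L):
        raise ValueError(
            f"coefficient length {m} inconsistent with original length {n} "
            f"and filter length {L}"
        )
    rec_lo = filters.lowpass[::-1]
    rec_hi = filters.highpass[::-1]
    up_a = np.zeros(2 * m)
    up_a[::2] = coeffs.cA
    up_d = np.zeros(2 * m)
    up_d[::2] = coeffs.cD
    full = np.convolve(up_a, rec_lo) + np.convolve(up_d, rec_hi)
    return full[L - 2 : L - 2 + n]
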