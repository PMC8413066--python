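"""Per-channel sEMG features behind the three image views.

Three feature families are used to build view images from a windowed
signal: discrete wavelet packet transform coefficients (DWPTC), discrete
wavelet transform coefficients (DWTC), and a compact time-domain /
complexity feature group (the first Phinyomark feature set, ``Phin_FS1``)
composed of sample entropy, four AR-model cepstral coefficients, root mean
square and waveform length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from statsmodels.tsa.stattools import levinson_durbin

__all__ = [
    "WaveletConfig",
    "dwt_coeffs",
    "dwpt_coeffs",
    "rms",
    "waveform_length",
    "sample_entropy",
    "ar_cepstral",
    "cepstral_from_ar",
    "phin_fs1",
    "PHIN_FS1_LENGTH",
]


@dataclass(frozen=True)
class WaveletConfig:
    """Mother wavelet, decomposition depth and boundary handling.

    The wavelet family and depth are tunable; db1 (Haar) at 3 levels with
    symmetric extension is the default.  A window must hold at least
    ``2**levels`` frames.
    """

    family: str = "db1"
    levels: int = 3
    extension_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        pywt.Wavelet(self.family)  # raises on unknown family


def _check_length(L: int, cfg: WaveletConfig) -> None:
    if L < 2 ** cfg.levels:
        raise ValueError(
            f"signal of length {L} too short for {cfg.levels}-level "
            f"decomposition (need >= {2 ** cfg.levels} samples)")


def dwt_coeffs(x: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Multilevel DWT coefficients along the last axis.

    Returns the concatenation of the deepest approximation coefficients
    followed by detail coefficients from the deepest to the shallowest
    level.  Works on a single signal or any batch with time last.
    """
    x = np.asarray(x, dtype=np.float64)
    _check_length(x.shape[-1], cfg)
    coeffs = pywt.wavedec(x, cfg.family, mode=cfg.extension_mode,
                          level=cfg.levels, axis=-1)
    return np.concatenate(coeffs, axis=-1)


def dwpt_coeffs(x: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Full wavelet packet decomposition: all ``2**levels`` leaf blocks.

    Leaves are concatenated in natural node order along the last axis.
    """
    x = np.asarray(x, dtype=np.float64)
    _check_length(x.shape[-1], cfg)
    wp = pywt.WaveletPacket(x, cfg.family, mode=cfg.extension_mode,
                            maxlevel=cfg.levels, axis=-1)
    leaves = [wp[node.path].data for node in wp.get_level(cfg.levels, "natural")]
    return np.concatenate(leaves, axis=-1)


def rms(x: np.ndarray) -> float | np.ndarray:
    """Root mean square, ``sqrt(sum(x^2)/L)``, along the last axis."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("rms needs at least 2 samples")
    return np.sqrt(np.mean(x * x, axis=-1))


def waveform_length(x: np.ndarray) -> float | np.ndarray:
    """Cumulative absolute first difference along the last axis."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return np.sum(np.abs(np.diff(x, axis=-1)), axis=-1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` with Chebyshev tolerance ``r``.

    ``B`` counts unordered template pairs of length ``m`` within distance
    ``r``; ``A`` the same for length ``m + 1``; self-matches are excluded.
    If either count is zero the value is undefined, and a large finite
    sentinel (the log of the pair-count upper bound) is returned so that
    downstream feature images stay finite.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    L = x.shape[0]
    if L <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {L}")
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    def _count(mm: int) -> int:
        n = L - m  # same template count for both lengths keeps A/B comparable
        tpl = np.lib.stride_tricks.sliding_window_view(x, mm)[:n]
        d = np.abs(tpl[:, None, :] - tpl[None, :, :]).max(axis=-1)
        iu = np.triu_indices(n, k=1)
        return int((d[iu] <= r).sum())

    B = _count(m)
    A = _count(m + 1)
    if A == 0 or B == 0:
        n = L - m
        return float(np.log(max(n * (n - 1) / 2.0, np.e)))
    return float(-np.log(A / B))


def ar_cepstral(x: np.ndarray, order: int = 4) -> np.ndarray:
    """AR-model cepstral coefficients ``c_1 .. c_order``.

    Fits an AR(p) model by Levinson-Durbin on the biased (1/L)
    autocovariance — the biased estimator keeps the Toeplitz system
    positive definite — and converts the prediction-error coefficients
    ``a_k`` (convention ``x_t + a_1 x_{t-1} + ... = e_t``) to cepstral
    coefficients with the standard recursion
    ``c_1 = -a_1``, ``c_k = -a_k - sum_{l<k} (1 - l/k) a_l c_{k-l}``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    L = x.shape[0]
    if L <= order:
        raise ValueError(f"need more than order={order} samples, got {L}")
    xm = x - x.mean()
    acov = np.array([np.dot(xm[k:], xm[: L - k]) for k in range(order + 1)]) / L
    if acov[0] <= 0:
        raise ValueError("zero-variance signal: AR model undefined")
    _, arcoefs, *_ = levinson_durbin(acov, nlags=order, isacov=True)
    a = -np.asarray(arcoefs)  # prediction-error sign convention
    return cepstral_from_ar(a)


def cepstral_from_ar(a: np.ndarray) -> np.ndarray:
    """Cepstral coefficients of an AR model given ``a_1 .. a_p``."""
    a = np.asarray(a, dtype=np.float64)
    order = a.shape[0]
    c = np.zeros(order)
    for k in range(1, order + 1):
        acc = -a[k - 1]
        for l in range(1, k):
            acc -= (1.0 - l / k) * a[l - 1] * c[k - l - 1]
        c[k - 1] = acc
    return c


#: Length of the Phin_FS1 vector: SampEn + 4 cepstral + RMS + WL.
PHIN_FS1_LENGTH = 7


def phin_fs1(x: np.ndarray, m: int = 2, r_factor: float = 0.2,
             ar_order: int = 4) -> np.ndarray:
    """The compact Phinyomark time-domain/complexity feature group.

    Concatenates ``[SampEn, c_1..c_4, RMS, WL]`` (7 values per channel).
    On a zero-variance (constant) window the entropy tolerance and the AR
    model are undefined; both degenerate components are reported as 0 so
    the feature image stays finite.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    sigma = x.std()
    if sigma > 0:
        se = sample_entropy(x, m=m, r=r_factor * sigma)
        ceps = ar_cepstral(x, order=ar_order)
    else:
        se = 0.0
        ceps = np.zeros(ar_order)
    return np.concatenate([[se], ceps, [rms(x)], [waveform_length(x)]])
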