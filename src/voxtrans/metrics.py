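"""Volumetric similarity indices: CAD, L2, MSE, PSNR, MSSIM.

CAD (cosine angle distance) and L2 treat the two volumes as flat vectors:
CAD is the cosine of the angle between them, L2 the Euclidean distance.
MSSIM is the mean of local SSIM scores — luminance * contrast * structure —
over all fully-interior sliding windows, weighted by a circular-symmetric
Gaussian of standard deviation 1.5 samples normalized to unit sum.

For identical inputs the suite reports (1, 0, 0, +inf, 1); PSNR of
identical inputs is the +inf sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import Volume

__all__ = ["SsimParams", "SimilarityReport", "cad", "l2", "mse", "psnr",
           "mssim", "evaluate"]


def _arr(x) -> np.ndarray:
    if isinstance(x, Volume):
        x = x.data
    return np.asarray(x, dtype=np.float64)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass(frozen=True)
class SsimParams:
    """Window and stabilization constants of the SSIM factors.

    Defaults: 11^3 Gaussian window (sigma = 1.5 samples, truncated,
    unit-sum), C1 = (0.01 L)^2, C2 = (0.03 L)^2, C3 = C2 / 2, and unit
    exponents — with which l * c * s reduces to the familiar two-term SSIM.
    A uniform 7^3 window mode is available for parity with tools whose
    default skips Gaussian weighting.
    """

    window: str = "gaussian"     # "gaussian" | "uniform"
    window_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def kernel_1d(self) -> np.ndarray:
        if self.window == "uniform":
            size = self.window_size if self.window_size != 11 else 7
            return np.full(size, 1.0 / size)
        r = (self.window_size - 1) // 2
        x = np.arange(-r, r + 1, dtype=np.float64)
        w = np.exp(-(x ** 2) / (2.0 * self.sigma ** 2))
        return w / w.sum()


def cad(a, b) -> float:
    """Cosine angle distance: A.B / (||A|| * ||B||) on the flattened volumes."""
    a, b = _arr(a).ravel(), _arr(b).ravel()
    _check_shapes(a, b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("CAD is undefined for an all-zero volume")
    return float(a @ b / (na * nb))


def l2(a, b) -> float:
    """Euclidean distance: sqrt(sum (a_i - b_i)^2)."""
    a, b = _arr(a), _arr(b)
    _check_shapes(a, b)
    return float(np.sqrt(((a - b) ** 2).sum()))


def mse(a, b) -> float:
    a, b = _arr(a), _arr(b)
    _check_shapes(a, b)
    return float(((a - b) ** 2).mean())


def psnr(a, b, data_range: float = 1.0) -> float:
    """10 log10(L^2 / MSE) in dB; +inf sentinel for identical inputs."""
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    err = mse(a, b)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / err))


def _local_means(x: np.ndarray, k1d: np.ndarray) -> np.ndarray:
    """Separable windowed means; boundary values are cropped by the caller."""
    out = x
    for axis in range(x.ndim):
        out = ndimage.correlate1d(out, k1d, axis=axis, mode="constant", cval=0.0)
    return out

def mssim(a, b, params: SsimParams | None = None, data_range: float | None = None) -> float:
    """Mean SSIM over all fully-interior sliding windows.

    Per window: weighted means mu, weighted standard deviations sigma and
    covariance (weights sum to 1, no sample correction), then
    SSIM = l^alpha * c^beta * s^gamma with
    l = (2 mu_a mu_b + C1)/(mu_a^2 + mu_b^2 + C1),
    c = (2 s_a s_b + C2)/(s_a^2 + s_b^2 + C2),
    s = (cov + C3)/(s_a s_b + C3), C3 = C2/2.
    """
    params = params or SsimParams()
    a, b = _arr(a), _arr(b)
    _check_shapes(a, b)
    k1d = params.kernel_1d()
    size = k1d.size
    if min(a.shape) < size:
        raise ValueError(f"volume {a.shape} smaller than the {size}^3 window")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = float(hi - lo) if hi > lo else 1.0
    c1 = (params.k1 * data_range) ** 2
    c2 = (params.k2 * data_range) ** 2
    c3 = c2 / 2.0

    mu_a = _local_means(a, k1d)
    mu_b = _local_means(b, k1d)
    e_aa = _local_means(a * a, k1d)
    e_bb = _local_means(b * b, k1d)
    e_ab = _local_means(a * b, k1d)
    var_a = np.clip(e_aa - mu_a ** 2, 0.0, None)
    var_b = np.clip(e_bb - mu_b ** 2, 0.0, None)
    cov = e_ab - mu_a * mu_b
    sd_a, sd_b = np.sqrt(var_a), np.sqrt(var_b)

    lum = (2 * mu_a * mu_b + c1) / (mu_a ** 2 + mu_b ** 2 + c1)
    con = (2 * sd_a * sd_b + c2) / (var_a + var_b + c2)
    stru = (cov + c3) / (sd_a * sd_b + c3)
    ssim_map = np.sign(lum) * np.abs(lum) ** params.alpha \
        * con ** params.beta * np.sign(stru) * np.abs(stru) ** params.gamma

    r = (size - 1) // 2
    interior = tuple(slice(r, n - r) for n in a.shape)
    return float(ssim_map[interior].mean())


@dataclass(frozen=True)
class SimilarityReport:
    """The five indices for one (target, prediction) pair."""

    cad: float
    l2: float
    mse: float
    psnr: float
    mssim: float
    params: SsimParams = field(default_factory=SsimParams, compare=False)

    def as_dict(self) -> dict:
        return {"cad": self.cad, "l2": self.l2, "mse": self.mse,
                "psnr": self.psnr, "mssim": self.mssim}


def evaluate(target, prediction, params: SsimParams | None = None) -> SimilarityReport:
    """All five indices with the module defaults.

    CAD and L2 use the raw intensities.  MSE, PSNR, and MSSIM are computed
    after both volumes are rescaled together (joint min/max) onto [0, 1], so
    the data range L is 1; this keeps the three range-dependent indices on
    the scale at which MSE ~ 1e-3 and PSNR ~ 30 dB are mutually consistent.
    """
    params = params or SsimParams()
    a, b = _arr(target), _arr(prediction)
    _check_shapes(a, b)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    span = hi - lo if hi > lo else 1.0
    a01 = (a - lo) / span
    b01 = (b - lo) / span
    return SimilarityReport(
        cad=cad(a, b),
        l2=l2(a, b),
        mse=mse(a01, b01),
        psnr=psnr(a01, b01, data_range=1.0),
        mssim=mssim(a01, b01, params=params, data_range=1.0),
        params=params,
    )
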