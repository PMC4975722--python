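"""Rician magnitude-noise model: density, mean, bias adjustment, sigma estimation.

Magnitude MR signals with complex Gaussian noise follow the Rician law

    f(S; E, sigma) = S/sigma^2 exp(-(S^2 + E^2)/(2 sigma^2)) I0(S E / sigma^2),

whose mean exceeds the true signal E, most severely at low SNR.  The bias
adjustment inverts the mean function: the adjusted signal is the E >= 0
whose Rician mean best matches the measurement, which is a monotone 1-D
root-finding problem.  The noise level sigma is estimated voxelwise by
maximum likelihood from repeated b=0 images and summarized by its median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .exceptions import EstimationError

__all__ = [
    "NoiseModel",
    "rician_pdf",
    "rician_mean",
    "adjust_signal",
    "estimate_sigma_ml",
]

#: E[S]/sigma at E=0 (Rayleigh mean), sqrt(pi/2).
_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)


@dataclass(frozen=True)
class NoiseModel:
    """Scalar noise level sigma, in the same units as the signal."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


def rician_pdf(s, e, sigma):
    """Rician probability density of the measured magnitude s.

    Evaluated via the exponentially scaled Bessel function so that the
    large-argument regime (high SNR) does not overflow:
    f = s/sigma^2 * exp(-(s-e)^2 / (2 sigma^2)) * i0e(s e / sigma^2).
    """
    s = np.asarray(s, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(s < 0) or np.any(e < 0):
        raise ValueError("s and e must be >= 0")
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be > 0")
    s2 = sigma * sigma
    out = (s / s2) * np.exp(-((s - e) ** 2) / (2.0 * s2)) * special.i0e(s * e / s2)
    return out if out.ndim else float(out)


def _laguerre_half_neg(t):
    """Laguerre function L_{1/2}(-t) for t >= 0, overflow-safe.

    L_{1/2}(-t) = e^{-t/2} [ (1+t) I0(t/2) + t I1(t/2) ]
                = (1+t) i0e(t/2) + t i1e(t/2).
    """
    t = np.asarray(t, dtype=float)
    h = t / 2.0
    return (1.0 + t) * special.i0e(h) + t * special.i1e(h)


def rician_mean(e, sigma):
    """Expected magnitude sqrt(pi sigma^2 / 2) * L_{1/2}(-e^2 / (2 sigma^2)).

    Always >= max(e, sigma*sqrt(pi/2)); strictly increasing in e, which is
    what makes the bias adjustment well posed.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("e must be >= 0")
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be > 0")
    t = e * e / (2.0 * sigma * sigma)
    out = sigma * _RAYLEIGH_MEAN * _laguerre_half_neg(t)
    return out if out.ndim else float(out)


def adjust_signal(s, sigma):
    """Rician bias adjustment: invert the mean function at the measurement.

    Returns the nonnegative E with rician_mean(E, sigma) = s, i.e. the
    least-squares projection of s onto the attainable Rician means.
    Measurements at or below the noise floor sigma*sqrt(pi/2) (the infimum
    of the mean function) map to 0.  Vectorized bisection, monotone
    nondecreasing in s, accurate to ~1e-12 relative.
    """
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be > 0")
    s_arr = np.asarray(s, dtype=float)
    scalar = s_arr.ndim == 0
    s_arr = np.atleast_1d(s_arr).astype(float)
    out = np.zeros_like(s_arr)

    floor = sigma * _RAYLEIGH_MEAN
    active = s_arr > floor
    if np.any(active):
        sa = s_arr[active]
        lo = np.zeros_like(sa)
        hi = sa + 5.0 * sigma  # rician_mean(hi) >= hi > s, so the root is bracketed
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            too_low = rician_mean(mid, sigma) < sa
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        out[active] = 0.5 * (lo + hi)
    return float(out[0]) if scalar else out


def _rice_nll(theta, samples):
    e, sigma = theta
    if sigma <= 0 or e < 0:
        return np.inf
    s2 = sigma * sigma
    z = samples * e / s2
    ll = (
        np.log(samples / s2)
        - (samples - e) ** 2 / (2.0 * s2)
        + np.log(special.i0e(z))
        + 0.0
    )
    return -float(np.sum(ll))


def _moment_init(samples: np.ndarray) -> tuple[float, float]:
    """Rayleigh-corrected moment initialization for (E, sigma)."""
    m2 = float(np.mean(samples**2))
    var = float(np.var(samples))
    sigma0 = np.sqrt(max(var, 1e-12 * max(m2, 1e-30)))
    e0sq = m2 - 2.0 * sigma0 * sigma0
    if e0sq <= 0:  # Rayleigh-like: E[S^2] = 2 sigma^2
        return 0.0, np.sqrt(m2 / 2.0)
    return np.sqrt(e0sq), sigma0


def estimate_sigma_ml(b0_samples) -> NoiseModel:
    """Noise level from repeated unweighted (b=0) magnitudes.

    Per voxel, (E, sigma) are estimated jointly by maximizing the Rician
    log-likelihood of the repeats (Nelder-Mead from a moment start); the
    returned noise level is the median of the voxelwise sigma estimates,
    robust to the spatial variation and occasional non-convergence.

    Parameters
    ----------
    b0_samples : (n_voxels, n_repeats) array, n_repeats >= 2

    Raises
    ------
    EstimationError
        if estimation fails (or degenerates) in every voxel.
    """
    samples = np.atleast_2d(np.asarray(b0_samples, dtype=float))
    if samples.shape[1] < 2:
        raise ValueError("need at least 2 repeats per voxel")
    sigmas = []
    n_skipped = 0
    for vox in samples:
        vox = vox[np.isfinite(vox)]
        if vox.size < 2 or np.ptp(vox) == 0:
            n_skipped += 1  # identical repeats: sigma -> 0 boundary
            continue
        e0, s0 = _moment_init(vox)
        res = optimize.minimize(
            _rice_nll,
            x0=[e0, s0],
            args=(vox,),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if not res.success or res.x[1] <= 0:
            n_skipped += 1
            continue
        sigmas.append(float(res.x[1]))
    if n_skipped:
        warnings.warn(
            f"sigma estimation skipped {n_skipped} degenerate or "
            "non-converged voxel(s)",
            RuntimeWarning,
            stacklevel=2,
        )
    if not sigmas:
        raise EstimationError("noise estimation failed in every voxel")
    return NoiseModel(sigma=float(np.median(sigmas)))
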