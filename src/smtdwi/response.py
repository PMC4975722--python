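"""Axially symmetric per-axon impulse response and its spherical mean.

The diffusion signal of a small axonal segment (plus its characteristic
neighborhood) is modelled as a second-order, axially symmetric microscopic
tensor with effective diffusivities ``lam_par`` parallel and ``lam_perp``
perpendicular to the segment axis,

    h_b(c) = exp(-b c^2 lam_par) * exp(-b (1 - c^2) lam_perp),

where ``c`` is the cosine of the angle between the gradient direction and
the segment axis and ``b`` the diffusion weighting.  Its orientation
average over the sphere (the powder average) has the closed form

    e_bar(b) = exp(-b lam_perp) * sqrt(pi) * erf(sqrt(x)) / (2 sqrt(x)),
    x = b (lam_par - lam_perp),

equivalently ``exp(-b lam_perp) 1F1(1/2; 3/2; -x)``.  All b-values are in
ms/um^2 (1000 s/mm^2 == 1.0 ms/um^2) so diffusivities are O(1) um^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "LAMBDA_FREE",
    "MicroParams",
    "impulse_response",
    "spherical_mean_model",
    "spherical_mean_quadrature",
    "micro_md",
    "micro_fa",
    "anisotropy_index",
]

#: Bulk diffusivity of free water at body temperature (37 C), um^2/ms.
#: Physical upper bound for tissue diffusivities; configurable per fit for
#: e.g. ex-vivo data acquired at lower temperature.
LAMBDA_FREE = 3.05

# Below this value of x = b*(lam_par - lam_perp) the erf form of the
# spherical mean is evaluated by its Taylor series to avoid 0/0.
_SERIES_THRESHOLD = 1e-6


@dataclass(frozen=True)
class MicroParams:
    """Per-axon (microscopic) diffusivity pair in um^2/ms.

    Invariant: ``0 <= lam_perp <= lam_par <= LAMBDA_FREE`` — axonal
    membranes perpendicular to the fiber axis are the dominant barriers,
    and no tissue compartment diffuses faster than free water.
    """

    lam_par: float
    lam_perp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam_par) or not np.isfinite(self.lam_perp):
            raise ValueError("diffusivities must be finite")
        if self.lam_perp < 0:
            raise ValueError(f"lam_perp must be >= 0, got {self.lam_perp}")
        if self.lam_par < self.lam_perp:
            raise ValueError(
                f"lam_par ({self.lam_par}) must be >= lam_perp ({self.lam_perp})"
            )
        if self.lam_par > LAMBDA_FREE * (1 + 1e-12):
            raise ValueError(
                f"lam_par ({self.lam_par}) exceeds free-water bound {LAMBDA_FREE}"
            )

    def as_tuple(self) -> tuple[float, float]:
        return (self.lam_par, self.lam_perp)


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or not np.all(np.isfinite(b)):
        raise ValueError("b-values must be finite and >= 0 (ms/um^2)")
    return b


def impulse_response(b, cos_angle, params: MicroParams):
    """Signal fraction of a single fiber segment at angle arccos(c) to the gradient.

    Parameters
    ----------
    b : float or array
        Diffusion weighting, ms/um^2.
    cos_angle : float or array
        Cosine of the angle between gradient direction and segment axis,
        in [-1, 1].  The response is antipodally symmetric (even in c).
    params : MicroParams

    Returns
    -------
    float or ndarray in [0, 1]
    """
    b = _check_b(b)
    c = np.asarray(cos_angle, dtype=float)
    if np.any(np.abs(c) > 1 + 1e-12):
        raise ValueError("cos_angle must lie in [-1, 1]")
    c2 = np.clip(c * c, 0.0, 1.0)
    out = np.exp(-b * (c2 * params.lam_par + (1.0 - c2) * params.lam_perp))
    return out if out.ndim else float(out)


def _mean_kernel(x):
    """sqrt(pi)*erf(sqrt(x))/(2 sqrt(x)) = 1F1(1/2; 3/2; -x) for x >= 0.

    Switches to the hypergeometric series near zero where the erf form
    degenerates to 0/0.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < _SERIES_THRESHOLD
    xs = x[small]
    # 1F1(1/2;3/2;-x) = 1 - x/3 + x^2/10 - x^3/42 + ...
    out[small] = 1.0 - xs / 3.0 + xs * xs / 10.0 - xs ** 3 / 42.0
    xl = x[~small]
    sq = np.sqrt(xl)
    out[~small] = np.sqrt(np.pi) * special.erf(sq) / (2.0 * sq)
    return out


def spherical_mean_model(b, params: MicroParams):
    """Closed-form spherical mean (powder average) of the impulse response.

    ``exp(-b lam_perp) * 1F1(1/2; 3/2; -b (lam_par - lam_perp))``; the
    sufficient statistic the spherical mean technique fits per b-shell.
    """
    b = _check_b(b)
    x = b * (params.lam_par - params.lam_perp)
    out = np.exp(-b * params.lam_perp) * _mean_kernel(x)
    return out if out.ndim else float(out)


def spherical_mean_quadrature(b, params: MicroParams, n_nodes: int = 64):
    """Brute-force spherical mean by Gauss-Legendre quadrature.

    Integrates ``h_b(cos(theta)) sin(theta)`` over theta in [0, pi/2]
    (antipodal symmetry halves the domain).  Independent oracle for
    :func:`spherical_mean_model`.
    """
    if n_nodes < 16:
        raise ValueError("n_nodes must be >= 16")
    b = _check_b(b)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    theta = (nodes + 1.0) * (np.pi / 4.0)  # map [-1,1] -> [0, pi/2]
    w = weights * (np.pi / 4.0)
    c = np.cos(theta)
    integrand = impulse_response(
        np.atleast_1d(b)[..., None], c, params
    ) * np.sin(theta)
    out = integrand @ w
    return float(out[0]) if np.ndim(b) == 0 else out


def micro_md(params: MicroParams) -> float:
    """Per-axon mean diffusivity, (lam_par + 2 lam_perp) / 3, um^2/ms."""
    return (params.lam_par + 2.0 * params.lam_perp) / 3.0


def micro_fa(params: MicroParams) -> float:
    """Per-axon fractional anisotropy of the axially symmetric micro-tensor.

    FA = sqrt(3/2) * sqrt(((lam_par - md)^2 + 2 (lam_perp - md)^2)
                          / (lam_par^2 + 2 lam_perp^2))

    Defined as 0 for the fully degenerate case lam_par = lam_perp = 0
    (background / fluid voxels must not produce NaN maps).
    """
    lp, lt = params.lam_par, params.lam_perp
    denom = lp * lp + 2.0 * lt * lt
    if denom == 0.0:
        return 0.0
    md = (lp + 2.0 * lt) / 3.0
    fa = np.sqrt(1.5) * np.sqrt(((lp - md) ** 2 + 2.0 * (lt - md) ** 2) / denom)
    return float(min(fa, 1.0))


def anisotropy_index(params: MicroParams) -> float:
    """Per-axon anisotropy index lam_par / lam_perp (>= 1).

    Returns ``inf`` when lam_perp == 0 (and 1.0 for 0/0): an explicit
    sentinel rather than a crash, so map generation survives background
    voxels.
    """
    if params.lam_perp == 0.0:
        return 1.0 if params.lam_par == 0.0 else float("inf")
    return params.lam_par / params.lam_perp
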