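"""Spherical-mean estimation: shell means, constrained fits, maps, Monte Carlo.

The estimator works on the per-shell sample spherical means of the
(Rician-adjusted, b0-normalized) diffusion signal.  Because the spherical
mean is invariant to the fiber orientation distribution, fitting the
closed-form powder average e_bar(b; lam_par, lam_perp) to the shell means
recovers the per-axon diffusivities regardless of fiber dispersion and
crossing.  The fit is a constrained least squares over the physical
triangle 0 <= lam_perp <= lam_par <= lam_free: a coarse grid scan excludes
spurious local minima, then a bounded local refinement polishes the
solution — small, deterministic, and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import EstimationError
from .fod import DPMHyper, add_rician_noise, sample_dpm_fod, synthesize_signal
from .gradients import B0_THRESHOLD, GradientScheme, generate_uniform_scheme
from .response import (
    LAMBDA_FREE,
    MicroParams,
    _mean_kernel,
    anisotropy_index,
    micro_fa,
    micro_md,
)
from .rician import NoiseModel, adjust_signal

__all__ = [
    "ShellPartition",
    "ShellMeans",
    "SMTFit",
    "ParameterMaps",
    "group_shells",
    "shell_mean",
    "compute_shell_means",
    "fit_smt",
    "fit_volume",
    "shell_mean_volume",
    "dti_fit",
    "monte_carlo_experiment",
]

_GRID_N = 40  # coarse grid resolution per axis for the global scan


@dataclass
class ShellPartition:
    """Indices of the b=0 group and of each nonzero b-shell."""

    b0_indices: np.ndarray
    shell_bvals: np.ndarray  # average b per shell, ms/um^2
    shell_indices: list[np.ndarray]

    @property
    def n_shells(self) -> int:
        return len(self.shell_indices)


@dataclass
class ShellMeans:
    """Per-shell spherical-mean signal estimates — the SMT sufficient statistic."""

    shell_b: np.ndarray
    means: np.ndarray
    n_dirs: np.ndarray

    def __post_init__(self) -> None:
        self.shell_b = np.asarray(self.shell_b, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.n_dirs = np.asarray(self.n_dirs, dtype=int)
        if not (self.shell_b.size == self.means.size == self.n_dirs.size):
            raise ValueError("shell_b, means, n_dirs must have equal length")


@dataclass
class SMTFit:
    """Result of the constrained spherical-mean fit for one voxel."""

    params: MicroParams
    residual: float
    at_bound: dict = field(default_factory=dict)
    md: float = 0.0
    fa: float = 0.0
    ratio: float = 0.0

    def __post_init__(self) -> None:
        self.md = micro_md(self.params)
        self.fa = micro_fa(self.params)
        self.ratio = anisotropy_index(self.params)


@dataclass
class ParameterMaps:
    """Voxelwise microstructure maps; out-of-mask voxels hold NaN."""

    lam_par_map: np.ndarray
    lam_perp_map: np.ndarray
    md_map: np.ndarray
    fa_map: np.ndarray
    ratio_map: np.ndarray
    mean_signal_maps: dict
    mask: np.ndarray
    shell_bvals: np.ndarray
    sigma: float | None = None


def group_shells(
    scheme: GradientScheme,
    rel_tolerance: float = 0.1,
    require_multi_shell: bool = True,
) -> ShellPartition:
    """Partition measurements into the b=0 group and nonzero b-shells.

    Nonzero b-values are clustered greedily in sorted order: a measurement
    joins the current shell while it stays within ``rel_tolerance`` of the
    running shell average; the shell's b is the average of its members
    (small per-measurement b variations are absorbed into the nominal
    shell value).

    Raises
    ------
    EstimationError
        with ``require_multi_shell`` if fewer than 2 nonzero shells are
        found — a single shell leaves (lam_par, lam_perp) underdetermined.
    """
    bvals = scheme.bvals
    b0_idx = np.flatnonzero(bvals <= B0_THRESHOLD)
    dw_idx = np.flatnonzero(bvals > B0_THRESHOLD)

    order = dw_idx[np.argsort(bvals[dw_idx], kind="stable")]
    shells: list[list[int]] = []
    sums: list[float] = []
    for i in order:
        b = bvals[i]
        if shells:
            avg = sums[-1] / len(shells[-1])
            if abs(b - avg) <= rel_tolerance * avg:
                shells[-1].append(int(i))
                sums[-1] += b
                continue
        shells.append([int(i)])
        sums.append(float(b))

    if require_multi_shell and len(shells) < 2:
        raise EstimationError(
            "the spherical mean technique requires at least two nonzero "
            f"diffusion weightings; found {len(shells)} shell(s)"
        )
    shell_indices = [np.array(sorted(s)) for s in shells]
    shell_bvals = np.array([s / len(ix) for s, ix in zip(sums, shell_indices)])
    return ShellPartition(b0_idx, shell_bvals, shell_indices)


def shell_mean(normalized_signals, member_indices) -> float:
    """Sample spherical mean over one shell's gradient directions.

    The arithmetic mean is an unbiased estimate of the spherical mean when
    the directions together with their antipodes are uniform on the sphere.
    """
    idx = np.asarray(member_indices)
    if idx.size < 6:
        raise ValueError("a shell needs at least 6 directions for a stable mean")
    vals = np.asarray(normalized_signals, dtype=float)[idx]
    return float(np.mean(vals))


def compute_shell_means(
    normalized_signals, partition: ShellPartition
) -> ShellMeans:
    """Shell means for all nonzero shells of a partition."""
    means = [shell_mean(normalized_signals, ix) for ix in partition.shell_indices]
    n_dirs = [ix.size for ix in partition.shell_indices]
    return ShellMeans(partition.shell_bvals, np.array(means), np.array(n_dirs))


def _sse(lam_par, lam_perp, shell_b, means):
    pred = np.exp(-np.multiply.outer(lam_perp, shell_b))
    pred = pred * _mean_kernel(np.multiply.outer(lam_par - lam_perp, shell_b))
    return np.sum((pred - means) ** 2, axis=-1)


def fit_smt(shell_means: ShellMeans, lam_free: float = LAMBDA_FREE) -> SMTFit:
    """Constrained least-squares fit of (lam_par, lam_perp) to shell means.

    Minimizes sum_i (e_hat_i - e_bar(b_i; lam_par, lam_perp))^2 subject to
    0 <= lam_perp <= lam_par <= lam_free.  Strategy: coarse grid over the
    feasible triangle, then bounded local least squares in the
    reparameterization (u, v) -> (lam_perp, lam_par) = (u, u + v (1 - u/lam_free))
    which maps the unit box onto the triangle and enforces the ordering by
    construction.  Deterministic for fixed input.
    """
    b = shell_means.shell_b
    means = shell_means.means
    if b.size < 2:
        raise EstimationError("SMT needs >= 2 nonzero shells")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(means))):
        raise ValueError("non-finite shell means or b-values")

    # coarse global scan over the triangle
    u = np.linspace(0.0, lam_free, _GRID_N)  # lam_perp
    v = np.linspace(0.0, lam_free, _GRID_N)  # lam_par - lam_perp (scaled)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pp = uu + vv * (1.0 - uu / lam_free)
    sse = _sse(pp.ravel(), uu.ravel(), b, means)
    order = np.argsort(sse)[:3]  # multistart from the best grid cells

    def residuals(x):
        lam_perp = x[0]
        lam_par = x[0] + x[1] * (1.0 - x[0] / lam_free)
        pred = np.exp(-lam_perp * b) * _mean_kernel((lam_par - lam_perp) * b)
        return pred - means

    # starts are nudged off the box boundary, where the trust-region step
    # can stall on a degenerate direction
    eps = 1e-3 * lam_free
    res = None
    for k in order:
        x0 = np.clip(
            [uu.ravel()[k], vv.ravel()[k]], eps, lam_free - eps
        )
        cand = optimize.least_squares(
            residuals,
            x0=x0,
            bounds=([0.0, 0.0], [lam_free, lam_free]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=500,
        )
        if res is None or cand.cost < res.cost:
            res = cand
        if res.cost < 1e-24:
            break
    u_hat, v_hat = res.x
    lam_perp = float(np.clip(u_hat, 0.0, lam_free))
    lam_par = float(
        np.clip(u_hat + v_hat * (1.0 - u_hat / lam_free), lam_perp, lam_free)
    )
    params = MicroParams(lam_par=lam_par, lam_perp=lam_perp)

    tol = 1e-6 * lam_free
    at_bound = {
        "perp_at_zero": lam_perp <= tol,
        "equal_diffusivities": (lam_par - lam_perp) <= tol,
        "par_at_free": (lam_free - lam_par) <= tol,
    }
    return SMTFit(
        params=params,
        residual=float(np.sum(residuals(res.x) ** 2)),
        at_bound=at_bound,
    )


def fit_volume(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    lam_free: float = LAMBDA_FREE,
    rel_tolerance: float = 0.1,
) -> ParameterMaps:
    """Voxelwise SMT over a 4-D volume.

    Pipeline per in-mask voxel: Rician bias adjustment of all measurements
    (if a noise model is given) -> normalization by the adjusted mean b=0
    signal -> clamp of the normalized fractions to [0, 1] -> per-shell
    sample means -> constrained fit -> derived per-axon metrics.  Voxels
    whose mean b=0 signal does not exceed 3 sigma are treated as background
    and excluded.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4-D (x, y, z, measurement)")
    if dwi.shape[-1] != len(scheme):
        raise ValueError(
            f"dwi has {dwi.shape[-1]} measurements but scheme has {len(scheme)}"
        )
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match volume")

    partition = group_shells(scheme, rel_tolerance=rel_tolerance)
    if partition.b0_indices.size == 0:
        raise ValueError("scheme contains no b=0 measurement to normalize by")

    data = dwi[mask]  # (n_vox, n_meas)
    if noise is not None:
        data = adjust_signal(data, noise.sigma)
    b0_mean = data[:, partition.b0_indices].mean(axis=1)

    sigma = noise.sigma if noise is not None else 0.0
    foreground = b0_mean > 3.0 * sigma
    nan = np.full(shape, np.nan)
    maps = ParameterMaps(
        lam_par_map=nan.copy(),
        lam_perp_map=nan.copy(),
        md_map=nan.copy(),
        fa_map=nan.copy(),
        ratio_map=nan.copy(),
        mean_signal_maps={
            f"{b:g}": nan.copy() for b in partition.shell_bvals
        },
        mask=mask & _scatter(mask, foreground, shape),
        shell_bvals=partition.shell_bvals,
        sigma=(noise.sigma if noise is not None else None),
    )

    vox_coords = np.argwhere(mask)
    for row, (keep, b0) in enumerate(zip(foreground, b0_mean)):
        if not keep or b0 <= 0:
            continue
        normalized = np.clip(data[row] / b0, 0.0, 1.0)
        sm = compute_shell_means(normalized, partition)
        fit = fit_smt(sm, lam_free=lam_free)
        x, y, z = vox_coords[row]
        maps.lam_par_map[x, y, z] = fit.params.lam_par
        maps.lam_perp_map[x, y, z] = fit.params.lam_perp
        maps.md_map[x, y, z] = fit.md
        maps.fa_map[x, y, z] = fit.fa
        maps.ratio_map[x, y, z] = fit.ratio
        for bkey, m in zip(maps.mean_signal_maps, sm.means):
            maps.mean_signal_maps[bkey][x, y, z] = m
    return maps


def shell_mean_volume(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    rel_tolerance: float = 0.1,
) -> tuple[dict, np.ndarray]:
    """Spherical-mean maps only (no microstructure fit), fully vectorized.

    Returns ``(mean_maps, shell_bvals)`` where ``mean_maps`` maps the shell
    b-value label to a 3-D volume of sample spherical means of the
    adjusted, b0-normalized, clamped signal.  Useful on its own: the
    per-voxel vector of shell means is orientation-invariant and a
    microstructural biomarker in its own right.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[-1] != len(scheme):
        raise ValueError("dwi shape inconsistent with scheme")
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)

    partition = group_shells(
        scheme, rel_tolerance=rel_tolerance, require_multi_shell=False
    )
    if partition.b0_indices.size == 0:
        raise ValueError("scheme contains no b=0 measurement to normalize by")
    data = dwi[mask]
    if noise is not None:
        data = adjust_signal(data, noise.sigma)
    b0 = data[:, partition.b0_indices].mean(axis=1)
    ok = b0 > (3.0 * noise.sigma if noise is not None else 0.0)
    normalized = np.clip(
        data / np.where(b0 > 0, b0, np.inf)[:, None], 0.0, 1.0
    )
    mean_maps = {}
    for b, ix in zip(partition.shell_bvals, partition.shell_indices):
        vol = np.full(shape, np.nan)
        vals = normalized[:, ix].mean(axis=1)
        vals[~ok] = np.nan
        vol[mask] = vals
        mean_maps[f"{b:g}"] = vol
    return mean_maps, partition.shell_bvals


def _scatter(mask, values, shape):
    out = np.zeros(shape, dtype=bool)
    out[mask] = values
    return out


def dti_fit(normalized_signals, scheme: GradientScheme):
    """Ordinary log-linear diffusion tensor fit (voxel-scale comparison).

    Fits ln e = -b g^T D g by least squares over measurements with positive
    signal; returns (eigenvalues desc, FA, MD).  The tensor FA conflates
    microstructure with orientation dispersion — the contrast SMT removes.
    """
    e = np.asarray(normalized_signals, dtype=float)
    dw = ~scheme.b0_mask
    usable = dw & (e > 0)
    if usable.sum() < 6:
        raise EstimationError("tensor fit needs >= 6 usable weighted signals")
    g = scheme.bvecs[usable]
    b = scheme.bvals[usable]
    design = -b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    coef, *_ = np.linalg.lstsq(design, np.log(e[usable]), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    tensor = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    evals = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    md = float(evals.mean())
    denom = float(np.sum(evals**2))
    fa = 0.0 if denom == 0 else float(
        np.sqrt(1.5 * np.sum((evals - md) ** 2) / denom)
    )
    return evals, fa, md


def _trial_estimate(
    noisy: np.ndarray,
    scheme: GradientScheme,
    partition: ShellPartition,
    sigma: float | None,
    lam_free: float,
) -> tuple[np.ndarray, SMTFit]:
    """Adjust -> normalize -> clamp -> shell means -> fit, for one trial."""
    sig = noisy if sigma is None else adjust_signal(noisy, sigma)
    b0 = sig[partition.b0_indices].mean()
    normalized = np.clip(sig / b0, 0.0, 1.0)
    sm = compute_shell_means(normalized, partition)
    fit = fit_smt(sm, lam_free=lam_free)
    return sm.means, fit


def monte_carlo_experiment(
    snr_grid=(5.0, 10.0, 17.5, 20.0, 40.0),
    ndir_grid=(12, 25, 50, 76),
    n_trials: int = 500,
    truth: MicroParams = MicroParams(2.5, 0.1),
    hyper: DPMHyper = DPMHyper(),
    rng_seed: int = 0,
    shells=(1.0, 2.5),
    protocol_dirs=(76, 75),
    n_b0: int = 10,
    protocol_snr: float = 17.5,
    lam_free: float = LAMBDA_FREE,
    quad_order: int = 4096,
) -> pd.DataFrame:
    """Monte-Carlo accuracy study of the spherical-mean estimator.

    Per trial a random FOD is drawn from the Dirichlet-process Watson
    mixture, the two-shell signal is synthesized by spherical convolution,
    corrupted with Rician noise, bias-adjusted, normalized, averaged per
    shell and fitted.  Two sweeps share the per-trial FOD and noiseless
    signals (common random numbers): SNR at the full protocol, and
    direction count (prefix subsets per shell) at the protocol SNR.

    Returns a tidy DataFrame with one row per (trial, configuration):
    columns sweep, snr, n_dirs, trial, mean_b<k> per shell, lam_par_hat,
    lam_perp_hat.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    scheme = generate_uniform_scheme(
        list(protocol_dirs), list(shells), n_b0=n_b0, rng_seed=rng_seed
    )
    partition = group_shells(scheme)

    # prefix subsets: first n directions of each shell + all b0s
    subset_idx = {}
    for n in ndir_grid:
        keep = list(partition.b0_indices)
        for ix in partition.shell_indices:
            keep.extend(ix[: min(n, ix.size)])
        subset_idx[n] = np.array(sorted(keep))

    ss = np.random.SeedSequence(rng_seed)
    fod_seeds = ss.spawn(n_trials)

    rows = []
    for t in range(n_trials):
        fod = sample_dpm_fod(hyper, fod_seeds[t])
        clean = synthesize_signal(fod, scheme, truth, quad_order=quad_order)
        # per-config independent noise, reproducible: seed from (trial, config)
        for k, snr in enumerate(snr_grid):
            if np.isinf(snr):
                noisy, sigma = clean.copy(), None
            else:
                sigma = 1.0 / float(snr)
                seed = np.random.SeedSequence([rng_seed, 7919, t, k])
                noisy = add_rician_noise(clean, sigma, seed)
            means, fit = _trial_estimate(noisy, scheme, partition, sigma, lam_free)
            rows.append(
                _row("snr", snr, max(protocol_dirs), t, means, fit)
            )
        sigma = 1.0 / float(protocol_snr)
        seed = np.random.SeedSequence([rng_seed, 104729, t])
        noisy_full = add_rician_noise(clean, sigma, seed)
        for n in ndir_grid:
            idx = subset_idx[n]
            sub_scheme = scheme.subset(idx)
            sub_part = group_shells(sub_scheme)
            means, fit = _trial_estimate(
                noisy_full[idx], sub_scheme, sub_part, sigma, lam_free
            )
            rows.append(_row("ndirs", protocol_snr, n, t, means, fit))
    return pd.DataFrame(rows)


def _row(sweep, snr, n_dirs, trial, means, fit: SMTFit) -> dict:
    row = {
        "sweep": sweep,
        "snr": snr,
        "n_dirs": int(n_dirs),
        "trial": int(trial),
        "lam_par_hat": fit.params.lam_par,
        "lam_perp_hat": fit.params.lam_perp,
    }
    for k, m in enumerate(means, start=1):
        row[f"mean_b{k}"] = float(m)
    return row
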