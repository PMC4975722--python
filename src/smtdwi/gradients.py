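"""Gradient schemes: containers, uniform-direction generation, FSL text I/O.

Internally b-values are ms/um^2; on disk (FSL bval files) they are s/mm^2.
Directions are unit vectors; the zero vector is allowed only for b=0
entries.  Antipodal symmetry of the diffusion signal makes the sign of a
direction irrelevant, so vectors are taken as given and never re-signed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .exceptions import FormatError

__all__ = [
    "B0_THRESHOLD",
    "GradientScheme",
    "generate_uniform_scheme",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "SMM2_PER_MSUM2",
]

#: b-values below this (ms/um^2, i.e. 50 s/mm^2) count as unweighted (b=0).
B0_THRESHOLD = 0.05

#: s/mm^2 per ms/um^2.
SMM2_PER_MSUM2 = 1000.0


@dataclass
class GradientScheme:
    """Per-measurement diffusion weightings and gradient directions.

    bvals : (n,) array, ms/um^2
    bvecs : (n, 3) array of unit vectors (zero allowed where b ~ 0)
    shell_ids : optional (n,) array of shell labels; "b0" for unweighted
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise FormatError(
                f"bvecs shape {self.bvecs.shape} inconsistent with "
                f"{self.bvals.size} b-values"
            )
        if np.any(self.bvals < 0):
            raise FormatError("negative b-value in scheme")
        norms = np.linalg.norm(self.bvecs, axis=1)
        weighted = self.bvals > B0_THRESHOLD
        bad = weighted & (np.abs(norms - 1.0) > 1e-8)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"gradient direction {i} (b={self.bvals[i]:g} ms/um^2) is not "
                f"unit norm (|g|={norms[i]:g})"
            )

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    def subset(self, indices) -> "GradientScheme":
        idx = np.asarray(indices)
        ids = None if self.shell_ids is None else self.shell_ids[idx]
        return GradientScheme(self.bvals[idx], self.bvecs[idx], ids)


def _pair_energy(x: np.ndarray) -> float:
    """Electrostatic energy of antipodal point pairs (1/r Coulomb)."""
    d = x[:, None, :] - x[None, :, :]
    s = x[:, None, :] + x[None, :, :]
    dn = np.linalg.norm(d, axis=-1)
    sn = np.linalg.norm(s, axis=-1)
    iu = np.triu_indices(len(x), k=1)
    return float(np.sum(1.0 / dn[iu]) + np.sum(1.0 / sn[iu]))


def _repulsion_directions(n: int, rng: np.random.Generator,
                          n_iter: int = 400) -> np.ndarray:
    """Minimize the Coulomb energy of n antipodal point pairs on the sphere.

    Projected gradient descent with backtracking from a random start; the
    classic electrostatic-repulsion construction of uniform DWI schemes.
    """
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    energy = _pair_energy(x)
    step = 0.05 / n
    for _ in range(n_iter):
        d = x[:, None, :] - x[None, :, :]
        s = x[:, None, :] + x[None, :, :]
        dn = np.linalg.norm(d, axis=-1)
        sn = np.linalg.norm(s, axis=-1)
        np.fill_diagonal(dn, np.inf)
        force = np.sum(d / dn[..., None] ** 3, axis=1)
        force += np.sum(s / sn[..., None] ** 3, axis=1)
        # tangential component only
        force -= np.sum(force * x, axis=1, keepdims=True) * x
        x_new = x + step * force
        x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
        e_new = _pair_energy(x_new)
        if e_new < energy:
            x, energy = x_new, e_new
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12 / n:
                break
    return x


def generate_uniform_scheme(
    n_dirs_per_shell,
    bvals_shells,
    n_b0: int = 10,
    rng_seed: int = 0,
) -> GradientScheme:
    """Generate an antipodally uniform multi-shell gradient scheme.

    Each shell's directions (together with their antipodal points) are
    spread over the sphere by electrostatic-repulsion minimization from a
    seeded random start.  b=0 measurements are interleaved evenly across
    the experiment, mirroring how unweighted volumes are acquired.

    Parameters
    ----------
    n_dirs_per_shell : sequence of int (each >= 6)
    bvals_shells : sequence of float, ms/um^2
    n_b0 : number of unweighted measurements
    rng_seed : seed for the repulsion starts
    """
    n_dirs_per_shell = list(n_dirs_per_shell)
    bvals_shells = [float(b) for b in bvals_shells]
    if len(n_dirs_per_shell) != len(bvals_shells):
        raise ValueError("n_dirs_per_shell and bvals_shells lengths differ")
    if any(n < 6 for n in n_dirs_per_shell):
        raise ValueError("each shell needs at least 6 directions")

    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(n_dirs_per_shell))
    bvals, bvecs, ids = [], [], []
    for k, (n, b, child) in enumerate(
        zip(n_dirs_per_shell, bvals_shells, children)
    ):
        dirs = _repulsion_directions(n, np.random.default_rng(child))
        bvals.extend([b] * n)
        bvecs.extend(dirs)
        ids.extend([f"b{k + 1}"] * n)
    bvals = np.array(bvals)
    bvecs = np.array(bvecs)
    ids = np.array(ids, dtype=object)

    n_dw = len(bvals)
    total = n_dw + n_b0
    # evenly spaced slots for the unweighted measurements
    b0_pos = np.round(np.linspace(0, total - 1, n_b0)).astype(int) if n_b0 else []
    out_b = np.zeros(total)
    out_v = np.zeros((total, 3))
    out_i = np.empty(total, dtype=object)
    dw_slots = np.setdiff1d(np.arange(total), b0_pos)
    out_b[dw_slots] = bvals
    out_v[dw_slots] = bvecs
    out_i[dw_slots] = ids
    out_i[list(b0_pos)] = "b0"
    return GradientScheme(out_b, out_v, out_i)


def _parse_numeric_table(text: str, path: str) -> np.ndarray:
    """Parse whitespace- or comma-separated numeric rows, tolerating a
    single non-numeric header line."""
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip().lstrip("﻿")
        if not line or line.startswith("#"):
            continue
        tokens = line.replace(",", " ").split()
        try:
            rows.append([float(t) for t in tokens])
        except ValueError:
            if not rows and lineno <= 2:  # tolerated header row
                continue
            raise FormatError(
                f"{path}: non-numeric entry on line {lineno}: {line[:60]!r}"
            ) from None
    if not rows:
        raise FormatError(f"{path}: no numeric data found")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise FormatError(f"{path}: ragged rows (lengths {sorted(lengths)})")
    return np.array(rows)


def read_bvals_bvecs(bvals_path, bvecs_path) -> GradientScheme:
    """Read an FSL-style bval/bvec pair into a scheme (converting to ms/um^2).

    bvals: one row (or column) of b-values in s/mm^2.  bvecs: 3 rows x n
    columns (or n x 3).  Nonzero-b directions are normalized to unit
    length; an unnormalizable (zero) vector at nonzero b is a format error.
    """
    with open(bvals_path) as fh:
        bvals = _parse_numeric_table(fh.read(), str(bvals_path))
    with open(bvecs_path) as fh:
        bvecs = _parse_numeric_table(fh.read(), str(bvecs_path))

    bvals = bvals.ravel() / SMM2_PER_MSUM2
    # FSL convention: 3 rows (x, y, z) x n measurements; a 3x3 table is
    # read as FSL rows
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise FormatError(
            f"{bvecs_path}: expected 3 x n or n x 3 table, got {bvecs.shape}"
        )
    if bvecs.shape[0] != bvals.size:
        raise FormatError(
            f"{bvecs_path}: {bvecs.shape[0]} directions but "
            f"{bvals.size} b-values in {bvals_path}"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > B0_THRESHOLD
    if np.any(weighted & (norms < 1e-12)):
        i = int(np.flatnonzero(weighted & (norms < 1e-12))[0])
        raise FormatError(
            f"{bvecs_path}: zero gradient vector at measurement {i} with "
            f"b={bvals[i] * SMM2_PER_MSUM2:g} s/mm^2"
        )
    safe = np.where(norms > 1e-12, norms, 1.0)
    bvecs = bvecs / safe[:, None]
    bvecs[~weighted & (norms < 1e-12)] = 0.0
    return GradientScheme(bvals, bvecs)


def write_bvals_bvecs(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    """Write FSL-style text files (bvals in s/mm^2, bvecs as 3 rows)."""
    with open(bvals_path, "w") as fh:
        fh.write(" ".join(f"{b * SMM2_PER_MSUM2:.6g}" for b in scheme.bvals))
        fh.write("\n")
    with open(bvecs_path, "w") as fh:
        buf = io.StringIO()
        np.savetxt(buf, scheme.bvecs.T, fmt="%.17g", delimiter=" ")
        fh.write(buf.getvalue())
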