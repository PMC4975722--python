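"""NIfTI / gradient-table I/O and the JSON fit report.

Volumes are float32 on disk, float64 in memory; maps are written in the
input volume's native grid and affine (no resampling).  The fit report is
a small JSON document recording the configuration, noise level and shell
table of a run so that results are reproducible from the report alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .estimation import ParameterMaps
from .exceptions import FormatError
from .gradients import GradientScheme, read_bvals_bvecs
from .response import LAMBDA_FREE

__all__ = [
    "VolumeStack",
    "RunConfig",
    "read_dwi",
    "write_maps",
    "validate_report",
    "REPORT_REQUIRED_KEYS",
]

REPORT_REQUIRED_KEYS = (
    "software",
    "version",
    "config",
    "sigma",
    "shells",
    "n_voxels_fit",
)


@dataclass
class VolumeStack:
    """4-D data array (x, y, z, measurement) plus its spatial affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected a 4-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine must be an invertible 4x4 matrix")


@dataclass
class RunConfig:
    """Serializable configuration of a fit run (written into the report)."""

    lambda_free: float = LAMBDA_FREE
    shell_tolerance: float = 0.1
    sigma_mode: str = "given"  # "given" | "estimate" | "none"
    seed: int = 0
    clamp_policy: bool = True
    log_level: str = "INFO"


def read_dwi(nifti_path, bvals_path, bvecs_path) -> tuple[VolumeStack, GradientScheme]:
    """Load a 4-D DWI NIfTI with its FSL bval/bvec pair.

    b-values are converted from s/mm^2 on disk to ms/um^2 in memory;
    measurement order is preserved and checked against the 4th dimension.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: expected 4-D data, got {data.ndim}-D")
    scheme = read_bvals_bvecs(bvals_path, bvecs_path)
    if len(scheme) != data.shape[-1]:
        raise FormatError(
            f"{nifti_path}: {data.shape[-1]} volumes but gradient table has "
            f"{len(scheme)} entries"
        )
    return VolumeStack(data, img.affine), scheme


def _save_map(arr: np.ndarray, affine: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))


def write_maps(
    maps: ParameterMaps,
    affine: np.ndarray,
    out_prefix,
    config: RunConfig | None = None,
) -> dict:
    """Write one NIfTI per parameter map plus a JSON fit report.

    Returns a dict mapping logical map names to the written file paths.
    Out-of-mask voxels are NaN in the float maps.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    named = {
        "lam_par": maps.lam_par_map,
        "lam_perp": maps.lam_perp_map,
        "md": maps.md_map,
        "fa": maps.fa_map,
        "ratio": maps.ratio_map,
        "mask": maps.mask.astype(np.float32),
    }
    for key, vol in maps.mean_signal_maps.items():
        named[f"mean_b{key}"] = vol

    written = {}
    for name, vol in named.items():
        path = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        _save_map(vol, affine, path)
        written[name] = str(path)

    report = {
        "software": "smtdwi",
        "version": __version__,
        "config": asdict(config) if config is not None else asdict(RunConfig()),
        "sigma": maps.sigma,
        "shells": [
            {"b_ms_per_um2": float(b), "mean_map": f"mean_b{b:g}"}
            for b in maps.shell_bvals
        ],
        "n_voxels_fit": int(np.sum(maps.mask)),
        "maps": written,
    }
    report_path = prefix.parent / f"{prefix.name}_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    written["report"] = str(report_path)
    return written


def validate_report(report: dict) -> None:
    """Check a fit report against the repository schema (required keys)."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise FormatError(f"fit report missing required keys: {missing}")
    if not isinstance(report["shells"], list) or len(report["shells"]) < 1:
        raise FormatError("fit report must list at least one shell")
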