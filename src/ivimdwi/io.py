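"""Reading and writing the package's on-disk formats.

Stacks travel as 4-D NIfTI volumes with a companion whitespace-separated
b-value file (FSL ``.bval`` dialect: one row, same order as the volumes).
Parameter maps are written as 3-D NIfTI in x10^-3 mm^2/s units — the
conventional reporting scale — with the convention recorded in the NIfTI
description field; the in-memory maps stay in mm^2/s.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import DWIStack, ParameterMaps
from .signal_models import BValueScheme

__all__ = [
    "read_bvals",
    "write_bvals",
    "read_dwi_stack",
    "write_dwi_stack",
    "write_parameter_maps",
    "read_parameter_map",
]

MAP_SCALE = 1e3  # mm^2/s -> x10^-3 mm^2/s at the serialization boundary
_DESC = b"ADC maps in x10^-3 mm^2/s"


def read_bvals(path) -> BValueScheme:
    """Parse a one-row whitespace-separated b-value file."""
    text = Path(path).read_text().split()
    return BValueScheme(tuple(float(v) for v in text))


def write_bvals(scheme: BValueScheme, path) -> None:
    Path(path).write_text(" ".join(f"{v:g}" for v in scheme.values) + "\n")


def _default_affine(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def read_dwi_stack(nifti_path, bval_path) -> DWIStack:
    """Load a 4-D NIfTI plus bval file into a :class:`DWIStack`."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path} is not a 4-D volume")
    scheme = read_bvals(bval_path)
    zooms = img.header.get_zooms()[:3]
    return DWIStack(
        data=data,
        scheme=scheme,
        spacing=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
        affine=np.asarray(img.affine),
    )


def write_dwi_stack(stack: DWIStack, nifti_path, bval_path) -> None:
    affine = stack.affine if stack.affine is not None else _default_affine(stack.spacing)
    # float64 keeps noiseless round trips exact; stacks are small
    img = nib.Nifti1Image(stack.data.astype(np.float64), affine)
    img.header.set_zooms((*stack.spacing, 1.0))
    nib.save(img, str(nifti_path))
    write_bvals(stack.scheme, bval_path)


def write_parameter_maps(
    maps: ParameterMaps, out_dir, affine: np.ndarray | None = None,
    spacing=(1.0, 1.0, 5.0),
) -> dict[str, str]:
    """Write every map as a 3-D NIfTI; ADC maps scaled to x10^-3 mm^2/s.

    The perfusion fraction ``f`` and the quality codes are written
    unscaled.  Returns a name -> path manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = _default_affine(spacing)
    manifest: dict[str, str] = {}

    def _save(name: str, data: np.ndarray, scale: float, desc: bytes) -> None:
        img = nib.Nifti1Image((data * scale).astype(np.float32), affine)
        img.header["descrip"] = desc
        path = out_dir / f"{name}.nii.gz"
        nib.save(img, str(path))
        manifest[name] = str(path)

    for b, vol in maps.adc_b.items():
        _save(f"adc_{int(b)}", vol, MAP_SCALE, _DESC)
    _save("adc_total", maps.adc_total, MAP_SCALE, _DESC)
    _save("adc_slow", maps.adc_slow, MAP_SCALE, _DESC)
    _save("adc_fast", maps.adc_fast, MAP_SCALE, _DESC)
    _save("f", maps.f, 1.0, b"perfusion fraction (dimensionless)")
    _save("quality", maps.quality.astype(np.float32), 1.0, b"fit quality codes")
    (out_dir / "maps_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_parameter_map(path, rescale: bool = True) -> np.ndarray:
    """Load a single map back into mm^2/s (undoing the x10^-3 convention)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if rescale:
        data = data / MAP_SCALE
    return data
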