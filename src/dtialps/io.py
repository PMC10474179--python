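"""NIfTI, gradient-table and YAML configuration I/O.

Tensor volumes are written as 6-volume NIfTI in lower-triangular order
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz), the layout FSL's dtifit and most viewers
expect; loading converts back to the package's internal (Dxx, Dyy, Dzz,
Dxy, Dxz, Dyz) order.  Images are reoriented to RAS on load.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .alps import ROIConfig
from .gradients import GradientTable, load_fsl_gradients, save_fsl_gradients
from .tensor import DiffusionVolume, ScalarMap, TensorVolume

__all__ = [
    "save_nifti",
    "load_labels",
    "save_tensor",
    "load_tensor",
    "save_dwi",
    "load_dwi",
    "save_scalar_map",
    "load_scalar_map",
    "load_roi_config",
    "save_roi_config",
    "write_sidecar",
]

_LOWTRI_TO_INTERNAL = (0, 2, 5, 1, 3, 4)  # inverse of tensor.LOWER_TRI_ORDER


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float)), str(path))


def _load_canonical(path: str | Path) -> nib.Nifti1Image:
    return nib.as_closest_canonical(nib.load(str(path)))


def load_labels(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = _load_canonical(path)
    return np.asarray(img.dataobj).astype(np.int32), img.affine


def save_tensor(tensor: TensorVolume, path: str | Path, sidecar: dict | None = None) -> None:
    save_nifti(tensor.lower_triangular(), tensor.affine, path)
    if sidecar is not None:
        write_sidecar(path, sidecar)


def load_tensor(path: str | Path) -> TensorVolume:
    img = _load_canonical(path)
    lowtri = np.asarray(img.dataobj, dtype=float)
    if lowtri.ndim != 4 or lowtri.shape[-1] != 6:
        raise ValueError(f"expected a 6-volume tensor image, got shape {lowtri.shape}")
    return TensorVolume(components=lowtri[..., list(_LOWTRI_TO_INTERNAL)], affine=img.affine)


def save_dwi(dwi: DiffusionVolume, prefix: str | Path) -> None:
    """Write ``<prefix>.nii.gz`` plus FSL ``<prefix>.bval``/``.bvec``."""
    prefix = Path(prefix)
    save_nifti(dwi.signal, dwi.affine, prefix.with_suffix(".nii.gz"))
    save_fsl_gradients(dwi.gradients, prefix.with_suffix(".bval"), prefix.with_suffix(".bvec"))


def load_dwi(nifti_path: str | Path, bval_path: str | Path, bvec_path: str | Path) -> DiffusionVolume:
    img = _load_canonical(nifti_path)
    gtab = load_fsl_gradients(bval_path, bvec_path)
    zooms = img.header.get_zooms()[:3]
    return DiffusionVolume(
        signal=np.asarray(img.dataobj, dtype=float),
        gradients=gtab,
        affine=img.affine,
        voxel_size=float(zooms[0]),
    )


def save_scalar_map(m: ScalarMap, path: str | Path) -> None:
    save_nifti(m.values, m.affine, path)


def load_scalar_map(path: str | Path, name: str = "scalar") -> ScalarMap:
    img = _load_canonical(path)
    return ScalarMap(values=np.asarray(img.dataobj, dtype=float), affine=img.affine, name=name)


def write_sidecar(image_path: str | Path, payload: dict) -> Path:
    """Write a provenance JSON next to an image (``.nii[.gz]`` → ``.json``)."""
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    out = p.with_name(name + ".json")
    out.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return out


def load_roi_config(path: str | Path) -> ROIConfig:
    """ROIConfig from a YAML mapping (keys mirror the dataclass fields)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "proj_label_ids" in raw:
        kwargs["proj_label_ids"] = frozenset(int(i) for i in raw["proj_label_ids"])
    if "assoc_label_ids" in raw:
        kwargs["assoc_label_ids"] = frozenset(int(i) for i in raw["assoc_label_ids"])
    for key in ("hemisphere", "fa_threshold", "min_voxels"):
        if key in raw:
            kwargs[key] = raw[key]
    if raw.get("x_range") is not None:
        kwargs["x_range"] = tuple(int(v) for v in raw["x_range"])
    return ROIConfig(**kwargs)


def save_roi_config(cfg: ROIConfig, path: str | Path) -> None:
    payload = {
        "proj_label_ids": sorted(cfg.proj_label_ids),
        "assoc_label_ids": sorted(cfg.assoc_label_ids),
        "hemisphere": cfg.hemisphere,
        "x_range": list(cfg.x_range) if cfg.x_range else None,
        "fa_threshold": cfg.fa_threshold,
        "min_voxels": cfg.min_voxels,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
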