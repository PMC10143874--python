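"""Configuration and image-series I/O.

JSON carries protocol and parameter configs; NPZ is the canonical
lossless interchange for dynamic image series, with NIfTI (4-D volume +
JSON sidecar) supported for imaging viewers.  Image orientation is
row-major (y, x) with y increasing downward.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .acquisition import AcquisitionProtocol
from .fitting import DynamicImageSeries
from .kinetics import GammaInput, PKParams

__all__ = [
    "load_params", "load_input_function", "load_protocol",
    "write_series", "read_series", "write_manifest",
]

_PARAM_KEYS = ("kpl", "t1_pyr", "t1_lac")


def load_params(path) -> PKParams:
    """Read kinetic parameters from a JSON config block."""
    d = _read_json(path)
    for k in _PARAM_KEYS:
        if k not in d:
            raise ValueError(f"params config {path} missing key {k!r}")
    return PKParams(kpl=d["kpl"], t1_pyr=d["t1_pyr"], t1_lac=d["t1_lac"])


def load_input_function(path) -> GammaInput:
    """Read the bolus input function from the same JSON config block."""
    return GammaInput.from_dict(_read_json(path))


def load_protocol(path) -> AcquisitionProtocol:
    d = _read_json(path)
    try:
        return AcquisitionProtocol.from_dict(d)
    except TypeError as exc:
        raise ValueError(f"malformed protocol config {path}: {exc}") from exc


def _read_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return json.load(fh)


def write_series(path, series: DynamicImageSeries) -> Path:
    """Write a dynamic series; format chosen by suffix (.npz or .nii/.nii.gz).

    NPZ round-trips bit-exactly; NIfTI stores float32 with a JSON sidecar
    (same stem, ``.json``) holding times, flips, metabolite order and
    voxel size.
    """
    path = Path(path)
    if path.suffix == ".npz":
        arrays = {
            "data": series.data,
            "times": series.times,
            "metabolites": np.array(series.metabolites),
            "flip_metabolites": np.array(list(series.flips)),
            "flip_degrees": np.array([series.flips[m] for m in series.flips]),
        }
        if series.noise_mask is not None:
            arrays["noise_mask"] = series.noise_mask
        if series.voxel_mm is not None:
            arrays["voxel_mm"] = np.array(series.voxel_mm)
        for name, m in series.masks.items():
            arrays[f"mask_{name}"] = m
        np.savez(path, **arrays)
        return path
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        # (x, y, time, metabolite) on disk, standard NIfTI axis order
        vol = np.transpose(series.data, (3, 2, 1, 0)).astype(np.float32)
        affine = np.eye(4)
        if series.voxel_mm is not None:
            affine[0, 0] = affine[1, 1] = series.voxel_mm
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        sidecar = {
            "times": series.times.tolist(),
            "metabolites": list(series.metabolites),
            "flips": {m: float(a) for m, a in series.flips.items()},
            "voxel_mm": series.voxel_mm,
        }
        stem = path.name[:-len(".nii.gz")] if path.name.endswith(".nii.gz") \
            else path.stem
        with open(path.parent / f"{stem}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
        return path
    raise ValueError(f"unsupported series format: {path.suffix!r} "
                     "(expected .npz, .nii or .nii.gz)")


def read_series(path) -> DynamicImageSeries:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            for key in ("data", "times", "metabolites"):
                if key not in z:
                    raise ValueError(f"series file {path} missing array {key!r}")
            flips = dict(zip((str(m) for m in z["flip_metabolites"]),
                             (float(a) for a in z["flip_degrees"])))
            masks = {k[len("mask_"):]: z[k].astype(bool)
                     for k in z.files if k.startswith("mask_")}
            return DynamicImageSeries(
                data=z["data"], times=z["times"],
                metabolites=tuple(str(m) for m in z["metabolites"]),
                flips=flips,
                noise_mask=z["noise_mask"] if "noise_mask" in z else None,
                voxel_mm=float(z["voxel_mm"]) if "voxel_mm" in z else None,
                masks=masks)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        stem = path.name[:-len(".nii.gz")] if path.name.endswith(".nii.gz") \
            else path.stem
        sidecar_path = path.parent / f"{stem}.json"
        if not sidecar_path.exists():
            raise ValueError(f"missing JSON sidecar for {path}: {sidecar_path}")
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        for key in ("times", "metabolites", "flips"):
            if key not in sidecar:
                raise ValueError(f"sidecar {sidecar_path} missing key {key!r}")
        vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)
        data = np.transpose(vol, (3, 2, 1, 0))
        if data.shape[0] != len(sidecar["metabolites"]):
            raise ValueError(
                f"{path}: metabolite axis ({data.shape[0]}) does not match "
                f"sidecar metabolites ({len(sidecar['metabolites'])})")
        return DynamicImageSeries(
            data=data, times=np.asarray(sidecar["times"], dtype=float),
            metabolites=tuple(sidecar["metabolites"]),
            flips={m: float(a) for m, a in sidecar["flips"].items()},
            voxel_mm=sidecar.get("voxel_mm"))
    raise ValueError(f"unsupported series format: {path.suffix!r}")


def write_manifest(out_dir, config: dict, seed: int) -> Path:
    """Record inputs, config hash, seed and package version for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "hp13c",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
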