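"""NIfTI-1 input/output for wave fields and elastograms.

Complex displacement volumes are stored as real/imaginary NIfTI pairs per
component (``<prefix>_X_real.nii.gz`` ...), maximally portable, with an
optional single 5D file of axis order (x, y, z, component, part).
Acquisition metadata (vibration frequency) lives in a JSON sidecar rather
than abused NIfTI header fields.  Lengths are mm, wavenumbers rad/m,
moduli Pa; reports echo kPa for readability.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .inversion import ElastogramSet
from .simulate import COMPONENTS, WaveField

__all__ = ["write_wavefield", "read_wavefield", "write_outputs", "read_volume"]


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def _save(path: Path, volume: np.ndarray, spacing_mm) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), _affine(spacing_mm)), str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a scalar NIfTI volume; returns (data, voxel spacing in mm)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), spacing


def write_wavefield(
    field: WaveField, out_dir, prefix: str = "wavefield", single_file: bool = False
) -> dict:
    """Write a complex wave field plus JSON sidecar; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if single_file:
        stacked = np.stack(
            [np.real(field.data), np.imag(field.data)], axis=-1
        )  # (3, nx, ny, nz, 2)
        stacked = np.moveaxis(stacked, 0, 3)  # (nx, ny, nz, component, part)
        p = out_dir / f"{prefix}_complex5d.nii.gz"
        nib.save(nib.Nifti1Image(stacked, _affine(field.voxel_spacing_mm)), str(p))
        paths["complex5d"] = str(p)
    else:
        for ci, label in enumerate(COMPONENTS):
            for part, fn in (("real", np.real), ("imag", np.imag)):
                p = out_dir / f"{prefix}_{label}_{part}.nii.gz"
                _save(p, fn(field.data[ci]), field.voxel_spacing_mm)
                paths[f"{label}_{part}"] = str(p)
    if field.ground_truth_k_map is not None:
        p = out_dir / f"{prefix}_ground_truth_k.nii.gz"
        _save(p, field.ground_truth_k_map, field.voxel_spacing_mm)
        paths["ground_truth_k"] = str(p)
    sidecar = out_dir / f"{prefix}_sidecar.json"
    sidecar.write_text(
        json.dumps(
            {
                "frequency_hz": field.frequency_hz,
                "voxel_spacing_mm": list(field.voxel_spacing_mm),
                "components": list(COMPONENTS),
                "layout": "complex5d" if single_file else "real_imag_pairs",
            },
            indent=2,
        )
    )
    paths["sidecar"] = str(sidecar)
    return paths


def read_wavefield(
    in_dir, prefix: str = "wavefield", frequency_hz: Optional[float] = None
) -> WaveField:
    """Read a wave field written by :func:`write_wavefield`.

    The vibration frequency comes from the JSON sidecar unless overridden;
    grids and affines must agree across component files.
    """
    in_dir = Path(in_dir)
    sidecar = in_dir / f"{prefix}_sidecar.json"
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    freq = frequency_hz if frequency_hz is not None else meta.get("frequency_hz")
    if freq is None:
        raise ValueError(
            "vibration frequency not found: provide frequency_hz or a sidecar"
        )

    def _spacing(img):
        # sidecar keeps full float64 precision; NIfTI zooms are float32
        if "voxel_spacing_mm" in meta:
            return tuple(float(v) for v in meta["voxel_spacing_mm"])
        return tuple(float(z) for z in img.header.get_zooms()[:3])

    five_d = in_dir / f"{prefix}_complex5d.nii.gz"
    if five_d.exists():
        img = nib.load(str(five_d))
        arr = np.asarray(img.get_fdata())
        if arr.ndim != 5 or arr.shape[3] != 3 or arr.shape[4] != 2:
            raise ValueError(f"{five_d}: expected shape (nx, ny, nz, 3, 2)")
        data = np.moveaxis(arr[..., 0] + 1j * arr[..., 1], 3, 0)
        return WaveField(data=data, voxel_spacing_mm=_spacing(img), frequency_hz=freq)

    parts, spacing, affine = {}, None, None
    for label in COMPONENTS:
        pair = []
        for part in ("real", "imag"):
            p = in_dir / f"{prefix}_{label}_{part}.nii.gz"
            if not p.exists():
                raise FileNotFoundError(f"missing component volume: {p}")
            img = nib.load(str(p))
            arr = np.asarray(img.get_fdata())
            if spacing is None:
                spacing = _spacing(img)
                affine = img.affine
                shape = arr.shape
            else:
                if arr.shape != shape:
                    raise ValueError(f"{p}: grid shape differs from other components")
                if not np.allclose(img.affine, affine):
                    raise ValueError(f"{p}: affine differs from other components")
            pair.append(arr)
        parts[label] = pair[0] + 1j * pair[1]
    data = np.stack([parts[label] for label in COMPONENTS])
    return WaveField(data=data, voxel_spacing_mm=spacing, frequency_hz=freq)


def write_outputs(
    elastograms: ElastogramSet,
    out_dir,
    similarity: Optional[dict] = None,
    report_extras: Optional[dict] = None,
    spacing_mm=None,
) -> dict:
    """Write elastogram volumes, similarity maps and a JSON report.

    Produces k/c/mu NIfTI volumes per available component, the composite
    modulus, chi maps and reverberant masks when given, and
    ``report.json`` containing summary statistics and the full effective
    configuration (the provenance of the reconstruction).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacing = spacing_mm or elastograms.provenance.get("voxel_spacing_mm", (1.0, 1.0, 1.0))
    written = {}
    present, absent = [], []
    for label in COMPONENTS:
        if label not in elastograms.per_component:
            absent.append(label)
            continue
        present.append(label)
        maps = elastograms.per_component[label]
        for quantity in ("k", "c", "mu"):
            p = out_dir / f"{quantity}_{label}.nii.gz"
            _save(p, maps[quantity], spacing)
            written[f"{quantity}_{label}"] = str(p)
    p = out_dir / "mu_composite.nii.gz"
    _save(p, elastograms.composite_mu, spacing)
    written["mu_composite"] = str(p)

    reverberant_percent = {}
    if similarity:
        for label, smap in similarity.items():
            p = out_dir / f"chi_{label}.nii.gz"
            _save(p, smap.chi_percent, spacing)
            written[f"chi_{label}"] = str(p)
            p = out_dir / f"reverberant_mask_{label}.nii.gz"
            _save(p, smap.reverberant_mask.astype(np.uint8), spacing)
            written[f"reverberant_mask_{label}"] = str(p)
            reverberant_percent[label] = smap.reverberant_percent

    def _nanstats(vol):
        finite = np.isfinite(vol)
        if not finite.any():
            return None
        vals = vol[finite]
        return {
            "median_pa": float(np.median(vals)),
            "mean_pa": float(vals.mean()),
            "std_pa": float(vals.std(ddof=0)),
            "median_kpa": float(np.median(vals)) / 1000.0,
            "n_voxels": int(vals.size),
            "nan_voxels": int((~finite).sum()),
        }

    report = {
        "config": dict(elastograms.provenance),
        "components_present": present,
        "components_absent": absent,
        "composite_mu": _nanstats(elastograms.composite_mu),
        "per_component_mu": {
            label: _nanstats(elastograms.per_component[label]["mu"]) for label in present
        },
        "reverberant_percent": reverberant_percent,
    }
    if report_extras:
        report.update(report_extras)
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    written["report"] = str(report_path)
    return written
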