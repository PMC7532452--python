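"""NIfTI / JSON / HDF5 serialization of phantoms, image series and maps."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .phantom import FetoplacentalPhantom, TRUTH_MAP_NAMES
from .presets import TissueCompartment
from .spen import DwiSeries, ShotData


def _affine(pixel_size: float, slice_thickness: float = 1.0) -> np.ndarray:
    return np.diag([pixel_size, pixel_size, slice_thickness, 1.0])


def save_nifti(data: np.ndarray, path: Path, pixel_size: float = 1.0) -> Path:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(pixel_size))
    nib.save(img, str(path))
    return path


def load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_phantom(phantom: FetoplacentalPhantom, directory: Path) -> dict:
    """Write a phantom as NIfTI volumes (label map + one per truth map) with
    a JSON sidecar carrying compartments, seed, model and geometry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    lab = nib.Nifti1Image(
        phantom.label_map.astype(np.int16), _affine(phantom.pixel_size)
    )
    paths["label_map"] = directory / "label_map.nii"
    nib.save(lab, str(paths["label_map"]))
    for name in TRUTH_MAP_NAMES:
        p = directory / f"truth_{name}.nii"
        save_nifti(phantom.truth_maps[name], p, phantom.pixel_size)
        paths[name] = p
    sidecar = dict(
        model_class=phantom.model_class,
        gestational_day=phantom.gestational_day,
        pixel_size=phantom.pixel_size,
        seed=phantom.seed,
        dam_id=phantom.dam_id,
        unit_id=phantom.unit_id,
        compartments={
            str(k): dataclasses.asdict(v) for k, v in phantom.compartments.items()
        },
    )
    paths["sidecar"] = directory / "phantom.json"
    paths["sidecar"].write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return paths


def load_phantom(directory: Path) -> FetoplacentalPhantom:
    directory = Path(directory)
    meta = json.loads((directory / "phantom.json").read_text())
    label_map = np.asarray(
        nib.load(str(directory / "label_map.nii")).dataobj
    ).astype(np.int16)
    truth = {
        name: load_nifti(directory / f"truth_{name}.nii") for name in TRUTH_MAP_NAMES
    }
    comps = {
        int(k): TissueCompartment(**v) for k, v in meta["compartments"].items()
    }
    return FetoplacentalPhantom(
        label_map=label_map,
        pixel_size=meta["pixel_size"],
        compartments=comps,
        gestational_day=meta["gestational_day"],
        model_class=meta["model_class"],
        truth_maps=truth,
        seed=meta["seed"],
        dam_id=meta["dam_id"],
        unit_id=meta["unit_id"],
    )


def save_dwi_series(series: DwiSeries, directory: Path, pixel_size: float = 1.0) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = dict(
        images=save_nifti(
            np.moveaxis(series.images, 0, -1), directory / "dwi.nii", pixel_size
        ),
        bmaps=save_nifti(
            np.moveaxis(series.bmaps, 0, -1), directory / "bmaps.nii", pixel_size
        ),
    )
    meta = dict(
        nominal_b=list(series.nominal_b),
        snr=series.snr,
        noise_sigma=series.noise_sigma,
        directions=[
            (list(d.orientation) if d is not None else None) for d in series.modules
        ],
    )
    paths["sidecar"] = directory / "dwi.json"
    paths["sidecar"].write_text(json.dumps(meta, indent=1))
    return paths


def load_dwi_series(directory: Path) -> DwiSeries:
    from .spen import DiffusionModule

    directory = Path(directory)
    meta = json.loads((directory / "dwi.json").read_text())
    images = np.moveaxis(load_nifti(directory / "dwi.nii"), -1, 0)
    bmaps = np.moveaxis(load_nifti(directory / "bmaps.nii"), -1, 0)
    modules = tuple(
        None
        if d is None
        else DiffusionModule(3.2, 10.0, 33.0, tuple(d))
        for d in meta["directions"]
    )
    return DwiSeries(
        images=images,
        bmaps=bmaps,
        modules=modules,
        nominal_b=tuple(meta["nominal_b"]),
        snr=meta["snr"],
        noise_sigma=meta.get("noise_sigma"),
    )


def save_dce_series(signal: np.ndarray, timestamps: np.ndarray, directory: Path,
                    pixel_size: float = 1.0) -> dict:
    """4D NIfTI (time last) plus a JSON sidecar of time stamps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = dict(
        series=save_nifti(np.moveaxis(signal, 0, -1), directory / "dce.nii", pixel_size)
    )
    paths["sidecar"] = directory / "dce_timestamps.json"
    paths["sidecar"].write_text(json.dumps(dict(timestamps_s=list(timestamps))))
    return paths


def shots_to_hdf5(shots: list[ShotData], path: Path) -> Path:
    """Archive interleave raw data with per-shot metadata."""
    with h5py.File(path, "w") as f:
        for shot in shots:
            g = f.create_group(f"shot_{shot.shot_index:03d}")
            g.create_dataset("samples", data=shot.samples)
            g.create_dataset("line_k", data=shot.line_k)
            g.create_dataset("line_times", data=shot.line_times)
            g.attrs["shot_index"] = shot.shot_index
            g.attrs["k_shot_offset"] = shot.k_shot_offset
    return Path(path)


def shots_from_hdf5(path: Path) -> list[ShotData]:
    shots = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            shots.append(
                ShotData(
                    samples=g["samples"][()],
                    shot_index=int(g.attrs["shot_index"]),
                    k_shot_offset=float(g.attrs["k_shot_offset"]),
                    line_k=g["line_k"][()],
                    line_times=g["line_times"][()],
                )
            )
    return shots
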