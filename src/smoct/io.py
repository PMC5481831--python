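"""File I/O glue: multi-page TIFF frame stacks, HDF5 spectra, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .diffuser import DiffuserSurface
from .forward import FrameStack
from .recon import RawSpectra

__all__ = [
    "save_frame_stack",
    "load_frame_stack",
    "save_surface",
    "load_surface",
    "save_raw_spectra",
    "load_raw_spectra",
    "save_yaml",
    "load_yaml",
]


def save_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Multi-page 32-bit float TIFF (one page per frame) + YAML sidecar."""
    path = Path(path)
    meta = {
        "pixel_dz_um": stack.pixel_dz_um,
        "pixel_dx_um": stack.pixel_dx_um,
        "kind": stack.kind,
    }
    tifffile.imwrite(
        path, stack.data.astype(np.float32), description=json.dumps(meta),
        photometric="minisblack",
    )
    sidecar = dict(meta)
    if len(stack.frame_meta):
        sidecar["frame_meta"] = stack.frame_meta.to_dict(orient="list")
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))


def load_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar = Path(str(path) + ".meta.yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
    else:
        with tifffile.TiffFile(path) as tf:
            meta = json.loads(tf.pages[0].description or "{}")
    fm = meta.get("frame_meta")
    return FrameStack(
        data=np.asarray(data, dtype=float),
        pixel_dz_um=float(meta.get("pixel_dz_um", 1.0)),
        pixel_dx_um=float(meta.get("pixel_dx_um", 1.0)),
        frame_meta=pd.DataFrame(fm) if fm else pd.DataFrame(),
        kind=meta.get("kind", "bscan"),
    )


def save_surface(surface: DiffuserSurface, path: str | Path) -> None:
    """Single-page 32-bit float TIFF with the um pitch in metadata."""
    meta = {
        "pitch_um": surface.pitch_um,
        "rms_roughness_um": surface.rms_roughness_um,
        "corr_length_um": surface.corr_length_um,
        "delta_n": surface.delta_n,
        "transmission": surface.transmission,
    }
    tifffile.imwrite(
        Path(path), surface.height_um.astype(np.float32), description=json.dumps(meta)
    )


def load_surface(path: str | Path) -> DiffuserSurface:
    with tifffile.TiffFile(Path(path)) as tf:
        meta = json.loads(tf.pages[0].description or "{}")
        height = tf.asarray()
    return DiffuserSurface(height_um=np.asarray(height, dtype=float), **meta)


def save_raw_spectra(raw: RawSpectra, path: str | Path) -> None:
    import h5py

    with h5py.File(Path(path), "w") as f:
        f.create_dataset("spectra", data=raw.spectra)
        f.create_dataset("k_axis", data=raw.k_axis)
        f.create_dataset("source_spectrum", data=raw.source_spectrum)
        f.attrs["beta"] = raw.beta
        f.attrs["reference_amplitude"] = raw.reference_amplitude
        if raw.seed is not None:
            f.attrs["seed"] = raw.seed


def load_raw_spectra(path: str | Path) -> RawSpectra:
    import h5py

    with h5py.File(Path(path), "r") as f:
        return RawSpectra(
            spectra=f["spectra"][...],
            k_axis=f["k_axis"][...],
            source_spectrum=f["source_spectrum"][...],
            beta=float(f.attrs.get("beta", 0.0)),
            reference_amplitude=float(f.attrs.get("reference_amplitude", 100.0)),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
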