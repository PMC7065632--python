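"""Readers/writers for stacks, volumes, feature tables and configs.

HDF5 is the canonical container (datasets ``/frames`` + ``/lambda_nm`` for
raw stacks, ``/intensity`` + ``/depth_axis_um`` for volumes, with config
metadata in attributes).  Multi-page TIFF with a JSON sidecar is supported
for interoperability with imaging tools: one page per wavelength (stack)
or per depth (volume), sidecar ``<stem>.json`` carrying the metadata.
Feature tables are CSV; configs and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .features import FeatureVector
from .phantom import SweepConfig, SweepStack
from .recon import ReconVolume

__all__ = [
    "write_sweep_stack",
    "read_sweep_stack",
    "write_volume",
    "read_volume",
    "write_feature_table",
    "read_feature_table",
    "write_json",
    "read_json",
]

_FEATURE_COLUMNS = [
    "sample_id",
    "animal_id",
    "class_label",
    "glcm_contrast",
    "glcm_correlation",
    "attenuation_mu",
    "glcm_energy",
    "glcm_homogeneity",
    "attenuation_r2",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_sweep_stack(stack: SweepStack, path: str | Path) -> None:
    """Write a raw stack to ``.h5``/``.hdf5`` or ``.tif``/``.tiff`` (+ sidecar)."""
    path = Path(path)
    meta = {
        "sweep": stack.sweep.to_dict(),
        "provenance": stack.provenance,
        "kind": "sweep_stack",
    }
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=stack.frames)
            f.create_dataset("lambda_nm", data=stack.sweep.wavelengths_nm)
            f.attrs["meta"] = json.dumps(meta)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))
        write_json(meta, _sidecar(path))
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")


def read_sweep_stack(path: str | Path) -> SweepStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "frames" not in f or "meta" not in f.attrs:
                raise ValueError(f"{path} is not a sweep-stack container")
            frames = f["frames"][()]
            meta = json.loads(f.attrs["meta"])
    elif path.suffix in (".tif", ".tiff"):
        side = _sidecar(path)
        if not side.exists():
            raise FileNotFoundError(f"missing metadata sidecar {side}")
        meta = read_json(side)
        frames = tifffile.imread(path).astype(float)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    sweep = SweepConfig.from_dict(meta["sweep"])
    if frames.shape[0] != sweep.n_frames:
        raise ValueError(
            f"{path}: frame count {frames.shape[0]} does not match sweep metadata"
        )
    return SweepStack(
        frames=np.asarray(frames, dtype=float),
        sweep=sweep,
        provenance=meta.get("provenance", ""),
    )


def write_volume(vol: ReconVolume, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "medium_index": vol.medium_index,
        "source": vol.source,
        "kind": "recon_volume",
    }
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("intensity", data=vol.intensity)
            f.create_dataset("depth_axis_um", data=vol.depth_axis)
            f.attrs["meta"] = json.dumps(meta)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(vol.intensity, dtype=np.float32))
        meta["depth_axis_um"] = vol.depth_axis.tolist()
        write_json(meta, _sidecar(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "intensity" not in f:
                raise ValueError(f"{path} is not a volume container")
            intensity = f["intensity"][()]
            depth = f["depth_axis_um"][()]
            meta = json.loads(f.attrs["meta"])
    elif path.suffix in (".tif", ".tiff"):
        side = _sidecar(path)
        if not side.exists():
            raise FileNotFoundError(f"missing metadata sidecar {side}")
        meta = read_json(side)
        intensity = tifffile.imread(path).astype(float)
        depth = np.asarray(meta["depth_axis_um"])
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return ReconVolume(
        intensity=np.asarray(intensity, dtype=float),
        depth_axis=depth,
        medium_index=meta["medium_index"],
        source=meta.get("source", ""),
    )


def write_feature_table(vectors: list[FeatureVector], path: str | Path) -> None:
    rows = [
        {c: getattr(v, c) for c in _FEATURE_COLUMNS}
        for v in vectors
    ]
    pd.DataFrame(rows, columns=_FEATURE_COLUMNS).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path)
    missing = set(_FEATURE_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    vectors = []
    for _, row in df.iterrows():
        vectors.append(
            FeatureVector(
                glcm_contrast=float(row["glcm_contrast"]),
                glcm_correlation=float(row["glcm_correlation"]),
                attenuation_mu=float(row["attenuation_mu"]),
                sample_id=str(row["sample_id"]),
                animal_id=str(row["animal_id"]),
                class_label=None if pd.isna(row["class_label"]) else str(row["class_label"]),
                glcm_energy=float(row.get("glcm_energy", np.nan)),
                glcm_homogeneity=float(row.get("glcm_homogeneity", np.nan)),
                attenuation_r2=float(row.get("attenuation_r2", np.nan)),
            )
        )
    return vectors
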