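"""File I/O: NIfTI volumes, decay CSVs, cohort tables and sidecar JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .images import DualEchoVolume, LabelMap, T2Map
from .phantom import CODE_TABLE, AcquisitionSpec
from .relaxometry import DecayCurve

__all__ = [
    "save_nifti",
    "load_volume",
    "save_dual_echo",
    "load_dual_echo",
    "save_labelmap",
    "load_labelmap",
    "save_t2_map",
    "save_decay",
    "load_decay",
    "save_cohort",
    "load_cohort",
    "save_acquisition",
    "load_acquisition",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_nifti(data: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def save_dual_echo(vol: DualEchoVolume, prefix) -> tuple[Path, Path]:
    """One NIfTI file per echo: <prefix>_te<TE>.nii."""
    prefix = Path(prefix)
    p1 = prefix.with_name(f"{prefix.name}_te{vol.te1:g}.nii")
    p2 = prefix.with_name(f"{prefix.name}_te{vol.te2:g}.nii")
    save_nifti(vol.si_te1, vol.voxel_size, p1)
    save_nifti(vol.si_te2, vol.voxel_size, p2)
    return p1, p2


def load_dual_echo(path1, path2, te1: float, te2: float) -> DualEchoVolume:
    d1, vx = load_volume(path1)
    d2, _ = load_volume(path2)
    return DualEchoVolume(si_te1=d1, si_te2=d2, te1=te1, te2=te2, voxel_size=vx)


def save_labelmap(lm: LabelMap, path) -> None:
    save_nifti(lm.labels.astype(np.int16), lm.voxel_size, path)


def load_labelmap(path, code_table: dict[int, str] | None = None) -> LabelMap:
    data, vx = load_volume(path)
    labels = np.rint(np.asarray(data)).astype(np.int16)
    if code_table is None:
        present = [int(l) for l in np.unique(labels)]
        code_table = {
            l: CODE_TABLE.get(l, f"label_{l}") for l in present
        }
    return LabelMap(labels=labels, voxel_size=vx, code_table=code_table)


def save_t2_map(t2_map: T2Map, path, valid_path=None) -> None:
    """T2 in ms (NaN where invalid); optional companion validity mask."""
    save_nifti(t2_map.t2, t2_map.voxel_size, path)
    if valid_path is not None:
        save_nifti(t2_map.valid.astype(np.uint8), t2_map.voxel_size, valid_path)


def save_decay(curve: DecayCurve, path) -> None:
    sig = np.asarray(curve.signal, dtype=complex)
    pd.DataFrame(
        {
            "te_ms": curve.te,
            "real": sig.real,
            "imag": sig.imag,
            "magnitude": np.abs(sig),
        }
    ).to_csv(path, index=False)


def load_decay(path) -> DecayCurve:
    df = pd.read_csv(path)
    if {"real", "imag"}.issubset(df.columns):
        signal = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
        if np.allclose(signal.imag, 0):
            signal = signal.real
    elif "magnitude" in df.columns:
        signal = df["magnitude"].to_numpy(dtype=float)
    else:
        raise ValueError("decay CSV needs (real, imag) or magnitude columns")
    return DecayCurve(te=df["te_ms"].to_numpy(dtype=float), signal=signal)


def save_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal", "group", "measurement", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort CSV needs columns {sorted(required)}")
    return df


def save_acquisition(acq: AcquisitionSpec, path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(acq), indent=2, sort_keys=True) + "\n"
    )


def load_acquisition(path) -> AcquisitionSpec:
    d = json.loads(Path(path).read_text())
    for key in ("te_list", "fov", "matrix"):
        d[key] = tuple(d[key])
    return AcquisitionSpec(**d)
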