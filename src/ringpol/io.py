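"""Readers/writers for the package's on-disk conventions.

Intensity stacks and volumes travel as multi-page TIFF with a YAML
sidecar carrying acquisition metadata; parameter maps as 32-bit float
single-page TIFFs; matrices, instruments and truth bundles as HDF5;
tables and profiles as CSV.
"""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import tifffile
import yaml

from .calibration import CalibrationResult
from .instrument import InstrumentModel, IntensityStack
from .mueller import ElementarySampleSpec
from .reconstruct import MuellerImage


def write_matrix_txt(path, M):
    np.savetxt(path, np.asarray(M), fmt="%.12g")


def read_matrix_txt(path) -> np.ndarray:
    M = np.loadtxt(path)
    if M.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {M.shape}")
    return M


def _sidecar(path) -> pathlib.Path:
    p = pathlib.Path(path)
    return p.with_suffix(p.suffix + ".yaml")


def write_stack_tiff(path, stack: IntensityStack):
    """One TIFF page per frame (48 pages), metadata in a YAML sidecar."""
    frames = np.moveaxis(stack.frames, -1, 0)  # (48, H, W)
    if stack.bit_depth == 8:
        frames = frames.astype(np.uint8)
    elif stack.bit_depth == 16:
        frames = frames.astype(np.uint16)
    else:
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    meta = dict(stack.meta)
    meta["bit_depth"] = stack.bit_depth
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_stack_tiff(path) -> IntensityStack:
    frames = tifffile.imread(path).astype(float)
    frames = np.moveaxis(frames, 0, -1)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
    return IntensityStack(frames, bit_depth=meta.get("bit_depth"), meta=meta)


def write_maps_tiff(outdir, maps: dict, prefix: str = ""):
    """Each parameter map as a 32-bit float single-page TIFF."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in maps.items():
        p = outdir / f"{prefix}{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths[name] = p
    return paths


def write_volume_tiff(path, volume):
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32))


def read_volume_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def save_instrument_h5(path, instrument: InstrumentModel):
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=instrument.W)
        f.create_dataset("A", data=instrument.A)


def load_instrument_h5(path) -> InstrumentModel:
    with h5py.File(path, "r") as f:
        return InstrumentModel(W=f["W"][()], A=f["A"][()])


def save_calibration_h5(path, result: CalibrationResult):
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=result.instrument.W)
        f.create_dataset("A", data=result.instrument.A)
        f.attrs["residual"] = result.residual
        grp = f.create_group("fitted_refs")
        for i, spec in enumerate(result.fitted_refs):
            g = grp.create_group(str(i))
            g.attrs["kind"] = spec.kind
            g.attrs["retardance_deg"] = spec.retardance_deg
            g.attrs["axis_deg"] = spec.axis_deg
            g.attrs["q_transmittance"] = spec.q_transmittance
            g.attrs["r_transmittance"] = spec.r_transmittance


def load_calibration_h5(path) -> CalibrationResult:
    with h5py.File(path, "r") as f:
        inst = InstrumentModel(W=f["W"][()], A=f["A"][()])
        refs = []
        for key in sorted(f["fitted_refs"], key=int):
            g = f["fitted_refs"][key]
            refs.append(
                ElementarySampleSpec(
                    kind=g.attrs["kind"],
                    retardance_deg=float(g.attrs["retardance_deg"]),
                    axis_deg=float(g.attrs["axis_deg"]),
                    q_transmittance=float(g.attrs["q_transmittance"]),
                    r_transmittance=float(g.attrs["r_transmittance"]),
                )
            )
        return CalibrationResult(
            instrument=inst, fitted_refs=tuple(refs),
            residual=float(f.attrs["residual"]),
        )


def save_mueller_image_h5(path, img: MuellerImage):
    with h5py.File(path, "w") as f:
        f.create_dataset("field", data=img.field, compression="gzip")
        f.create_dataset("valid", data=img.valid)
        f.attrs["normalized"] = img.normalized


def load_mueller_image_h5(path) -> MuellerImage:
    with h5py.File(path, "r") as f:
        return MuellerImage(
            field=f["field"][()], normalized=bool(f.attrs["normalized"]),
            valid=f["valid"][()],
        )


def save_truth_h5(path, truth: dict):
    with h5py.File(path, "w") as f:
        for name, arr in truth.items():
            f.create_dataset(name, data=np.asarray(arr))


def load_truth_h5(path) -> dict:
    with h5py.File(path, "r") as f:
        return {k: f[k][()] for k in f}
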