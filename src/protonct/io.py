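"""File formats: columnar event/hit tables (HDF5 + CSV), calibration and
fluence-curve CSVs, and volume output as MetaImage (MHD) or NIfTI.

Hit/frame tables round-trip bit-exactly (integer columns) through both
backends; HDF5 is the working format, CSV the small-fixture dialect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .range_telescope import CalibrationTable
from .recon import ReconImage

__all__ = [
    "write_frames_h5",
    "read_frames_h5",
    "write_frames_csv",
    "read_frames_csv",
    "write_events_h5",
    "read_events_h5",
    "write_calibration_csv",
    "read_calibration_csv",
    "write_fluence_csv",
    "write_image_mhd",
    "write_image_nifti",
    "read_image",
]

_FRAME_COLS = {"plane_id": np.int16, "frame_index": np.int64,
               "strip": np.int64, "high_flag": bool}


def write_frames_h5(path, frames: pd.DataFrame) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("frames")
        for col, dtype in _FRAME_COLS.items():
            data = frames[col].to_numpy().astype(dtype)
            g.create_dataset(col, data=data)


def read_frames_h5(path) -> pd.DataFrame:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["frames"]
        return pd.DataFrame({col: g[col][...] for col in _FRAME_COLS})


def write_frames_csv(path, frames: pd.DataFrame) -> None:
    out = frames[list(_FRAME_COLS)].copy()
    out["high_flag"] = out["high_flag"].astype(int)
    out.to_csv(path, index=False)


def read_frames_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col, dtype in _FRAME_COLS.items():
        df[col] = df[col].astype(dtype)
    return df


def write_events_h5(path, events: pd.DataFrame) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("events")
        for col in events.columns:
            g.create_dataset(col, data=events[col].to_numpy())


def read_events_h5(path) -> pd.DataFrame:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["events"]
        return pd.DataFrame({col: g[col][...] for col in g})


def write_calibration_csv(path, calib: CalibrationTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# beam_energy_mev={calib.beam_energy}\n")
        fh.write(f"# upstream_wet_mm={calib.upstream_wet}\n")
        fh.write("layer,residual_wet_mm\n")
        for layer, r in enumerate(calib.residual_wet):
            fh.write(f"{layer},{r:.6f}\n")


def read_calibration_csv(path) -> CalibrationTable:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, val = line[1:].split("=")
                meta[key.strip()] = float(val)
            elif line and not line.startswith("layer"):
                _, r = line.split(",")
                rows.append(float(r))
    return CalibrationTable(
        np.array(rows),
        beam_energy=meta["beam_energy_mev"],
        upstream_wet=meta.get("upstream_wet_mm", 0.0),
    )


def write_fluence_csv(path, curve: np.ndarray) -> None:
    pd.DataFrame(
        {"layer": np.arange(len(curve)), "normalized_counts": curve}
    ).to_csv(path, index=False)


def _image_3d(image: ReconImage) -> np.ndarray:
    """A single transverse slice as a (1, nz, nx) volume."""
    return image.data.T[None, :, :].astype(np.float32)


def write_image_mhd(path, image: ReconImage) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(_image_3d(image))
    img.SetSpacing((image.voxel_size, image.voxel_size, 1.0))
    img.SetOrigin((float(image.origin[0]), float(image.origin[1]), 0.0))
    sitk.WriteImage(img, str(path))


def write_image_nifti(path, image: ReconImage) -> None:
    import nibabel as nib

    affine = np.diag([image.voxel_size, image.voxel_size, 1.0, 1.0])
    affine[0, 3] = float(image.origin[0])
    affine[1, 3] = float(image.origin[1])
    vol = image.data[:, :, None].astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_image(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        return sitk.GetArrayFromImage(sitk.ReadImage(path))
    import nibabel as nib

    return np.asarray(nib.load(path).dataobj)
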