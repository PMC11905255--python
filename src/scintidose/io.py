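"""Round-trip-safe file I/O for volumes, matrices, and camera frames.

HDF5 is the primary volumetric container: a :class:`DoseVolume` is a "dose"
dataset with "voxel_size_mm" / "origin_mm" attributes, a response matrix a
sparse triplet layout (row, col, value + shape), and frame stacks live in
per-camera groups.  NPZ is supported for volumes as a lighter alternative,
and single camera images can be written as grayscale TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp
import tifffile

from .grid import DoseVolume, GridSpec
from .optics import CameraModel, ProjectionSet, ResponseMatrix

__all__ = [
    "save_dose",
    "load_dose",
    "save_response_matrix",
    "load_response_matrix",
    "save_projections",
    "load_projections",
    "save_image_tiff",
    "load_image_tiff",
]


def save_dose(path, dose: DoseVolume) -> None:
    """Write a dose volume to HDF5 (.h5/.hdf5) or NPZ (.npz)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            dose=dose.values,
            voxel_size_mm=np.asarray(dose.grid.voxel_size),
            origin_mm=np.asarray(dose.grid.origin),
        )
        return
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("dose", data=dose.values)
        ds.attrs["voxel_size_mm"] = np.asarray(dose.grid.voxel_size)
        ds.attrs["origin_mm"] = np.asarray(dose.grid.origin)


def load_dose(path) -> DoseVolume:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            grid = GridSpec(
                shape=data["dose"].shape,
                voxel_size=tuple(data["voxel_size_mm"]),
                origin=tuple(data["origin_mm"]),
            )
            return DoseVolume(grid, data["dose"])
    with h5py.File(path, "r") as f:
        ds = f["dose"]
        grid = GridSpec(
            shape=ds.shape,
            voxel_size=tuple(ds.attrs["voxel_size_mm"]),
            origin=tuple(ds.attrs["origin_mm"]),
        )
        return DoseVolume(grid, ds[()])


def _camera_to_json(cam: CameraModel) -> str:
    return json.dumps(
        {
            "id": cam.id,
            "view_axis": cam.view_axis,
            "pixel_shape": list(cam.pixel_shape),
            "pixel_pitch": cam.pixel_pitch,
            "attenuation_lambda": cam.attenuation_lambda,
            "scatter_fraction": cam.scatter_fraction,
            "projection_mode": cam.projection_mode,
            "focal_length": cam.focal_length,
            "gain": cam.gain,
        }
    )


def _camera_from_json(s: str) -> CameraModel:
    d = json.loads(s)
    d["pixel_shape"] = tuple(d["pixel_shape"])
    return CameraModel(**d)


def save_response_matrix(path, A: ResponseMatrix) -> None:
    """Persist a sparse response matrix as HDF5 triplets (row, col, value)."""
    coo = A.matrix.tocoo()
    with h5py.File(path, "w") as f:
        f.create_dataset("row", data=coo.row)
        f.create_dataset("col", data=coo.col)
        f.create_dataset("value", data=coo.data)
        f.attrs["shape"] = np.asarray(coo.shape)
        f.attrs["grid_shape"] = np.asarray(A.grid.shape)
        f.attrs["voxel_size_mm"] = np.asarray(A.grid.voxel_size)
        f.attrs["origin_mm"] = np.asarray(A.grid.origin)
        f.attrs["cameras"] = json.dumps([_camera_to_json(c) for c in A.cameras])


def load_response_matrix(path) -> ResponseMatrix:
    with h5py.File(path, "r") as f:
        try:
            shape = tuple(f.attrs["shape"])
            matrix = sp.coo_matrix(
                (f["value"][()], (f["row"][()], f["col"][()])), shape=shape
            ).tocsr()
            grid = GridSpec(
                shape=tuple(f.attrs["grid_shape"]),
                voxel_size=tuple(f.attrs["voxel_size_mm"]),
                origin=tuple(f.attrs["origin_mm"]),
            )
            cameras = tuple(_camera_from_json(s) for s in json.loads(f.attrs["cameras"]))
        except KeyError as exc:
            raise ValueError(f"{path} is not a valid response-matrix file: {exc}") from exc
    return ResponseMatrix(matrix=matrix, grid=grid, cameras=cameras)


def save_projections(path, frames: list[ProjectionSet]) -> None:
    """Write one or more frames of per-camera images to an HDF5 stack.

    Layout: one group per camera, each holding a frame-major "frames"
    dataset plus the camera description.
    """
    if not frames:
        raise ValueError("no frames to save")
    cams = frames[0].cameras
    with h5py.File(path, "w") as f:
        f.attrs["n_frames"] = len(frames)
        f.attrs["camera_order"] = json.dumps([c.id for c in cams])
        times = [fr.time if fr.time is not None else np.nan for fr in frames]
        f.create_dataset("times", data=np.asarray(times, dtype=float))
        for cam in cams:
            g = f.create_group(cam.id)
            stack = np.stack([fr.images[cam.id] for fr in frames])
            g.create_dataset("frames", data=stack)
            g.attrs["camera"] = _camera_to_json(cam)


def load_projections(path) -> list[ProjectionSet]:
    with h5py.File(path, "r") as f:
        n_frames = int(f.attrs["n_frames"])
        times = f["times"][()]
        order = json.loads(f.attrs["camera_order"])
        cams = []
        stacks = {}
        for key in order:
            g = f[key]
            cam = _camera_from_json(g.attrs["camera"])
            cams.append(cam)
            stacks[cam.id] = g["frames"][()]
        frames = []
        for k in range(n_frames):
            t = None if np.isnan(times[k]) else float(times[k])
            frames.append(
                ProjectionSet(
                    images={c.id: stacks[c.id][k] for c in cams},
                    cameras=tuple(cams),
                    time=t,
                )
            )
    return frames


def save_image_tiff(path, image: np.ndarray, bit_depth: int = 16, max_value: float = None):
    """Write one camera image as grayscale TIFF.

    With ``bit_depth=16`` the image is linearly scaled so that ``max_value``
    (default: the image maximum) maps to the top code; the scale is stored in
    the TIFF description for exact inversion.  ``bit_depth=32`` stores raw
    float32 values.
    """
    image = np.asarray(image, dtype=float)
    path = Path(path)
    if bit_depth == 32:
        tifffile.imwrite(path, image.astype(np.float32))
        return
    if bit_depth != 16:
        raise ValueError("bit_depth must be 16 or 32")
    top = float(max_value) if max_value is not None else float(image.max())
    scale = (2**16 - 1) / top if top > 0 else 1.0
    coded = np.clip(np.round(image * scale), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(path, coded, description=json.dumps({"scale": scale}))


def load_image_tiff(path) -> np.ndarray:
    """Read a camera image written by :func:`save_image_tiff`, undoing the
    16-bit scaling when present."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        image = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                scale = json.loads(desc.value).get("scale")
                if scale:
                    image = image / scale
            except (json.JSONDecodeError, AttributeError):
                pass
    return image
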