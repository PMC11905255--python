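"""Optical system model: response matrix, forward projection, calibration.

Scintillation light emitted by each dose voxel is imaged by up to three
orthogonally placed cameras.  The system response matrix A (n pixels x m
voxels) is built by deterministic geometric projection with Beer-Lambert
attenuation exp(-lambda * path), replacing physical-optics ray tracing; lens
distortion and refraction at the phantom shell are neglected.

Two projection geometries are supported:

* ``parallel`` (default, telecentric approximation): each voxel's emission is
  shared among pixels by the area overlap of its footprint with the pixel
  grid at the object plane, attenuated along the straight path to the camera-
  side exit face.  With full sensor coverage and lambda = 0 every voxel's row
  weights sum to one, so flux is conserved.
* ``pinhole``: central-ray projection through an aperture placed
  ``focal_length`` mm beyond the exit face, with unit magnification at the
  isocenter plane and the same attenuation weight; emission is shared
  bilinearly between the four nearest pixels.

Optical scattering inside the scintillator is modelled as a uniform
background proportional to the total deposited dose, added in
:func:`forward_project` and removed again in
:func:`estimate_and_remove_scatter` from sensor margins whose rays miss the
phantom.

Calibration follows the reference-field procedure: each pixel's calibrated
measurement is the weighted dose integral
``p_j = I_j / I_ref,j * (A_j,* . D_ref)`` against a standard field of known
dose, and the final dose scale is set from the mean over a central region of
a calibration field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .grid import DoseVolume, GridSpec

__all__ = [
    "CameraModel",
    "ResponseMatrix",
    "ProjectionSet",
    "ReferenceField",
    "CalibrationRegion",
    "build_response_matrix",
    "margin_mask",
    "forward_project",
    "estimate_and_remove_scatter",
    "weighted_dose_integral",
    "calibrate_dose_scale",
]

_AXES = {"x": 0, "y": 1, "z": 2}
# image (rows, cols) <-> grid axes for each view axis
_TRANSVERSE = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


@dataclass(frozen=True)
class CameraModel:
    """Geometry and optics of one viewing direction.

    ``view_axis`` is a signed axis label (``"+x"``, ``"-z"``, ...): the
    camera sits on that side of the phantom looking inward.  ``pixel_pitch``
    is the pixel size at the object plane, mm.  ``attenuation_lambda`` is the
    optical attenuation coefficient of the scintillator, per mm.
    ``scatter_fraction`` is the default scattered-light fraction used when
    forward projecting through this camera.  ``gain`` is a per-camera
    intensity scale (cameras are photometrically normalized in hardware; the
    reference-field ratio cancels it, but it is exposed for realism).
    """

    id: str
    view_axis: str = "+z"
    pixel_shape: tuple[int, int] = (100, 100)
    pixel_pitch: float = 1.0
    attenuation_lambda: float = 0.0
    scatter_fraction: float = 0.0
    projection_mode: str = "parallel"
    focal_length: Optional[float] = None
    gain: float = 1.0

    def __post_init__(self):
        axis = self.view_axis
        if len(axis) != 2 or axis[0] not in "+-" or axis[1] not in _AXES:
            raise ValueError(f"view_axis must be like '+z' or '-x', got {axis!r}")
        if any(n < 1 for n in self.pixel_shape):
            raise ValueError("pixel_shape entries must be >= 1")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.attenuation_lambda < 0:
            raise ValueError("attenuation_lambda must be >= 0")
        if self.scatter_fraction < 0:
            raise ValueError("scatter_fraction must be >= 0")
        if self.projection_mode not in ("parallel", "pinhole"):
            raise ValueError("projection_mode must be 'parallel' or 'pinhole'")
        if self.projection_mode == "pinhole" and (
            self.focal_length is None or self.focal_length <= 0
        ):
            raise ValueError("pinhole mode requires a positive focal_length")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")

    @property
    def axis(self) -> int:
        return _AXES[self.view_axis[1]]

    @property
    def sign(self) -> int:
        return 1 if self.view_axis[0] == "+" else -1

    @property
    def n_pixels(self) -> int:
        return int(self.pixel_shape[0] * self.pixel_shape[1])

    def pixel_coords(self, which: str, grid: GridSpec) -> np.ndarray:
        """Object-plane pixel-center coordinates (mm) for rows or cols,
        centered on the grid center along the matching transverse axis."""
        row_axis, col_axis = _TRANSVERSE[self.axis]
        if which == "rows":
            n, axis = self.pixel_shape[0], row_axis
        elif which == "cols":
            n, axis = self.pixel_shape[1], col_axis
        else:
            raise ValueError("which must be 'rows' or 'cols'")
        c = grid.center[axis]
        return c + (np.arange(n) - (n - 1) / 2.0) * self.pixel_pitch


@dataclass
class ResponseMatrix:
    """Sparse stacked system matrix A for one or several cameras.

    Rows are camera pixels in camera order (row-major within each camera);
    columns are voxels in C order of the grid.  All entries are >= 0.
    """

    matrix: sp.csr_matrix = field(repr=False)
    grid: GridSpec = None
    cameras: tuple[CameraModel, ...] = ()

    def __post_init__(self):
        self.matrix = sp.csr_matrix(self.matrix)
        n = sum(c.n_pixels for c in self.cameras)
        if self.matrix.shape != (n, self.grid.n_voxels):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with cameras "
                f"({n} pixels) and grid ({self.grid.n_voxels} voxels)"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("response matrix entries must be >= 0")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def camera_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.cameras)

    def camera_slice(self, camera_id: str) -> slice:
        """Row slice of the stacked matrix belonging to one camera."""
        start = 0
        for cam in self.cameras:
            if cam.id == camera_id:
                return slice(start, start + cam.n_pixels)
            start += cam.n_pixels
        raise KeyError(f"unknown camera id {camera_id!r}")

    def split(self, vector: np.ndarray) -> dict[str, np.ndarray]:
        """Reshape a stacked pixel vector into per-camera images."""
        out = {}
        for cam in self.cameras:
            sl = self.camera_slice(cam.id)
            out[cam.id] = np.asarray(vector[sl]).reshape(cam.pixel_shape)
        return out


@dataclass
class ProjectionSet:
    """Per-camera pixel images and, after calibration, the stacked p vector.

    ``images`` maps camera id -> 2D array matching the camera's pixel shape.
    ``p`` (if set) is the stacked calibrated weighted-dose-integral vector
    and ``valid`` the mask of pixels usable for reconstruction.
    """

    images: dict[str, np.ndarray]
    cameras: tuple[CameraModel, ...]
    time: Optional[float] = None
    p: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.cameras = tuple(self.cameras)
        for cam in self.cameras:
            img = np.asarray(self.images[cam.id], dtype=float)
            if img.shape != tuple(cam.pixel_shape):
                raise ValueError(
                    f"image for camera {cam.id!r} has shape {img.shape}, "
                    f"expected {cam.pixel_shape}"
                )
            self.images[cam.id] = img

    @property
    def vector(self) -> np.ndarray:
        """Stacked raw intensity vector in camera order."""
        return np.concatenate([self.images[c.id].ravel() for c in self.cameras])

    def with_images(self, images: dict[str, np.ndarray]) -> "ProjectionSet":
        return ProjectionSet(images=images, cameras=self.cameras, time=self.time)


@dataclass
class ReferenceField:
    """A standard radiation field of known dose and its measured images."""

    dose: DoseVolume
    images: ProjectionSet
    description: str = "reference field"


def _overlap_matrix(pixel_centers: np.ndarray, pitch: float, voxel_centers: np.ndarray,
                    voxel_size: float) -> sp.csr_matrix:
    """1D fraction of each voxel's footprint covered by each pixel.

    Entry (j, i) = overlap length of pixel j and voxel i, divided by the
    voxel size, so a fully covered voxel's column sums to 1.
    """
    p_lo = pixel_centers[:, None] - pitch / 2.0
    p_hi = pixel_centers[:, None] + pitch / 2.0
    v_lo = voxel_centers[None, :] - voxel_size / 2.0
    v_hi = voxel_centers[None, :] + voxel_size / 2.0
    overlap = np.clip(np.minimum(p_hi, v_hi) - np.maximum(p_lo, v_lo), 0.0, None)
    return sp.csr_matrix(overlap / voxel_size)


def _attenuation_row(grid: GridSpec, camera: CameraModel) -> np.ndarray:
    """exp(-lambda * path) from each voxel center (along the view axis) to
    the camera-side exit face."""
    axis = camera.axis
    lo, hi = grid.bounds
    coords = grid.axis_coords(axis)
    path = (hi[axis] - coords) if camera.sign > 0 else (coords - lo[axis])
    return np.exp(-camera.attenuation_lambda * path)


def _camera_matrix_parallel(grid: GridSpec, camera: CameraModel) -> sp.csr_matrix:
    row_axis, col_axis = _TRANSVERSE[camera.axis]
    O_row = _overlap_matrix(
        camera.pixel_coords("rows", grid), camera.pixel_pitch,
        grid.axis_coords(row_axis), grid.voxel_size[row_axis],
    )
    O_col = _overlap_matrix(
        camera.pixel_coords("cols", grid), camera.pixel_pitch,
        grid.axis_coords(col_axis), grid.voxel_size[col_axis],
    )
    w = sp.csr_matrix(_attenuation_row(grid, camera)[None, :])
    # Assemble so that kron row index == (row, col) row-major and kron column
    # index == C-order voxel index (i, j, k).
    factors = {camera.axis: w, row_axis: O_row, col_axis: O_col}
    A = sp.kron(factors[0], sp.kron(factors[1], factors[2], format="csr"), format="csr")
    return camera.gain * A


def _camera_matrix_pinhole(grid: GridSpec, camera: CameraModel) -> sp.csr_matrix:
    axis = camera.axis
    row_axis, col_axis = _TRANSVERSE[axis]
    lo, hi = grid.bounds
    # aperture sits focal_length beyond the exit face on the camera side
    if camera.sign > 0:
        aperture = hi[axis] + camera.focal_length
    else:
        aperture = lo[axis] - camera.focal_length
    d_iso = abs(aperture - grid.center[axis])

    X, Y, Z = grid.meshgrid()
    coords = (X.ravel(), Y.ravel(), Z.ravel())
    d_vox = np.abs(aperture - coords[axis])
    scale = d_iso / d_vox  # magnification relative to the isocenter plane

    atten = _attenuation_row(grid, camera)
    w_full = np.ones(grid.shape)
    idx = [None, None, None]
    idx[axis] = slice(None)
    w_full *= atten[tuple(idx)]
    weights = (camera.gain * w_full).ravel()

    rows_c = camera.pixel_coords("rows", grid)
    cols_c = camera.pixel_coords("cols", grid)
    nr, nc = camera.pixel_shape
    center_r = grid.center[row_axis]
    center_c = grid.center[col_axis]
    # fractional pixel index of the projected voxel center (magnified about
    # the grid center, where the pixel lattice is anchored)
    fr = (center_r + scale * (coords[row_axis] - center_r) - rows_c[0]) / camera.pixel_pitch
    fc = (center_c + scale * (coords[col_axis] - center_c) - cols_c[0]) / camera.pixel_pitch

    r0 = np.floor(fr).astype(int)
    c0 = np.floor(fc).astype(int)
    wr = fr - r0
    wc = fc - c0

    data, rows_i, cols_i = [], [], []
    m = grid.n_voxels
    vox = np.arange(m)
    for dr, wgt_r in ((0, 1.0 - wr), (1, wr)):
        for dc, wgt_c in ((0, 1.0 - wc), (1, wc)):
            rr = r0 + dr
            cc = c0 + dc
            ok = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
            wt = weights * wgt_r * wgt_c
            ok &= wt > 0
            data.append(wt[ok])
            rows_i.append((rr * nc + cc)[ok])
            cols_i.append(vox[ok])
    A = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(camera.n_pixels, m),
    )
    return A.tocsr()


def build_response_matrix(grid: GridSpec, cameras: Sequence[CameraModel]) -> ResponseMatrix:
    """Build the stacked sparse system matrix A for a set of cameras.

    Raises on duplicate view axes (degenerate tomography).
    """
    cameras = tuple(cameras)
    if not cameras:
        raise ValueError("at least one camera is required")
    axes = [c.view_axis for c in cameras]
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate camera view axes {axes}: degenerate tomography")
    blocks = []
    for cam in cameras:
        if cam.projection_mode == "parallel":
            blocks.append(_camera_matrix_parallel(grid, cam))
        else:
            blocks.append(_camera_matrix_pinhole(grid, cam))
    A = sp.vstack(blocks, format="csr")
    return ResponseMatrix(matrix=A, grid=grid, cameras=cameras)


def forward_project(
    A: ResponseMatrix, D: DoseVolume, scatter_fraction: float = 0.0, time: float = None
) -> ProjectionSet:
    """Forward model p = A.D plus a uniform scattered-light background.

    The background adds ``scatter_fraction * total_dose / n`` to every pixel,
    implementing scattered scintillation light proportional to the total dose
    deposited in the phantom.
    """
    if D.grid != A.grid:
        raise ValueError("dose volume grid does not match the response matrix grid")
    if scatter_fraction < 0:
        raise ValueError("scatter_fraction must be >= 0")
    p = A.matrix @ D.ravel()
    if scatter_fraction > 0:
        p = p + scatter_fraction * D.total / A.n
    return ProjectionSet(images=A.split(p), cameras=A.cameras, time=time)


def margin_mask(A: ResponseMatrix, camera_id: str) -> np.ndarray:
    """Pixels of one camera whose geometric rays miss the scintillator
    (all-zero rows of A); used for background estimation."""
    sl = A.camera_slice(camera_id)
    row_sums = np.asarray(A.matrix[sl].sum(axis=1)).ravel()
    cam = A.cameras[A.camera_ids.index(camera_id)]
    return (row_sums == 0).reshape(cam.pixel_shape)


def estimate_and_remove_scatter(
    images: ProjectionSet,
    cameras: Sequence[CameraModel] = None,
    response: ResponseMatrix = None,
    background: dict[str, float] = None,
) -> tuple[ProjectionSet, dict[str, float]]:
    """Subtract the uniform scattered-light background per camera.

    The background is the mean intensity over margin pixels whose rays miss
    the phantom (derived from ``response``), unless supplied explicitly via
    ``background``.  The result is clipped at zero.
    """
    cams = tuple(cameras) if cameras is not None else images.cameras
    estimated: dict[str, float] = {}
    cleaned: dict[str, np.ndarray] = {}
    for cam in cams:
        img = images.images[cam.id]
        if np.any(img < 0):
            raise ValueError(f"image for camera {cam.id!r} has negative pixels")
        if background is not None and cam.id in background:
            b = float(background[cam.id])
        elif response is not None:
            mask = margin_mask(response, cam.id)
            if not mask.any():
                raise ValueError(
                    f"camera {cam.id!r} has no out-of-phantom margin pixels; "
                    "pass the background explicitly"
                )
            b = float(img[mask].mean())
        else:
            raise ValueError(
                "no response matrix for margin estimation and no explicit background"
            )
        estimated[cam.id] = b
        cleaned[cam.id] = np.clip(img - b, 0.0, None)
    return images.with_images(cleaned), estimated


def weighted_dose_integral(
    I: ProjectionSet,
    ref: ReferenceField,
    A: ResponseMatrix,
    floor_frac: float = 1e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """Calibrate raw intensities to weighted dose integrals.

    For each pixel j, ``p_j = I_j / I_ref,j * (A_j,* . D_ref)``.  Pixels whose
    reference intensity falls below ``floor_frac * max(I_ref)`` are flagged
    invalid (mask False, p set to 0) and should be excluded from
    reconstruction rather than divided.

    Returns
    -------
    p : stacked calibrated vector (length A.n)
    valid : boolean mask of usable pixels
    """
    if ref.dose.grid != A.grid:
        raise ValueError("reference dose grid does not match the response matrix")
    I_vec = I.vector
    I_ref = ref.images.vector
    floor = floor_frac * I_ref.max() if I_ref.size else 0.0
    valid = I_ref > max(floor, 0.0)
    if not valid.any():
        raise ValueError("all pixels fall below the reference-intensity floor; no usable data")
    ADref = A.matrix @ ref.dose.ravel()
    p = np.zeros(A.n)
    p[valid] = I_vec[valid] / I_ref[valid] * ADref[valid]
    p = np.clip(p, 0.0, None)
    if not np.all(np.isfinite(p)):
        raise ValueError("calibrated projections are not finite")
    return p, valid


@dataclass(frozen=True)
class CalibrationRegion:
    """Central square region on a plane, for dose-scale calibration.

    ``axis`` is the plane normal ('x', 'y' or 'z'); ``coordinate`` its
    physical position in mm; ``width``/``height`` the square's extent (mm)
    along the two in-plane axes in ascending axis order.
    """

    width: float = 50.0
    height: float = 50.0
    axis: str = "z"
    coordinate: float = 0.0

    def mask(self, grid: GridSpec) -> np.ndarray:
        ax = _AXES[self.axis]
        in_plane = _TRANSVERSE[ax]
        lo, hi = grid.bounds
        if not (lo[ax] <= self.coordinate <= hi[ax]):
            raise ValueError("calibration plane lies outside the grid")
        k = int(np.clip(np.round(grid.physical_to_index([self.coordinate] * 3)[ax]),
                        0, grid.shape[ax] - 1))
        c = grid.center
        mask = np.zeros(grid.shape, dtype=bool)
        u = grid.axis_coords(in_plane[0]) - c[in_plane[0]]
        v = grid.axis_coords(in_plane[1]) - c[in_plane[1]]
        sq = (np.abs(u)[:, None] <= self.width / 2.0) & (np.abs(v)[None, :] <= self.height / 2.0)
        sel = [slice(None)] * 3
        sel[ax] = k
        plane = np.zeros(mask[tuple(sel)].shape, dtype=bool)
        plane[...] = sq
        mask[tuple(sel)] = plane
        if not mask.any():
            raise ValueError("calibration region contains no voxels")
        return mask


def calibrate_dose_scale(
    D0: DoseVolume, ref_dose: DoseVolume, region: CalibrationRegion = None
) -> tuple[float, DoseVolume]:
    """Scale an uncalibrated dose to a known reference over a central region.

    scale = mean(ref over region) / mean(D0 over region); the default region
    is the central 5 cm x 5 cm square of the transverse midplane, matching
    the square-field calibration protocol.
    """
    if D0.grid != ref_dose.grid:
        raise ValueError("volumes must share a grid")
    region = region or CalibrationRegion()
    mask = region.mask(D0.grid)
    denom = D0.values[mask].mean()
    if denom <= 0:
        raise ValueError("uncalibrated dose has zero mean in the calibration region")
    scale = float(ref_dose.values[mask].mean() / denom)
    return scale, DoseVolume(D0.grid, scale * D0.values)
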