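"""Synthetic phantoms, analytic beam doses, time-resolved delivery, camera noise.

The dose engine is a deliberately simple analytic stand-in for a treatment
planning system: each beam deposits

    dose(r) = weight * edge(u) * edge(v) * exp(-mu * depth(r))

where ``(u, v)`` are transverse coordinates perpendicular to the beam axis,
``edge`` is a rectangular field profile convolved with a Gaussian penumbra,
and ``depth`` is the distance travelled inside the phantom from the entry
face.  This keeps ground truth exactly known, so every downstream stage
(projection, calibration, reconstruction, gamma evaluation) can be tested
without external data.

Gantry convention: rotation about the +y axis in the x-z plane, with 270
degrees meaning the beam travels vertically downward (-z).  The field
rectangle is centered on the beam axis through the isocenter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .grid import DoseVolume, GridSpec, make_grid  # noqa: F401  (make_grid re-exported)

__all__ = [
    "BeamSpec",
    "NoiseModel",
    "make_grid",
    "generate_beam_dose",
    "generate_plan_dose",
    "render_frames",
    "apply_noise",
]


@dataclass(frozen=True)
class BeamSpec:
    """One beam (subfield) of a delivery plan.

    Parameters
    ----------
    gantry_angle : float
        Degrees in [0, 360); 270 is vertical downward irradiation.
    field_size : (width, height)
        Field rectangle at isocenter, mm.  Width lies in the gantry rotation
        plane (x-z), height along y.
    penumbra_sigma : float
        Gaussian penumbra width, mm (0 gives a sharp rectangular field).
    attenuation_mu : float
        Effective linear attenuation of dose with depth, per mm.
    weight : float
        Relative intensity (monitor-unit proxy); scales the dose linearly.
    duration : float
        Delivery time in seconds, used by :func:`render_frames`.
    """

    gantry_angle: float = 270.0
    field_size: tuple[float, float] = (80.0, 80.0)
    penumbra_sigma: float = 0.0
    attenuation_mu: float = 0.0
    weight: float = 1.0
    duration: float = 1.0

    def __post_init__(self):
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError(f"field_size must be positive, got {self.field_size}")
        if self.penumbra_sigma < 0:
            raise ValueError("penumbra_sigma must be >= 0")
        if self.attenuation_mu < 0:
            raise ValueError("attenuation_mu must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if not 0 <= self.gantry_angle < 360:
            raise ValueError("gantry_angle must lie in [0, 360)")

    @property
    def direction(self) -> np.ndarray:
        """Unit propagation direction of the beam."""
        a = np.deg2rad(self.gantry_angle - 270.0)
        return np.array([-np.sin(a), 0.0, -np.cos(a)])

    @property
    def transverse_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors (u, v) spanning the field plane; u in-plane, v = +y."""
        a = np.deg2rad(self.gantry_angle - 270.0)
        u = np.array([np.cos(a), 0.0, -np.sin(a)])
        v = np.array([0.0, 1.0, 0.0])
        return u, v


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise plus Gaussian read noise.

    ``poisson_gain`` is the expected count per unit of projected dose; 0
    disables the Poisson term.  ``read_sigma`` is in count units (applied
    after dividing counts back by the gain).  A fixed ``seed`` reproduces
    images bit-for-bit.
    """

    poisson_gain: float = 1e4
    read_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.poisson_gain < 0:
            raise ValueError("poisson_gain must be >= 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


def _edge_profile(t: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Rectangular field edge convolved with a Gaussian of width sigma."""
    if sigma == 0:
        return (np.abs(t) <= half_width).astype(float)
    # ndtr(+-inf) is exact, so overflow of the ratio is harmless
    with np.errstate(over="ignore"):
        return ndtr((half_width - t) / sigma) - ndtr((-half_width - t) / sigma)


def _entry_depth(grid: GridSpec, direction: np.ndarray) -> np.ndarray:
    """Distance (mm) from the phantom entry face to each voxel center,
    measured along the beam direction.  Voxel centers are inside the box, so
    a slab test per axis suffices."""
    lo, hi = grid.bounds
    X, Y, Z = grid.meshgrid()
    coords = (X, Y, Z)
    s_entry = np.full(grid.shape, -np.inf)
    for axis in range(3):
        d = direction[axis]
        if abs(d) < 1e-12:
            continue
        t1 = (lo[axis] - coords[axis]) / d
        t2 = (hi[axis] - coords[axis]) / d
        s_entry = np.maximum(s_entry, np.minimum(t1, t2))
    depth = -s_entry
    return np.clip(depth, 0.0, None)


def _axis_hits_grid(grid: GridSpec, direction: np.ndarray) -> bool:
    """Slab test: does the central beam axis (through the isocenter) cross
    the grid bounding box?"""
    lo, hi = grid.bounds
    s_near, s_far = -np.inf, np.inf
    for axis in range(3):
        d = direction[axis]
        if abs(d) < 1e-12:
            if not (lo[axis] <= 0.0 <= hi[axis]):
                return False
            continue
        t1, t2 = lo[axis] / d, hi[axis] / d
        s_near = max(s_near, min(t1, t2))
        s_far = min(s_far, max(t1, t2))
    return s_near <= s_far


def generate_beam_dose(grid: GridSpec, beam: BeamSpec) -> DoseVolume:
    """Analytic dose of a single beam on ``grid``.

    Returns an all-zero volume (with a warning) when the beam axis misses the
    grid entirely.
    """
    if not _axis_hits_grid(grid, beam.direction):
        warnings.warn(
            f"beam axis (gantry {beam.gantry_angle} deg) does not intersect the grid; "
            "returning a zero dose volume",
            stacklevel=2,
        )
        return DoseVolume(grid, np.zeros(grid.shape))

    X, Y, Z = grid.meshgrid()
    pts = np.stack([X, Y, Z], axis=-1)
    u, v = beam.transverse_axes
    tu = pts @ u
    tv = pts @ v
    w, h = beam.field_size
    profile = _edge_profile(tu, w / 2.0, beam.penumbra_sigma) * _edge_profile(
        tv, h / 2.0, beam.penumbra_sigma
    )
    if beam.attenuation_mu > 0:
        profile = profile * np.exp(-beam.attenuation_mu * _entry_depth(grid, beam.direction))
    return DoseVolume(grid, beam.weight * profile)


def generate_plan_dose(
    grid: GridSpec, beams: list[BeamSpec]
) -> tuple[DoseVolume, list[DoseVolume]]:
    """Total plan dose (voxelwise sum) plus the per-beam volumes.

    The per-beam list feeds :func:`render_frames` for time-resolved delivery.
    """
    if not beams:
        raise ValueError("plan must contain at least one beam")
    per_beam = [generate_beam_dose(grid, b) for b in beams]
    total = np.zeros(grid.shape)
    for d in per_beam:
        total += d.values
    return DoseVolume(grid, total), per_beam


def render_frames(
    per_beam_doses: list[DoseVolume],
    beams: list[BeamSpec],
    frame_rate: float,
) -> list[DoseVolume]:
    """Split a sequential delivery into per-frame dose increments.

    Beams are delivered one after another in list order at constant dose
    rate; each frame covers ``1/frame_rate`` seconds (the last frame of a
    beam may be shorter).  The increments sum exactly to the plan total.
    Beams with zero duration contribute no frames.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    if len(per_beam_doses) != len(beams):
        raise ValueError("per_beam_doses and beams must have equal length")
    frames: list[DoseVolume] = []
    for dose, beam in zip(per_beam_doses, beams):
        if beam.duration < 0:
            raise ValueError("beam duration must be >= 0")
        if beam.duration == 0:
            continue
        n = int(np.ceil(beam.duration * frame_rate - 1e-12))
        edges = np.minimum(np.arange(1, n + 1) / frame_rate, beam.duration)
        fractions = np.diff(np.concatenate([[0.0], edges])) / beam.duration
        for f in fractions:
            frames.append(dose * f)
    return frames


def apply_noise(image: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """Apply the camera noise model to one (or a stack of) pixel image(s).

    output = Poisson(gain * image) / gain + N(0, read_sigma), clipped at 0.
    Deterministic for a fixed :attr:`NoiseModel.seed`.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("input image must be nonnegative")
    rng = np.random.default_rng(noise.seed)
    if noise.poisson_gain > 0:
        out = rng.poisson(noise.poisson_gain * image).astype(float) / noise.poisson_gain
    else:
        out = image.copy()
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=image.shape)
    return np.clip(out, 0.0, None)
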