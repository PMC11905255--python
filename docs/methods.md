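# Methods

`scintidose` models an optical 3D dosimetry system in which a transparent
scintillator block serves simultaneously as the measurement phantom and the
detector: radiation deposits dose, the scintillator converts dose to light
in proportion, and three orthogonally placed cameras image the light field.
The package implements the complete computational chain — synthetic dose
generation, the optical forward model, calibration, the LASSO-TV
reconstruction, and the clinical evaluation metrics — so that every stage
can be exercised and validated against exactly known ground truth without
any measured data.

## Coordinate conventions

Right-handed axes (x, y, z) with 0-based voxel indices and voxel-center
sampling; the grid is centered on the machine isocenter by default, so
symmetric fields are exactly symmetric.  The gantry rotates about the +y
axis in the x–z plane, with 270° meaning the beam travels vertically
downward (−z).  For a supine patient under such a beam, room z is the
patient's anterior–posterior axis: the *coronal* plane is the horizontal,
beam-perpendicular constant-z plane (this is also the plane a flat diode
array on the couch measures), the transverse plane is constant y (couch long
axis) and the sagittal plane constant x.

The default study grid is a 10 cm cube divided into 100×100×100 voxels of
1 mm; the desk-scale experiment twins use 50×50×50 voxels of 2 mm, which
preserves the physical extent while keeping end-to-end runs to about a
minute on one core.

## Synthetic beam model

The dose engine stands in for a treatment planning system with an analytic
model chosen so that the ground truth is known in closed form:

    dose(r) = weight · E(u; w, σ) · E(v; h, σ) · exp(−μ · depth(r))

where (u, v) are transverse coordinates perpendicular to the beam axis,
`E(t; w, σ) = Φ((w/2 − t)/σ) − Φ((−w/2 − t)/σ)` is a rectangular field edge
convolved with a Gaussian penumbra of width σ (applied transversely; blur
along the beam axis is neglected), and `depth` is the distance travelled
inside the phantom from the entry face.  Defaults are chosen to resemble a
6 MV linac beam: penumbra σ = 3 mm, effective depth attenuation
μ = 0.005 /mm (≈ tissue attenuation beyond the build-up region; build-up
itself is not modelled).  The single-field verification twin uses a
60×60 mm field; the square calibration field is 80×80 mm with the dose
scale taken from the central 5×5 cm region of the coronal midplane.
Field sizes, σ, μ and beam weights are all free parameters of `BeamSpec`.

Time-resolved delivery splits each beam's dose uniformly over its duration
into camera frames (1 Hz by default); beams are delivered sequentially, and
the frame increments sum exactly to the plan total.

## Optical forward model

The system response matrix A (n pixels × m voxels) is built by
deterministic geometric projection with Beer–Lambert attenuation
`exp(−λ · path)`, where λ (default 0.002 /mm in the twins) is the optical
attenuation coefficient of the scintillator and `path` is the straight-line
distance from the voxel center to the camera-side exit face.  In the default
parallel (telecentric) mode each voxel's emission is shared among pixels by
the area overlap of its footprint with the pixel grid at the object plane;
with full sensor coverage and λ = 0 each camera then collects exactly the
total dose (flux conservation), which the tests assert to 1e-9.  A pinhole
mode with unit magnification at the isocenter plane is provided for
perspective studies; physical lens design, distortion and refraction at the
phantom shell are out of scope.

Light scattered inside the scintillator is modelled as a uniform background
proportional to the total deposited dose (`scatter_fraction · ΣD / n` per
pixel).  It is estimated per camera from margin pixels whose rays miss the
phantom — the twin cameras extend 10 mm beyond the phantom on every side for
this purpose — and subtracted before calibration.

Pixel intensities are converted to *weighted dose integrals* against a
reference field of known dose: `p_j = I_j / I_ref,j · (A_j,· · D_ref)`.
Pixels whose reference intensity falls below 1% of the reference maximum
are flagged and excluded from reconstruction rather than divided (the
behaviour of near-dark reference pixels is otherwise undefined).  A final
global dose scale is set by reconstructing the calibration field itself and
matching its central-region mean to the known dose.

## LASSO-TV reconstruction

The dose is recovered as

    D# = argmin_{D ≥ 0}  α·TV(D) + β·‖D‖₁ + ½‖A·D − p‖₂²

TV uses one-sided forward differences with zero gradient across the far
volume boundary; both isotropic (default) and anisotropic flavors are
implemented.  The solver is a monotone accelerated proximal-gradient
(FISTA) iteration with:

* step size 1/L from a 50-step power iteration on AᵀA (1% safety margin)
  plus a halving backtracking safeguard on the smooth term;
* an exact composite proximal step: under the nonnegativity constraint the
  L1 term is linear, so the prox of the full nonsmooth part is "shift by
  β·step, then box-constrained TV prox".  The TV prox is solved by a fixed
  number (default 10) of fast-gradient-projection iterations on the dual,
  with the dual field warm-started across outer iterations so the inner
  inexactness vanishes as the outer iteration converges;
* monotone acceptance: a candidate that increases the objective is rejected
  and the momentum restarted.  Small rejected increases (below the inner
  prox accuracy floor) terminate the iteration as converged; ten
  consecutive large increases raise a divergence error.
* zero initialization and a fixed seed for the power iteration, so runs are
  bit-reproducible; warm starts are used only across time-series frames.

Regularization weights default to α = 1e-4·‖Aᵀp‖∞ and β = 1e-5·‖Aᵀp‖∞.
They were calibrated once with the provided `tune_regularization` grid
search on the synthetic noisy single-field twin, maximizing the 3D gamma
passing rate of the end-to-end reconstruction: heavier TV (1e-3·‖Aᵀp‖∞)
rounds the corners of the field at the volume boundary, while the chosen
setting scored best among configurations that converge within the default
iteration budget and leaves no corner artifacts on noise-free runs.
On small full-rank systems the solution approaches the nonnegative
least-squares solution as α, β → 0, and on systems with m ≤ 64 the attained
objective matches an independent general-purpose convex solve to better
than 0.01% (both are asserted in the tests).

The three cameras are solved jointly through the stacked matrix; per-view
reconstruction followed by fusion would also be possible but is not
implemented.  The time-resolved path solves each frame's increment
separately (warm-started) and sums them; for a linear noise-free system
this agrees with reconstructing the summed projections to within the
solver tolerance.

## Evaluation

*Relative error* δ = (D_M − D_R)/D_R × 100% is computed per point where the
reference exceeds 5% of its maximum, with the mean and maximum of |δ|
reported.  *Detector resampling* emulates a planar diode array with 7.07 mm
spacing: lattice points centered on a plane, each assigned the nearest
voxel-center dose (ties toward the lower index), no interpolation.

The *gamma index* combines dose difference and distance to agreement:

    γ(r_e) = min_r √( ‖r − r_e‖²/Δd² + (D_e(r_e) − D_r(r))²/(ΔD·D_norm)² )

with clinical defaults Δd = 3 mm, ΔD = 3% of the global reference maximum,
and a 5% low-dose exclusion threshold; γ ≤ 1 (boundary included, with a
1e-9 numerical tolerance) counts as a pass.  The reference is linearly
interpolated on a subgrid that subdivides each voxel interval to a step of
at most Δd/10 (so original grid points remain in the search set), and the
search is capped at 3×Δd.  Candidate displacements are processed in shells
of increasing radius with running-minimum pruning: a point whose current γ
is below the purely spatial cost of the next shell can never improve, so
the search is exact on the subgrid at a fraction of the exhaustive cost
(the tests verify agreement with an independent exhaustive search to 0.02).
The "5% dose threshold" is implemented as low-dose *exclusion* (points with
reference dose below 5% of maximum are not evaluated), matching the
dose-comparison threshold convention of planar QA devices.

## What the synthetic twin does and does not show

The twin exercises the full measurement chain under exactly known ground
truth, with the forward projection, calibration and reconstruction using
the same response matrix.  Passing it demonstrates the internal consistency
and numerical accuracy of the chain — calibration bias, scatter-removal
residuals, Poisson noise propagation and reconstruction artifacts are all
present — but not robustness to model mismatch: real systems add lens
distortion, imperfect response-matrix knowledge, Cherenkov light,
scintillation quenching, spatially varying scatter, and camera
synchronization error, none of which are simulated.  Accuracy at the
volume boundary along the beam axis is intrinsically weaker: with three
orthogonal views the data under-determine field corners at the entry/exit
faces, and the reconstruction there relies on the TV prior.

## Numerical choices and degenerate inputs

* Nearest-neighbor ties in detector resampling break toward the lower index.
* A beam whose axis misses the grid yields a zero volume with a warning,
  not an error; an empty beam list is an error.
* Beams of zero duration contribute no frames.
* `poisson_gain = 0` disables the Poisson term (deterministic images).
* Gamma analysis requires a strictly positive reference maximum and at
  least one point above the threshold.
* All randomness flows from a single seed through `numpy` SeedSequence
  spawning (sub-seeds kept below 2³¹); identical seeds reproduce identical
  images, reconstructions and reports bit-for-bit.

## Problem sizes

The bundled experiment configurations are desk-scale by design: 50³ voxels
at 2 mm with three 60×60-pixel cameras (n = 10 800, m = 125 000,
~375 000 nonzeros in A).  A full twin — simulation, calibration, 600
solver iterations and 3D gamma — runs in roughly one to two minutes on a
single core; the full-resolution 100³/1 mm geometry is supported by the
same code path at proportionally higher cost.
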