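# Methods

## Physical model

PRFS thermometry converts the phase difference between a dynamic and a
reference acquisition into a temperature variation,
`dT = dPhi / (alpha B0 gamma TE)` with `gamma = 2 pi * 42.58e6 rad/s/T` and
`alpha = -0.0094 ppm/degC` for aqueous tissue. A susceptibility variation
`chi` adds `d (*) chi` to the relative difference field (RDF), where `d` is
the unit dipole kernel; in RDF units (ppm) the measured field is
`alpha dT_true + d (*) chi`, so a bubble-induced `chi` masquerades as a
temperature error of `(1/alpha)(d (*) chi)` — negative along B0 and positive
equatorially, since `alpha < 0`.

The correction assumes (i) bubble establishment is fast compared with the
heating duration, and (ii) the artifact is temporally constant after
establishment. A single `chi` is therefore estimated once and subtracted as
a constant term from every dynamic in the correction interval (by default
from the onset to the end of the series; bubble disappearance during
cooling is out of scope).

## Discretization

The acquisition lattice is modelled with the inter-slice gap folded into
the slice pitch (3 mm thickness + 1.5 mm gap = 4.5 mm), one contiguous slab
per slice. Susceptibility lives on a factor-2 refinement of this lattice
(subvoxels), which mitigates the unbounded near-field of the dipole kernel:
sources need not sit directly adjacent to data voxels, and partial-volume
structure within a voxel can be represented. The discrete kernel is the
analytic density evaluated at cell-center offsets times the cell volume
(point-dipole approximation), with the zero-offset sample set exactly to
zero. Whether the refinement should be per-axis is not settled; the stated
subvoxel resolution implies a uniform factor 2, which is what the package
adopts (arbitrary integer factors are supported by the grid types).

Convolution uses zero-padding to twice the grid size per axis, making the
circular FFT product equal to the linear convolution; a brute-force
direct-summation oracle in the test suite confirms agreement to <= 1e-9 ppm
on small grids. The padding amount is a package choice; no claim is made
that it matches any particular prior implementation.

## Inverse problem

The data vector `b` is the prior image — mean of `n_avg = 5` dynamics after
stabilization minus the mean of 5 dynamics before onset — converted to ppm
and restricted to the ROI with per-voxel weights applied. The operator
`A = M_ROI . W . P . D_A . D_s` is assembled densely, column by column, by
evaluating the kernel at child-subvoxel-to-candidate offsets (exactly
equivalent to the convolution route, and cheap because candidates are few).
Weights are `SNR * B0 gamma TE * 1e-6` per ppm, where SNR is the mean
"during"-window magnitude over the temporal standard deviation of the
pre-heating magnitude; a voxel with zero temporal variance is capped at a
configurable maximum SNR (1e6) with a warning. Any uniform rescaling of the
weights scales `A` and `b` equally and leaves the solution unchanged.

`chi` is bounded to [0, 10] ppm and solved with SciPy's bounded-variable
least squares (`lsq_linear`, method `bvls`, tolerance 1e-8). The problem is
convex, so the optimum is solver-independent up to tolerance; with multiple
candidate subvoxels it can be degenerate (several `chi` reproduce the same
data), in which case any minimizer is acceptable — the subtracted artifact
is what matters, and it is determined on the data voxels. A zero data
vector skips the solver (`chi = 0`).

Per-slice mode (default): each data slice `z` is corrected independently
using its own ROI rows, with candidate sources in the six subslices of
voxel slices `z-1, z, z+1` (central plus adjacent slabs; boundary slices
drop missing neighbors; slices with no bubble voxels within reach are
skipped). Slice results are independent of processing order. The
`all_slices` mode solves one problem with every ROI voxel and every bubble
subvoxel. The composite chi map stores, per slice, the solution on that
slice's own subslices.

## Masks

`M_b` marks possible bubble positions: voxels within one voxel of the
annotated two-voxel-thick probe line whose pre-ablation magnitude is below
`void_fraction = 0.5` of the median magnitude over the probe neighborhood;
a manual mask may be supplied instead, and overestimating `M_b` is safe
(superfluous candidates receive negligible susceptibility). By default it
spans every slice the probe line intersects. `M_ROI` is the per-slice
Euclidean dilation of the probe line by 9 voxels with `M_b` removed, so the
two are disjoint by construction. Dilation uses the Euclidean disk
(distance-transform semantics): radius 1 yields the 4-connected
neighborhood.

## Dosimetry and evaluation

Corrected temperatures are low-pass filtered with a first-order Butterworth
at 0.04 Hz. The default is a causal single pass (real-time compatible),
initialized at the first sample so a constant series is unaffected; a
zero-phase forward-backward mode exists for retrospective analysis. CEM43
accumulates `(dt/60) * R^(43 - T)` per dynamic from a 37 degC baseline with
`R = 0.5` above the breakpoint and `R = 0.25` below (the standard Sapareto
convention; the rate below the breakpoint is configurable). The lesion is
the set of voxels whose final dose reaches 240 equivalent minutes
(>= convention at the boundary). Consistency check: at a constant 60 degC
the rate is 2^17 equivalent minutes per minute, so 240 CEM43 is reached in
240*60/2^17 = 0.11 s.

Overlap metrics are Dice, total overlap `|S n T|/|T|`, and false-negative
rate `1 - TO` against a reference mask; geometry metrics are the volume and
the extents of the voxel-center point cloud along its PCA axes (the
"three main axes" are not further specified anywhere authoritative;
principal-component extents are the package's choice). Registration between
the dose and reference spaces is out of scope — a user-supplied affine is
applied with nearest-neighbor resampling.

## Synthetic data

The generator emulates the reference acquisition: seven slices, 128 x 128
matrix, 2.3 x 2.3 mm in-plane, 4.5 mm slice pitch, ~0.2 Hz update
(5 s dynamic period). Defaults, chosen once as the study conditions:

- **Sources**: per-subvoxel amplitudes uniform on a two-voxel-thick,
  six-voxel-long line footprint over the two central and four adjacent
  subslices, rescaled so the voxel-level artifact peaks at 35 degC outside
  the source lines (boiling artifacts corrupt measurements by roughly
  +-30-40 degC) and capped so chi stays within [0, 10] ppm. The resulting
  chi values (~1-2 ppm) sit well inside the bounds.
- **Heating**: an analytic 3D Gaussian around the probe (sigma 4 mm) with
  an exponential-saturation ramp (tau 30 s) to +43 degC — a feedback-
  stabilized ablation reaching its setpoint before bubbles form, so the
  temperature is approximately stationary across the prior windows. No
  bioheat PDE is solved; heating realism beyond this is not required for
  testing the artifact correction.
- **Timing**: 55 dynamics (275 s, a scaled-down session), heating from
  dynamic 5, bubble onset at dynamic 35.
- **Signal**: magnitude 100 with a 10x void on the probe line; complex
  Gaussian noise at configurable SNR (default 20). The measured phase is
  the true (unwrapped) phase plus the noise-induced angular deviation of
  the complex signal — exact complex-noise statistics without introducing
  phase wraps, since no unwrapping is performed anywhere in the package.

What the generator does **not** emulate: respiratory motion, blood-flow
transients, drift, fat, EPI/GRAPPA reconstruction artifacts, time-varying
bubbles, T2*-related magnitude loss on heating. Passing tests therefore
demonstrate correctness of the model, inversion and dosimetry under the
stated assumptions, not robustness to those confounders on real data.

In the Method 1/2/3 comparison harness the inversion is given the true
source footprint as `M_b` and noiseless central-slice data with unit
weights. Method 3's support then matches the truth, so it fits the data
essentially exactly (RMSE ~ machine precision); Methods 2 and 1 are
progressively restricted and misspecified, and their residual errors
(~1.4 and ~3 degC on the default phantom) quantify what subvoxel
resolution and adjacent-slice sources contribute. The discriminating check
is the ordering RMSE(M3) <= RMSE(M2) <= RMSE(M1), verified as a median over
ten random phantoms; exact error magnitudes depend on the (unpublished)
amplitude distribution of the sources.

## Numerical choices and degenerate inputs

- Solver tolerance 1e-8 (projected-gradient), iteration cap >= number of
  candidates; bound violations from round-off are clipped.
- Temperature/phase/RDF conversions are exact linear maps; round-trips are
  identities to machine precision.
- Empty bubble mask, empty ROI, overlapping masks, windows out of range,
  zero TE/B0/alpha, cutoff at or above Nyquist: all rejected with
  `ValueError` at the boundary of the offending operation; pipeline stages
  wrap failures with the stage name.
- Onset detection counts ROI voxels below -10 degC inside the 90-degree
  double cone along +-B0 from the probe line, and fires when the count
  holds at >= 5 voxels for 2 consecutive dynamics (all configurable).
  Detection thresholds were chosen for the stated noise level; absence of
  an onset is a valid result, not an error.
- Drift correction is a pass-through hook for a user-supplied transform;
  none is implemented.

## Limitations

- Phase wraps are not handled; inputs must be unwrapped differences.
- The artifact is assumed temporally constant; gradual bubble evolution or
  disappearance during cooling is not modelled.
- Per-slice correction ignores cross-slice data consistency by design (the
  `all_slices` mode trades artifact-shape fidelity for a better-posed
  problem).
- In vivo overlap statistics require animal data and registration to
  post-procedural imaging; the evaluation module computes the metrics but
  the package makes no claim about reproducing in vivo values.
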