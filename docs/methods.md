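# Methods

## Scope and model

`cochleomap` computes the three coordinate systems in which human cochlear
tonotopy is reported — curvilinear length along a structure's centerline
(mm), unwrapped angular depth about the mid-modiolar axis (degrees, 0° at
the round-window center), and characteristic frequency (Hz) — and the
morphometric arithmetic that links them to innervation density. It operates
on ordered 3D point sets (mm) such as landmarks traced in 3D Slicer on
synchrotron or micro-CT volumes; no image processing is performed.

### Arc length

Curvilinear length is the piecewise-linear chord sum over the ordered
landmarks. This matches how landmark-based tracing defines length: the
resolution is controlled by the tracing (or by `resample_centerline`, which
redistributes points at uniform arc spacing), not by a smoothing spline
whose stiffness would be an extra free parameter. Chord sums underestimate
a curve's true length by O(Δs²); at the default synthetic sampling
(≈0.017 mm spacing) the relative error on a cochlear spiral is below 10⁻⁶.

### Mid-modiolar axis

The angular coordinate needs an axis. We estimate it from the BM centerline
itself as the line about which the centerline is best explained as a
*smooth conical spiral*. In a candidate frame (axis point `c`, unit
direction `d`), the in-plane projection of the points is written as a
complex signal

    w(θ) = B(θ) · e^{iθ},

where θ is the unwrapped in-plane angle and B is a real Chebyshev
polynomial in θ (the slowly varying spiral radius). For fixed frame
parameters B is solved by linear least squares (variable projection); the
frame's four free parameters (two tilt, two in-plane offset components) are
then optimized with `scipy.optimize.least_squares` on the model misfit,
starting from the centerline's net winding direction
Σ (pᵢ − p̄) × (pᵢ₊₁ − pᵢ), which is exact for a planar circle and robust
for helices whose height is comparable to their radius (where the PCA
principal direction is ill-defined).

The key property is identifiability: an axis offset adds a constant to
`w` and a tilt adds a term linear in the axial coordinate — both have
*constant phase*, which `B(θ)e^{iθ}` with a real, low-order B cannot
reproduce — whereas the conical taper of the radius lives entirely in B.
The trend degree scales with the angular span (`deg = clip(round(2.8 ·
turns), 6, 10)`): high enough to follow a decaying radius over 1.5–3 turns,
low enough that it cannot oscillate at one cycle per turn and absorb a
misalignment signal. On noise-free synthetic spirals of 1.5–3 turns the
axis is recovered to ≲0.2° and ≲0.04 mm; with 0.02 mm isotropic tracing
noise, to ≲0.5°. A planar circle (zero pitch) returns its normal
essentially exactly. Degenerate inputs are rejected: collinear point sets
(no winding direction), centerlines winding less than 360° (checked post
hoc against the fitted axis), and a round-window landmark within 1 µm of
the axis (zero ray undefined).

Handedness (left vs right ear) is an explicit input, default +1 for a left
ear with angle increasing toward the apex.

### Angular depth

Each point's angle is measured in the plane orthogonal to the axis from
the zero ray through the round-window center, signed by handedness, and
unwrapped cumulatively (adding 360° at each wrap) so a base-to-apex
centerline yields a monotone profile whose maximum is the structure's
angular length. Unwrapping assumes no reversal exceeding 180° between
consecutive samples, which resampling to ≤0.5 mm spacing guarantees for
cochlear geometry. Points on the axis have undefined angle and raise an
error naming their indices rather than being silently dropped.

### Greenwood frequency map

The organ-of-Corti map uses Greenwood's function F(x) = A(10^{a·x} − k)
with x the proportional distance from the apex, so F is lowest (≈20 Hz) at
the helicotrema and highest (≈20.7 kHz) at the base. Defaults are the
standard human constants A = 165.4 Hz, a = 2.1, k = 0.88; with these and
the specimen turn lengths (21.38, 8.37, 4.35 mm of 34.10 mm) the turn-end
frequencies round to 859, 161 and 20 Hz. `fit_greenwood` refits the
constants to (x, f) samples by nonlinear least squares on log₁₀-frequency
residuals — frequencies span three decades, so relative (perceptual) error
is the right loss.

### Frequency transfer to the spiral ganglion

The SG tonotopic map is built by transfer along individually traced
peripheral dendrites: each trace carries the OC frequency at its BM
attachment (log₂-linear interpolation in arc position) to its SG
attachment. Log-domain interpolation and geometric averaging of coincident
attachments keep all operations linear in semitones. Attachments farther
than 0.2 mm (configurable) from their centerline are rejected with the
trace named. The SG's own curvilinear coordinate treats the ganglion as a
single 14.73 mm curve continuing through the central modiolar space beyond
Rosenthal's canal.

### Rates and octave bands

Rate-of-change profiles are 12·|d log₂ f / dp| with p either arc length or
angular depth, computed by central differences (one-sided at the ends) on
a moving-average-smoothed log₂-frequency series. The default window is
1 mm or 30°; at the ends the window shrinks *symmetrically*, which keeps a
linear log-frequency series exactly linear so an exponential map yields a
constant rate everywhere. Octave-band boundaries are placed at ref·2ⁿ and
positioned by monotone log-frequency interpolation; adjacent-band semitone
spans sum to the map's total span by construction.

### Morphometry

Five auditable operations: cylinder-packing soma capacity
floor(packing · V_cyl / V_sphere), linear axon-density scaling
round(n · L_target / L_ref), IHC counts round(density · length),
axons-per-IHC to one decimal, and integer length-percentages. Packing
counts are floored (a capacity cannot be exceeded); density scalings round
half-up, with inputs snapped to 9 decimals first so products that are
exactly x.5 in decimal round up regardless of binary representation.
The default `packing_fraction` is 1.0 — a pure volume ratio, giving 8508
somata for the 22 µm / 1.51 mm / 200 µm apical cell mass. This is a
capacity bound, not a count: no packing correction is applied because none
can be justified from first principles, and the summary table reports it
*alongside* the density-scaled estimate (8152 neurons from 3694 axons over
4.35 mm extended to 9.6 mm) rather than merging the two.

## Synthetic geometry generator

The generator emulates the studied specimen so every stage is testable
without imaging data. The BM is a conical helix about the z axis with
radius r(θ) = R₀·exp(P(θ)), P a polynomial with one coefficient per
cochlear turn, solved (`scipy.optimize.fsolve`; bisection in the
single-segment case) so that the *discrete polyline's* chord length matches
each printed turn length — hence `arc_length` reproduces 34.10 mm and the
turn boundaries at 21.38 / 29.75 mm identically, not just asymptotically.
A smooth radius profile is deliberate: per-turn exponential pieces would
put slope cusps at every 360° boundary, a one-cycle-per-turn radial signal
that is spectrally indistinguishable from axis misalignment and would make
the geometry unfairly hostile to any axis estimator, unlike a real cochlea.
The SG is an inner helix (base radius 0.55·R₀) spanning 720° and 14.73 mm.

Defaults pin only what the specimen pins: total lengths, turn lengths,
angular spans, and the 650° dendrite-rotation onset. Base radius (4.2 mm)
and pitch (2.0 mm/turn) are plausible cochlear dimensions chosen once;
no frequency- or length-based result depends on them. Dendrites leave the
BM at evenly spaced landmarks and attach to the SG at the same angle below
the rotation onset (radial), then with a linear clockwise angular ramp that
reaches the SG terminus (720°) at the BM apex — the paper-level fact is
onset and direction; the linear ramp is the simplest monotone form.
Optional noise is i.i.d. isotropic Gaussian per coordinate (the simplest
model of tracing jitter at ~9 µm voxel scale); identical seeds give
bit-identical bundles via `numpy.random.default_rng(seed)`.

What the generator does **not** emulate: true scala geometry and
non-circular cross-sections, measurement anisotropy along the viewing
axis, systematic (non-white) tracing error, inter-specimen variability,
and the real specimen's radius/pitch profile (unpublished). Tests passing
on this geometry therefore validate the *mathematics* of the pipeline —
lengths, angles, transfer, rates — under the specimen's printed summary
dimensions, not segmentation accuracy on real images.

## Numerical choices

- Frame-fit tolerances: `least_squares` with xtol 1e-10, ftol/gtol 1e-12,
  max 400 evaluations; axis sign ties broken toward the apex-most point.
- Greenwood fit: bounds A > 0, a > 0, 0 ≤ k < 1; failure raises with the
  last iterate attached.
- Unwrapping maps the first angle to [−180°, 180°) and each step to
  (−180°, 180°].
- Reported precisions follow the field's tables: integer Hz, one-decimal
  semitones, integer percent.
- Problem sizes: the synthetic BM/SG are sampled at 2 points per degree
  (2081/1441 points), and analysis drivers subsample every 40th landmark
  for Greenwood refits; these sizes make every pipeline stage run in
  seconds while keeping discretization error far below the reported
  precisions.

## Known limitations

- The mid-modiolar axis of the actual study was defined in the imaging
  viewer; any numerical axis definition (including this one) is a modeling
  choice, and results within ~0.5° of axis direction should be treated as
  equivalent.
- `transfer_to_sg` trusts the traced dendrites; crossing or misattached
  traces surface only through the 0.2 mm attachment tolerance.
- Semitone-difference tables computed from *rounded* integer-Hz
  frequencies can differ from those computed on unrounded values by up to
  ~0.05 semitones near the printed one-decimal boundary.
- The cylinder-packing estimate ignores stereological corrections and
  non-spherical somata; it is reported as a bound, not an estimate.
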