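# Methods

This note records the models, numerical choices and known limitations
behind `divmap`, at the level of detail a maintainer or reviewer needs
to interpret its outputs.

## Interpolation model

Activation maps are reconstructed as polyharmonic-spline interpolants:
Duchon's radial cubic kernel r³ augmented with a first-order
polynomial, fitted under the standard orthogonality side constraints
(Σα = Σαx = Σαy = 0). The (N+3)×(N+3) saddle-point system is solved by
direct dense factorization — clinical recordings have N ≲ a few
hundred sites, so iterative or fast-multipole machinery would add
nothing. Before assembly, coordinates are centered and rescaled by the
mean pairwise site distance (the r³ kernel on raw millimetre
coordinates produces a large dynamic range in the system matrix); the
returned weights are de-scaled, so the model is exactly the
interpolant of the original data. The fit is pure interpolation: no
smoothing parameter exists, matching the method's premise that the
annotated activation times are honored exactly. Consequences worth
knowing:

* duplicate sites (< 1 µm apart) are rejected rather than averaged —
  averaging would silently change the data, and the system is singular
  otherwise;
* sites with a missing activation for a beat are dropped from that
  beat's fit (no imputation); at least 3 non-collinear sites must
  remain;
* the interpolant extrapolates freely outside the convex hull of the
  sites, and extrapolated values degrade quickly — all default
  evaluation masks are hull-restricted, and error metrics are computed
  inside the hull of the *available* (post-removal) sites.

Gradient and Hessian of the interpolant are evaluated in closed form
(∇r³ = 3r·d, with the continuous limit 0 at a center), which makes the
CV field v = ∇f/‖∇f‖² and the divergence of the unit field
D = tr(H)/‖g‖ − gᵀHg/‖g‖³ analytic. Divergence is *not* computed by
finite differences of the sampled field: on coarse grids FD aliases
badly near sources; the FD route is retained only as a test oracle.
Nodes with ‖∇f‖ < 10⁻⁶ ms/mm (isochrone extrema, the immediate focal
origin) are flagged invalid instead of producing unbounded speeds.

## Catheter geometry

The bundled five-spline layout places 15 bipole midpoints on splines at
72° increments (starting at +90°), at radii {4, 8, 12} mm scaled so the
outermost ring equals the swept radius R = 2.7/√0.05 ≈ 12.07 mm. Only
the relative geometry (3 bipoles per spline, inner→outer label order
X_34 → X_12) is constrained by the mapping hardware; the angular offset
is a convention. R is fixed by the chance-level construction of the
localization threshold (r = R√0.05 = 2.7 mm exactly) rather than by a
physical catheter dimension. A second constructor derives the 15
bipole midpoints from 20 electrodes at a configurable interelectrode
spacing (4 mm default), matching the hardware description used for
anatomically realistic simulations.

## Synthetic substrate

The tissue-patch generator emulates the validation conditions of the
reference study: a 4×4 cm patch sampled on a 200×200 grid
(0.2 mm/cell), cycle length 150 ms, and four patterns — plane wave
(60.4 cm/s), focal source in homogeneous tissue (54.6 cm/s), focal
source in heterogeneous tissue, and two colliding plane waves
(55.8 cm/s, entering from opposite edges with equal speed, so the
collision line bisects the patch). Activation times are generated
analytically (plane/focal/collision) or by a fast-marching eikonal
solve (heterogeneous), then quantized to 1 ms to emulate activation
detection on 1 kHz-sampled electrograms (`time_quantum=0` gives ideal
fields for analytic tests).

The heterogeneous pattern realizes "eight areas with different
conduction properties around the focal site" as 8 equal angular
sectors whose speeds are drawn per seed from Normal(60, 13) cm/s
truncated below at 20 cm/s; across seeds the realized speed field
averages ≈ 59.9 ± 12.5 cm/s, the reported tissue statistics. The
original study used a cellular-automaton substrate whose update rules
live in prior work; the analytic/eikonal substitute reproduces the
printed exact median speeds and heterogeneity statistics, which is
what the validation experiments consume. What it does *not* reproduce
is the lattice roughness of an automaton's wavefronts: our
ground-truth fields are exactly radial/planar, so noiseless
reconstruction errors here are *smaller* than against an automaton
truth (e.g. the noiseless focal-pattern pointwise speed error is
≈ 3.7% here versus 7.6% reported), while the perfectly centered
collision crease is *harder* than the reference geometry appears to be
(≈ 15% versus 11.4%). Passing or missing those two baselines therefore
reflects the substrate model, not the reconstruction code.

The eikonal solver is a second-order upwind fast-marching scheme
(min-heap sweep; two-sided quadratic update; second-order one-sided
differences where two upwind neighbors exist, with a causal fallback).
Nodes within 6 cells of the source are seeded with exact radial times
— legitimate for angular-sector speed maps, where the exact ray to a
near-source node stays inside one sector — which removes the source
singularity error. Against the closed-form radial solution the solver
is accurate to < 0.5% for r ≥ 5 cells.

## Corruption models and experiment protocol

* **Jitter.** Activation-time misdetection is modelled as i.i.d.
  uniform jitter; the amplitude ε (a fraction of the 150 ms cycle
  length) is interpreted as the *full width* of the distribution,
  jitter ∈ [−ε/2, +ε/2]. The reference text is ambiguous between
  half- and full-width; we calibrated against the published plane-wave
  noise row (speed error ≈ 28% at ε = 10%, which full-width reproduces
  at ≈ 32% while half-width gives ≈ 50%) and fixed the convention once.
* **Removal.** A uniform random subset of sites is removed, all beats
  affected identically; fits proceed on the survivors.
* **Error metrics.** Estimated fields are compared to ground truth
  point-by-point on the 200×200 truth grid restricted to the convex
  hull of the available sites; reported values are the median over
  nodes of the absolute CV-magnitude error (percent) and of the
  absolute angle between unit vectors, aggregated as median (IQR) over
  100 stochastic repetitions. Catheter placement is fixed and
  patch-centered for the error tables (the unperturbed rows are then
  single deterministic values); only the localization sweeps re-place
  the catheter randomly per repetition, keeping the source inside the
  swept circle.
* **Beat averaging.** For multi-beat analyses the per-beat CV fields
  are combined node-wise by averaging CV *magnitudes* arithmetically
  and directions as the normalized mean unit vector, keeping a node
  only where every beat yields a valid vector. A plain vector mean was
  tried first and rejected: noise-rotated vectors shrink the mean
  magnitude, which inflates 10-beat speed errors well beyond the
  published behaviour, whereas magnitude/direction averaging matches
  it closely. Divergence maps are averaged node-wise as maps (a node
  is kept when valid in at least half the beats).
* **Randomness.** Every stochastic operation draws from
  `numpy.random.Generator` streams spawned from a single seed
  (per-level, per-repetition substreams), so whole experiment tables
  are bit-reproducible.

Our pipeline's sensitivity to jitter runs uniformly ≈ 15% above the
published values (all patterns, all noise levels); at fixed geometry
this sensitivity is a property of exact polyharmonic interpolation, so
the residual points to an unprinted difference in the effective jitter
magnitude or catheter span of the reference setup. It shifts the
noisy-case localization accuracy limit from ≈ 11% noise to ≈ 9.5%
here; no compensation is applied.

## Activation detection

The barycenter annotator band-passes the bipolar electrogram
(40–250 Hz), rectifies, low-pass smooths (20 Hz) into an envelope,
segments activation waves by threshold crossing (0.5 × the 75th
percentile of envelope peak heights), merges windows closer than a
50 ms blanking interval, and stamps each wave at the envelope-weighted
barycenter Σtw/Σw. None of these constants are prescribed by the
divergence method itself — they are conventional values for atrial
electrograms and all are exposed in `DetectionParams`. The synthetic
electrogram generator produces biphasic wavelets (optionally
fragmented into sub-deflections that preserve the energy barycenter)
plus white noise at a set SNR; it contains no ventricular far-field
component, so the detector is validated only against atrial-like
morphology. Beat alignment clusters pooled detections by gap
splitting at 40% of the cycle-length hint, takes per-site nearest
detections, drops clusters spanning > 0.8 cycle lengths, and reports
(rather than resolves) suspicious cluster spacing.

## Degenerate inputs and tie-breaks

Collinear or near-duplicate site sets raise explicit errors before the
linear algebra can go singular. The focal localizer returns the global
argmax over valid nodes, ties broken by row-major order, with no
sub-grid refinement (distances are meant in grid cells). No divergence
cutoff is applied to declare that a source exists at all — the maximal
value is reported and the decision left to the caller, since any such
threshold would need ROC calibration against labelled data.

## Problem sizes

Default experiment sizes — 200×200 truth grids, 15 sites, 100
repetitions, 10-beat averaging — run in seconds to a couple of minutes
on one CPU; they are the reference study's own sizes and are exposed
as parameters throughout.

## Known limitations

* Rotors: a sum of continuous radial functions cannot represent the
  phase discontinuity at a rotor's head-meet-tail line; the method
  maps rotational activation as a curved wave and must be supplemented
  by dedicated rotor detectors.
* Conduction block: exact interpolation across a block line invents
  continuous conduction; missing activations are dropped, not marked
  as barriers.
* Single-source assumption: only the global divergence maximum is
  reported; multi-source discrimination is future work.
* Clinical generalization: all quantitative claims here are against
  synthetic substrates; the electrogram fixtures lack ventricular
  interference, far-field components and electrode-contact artifacts.
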