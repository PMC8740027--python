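# divmap

Divergence-based identification of atrial-fibrillation focal drivers
from multipolar catheter mapping data.

During atrial fibrillation, focal drivers activate the surrounding
tissue centrifugally. Multipolar mapping catheters (e.g. the
five-spline PentaRay) record simultaneous bipolar electrograms at ~15
scattered sites, from which local activation times (LATs) can be
annotated beat by beat. `divmap` turns those scattered LATs into
continuous activation maps, conduction-velocity (CV) vector fields and
divergence maps, and localizes focal sources — the full analysis chain,
plus the synthetic substrate and Monte-Carlo experiments used to
characterize its robustness.

## Method

Given sites **X**ᵢ with activation times tᵢ for one beat, the
activation map is the polyharmonic interpolant with Duchon's radial
cubic kernel and a first-order polynomial,

    f(X) = Σᵢ αᵢ ‖X − Xᵢ‖³ + β₁ + β₂x + β₃y,

with the side constraints Σαᵢ = Σαᵢxᵢ = Σαᵢyᵢ = 0; the weights solve a
symmetric (N+3)×(N+3) saddle-point system. The kernel needs no tuning
parameter and f is smooth, so everything downstream is analytic:

* **CV field** — the wavefront moves along ∇f with speed 1/‖∇f‖:
  **v** = ∇f / ‖∇f‖² (reported in cm/s).
* **Divergence map** — with g = ∇f and H the Hessian of f, the
  divergence of the *normalized* field v̂ = g/‖g‖ is
  D = tr(H)/‖g‖ − gᵀHg/‖g‖³ (mm⁻¹). D > 0 marks centrifugal sources,
  D < 0 collision lines, D ≈ 0 planar propagation.
* **Localization** — a focal driver is the global maximum of the
  (optionally beat-averaged) divergence map; an estimate is accurate
  when it falls within r = R·√0.05 of the true source, the radius at
  which a random guess inside the catheter's swept circle (radius R)
  would hit with 5% probability. For the bundled 15-bipole layout
  (R = 2.7/√0.05 ≈ 12.07 mm) this gives r = 2.7 mm.

The package also provides: synthetic tissue-patch activation patterns
(plane wave, focal source in homogeneous and in 8-sector heterogeneous
tissue via a built-in fast-marching eikonal solver, wavefront
collision), the corruption models used in robustness studies (uniform
LAT jitter as a fraction of the 150 ms cycle length; random electrode
removal), a Monte-Carlo stability harness, and a barycenter-based LAT
annotator for bipolar electrograms.

## Worked example

```python
import numpy as np
from divmap import (
    PatternConfig, simulate_activation_field, sample_multisite,
    pentaray_patch_layout, fit_interpolant, make_grid,
    velocity_field, divergence_field, median_speed,
    locate_focal_source, assess_localization, localization_threshold,
)

# a focal source at the center of a 4x4 cm patch, conducting at 54.6 cm/s
field = simulate_activation_field(PatternConfig(pattern="focal_homogeneous"))
layout = pentaray_patch_layout()                  # 15 bipoles, 5 splines
rec = sample_multisite(field, layout, center=(18.0, 22.0))

model = fit_interpolant(rec)                      # Duchon-cubic RBF + linear term
grid = make_grid(rec, resolution=100)             # hull-masked evaluation grid
cv = velocity_field(model, grid)
dmap = divergence_field(model, grid)

r = localization_threshold(layout.swept_radius)   # 5% chance-level radius
res = assess_localization(locate_focal_source(dmap), field.true_source, r)

print(f"median CV        : {median_speed(cv):.1f} cm/s")
print(f"divergence max   : {res.d_max:.2f} 1/mm")
print(f"estimated source : ({res.estimated_position[0]:.2f}, {res.estimated_position[1]:.2f}) mm")
print(f"distance to truth: {res.distance:.2f} mm (threshold r = {r:.2f} mm) -> accurate={res.accurate}")
```

Output:

```
median CV        : 53.8 cm/s
divergence max   : 8.04 1/mm
estimated source : (20.25, 19.48) mm
distance to truth: 0.57 mm (threshold r = 2.70 mm) -> accurate=True
```

The median reconstructed CV (53.8 cm/s) approximates the set speed of
54.6 cm/s (the interpolant rounds the cone tip of the radial
activation map, which depresses nearby speed estimates slightly). The
divergence maximum sits 0.57 mm from the planted source — well within
the 2.7 mm chance-level threshold.

A command-line interface wraps the same pipeline:

```bash
divmap simulate --pattern focal_homogeneous --seed 1 --out run/
divmap map run/recording.csv --png --out run/
divmap localize run/recording.csv --true-source 20 20 --out run/
divmap stability --pattern plane --axis noise --reps 100 --out run/
```

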