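# scaffold-regen

Tools for designing porous bone-scaffold lattices, homogenizing their
directional stiffness with a 3D frame solver, and quantifying bone ingrowth
in micro-CT volumes of scaffold-filled metaphyseal defects — together with
a synthetic ovine-cohort generator that makes the whole chain testable end
to end.

The package targets researchers in scaffold-guided bone regeneration who
want to reproduce or extend the computational side of a classic study
design: four 3D-printed scaffolds (stiff titanium octet truss **TC**,
stochastic titanium **TB**, polyamide octet truss **PB**, polyamide
orthogonal grid **PC**) implanted pairwise into twelve sheep, with bone
ingrowth read out at six weeks as a percentage of the scaffold pore volume.

## The models at the core

**Lattice mechanics.** Scaffolds are strut networks (octet/FCC tiling,
cubic grid, or Poisson-disk stochastic network wired to mean degree 4.5).
Each strut is a shear-flexible 3D frame element (6 DOF/node); the apparent
modulus in a loading direction is

    E_app(φ, θ) = (F / A) / (δ / H)

from a displacement-controlled platen test, swept over the hemisphere in
15° increments of φ and θ. The anisotropy coefficient is
`max E_app : min E_app`, and strut radii are solved so the voxel-measured
porosity of the implant cylinder matches the design's nominal value.

**Synthetic cohort.** The latent ingrowth model encodes two osteogenic
mechanisms: an injury-driven peripheral rim, equal in every defect
(baseline B = 6.8 pp of pore volume), and a strain-driven central gain d on
the more compliant scaffold of each animal's pair — d ≈ 14 pp in the seven
strong responders, ≈ 3 pp in the five weak ones, with one animal reversed.
Phantoms render this truth at 100 µm voxels with material-specific gray
levels, a beam-hardening halo around titanium, partial-volume blur and
noise.

**Quantification.** Exactly the study's two segmentation chains: a global
threshold inside the known defect cylinder for polyamide, and a
metal-label + dilation + local-threshold-on-every-second-slice +
interpolation chain for titanium; ingrowth fraction
`100 · bone / (defect · porosity)`. Virtual sections at 2/5/8/11/14 mm are
scored 0–4 for interface and interior osteogenesis by three simulated
raters with consensus resolution, fluorescence sections yield the mineral
apposition rate (label-band offset / 14 days), and the statistics stage
runs exact sign-enumeration Wilcoxon tests, a log-stiffness regression and
a two-means responder split.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from scaffold_regen import DESIGNS, design_direction_sweep, anisotropy_coefficient
from scaffold_regen.pipeline import cohort_run

sweep = design_direction_sweep(DESIGNS["PC"])
print(f"PC anisotropy max:min = {anisotropy_coefficient(sweep):.2f}")

run = cohort_run(seed=1)
s = run.report["summary"]
print(f"strong responders: n={s['n_strong']}, "
      f"mean paired gain {s['strong_mean_difference_pp']} pp")
print(f"weak responders:   n={s['n_weak']}, "
      f"mean paired gain {s['weak_mean_difference_pp']} pp")
print(f"ingrowth range {s['fraction_min_pct']}-{s['fraction_max_pct']} % "
      f"of pore volume")
print(f"stiffness regression: slope {run.report['regression']['slope']:.1f} "
      f"pp/decade, r2 {run.report['regression']['r2']:.3f}, "
      f"p {run.report['regression']['p']:.4f}")
```

prints (about four minutes, single core):

```
PC anisotropy max:min = 5.25
strong responders: n=7, mean paired gain 14.0 pp
weak responders:   n=5, mean paired gain 2.9 pp
ingrowth range 6.3-20.9 % of pore volume
stiffness regression: slope -6.2 pp/decade, r2 0.411, p 0.0007
```

The anisotropy ratio says the orthogonal grid is ~5× softer in its weakest
loading direction than along its struts; the cohort lines show the pipeline
recovering the two responder groups (7/5 split), their mean paired gains
(≈14 and ≈3 pp), the 7–21% ingrowth range, and the inverse
stiffness–ingrowth correlation from the synthetic volumes alone.

A CLI mirrors the stages: `scaffold build|sweep|cohort|run|stats`
(`scaffold sweep --design PB` writes the direction sweep as CSV).

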