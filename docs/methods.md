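# Methods

This package re-implements, as a tested computational pipeline, the analysis
chain of a scaffold-guided bone-regeneration experiment in the ovine distal
femur: four 3D-printed scaffold designs spanning two orders of magnitude in
apparent stiffness, implanted pairwise into twelve animals, imaged by
micro-CT at six weeks, and analyzed for bone ingrowth, regional osteogenesis
and mineral apposition.  Because no raw data are publicly deposited, the
in-vivo arm is replaced by a synthetic cohort generator whose latent model
encodes the study's two-mechanism interpretation; everything downstream of
image formation (segmentation, scoring, statistics) is implemented exactly
as the study describes and is exercised against the generator's ground
truth.

## Scaffold designs and lattice generation

Four designs combine two solid materials (CP-Ti grade 2, E = 100 GPa,
nu = 0.34; PA12 nylon, E = 2 GPa, nu = 0.40) with three strut
architectures:

| acronym | material  | architecture   | nominal porosity |
|---------|-----------|----------------|------------------|
| TC      | titanium  | octet truss    | 0.60             |
| TB      | titanium  | stochastic     | 0.80             |
| PB      | polyamide | octet truss    | 0.45             |
| PC      | polyamide | orthogonal grid| 0.35             |

The octet truss is generated as the FCC nearest-neighbour edge set (cell
corners plus face centers, all struts of length `a/sqrt(2)`), the only fully
triangulated space-filling interpretation of the design; the orthogonal
grid is a simple cubic edge lattice.  The stochastic network places points
by Poisson-disk sampling (`scipy.stats.qmc.PoissonDisk`; the minimum
distance is set from the point budget at a conservative 20% sphere-packing
fraction) and wires them to a mean degree of 4.5 +/- 0.1 by taking the
minimum spanning tree of the k-nearest-neighbour candidate graph (which
guarantees a single connected component) and adding the shortest remaining
candidate edges up to the target edge count.

Unit-cell sizes are repo conventions, not published values: 3 mm for the
polyamide octet and cubic cells, scaled by 1.3 for the titanium octet
(reflecting the metal-sintering feature-size constraint).  The stochastic
design's point density corresponds to ~5000 points in the implant cylinder.
Implants are blocks trimmed to the 16 mm x 15 mm cylinder; boundary-crossing
struts are clipped at the surface (press-fit realism), not dropped.

Strut radii are solved against the nominal porosity by bisection on the
voxel-measured porosity of the trimmed cylinder (50 um grid, |measured -
nominal| < 0.002).  When the voxel grid is commensurate with the unit cell,
whole symmetry orbits of voxels change state together and the attainable
porosity is quantized; the solver then returns the nearest attainable
radius and warns (residual always <= 0.005 for the four designs).  The
analytic porosity mode (summed clipped strut volumes with a coarse
spherical-cap junction correction) is a slender-strut approximation used
for bracketing and cross-checks; the voxel mode is authoritative.

## Apparent modulus and anisotropy

Each strut is a two-node 3D frame element with 6 DOF per node: axial,
torsional and biaxial bending stiffness of a solid circular section.
Bending uses the shear-flexible (Timoshenko) formulation by default, with
`phi = 12EI/(G A_s L^2)` and the circular-section shear correction
`kappa = 6(1+nu)/(7+6nu)`.  This matters: at nominal porosity 0.35 the
orthogonal grid's struts have slenderness L/r ~ 2.9, where the
Euler-Bernoulli element overstiffens the bending-dominated oblique loading
directions by roughly a factor of two and visibly distorts the anisotropy
ratio; `shear=False` recovers the classical element exactly (and is what
the closed-form cantilever check uses).

The apparent modulus for a loading direction is obtained from a
displacement-controlled compression test between rigid platens: nodes on
the two faces perpendicular to the load are constrained in the load
direction (one face displaced) with rotations fixed and lateral translation
free; a single node is pinned laterally to remove in-plane rigid modes;
components not bridging both faces are dropped (they carry no load), and a
specimen with no bridging path raises a singularity error.  The modulus is
`(reaction force / footprint area) / (displacement / span)` with the
footprint taken as the full cylinder cross-section, as in the physical
test.

The multidirectional sweep covers the unique hemisphere at 15 degree
increments of the polar and azimuthal angles (pole deduplicated, 145
directions).  Loading off-axis is realized by rigidly rotating the
untrimmed block so the direction maps onto z and re-trimming to the axial
test cylinder, which makes the result identical whether the lattice or the
load frame is rotated.  The anisotropy coefficient is max:min over the
sweep; the direction-averaged modulus weights each sample by the solid
angle of its polar band.

With these choices the PB octet reproduces both its published axial
apparent modulus (~220 MPa) and its anisotropy (~1.5), and the PC grid its
anisotropy (~5.3).  One published inconsistency is worth recording: a
uniform cubic grid at porosity 0.35 necessarily has an axial apparent
modulus near 0.37 x E_s ~ 700 MPa (the area fraction of axial struts), not
220 MPa; porosity, axial modulus and architecture cannot all three hold
simultaneously for PC.  The anisotropy ratio is scale-invariant and
unaffected; the published 220 MPa is still used as the regression
covariate, since that is the characterization the study's statistics used.

Crush testing to 50% strain is outside the linear solver's scope; the
hysteresis-loop modulus extraction (OLS slope of the unload-reload branch
between 20% and 70% of estimated yield, excluding the initial plastic toe)
is implemented against a synthetic stress-strain curve generator that
reproduces the test protocol's branch structure.

## Synthetic cohort: latent model

Twelve ewes (weights drawn from N(72.8, 5.7) kg truncated to [62, 85]),
each receiving two different scaffolds (fixture allocation, each design
used six times).  The latent ingrowth model is parameterized directly by
the study's printed effect structure:

* every defect receives the same injury-driven peripheral baseline
  B = 6.8 percentage points (pp) of pore volume;
* the more compliant scaffold of each pair (compliance order PC < PB < TB
  < TC, the PB/PC tie broken by anisotropy) additionally receives a
  strain-driven central gain d;
* strong responders (animals 1, 5-9, 11) have d = {13.8...14.2} pp, mean
  14.0; weak responders (2-4, 10, 12) have d = {3.8, 3.7, -0.5, 3.9, 4.1},
  mean 3.0, with the single negative pair on animal 4 (the one animal whose
  stiffer scaffold accrued more bone; its compliant leg simply gets a
  thinner rim, since central bone cannot be negative).

Latent totals therefore span 6.3-21.0 pp, matching the reported 7-21%
ingrowth range.  Optional Gaussian jitter on B and d (default off) is
available for sensitivity runs.  All values are pp of pore volume =
100 x bone / (defect volume x porosity), the same normalization the
quantification uses.

## Synthetic cohort: image formation

Phantoms are rendered at 100 um voxels by default (a desk-scale setting;
the acquisition range 27-136 um is accepted).  Gray levels follow the
radiographic ordering marrow (0.20) < polyamide = soft tissue (0.30) <
bone (0.70) << titanium (1.60, metal attenuation far above bone), in
arbitrary reconstruction units.  Titanium struts receive an additive
structureless beam-hardening halo (amplitude 0.30 decaying exponentially
with a 1-voxel length).  Partial volume is emulated by a Gaussian blur of
0.5 voxel and acquisition noise by additive Gaussian noise at 5% of the
bone-marrow contrast.

Bone is placed in two disjoint compartments with exact voxel budgets
(voxels are filled in priority order until the latent fraction is reached,
so the ground truth is exact by construction):

* the peripheral rim fills pore voxels round-robin over (slice, 0.5-degree
  angular sector) bins, outermost first, producing an angularly complete
  contact rim that dips inward around wall-crossing struts;
* central deposits fill randomly ordered pore-scale blocks (1.5 x 1.5 x
  3 mm, the long axis axial), core-outward within the final partial block.
  On polyamide the deposits seat directly on strut surfaces (the lamellar
  interlocking apposition seen histologically); on titanium all bone keeps
  a 0.3 mm fibrous-tissue clearance from the metal (woven bone and struts
  interdigitate without intimate contact).

Calibration note.  The blur width, the titanium gray level, the clearance
and the block size were calibrated jointly so that the full segmentation
chain recovers every cohort condition within 0.5 pp of its latent truth at
the default scale -- the generator's stated accuracy contract.  A 1-voxel
blur at 100 um cannot satisfy it: at porosity 0.45 the octet pore network
is an interstitial web with a median half-width of ~1.4 voxels, and any
deposit placed in it loses several pp to partial volume regardless of the
threshold.  The synthetic structures are therefore deliberately coarser
than real nascent bone imaged at 30 um: deposits are pore-scale blocks
rather than trabecular fine structure.  Passing tests consequently
demonstrate that the measurement chain is volume-faithful for structures it
can resolve, not that it would resolve real 30 um-scale woven bone at
100 um voxels.

Fluorescence sections are rendered as radial geometry at 5 um pixels: a
bright peripheral rim at the bone-implant interface, interior brightness
scaled by the central compartment, and a thin mineral-label band at a known
offset from the bone front (deposited 14 days before endpoint, hence
sitting deeper, toward the wall).  Default offsets are drawn uniformly from
[28, 42] um, i.e. true apposition rates of 2-3 um/day.

## Quantification

Two segmentation chains, as in the study:

* Polyamide (2 steps): the defect is delineated as the known 15 x 15 mm
  cylinder (purely geometric), then bone is labelled by a single global
  threshold inside it.  The default selector partitions the
  defect-restricted histogram into three classes (multi-Otsu: marrow,
  polymer at soft-tissue density, bone) and thresholds midway between the
  marrow class mean and the bone plateau (upper decile of the bone class).
  The midpoint of the flanking levels is the volume-conserving level under
  symmetric blur; the marrow mode is the relevant flank because deposits
  sit in marrow-filled pore space.  Plain Otsu and isodata are available
  but both collapse to the marrow/polymer gap on trimodal polyamide
  content.
* Titanium (3 steps): metal is labelled by value (threshold 1.0, midway
  between halo peak and metal level, so the full strut cross-section is
  captured) and dilated with the 3-voxel cube kernel; bone is then labelled
  by its local gray value on every second axial slice -- a voxel must
  exceed the metal-excluded local mean (15-voxel window) by 0.12, and
  surviving candidates are re-thresholded at the half-contrast level
  between the candidate-free local background and the candidate plateau --
  and the labels are interpolated to the skipped slices.  The smooth
  beam-hardening halo tracks its local mean and is rejected; bone stands
  above it.  Slice interpolation defaults to nearest-slice propagation,
  which is volume-unbiased; the classical level-set (signed-EDT average)
  shape interpolation is available but systematically shrinks thin
  cross-sections that shift between slices.

The ingrowth fraction is `100 x bone voxels / (defect voxels x porosity)`
with the nominal design porosity ("known by design"), used consistently on
both the truth and the measurement side.

Virtual sections are taken perpendicular to the implant axis at 2, 5, 8,
11 and 14 mm below the periosteal face (5 per sample, 120 per cohort).

## Regional scoring and MAR

The 0-4 rubric is operationalized with fixed cut points calibrated once
against the generator:

* interface: fraction of the defect circumference (360 one-degree bins,
  bins fully blocked by strut cross-sections excluded) where bone lies in
  the outermost pore tier (1.5 mm band); cuts at 1/6, 1/2 and 5/6 separate
  scores 0-3, and >= 80% occupancy of the outermost tier (engulfment)
  scores 4;
* interior: bone area fraction of the interior pore space with cuts at
  0.02, 0.08 and 0.20; components with half-thickness below 1.5 voxels are
  thin/reticulate (cap at 2), thicker deposits reach 3 at the same area,
  and 4 additionally requires bone within 1.5 mm of >= 90% of the pore
  space ("all discernible pores").

Known desk-scale artifact: the titanium fibrous clearance leaves genuinely
bone-free angular spans behind wall-crossing struts, so titanium interface
scores sit one rubric point below polyamide (2 vs 3) even though the
peripheral budget is identical.  The qualitative regional pattern the study
reports -- interface substantial and comparable everywhere, interior
strongly material-dependent -- is asserted in the tests at that
granularity (interface within one point across designs, interior separated
by >= 1.5 points between materials).

Three simulated raters report `truth + e`, `e in {-1, 0, +1}` with
P(+-1) = 0.1 each, clipped to the scale.  Images with an inter-rater range
above 1 are flagged and rescored (redraws around the running median) until
consensus; the consensus value is the three-rater mean.

MAR is measured per section as the distance from the label band
(intensity-weighted mean radius of band pixels) to the bone front (subpixel
50% crossing of the radial occupancy of the bone signal), divided by the
14-day interval.  Angular averaging makes the estimate accurate to well
under 0.1 um/day in the study regime; at offsets below the band width the
band merges with the front and the estimate degrades, which is outside the
2-3 um/day regime of interest.

## Statistics

The paired Wilcoxon signed-rank test is exact: zeros dropped, tied absolute
differences mid-ranked, and the two-sided p-value computed from the
conditional null distribution enumerated over all 2^n sign assignments
(n <= 20 guard; the study's n is 6).  Between-design comparisons with
incomplete within-animal co-occurrence are paired primarily by within-animal
pairs plus rank-ordered remainders; a pure rank pairing is computed
alongside and both are reported.  The six pairwise design tests are
reported unadjusted (a Holm flag exists in the report consumer's hands; the
study reported unadjusted values).

The stiffness-ingrowth association is OLS of fraction on log10(apparent
modulus) -- the designs are exponentially spaced in stiffness -- using the
published apparent moduli as covariate; slope, r^2 and the slope-t p-value
are reported.

Responder classification computes each animal's signed paired difference
(compliant minus stiffer) and splits the twelve differences with an exact
1D two-means (scan over sorted split points minimizing within-cluster SSE);
the upper cluster is "strong".  Group summaries (mean paired difference per
class, fraction range, per-design means) are carried at one decimal.

## Orchestration and reproducibility

All randomness derives from one master seed through a
`numpy.random.SeedSequence` hierarchy (cohort truth, per-sample phantoms,
raters, consensus redraws, fluorescence offsets), so any stage can be
reproduced in isolation and a re-run is bit-identical.  The file pipeline
writes phantoms and sections as compressed TIFF, tables as CSV, the report
as JSON, and a manifest with SHA-256 hashes of every artifact;
`verify_manifest` re-hashes a run directory and names the first corrupted
file.  Scaffold voxel models are design properties (fixed generator seed)
and are cached per process, mirroring the study's use of six replicas of
each manufactured design.

Problem sizes used throughout are desk-scale choices: 100 um phantom
voxels (50 um only for the porosity round-trip), five cohort seeds in the
acceptance script, a 23 mm sweep block containing the rotated implant
cylinder.  The acceptance script completes in roughly a quarter hour on a
single CPU.

## Limitations

* The generator encodes the study's summary effect structure, not its raw
  per-animal values (never published); per-animal scatter is therefore
  minimal by default and the pairwise Wilcoxon pattern depends on the
  invented allocation fixture, so printed per-pair p-values are not
  reproduction targets.
* Linear elasticity only: no yield, buckling or contact; the 50%-strain
  crush protocol is represented by the synthetic hysteresis curve
  generator.
* The stochastic lattice's local thickness grading is a uniform radius
  scale by default; spatially varying grading laws are left to the caller.
* A pin-jointed (truss-only) solver mode is not provided; the frame element
  with shear flexibility is the single mechanical model.
* Off-cohort operating points can exceed the 0.5 pp recovery contract
  (e.g. titanium phantoms loaded far above the cohort's central budgets
  lose ~1.5 pp to the clearance-web/slice-interpolation interaction).
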