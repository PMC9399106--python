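# Methods

## Scope and model chain

`alphafoci` models the measurement physics of γ-H2AX focus counting after
alpha-particle exposure of a cell monolayer: source-to-nucleus transport
and dosimetry, DSB induction along tracks, stochastic focus formation,
random-orientation 2D projection, focal-image analysis, and the overlap
correction. DSB repair kinetics, focus time evolution, microscope optics
(point-spread function, intensity thresholds) and cell-cycle variability
are deliberately out of scope; measurements are interpreted at the
~1 h post-irradiation peak where overlap is expected to match the
initially formed pattern.

## Irradiator geometry and dosimetry

The default configuration is a 9.5 mm diameter disc source 30 mm below
the 4 µm Mylar dish bottom (35 mm dish), emission lines 5.48 MeV (0.85)
and 5.44 MeV (0.13) renormalised over lines, an evacuated gap (air is a
config option; 30 mm of air removes ~2.9 MeV and is inconsistent with the
~100 keV/µm LET the model reproduces), and cells as 15 µm water spheres
resting on the Mylar with concentric 10 µm nuclei of density 1.0 g/cm³.

A nucleus subtends ~1e-8 of the emission sphere, so analog ray tracing is
useless at realistic emission counts. Hits are instead importance-sampled
exactly: the per-nucleus hit rate per decay is the solid-angle average
πr²/4πd² over source points (spheres present the same cross-section from
every direction), hit counts are Poisson, and each hit ray draws a source
point with probability ∝ 1/d² and an impact parameter uniform on the
nucleus cross-section (far-field parallel-ray approximation, error
O(µm/30 mm)). This construction is validated in the tests against a
brute-force ray tracer on an artificially enlarged nucleus.

Stopping powers for water, Mylar and air are embedded on a log-spaced
0.1–6 MeV grid with log-log interpolation. The water curve is an
ICRU-49-consistent construction (z²-scaled proton Bethe stopping with
I = 75 eV plus a Barkas-region correction, anchored to 87.7 keV/µm at
5.48 MeV); Mylar and air follow by Z/A and mean-excitation scaling.
Absolute accuracy is estimated at ±2–3%, adequate for the ~1 MeV of
slowing between source and nucleus. Transport integrates dE/dx with
midpoint steps limited to 1% fractional loss (tested within 1% of a ≤1 nm
fine-step oracle); the batched pipeline path uses a lockstep RK2 variant.

Dose bookkeeping follows the chord model: LET is evaluated in water at
the nucleus entry energy and held constant along the ≤10 µm chord,
`D = Σ LET·ℓ × 1.602e-16 J/keV / 5.236e-13 kg`. One mean-chord traversal
(100 keV/µm × 6.67 µm) deposits 0.2040 Gy, giving the closed-form hit
model: hits per nucleus ~ Poisson(4.90 per Gy of average nucleus dose).
The *reported average LET* is the mean entry LET over nucleus-hitting
tracks — i.e. after the oblique Mylar path and the intracellular water up
to the nucleus surface — which evaluates to ≈101 keV/µm; LET evaluated at
the Mylar exit alone would be ~5% lower and is not what the damage model
uses. Two run modes exist: an emission-driven mode that reports radial
dose profiles across the dish (edge nuclei see ~20% lower rates), and a
dose-driven mode keyed to the average nucleus dose that underlies all
foci statistics; the latter keeps the per-nucleus hit number exactly
Poisson, which is how hit-number distributions are tabulated.

## Damage chain

The nanometric track core is emulated parametrically: energy depositions
occur along each chord with linear density LET / ⟨E_event⟩
(default ⟨E_event⟩ = 45 eV, exponential), displaced transversely by an
isotropic 3 nm Gaussian, so total deposited energy matches LET × chord in
expectation and damage stays concentrated near the trajectory — the
feature responsible for focus overlap. No delta-ray tail is modelled; at
these energies the tail carries dose but contributes little to the
clustered damage that drives overlap statistics.

Depositions become SSBs with probability f_dna × p(E), where p rises
linearly from 0 at 5 eV to 1 at 37.5 eV; strand labels are fair coins
(duplex geometry is not modelled at base-pair resolution). DSBs are
DBSCAN clusters (ε = 3.3 nm interpreted as 3D Euclidean radius,
min 2 points) containing both strands, retained with probability p_f.
All SSBs of a nucleus (across its traversals) are clustered jointly; the
implementation packs many nuclei into one clustering call with a 0.1 mm
coordinate offset, which cannot bridge clusters and is exactly DBSCAN
for the default min_samples = 2 (ε-graph connected components).

f_dna = 0.15 and p_f = 0.20 are not observable from the model's inputs;
they were fixed once (`scripts/calibrate_damage_defaults.py`) so the
default chain yields ≈70 DSB/Gy per nucleus, in the range event-by-event
track-structure codes report for ~100 keV/µm alphas. Downstream results
are insensitive to the exact yield as long as DSBs comfortably outnumber
the 8 foci/Gy that are placed on them.

## Focus formation and sizes

Focus number per nucleus is Poisson with mean 8 × (its own dose in Gy) —
the minimal dispersion model consistent with a fitted mean yield; loci
are drawn uniformly without replacement from the nucleus' DSB centroids
(shortfalls are logged; at default yields they are rare). A focus is a
sphere whose equatorial section equals its sampled image area, making the
3D object and its 2D image consistent under arbitrary rotation.

Image areas follow a lognormal truncated to [0.205, 16.7] µm² (exact
inverse-CDF sampling). Because the source size histogram exists only as a
figure, the defaults (median 1.2 µm², geometric SD 3.0) were calibrated
once (`scripts/calibrate_size_distribution.py`) against the reported
dose-dependent statistics, weighting the overlap fractions (~30% at
0.05 Gy, ~40% at 1 Gy) and the dose-averaged correction factor (~1.8)
most heavily. Known limitation: no two-parameter lognormal simultaneously
reaches the reported absolute multiplicities of the largest size group
(3 → 6.5 from 0.05 to 1 Gy) while holding those statistics — the
calibrated model gives ≈2.5 → 4.6, reproducing the qualitative pattern
(multiplicity rising with size group and dose, roughly doubling in the
top group) but under-producing the deepest pileups. A heavier-bodied,
shorter-tailed size law (only graphically available) would be required.

## Projection and focal-image analysis

Each irradiated nucleus is rotated by a rotation drawn uniformly from
SO(3) — not uniform in Euler angles, which would pile viewing axes at the
poles — and foci are orthographically projected. Circles merge into a
focal image when centre distance < r₁ + r₂ (strict inequality: tangency,
a measure-zero event, is documented as non-overlap for determinism).
Union areas are exact for one or two discs (lens formula) and polygonal
(256-gon per circle, inscribed-area bias corrected, relative error well
below 1e-3) for more; a Monte Carlo rejection oracle checks them in the
tests. Multiplicity statistics use true member counts; a boundary
classification (`single_circle` when one member disc contains all others,
`multi_arc` otherwise) is emitted alongside, since a fully contained
focus is invisible to 2D microscopy. Size groups are nine half-open bins
whose anchored edges (0.205, 0.463, 0.823, 5.15, 16.7 µm²) are equally
spaced in equivalent-circle radius (step ≈ 0.128 µm); intermediate edges
continue that spacing. Out-of-range areas clamp to the end groups with a
warning (multi-focus unions can exceed 16.7 µm²).

## Correction equations

CF(D) = Σᵢ m(D; Aᵢ) · r(D; Aᵢ) over the nine groups, with m the simulated
mean multiplicity per group and r the observed image-share per group;
corrected foci per nucleus = CF × observed mean images per nucleus. With
self-consistent (simulated) ratios the weighted mean collapses exactly to
total foci / total images — an algebraic identity the tests assert to
machine precision. Empty simulated groups are *missing*, not zero;
correcting an observed table that populates a missing group fails loudly
rather than imputing. Observed doses must match simulated doses exactly
(no interpolation across dose).

## Randomness and determinism

All stages consume `numpy.random.Generator` streams. Pipeline substreams
are derived from the master seed keyed by (seed, dose value, stage), so
adding a dose to the list does not perturb the others; fixtures derive an
independent seed so round-trip tests never share randomness with the run
being corrected. The geometry-averaged dose per traversal is evaluated by
a fixed-seed Monte Carlo quadrature (40 000 samples) and cached, making
it a deterministic property of the configuration.

## Problem sizes

Default test and analysis scales were chosen for stable statistics on a
single CPU: the acceptance computation uses 20 000 nuclei at 0.05 Gy
(hits are rare there) and 4 000 per higher dose, giving overlap-fraction
uncertainties well under one percentage point; the shared test fixture
runs 350 nuclei per dose, and property-based suites use exhaustive
oracles on ≤25-point instances.
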