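# Methods

This note documents the models behind `tcmdose`, the defaults and why they
were chosen, and what the synthetic validation does and does not
demonstrate.

## Study design being emulated

The package reproduces, at desk scale, a within-patient comparison of two
chest-CT automatic exposure control strategies.  For each patient one
obtains a tube-current scheme `I(z, Θ)` (table position × gantry angle) for

* **ATCM** — attenuation-based modulation predicted from the localizer
  radiograph (topogram), and
* **OBTCM** — organ-based modulation that reduces current over the anterior
  120° sector,

runs Monte Carlo photon transport with the normalized scheme as per-history
weights, tallies breast and lung dose, normalizes each by the scan's 32-cm
CTDIvol, and reports the within-patient percent difference
`ΔnD = 100·(nD_OB − nD_AT)/nD_AT` (negative = dose saving).  Because the
original patients' image data, raw-projection modulation extractions and
vendor source models are not publicly available, the per-patient inputs here
are synthetic; the study's printed per-patient results are packaged as
reference tables and every derived statistic is recomputed from them.

## Synthetic thorax generator

`phantoms.generate_thorax_phantom` builds a supine thorax on a
(z, y, x) grid (anterior = −y, patient-left = +x), default 112×112 pixels of
0.5 cm and 1 cm slices:

* elliptical soft-tissue body (AP/LAT axis ratio 0.72, mild longitudinal
  taper), soft tissue ≈ 35 HU with seeded Gaussian texture;
* two posteriorly shifted lung ellipses at ≈ −750 HU;
* a posterior vertebral column at +700 HU;
* for female phantoms, two breast mounds (fat ≈ −80 HU) with glandular
  cores (≈ 30 HU) placed on the anterior surface.  The mound polar angle
  grows with `breast_lateral_offset` (≈ 20° + 9°/cm); at 0 cm the glandular
  mask sits fully inside the anterior ±60° sector, at ≈ 3 cm it straddles
  the sector edge — the anatomical situation reported for real supine
  patients, all of whom had some glandular tissue outside the reduced
  sector.

The lateral semi-axis is solved by bisection so the central-slice
water-equivalent diameter matches the requested target within 0.5 cm.  The
target range follows the study population (17.8–36.2 cm, means ≈ 24 cm),
and default comparisons use `target_dw = 24 cm`.  `D_w` uses the AAPM-220
convention `D_w = 2·sqrt(A_w/π)`, `A_w = Σ_ROI (HU/1000 + 1)·pixel_area`,
with the body-contour mask as ROI and slice `⌊N/2⌋` as the central slice.

What the generator does **not** emulate: realistic segmented anatomy
(ribs, mediastinum, arms), patient mis-centering, breast deformation
beyond a rigid lateral shift, or the HU textures of real reconstructions.
Passing tests therefore validate the *machinery* (modulation laws,
transport, normalization, statistics) and the *sign and mechanism* of the
organ-based trade-off — not the study's absolute per-patient dose values.

## HU → transport phantom

Fixed threshold table: air < −930 ≤ lung < −250 ≤ fat < −20 ≤ water < +20 ≤
muscle < +100 ≤ bone.  Density follows the linear ramp ρ = 1 + HU/1000,
snapped to 17 evenly spaced levels per family (air is pinned at
0.0012 g/cm³; bone is clipped to [1.10, 2.2] g/cm³).  The mapping is a pure,
monotone function of HU; HU 0 maps exactly to (water, 1.000 g/cm³).  The
known artifact of CT-number-based mapping — vertebral spongiosa falling into
soft-tissue families — is intentionally left uncorrected, matching clinical
voxelization practice.

## Topogram and ATCM prediction

The synthetic topogram is the scatter-free water-equivalent path length
`∫(μ/μ_water) dl` along parallel anterior–posterior and lateral rays, taking
the per-position maximum over rays, evaluated at 66 keV where the package's
water attenuation equals the conventional 0.2 cm⁻¹ used for 120 kVp
topogram calculations.

Longitudinal law: `A_max(i) = max(exp(μ_w·AP(i)), exp(μ_w·LAT(i)))`,
`mA(i) = QRM·pitch/t·(A_max/A_ref)^b` with b = 0.33 above the reference
attenuation and 0.5 below ("Average" strength), clamped to [20, 800] mA.
Protocol constants (QRM 140 effective mAs at 120 kVp — 269 at 100 kVp —
rotation time 0.5 s, pitch 0.6) are packaged per scanner in
`data/protocols.yaml`.

Three quantities of the vendor algorithm are not public and were fixed once
as package defaults, all configurable:

* **A_ref** = exp(μ_w·24 cm): anchors the quality-reference current to an
  average 24-cm adult, giving the exact anchor `mA = QRM·pitch/t = 168 mA`
  for a patient at the reference attenuation;
* **q** = 0.75 (documented only as lying in [0.5, 1.0]);
* **μ(i)** = 0.9, constant for the 0.5 s rotation (the rotation-time
  dependence is not published).

Angular weighting: the published description multiplies the longitudinal
current by an angular term whose floor is
`m(i) = 1 − μ(i)·(A_max^q − A(i−hROT)^q)/(A_max^q − A_min^q)` over the
previous half rotation of table travel (`hROT = collimation·pitch/2`); the
interpolation between floor and unity is not specified.  The package uses
`w(i,Θ) = m(i) + (1−m(i))·sin²Θ` — minimum at AP/PA, maximum laterally,
period π — the shape implied by elliptical patient attenuation.  Degenerate
windows (`A_max = A_min`) default to m = 1.

## Organ-based reduction

`apply_obtcm` scales the anterior sector (hard edges at ±60°, width
configurable) by r, default 0.25.  The vendor value is proprietary;
r = 0.25 sits between the anterior reductions reported by physical
measurements (17–52%) with the posterior compensation the technique
requires.  With `compensate=True` the posterior arc of each table position
is raised so that that rotation's mean current is preserved *exactly*; on
the discrete angle grid the sector edges are handled by cell-overlap
fractions, and for an angle-flat scheme the posterior factor reduces to the
closed form `c = (1 − f·r)/(1 − f)`, f = sector/360 (e.g. flat 100 mA →
anterior 25 mA, posterior 137.5 mA).  Whether the clinical implementation
preserves scanner output per patient is explicitly unknown, so compensation
is a flag, not an assumption.

## Source model

Filtered Kramers bremsstrahlung on a 1 keV grid (characteristic tungsten
lines omitted), hardened by aluminium filtration.  The half-value layer is
computed on an air-kerma weighting (energy fluence × μ_en/ρ of air) by
bisection to 10⁻³ mm, and the added filtration is itself bisected so the
HVL hits the protocol target (8.0 / 7.9 / 6.8 mm Al) within 0.05 mm.  Since
dose ratios, not absolute spectra, drive every reported quantity, beam
fidelity is asserted through the HVL alone.  The bowtie is a parametric
body profile, aluminium-equivalent thickness τ(φ) = τ₀·k·(sec φ − 1) with
defaults giving ≈ 0.35 transmission at the fan edge; it is symmetric and
energy-dependent but not vendor-exact — a documented limitation.

## Photon transport

Kerma-approximation Monte Carlo: photons only; secondary-electron energy is
deposited at the interaction site; histories end below 1 keV or on leaving
the grid.  Interactions: photoelectric absorption, incoherent scatter with
the exact integrated/differential Klein–Nishina law (incoherent scattering
function neglected), and coherent scatter (Thomson angular shape, on by
default, flag to disable for analytic tests).  Cross sections are
semi-empirical: photoelectric ∝ Z_eff^3.8/E³ and coherent ∝ Z_eff^2.5/E²
anchored to water at 30 keV, plus exact Klein–Nishina × electron density;
water's total attenuation lands within ~2% of accepted values over
30–120 keV, heavier materials (bone) are less accurate.  All analytic
oracles in the test suite (slab transmission, HVL closed forms) use the
same coefficient tables, so the validation is internally consistent; the
package does not claim benchmark-grade absolute cross sections.

Voxel traversal uses Woodcock (delta) tracking with an energy-indexed
majorant (per-material maximum μ over the densities present), unbiased in
expectation with respect to exact ray tracing.  Histories are emitted
uniformly along the helix `z(α) = start_z + pitch·collimation·α/2π`
(start angle 0 = anterior, seedable), with fan angle uniform across the fan
(bowtie transmission applied as a weight) and longitudinal aperture set by
the collimation.  Each history carries the scheme weight `I(z,Θ)/I_max` at
its emission point.  Tallies are per-voxel deposited energy accumulated in
independent batches; `estimate_uncertainty` reports the batch standard
error of any region sum.  The RNG is an explicit xorshift64* stream seeded
per batch, so runs are bit-reproducible.

Default problem sizes were chosen to keep a paired comparison around a few
seconds while holding organ-region standard errors near or below 2%:
2×10⁶ histories in 10 batches on a 16×96×96 phantom (the ≤1% regime of the
emulated study is a history-count flag away).

## Dosimetry conventions

* Organ dose = Σ E_v / Σ ρ_v·V_v over the mask (mass-weighted), in
  per-history units.
* Because history weights are `I/I_max` and the two schemes have different
  maxima, the pipeline multiplies each per-history dose by its scheme's
  `I_max`, putting both schemes on a common current-proportional scale; the
  subsequent CTDIvol division makes `nD` independent of the absolute MC
  calibration altogether, which is why no mAs-to-fluence constant is needed
  (or provided) for ΔnD.
* CTDIvol = (measured dose-index output per effective mAs, a protocol
  constant: 0.115 / 0.140 / 0.087 mGy/mAs) × scan-averaged per-rotation
  mAs/pitch.  The per-effective-mAs reading of the constants matches their
  quotation for a pitch-0.6 protocol; a flag switches to per-actual-mAs.
* Printed-table comparisons round half away from zero (the convention the
  printed pooled median requires).

## Statistics

Summaries use the sample (n−1) SD.  R² is the squared Pearson correlation.
The covariate-adjusted test of a mean contrast is OLS of ΔnD on a scanner
indicator and D_w, the intercept p-value being the adjusted test — one of
two defensible parameterizations, so printed regression p-values are not
asserted anywhere.  Tolerance intervals covering fraction p of a normal
population with confidence γ use one-sided non-central-t factors
`k = t'_{γ,n−1}(z_p√n)/√n` applied on both sides of the mean, matching
published one-sided k-factor tables to 3 decimals (1.926 at n = 20,
p = 0.90, γ = 0.95).  Proportion tests use the plain normal approximation
without continuity correction, which reproduces the printed p-values.  The
within/outside classification against a tolerance interval supports both a
magnitude and a signed convention because the printed counts cannot
disambiguate them; no multiple-testing correction is applied, and 0.05
(with 0.05–0.10 "trending") mirrors the reporting style of the emulated
analysis.

## Known limitations

* Anatomy is parametric, not patient-derived; absolute organ doses are in
  relative units by design.
* Vendor spectrum, bowtie, A_ref, q, μ(i) and the anterior reduction factor
  are proprietary; the package's defaults are physically anchored stand-ins
  and every one is configurable.
* Electron transport, bremsstrahlung, flying focal spot, heel effect and
  patient mis-centering are out of scope.
* The two reference tables disagree on one patient's ATCM CTDIvol (10.4 vs
  10.8 mGy) and the population block prints a female D_w SD (3.9) that the
  per-patient column contradicts (3.6); the package stores both readings
  and flags them rather than silently reconciling.
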