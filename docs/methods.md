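# Methods

This note records the physical models, calibrations and numerical
choices behind `protonct`, and what the simulated results do and do not
say about a real proton-CT instrument.

## Transport model

Each proton carries a water-equivalent range budget. The range–energy
relation is the Bragg–Kleeman power law calibrated to water,
R[cm] = 0.0022·E[MeV]^1.77, exactly invertible and within ~3% of
reference CSDA ranges over 30–250 MeV (the unit tests cross-check it
against a numerical integration of the Bethe stopping power). Transport
proceeds in 1 mm geometric steps; each step through material of relative
stopping power `rsp` consumes `rsp × step` of the budget. The material
occupancy of a step is sampled at a uniformly *jittered* point rather
than the midpoint: midpoint sampling deterministically skips material
slivers thinner than the step (the compensator's cube faces near the
cavity axis are ~0.1 mm thick), whereas jittering makes the consumed
WEPL unbiased at the cost of sub-mm per-step noise.

Stochastic components:

* **Multiple Coulomb scattering** — independent Highland kicks in the two
  transverse directions per material step,
  σ_θ = 13.6 MeV/(pv) · √(x/X₀) · (1 + 0.038 ln(x/X₀)), with the
  bracket clipped below at 0.25. Each material carries its physical
  radiation length.
* **Range straggling** — the budget is drawn once per proton as
  R₀(1 + 0.011·Z), Z standard normal, so the stopping-depth spread of a
  fully stopped beam is 1.1% of its range (σ_s = 0.011·R_tot) while a
  vacuum flight leaves the energy bookkeeping exact.
* **Nuclear attenuation** — removal with probability 0.001 per mm of
  water-equivalent depth (≈1%/cm), both in the object and per telescope
  layer. Secondaries are not simulated.

Not modelled: energy-loss fluctuation shapes beyond the Gaussian budget,
charge sharing between strips, detector noise hits, the tracker's own
silicon WET (150 µm per plane; a low-material-budget design), and beam
optics (the beam is a parallel uniform disk).

## Geometry and scan

Coordinates are right-handed, lengths in mm, beam along +z, phantom
centre at the origin, rotation stage about +y. The default object is a
75 mm PMMA sphere (RSP 1.16, configurable) with three vertical 15 mm
cylindrical inserts, 120° apart at 18 mm radius (water-equivalent 1.00
top-left, adipose 0.95 top-right, average bone 1.21 bottom — the layout
is this package's choice; only the insert set, not their coordinates, is
fixed by the instrument description). The compensator is
a 75 mm PMMA cube minus a 75 mm sphere, centred on the beam axis
upstream of the proximal tracker (cube centre at z = −232.5); it does
not rotate with the phantom. For parallel rays inside the silhouette,
cavity chord + body chord = 75 mm exactly, which is what flattens the
residual range.

The desk-scale scan is 90 projections over 360° of 2·10⁴ protons each
(1.8·10⁶ histories per scan), reconstructed on a 128×128 grid of 1 mm
voxels — scaled down from a clinical-style scan of ~3·10⁸ histories so a
full run takes about two minutes on one core. Frames are single
occupancy by default: at desk-scale fluence the instantaneous rate is
far below the 2·10⁸ protons/s design budget (~7.7 protons per 26 MHz
frame); multi-occupancy reconstruction is exercised by dedicated tests
through the same object-level code path.

## Detectors

Tracker stations hold three 2048-strip planes (90.8 µm pitch) at axis
angles 0/60/120°, stations at z = −180, −120, +120, +180 mm with 2 mm
plane gaps (inter-plane distances are free design parameters here; the
gap is kept small because lateral track motion across the gaps enters
the triple-coincidence residual). Digitization is half-open binning of
the projected coordinate with 99% Bernoulli efficiency; two protons on
one strip in one frame collapse to a single fired strip with the
high-threshold (double-hit) flag.

Note one internal inconsistency of the instrument description that the
config carries verbatim: 2048 strips × 90.8 µm is 186 mm, not the
quoted ~93 mm active width; the strip count and pitch are authoritative
here. Similarly the telescope stores both the per-layer WET (2.6 mm,
21 layers = 54.6 mm) and the separately quoted 55.4 mm overall WET; the
calibration is anchored to the per-layer value.

## Event reconstruction

A virtual pixel requires strips in all three planes of a station with
|m₀ − m₆₀ + m₁₂₀| below tolerance; candidates are assigned greedily by
smallest residual, each strip used once, lower strip index breaking
ties. The object-level default tolerance is 1.5× pitch (the worst-case
digitization error of three co-located planes); the scan stream uses
0.6 mm to absorb track motion across the finite plane gaps at
post-phantom scattering angles. Entry/exit vectors connect the two
station points of a side; upstream/downstream matching is
nearest-neighbour at the phantom mid-plane with a 5 mm gate.

Range-telescope track following seeds on first-layer hits and extends
layer by layer, accepting the nearest unused hit within a displacement
window of 2 mm + 0.5 mm per layer (the widening follows the growing
scattering cone). A single missing layer is bridged (`max_gap = 1`):
with 99% per-layer efficiency, ending tracks at the first gap would
truncate ~10% of them one layer early and bias the range scale; a track
ends after two consecutive misses. Tracks reaching the last layer are
punch-through and vetoed; tracks must start at layer 0.

## WEPL calibration

No-phantom runs with ideal degraders of 59–111 mm WET in 1 mm steps
(residual energies spanning roughly 30–80 MeV) map each setting's known
residual range R(E₀) − w to its modal stopping layer. Settings whose
mode is a veto layer are skipped — their stopping distribution is
truncated and would mis-anchor the end of the table. Averaging the
residual ranges of the ~2.6 settings sharing each mode approximates the
layer-centre residual without systematic offset; monotone interpolation
fills all 21 layers and WET-per-layer extrapolation the unobserved ends.
A proton's total upstream WEPL is then R(E₀) − residual(last layer).

The analytic uncertainty budget combines straggling and layer
quantization in quadrature: σ_r = √((0.011 R_tot)² + (WET/√12)²), which
is 1.5 mm (1.3% of range) for a 125 MeV beam on 2.6 mm layers. The
measured stopping-layer spread reproduces it within 15% once nuclear
truncation (handled downstream by the data-quality gate) is excluded.

## Compensator flat-field and data-quality gate

Subtracting the compensator's WEPL by ray tracing the measured entry ray
is biased: scattering *inside* the compensator bends the path, the
cavity profile is convex, and selections downstream correlate with the
in-compensator trajectory. The package instead builds a Monte Carlo
flat-field: the conditional mean and spread of the true compensator WEPL
given the measured entry ray, binned by the ray's radius and radial
slope at the compensator plane. Because the measured ray is the exact
downstream asymptote, conditioning on both coordinates makes the
subtraction error independent of everything that happens in the phantom.
(A real instrument would measure this map with compensator-only runs or
compute it from its own Monte Carlo model.)

Events pass a WEPL quality gate around the per-ray expectation
(flat-field + nominal body RSP × hull chord). The window is asymmetric:
wide below (genuine low-RSP inserts only lower the total WEPL) and tight
above (+5 mm: nuclear truncation and a missed last layer only raise the
apparent WEPL, in 2.6 mm quanta), widening with the per-radius flat-field
spread so the noisy cavity-rim rays are not clipped. A symmetric cut
would bias insert ROIs by clipping their genuine WEPL deficit.

## BPF reconstruction

The transverse slice is reconstructed from events whose mid-plane
position lies in a |y| ≤ 10 mm slab (the inserts are vertical cylinders,
so the geometry is y-invariant there). Each event contributes its
phantom-only WEPL along an estimated path: a cubic Hermite spline
between the hull piercing points of the measured entry and exit rays
(tangents = measured directions), continued outside the hull along the
straight chord line — the chord's impact parameter is the offset the
WEPL corresponds to, so chord-line extensions keep the sinogram
geometrically consistent near the hull-tangent edge. Chords missing the
known spherical hull are excluded (their phantom line integral is zero)
and the missing angular coverage outside the silhouette is restored
analytically.

Two backprojection accumulators exist: the per-unit-length normalized
image (mean RSP along crossing paths — an unfiltered preview, exactly 1
in uniform water) and the length-weighted mean-WEPL image B, which with
uniform angular coverage is the classical unfiltered backprojection
B = (1/π)·f ∗ 1/|r|. Events are reweighted by the inverse of the pooled
impact-parameter density before accumulation: upstream scattering
redistributes fluence across offsets (the compensator rim depletes the
near-tangent band by a factor ~2–3), and an unflattened B mixes angles
with the wrong weights, which showed up as a ~5% scale error.

The filter divides B's 2-D spectrum by the spectrum of the sampled
1/|r| kernel (self-value = the exact voxel mean 4 ln(1+√2)/Δ) with a
radial Hann window at Nyquist. Because the 1/|r| tail decays slowly,
B is accumulated on a grid 1.5× the requested extent, completed beyond
the measured field by its fitted multipole tail (B ≈ (M/πρ)(1 + c/ρ²)),
and the arbitrary zero-frequency offset is fixed by zeroing the mean of
a known-vacuum ring outside the hull. The whole stage is validated
against an analytically blurred disk (RMSE < 5% inside) and truth-event
scans of a uniform water sphere (interior 1.00 ± 0.05).

## Evaluation

Insert ROIs are 4 mm disks (~50 voxels of 1 mm) at the known insert
centres; accuracy is the signed relative error of the ROI mean against
the nominal insert RSP. The per-stage counters satisfy an exact ledger:
generated = nuclear_lost + stopped_in_phantom + punch_through +
unreconstructed + wepl_rejected + imaged. Runs are bytewise
reproducible for a fixed seed (a single `SeedSequence` spawns every
stage's generator).

## What passing tests do and do not show

The generator reproduces the *designed* behaviour of a proton-counting
scanner: CSDA-scale ranges, Highland-scale scattering, 1.1%-of-range
straggling, binomial detector efficiency and Poisson-free uniform beams.
Real instruments add effects deliberately out of scope here — beam
energy spread and halo, strip charge sharing and noise, sensor
misalignment, nuclear secondaries, data-driven hull estimation — so the
sub-percent RSP accuracies achieved on simulated data bound the
*algorithmic* error of the chain, not the accuracy of any physical
device. The DAQ figures are configuration arithmetic, including the
4 Gb/s inconsistency between the quoted subsystem and combined rates,
which is reported but not resolved.
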