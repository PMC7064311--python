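# Methods

This note records the modeling choices behind `rdspeech`: the assumptions
of each stage, the parameters that matter and their defaults, what the
built-in stand-ins emulate, and the places where the design was genuinely
open and a choice had to be made.

## Tract geometry

The tract is `N_x = 44` uniform cylindrical tubelets of identical length
`L = c / (2 F_s)` (0.396825 cm at `c = 35 000 cm/s`, `F_s = 44 100 Hz`;
17.46 cm total).  Coupling `L` to the audio rate is what lets the
time-domain lattice treat one section as one one-way half-sample of travel.
Sections are indexed 1…44 from glottis to lips; a section's "distance" is
its lip-side edge.  Geometry permits zero areas (occlusions); the
frequency-domain solver rejects them and callers floor areas instead (see
below), while the time-domain synthesizer treats them as closed junctions.

**Neutral tract stand-in.**  The published adult-male neutral area function
is not tabulated in this repository, so `neutral_tract_standin` builds a
deterministic PCHIP spline through twelve control points chosen to be
anatomically plausible for an adult male schwa: a narrow laryngeal inlet
(0.40–0.90 cm²), a wide pharynx (≈2.9 cm² around 6–9 cm from the glottis)
and a mild oral taper to ≈1.1 cm² at the lips.  With default losses and the
branch its resonances are ≈502/1522/2416 Hz — a plausible schwa, but *not*
the published 596/1401/2331 Hz, which require the published table (loadable
via `read_area_table`).  Every numerical claim in the test suite that would
depend on the exact published tract is therefore formulated against
closed-form oracles (uniform-tube quarter-wave resonances) or as
qualitative/sign properties of the stand-in.

**Piriform side branch.**  Only the attachment point (2.4 cm above the
glottis) is specified by the model; the default branch is eight sections of
main-grid length tapering 1.2 → 0.25 cm² with a closed far end — roughly
2 cm³, a plausible combined piriform volume — and is fully replaceable.  It
perturbs the stand-in's resonances by < 10% (largest effect on f_R2), which
is the intended order of magnitude for piriform coupling.

## Frequency-domain acoustics

Each tubelet is a segment of lossy transmission line: series impedance
`z = R_v + jωρ/A`, shunt admittance `y = G_t + jωA/(ρc²) + y_w` per unit
length, cascaded as ABCD (chain) matrices with
`γ = sqrt(zy)`, `Z_c = sqrt(z/y)`.  Loss defaults (cgs, all configurable in
`LossConfig`):

* viscous surface loss `R_v = (S/A²)·sqrt(ωρμ/2)` with μ = 1.86e-4 dyn·s/cm²;
* heat-conduction loss `G_t = S(η−1)/(ρc²)·sqrt(λω/(2 c_p ρ))`
  (η = 1.4, λ = 2.3e3 erg/(cm·s·K), c_p = 1.005e7 erg/(g·K));
* yielding walls as a per-unit-wall-area series RLC shunt branch:
  resistance 1600 dyn·s/cm³, mass 1.5 g/cm², stiffness 3e5 dyn/cm³
  (standard soft-tissue values);
* lip radiation as the piston-in-baffle parallel pair
  `R_r = 128ρc/(9π²A)`, `L_r = 8ρa/(3πA)`, `a = sqrt(A/π)`.

The glottal end is an ideal flow source (closed-end approximation), so the
reported transfer function is lip flow over glottal flow — its peaks define
the resonances.  `lossless=True` zeroes every loss and replaces the
radiation load by an ideal open end, which is the configuration the
quarter-wave closed-form oracle `f_k = (2k−1)c/(4·17.46 cm)` =
501.1/1503.4/2505.7 Hz applies to; the implementation reproduces these to
≲0.05%.

**Peak picking.**  The default grid is 50–5000 Hz at 10 Hz; peaks are
refined parabolically on the dB grid (`find_resonances`), and the
convenience wrapper `resonances` additionally polishes each peak by bounded
maximization of the continuous |H(f)| to ≈1e-4 Hz.  That precision is not
cosmetic: the first-order perturbation oracle compares resonance shifts of
order 0.1 Hz, far below the grid spacing.  Merged peaks resolve to the
lower-frequency maximum by construction (first `n` peaks are taken).

**Modal distributions** are the per-section midpoint pressures and flows of
the cascade driven at a resonance frequency.  The normalization is
arbitrary; the sensitivity ratio cancels it (property-tested).

## Sensitivity functions and their adjustment

Per-tubelet modal energies use the standard acoustic forms
`Ke = (ρL/2A)|u|²` and `Pe = (AL/2ρc²)|p|²`.  The sensitivity of resonance
j to a fractional area change of section i is
`S_j(i) = (Ke_j − Pe_j) / Σ(Ke_j + Pe_j)`, and
`Δf_Rj/f_Rj = Σ_i S_j(i)·ΔA(i)/A(i)` to first order.  For the lossless
uniform tube the prediction matches brute-force recomputation to ≈3% for 1%
single-section perturbations; with losses and the branch the energy-based
first-order form is an approximation and agreement is held to the absolute
near-zero tolerance (0.1 percentage points) instead.

The balancing adjustment stores polarities `Q(i)`, low-pass filters
`|S_j|` along the *section axis* (second-order Butterworth, normalized
cutoff 0.1 of the spatial Nyquist) into `R(i)`, forms the bounding trend
`Ro = R + max(|S_j| − R)`, detrends, re-signs and normalizes to unit peak.
Two conventions were open and are fixed here: the filter is applied
**zero-phase** (forward–backward, reflect-padded by three filter lengths)
so the magnitude trend is not spatially shifted — a causal pass would bias
constriction locations toward the lips — and "normalized cutoff 0.1" is
read in the usual signal-processing sense, as a fraction of Nyquist.

## Events and scripts

Event timing is authored in seconds and converted to frames at
`f_svt = 146 Hz` by nearest-integer rounding, so the Gaussian attains
exactly 1.0 at its peak frame — which is what lets `μ = 1` produce an exact
zero-area section.  A hold of duration `t_h` inserts a unit plateau
**centered** on the peak (the least-committal reading; the alternative
leading/trailing placements are one function away).  The neutral vowel is
the absence of events.  Scripts are JSON (schema-checked on read) and the
two demonstration sentences ship both as builders (`rdspeech.fixtures`) and
as packaged JSON.  Fixture values that are editorial rather than published
are marked in `fixtures.py`: vowel μ (0.5; {ih} 0.6), stop μ (1.0; {d} 1.1),
and the RDPs of vowels other than {ao}.  Where two vowels with opposing
deflections overlap heavily ({aa}–{ih}), coefficients were balanced so each
event's specified signs are realized at its own peak — utterances for this
model are hand-adjusted in exactly this way.

## Deformation and sequencing

`D(i) = 1 − μE·y(i)/min(y)`, clipped at zero.  The reconstruction with the
explicit neutral offset (the "1 −" term) is adopted because it satisfies
every stated behavior simultaneously: identity at `E = 0`, exact closure at
the argmin of y when `μE = 1`, spreading closure for `μ > 1` (the clip
boundary defines the spread), and `D > 1` expansion where `y > 0`.  Note a
closure at the lip edge (bilabial patterns) cannot spread inward as far as
an interior (alveolar/velar) closure at equal overdrive, because the spread
region is truncated at the tract end.

The sequencing loop applies, per frame, all events with `E(n) ≥ 1e-3`
(Gaussians never reach zero; the threshold bounds work and alters areas by
< 0.1% of the deformation range) in ascending μ, ties broken by ascending
t_p then script order.  Sensitivities are recomputed from the working tract
before **every** application — the full feedback reading of the sequencing
rule; a `fast=True` mode reuses the neutral tract's sensitivities for each
frame's first event.  When an intermediate working tract is occluded, its
areas are floored at 0.01 cm² *for the acoustics only*; the geometry keeps
true zeros.  The floor value matters little: it only shapes the sensitivity
functions of already-extreme tracts.

## Time-domain synthesis

Kelly–Lochbaum pressure-wave scattering with reflection coefficients
`r_i = (A_i − A_{i+1})/(A_i + A_{i+1})`, run at an internal rate of 2·F_s
(each tubelet = one one-way sample at 88.2 kHz) and decimated by
pair-averaging.  Area frames are linearly interpolated to the internal
rate.  Sections below 0.001 cm² act as closed junctions through the
scattering arithmetic itself (areas are floored at 1e-6 cm², driving
`r → ±1`); closure and release transients emerge from the lattice state.
The lip end uses a first-order digital reflectance obtained by bilinear
transform of the same radiation load as the frequency-domain model; the
output tap is lip volume velocity, the quantity whose transfer function
defines the resonances.  Interior losses are a per-section damping factor
(default 0.998 per half-sample): this reproduces realistic formant
bandwidths but **not** the F1 upshift of yielding walls, so audio-level
checks compare against the frequency-domain model with rigid walls.  The
lossless lattice rings an impulse at the quarter-wave frequencies to within
1%, cross-validating the two acoustic implementations.

**Voice source.**  A raised-cosine glottal-flow pulse train (peak 350
cm³/s, open quotient 0.6) follows a piecewise-linear F0 contour; abduction
intervals ramp the pulses off over 16 ms and open a steady 200 cm³/s leak
through 0.1 cm².  Any other generator can be injected via
`flow_generator`.  This deliberately replaces a kinematic vocal-fold model
with the simplest source that supports the needed gestures (F0 movement,
devoicing, aspiration); glottal-level realism is out of scope.

**Turbulence noise.**  Uniform noise in [−0.5, 0.5], band-passed 500–2500
Hz (second-order Butterworth), scaled by `(Re² − Re_c²)·1e-6` above the
critical Reynolds number `Re_c = 1200`, zero below.  Reynolds numbers use
ρ = 1.14e-3 g/cm³, kinematic viscosity 0.15 cm²/s and the
circular-equivalent hydraulic diameter.  Glottal noise is added to the
glottal flow (computable in advance — the source does not depend on the
lattice).  Supraglottal noise is injected one junction downstream of the
most constricted *open* section when its Re exceeds threshold; only that
single site injects per sample.  Two stabilizers keep the acoustic-flow
estimate of Re physical: the constriction flow is smoothed by a one-pole
low-pass (≈150 Hz) before entering the gate — otherwise the injected noise
itself feeds back into Re and diverges — and Re is capped at 8000.
Closed sections generate no noise (they carry no mean flow), so stop
closures are silent until release.  All noise is seeded; synthesis is
bit-reproducible for a fixed seed.

## Analysis tracks

Resonance tracks are computed from the **area function**, frame by frame
(never from the audio): frames with minimum area below 0.05 cm² are marked
as gaps ("fully occluded or nearly so" has no published numeric criterion;
0.05 cm² is configurable), other frames are analyzed with the 0.01 cm²
floor.  The vowels-only variant zeroes μ for consonants, identified by the
per-event tag the fixtures carry or by a μ ≥ 0.9 heuristic for untagged
scripts ({r} at μ = 0.8 is why the explicit tag exists).  Deflection
verdicts compare two track sets at the last frame at or before the event
peak that is gap-free in both — occluded peaks have no defined resonances,
and this is the closest realizable probe of the event's effect.

## Problem sizes and determinism

The shipped analyses run at the model's native sizes: 44 sections, 239
frames per 1.64 s sentence, 10 Hz frequency grids, 44.1 kHz audio.  The
full deflection-direction suite (two sentences × two renderings with full
per-event sensitivity recomputation, plus tracking) takes on the order of a
minute on one core; a single sentence synthesis a few seconds.  Everything
downstream of the (seeded) noise generators is deterministic, and a run's
manifest (seed + configuration + versions) reproduces its outputs
bit-exactly.

## Known limitations

* The stand-in neutral tract is plausible, not published; absolute
  resonance values differ from the published neutral configuration.
* First-order sensitivity prediction degrades for lossy/branched tracts
  and for perturbations near the radiation-loaded lip end.
* The waveguide does not model wall vibration (F1 upshift) or the side
  branch in the time domain; the branch exists only in the
  frequency-domain analysis path.
* The glottal source is kinematic-free and has no pressure-flow
  interaction with the tract beyond the fixed source coupling; voice
  quality is serviceable, not realistic.
* No nasal tract, no tract-length perturbations, no inverse modeling
  (recovering deflection patterns from observed area functions).
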