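# rdspeech

Sentence-level speech synthesis in which an utterance is planned **entirely
in acoustic terms**: as a timeline of discrete events, each specifying only
the *direction* in which the first three vocal tract resonances should be
deflected relative to whatever the tract is currently doing.  The package is
aimed at speech-production researchers who want to experiment with
relative-acoustic utterance planning — no articulators, no constriction
locations: the model itself discovers where to constrict or expand the
tract.

## The model

The vocal tract is a chain of `N_x = 44` tubelets of length
`L = c / (2 F_s) = 0.396825 cm` (`c = 35 000 cm/s`, `F_s = 44 100 Hz`;
17.46 cm overall).  The time-varying area function is the product of a
neutral configuration and a deformation function,

```
A(i, n) = Ω(i) · D(i, n)
```

Each event carries a *resonance deflection pattern* `(δ1, δ2, δ3)`,
δj ∈ [−1, 1], a constriction degree `μ`, and a Gaussian event function

```
E(n) = exp(−ln 16 · ((n − N_p) / N_w)²)
```

(peak frame `N_p`, full width at half maximum `N_w`, frame rate
`f_svt = 146 Hz`, optional hold at peak).  For the running tract the model
computes acoustic **sensitivity functions** from the kinetic/potential
energy distributions of each resonant mode,

```
S_j(i) = (Ke_j(i) − Pe_j(i)) / Σ_i (Ke_j(i) + Pe_j(i)),
Δf_Rj / f_Rj = Σ_i S_j(i) · ΔA(i) / A(i),
```

balances them along the tract into `Z_j(i)`, combines them with the event's
weights, `y(i) = δ1 Z1 + δ2 Z2 + δ3 Z3`, and deforms the tract by

```
D(i) = 1 − μ E(n) · y(i) / min_i y(i)     (clipped at 0)
```

so that `μE = 1` closes the tract exactly at the minimum of `y`, `μ > 1`
spreads the closure, and regions with `y > 0` expand synergistically.
Overlapping events are applied per frame in ascending order of `μ`, each on
the tract the previous ones produced — coarticulation falls out of the
arithmetic.  A transmission-line model (yielding walls, viscous and thermal
losses, lip radiation, piriform side branch) supplies resonances and modal
distributions; a Kelly–Lochbaum waveguide with a parameterized glottal
source and Reynolds-gated turbulence noise renders the audio.

## Worked example

```
$ rdspeech sensitivity --out sens_demo
resonances: [502.0, 1522.2, 2416.1] Hz -> sens_demo
```

Those are the first three resonances of the built-in neutral (schwa-like)
tract with losses and the piriform branch — the reference lines every
deflection is measured against.  (The published adult-male neutral tract is
not tabulated here; supply your own table with `--tract` to reproduce its
596/1401/2331 Hz.)  `sens_demo/` also receives the frequency response and
the raw/adjusted sensitivity functions per section.

```
$ rdspeech fixtures --out fx
wrote fx/sentence1.json, fx/sentence2.json
$ rdspeech synth --script fx/sentence1.json --out s1_demo --seed 1
wrote 5 output sets to s1_demo (1.640 s of audio)
```

`fx/sentence1.json` is the nine-event script for "a dog ate a bug"
(`d ao g eh ih t b ah g`, plus two neutral vowels expressed by the absence
of events).  The run writes `audio.wav` (16-bit, 44.1 kHz), the tract movie
`tract_movie.tsv`, per-sample diagnostics, a reproducibility manifest, and
three resonance-track tables.  The first rows of
`s1_demo/tracks_all_events.tsv`:

```
# time_s  fR1_Hz   fR2_Hz    fR3_Hz    gap  variant
0.006849  500.505  1526.869  2422.729  0    all_events
0.013699  499.790  1528.939  2427.032  0    all_events
```

`gap = 1` rows mark frames where the tract is fully occluded (the stop
closures); comparing `tracks_all_events.tsv` against `tracks_vowels_only.tsv`
and `tracks_neutral.tsv` shows each consonant's deflections riding on the
vowel context — e.g. the {t} of "ate" pushes `f_R2`/`f_R3` above the
already-raised diphthong values.

## Layout

| module | role |
| --- | --- |
| `rdspeech.geometry` | tubelet grids, area functions, neutral stand-in, side branch, table I/O |
| `rdspeech.acoustics` | transmission-line frequency response, resonances, modal distributions |
| `rdspeech.sensitivity` | sensitivity functions, first-order shift prediction, balancing adjustment |
| `rdspeech.events` | RDPs, event functions, utterance scripts (JSON I/O) |
| `rdspeech.deformation` | deformation frames, multi-event sequencing, tract movies |
| `rdspeech.synthesis` | waveguide synthesis, glottal source, turbulence noise, WAV I/O |
| `rdspeech.tracks` | resonance tracks, vowels-only variant, deflection verdicts, spectrograms |
| `rdspeech.cli` | `rdspeech synth / sensitivity / tracks / fixtures / validate` |

See `docs/methods.md` for modeling details, parameter defaults and known
limitations.
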