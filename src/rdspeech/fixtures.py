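"""Built-in utterance scripts for the two demonstration sentences.

The timing parameters (t_p, t_w, t_h) of every event in "a dog ate a bug"
and "a frog ate a fly" are the published ones.  Deflection patterns use the
canonical consonant-class RDPs (bilabial/alveolar/velar), the stated liquid
and fricative values ({r}: (-0.3, 0, -1), mu 0.8; {l}: (-0.3, 0, +1),
mu 0.9; {f}: first two resonances down, mu 0.98), and the stated {ao}
directions (first resonance up, second down, third unspecified).

Values not published anywhere are editorial choices of this package and are
marked below: vowel constriction degrees (mu = 0.5, consistent with
"less than 1.0"), stop mu = 1.0 except {d} = 1.1, and the RDP signs of the
remaining vowels, chosen from each vowel's usual first/second-formant
position relative to a neutral schwa ({eh}/{ih} front: first resonance
down, second and third up; {ah} low: first up, second down).  Where two
vowels with opposing deflections overlap heavily ({aa}-{ih} in "fly"), the
coefficients and constriction degrees are balanced so each event's
specified deflections dominate at its own peak — the same hand-adjustment
of event values any utterance authored for this model goes through.

The unstressed {ax} vowels of both sentences are not events: they are the
neutral tract, expressed wherever no event is active.
"""

from __future__ import annotations

from pathlib import Path

from .events import RDP, Event, UtteranceScript, builtin_rdp, write_script

__all__ = [
    "sentence1",
    "sentence2",
    "make_fixtures",
    "SENTENCE_DURATION",
    "symbol_rdp",
    "symbol_mu",
]

#: total utterance duration, s (both sentences)
SENTENCE_DURATION = 1.64

# (rdp, mu, consonant) per ARPAbet symbol used by the fixtures
_SYMBOLS: dict[str, tuple[RDP, float, bool]] = {
    "d": (builtin_rdp("alveolar"), 1.1, True),
    "t": (builtin_rdp("alveolar"), 1.0, True),
    "g": (builtin_rdp("velar"), 1.0, True),
    "b": (builtin_rdp("bilabial"), 1.0, True),
    "f": (RDP(-1.0, -1.0, 0.0), 0.98, True),
    "r": (RDP(-0.3, 0.0, -1.0), 0.8, True),
    "l": (RDP(-0.3, 0.0, 1.0), 0.9, True),
    # vowels (mu and non-{ao} RDPs editorial, see module docstring)
    "ao": (RDP(1.0, -1.0, 0.0), 0.5, False),
    "eh": (RDP(-1.0, 1.0, 1.0), 0.5, False),
    # {ih} slightly stronger than the other vowels so that its deflections
    # dominate at its own peak where it overlaps an opposing vowel ({aa})
    "ih": (RDP(-1.0, 1.0, 1.0), 0.6, False),
    "ah": (RDP(1.0, -1.0, 0.0), 0.5, False),
    # {aa}'s second/third deflections left unspecified: it overlaps the
    # final {ih} symmetrically, and only its low-vowel first-resonance raise
    # is essential to the diphthong
    "aa": (RDP(1.0, 0.0, 0.0), 0.5, False),
}


def symbol_rdp(symbol: str) -> RDP:
    return _SYMBOLS[symbol][0]


def symbol_mu(symbol: str) -> float:
    return _SYMBOLS[symbol][1]


def _event(symbol: str, t_p: float, t_w: float, t_h: float = 0.0) -> Event:
    rdp, mu, cons = _SYMBOLS[symbol]
    return Event(symbol, rdp, mu, t_p, t_w, t_h, consonant=cons)


def sentence1() -> UtteranceScript:
    """"a dog ate a bug": nine events (vowels and stop consonants)."""
    events = [
        _event("d", 0.14, 0.10),
        _event("ao", 0.34, 0.21),
        _event("g", 0.55, 0.14, 0.03),
        _event("eh", 0.79, 0.21),
        _event("ih", 0.86, 0.21),
        _event("t", 0.92, 0.10),
        _event("b", 1.13, 0.07, 0.03),
        _event("ah", 1.27, 0.24),
        _event("g", 1.47, 0.14, 0.01),
    ]
    return UtteranceScript(
        events=events,
        duration=SENTENCE_DURATION,
        f0_contour=[(0.0, 104.0), (0.55, 126.0), (1.05, 116.0), (1.64, 92.0)],
        abduction_intervals=[(0.85, 1.01)],  # devoice the {t}
    )


def sentence2() -> UtteranceScript:
    """"a frog ate a fly": eleven events incl. fricative-liquid clusters."""
    events = [
        _event("f", 0.10, 0.10, 0.03),
        _event("r", 0.21, 0.10, 0.03),
        _event("ao", 0.34, 0.17),
        _event("g", 0.58, 0.14, 0.03),
        _event("eh", 0.79, 0.21),
        _event("ih", 0.86, 0.21),
        _event("t", 0.92, 0.10),
        _event("f", 1.13, 0.10, 0.03),
        _event("l", 1.23, 0.10),
        _event("aa", 1.37, 0.21),
        _event("ih", 1.47, 0.21),
    ]
    return UtteranceScript(
        events=events,
        duration=SENTENCE_DURATION,
        f0_contour=[(0.0, 104.0), (0.55, 126.0), (1.05, 116.0), (1.64, 92.0)],
        # devoice both {f}'s and the {t}
        abduction_intervals=[(0.02, 0.18), (0.85, 1.01), (1.05, 1.21)],
    )


def make_fixtures(output_dir) -> list[Path]:
    """Write sentence1.json and sentence2.json into ``output_dir``.

    Regeneration is byte-identical (the scripts are fully deterministic).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, build in (("sentence1", sentence1), ("sentence2", sentence2)):
        path = out / f"{name}.json"
        write_script(build(), path)
        paths.append(path)
    return paths
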