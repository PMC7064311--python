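"""Utterance scripts: resonance deflection patterns and timed events.

An utterance is planned as an ordered list of *acoustic events*.  Each event
carries a resonance deflection pattern (RDP) — three coefficients
``delta_1..delta_3`` in [-1, 1] giving the intended direction and relative
magnitude of deflection of the first three tract resonances — a constriction
degree ``mu``, and a time course: a Gaussian event function

    E(n) = exp(-ln(16) * ((n - N_p) / N_w)^2),   n = 1..N_d,

peaking at 1 at frame ``N_p`` with full width ``N_w`` at half maximum,
optionally widened by a hold plateau of ``N_h`` frames at peak value 1,
centered on the peak.  Times are authored in seconds and converted to frames
at the vocal-tract modulation rate ``f_svt`` (default 146 Hz).

The unstressed neutral vowel is represented by the *absence* of events: any
stretch of the timeline with no active event leaves the tract in its neutral
configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RDP",
    "Event",
    "UtteranceScript",
    "builtin_rdp",
    "event_function",
    "time_to_samples",
    "read_script",
    "write_script",
    "DEFAULT_FRAME_RATE",
]

#: vocal-tract modulation frame rate, Hz
DEFAULT_FRAME_RATE = 146.0

_LN16 = float(np.log(16.0))


class ScriptSchemaError(ValueError):
    """A script document violates the schema or a type invariant."""


@dataclass(frozen=True)
class RDP:
    """Resonance deflection pattern (delta_1, delta_2, delta_3) in [-1, 1]."""

    delta1: float
    delta2: float
    delta3: float

    def __post_init__(self) -> None:
        for name, v in zip(("delta1", "delta2", "delta3"), self.as_array()):
            if not -1.0 <= v <= 1.0:
                raise ScriptSchemaError(f"{name} = {v} outside [-1, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.delta1, self.delta2, self.delta3], dtype=float)


#: canonical consonant-class RDPs; the vector (delta1, delta2, delta3)
_BUILTIN_RDPS = {
    "bilabial": RDP(-1.0, -1.0, -1.0),  # all three resonances down
    "alveolar": RDP(-1.0, 1.0, 1.0),    # first down, second & third up
    "velar": RDP(-1.0, 1.0, -1.0),      # first down, second up, third down
}


def builtin_rdp(class_name: str) -> RDP:
    """Canonical RDP for a consonant place class (bilabial/alveolar/velar)."""
    try:
        return _BUILTIN_RDPS[class_name]
    except KeyError:
        raise ScriptSchemaError(
            f"unknown RDP class {class_name!r}; choose from {sorted(_BUILTIN_RDPS)}"
        ) from None


@dataclass(frozen=True)
class Event:
    """One acoustic event: label, RDP, constriction degree and timing.

    ``mu`` scales the constriction: < 1 partial (vowels, liquids,
    fricatives), = 1 full closure at one section, > 1 a spatially spread
    closure.  ``t_p`` is the peak time, ``t_w`` the full width at half
    maximum, ``t_h`` an optional hold at peak amplitude; all seconds.
    ``consonant`` optionally tags the event explicitly for the vowels-only
    analysis variant (otherwise a mu-threshold heuristic applies).
    """

    label: str
    rdp: RDP
    mu: float
    t_p: float
    t_w: float
    t_h: float = 0.0
    consonant: bool | None = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ScriptSchemaError(f"event {self.label!r}: mu must be >= 0")
        if self.t_p < 0:
            raise ScriptSchemaError(f"event {self.label!r}: t_p must be >= 0")
        if self.t_w <= 0:
            raise ScriptSchemaError(f"event {self.label!r}: t_w must be > 0")
        if self.t_h < 0:
            raise ScriptSchemaError(f"event {self.label!r}: t_h must be >= 0")


@dataclass
class UtteranceScript:
    """Ordered events plus utterance duration, frame rate and voice gestures.

    ``f0_contour`` is a piecewise-linear fundamental-frequency contour as
    (time s, Hz) breakpoints; ``abduction_intervals`` are (start, end)
    stretches during which the glottis is abducted (voicing suppressed).
    """

    events: list[Event]
    duration: float
    frame_rate: float = DEFAULT_FRAME_RATE
    f0_contour: list[tuple[float, float]] = field(default_factory=list)
    abduction_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ScriptSchemaError("duration and frame_rate must be positive")
        if self.n_frames < 1:
            raise ScriptSchemaError("utterance shorter than one frame")
        for t, f0 in self.f0_contour:
            if f0 <= 0:
                raise ScriptSchemaError(f"F0 breakpoint at t={t}: F0 must be > 0")
        for start, end in self.abduction_intervals:
            if not 0 <= start < end <= self.duration + 1e-9:
                raise ScriptSchemaError(
                    f"abduction interval ({start}, {end}) outside the utterance"
                )

    @property
    def n_frames(self) -> int:
        """Number of vocal-tract modulation frames, N_d."""
        return int(round(self.duration * self.frame_rate))

    def times(self) -> np.ndarray:
        """Frame times in seconds (frame n at n/f_svt, n = 1..N_d, so that
        the peak frame N_p = t_p * f_svt sits at time t_p)."""
        return np.arange(1, self.n_frames + 1) / self.frame_rate

    def copy(self) -> "UtteranceScript":
        return UtteranceScript(
            list(self.events),
            self.duration,
            self.frame_rate,
            list(self.f0_contour),
            list(self.abduction_intervals),
        )


def time_to_samples(t: float, f_svt: float = DEFAULT_FRAME_RATE) -> int:
    """Convert a time in seconds to a frame count at ``f_svt`` (nearest)."""
    if t < 0:
        raise ScriptSchemaError("time must be non-negative")
    return int(round(t * f_svt))


def event_function(ev: Event, script: UtteranceScript) -> np.ndarray:
    """Sampled event function E(n) over the whole utterance, in [0, 1].

    The Gaussian peaks at exactly 1 at the (integer) peak frame; a nonzero
    hold inserts a plateau of value 1 centered on the peak, with the two
    Gaussian flanks attached at the plateau edges.
    """
    n_d = script.n_frames
    n_p = time_to_samples(ev.t_p, script.frame_rate)
    n_w = time_to_samples(ev.t_w, script.frame_rate)
    n_w = max(n_w, 1)
    half_hold = 0.5 * ev.t_h * script.frame_rate
    n = np.arange(1, n_d + 1, dtype=float)
    # distance beyond the plateau edge; zero inside the hold
    dist = np.maximum(np.abs(n - n_p) - half_hold, 0.0)
    return np.exp(-_LN16 * (dist / n_w) ** 2)


# ---------------------------------------------------------------------------
# JSON script I/O


def _event_to_dict(ev: Event) -> dict:
    d = {
        "label": ev.label,
        "delta": [ev.rdp.delta1, ev.rdp.delta2, ev.rdp.delta3],
        "mu": ev.mu,
        "tp": ev.t_p,
        "tw": ev.t_w,
        "th": ev.t_h,
    }
    if ev.consonant is not None:
        d["consonant"] = ev.consonant
    return d


def _event_from_dict(d: dict, index: int) -> Event:
    try:
        delta = d["delta"]
        if len(delta) != 3:
            raise ScriptSchemaError(f"event {index}: delta must have 3 entries")
        return Event(
            label=str(d["label"]),
            rdp=RDP(*map(float, delta)),
            mu=float(d["mu"]),
            t_p=float(d["tp"]),
            t_w=float(d["tw"]),
            t_h=float(d.get("th", 0.0)),
            consonant=d.get("consonant"),
        )
    except ScriptSchemaError as exc:
        raise ScriptSchemaError(f"event {index}: {exc}") from None
    except (KeyError, TypeError, ValueError) as exc:
        raise ScriptSchemaError(f"event {index}: {exc}") from exc


def write_script(script: UtteranceScript, path) -> None:
    """Write an utterance script as a JSON document."""
    doc = {
        "duration": script.duration,
        "frame_rate": script.frame_rate,
        "events": [_event_to_dict(ev) for ev in script.events],
        "f0": [[t, f0] for t, f0 in script.f0_contour],
        "abduction": [[a, b] for a, b in script.abduction_intervals],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_script(path) -> UtteranceScript:
    """Read and validate a JSON utterance script."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ScriptSchemaError(f"invalid JSON: {exc}") from exc
    try:
        events = [_event_from_dict(d, i) for i, d in enumerate(doc["events"])]
        return UtteranceScript(
            events=events,
            duration=float(doc["duration"]),
            frame_rate=float(doc.get("frame_rate", DEFAULT_FRAME_RATE)),
            f0_contour=[(float(t), float(f)) for t, f in doc.get("f0", [])],
            abduction_intervals=[
                (float(a), float(b)) for a, b in doc.get("abduction", [])
            ],
        )
    except ScriptSchemaError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ScriptSchemaError(str(exc)) from exc
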