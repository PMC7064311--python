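"""From deflection patterns to time-varying area functions.

A single event deforms the tract as follows: the three adjusted sensitivity
functions are combined with the event's RDP weights,

    y(i) = delta_1 Z_1(i) + delta_2 Z_2(i) + delta_3 Z_3(i),

and turned into a multiplicative deformation of the current tract,

    D(i) = 1 - mu * E(n) * y(i) / min_i y(i),      D(i) clipped below at 0,

so that the tract is neutral (D = 1) when the event is inactive, fully
occluded at the most negative section of y when ``mu E = 1``, occluded over
a spreading run of sections when ``mu E > 1``, and synergistically expanded
(D > 1) wherever y is positive.  The frame's area function is the product
``A(i) = A_prev(i) * D(i)``.

For overlapping events the deformations are *sequenced*: at every frame the
active events are applied in ascending order of ``mu``, and after each
application the sensitivity functions are recomputed from the deformed
tract, so that each event deflects the resonances relative to the tract the
earlier (weaker) events have already shaped.  This is what makes the events
relative, and coarticulation automatic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .acoustics import LossConfig
from .events import Event, UtteranceScript, event_function
from .geometry import AreaFunction, SideBranch
from .sensitivity import SensitivityFunctions, sensitivity_functions

__all__ = [
    "DeformationFrame",
    "TractMovie",
    "combine_sensitivities",
    "deformation_frame",
    "render_movie",
    "write_movie_table",
    "read_movie_table",
    "ACTIVITY_THRESHOLD",
    "OCCLUSION_FLOOR",
]

log = logging.getLogger(__name__)

#: events with E(n) below this are skipped at frame n
ACTIVITY_THRESHOLD = 1e-3
#: areas below this (cm^2) are floored for in-loop acoustics only
OCCLUSION_FLOOR = 0.01


class DegeneratePatternError(ValueError):
    """The combined sensitivity y(i) has no negative minimum: no constriction
    direction is defined for this RDP on this tract."""


@dataclass
class DeformationFrame:
    """One event's deformation at one frame."""

    y: np.ndarray      # combined sensitivity
    D: np.ndarray      # clipped deformation multipliers, >= 0
    mu_E: float        # effective constriction drive mu * E(n)


@dataclass
class TractMovie:
    """Time-varying area function A(i, n) at the modulation frame rate."""

    frames: np.ndarray          # shape (N_d, N_x), cm^2
    frame_rate: float
    script: UtteranceScript | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a (N_d, N_x) array")
        if np.any(self.frames < 0):
            raise ValueError("areas must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(1, self.n_frames + 1) / self.frame_rate

    def min_areas(self) -> np.ndarray:
        """Minimum cross-sectional area per frame (occlusion indicator)."""
        return self.frames.min(axis=1)


def combine_sensitivities(Z: np.ndarray, rdp) -> np.ndarray:
    """Weighted sum ``y = delta_1 Z_1 + delta_2 Z_2 + delta_3 Z_3``."""
    Z = np.asarray(Z, dtype=float)
    d = rdp.as_array() if hasattr(rdp, "as_array") else np.asarray(rdp, float)
    if Z.shape[0] != len(d):
        raise ValueError("need one Z vector per deflection coefficient")
    return d @ Z


def deformation_frame(y: np.ndarray, E_n: float, mu: float) -> DeformationFrame:
    """Deformation multipliers for one event at one frame.

    Requires ``min y < 0`` (some section driven toward constriction) unless
    y is identically zero, which is treated as "no event" (D = 1).
    """
    y = np.asarray(y, dtype=float)
    if not 0.0 <= E_n <= 1.0 + 1e-12:
        raise ValueError("event amplitude E_n must be in [0, 1]")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if np.all(y == 0):
        log.info("all-zero deflection pattern: treating as no event (D = 1)")
        return DeformationFrame(y, np.ones_like(y), 0.0)
    y_min = float(np.min(y))
    if y_min >= 0:
        raise DegeneratePatternError(
            "combined sensitivity has no negative minimum; no constriction "
            "location is defined for this deflection pattern"
        )
    d = 1.0 - mu * E_n * y / y_min
    return DeformationFrame(y, np.clip(d, 0.0, None), mu * E_n)


def _event_order(active: list[tuple[int, Event, float]]) -> list[tuple[int, Event, float]]:
    """Ascending mu; ties broken by ascending t_p, then script order."""
    return sorted(active, key=lambda t: (t[1].mu, t[1].t_p, t[0]))


def render_movie(
    script: UtteranceScript,
    omega: AreaFunction,
    branch: SideBranch | None = None,
    losses: LossConfig | None = None,
    activity_threshold: float = ACTIVITY_THRESHOLD,
    occlusion_floor: float = OCCLUSION_FLOOR,
    fast: bool = False,
) -> TractMovie:
    """Run the multi-event sequencing loop over the whole utterance.

    Per frame: events with E(n) above ``activity_threshold`` are applied in
    ascending-``mu`` order to a working tract initialized to the neutral
    configuration; the sensitivity functions are recomputed from the working
    tract before each application (with areas floored at
    ``occlusion_floor`` for the acoustics only, so an occluded intermediate
    tract remains analyzable).  Frames with no active event equal the
    neutral tract exactly.

    ``fast`` reuses the neutral tract's sensitivities for the first event of
    every frame (an approximation; off by default).
    """
    cfg = losses or LossConfig()
    n_d = script.n_frames
    n_x = omega.n_sections
    env = np.array([event_function(ev, script) for ev in script.events]) if script.events else np.zeros((0, n_d))
    frames = np.tile(omega.areas, (n_d, 1))

    neutral_sens: SensitivityFunctions | None = None
    if fast and script.events:
        neutral_sens = sensitivity_functions(omega, branch, cfg)

    for n in range(n_d):
        active = [
            (k, ev, float(env[k, n]))
            for k, ev in enumerate(script.events)
            if env[k, n] >= activity_threshold
        ]
        if not active:
            continue
        working = omega.areas.copy()
        for pos, (k, ev, e_n) in enumerate(_event_order(active)):
            if not np.any(ev.rdp.as_array()):
                continue
            if fast and pos == 0 and neutral_sens is not None:
                sens = neutral_sens
            else:
                floored = np.maximum(working, occlusion_floor)
                af = omega.with_areas(floored)
                sens = sensitivity_functions(af, branch, cfg)
            y = combine_sensitivities(sens.Z, ev.rdp)
            if np.all(y == 0) or float(np.min(y)) >= 0:
                log.warning(
                    "event %d (%s) at frame %d: no constriction direction; skipped",
                    k, ev.label, n + 1,
                )
                continue
            frame = deformation_frame(y, e_n, ev.mu)
            working = working * frame.D
        frames[n] = working
    return TractMovie(frames, script.frame_rate, script)


_MOVIE_HEADER = "# time_s\tsection\tdistance_cm\tarea_cm2"


def write_movie_table(movie: TractMovie, grid, path) -> None:
    """Delimited-text export: one row per (frame, section)."""
    times = movie.times()
    dist = grid.distances()
    with open(path, "w") as fh:
        fh.write(_MOVIE_HEADER + "\n")
        for n in range(movie.n_frames):
            for i in range(movie.frames.shape[1]):
                fh.write(
                    f"{times[n]:.6f}\t{i + 1}\t{dist[i]:.6f}\t{movie.frames[n, i]:.9f}\n"
                )


def read_movie_table(path) -> TractMovie:
    """Inverse of :func:`write_movie_table` (frame rate inferred from times)."""
    data = np.loadtxt(path, comments="#")
    times = np.unique(data[:, 0])
    sections = np.unique(data[:, 1]).astype(int)
    frames = data[:, 3].reshape(len(times), len(sections))
    if len(times) > 1:
        rate = 1.0 / float(np.median(np.diff(times)))
    else:
        rate = 1.0 / times[0] if times[0] > 0 else 146.0
    return TractMovie(frames, rate)
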