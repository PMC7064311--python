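"""Resonance tracks, analysis variants, and spectrograms.

The model's output is naturally analyzed as three sets of resonance tracks
over the utterance: the static resonances of the neutral tract (the
reference lines every deflection is relative to), the tracks of a
vowels-only rendering (consonant constriction degrees zeroed), and the
tracks of the full rendering.  Tracks are computed frame-by-frame from the
area function itself, not from the audio; frames whose tract is occluded or
nearly so (minimum area below a gap threshold) carry no defined resonances
and are marked as gaps — these are the track breaks at stop closures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import stft

from .acoustics import LossConfig, ResolutionError, resonances
from .deformation import OCCLUSION_FLOOR, TractMovie
from .events import Event, UtteranceScript
from .geometry import AreaFunction, SideBranch, TubeletGrid
from .synthesis import AudioResult

__all__ = [
    "ResonanceTracks",
    "track_resonances",
    "vowels_only_variant",
    "deflection_verdict",
    "spectrogram",
    "write_tracks_table",
    "DEFAULT_GAP_THRESHOLD",
    "MU_CONSONANT_THRESHOLD",
]

#: minimum area (cm^2) below which a frame counts as occluded ("gap")
DEFAULT_GAP_THRESHOLD = 0.05
#: events with mu at or above this default to "consonant" when untagged
MU_CONSONANT_THRESHOLD = 0.9


@dataclass
class ResonanceTracks:
    """Per-frame resonance frequencies with gap markers.

    ``f_R`` has shape (N_d, 3) with NaN at gap frames; ``variant`` is one of
    "neutral", "vowels_only", "all_events" (or any caller-chosen tag).
    """

    times: np.ndarray
    f_R: np.ndarray
    variant: str = "all_events"

    @property
    def gaps(self) -> np.ndarray:
        """Boolean mask of frames with no defined resonances."""
        return np.isnan(self.f_R).any(axis=1)

    def at_or_before(self, t: float) -> int | None:
        """Index of the last non-gap frame at or before time ``t``."""
        valid = np.flatnonzero(~self.gaps & (self.times <= t + 1e-9))
        return int(valid[-1]) if len(valid) else None


def track_resonances(
    movie: TractMovie,
    branch: SideBranch | None = None,
    losses: LossConfig | None = None,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    variant: str = "all_events",
    occlusion_floor: float = OCCLUSION_FLOOR,
    grid: TubeletGrid | None = None,
) -> ResonanceTracks:
    """Per-frame resonances of a tract movie, with occlusion gaps.

    A frame whose minimum area is below ``gap_threshold`` is marked as a
    gap; other frames are analyzed with areas floored at
    ``occlusion_floor`` (the same floor the sequencing loop uses).  A
    ``gap_threshold`` of 0 disables gaps entirely.  Raw per-frame peaks; no
    continuity constraint is imposed.
    """
    cfg = losses or LossConfig()
    grid = grid or TubeletGrid(n_sections=movie.frames.shape[1])
    n_d = movie.n_frames
    f_R = np.full((n_d, 3), np.nan)
    cache: dict[bytes, np.ndarray] = {}
    for n in range(n_d):
        areas = movie.frames[n]
        if gap_threshold > 0 and areas.min() < gap_threshold:
            continue
        floored = np.maximum(areas, occlusion_floor)
        key = floored.tobytes()
        if key not in cache:
            af = AreaFunction(grid, floored)
            try:
                cache[key] = resonances(af, branch, cfg, refine=False).f_R
            except ResolutionError:
                cache[key] = np.full(3, np.nan)
        f_R[n] = cache[key]
    return ResonanceTracks(movie.times(), f_R, variant)


def _is_consonant(ev: Event, mu_threshold: float) -> bool:
    if ev.consonant is not None:
        return ev.consonant
    return ev.mu >= mu_threshold


def vowels_only_variant(
    script: UtteranceScript, mu_threshold: float = MU_CONSONANT_THRESHOLD
) -> UtteranceScript:
    """Copy of the script with every consonant's ``mu`` set to zero.

    Consonants are identified by their explicit tag when present, else by
    ``mu >= mu_threshold``.  Vowel events are untouched.
    """
    out = script.copy()
    out.events = [
        replace(ev, mu=0.0) if _is_consonant(ev, mu_threshold) else ev
        for ev in script.events
    ]
    return out


def deflection_verdict(
    tracks_event: ResonanceTracks,
    tracks_reference: ResonanceTracks,
    ev: Event,
    tol_hz: float = 1e-6,
) -> tuple[int | None, int | None, int | None]:
    """Signs of the resonance deflections an event realizes.

    For each resonance j, compares the event rendering against the
    reference rendering at the last frame at or before the event's peak
    time that is gap-free in *both* track sets, returning the sign of
    ``f_Rj(event) - f_Rj(reference)`` (None when no comparable frame
    exists).  Agreement with ``sign(delta_j)`` at nonzero ``delta_j`` is the
    model's central behavioral check.
    """
    if len(tracks_event.times) != len(tracks_reference.times) or not np.allclose(
        tracks_event.times, tracks_reference.times
    ):
        raise ValueError("tracks are not on a common time base")
    both = ~tracks_event.gaps & ~tracks_reference.gaps
    valid = np.flatnonzero(both & (tracks_event.times <= ev.t_p + 1e-9))
    if not len(valid):
        return (None, None, None)
    n = int(valid[-1])
    diff = tracks_event.f_R[n] - tracks_reference.f_R[n]
    return tuple(0 if abs(d) <= tol_hz else int(np.sign(d)) for d in diff)


def spectrogram(
    audio: AudioResult, window_ms: float = 5.0, hop_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wideband short-time magnitude spectrogram (times, freqs, magnitude)."""
    x = np.asarray(audio.samples, dtype=float)
    if len(x) == 0:
        raise ValueError("empty audio")
    nper = int(round(window_ms * 1e-3 * audio.rate))
    hop = max(int(round(hop_ms * 1e-3 * audio.rate)), 1)
    if nper > len(x):
        raise ValueError("window longer than the signal")
    f, t, z = stft(
        x, fs=audio.rate, nperseg=nper, noverlap=nper - hop, padded=False,
        boundary=None,
    )
    return t, f, np.abs(z)


def write_tracks_table(tracks: ResonanceTracks, path) -> None:
    """Delimited-text export: time_s, fR1_Hz, fR2_Hz, fR3_Hz, gap, variant."""
    with open(path, "w") as fh:
        fh.write("# time_s\tfR1_Hz\tfR2_Hz\tfR3_Hz\tgap\tvariant\n")
        for n in range(len(tracks.times)):
            gap = int(bool(np.isnan(tracks.f_R[n]).any()))
            vals = "\t".join(
                "nan" if np.isnan(v) else f"{v:.3f}" for v in tracks.f_R[n]
            )
            fh.write(f"{tracks.times[n]:.6f}\t{vals}\t{gap}\t{tracks.variant}\n")
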