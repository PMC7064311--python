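"""Shared fixtures: reference tracts, configs, and the (expensive) rendered
sentence movies/tracks, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from rdspeech import (
    LossConfig,
    ResonanceTracks,
    default_side_branch,
    make_grid,
    neutral_tract_standin,
    render_movie,
    resonances,
    track_resonances,
    uniform_tract,
    vowels_only_variant,
)
from rdspeech.fixtures import sentence1, sentence2


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def neutral(grid):
    return neutral_tract_standin(grid)


@pytest.fixture(scope="session")
def branch():
    return default_side_branch()


@pytest.fixture(scope="session")
def losses():
    return LossConfig()


@pytest.fixture(scope="session")
def lossless():
    return LossConfig(lossless=True)


@pytest.fixture(scope="session")
def uniform(grid):
    return uniform_tract(grid, 4.0)


@pytest.fixture(scope="session")
def rendered_sentences(neutral, branch, losses):
    """Movies and resonance tracks for both demonstration sentences.

    Returns {name: dict} with the script, the full and vowels-only movies,
    and the three track variants on a common time base.
    """
    out = {}
    for name, build in (("s1", sentence1), ("s2", sentence2)):
        script = build()
        movie_all = render_movie(script, neutral, branch, losses)
        movie_vow = render_movie(
            vowels_only_variant(script), neutral, branch, losses
        )
        tr_all = track_resonances(movie_all, branch, losses, variant="all_events")
        tr_vow = track_resonances(movie_vow, branch, losses, variant="vowels_only")
        f_neu = resonances(neutral, branch, losses).f_R
        tr_neu = ResonanceTracks(
            tr_all.times, np.tile(f_neu, (len(tr_all.times), 1)), "neutral"
        )
        out[name] = {
            "script": script,
            "movie_all": movie_all,
            "movie_vow": movie_vow,
            "tracks_all": tr_all,
            "tracks_vow": tr_vow,
            "tracks_neu": tr_neu,
        }
    return out


def formant_peaks(x, fs, n_fft=8192, lifter_ms=2.0, preemph=0.97, f_max=4000.0):
    """Formant-like spectral envelope peaks via cepstral smoothing.

    Pre-emphasized log spectrum, liftered below ``lifter_ms`` quefrency;
    returns envelope peak frequencies below ``f_max``.  Test-only helper
    (the library's resonance tracks come from the area function, not audio).
    """
    from scipy.signal import find_peaks

    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    x = np.append(x[0], x[1:] - preemph * x[:-1])
    w = x[: n_fft] * np.hanning(min(len(x), n_fft))
    logmag = np.log(np.abs(np.fft.rfft(w, n_fft)) + 1e-12)
    cep = np.fft.irfft(logmag)
    q = int(lifter_ms * fs / 1000)
    cep[q:-q] = 0
    env = np.fft.rfft(cep).real
    f = np.fft.rfftfreq(n_fft, 1 / fs)
    pk, _ = find_peaks(env)
    return f[pk][f[pk] < f_max]


def periodicity_strength(x, fs=44100.0, f_lo=70.0, f_hi=300.0):
    """Peak of the normalized autocorrelation in the pitch-lag range."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if x.std() == 0:
        return 0.0
    ac = np.correlate(x, x, "full")[len(x) - 1 :]
    ac = ac / ac[0]
    lo, hi = int(fs / f_hi), int(fs / f_lo)
    return float(ac[lo:hi].max())


def low_energy_runs(x, fs=44100.0, frame_s=0.01, rel_threshold=0.15):
    """(start, end) times of contiguous low-RMS stretches of a waveform."""
    fl = int(frame_s * fs)
    nfr = len(x) // fl
    rms = np.sqrt((x[: nfr * fl].reshape(nfr, fl) ** 2).mean(axis=1))
    t = (np.arange(nfr) + 0.5) * fl / fs
    low = rms < rel_threshold * np.median(rms)
    runs, start = [], None
    for i, v in enumerate(low):
        if v and start is None:
            start = i
        if not v and start is not None:
            runs.append((t[start], t[i]))
            start = None
    if start is not None:
        runs.append((t[start], t[-1]))
    return runs
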