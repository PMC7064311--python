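"""Time-domain synthesis: waveguide tract, glottal source, turbulence noise.

The time-varying area function is rendered audible with a one-dimensional
wave-propagation (Kelly-Lochbaum scattering) model: each tubelet carries a
right- and left-going pressure wave, adjacent tubelets exchange energy at
scattering junctions with reflection coefficients
``r_i = (A_i - A_{i+1}) / (A_i + A_{i+1})``, the glottal end is driven by a
flow source, and the lip end is terminated by a first-order reflectance
fitted to the piston-in-baffle radiation load.  Because each tubelet is
``c / (2 F_s)`` long, its one-way travel time is half an audio sample; the
lattice therefore runs at an internal rate of ``2 F_s`` and the output is
decimated by pair-averaging back to ``F_s``.

The voice source is a parameterized glottal-flow pulse train (raised-cosine
open phase) following a piecewise-linear F0 contour.  During abduction
intervals the pulses ramp off and a steady leak flow opens, producing
voiceless (aspirated) stretches.  Turbulence noise is gated by the Reynolds
number: a band-passed (500-2500 Hz, second-order Butterworth) uniform noise
signal ``N_f`` in [-0.5, 0.5] is scaled by ``(Re^2 - Re_c^2) * 1e-6`` and
added wherever ``Re`` exceeds the critical value ``Re_c = 1200`` — at the
glottis (added to the glottal flow) and immediately downstream of the most
constricted supraglottal section that exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, lfilter

from .acoustics import LossConfig
from .deformation import TractMovie
from .geometry import SideBranch

__all__ = [
    "VoiceSource",
    "NoiseParams",
    "AudioResult",
    "noise_flow",
    "reynolds_number",
    "synthesize",
    "write_wav",
    "read_wav",
]

#: areas below this (cm^2) are acoustically closed junctions
CLOSURE_THRESHOLD = 1e-3


class ConfigurationError(ValueError):
    """Inconsistent grid/rate configuration for synthesis."""


@dataclass
class VoiceSource:
    """Simplified parameterized glottal source.

    A raised-cosine flow pulse train (peak ``amplitude`` cm^3/s, open
    quotient ``open_quotient``) follows the piecewise-linear ``f0_contour``;
    inside ``abduction_intervals`` the pulse amplitude ramps to zero over
    ``ramp_time`` s and a steady ``leak_flow`` through ``leak_area`` opens.
    Any other glottal-flow generator can be substituted via
    ``flow_generator`` (callable: times (s) -> flow (cm^3/s)).
    """

    f0_contour: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 110.0)]
    )
    abduction_intervals: list[tuple[float, float]] = field(default_factory=list)
    amplitude: float = 350.0       # peak glottal flow, cm^3/s
    open_quotient: float = 0.6
    leak_flow: float = 200.0       # cm^3/s during abduction
    leak_area: float = 0.1         # cm^2 during abduction
    pulse_area: float = 0.15       # peak glottal area during a pulse, cm^2
    rest_area: float = 0.005       # minimum (posterior-gap) glottal area, cm^2
    ramp_time: float = 0.016       # s, abduction on/off ramp
    flow_generator: object | None = None

    @classmethod
    def from_script(cls, script, **kwargs) -> "VoiceSource":
        return cls(
            f0_contour=list(script.f0_contour) or [(0.0, 110.0)],
            abduction_intervals=list(script.abduction_intervals),
            **kwargs,
        )

    def f0_at(self, t: np.ndarray) -> np.ndarray:
        pts = sorted(self.f0_contour)
        return np.interp(t, [p[0] for p in pts], [p[1] for p in pts])

    def voicing_gate(self, t: np.ndarray) -> np.ndarray:
        """1 while voiced, 0 while abducted, raised-cosine ramps between."""
        gate = np.ones_like(t)
        for start, end in self.abduction_intervals:
            ramp = max(self.ramp_time, 1e-6)
            down = np.clip((t - (start - ramp)) / ramp, 0.0, 1.0)
            up = np.clip((t - end) / ramp, 0.0, 1.0)
            seg = 1.0 - 0.5 * (1 - np.cos(np.pi * down)) + 0.5 * (1 - np.cos(np.pi * up))
            gate = np.minimum(gate, np.clip(seg, 0.0, 1.0))
        return gate

    def glottal_waveforms(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(flow cm^3/s, glottal area cm^2) sampled at times ``t``."""
        if self.flow_generator is not None:
            flow = np.asarray(self.flow_generator(t), dtype=float)
            area = np.maximum(self.pulse_area * flow / max(self.amplitude, 1e-9),
                              self.rest_area)
            return flow, area
        dt = np.diff(t, prepend=t[0])
        phase = np.cumsum(self.f0_at(t) * dt) % 1.0
        oq = min(max(self.open_quotient, 1e-3), 1.0)
        open_phase = phase < oq
        pulse = np.where(
            open_phase, 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / oq)), 0.0
        )
        gate = self.voicing_gate(t)
        flow = self.amplitude * pulse * gate + self.leak_flow * (1.0 - gate)
        area = (
            self.pulse_area * pulse * gate
            + self.leak_area * (1.0 - gate)
            + self.rest_area
        )
        return flow, area


@dataclass
class NoiseParams:
    """Reynolds-gated turbulence noise parameters."""

    re_c: float = 1200.0
    gain: float = 1e-6
    band: tuple[float, float] = (500.0, 2500.0)
    order: int = 2
    rng_seed: int = 0
    #: cap on the Reynolds number used for noise scaling (keeps the
    #: acoustic-flow estimate of Re from running away at very narrow
    #: constrictions)
    re_cap: float = 8000.0

    def __post_init__(self) -> None:
        if self.re_c <= 0:
            raise ValueError("re_c must be positive")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band edges must be increasing and positive")

    def filtered_noise(self, n: int, rate: float, stream: int = 0) -> np.ndarray:
        """Band-passed uniform noise N_f in [-0.5, 0.5], seeded."""
        rng = np.random.default_rng((self.rng_seed, stream))
        raw = rng.uniform(-0.5, 0.5, n)
        lo, hi = self.band
        hi = min(hi, 0.499 * rate)
        b, a = butter(self.order, [lo / (rate / 2), hi / (rate / 2)], btype="band")
        return lfilter(b, a, raw)


@dataclass
class AudioResult:
    """Synthesized audio plus per-sample diagnostics."""

    samples: np.ndarray    # normalized pressure waveform
    rate: float            # Hz
    diagnostics: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def noise_flow(Re: float, Nf_sample: float, params: NoiseParams) -> float:
    """Reynolds-gated noise flow increment: 0 at or below the critical
    Reynolds number, ``N_f (Re^2 - Re_c^2) * gain`` above it."""
    if Re <= params.re_c:
        return 0.0
    return Nf_sample * (Re * Re - params.re_c * params.re_c) * params.gain


def reynolds_number(
    flow: float,
    area: float,
    kinematic_viscosity: float = 0.15,
) -> float:
    """Reynolds number of flow through a circular-equivalent section.

    ``Re = v d_h / nu`` with mean velocity ``v = |U| / A`` and hydraulic
    diameter ``d_h = 2 sqrt(A / pi)``; zero area is treated as a closed
    section carrying no flow.
    """
    if area <= 0:
        return 0.0
    return 2.0 * abs(flow) / (kinematic_viscosity * np.sqrt(np.pi * area))


def _lip_reflectance_coeffs(
    area: float, cfg: LossConfig, rate2: float
) -> tuple[float, float, float]:
    """First-order digital reflectance (b0, b1, a1) at the lip end.

    Bilinear transform of ``r(s) = (Z_rad(s) - Z0) / (Z_rad(s) + Z0)`` with
    the parallel resistance-inertance radiation load; without radiation the
    end is an ideal pressure release (r = -1).
    """
    if not cfg.radiation:
        return -1.0, 0.0, 0.0
    rho, c = cfg.air_density, cfg.sound_speed
    z0 = rho * c / area
    a_eq = np.sqrt(area / np.pi)
    r_r = 128.0 * rho * c / (9.0 * np.pi**2 * area)
    l_r = 8.0 * rho * a_eq / (3.0 * np.pi * area)
    k = 2.0 * rate2
    num0 = (r_r - z0) * l_r * k - z0 * r_r
    num1 = -(r_r - z0) * l_r * k - z0 * r_r
    den0 = (r_r + z0) * l_r * k + z0 * r_r
    den1 = -(r_r + z0) * l_r * k + z0 * r_r
    return num0 / den0, num1 / den0, den1 / den0


def synthesize(
    movie: TractMovie,
    source: VoiceSource,
    noise: NoiseParams | None = None,
    branch: SideBranch | None = None,
    losses: LossConfig | None = None,
    audio_rate: float = 44_100.0,
    damping_per_section: float = 0.998,
    grid=None,
) -> AudioResult:
    """Propagate the glottal source through the time-varying tract.

    Areas are linearly interpolated from the movie frame rate to the
    internal lattice rate; sections below ``CLOSURE_THRESHOLD`` cm^2 act as
    closed junctions (full reflection) through the scattering coefficients.
    Deterministic for a fixed noise seed.  The ``branch`` argument is
    accepted for interface symmetry but the side branch is not modeled in
    the time domain.
    """
    cfg = (losses or LossConfig()).effective()
    noise = noise or NoiseParams()
    rho, c = cfg.air_density, cfg.sound_speed
    n_x = movie.frames.shape[1]
    if grid is not None:
        expected = grid.sound_speed / (2.0 * audio_rate)
        if abs(grid.section_length - expected) > 1e-9 * expected:
            raise ConfigurationError(
                f"section length {grid.section_length} cm inconsistent with "
                f"audio rate {audio_rate} Hz (expected c/(2 F_s) = {expected})"
            )
        if grid.n_sections != n_x:
            raise ConfigurationError("movie section count does not match grid")
    t_d = (
        movie.script.duration
        if movie.script is not None
        else movie.n_frames / movie.frame_rate
    )
    n_out = int(round(t_d * audio_rate))
    rate2 = 2.0 * audio_rate
    n_steps = 2 * n_out
    if cfg.lossless:
        damping_per_section = 1.0

    t2 = np.arange(n_steps) / rate2
    flow_g, area_g = source.glottal_waveforms(t2)

    # Reynolds-gated aspiration noise at the glottis (vectorized: the
    # glottal flow does not depend on the lattice state)
    nf_g = noise.filtered_noise(n_steps, rate2, stream=0)
    re_g = 2.0 * np.abs(flow_g) / (0.15 * np.sqrt(np.pi * np.maximum(area_g, 1e-9)))
    gate = re_g > noise.re_c
    flow_total = flow_g + np.where(
        gate, nf_g * (re_g**2 - noise.re_c**2) * noise.gain, 0.0
    )
    nf_s = noise.filtered_noise(n_steps, rate2, stream=1)

    # frame interpolation indices: frame n (0-based) sits at time (n+1)/f_svt
    pos = np.clip(t2 * movie.frame_rate - 1.0, 0.0, movie.n_frames - 1.0)
    idx0 = np.minimum(pos.astype(int), movie.n_frames - 2) if movie.n_frames > 1 else np.zeros(n_steps, int)
    frac = pos - idx0

    glottal_reflection = 1.0 if cfg.lossless else 0.98
    fw = np.zeros(n_x)  # right-going pressure waves
    bw = np.zeros(n_x)  # left-going pressure waves
    out2 = np.empty(n_steps)
    min_area = np.empty(n_steps)
    re_supra = np.zeros(n_steps)
    lip_x1 = 0.0  # previous lip-incident wave
    lip_y1 = 0.0  # previous lip-reflected wave
    u_lp = 0.0    # smoothed |flow| at the constriction, for the Re gate
    frames = movie.frames

    for m in range(n_steps):
        if movie.n_frames > 1:
            a0 = frames[idx0[m]]
            areas = a0 + frac[m] * (frames[idx0[m] + 1] - a0)
        else:
            areas = frames[0]
        areas = np.maximum(areas, 1e-6)
        min_area[m] = areas.min()
        z = rho * c / areas

        # supraglottal turbulence at the most constricted *open* section;
        # closed sections carry no flow and generate no noise
        open_mask = areas >= CLOSURE_THRESHOLD
        if open_mask.all():
            i_c = int(np.argmin(areas))
        elif open_mask.any():
            masked = np.where(open_mask, areas, np.inf)
            i_c = int(np.argmin(masked))
        else:
            i_c = -1
        if i_c >= 0:
            u_c = (fw[i_c] - bw[i_c]) / z[i_c]
            # one-pole smoothing of |u| (~150 Hz) so the Re estimate tracks
            # the mean flow, not the injected noise itself
            u_lp += 0.01 * (abs(u_c) - u_lp)
            re_c_site = 2.0 * u_lp / (0.15 * np.sqrt(np.pi * areas[i_c]))
            re_c_site = min(re_c_site, noise.re_cap)
        else:
            re_c_site = 0.0
        re_supra[m] = re_c_site

        # glottal boundary: flow source with near-total reflection
        fw_new = np.empty(n_x)
        fw_new[0] = glottal_reflection * bw[0] + z[0] * flow_total[m] * 0.5 * (
            1.0 + glottal_reflection
        )

        # interior scattering junctions
        r = (areas[:-1] - areas[1:]) / (areas[:-1] + areas[1:])
        fw_new[1:] = (1.0 + r) * fw[:-1] - r * bw[1:]
        bw_new = np.empty(n_x)
        bw_new[:-1] = (1.0 - r) * bw[1:] + r * fw[:-1]

        if noise.re_c < re_c_site and 0 <= i_c < n_x - 1 and open_mask[i_c + 1]:
            u_n = nf_s[m] * (re_c_site**2 - noise.re_c**2) * noise.gain
            fw_new[i_c + 1] += z[i_c + 1] * u_n

        # lip boundary: first-order radiation reflectance
        b0, b1, a1 = _lip_reflectance_coeffs(float(areas[-1]), cfg, rate2)
        lip_y = b0 * fw[-1] + b1 * lip_x1 - a1 * lip_y1
        bw_new[-1] = lip_y
        # output = lip volume velocity (the same quantity whose transfer
        # function defines the resonances in the frequency-domain model)
        out2[m] = (fw[-1] - lip_y) / z[-1]
        lip_x1, lip_y1 = fw[-1], lip_y

        att = damping_per_section
        fw = fw_new * att
        bw = bw_new * att

    samples = 0.5 * (out2[0::2] + out2[1::2])
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak
    diagnostics = {
        "glottal_flow": flow_total[0::2],
        "re_glottis": re_g[0::2],
        "re_supraglottal": re_supra[0::2],
        "min_area_cm2": min_area[0::2],
    }
    return AudioResult(samples, audio_rate, diagnostics)


def write_wav(audio: AudioResult, path) -> None:
    """16-bit PCM mono WAV, peak-normalized to -1 dBFS."""
    samples = np.asarray(audio.samples, dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ValueError("non-finite samples")
    peak = np.max(np.abs(samples)) if len(samples) else 0.0
    if peak > 0:
        samples = samples / peak * 10.0 ** (-1.0 / 20.0)
    pcm = np.round(samples * 32767.0).astype(np.int16)
    wavfile.write(path, int(audio.rate), pcm)


def read_wav(path) -> AudioResult:
    """Read a 16-bit PCM WAV back to a float AudioResult."""
    rate, pcm = wavfile.read(path)
    return AudioResult(pcm.astype(float) / 32767.0, float(rate))
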