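"""Frequency-domain transmission-line acoustics of a tubelet tract.

Each tubelet is one segment of a lossy acoustic transmission line with
per-unit-length series impedance ``z = R_v + j w rho / A`` and shunt
admittance ``y = G_t + j w A / (rho c^2) + y_w``, where ``R_v`` and ``G_t``
are the frequency-dependent viscous and heat-conduction surface losses and
``y_w`` the yielding-wall branch (per-unit-wall-area resistance, mass and
stiffness).  A segment of length ``L`` contributes the chain (ABCD) matrix

    [[cosh(g L),  Zc sinh(g L)],
     [sinh(g L)/Zc,  cosh(g L)]],   g = sqrt(z y),  Zc = sqrt(z / y),

and the tract response is the cascade of all segments, driven by an ideal
flow source at the glottis (closed-end approximation) and terminated at the
lips by a piston-in-baffle radiation load (parallel resistance-inertance).
The piriform side branch enters as a parallel shunt admittance at its
attachment junction.  Resonances are the peaks of ``|U_lips / U_glottis|``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .geometry import AreaFunction, SideBranch

__all__ = [
    "LossConfig",
    "FrequencyResponse",
    "ResonanceSet",
    "frequency_response",
    "find_resonances",
    "resonances",
    "modal_distributions",
    "default_frequency_grid",
    "DegenerateTractError",
    "ResolutionError",
]


class DegenerateTractError(ValueError):
    """The tract contains a non-positive area; the frequency-domain solver
    cannot handle occlusions (use the time-domain synthesizer, or floor the
    areas)."""


class ResolutionError(RuntimeError):
    """Fewer resonance peaks were found than requested; use a denser or
    wider frequency grid."""


@dataclass(frozen=True)
class LossConfig:
    """Energy-loss parameterization of the transmission line (cgs units).

    Defaults are standard tube-acoustics values: soft-wall RLC per unit wall
    area, air viscosity/heat-conduction surface losses, and a first-order
    radiation load.  ``lossless`` zeroes every loss term and replaces the
    radiation load with an ideal open end (pressure release).
    """

    air_density: float = 1.14e-3        # rho, g/cm^3
    sound_speed: float = 35_000.0       # c, cm/s
    viscosity: float = 1.86e-4          # dynamic, dyn s/cm^2
    thermal_conductivity: float = 2.3e3  # erg/(cm s K)
    specific_heat_cp: float = 1.005e7   # erg/(g K)
    gamma_adiabatic: float = 1.4
    wall_resistance: float = 1600.0     # dyn s/cm^3 per unit wall area
    wall_mass: float = 1.5              # g/cm^2
    wall_stiffness: float = 3.0e5       # dyn/cm^3
    wall_losses: bool = True
    surface_losses: bool = True         # viscosity + heat conduction
    radiation: bool = True
    lossless: bool = False

    def effective(self) -> "LossConfig":
        if not self.lossless:
            return self
        return replace(
            self, wall_losses=False, surface_losses=False, radiation=False
        )


@dataclass
class FrequencyResponse:
    """Sampled transfer function glottal flow -> lip flow."""

    frequencies: np.ndarray       # Hz, strictly increasing
    complex_transfer: np.ndarray  # U_lips / U_glottis

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.complex_transfer = np.asarray(self.complex_transfer, dtype=complex)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def magnitude(self) -> np.ndarray:
        """Magnitude in dB (floored far below any physical peak)."""
        mag = np.abs(self.complex_transfer)
        return 20.0 * np.log10(np.maximum(mag, 1e-300))


@dataclass
class ResonanceSet:
    """First ``n`` resonance frequencies, optionally with the per-section
    modal pressure/flow distributions computed at each of them."""

    f_R: np.ndarray                     # Hz, strictly increasing
    pressures: np.ndarray | None = None  # shape (n, N_x), complex
    flows: np.ndarray | None = None      # shape (n, N_x), complex

    def __post_init__(self) -> None:
        self.f_R = np.asarray(self.f_R, dtype=float)
        if np.any(np.diff(self.f_R) <= 0):
            raise ValueError("resonance frequencies must be strictly increasing")


def default_frequency_grid(
    f_min: float = 50.0, f_max: float = 5000.0, step: float = 10.0
) -> np.ndarray:
    return np.arange(f_min, f_max + 0.5 * step, step)


def _line_parameters(
    areas: np.ndarray, omega: np.ndarray, cfg: LossConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit-length series impedance z and shunt admittance y.

    ``areas`` has shape (N,), ``omega`` shape (F,); returns (N, F) arrays.
    """
    rho, c = cfg.air_density, cfg.sound_speed
    A = areas[:, None]
    w = omega[None, :]
    S = 2.0 * np.sqrt(np.pi * A)  # circular-equivalent perimeter

    z = 1j * w * rho / A
    y = 1j * w * A / (rho * c * c)
    if cfg.surface_losses:
        z = z + (S / A**2) * np.sqrt(w * rho * cfg.viscosity / 2.0)
        y = y + S * (cfg.gamma_adiabatic - 1.0) / (rho * c * c) * np.sqrt(
            cfg.thermal_conductivity * w / (2.0 * cfg.specific_heat_cp * rho)
        )
    if cfg.wall_losses:
        zw = (
            cfg.wall_resistance
            + 1j * w * cfg.wall_mass
            + cfg.wall_stiffness / (1j * w)
        )
        y = y + S / zw
    return z, y


def _segment_terms(
    areas: np.ndarray, seg_len: float, omega: np.ndarray, cfg: LossConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """cosh(gL), sinh(gL) and Zc for every (section, frequency)."""
    z, y = _line_parameters(areas, omega, cfg)
    g = np.sqrt(z * y)
    zc = np.sqrt(z / y)
    gl = g * seg_len
    return np.cosh(gl), np.sinh(gl), zc


def radiation_impedance(area: float, omega: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Piston-in-baffle radiation load: parallel R_r and inertance L_r."""
    if not cfg.radiation:
        return np.zeros_like(np.asarray(omega, dtype=complex))
    rho, c = cfg.air_density, cfg.sound_speed
    a = np.sqrt(area / np.pi)
    r_r = 128.0 * rho * c / (9.0 * np.pi**2 * area)
    l_r = 8.0 * rho * a / (3.0 * np.pi * area)
    jwl = 1j * np.asarray(omega) * l_r
    return jwl * r_r / (r_r + jwl)


def _branch_admittance(
    branch: SideBranch, omega: np.ndarray, cfg: LossConfig
) -> np.ndarray:
    """Input admittance of the closed side branch at each frequency."""
    ch, sh, zc = _segment_terms(
        branch.branch_areas, branch.branch_section_length, omega, cfg
    )
    # cascade from attachment toward the closed far end
    a = np.ones_like(omega, dtype=complex)
    b = np.zeros_like(a)
    c_ = np.zeros_like(a)
    d = np.ones_like(a)
    for i in range(len(branch.branch_areas)):
        a, b, c_, d = (
            a * ch[i] + b * sh[i] / zc[i],
            a * zc[i] * sh[i] + b * ch[i],
            c_ * ch[i] + d * sh[i] / zc[i],
            c_ * zc[i] * sh[i] + d * ch[i],
        )
    return c_ / a  # u_att / p_att with u = 0 at the far end


def _validate_areas(af: AreaFunction) -> np.ndarray:
    areas = np.asarray(af.areas, dtype=float)
    if np.any(areas <= 0):
        bad = int(np.argmax(areas <= 0)) + 1
        raise DegenerateTractError(
            f"section {bad} has non-positive area; the frequency-domain solver "
            "rejects occluded tracts (use the time-domain synthesizer or floor "
            "the areas)"
        )
    return areas


def _cascade(
    af: AreaFunction,
    branch: SideBranch | None,
    cfg: LossConfig,
    omega: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Full-tract chain matrix [[A,B],[C,D]] mapping lip state to glottis
    state: ``[p_g; u_g] = K [p_l; u_l]``."""
    areas = _validate_areas(af)
    cfg = cfg.effective()
    ch, sh, zc = _segment_terms(areas, af.grid.section_length, omega, cfg)
    yb = None
    ib = None
    if branch is not None:
        yb = _branch_admittance(branch, omega, cfg)
        ib = branch.attach_index(af.grid)
    a = np.ones_like(omega, dtype=complex)
    b = np.zeros_like(a)
    c_ = np.zeros_like(a)
    d = np.ones_like(a)
    for i in range(len(areas)):
        a, b, c_, d = (
            a * ch[i] + b * sh[i] / zc[i],
            a * zc[i] * sh[i] + b * ch[i],
            c_ * ch[i] + d * sh[i] / zc[i],
            c_ * zc[i] * sh[i] + d * ch[i],
        )
        if ib is not None and i == ib:
            # shunt branch at the lip-side edge of the attachment section
            a, c_ = a + b * yb, c_ + d * yb
    return a, b, c_, d


def frequency_response(
    af: AreaFunction,
    branch: SideBranch | None = None,
    losses: LossConfig | None = None,
    f_grid: np.ndarray | None = None,
) -> FrequencyResponse:
    """Transfer function ``U_lips / U_glottis`` on a frequency grid."""
    cfg = (losses or LossConfig()).effective()
    if f_grid is None:
        f_grid = default_frequency_grid()
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(f_grid <= 0) or np.any(f_grid >= af.grid.acoustic_sampling_rate / 2):
        raise ValueError("f_grid must lie within (0, F_s/2)")
    omega = 2.0 * np.pi * f_grid
    a, b, c_, d = _cascade(af, branch, cfg, omega)
    zrad = radiation_impedance(float(af.areas[-1]), omega, cfg)
    h = 1.0 / (c_ * zrad + d)
    return FrequencyResponse(f_grid, h)


def _parabolic_peak(f: np.ndarray, m: np.ndarray, k: int) -> float:
    """Vertex of the parabola through three dB samples around index k."""
    if k == 0 or k == len(f) - 1:
        return float(f[k])
    y0, y1, y2 = m[k - 1], m[k], m[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0 or not np.isfinite(denom):
        return float(f[k])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(f[k] + delta * (f[k + 1] - f[k]))


def find_resonances(fr: FrequencyResponse, n: int = 3) -> ResonanceSet:
    """The ``n`` lowest-frequency local maxima of the magnitude response,
    each refined by parabolic interpolation on the dB grid."""
    mag = fr.magnitude
    peaks, _ = find_peaks(mag)
    if len(peaks) < n:
        raise ResolutionError(
            f"found {len(peaks)} peaks, need {n}; use a denser/wider grid"
        )
    freqs = [_parabolic_peak(fr.frequencies, mag, int(k)) for k in peaks[:n]]
    return ResonanceSet(np.array(freqs))


def resonances(
    af: AreaFunction,
    branch: SideBranch | None = None,
    losses: LossConfig | None = None,
    n: int = 3,
    f_grid: np.ndarray | None = None,
    refine: bool = True,
) -> ResonanceSet:
    """Resonance frequencies of an area function.

    Runs :func:`frequency_response` on the (default) grid, picks peaks, and,
    when ``refine`` is set, polishes each peak by a bounded maximization of
    the continuous ``|H(f)|`` within one grid step, for ~1e-4 Hz precision
    (needed when comparing sub-Hz resonance shifts).
    """
    fr = frequency_response(af, branch, losses, f_grid)
    rs = find_resonances(fr, n)
    if not refine:
        return rs
    step = float(np.median(np.diff(fr.frequencies)))

    def neg_mag(f: float) -> float:
        h = frequency_response(af, branch, losses, np.array([f]))
        return -float(np.abs(h.complex_transfer[0]))

    refined = []
    for f0 in rs.f_R:
        res = minimize_scalar(
            neg_mag,
            bounds=(max(f0 - step, 1e-3), f0 + step),
            method="bounded",
            options={"xatol": 1e-4},
        )
        refined.append(float(res.x))
    refined = np.sort(np.array(refined))
    return ResonanceSet(refined)


def modal_distributions(
    af: AreaFunction,
    branch: SideBranch | None = None,
    losses: LossConfig | None = None,
    f_R: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-section complex pressure and flow at a single drive frequency.

    The cascade is driven by a unit flow source at the glottis and loaded by
    the radiation impedance at the lips; values are reported at the midpoint
    of every main-tract section.  Normalization is arbitrary (it cancels in
    the sensitivity-function energy ratio).
    """
    if f_R <= 0:
        raise ValueError("f_R must be positive")
    cfg = (losses or LossConfig()).effective()
    areas = _validate_areas(af)
    omega = np.array([2.0 * np.pi * f_R])
    a, b, c_, d = _cascade(af, branch, cfg, omega)
    zrad = radiation_impedance(float(areas[-1]), omega, cfg)
    z_in = (a * zrad + b) / (c_ * zrad + d)

    u_g = 1.0 + 0.0j
    p = z_in[0] * u_g
    u = u_g
    ch, sh, zc = _segment_terms(areas, af.grid.section_length, omega, cfg)
    chh, shh, _ = _segment_terms(areas, af.grid.section_length / 2.0, omega, cfg)
    yb = ib = None
    if branch is not None:
        yb = _branch_admittance(branch, omega, cfg)[0]
        ib = branch.attach_index(af.grid)
    pressures = np.empty(len(areas), dtype=complex)
    flows = np.empty(len(areas), dtype=complex)
    for i in range(len(areas)):
        # midpoint: advance the glottis-side state half a section lipward
        pm = chh[i, 0] * p - zc[i, 0] * shh[i, 0] * u
        um = -shh[i, 0] / zc[i, 0] * p + chh[i, 0] * u
        pressures[i], flows[i] = pm, um
        # full section, then any branch shunt at its lip-side edge
        p, u = (
            ch[i, 0] * p - zc[i, 0] * sh[i, 0] * u,
            -sh[i, 0] / zc[i, 0] * p + ch[i, 0] * u,
        )
        if ib is not None and i == ib:
            u = u - yb * p
    return pressures, flows
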