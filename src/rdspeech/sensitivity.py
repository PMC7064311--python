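"""Acoustic sensitivity functions and their balanced normalization.

For each of the first three tract resonances the sensitivity function

    S_j(i) = (Ke_j(i) - Pe_j(i)) / sum_i (Ke_j(i) + Pe_j(i))

describes, to first order, how a small fractional change of cross-sectional
area at section ``i`` shifts resonance ``j``:

    df_Rj / f_Rj = sum_i S_j(i) * dA(i) / A(i).

``Ke`` and ``Pe`` are the per-section kinetic and potential acoustic
energies of the resonant mode, computed from the modal flow and pressure of
the transmission-line model.  A constriction (negative area change) where
``S_j > 0`` lowers the resonance, and raises it where ``S_j < 0``.

Because raw sensitivities can be dominated by a few sections, a balancing
adjustment equalizes their magnitude profile along the tract: the polarity
is stored, ``|S_j|`` is low-pass filtered along the section axis
(second-order Butterworth, normalized cutoff 0.1) into a trend, the trend is
offset so it everywhere bounds ``|S_j|``, and the detrended magnitude is
re-signed and normalized to unit peak, yielding ``Z_j(i)`` in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .acoustics import (
    LossConfig,
    ResonanceSet,
    modal_distributions,
    resonances,
)
from .geometry import AreaFunction, SideBranch

__all__ = [
    "EnergyDensities",
    "SensitivityFunctions",
    "energies",
    "sensitivity_functions",
    "predict_shift",
    "adjust_and_normalize",
]


class DegenerateSensitivityError(ValueError):
    """The sensitivity adjustment received an unusable (all-zero) input."""


@dataclass
class EnergyDensities:
    """Per-section kinetic and potential acoustic energies (erg)."""

    kinetic: np.ndarray
    potential: np.ndarray


@dataclass
class SensitivityFunctions:
    """Raw ``S_j(i)`` and adjusted/normalized ``Z_j(i)`` for j = 1..3."""

    S: np.ndarray                    # shape (3, N_x)
    Z: np.ndarray                    # shape (3, N_x), max |Z_j| = 1
    source_resonances: ResonanceSet


def energies(
    af: AreaFunction,
    p: np.ndarray,
    u: np.ndarray,
    rho: float = 1.14e-3,
    c: float = 35_000.0,
) -> EnergyDensities:
    """Standard per-tubelet acoustic energies of a mode.

    Kinetic: ``(rho L / 2 A) |u|^2`` (acoustic inertance of the air slug);
    potential: ``(A L / 2 rho c^2) |p|^2`` (compliance of the air volume).
    """
    areas = np.asarray(af.areas, dtype=float)
    if np.any(areas <= 0):
        raise DegenerateSensitivityError("zero area section: energies undefined")
    L = af.grid.section_length
    ke = rho * L / (2.0 * areas) * np.abs(np.asarray(u)) ** 2
    pe = areas * L / (2.0 * rho * c * c) * np.abs(np.asarray(p)) ** 2
    return EnergyDensities(ke, pe)


def sensitivity_functions(
    af: AreaFunction,
    branch: SideBranch | None = None,
    losses: LossConfig | None = None,
    res: ResonanceSet | None = None,
    adjusted: bool = True,
) -> SensitivityFunctions:
    """Compute ``S_j(i)`` (and ``Z_j(i)``) for the first three resonances.

    ``res`` may carry precomputed resonance frequencies to skip the search;
    modal pressure/flow distributions are always recomputed here.
    """
    cfg = losses or LossConfig()
    if res is None:
        res = resonances(af, branch, cfg)
    n = len(res.f_R)
    nx = af.n_sections
    S = np.empty((n, nx))
    pressures = np.empty((n, nx), dtype=complex)
    flows = np.empty((n, nx), dtype=complex)
    for j, f in enumerate(res.f_R):
        p, u = modal_distributions(af, branch, cfg, float(f))
        e = energies(af, p, u, rho=cfg.air_density, c=cfg.sound_speed)
        total = float(np.sum(e.kinetic + e.potential))
        if total <= 0:
            raise DegenerateSensitivityError("zero total modal energy")
        S[j] = (e.kinetic - e.potential) / total
        pressures[j], flows[j] = p, u
    res_full = ResonanceSet(res.f_R, pressures, flows)
    Z = np.array([adjust_and_normalize(s) for s in S]) if adjusted else np.zeros_like(S)
    return SensitivityFunctions(S, Z, res_full)


def predict_shift(sens: SensitivityFunctions, rel_area_change: np.ndarray) -> np.ndarray:
    """First-order relative resonance shifts for a fractional area change.

    Returns ``df_Rj / f_Rj = sum_i S_j(i) * dA(i)/A(i)`` for each resonance.
    """
    d = np.asarray(rel_area_change, dtype=float)
    if d.shape != (sens.S.shape[1],):
        raise ValueError("perturbation vector not aligned with the tract")
    return sens.S @ d


def adjust_and_normalize(S_j: np.ndarray, cutoff: float = 0.1) -> np.ndarray:
    """Balance and normalize one sensitivity function to ``Z_j(i)``.

    Steps: store polarity Q(i); low-pass ``|S_j|`` along the section axis
    (second-order Butterworth, zero-phase, normalized cutoff ``cutoff`` as a
    fraction of the spatial Nyquist, reflect-padded) into R(i); form the
    bounding trend ``Ro(i) = R(i) + max(|S_j| - R)``; detrend and re-sign
    ``Ra(i) = (|S_j|/Ro) Q``; normalize ``Z_j = Ra / max|Ra|``.

    Guarantees ``max |Z_j| = 1`` and ``sign(Z_j) = sign(S_j)`` wherever
    ``S_j != 0``.
    """
    s = np.asarray(S_j, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("S_j must be finite")
    if np.all(s == 0):
        raise DegenerateSensitivityError("all-zero sensitivity function")
    q = np.where(s >= 0, 1.0, -1.0)
    mag = np.abs(s)
    b, a = butter(2, cutoff)
    pad = 3 * max(len(b), len(a))
    padded = np.concatenate([mag[pad:0:-1], mag, mag[-2 : -pad - 2 : -1]])
    r = filtfilt(b, a, padded, padlen=0)[pad : pad + len(mag)]
    r_o = r + np.max(mag - r)
    if np.any(r_o <= 0):
        raise DegenerateSensitivityError("non-positive trend in adjustment")
    r_a = (mag / r_o) * q
    peak = np.max(np.abs(r_a))
    if peak == 0:
        raise DegenerateSensitivityError("adjustment collapsed to zero")
    return r_a / peak
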