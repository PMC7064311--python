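"""Tubelet-based vocal tract geometry.

The vocal tract is discretized into ``N_x`` contiguous uniform cylindrical
sections ("tubelets") of equal length ``L = c / (2 F_s)``, where ``c`` is the
speed of sound and ``F_s`` the acoustic sampling rate.  This coupling of the
spatial and temporal grids is what the time-domain wave-propagation
synthesizer requires: one section corresponds to one one-way travel sample.

Orientation is glottis-first everywhere: section ``i = 1`` is adjacent to the
glottis and section ``i = N_x`` terminates at the lips.  The distance of
section ``i`` from the glottis is the lip-side edge ``x(i) = i * L``.
Internally arrays are stored 0-based; all file I/O and documentation use the
1-based convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TubeletGrid",
    "AreaFunction",
    "SideBranch",
    "make_grid",
    "uniform_tract",
    "neutral_tract_standin",
    "default_side_branch",
    "read_area_table",
    "write_area_table",
]

#: default number of tubelet sections for an adult male tract
DEFAULT_N_SECTIONS = 44
#: speed of sound in warm humid air, cm/s
SOUND_SPEED = 35_000.0
#: acoustic sampling rate, Hz
AUDIO_RATE = 44_100.0


class InvalidParameterError(ValueError):
    """A constructor argument violates its physical constraint."""


class AreaTableFormatError(ValueError):
    """A delimited-text area table is malformed."""


@dataclass(frozen=True)
class TubeletGrid:
    """Spatial discretization of the tract: ``n_sections`` tubelets of
    length ``section_length = sound_speed / (2 * acoustic_sampling_rate)``."""

    n_sections: int = DEFAULT_N_SECTIONS
    sound_speed: float = SOUND_SPEED
    acoustic_sampling_rate: float = AUDIO_RATE

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise InvalidParameterError("n_sections must be >= 1")
        if self.sound_speed <= 0 or self.acoustic_sampling_rate <= 0:
            raise InvalidParameterError(
                "sound_speed and acoustic_sampling_rate must be positive"
            )

    @property
    def section_length(self) -> float:
        """Tubelet length in cm, ``c / (2 F_s)``."""
        return self.sound_speed / (2.0 * self.acoustic_sampling_rate)

    @property
    def total_length(self) -> float:
        """Overall tract length in cm."""
        return self.n_sections * self.section_length

    def distances(self) -> np.ndarray:
        """Distance from the glottis of each section's lip-side edge, cm."""
        return self.section_length * np.arange(1, self.n_sections + 1)


def make_grid(
    n_sections: int = DEFAULT_N_SECTIONS,
    sound_speed: float = SOUND_SPEED,
    sampling_rate: float = AUDIO_RATE,
) -> TubeletGrid:
    """Build a :class:`TubeletGrid`; all arguments must be positive."""
    return TubeletGrid(n_sections, sound_speed, sampling_rate)


@dataclass
class AreaFunction:
    """Cross-sectional areas (cm^2) on a tubelet grid, glottis to lips."""

    grid: TubeletGrid
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1 or len(self.areas) != self.grid.n_sections:
            raise InvalidParameterError(
                f"expected {self.grid.n_sections} areas, got {self.areas.shape}"
            )
        if np.any(self.areas < 0):
            raise InvalidParameterError("areas must be non-negative")

    @property
    def n_sections(self) -> int:
        return self.grid.n_sections

    def copy(self) -> "AreaFunction":
        return AreaFunction(self.grid, self.areas.copy())

    def with_areas(self, areas: np.ndarray) -> "AreaFunction":
        return AreaFunction(self.grid, np.asarray(areas, dtype=float))


@dataclass
class SideBranch:
    """Short closed side tube (piriform sinuses) coupled to the main tract.

    ``attach_distance`` is measured in cm from the glottis; the branch joins
    the main tract at the junction nearest that distance.  The far end is
    acoustically closed (zero flow).
    """

    attach_distance: float = 2.4
    branch_areas: np.ndarray = field(
        default_factory=lambda: np.linspace(1.2, 0.25, 8)
    )
    branch_section_length: float = SOUND_SPEED / (2.0 * AUDIO_RATE)

    def __post_init__(self) -> None:
        self.branch_areas = np.asarray(self.branch_areas, dtype=float)
        if self.attach_distance <= 0:
            raise InvalidParameterError("attach_distance must be positive")
        if np.any(self.branch_areas <= 0):
            raise InvalidParameterError("branch areas must be positive")
        if self.branch_section_length <= 0:
            raise InvalidParameterError("branch_section_length must be positive")

    def attach_index(self, grid: TubeletGrid) -> int:
        """0-based index of the main-tract section whose lip-side edge is
        nearest ``attach_distance``."""
        idx = int(round(self.attach_distance / grid.section_length)) - 1
        if not 0 <= idx < grid.n_sections:
            raise InvalidParameterError(
                f"attach_distance {self.attach_distance} cm falls outside the tract"
            )
        return idx


def default_side_branch() -> SideBranch:
    """Piriform branch stand-in: 8 sections tapering 1.5 -> 0.3 cm^2,
    attached 2.4 cm above the glottis, closed far end."""
    return SideBranch()


def uniform_tract(grid: TubeletGrid, area: float = 3.0) -> AreaFunction:
    """Uniform tube of the given cross-sectional area (cm^2)."""
    if area <= 0:
        raise InvalidParameterError("area must be positive")
    return AreaFunction(grid, np.full(grid.n_sections, float(area)))


# Control points of the parametric neutral-tract stand-in: (distance from
# glottis, cm; area, cm^2).  Narrow laryngeal inlet, wider pharynx, mild oral
# taper toward moderately open lips -- qualitatively an adult-male schwa.
_NEUTRAL_CONTROL_X = np.array(
    [0.0, 0.8, 1.8, 3.0, 4.5, 6.5, 9.0, 11.5, 13.5, 15.5, 16.8, 17.46]
)
_NEUTRAL_CONTROL_A = np.array(
    [0.40, 0.50, 0.90, 1.60, 2.40, 2.90, 2.90, 2.50, 2.10, 1.60, 1.25, 1.10]
)


def neutral_tract_standin(grid: TubeletGrid | None = None) -> AreaFunction:
    """Parametric neutral (schwa-like) area function.

    The published adult-male neutral tract is not tabulated here; this
    stand-in is a smooth, strictly positive monotone-spline (PCHIP) profile
    through plausible control points, deterministic for a fixed grid.  Users
    with the published table should load it with :func:`read_area_table`.
    """
    if grid is None:
        grid = make_grid()
    x = grid.distances() - 0.5 * grid.section_length  # section midpoints
    # rescale control points to the grid's actual total length
    scale = grid.total_length / _NEUTRAL_CONTROL_X[-1]
    spline = PchipInterpolator(_NEUTRAL_CONTROL_X * scale, _NEUTRAL_CONTROL_A)
    areas = np.asarray(spline(x), dtype=float)
    return AreaFunction(grid, areas)


_TABLE_HEADER = "# index distance_cm area_cm2"


def write_area_table(af: AreaFunction, path) -> None:
    """Write a delimited-text area table (1-based index, glottis first)."""
    dist = af.grid.distances()
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER + "\n")
        for i, (d, a) in enumerate(zip(dist, af.areas), start=1):
            fh.write(f"{i}\t{d:.9f}\t{a:.9f}\n")


def read_area_table(path, grid: TubeletGrid | None = None) -> AreaFunction:
    """Read a delimited-text area table written by :func:`write_area_table`.

    Columns are (index, distance_cm, area_cm2) with 1-based indices in
    glottis-first order.  Distances must be strictly increasing and areas
    non-negative.  If ``grid`` is given its section count must match;
    otherwise a grid is reconstructed from the number of rows and the
    default sound speed / sampling rate.
    """
    rows: list[tuple[int, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", "\t").split()
            if len(parts) != 3:
                raise AreaTableFormatError(
                    f"line {lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                idx, d, a = int(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise AreaTableFormatError(f"line {lineno}: {exc}") from exc
            if a < 0:
                raise AreaTableFormatError(f"line {lineno}: negative area {a}")
            rows.append((idx, d, a))
    if not rows:
        raise AreaTableFormatError("empty area table")
    indices = [r[0] for r in rows]
    if indices != list(range(1, len(rows) + 1)):
        raise AreaTableFormatError("indices must run 1..N in order")
    dist = np.array([r[1] for r in rows])
    if np.any(np.diff(dist) <= 0):
        bad = int(np.argmax(np.diff(dist) <= 0)) + 2
        raise AreaTableFormatError(f"line {bad}: distances not strictly increasing")
    if grid is None:
        grid = make_grid(n_sections=len(rows))
    elif grid.n_sections != len(rows):
        raise AreaTableFormatError(
            f"table has {len(rows)} rows but grid declares {grid.n_sections} sections"
        )
    return AreaFunction(grid, np.array([r[2] for r in rows]))
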