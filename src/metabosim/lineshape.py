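"""Lorentzian rendering of peak lists onto uniformly sampled ppm grids.

Peaks carry a position (ppm), a height (arbitrary units; databases store
heights, not areas) and a full width at half maximum in Hz, which is
field independent; rendering converts it to ppm by dividing by the
spectrometer frequency in MHz.  A rendered spectrum is the plain sum of
height-parameterized Lorentzians — no noise, apodization or baseline is
added here, mirroring the idealized character of simulated references.

The ppm axis is stored strictly decreasing (NMR display convention), with
the closed interval endpoints included: spacing (first - last)/(n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import ValidationError

__all__ = [
    "Peak",
    "PeakList",
    "SpectrumGrid",
    "lorentzian_profile",
    "render",
    "mixture",
    "write_xy",
    "read_xy",
    "write_jcamp",
    "read_jcamp",
]


@dataclass
class Peak:
    """One Lorentzian line: ppm position, height, FWHM in Hz.

    ``width_hz`` may be ``None`` for database entries whose source lacked
    width data; such peaks cannot be rendered until a placeholder width is
    assigned (``width_is_placeholder`` then records that the value is not a
    measurement).
    """

    position_ppm: float
    height: float
    width_hz: Optional[float] = None
    multiplet_id: Optional[str] = None
    peak_id: Optional[str] = None
    width_is_placeholder: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.position_ppm):
            raise ValidationError("peak position must be finite")
        if not np.isfinite(self.height):
            raise ValidationError("peak height must be finite")
        if self.width_hz is not None and not self.width_hz > 0:
            raise ValidationError("peak width must be positive when set")


@dataclass
class PeakList:
    """Ordered collection of peaks with provenance.

    ``source_kind`` distinguishes annotated (picked from experimental
    spectra) from spin-system-derived peak lists.
    """

    peaks: list[Peak] = field(default_factory=list)
    source_kind: str = "annotated"
    provenance: Optional[str] = None

    _KINDS = ("annotated", "spin_system")

    def __post_init__(self) -> None:
        if self.source_kind not in self._KINDS:
            raise ValidationError(
                f"source_kind must be one of {self._KINDS}"
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def scaled_widths(self, factor: float) -> "PeakList":
        """Copy with every width multiplied by ``factor``."""
        if factor <= 0:
            raise ValidationError("width factor must be positive")
        return PeakList(
            peaks=[
                Peak(
                    position_ppm=p.position_ppm,
                    height=p.height,
                    width_hz=None if p.width_hz is None else p.width_hz * factor,
                    multiplet_id=p.multiplet_id,
                    peak_id=p.peak_id,
                    width_is_placeholder=p.width_is_placeholder,
                )
                for p in self.peaks
            ],
            source_kind=self.source_kind,
            provenance=self.provenance,
        )

    def shifted(self, offset_ppm: float) -> "PeakList":
        """Copy with every position moved by ``offset_ppm``."""
        return PeakList(
            peaks=[
                Peak(
                    position_ppm=p.position_ppm + offset_ppm,
                    height=p.height,
                    width_hz=p.width_hz,
                    multiplet_id=p.multiplet_id,
                    peak_id=p.peak_id,
                    width_is_placeholder=p.width_is_placeholder,
                )
                for p in self.peaks
            ],
            source_kind=self.source_kind,
            provenance=self.provenance,
        )


_AXIS_TOL = 1e-9  # ppm; required uniformity of the axis spacing


@dataclass
class SpectrumGrid:
    """Uniformly sampled 1D spectrum: decreasing ppm axis + intensities."""

    spectrometer_mhz: float
    ppm_axis: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.spectrometer_mhz <= 0:
            raise ValidationError("spectrometer_mhz must be positive")
        if self.ppm_axis.size < 2:
            raise ValidationError("grid needs at least 2 points")
        if self.ppm_axis.shape != self.intensities.shape:
            raise ValidationError("axis and intensities differ in length")
        d = np.diff(self.ppm_axis)
        if not np.all(d < 0):
            raise ValidationError("ppm axis must be strictly decreasing")
        if np.ptp(d) > _AXIS_TOL:
            raise ValidationError(
                f"ppm axis spacing not uniform to {_AXIS_TOL} ppm"
            )

    @property
    def step_ppm(self) -> float:
        """Magnitude of the (uniform) axis spacing."""
        return float(self.ppm_axis[0] - self.ppm_axis[1])

    @property
    def n_points(self) -> int:
        return self.ppm_axis.size

    def same_axis(self, other: "SpectrumGrid", tol: float = _AXIS_TOL) -> bool:
        return (
            self.ppm_axis.size == other.ppm_axis.size
            and np.allclose(self.ppm_axis, other.ppm_axis, atol=tol, rtol=0.0)
            and np.isclose(
                self.spectrometer_mhz, other.spectrometer_mhz, rtol=1e-9
            )
        )

    def with_intensities(self, values: np.ndarray) -> "SpectrumGrid":
        return SpectrumGrid(
            spectrometer_mhz=self.spectrometer_mhz,
            ppm_axis=self.ppm_axis.copy(),
            intensities=np.asarray(values, dtype=float),
        )

    def slice_indices(self, ppm_high: float, ppm_low: float) -> np.ndarray:
        """Indices of axis points inside [ppm_low, ppm_high]."""
        mask = (self.ppm_axis <= ppm_high + _AXIS_TOL) & (
            self.ppm_axis >= ppm_low - _AXIS_TOL
        )
        return np.nonzero(mask)[0]


def lorentzian_profile(
    x: Union[float, np.ndarray], height: float, width_ppm: float
) -> Union[float, np.ndarray]:
    """Height-parameterized Lorentzian evaluated at offset ``x`` from center.

    value(0) = height, value(±width/2) = height/2; the analytic area is
    pi * height * width_ppm / 2.
    """
    if not width_ppm > 0:
        raise ValidationError("width must be positive")
    gamma = width_ppm / 2.0
    return height * gamma**2 / (np.asarray(x, dtype=float) ** 2 + gamma**2)


def render(
    peaklist: Union[PeakList, Iterable[Peak]],
    spectrometer_mhz: float,
    ppm_first: float,
    ppm_last: float,
    n_points: int,
) -> SpectrumGrid:
    """Sum of Lorentzians over a uniform grid from ppm_first down to ppm_last.

    Peaks outside the window still contribute their tails; nothing is
    truncated.  Matching an experimental grid is a matter of passing its
    window and point count.
    """
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if not ppm_first > ppm_last:
        raise ValidationError("ppm_first must exceed ppm_last")
    if spectrometer_mhz <= 0:
        raise ValidationError("spectrometer_mhz must be positive")
    axis = np.linspace(ppm_first, ppm_last, n_points)
    total = np.zeros(n_points)
    for p in peaklist:
        if p.width_hz is None:
            raise ValidationError(
                f"peak {p.peak_id or p.position_ppm} has no width; assign a "
                "placeholder width before rendering"
            )
        width_ppm = p.width_hz / spectrometer_mhz
        total += lorentzian_profile(axis - p.position_ppm, p.height, width_ppm)
    return SpectrumGrid(
        spectrometer_mhz=spectrometer_mhz, ppm_axis=axis, intensities=total
    )


def mixture(
    grids: Sequence[SpectrumGrid], concentrations: Sequence[float]
) -> SpectrumGrid:
    """Concentration-weighted pointwise sum of spectra on a shared axis."""
    if len(grids) == 0:
        raise ValidationError("mixture needs at least one grid")
    if len(grids) != len(concentrations):
        raise ValidationError("one concentration per grid required")
    ref = grids[0]
    total = np.zeros(ref.n_points)
    for g, c in zip(grids, concentrations):
        if c < 0:
            raise ValidationError("concentrations must be non-negative")
        if not ref.same_axis(g):
            raise ValidationError("all grids must share axis and field")
        total += c * g.intensities
    return ref.with_intensities(total)


# ---------------------------------------------------------------------------
# plain-text spectrum exchange


def write_xy(grid: SpectrumGrid, path) -> None:
    """Two-column delimited text (ppm, intensity) with a metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# spectrometer_mhz = {float(grid.spectrometer_mhz)!r}\n")
        fh.write("# columns: ppm intensity\n")
        for x, y in zip(grid.ppm_axis, grid.intensities):
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")


def read_xy(path) -> SpectrumGrid:
    mhz = None
    xs: list[float] = []
    ys: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "spectrometer_mhz" in line and "=" in line:
                    mhz = float(line.split("=", 1)[1])
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValidationError(f"bad spectrum line: {line!r}")
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
    if mhz is None:
        raise ValidationError(
            "spectrum file lacks a '# spectrometer_mhz = ...' header"
        )
    return SpectrumGrid(
        spectrometer_mhz=mhz, ppm_axis=np.array(xs), intensities=np.array(ys)
    )


def write_jcamp(grid: SpectrumGrid, path, title: str = "metabosim") -> None:
    """Minimal JCAMP-DX-like XY block (one x,y pair per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"##TITLE={title}\n")
        fh.write("##DATA TYPE=NMR SPECTRUM\n")
        fh.write(f"##.OBSERVE FREQUENCY={float(grid.spectrometer_mhz)!r}\n")
        fh.write("##XUNITS=PPM\n##YUNITS=ARBITRARY\n")
        fh.write(f"##NPOINTS={grid.n_points}\n")
        fh.write("##XYDATA=(XY..XY)\n")
        for x, y in zip(grid.ppm_axis, grid.intensities):
            fh.write(f"{float(x)!r}, {float(y)!r}\n")
        fh.write("##END=\n")


def read_jcamp(path) -> SpectrumGrid:
    mhz = None
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                if key == ".OBSERVE FREQUENCY":
                    mhz = float(value)
                in_data = key == "XYDATA"
                continue
            if in_data and line:
                x_str, _, y_str = line.partition(",")
                xs.append(float(x_str))
                ys.append(float(y_str))
    if mhz is None:
        raise ValidationError("JCAMP block lacks ##.OBSERVE FREQUENCY")
    return SpectrumGrid(
        spectrometer_mhz=mhz, ppm_axis=np.array(xs), intensities=np.array(ys)
    )
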