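"""Seeded generators for fixture spin systems, entries and noisy spectra.

Everything the other modules consume can be generated here without any
download: random (but connected) spin systems, complete database entries,
and "experimental-like" grids derived from a clean simulation by adding
the features real spectra have and simulations lack — chemical-shift
offset, line broadening, a slowly varying baseline, a reference peak at
0 ppm, a broad solvent signal near 4.7 ppm, and white noise.  All
randomness is fixed by the spec's integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .lineshape import Peak, PeakList, SpectrumGrid, lorentzian_profile, render
from .nef_io import MetaboliteEntry, Multiplet, Sample, Spectrum
from .spin_quantum import SpinSystemMatrix, simulate_peaklist

__all__ = [
    "SyntheticSpec",
    "make_spin_system",
    "make_experimental_like",
    "make_entry",
    "read_spec_file",
]

#: artifact defaults: reference singlet at 0 ppm, broad water line at 4.7 ppm
REFERENCE_PPM = 0.0
REFERENCE_WIDTH_HZ = 1.0
SOLVENT_PPM = 4.70
SOLVENT_WIDTH_HZ = 20.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fixture; the seed fixes all randomness."""

    seed: int = 0
    n_spins: int = 3
    shift_range_ppm: tuple[float, float] = (0.5, 9.0)
    coupling_dist_hz: tuple[float, float] = (7.0, 2.0)  # (mean, sd)
    noise_sd: float = 0.0  # fraction of max clean intensity
    baseline_amplitude: float = 0.0  # fraction of max clean intensity
    ppm_offset: float = 0.0
    width_scale: float = 1.0
    include_reference_peak: bool = False
    include_solvent: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.n_spins <= 12:
            raise ValidationError("n_spins must lie in [1, 12]")
        lo, hi = self.shift_range_ppm
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValidationError("shift_range_ppm must be a finite interval")
        if self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise ValidationError("noise/baseline amplitudes must be >= 0")
        if self.width_scale <= 0:
            raise ValidationError("width_scale must be positive")
        if not np.isfinite(self.ppm_offset):
            raise ValidationError("ppm_offset must be finite")


def make_spin_system(spec: SyntheticSpec) -> SpinSystemMatrix:
    """Random spin system: uniform shifts, couplings on a connected graph.

    Connectivity is a random tree (every spin coupled, directly or
    indirectly) plus occasional extra edges; J values are drawn from the
    normal coupling distribution.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_spins
    lo, hi = spec.shift_range_ppm
    shifts = np.sort(rng.uniform(lo, hi, size=n))
    couplings = np.zeros((n, n))
    mean, sd = spec.coupling_dist_hz
    for i in range(1, n):  # random spanning tree
        j = int(rng.integers(0, i))
        J = rng.normal(mean, sd)
        couplings[i, j] = couplings[j, i] = J
    for i in range(n):  # sparse extra edges
        for j in range(i + 1, n):
            if couplings[i, j] == 0.0 and rng.random() < 0.15:
                J = rng.normal(mean, sd)
                couplings[i, j] = couplings[j, i] = J
    labels = [f"H{i+1}" for i in range(n)]
    return SpinSystemMatrix(
        atom_labels=labels, shifts_ppm=shifts, couplings_hz=couplings
    )


def make_experimental_like(
    clean: SpectrumGrid,
    spec: SyntheticSpec,
    peaklist: Optional[PeakList] = None,
) -> SpectrumGrid:
    """Degrade a clean simulation into an experimental-looking grid.

    Applies, in order: ppm offset (axis re-interpolation), broadening by
    ``width_scale`` (an exact re-render when the peak list is known,
    otherwise convolution with a Lorentzian kernel), an additive low-order
    sinusoidal baseline, a reference peak at 0 ppm, a broad solvent line
    near 4.7 ppm, and white Gaussian noise with sd = noise_sd x max(clean).
    With every perturbation off this is the identity.
    """
    # seed sequence keyed off the spec seed, distinct from make_spin_system
    rng = np.random.default_rng([spec.seed, 1])
    axis = clean.ppm_axis
    mhz = clean.spectrometer_mhz
    ref_max = float(np.max(np.abs(clean.intensities))) or 1.0
    y = clean.intensities.copy()

    if spec.width_scale != 1.0:
        if peaklist is not None:
            y = render(
                peaklist.scaled_widths(spec.width_scale),
                mhz,
                float(axis[0]),
                float(axis[-1]),
                axis.size,
            ).intensities
        else:
            # Lorentzians convolve additively in width: kernel carries the
            # extra (scale - 1) x 1 Hz assuming placeholder-width lines
            extra_ppm = (spec.width_scale - 1.0) * 1.0 / mhz
            step = float(axis[0] - axis[1])
            half = int(min(axis.size, max(8, np.ceil(20 * extra_ppm / step))))
            kx = np.arange(-half, half + 1) * step
            kernel = lorentzian_profile(kx, 1.0, extra_ppm)
            kernel /= kernel.sum()
            y = np.convolve(y, kernel, mode="same")

    if spec.ppm_offset != 0.0:
        xi = axis[::-1]
        y = np.interp(axis - spec.ppm_offset, xi, y[::-1], left=0.0, right=0.0)

    if spec.baseline_amplitude > 0.0:
        t = (axis - axis[-1]) / (axis[0] - axis[-1])
        phase = rng.uniform(0.0, 2 * np.pi)
        y = y + spec.baseline_amplitude * ref_max * np.sin(
            2 * np.pi * 1.5 * t + phase
        )

    if spec.include_reference_peak:
        y = y + lorentzian_profile(
            axis - REFERENCE_PPM, 0.5 * ref_max, REFERENCE_WIDTH_HZ / mhz
        )
    if spec.include_solvent:
        y = y + lorentzian_profile(
            axis - SOLVENT_PPM, ref_max, SOLVENT_WIDTH_HZ / mhz
        )
    if spec.noise_sd > 0.0:
        y = y + rng.normal(0.0, spec.noise_sd * ref_max, size=axis.size)
    return clean.with_intensities(y)


def make_entry(
    spec: SyntheticSpec,
    spectrometer_mhz: float = 600.0,
    default_width_hz: float = 1.0,
) -> MetaboliteEntry:
    """Complete valid metabolite entry with spin system and derived peaks.

    The InChI-like tag is synthetic (unique per seed), not a real chemical
    identifier.
    """
    ssm = make_spin_system(spec)
    peaks = simulate_peaklist(
        ssm, spectrometer_mhz, default_width_hz=default_width_hz
    )
    rng = np.random.default_rng([spec.seed, 2])
    formula = f"C{int(rng.integers(2, 12))}H{spec.n_spins}O{int(rng.integers(1, 6))}"
    entry_id = f"SYN{spec.seed:06d}"
    ssm.entry_ref = entry_id

    multiplets: dict[str, list] = {}
    for p in peaks:
        multiplets.setdefault(p.multiplet_id, []).append(p)
    mlist = [
        Multiplet(
            multiplet_id=mid,
            center_ppm=float(
                np.average(
                    [p.position_ppm for p in plist],
                    weights=[p.height for p in plist],
                )
            ),
            atom_assignment=None,
            member_peak_ids=[p.peak_id for p in plist],
        )
        for mid, plist in sorted(multiplets.items())
    ]
    spectrum = Spectrum(
        spectrum_id=f"{entry_id}_SP1",
        spectrometer_mhz=spectrometer_mhz,
        peaklist=peaks,
        spin_system=ssm,
        multiplets=mlist,
    )
    sample = Sample(
        sample_id=f"{entry_id}_S1",
        ph=7.0,
        solvent="D2O",
        reference_compound="DSS",
        temperature_k=298.0,
        source_accession=f"syn{spec.seed:06d}",
        spectra=[spectrum],
    )
    entry = MetaboliteEntry(
        entry_id=entry_id,
        inchi=f"InChI=1S/{formula}/synthetic-{spec.seed}",
        name=f"synthetic metabolite {spec.seed}",
        smiles=None,
        synonyms=[f"syn-{spec.seed}"],
        accessions={"hmdb": f"SYNHMDB{spec.seed:07d}"},
        samples=[sample],
    )
    entry.validate()
    return entry


def read_spec_file(path) -> SyntheticSpec:
    """Read a SyntheticSpec from a plain ``key = value`` config file."""
    values: dict[str, object] = {}
    known = {f.name: f.type for f in fields(SyntheticSpec)}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"bad config line: {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValidationError(f"unknown spec key {key!r}")
            if key in ("seed", "n_spins"):
                values[key] = int(raw)
            elif key in ("include_reference_peak", "include_solvent"):
                values[key] = raw.lower() in ("1", "true", "yes", "on")
            elif key in ("shift_range_ppm", "coupling_dist_hz"):
                a, b = raw.replace(",", " ").split()
                values[key] = (float(a), float(b))
            else:
                values[key] = float(raw)
    return SyntheticSpec(**values)
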