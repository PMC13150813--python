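"""Exact quantum-mechanical simulation of spin-1/2 proton systems.

A metabolite's 1D 1H signature is field independent when abstracted as a
spin-system matrix: chemical shifts in ppm plus the symmetric matrix of
scalar J-couplings in Hz.  At a given spectrometer frequency the lab-frame
Hamiltonian (in Hz) is

    H = sum_i nu_i Iz(i) + sum_{i<j} J_ij (Ix(i)Ix(j) + Iy(i)Iy(j) + Iz(i)Iz(j))

with nu_i = shift_ppm[i] * spectrometer_mhz, so that larger ppm means higher
frequency.  Strong-coupling (second-order) effects — roof-effect intensity
asymmetry, extra lines, field-dependent multiplet shapes — emerge naturally
from diagonalization; no first-order approximation is made.

Single-quantum transitions are read off between eigenstates of adjacent
total-magnetization sectors; intensities are squared matrix elements of the
total Ix operator, scaled so that one isolated spin carries total intensity
1 (equivalently, the exact trace identity: total intensity = number of
spins, independent of field strength).

The exact treatment scales exponentially in spin count (the per-transition
work grows roughly cubically with matrix dimension), so systems are capped
at ``max_spins`` (default 12); larger metabolites need segmenting
approximations that are out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ComplexityError, ValidationError
from .lineshape import Peak, PeakList

__all__ = [
    "SpinSystemMatrix",
    "Transition",
    "build_hamiltonian",
    "transitions",
    "simulate_peaklist",
    "DEFAULT_MAX_SPINS",
]

DEFAULT_MAX_SPINS = 12
#: relative intensity below which transitions are discarded
INTENSITY_CUTOFF = 1e-9
#: transitions closer than this (Hz) are merged by summing intensities
MERGE_TOL_HZ = 1e-6

_SHIFT_RANGE_WARN = (-1.0, 12.0)


@dataclass
class SpinSystemMatrix:
    """Proton chemical shifts (ppm) plus symmetric J-coupling matrix (Hz).

    The field-independent abstraction of a metabolite's 1H spectrum:
    rendering it at any spectrometer frequency reproduces the correct
    first- and second-order multiplet structure.
    """

    atom_labels: list[str]
    shifts_ppm: np.ndarray
    couplings_hz: np.ndarray
    entry_ref: Optional[str] = None

    def __post_init__(self) -> None:
        self.shifts_ppm = np.asarray(self.shifts_ppm, dtype=float)
        self.couplings_hz = np.asarray(self.couplings_hz, dtype=float)
        n = self.shifts_ppm.size
        if self.shifts_ppm.ndim != 1:
            raise ValidationError("shifts_ppm must be one-dimensional")
        if len(self.atom_labels) != n:
            raise ValidationError(
                f"{len(self.atom_labels)} atom labels for {n} shifts"
            )
        if len(set(self.atom_labels)) != n:
            raise ValidationError("atom_labels must be unique")
        if self.couplings_hz.shape != (n, n):
            raise ValidationError(
                f"coupling matrix shape {self.couplings_hz.shape} does not "
                f"match {n} spins"
            )
        if not np.all(np.isfinite(self.shifts_ppm)):
            raise ValidationError("non-finite chemical shift")
        if not np.all(np.isfinite(self.couplings_hz)):
            raise ValidationError("non-finite coupling constant")
        if n and not np.allclose(
            self.couplings_hz, self.couplings_hz.T, atol=1e-9, rtol=0.0
        ):
            raise ValidationError("coupling matrix must be symmetric")
        if n and np.any(np.abs(np.diag(self.couplings_hz)) > 1e-12):
            raise ValidationError("coupling matrix diagonal must be zero")
        lo, hi = _SHIFT_RANGE_WARN
        if n and (self.shifts_ppm.min() < lo or self.shifts_ppm.max() > hi):
            warnings.warn(
                "chemical shift outside the usual 1H range "
                f"[{lo}, {hi}] ppm",
                stacklevel=2,
            )

    @property
    def n_spins(self) -> int:
        return self.shifts_ppm.size


@dataclass(frozen=True)
class Transition:
    """A single-quantum line: frequency (Hz) and non-negative intensity."""

    frequency_hz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError("transition intensity must be >= 0")


def _check_size(n: int, max_spins: int) -> None:
    if n > max_spins:
        raise ComplexityError(
            f"spin system has {n} spins, above the limit of {max_spins}: "
            "the exact simulation cost grows roughly cubically with the "
            "2^n matrix dimension, so large systems need segmenting "
            "approximations (not implemented)"
        )


def build_hamiltonian(
    ssm: SpinSystemMatrix,
    spectrometer_mhz: float,
    max_spins: int = DEFAULT_MAX_SPINS,
) -> np.ndarray:
    """Dense real-symmetric spin Hamiltonian (Hz) in the 2^n product basis.

    Basis states are indexed by bitmask: bit *i* set means spin *i* is
    "up" (m = +1/2).  The isotropic J term contributes diagonal
    J_ij m_i m_j pieces plus flip-flop elements J_ij/2 between states that
    differ by one up-down exchange, so the matrix is real.
    """
    n = ssm.n_spins
    if spectrometer_mhz <= 0:
        raise ValidationError("spectrometer_mhz must be positive")
    _check_size(n, max_spins)
    nu = ssm.shifts_ppm * spectrometer_mhz  # Hz
    dim = 1 << n
    H = np.zeros((dim, dim))
    states = np.arange(dim)
    m = np.array(
        [((states >> i) & 1) - 0.5 for i in range(n)]
    )  # (n, dim) single-spin m values
    diag = nu @ m
    for i in range(n):
        for j in range(i + 1, n):
            if ssm.couplings_hz[i, j] != 0.0:
                diag = diag + ssm.couplings_hz[i, j] * m[i] * m[j]
    H[states, states] = diag
    for i in range(n):
        for j in range(i + 1, n):
            J = ssm.couplings_hz[i, j]
            if J == 0.0:
                continue
            # flip-flop: states with spin i up, spin j down <-> swapped
            mask_i, mask_j = 1 << i, 1 << j
            sel = states[((states & mask_i) != 0) & ((states & mask_j) == 0)]
            partner = sel ^ (mask_i | mask_j)
            H[sel, partner] += J / 2.0
            H[partner, sel] += J / 2.0
    return H


def _sector_indices(n: int) -> list[np.ndarray]:
    """Basis indices grouped by number of up spins (0..n)."""
    states = np.arange(1 << n)
    pops = np.array([bin(s).count("1") for s in states])
    return [states[pops == k] for k in range(n + 1)]


def transitions(
    ssm: SpinSystemMatrix,
    spectrometer_mhz: float,
    max_spins: int = DEFAULT_MAX_SPINS,
    intensity_cutoff: float = INTENSITY_CUTOFF,
    merge_tol_hz: float = MERGE_TOL_HZ,
    _tag_spins: bool = False,
):
    """Single-quantum transitions of the spin system at the given field.

    Diagonalizes the Hamiltonian block-wise (total Fz commutes with H), then
    evaluates |<f| Fx |i>|^2 between eigenstates of adjacent sectors.
    Intensities are scaled by 2^(3-n) so the total is exactly the spin
    count.  Lines weaker than ``intensity_cutoff`` relative to the
    strongest are dropped; lines closer than ``merge_tol_hz`` are merged by
    summing intensities (intensity-weighted mean frequency).

    Returns a list of :class:`Transition`, sorted by frequency.  With
    ``_tag_spins`` a parallel list of dominant-spin indices is returned as
    well (used to assign peaks to multiplets).
    """
    n = ssm.n_spins
    if spectrometer_mhz <= 0:
        raise ValidationError("spectrometer_mhz must be positive")
    _check_size(n, max_spins)
    if n == 0:
        return ([], []) if _tag_spins else []

    H = build_hamiltonian(ssm, spectrometer_mhz, max_spins=max_spins)
    sectors = _sector_indices(n)
    eig = []
    for idx in sectors:
        block = H[np.ix_(idx, idx)]
        E, V = np.linalg.eigh(block)
        eig.append((idx, E, V))

    scale = 2.0 ** (3 - n)
    freqs: list[float] = []
    raw_int: list[float] = []
    spin_tag: list[int] = []
    for k in range(1, n + 1):
        idx_hi, E_hi, V_hi = eig[k]       # sector with k spins up
        idx_lo, E_lo, V_lo = eig[k - 1]   # one spin fewer up
        # product-basis Ix blocks: element 1/2 between states differing by
        # one spin flip
        pos_lo = {s: r for r, s in enumerate(idx_lo)}
        Fx = np.zeros((idx_lo.size, idx_hi.size))
        per_spin = (
            [np.zeros((idx_lo.size, idx_hi.size)) for _ in range(n)]
            if _tag_spins
            else None
        )
        for c, s in enumerate(idx_hi):
            for i in range(n):
                if s & (1 << i):
                    r = pos_lo[s ^ (1 << i)]
                    Fx[r, c] = 0.5
                    if per_spin is not None:
                        per_spin[i][r, c] = 0.5
        X = V_lo.T @ Fx @ V_hi            # (n_lo, n_hi) amplitudes
        inten = scale * X**2
        fr = E_hi[None, :] - E_lo[:, None]
        keep = inten > 0.0
        freqs.extend(fr[keep].tolist())
        raw_int.extend(inten[keep].tolist())
        if per_spin is not None:
            amps = np.stack(
                [np.abs(V_lo.T @ S @ V_hi)[keep] for S in per_spin]
            )
            spin_tag.extend(np.argmax(amps, axis=0).tolist())

    freqs_a = np.asarray(freqs)
    int_a = np.asarray(raw_int)
    tags_a = np.asarray(spin_tag) if _tag_spins else None
    if int_a.size == 0:
        return ([], []) if _tag_spins else []

    # drop negligibly weak lines
    keep = int_a >= intensity_cutoff * int_a.max()
    freqs_a, int_a = freqs_a[keep], int_a[keep]
    if tags_a is not None:
        tags_a = tags_a[keep]

    order = np.argsort(freqs_a, kind="stable")
    freqs_a, int_a = freqs_a[order], int_a[order]
    if tags_a is not None:
        tags_a = tags_a[order]

    # merge near-degenerate lines
    out: list[Transition] = []
    out_tags: list[int] = []
    start = 0
    for stop in range(1, freqs_a.size + 1):
        if (
            stop == freqs_a.size
            or freqs_a[stop] - freqs_a[stop - 1] > merge_tol_hz
        ):
            grp_f = freqs_a[start:stop]
            grp_i = int_a[start:stop]
            total = grp_i.sum()
            out.append(
                Transition(
                    frequency_hz=float(np.average(grp_f, weights=grp_i)),
                    intensity=float(total),
                )
            )
            if tags_a is not None:
                out_tags.append(int(tags_a[start:stop][np.argmax(grp_i)]))
            start = stop
    if _tag_spins:
        return out, out_tags
    return out


def _proton_groups(ssm: SpinSystemMatrix, tol_ppm: float = 1e-6) -> np.ndarray:
    """Group index per spin; spins with (near-)identical shifts share one."""
    n = ssm.n_spins
    group = -np.ones(n, dtype=int)
    next_id = 0
    order = np.argsort(ssm.shifts_ppm, kind="stable")
    last_shift = None
    for i in order:
        s = ssm.shifts_ppm[i]
        if last_shift is None or abs(s - last_shift) > tol_ppm:
            gid = next_id
            next_id += 1
        group[i] = gid
        last_shift = s
    return group


def simulate_peaklist(
    ssm: SpinSystemMatrix,
    spectrometer_mhz: float,
    default_width_hz: float = 1.0,
    max_spins: int = DEFAULT_MAX_SPINS,
) -> PeakList:
    """Field-specific peak list from a spin-system matrix.

    Each transition becomes a peak at frequency/spectrometer_mhz ppm with
    height equal to its intensity and the (relaxation-free) default width.
    Peaks are tagged with the multiplet of the proton group contributing
    the largest transition amplitude, which groups the second-order lines
    of equivalent protons together.
    """
    if default_width_hz <= 0:
        raise ValidationError("default_width_hz must be positive")
    trs, tags = transitions(
        ssm, spectrometer_mhz, max_spins=max_spins, _tag_spins=True
    )
    groups = _proton_groups(ssm)
    peaks = []
    for k, (tr, spin) in enumerate(zip(trs, tags)):
        peaks.append(
            Peak(
                position_ppm=tr.frequency_hz / spectrometer_mhz,
                height=tr.intensity,
                width_hz=default_width_hz,
                multiplet_id=f"M{groups[spin]}",
                peak_id=f"P{k}",
            )
        )
    return PeakList(
        peaks=peaks, source_kind="spin_system", provenance=ssm.entry_ref
    )
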