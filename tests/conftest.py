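import numpy as np
import pytest

from metabosim import Peak, PeakList, SpinSystemMatrix, render


def ab_lines(shift_a_ppm, shift_b_ppm, j_hz, mhz):
    """Closed-form AB spectrum: [(frequency_hz, intensity), ...].

    Independent textbook oracle for the two-spin case: line positions
    nu_center +/- (C +/- J)/2 with C = sqrt(dnu^2 + J^2); intensities
    (1 -/+ J/C)/2 per line under the total-intensity = n convention.
    """
    nu_a = shift_a_ppm * mhz
    nu_b = shift_b_ppm * mhz
    center = 0.5 * (nu_a + nu_b)
    dnu = abs(nu_a - nu_b)
    C = float(np.hypot(dnu, j_hz))
    outer = (1.0 - j_hz / C) / 2.0
    inner = (1.0 + j_hz / C) / 2.0
    lines = [
        (center - (C + j_hz) / 2.0, outer),
        (center - (C - j_hz) / 2.0, inner),
        (center + (C - j_hz) / 2.0, inner),
        (center + (C + j_hz) / 2.0, outer),
    ]
    return sorted(lines)


def first_order_lines(ssm: SpinSystemMatrix, mhz: float):
    """First-order (weak-coupling) multiplet construction.

    Each spin resonates at its Larmor frequency split into a binomial
    pattern by every coupling partner; valid only when shift differences
    dwarf the couplings.  Returns merged [(frequency_hz, intensity), ...].
    """
    from itertools import product

    lines: dict[float, float] = {}
    n = ssm.n_spins
    for i in range(n):
        partners = [j for j in range(n) if j != i and ssm.couplings_hz[i, j]]
        base = ssm.shifts_ppm[i] * mhz
        for signs in product((-0.5, 0.5), repeat=len(partners)):
            freq = base + sum(
                s * ssm.couplings_hz[i, j] for s, j in zip(signs, partners)
            )
            key = round(freq, 6)
            lines[key] = lines.get(key, 0.0) + 1.0 / 2 ** len(partners)
    return sorted(lines.items())


@pytest.fixture
def two_spin_ab():
    return SpinSystemMatrix(
        atom_labels=["Ha", "Hb"],
        shifts_ppm=np.array([1.00, 1.01]),
        couplings_hz=np.array([[0.0, 7.0], [7.0, 0.0]]),
    )


@pytest.fixture
def doublet_peaks():
    """Two-line multiplet near 2 ppm plus a singlet at 7 ppm."""
    return PeakList(
        peaks=[
            Peak(2.006, 1.0, 1.5, multiplet_id="M1", peak_id="P0"),
            Peak(1.994, 1.0, 1.5, multiplet_id="M1", peak_id="P1"),
            Peak(7.0, 2.0, 1.5, multiplet_id="M2", peak_id="P2"),
        ],
        source_kind="annotated",
    )


@pytest.fixture
def doublet_grid(doublet_peaks):
    return render(doublet_peaks, 600.0, 9.0, 0.0, 8192)
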