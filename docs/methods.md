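# Methods

This note records the models, conventions, defaults and known limitations
of `metabosim`, in the order data flows through the package.

## Spin-system quantum mechanics (`spin_quantum`)

**Model.** A metabolite's coupled protons are treated as an isolated
system of n spin-½ nuclei with the isotropic liquid-state Hamiltonian, in
frequency units (Hz):

    H = Σ_i ν_i Iz(i) + Σ_{i<j} J_ij [Ix(i)Ix(j) + Iy(i)Iy(j) + Iz(i)Iz(j)]

with ν_i = δ_i (ppm) × ν₀ (MHz). Conventions the literature leaves open
are fixed as: lab-frame offsets (no rotating-frame subtraction) and a
sign such that larger ppm means higher frequency. In the 2ⁿ product basis
(bit i set = spin i up) the matrix is real-symmetric: the J term
contributes J_ij·m_i·m_j on the diagonal and flip-flop elements J_ij/2
between states related by one up–down exchange.

**Diagonalization.** Total Fz commutes with H, so H block-diagonalizes by
the number of up spins; each sector is diagonalized densely. This reduces
the largest eigenproblem from 2ⁿ to C(n, n/2) and is what keeps n = 12
(the default `max_spins`) tractable; the per-transition cost still grows
roughly cubically with the block dimension, hence the cap. Larger
metabolites would require segmenting the spin system into approximately
independent fragments, which is out of scope.

**Transitions.** Single-quantum lines connect eigenstates of adjacent Fz
sectors; frequency = E(upper sector) − E(lower sector), intensity =
|⟨f| Σᵢ Ix(i) |i⟩|². Raw intensities are scaled by 2^(3−n), which by a
trace identity makes the total intensity exactly n at every field — one
isolated spin carries intensity 1, and total intensity is conserved
across fields by construction. Two numerical guards, both far below
spectral resolution: transitions weaker than 1e−9 of the strongest are
dropped (the literature does not state a cutoff; this is a package
decision), and lines closer than 1e−6 Hz are merged by summing
intensities at their intensity-weighted mean frequency. The merge makes
equivalent-spin systems collapse cleanly to a single line.

**Multiplet assignment.** Each transition is tagged with the proton group
(protons sharing a chemical shift to 1e−6 ppm) whose single-spin Ix
matrix element dominates it. This groups second-order lines with the
multiplet they belong to, which downstream ROI construction relies on.

**Relaxation is not modeled**: the QM stage produces stick spectra; line
widths enter only at rendering.

## Lorentzian rendering (`lineshape`)

Peaks are height-parameterized Lorentzians L(x) = h·γ²/(x²+γ²), γ =
FWHM/2, because the source databases store peak *heights*; the analytic
area πhw/2 is available where quantification needs it. Widths are carried
in Hz (field-independent) and divided by the spectrometer frequency at
render time. The ppm axis is strictly decreasing (display convention),
endpoints inclusive, spacing (first−last)/(n−1); grids are validated
uniform to 1e−9 ppm. Tails are never truncated and no noise or
apodization is added — simulated references are deliberately idealized.
Rendering is linear in the peak list and pointwise-analytic, so doubling
the grid resolution reproduces the coarse values exactly.

Spectra import/export as two-column text or a minimal JCAMP-DX-like XY
block, with full-precision float reprs, so round trips are numerically
exact (well beyond the 12 significant digits guaranteed).

## Similarity scoring (`similarity`)

The score between two intensity vectors is plain cosine similarity
A·B/(‖A‖‖B‖): 1 for a perfect match, −1 for a perfect inversion, and
invariant to overall scale (hence to concentration). For co-centered
Lorentzians of width ratio r the score is analytically 2√r/(1+r); the
0.9 acceptance threshold therefore tolerates up to a 2.5× width mismatch
but little position error — the property that makes the metric suitable
for peak matching.

Scores are computed per **region of interest** and averaged without
weights. ROI construction is a package decision (no published rule
exists): one interval per multiplet spanning its outermost peaks,
extended by `margin_factor` (default 10) × the widest member width in
ppm, with overlapping intervals merged. The margin covers Lorentzian
tails while keeping solvent and reference regions out of the score.

**SNR exclusion.** ROIs whose experimental signal-to-noise (max ROI
intensity / noise standard deviation) falls below 10 — the accepted limit
of quantification — are excluded from the mean. Whether the exclusion
should apply per peak or per ROI is ambiguous in the literature; it is
applied per ROI here, since a sub-threshold ROI contributes only noise to
the cosine. The noise estimator is caller-specified; the default is the
standard deviation over the widest ROI-free stretch of the axis. On
noiseless synthetic grids the deviation is zero, SNR is undefined, and no
exclusion is applied.

## Automatic remediation (`remediation`)

Simulations scoring under threshold are adjusted in a fixed order:

1. **Solvent suppression** — ROIs overlapping the water (4.6–4.9 ppm) or
   reference (−0.1–0.1 ppm) intervals are trimmed to the set difference
   or dropped. Contaminated ROIs corrupt both later fits, so this runs
   first.
2. **Offset alignment** — one global ppm shift, searched on a grid at
   axis resolution within ±0.05 ppm (covering typical TSP/DSS referencing
   offsets) and refined by parabolic interpolation; the search is seeded
   by aligning the lowest-ppm simulated multiplet to the nearest
   experimental maximum. Offset errors dominate the cosine penalty, so
   alignment precedes the width fit.
3. **Width scale** — one multiplicative factor on every peak width,
   fitted by bounded 1-D maximization on the log factor (bounds
   0.2–20), re-rendering per candidate. The fit is global-only; whether
   per-peak width fitting belongs in the automatic stage is an open
   question, and per-peak edits are left to manual curation.

Each step is kept only if it does not lower the score, so recorded scores
never decrease; the pipeline stops early at the threshold. Outcomes:
`verified` (already ≥ threshold, no steps), `remediated`, `needs_manual`,
and `unverified` for *exactly* 1.0 — a perfect score against supposedly
experimental data indicates a cleaned or simulated reference, so it is
flagged rather than trusted. Records carry a category label (the
dominant adjustment, or `unverifiable`); categories for manual repairs
(peak positions/heights, multiplet patterns, J-couplings) exist as labels
only — there is no interactive editor.

## Entry dialect and merging (`star`, `nef_io`)

One STAR-syntax file per metabolite. The saveframe/loop vocabulary
(`mdb_` prefix: metabolite with synonym/accession/ontology/concentration
loops; one frame per sample; one frame per spectrum with peak, multiplet,
multiplet-member, shift and coupling loops) is defined and documented by
this package: syntactically ordinary STAR, readable by any NEF/NMR-STAR
parser, but the frame names are not claimed identical to any external
database's. Floats are written with full repr precision, so
write→read→write is a byte-level fixed point (at least 9 significant
digits guaranteed). Ontology terms are stored as a flat table, not a
hierarchy; missing metadata (pH, temperature) is stored as explicit STAR
nulls, never imputed.

**Merging.** InChI is the only identifier canonical across source
databases, so entries merge by exact InChI match: samples, spectra,
synonyms, ontology terms and concentrations are unioned; the first
primary name wins and later names become synonyms (no error). HMDB-style
accessions are unambiguous per metabolite and stay at the metabolite
level; BMRB-style accessions identify measurements and live on samples.
Merging is idempotent and order-insensitive up to synonym ordering.

**Placeholder widths.** Peaks lacking a width receive 1 Hz — the
conventional stand-in where sources omit line widths — and are flagged,
so remediation (which typically fits a ~3× broader width) knows the value
is not a measurement. Bulk parsers for the real HMDB/BMRB/GISSMO archives
are out of scope; their content enters through this dialect or the
GISSMO-style spin-matrix XML reader.

## Synthetic fixtures (`synthetic`)

The generator emulates the features experimental spectra have and
simulations lack. Defaults chosen where no published value exists, with
rationale:

| parameter | default | why |
|---|---|---|
| shifts | uniform in 0.5–9.0 ppm | the usable ¹H window |
| couplings | N(7, 2²) Hz on a random connected graph | typical ³J range; connectivity guarantees one coupled system |
| noise | Gaussian, sd = fraction of max | dominant detector noise model |
| baseline | 1.5-period sinusoid, amplitude relative to max | enough to stress ROI scoring without modeling phase errors |
| reference peak | 1 Hz line at 0.00 ppm, half max height | DSS/TSP-like singlet |
| solvent | 20 Hz line at 4.70 ppm, max height | residual water after imperfect suppression |
| broadening | re-render with scaled widths when peaks known, else Lorentzian-kernel convolution | Lorentzian widths add under convolution |

All randomness derives from one integer seed (distinct seed streams per
purpose), so every fixture is reproducible. Generated entries carry
synthetic InChI-like tags, unique per seed — they are not real chemical
identifiers.

**What passing tests do and do not show.** The generator produces well
separated multiplets, ideal Lorentzian lineshapes, white noise and a
smooth baseline. Real biofluid spectra add heavy peak overlap, pH- and
matrix-dependent shift changes, phase/shimming distortions and
macromolecular backgrounds; success on these fixtures demonstrates the
correctness of the algorithms, not identification performance in plasma
or urine.

## Problem sizes and numerical choices

Test and acceptance runs use 2–4-spin systems on grids of 4k–64k points —
sizes at which every oracle comparison is exact and the full suite runs
in seconds; the algorithms themselves are size-independent up to the
12-spin cap. Width-fit convergence tolerance is 1e−4 on the log factor;
offset refinement is one parabolic step around the grid optimum and is
accepted only if it does not lower the score; degenerate cases (flat
experimental grid, all-ROI exclusion, zero vectors) raise typed errors
at the library surface and are downgraded to `needs_manual` outcomes
inside the remediation pipeline.

## Known limitations

- No nuclei other than ¹H, no relaxation, NOE or exchange dynamics.
- No Gaussian/Voigt lineshapes, phase errors or baseline models outside
  the synthetic generator.
- Spin systems above 12 spins are rejected rather than segmented.
- Peak-list-to-peak-list matching metrics and statistical
  total-correlation methods are out of scope.
- The entry dialect is self-documented; interoperability with other STAR
  dialects is syntactic, not semantic.
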