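"""Per-metabolite database entries in a NEF-style STAR dialect.

One file per metabolite, mirroring the relational structure of an NMR
metabolite annotation database: a metabolite table (identity, InChI,
SMILES, synonyms, ontology terms, typical concentrations, source
accessions), samples (pH, solvent, reference compound, temperature), and
per-sample spectra holding the data needed to recreate the spectrum —
annotated peak lists, multiplets, and/or a field-independent spin-system
matrix.  Entries from different source databases describing the same
compound are merged by InChI, the only identifier canonical across
sources; HMDB accessions are unambiguous per metabolite and stay at the
metabolite level, while BMRB accessions are per-measurement and stay at
the sample level.

The saveframe/loop vocabulary (``mdb_`` prefix) is defined by this package
and documented in docs/methods.md; it is ordinary STAR syntax, readable by
any NEF/NMR-STAR parser, but not claimed identical to any third party's
frame names.  Numeric round trips are exact: floats are written with full
repr precision (beyond the guaranteed 9 significant digits).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

from lxml import etree

from . import star
from .errors import ParseError, SchemaError, ValidationError
from .lineshape import Peak, PeakList
from .spin_quantum import SpinSystemMatrix

import numpy as np

__all__ = [
    "Multiplet",
    "Spectrum",
    "Sample",
    "MetaboliteEntry",
    "parse_spin_matrix_xml",
    "read_entry",
    "write_entry",
    "read_directory",
    "merge_by_inchi",
    "apply_placeholder_widths",
    "entry_stats",
]

DEFAULT_PLACEHOLDER_WIDTH_HZ = 1.0


@dataclass
class Multiplet:
    multiplet_id: str
    center_ppm: Optional[float] = None
    atom_assignment: Optional[str] = None
    member_peak_ids: list[str] = field(default_factory=list)


@dataclass
class Spectrum:
    """One recorded/simulatable spectrum; peak list and/or spin system."""

    spectrum_id: str
    spectrometer_mhz: float
    peaklist: Optional[PeakList] = None
    spin_system: Optional[SpinSystemMatrix] = None
    multiplets: list[Multiplet] = field(default_factory=list)
    verified: bool = False

    def usable(self) -> bool:
        return self.peaklist is not None or self.spin_system is not None

    def validate(self) -> None:
        if self.spectrometer_mhz <= 0:
            raise ValidationError(
                f"spectrum {self.spectrum_id}: non-positive field"
            )
        if self.peaklist is not None:
            ids = {
                p.peak_id for p in self.peaklist if p.peak_id is not None
            }
            for m in self.multiplets:
                for pid in m.member_peak_ids:
                    if pid not in ids:
                        raise ValidationError(
                            f"spectrum {self.spectrum_id}: multiplet "
                            f"{m.multiplet_id} references unknown peak {pid}"
                        )


@dataclass
class Sample:
    sample_id: str
    ph: Optional[float] = None  # missing pH is common and allowed
    solvent: Optional[str] = None
    reference_compound: Optional[str] = None  # DSS / TMS / TSP / other
    temperature_k: Optional[float] = None
    source_accession: Optional[str] = None  # e.g. BMRB accession
    spectra: list[Spectrum] = field(default_factory=list)


@dataclass
class MetaboliteEntry:
    """Everything known about one metabolite; one STAR file each."""

    entry_id: str
    inchi: str
    name: Optional[str] = None
    smiles: Optional[str] = None
    synonyms: list[str] = field(default_factory=list)
    accessions: dict[str, str] = field(default_factory=dict)
    ontology_terms: list[str] = field(default_factory=list)
    concentrations: list[tuple[str, float, str]] = field(default_factory=list)
    samples: list[Sample] = field(default_factory=list)

    def validate(self) -> None:
        if not self.inchi:
            raise ValidationError(f"entry {self.entry_id}: empty InChI")
        if not self.entry_id:
            raise ValidationError("entry id must be non-empty")
        seen = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(
                    f"entry {self.entry_id}: duplicate sample {s.sample_id}"
                )
            seen.add(s.sample_id)
            sp_seen = set()
            for sp in s.spectra:
                if sp.spectrum_id in sp_seen:
                    raise ValidationError(
                        f"sample {s.sample_id}: duplicate spectrum "
                        f"{sp.spectrum_id}"
                    )
                sp_seen.add(sp.spectrum_id)
                sp.validate()

    def n_spectra(self) -> int:
        return sum(len(s.spectra) for s in self.samples)


# ---------------------------------------------------------------------------
# GISSMO-style spin-matrix XML


def parse_spin_matrix_xml(document: str | bytes) -> SpinSystemMatrix:
    """Spin-system matrix from spin-matrix XML text.

    Expected elements: ``<spin index="1" name="H1"><chemical_shift>1.00
    </chemical_shift></spin>`` (shifts in ppm) and ``<coupling from="1"
    to="2">7.0</coupling>`` (Hz).  A coupling listed once is mirrored;
    conflicting duplicates are an error.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed spin-matrix XML: {exc}") from exc

    spins: dict[int, tuple[str, float]] = {}
    for el in root.iter("spin"):
        idx_s = el.get("index")
        if idx_s is None:
            raise ParseError("<spin> element lacks an index attribute")
        try:
            idx = int(idx_s)
        except ValueError as exc:
            raise ParseError(f"non-integer spin index {idx_s!r}") from exc
        shift_el = el.find("chemical_shift")
        shift_text = (
            shift_el.text if shift_el is not None else el.get("chemical_shift")
        )
        if shift_text is None:
            raise ParseError(f"spin {idx}: missing <chemical_shift>")
        try:
            shift = float(shift_text)
        except ValueError as exc:
            raise ParseError(
                f"spin {idx}: non-numeric chemical shift {shift_text!r}"
            ) from exc
        if idx in spins:
            raise ParseError(f"duplicate spin index {idx}")
        spins[idx] = (el.get("name") or f"H{idx}", shift)
    if not spins:
        raise ParseError("no <spin> elements found")

    order = sorted(spins)
    pos = {idx: k for k, idx in enumerate(order)}
    n = len(order)
    shifts = np.array([spins[idx][1] for idx in order])
    labels = [spins[idx][0] for idx in order]
    couplings = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for el in root.iter("coupling"):
        a_s, b_s = el.get("from"), el.get("to")
        if a_s is None or b_s is None:
            raise ParseError("<coupling> element lacks from/to attributes")
        try:
            a, b = int(a_s), int(b_s)
        except ValueError as exc:
            raise ParseError(
                f"non-integer coupling index in <coupling from={a_s!r} "
                f"to={b_s!r}>"
            ) from exc
        if a not in pos or b not in pos:
            raise ParseError(f"coupling references unknown spin ({a},{b})")
        if a == b:
            raise ParseError(f"self-coupling on spin {a}")
        text = el.text if el.text is not None else el.get("value")
        try:
            J = float(text)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"non-numeric coupling value {text!r} for ({a},{b})"
            ) from exc
        key = (min(a, b), max(a, b))
        if key in seen and abs(seen[key] - J) > 1e-9:
            raise ParseError(
                f"conflicting duplicate coupling for spins {key}: "
                f"{seen[key]} vs {J}"
            )
        seen[key] = J
        couplings[pos[a], pos[b]] = J
        couplings[pos[b], pos[a]] = J
    return SpinSystemMatrix(
        atom_labels=labels, shifts_ppm=shifts, couplings_hz=couplings
    )


# ---------------------------------------------------------------------------
# STAR serialization helpers


def _fmt(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(float(value))  # builtin float repr round-trips exactly
    return str(value)


def _as_float(value: str | None, where: str) -> Optional[float]:
    if value is None:
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise SchemaError(f"{where}: non-numeric value {value!r}") from exc


def _as_bool(value: str | None) -> bool:
    return value == "true"


def write_entry(entry: MetaboliteEntry, path) -> None:
    """Write one metabolite entry as a NEF-style STAR file."""
    entry.validate()
    block = star.DataBlock(name=entry.entry_id)

    met = star.Saveframe(name="mdb_metabolite")
    met.tags["_mdb_metabolite.sf_category"] = "mdb_metabolite"
    met.tags["_mdb_metabolite.entry_id"] = entry.entry_id
    met.tags["_mdb_metabolite.inchi"] = entry.inchi
    met.tags["_mdb_metabolite.name"] = entry.name
    met.tags["_mdb_metabolite.smiles"] = entry.smiles
    if entry.synonyms:
        met.loops.append(
            star.Loop(
                columns=["_mdb_synonym.name"],
                rows=[[s] for s in entry.synonyms],
            )
        )
    if entry.accessions:
        met.loops.append(
            star.Loop(
                columns=["_mdb_accession.source", "_mdb_accession.accession"],
                rows=[[k, v] for k, v in sorted(entry.accessions.items())],
            )
        )
    if entry.ontology_terms:
        met.loops.append(
            star.Loop(
                columns=["_mdb_ontology.term"],
                rows=[[t] for t in entry.ontology_terms],
            )
        )
    if entry.concentrations:
        met.loops.append(
            star.Loop(
                columns=[
                    "_mdb_concentration.biofluid",
                    "_mdb_concentration.value",
                    "_mdb_concentration.units",
                ],
                rows=[
                    [b, _fmt(float(v)), u]
                    for b, v, u in entry.concentrations
                ],
            )
        )
    block.frames[met.name] = met

    for s in entry.samples:
        fr = star.Saveframe(name=f"mdb_sample_{s.sample_id}")
        fr.tags["_mdb_sample.sf_category"] = "mdb_sample"
        fr.tags["_mdb_sample.sample_id"] = s.sample_id
        fr.tags["_mdb_sample.ph"] = _fmt(s.ph)
        fr.tags["_mdb_sample.solvent"] = s.solvent
        fr.tags["_mdb_sample.reference_compound"] = s.reference_compound
        fr.tags["_mdb_sample.temperature_k"] = _fmt(s.temperature_k)
        fr.tags["_mdb_sample.source_accession"] = s.source_accession
        block.frames[fr.name] = fr
        for sp in s.spectra:
            spf = star.Saveframe(name=f"mdb_spectrum_{sp.spectrum_id}")
            spf.tags["_mdb_spectrum.sf_category"] = "mdb_spectrum"
            spf.tags["_mdb_spectrum.spectrum_id"] = sp.spectrum_id
            spf.tags["_mdb_spectrum.sample_id"] = s.sample_id
            spf.tags["_mdb_spectrum.spectrometer_mhz"] = _fmt(
                float(sp.spectrometer_mhz)
            )
            spf.tags["_mdb_spectrum.verified"] = _fmt(sp.verified)
            if sp.peaklist is not None:
                spf.tags["_mdb_spectrum.peaklist_source"] = (
                    sp.peaklist.source_kind
                )
                spf.loops.append(
                    star.Loop(
                        columns=[
                            "_mdb_peak.peak_id",
                            "_mdb_peak.position_ppm",
                            "_mdb_peak.height",
                            "_mdb_peak.width_hz",
                            "_mdb_peak.width_is_placeholder",
                            "_mdb_peak.multiplet_id",
                        ],
                        rows=[
                            [
                                p.peak_id,
                                _fmt(float(p.position_ppm)),
                                _fmt(float(p.height)),
                                _fmt(p.width_hz),
                                _fmt(bool(p.width_is_placeholder)),
                                p.multiplet_id,
                            ]
                            for p in sp.peaklist
                        ],
                    )
                )
            if sp.multiplets:
                spf.loops.append(
                    star.Loop(
                        columns=[
                            "_mdb_multiplet.multiplet_id",
                            "_mdb_multiplet.center_ppm",
                            "_mdb_multiplet.atom_assignment",
                        ],
                        rows=[
                            [m.multiplet_id, _fmt(m.center_ppm), m.atom_assignment]
                            for m in sp.multiplets
                        ],
                    )
                )
                member_rows = [
                    [m.multiplet_id, pid]
                    for m in sp.multiplets
                    for pid in m.member_peak_ids
                ]
                if member_rows:
                    spf.loops.append(
                        star.Loop(
                            columns=[
                                "_mdb_multiplet_member.multiplet_id",
                                "_mdb_multiplet_member.peak_id",
                            ],
                            rows=member_rows,
                        )
                    )
            if sp.spin_system is not None:
                ssm = sp.spin_system
                spf.loops.append(
                    star.Loop(
                        columns=[
                            "_mdb_shift.index",
                            "_mdb_shift.atom_label",
                            "_mdb_shift.shift_ppm",
                        ],
                        rows=[
                            [str(i + 1), ssm.atom_labels[i], _fmt(float(v))]
                            for i, v in enumerate(ssm.shifts_ppm)
                        ],
                    )
                )
                coup_rows = [
                    [str(i + 1), str(j + 1), _fmt(float(ssm.couplings_hz[i, j]))]
                    for i in range(ssm.n_spins)
                    for j in range(i + 1, ssm.n_spins)
                    if ssm.couplings_hz[i, j] != 0.0
                ]
                spf.loops.append(
                    star.Loop(
                        columns=[
                            "_mdb_coupling.index_1",
                            "_mdb_coupling.index_2",
                            "_mdb_coupling.value_hz",
                        ],
                        rows=coup_rows,
                    )
                )
            block.frames[spf.name] = spf

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(star.serialize(block))


def _require(frame: star.Saveframe, tag: str) -> str:
    value = frame.tags.get(tag)
    if value is None:
        raise SchemaError(
            f"saveframe {frame.name!r}: required tag {tag} missing or null"
        )
    return value


def read_entry(path) -> MetaboliteEntry:
    """Read a NEF-style entry file; schema violations raise SchemaError."""
    with open(path, encoding="utf-8") as fh:
        block = star.parse(fh.read())

    met = None
    for frame in block.frames.values():
        if frame.tags.get("_mdb_metabolite.sf_category") == "mdb_metabolite":
            met = frame
            break
    if met is None:
        raise SchemaError(
            f"{path}: no mdb_metabolite saveframe — not a metabolite entry"
        )
    entry = MetaboliteEntry(
        entry_id=_require(met, "_mdb_metabolite.entry_id"),
        inchi=_require(met, "_mdb_metabolite.inchi"),
        name=met.tags.get("_mdb_metabolite.name"),
        smiles=met.tags.get("_mdb_metabolite.smiles"),
    )
    lp = met.loop("_mdb_synonym")
    if lp:
        entry.synonyms = [row[0] for row in lp.rows]
    lp = met.loop("_mdb_accession")
    if lp:
        entry.accessions = {row[0]: row[1] for row in lp.rows}
    lp = met.loop("_mdb_ontology")
    if lp:
        entry.ontology_terms = [row[0] for row in lp.rows]
    lp = met.loop("_mdb_concentration")
    if lp:
        entry.concentrations = [
            (
                row[0],
                _as_float(row[1], f"{path} concentration row"),
                row[2],
            )
            for row in lp.rows
        ]

    samples: dict[str, Sample] = {}
    for frame in block.frames.values():
        if frame.tags.get("_mdb_sample.sf_category") == "mdb_sample":
            s = Sample(
                sample_id=_require(frame, "_mdb_sample.sample_id"),
                ph=_as_float(
                    frame.tags.get("_mdb_sample.ph"), f"{frame.name} ph"
                ),
                solvent=frame.tags.get("_mdb_sample.solvent"),
                reference_compound=frame.tags.get(
                    "_mdb_sample.reference_compound"
                ),
                temperature_k=_as_float(
                    frame.tags.get("_mdb_sample.temperature_k"),
                    f"{frame.name} temperature",
                ),
                source_accession=frame.tags.get(
                    "_mdb_sample.source_accession"
                ),
            )
            samples[s.sample_id] = s
    for frame in block.frames.values():
        if frame.tags.get("_mdb_spectrum.sf_category") != "mdb_spectrum":
            continue
        sid = _require(frame, "_mdb_spectrum.sample_id")
        if sid not in samples:
            raise SchemaError(
                f"saveframe {frame.name!r}: sample {sid!r} does not exist"
            )
        sp = Spectrum(
            spectrum_id=_require(frame, "_mdb_spectrum.spectrum_id"),
            spectrometer_mhz=_as_float(
                _require(frame, "_mdb_spectrum.spectrometer_mhz"),
                f"{frame.name} spectrometer_mhz",
            ),
            verified=_as_bool(frame.tags.get("_mdb_spectrum.verified")),
        )
        lp = frame.loop("_mdb_peak")
        if lp is not None:
            peaks = []
            for r, row in enumerate(lp.rows):
                vals = dict(zip(lp.columns, row))
                peaks.append(
                    Peak(
                        peak_id=vals.get("_mdb_peak.peak_id"),
                        position_ppm=_as_float(
                            vals.get("_mdb_peak.position_ppm"),
                            f"{frame.name} peak row {r}",
                        ),
                        height=_as_float(
                            vals.get("_mdb_peak.height"),
                            f"{frame.name} peak row {r}",
                        ),
                        width_hz=_as_float(
                            vals.get("_mdb_peak.width_hz"),
                            f"{frame.name} peak row {r}",
                        ),
                        width_is_placeholder=_as_bool(
                            vals.get("_mdb_peak.width_is_placeholder")
                        ),
                        multiplet_id=vals.get("_mdb_peak.multiplet_id"),
                    )
                )
            sp.peaklist = PeakList(
                peaks=peaks,
                source_kind=frame.tags.get(
                    "_mdb_spectrum.peaklist_source", "annotated"
                )
                or "annotated",
                provenance=entry.entry_id,
            )
        lp = frame.loop("_mdb_multiplet")
        if lp is not None:
            members: dict[str, list[str]] = {}
            mem = frame.loop("_mdb_multiplet_member")
            if mem is not None:
                for row in mem.rows:
                    members.setdefault(row[0], []).append(row[1])
            for row in lp.rows:
                vals = dict(zip(lp.columns, row))
                mid = vals["_mdb_multiplet.multiplet_id"]
                sp.multiplets.append(
                    Multiplet(
                        multiplet_id=mid,
                        center_ppm=_as_float(
                            vals.get("_mdb_multiplet.center_ppm"),
                            f"{frame.name} multiplet {mid}",
                        ),
                        atom_assignment=vals.get(
                            "_mdb_multiplet.atom_assignment"
                        ),
                        member_peak_ids=members.get(mid, []),
                    )
                )
        lp = frame.loop("_mdb_shift")
        if lp is not None:
            idx_rows = []
            for row in lp.rows:
                vals = dict(zip(lp.columns, row))
                idx_rows.append(
                    (
                        int(vals["_mdb_shift.index"]),
                        vals.get("_mdb_shift.atom_label"),
                        _as_float(
                            vals.get("_mdb_shift.shift_ppm"),
                            f"{frame.name} shift row",
                        ),
                    )
                )
            idx_rows.sort()
            n = len(idx_rows)
            pos = {i: k for k, (i, _, _) in enumerate(idx_rows)}
            couplings = np.zeros((n, n))
            clp = frame.loop("_mdb_coupling")
            if clp is not None:
                for row in clp.rows:
                    vals = dict(zip(clp.columns, row))
                    a = int(vals["_mdb_coupling.index_1"])
                    b = int(vals["_mdb_coupling.index_2"])
                    if a not in pos or b not in pos:
                        raise SchemaError(
                            f"saveframe {frame.name!r}: coupling row "
                            f"references unknown spin ({a},{b})"
                        )
                    J = _as_float(
                        vals.get("_mdb_coupling.value_hz"),
                        f"{frame.name} coupling ({a},{b})",
                    )
                    couplings[pos[a], pos[b]] = J
                    couplings[pos[b], pos[a]] = J
            sp.spin_system = SpinSystemMatrix(
                atom_labels=[lab for _, lab, _ in idx_rows],
                shifts_ppm=np.array([s for _, _, s in idx_rows]),
                couplings_hz=couplings,
                entry_ref=entry.entry_id,
            )
        samples[sid].spectra.append(sp)

    entry.samples = list(samples.values())
    entry.validate()
    return entry


def read_directory(directory) -> tuple[list[MetaboliteEntry], list[tuple[str, str]]]:
    """Read every ``*.nef``/``*.star`` file; returns (entries, failures)."""
    import os

    entries: list[MetaboliteEntry] = []
    failures: list[tuple[str, str]] = []
    for name in sorted(os.listdir(directory)):
        if not name.endswith((".nef", ".star")):
            continue
        path = os.path.join(directory, name)
        try:
            entries.append(read_entry(path))
        except (ParseError, ValidationError, OSError) as exc:
            failures.append((name, str(exc)))
    return entries, failures


# ---------------------------------------------------------------------------
# merging and remediation bookkeeping


def merge_by_inchi(
    entries: Sequence[MetaboliteEntry],
) -> list[MetaboliteEntry]:
    """Deduplicate entries by InChI; one output entry per distinct InChI.

    Samples, spectra, synonyms, ontology terms and concentrations are
    unioned.  The first entry's primary name wins; later conflicting names
    become synonyms.  HMDB accessions merge at the metabolite level; BMRB
    accessions already live on samples and travel with them.
    """
    by_inchi: dict[str, MetaboliteEntry] = {}
    for src in entries:
        if not src.inchi:
            raise ValidationError(
                f"entry {src.entry_id}: cannot merge without an InChI"
            )
        src = copy.deepcopy(src)
        if src.inchi not in by_inchi:
            by_inchi[src.inchi] = src
            continue
        dst = by_inchi[src.inchi]
        if src.name and src.name != dst.name:
            if src.name not in dst.synonyms:
                dst.synonyms.append(src.name)
        for syn in src.synonyms:
            if syn not in dst.synonyms and syn != dst.name:
                dst.synonyms.append(syn)
        for key, val in src.accessions.items():
            dst.accessions.setdefault(key, val)
        for term in src.ontology_terms:
            if term not in dst.ontology_terms:
                dst.ontology_terms.append(term)
        for conc in src.concentrations:
            if conc not in dst.concentrations:
                dst.concentrations.append(conc)
        if dst.smiles is None:
            dst.smiles = src.smiles
        existing = {s.sample_id for s in dst.samples}
        for s in src.samples:
            if s.sample_id in existing:
                s.sample_id = f"{s.sample_id}__{src.entry_id}"
            dst.samples.append(s)
            existing.add(s.sample_id)
    out = list(by_inchi.values())
    for e in out:
        e.validate()
    return out


def apply_placeholder_widths(
    entry: MetaboliteEntry,
    default_width_hz: float = DEFAULT_PLACEHOLDER_WIDTH_HZ,
) -> MetaboliteEntry:
    """Assign the placeholder width to every width-less peak, flagging it.

    Source databases commonly omit line widths; 1 Hz is the conventional
    stand-in until remediation fits a realistic value.  The entry is
    modified in place and returned.
    """
    if default_width_hz <= 0:
        raise ValidationError("placeholder width must be positive")
    for s in entry.samples:
        for sp in s.spectra:
            if sp.peaklist is None:
                continue
            for p in sp.peaklist:
                if p.width_hz is None:
                    p.width_hz = default_width_hz
                    p.width_is_placeholder = True
    return entry


def entry_stats(entries: Sequence[MetaboliteEntry]) -> dict[str, int]:
    """Database content summary: metabolites/samples/spectra/multiplets/peaks."""
    n_samples = sum(len(e.samples) for e in entries)
    n_spectra = sum(e.n_spectra() for e in entries)
    n_mult = sum(
        len(sp.multiplets)
        for e in entries
        for s in e.samples
        for sp in s.spectra
    )
    n_peaks = sum(
        len(sp.peaklist)
        for e in entries
        for s in e.samples
        for sp in s.spectra
        if sp.peaklist is not None
    )
    return {
        "metabolites": len(entries),
        "samples": n_samples,
        "spectra": n_spectra,
        "multiplets": n_mult,
        "peaks": n_peaks,
    }
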