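"""Entry dialect: XML parsing, STAR round trips, InChI merging, widths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabosim import (
    MetaboliteEntry,
    ParseError,
    Peak,
    PeakList,
    Sample,
    SchemaError,
    Spectrum,
    SyntheticSpec,
    apply_placeholder_widths,
    entry_stats,
    make_entry,
    merge_by_inchi,
    parse_spin_matrix_xml,
    read_entry,
    write_entry,
)

TWO_SPIN_XML = """<spin_system>
  <spin index="1" name="Ha"><chemical_shift>1.00</chemical_shift></spin>
  <spin index="2" name="Hb"><chemical_shift>2.00</chemical_shift></spin>
  <coupling from="1" to="2">7.0</coupling>
</spin_system>"""


class TestSpinMatrixXML:
    def test_two_spin_fixture(self):
        ssm = parse_spin_matrix_xml(TWO_SPIN_XML)
        assert ssm.atom_labels == ["Ha", "Hb"]
        np.testing.assert_array_equal(ssm.shifts_ppm, [1.0, 2.0])
        np.testing.assert_array_equal(
            ssm.couplings_hz, [[0.0, 7.0], [7.0, 0.0]]
        )

    def test_single_listing_is_symmetrized(self):
        ssm = parse_spin_matrix_xml(TWO_SPIN_XML)
        assert ssm.couplings_hz[1, 0] == 7.0
        assert ssm.couplings_hz[0, 1] == 7.0

    def test_consistent_duplicate_coupling_accepted(self):
        xml = TWO_SPIN_XML.replace(
            "</spin_system>",
            '<coupling from="2" to="1">7.0</coupling></spin_system>',
        )
        assert parse_spin_matrix_xml(xml).couplings_hz[0, 1] == 7.0

    @pytest.mark.parametrize(
        "mutation, match",
        [
            (("1.00", "abc"), "non-numeric"),
            (('index="2"', ""), "index"),
            (
                (
                    "</spin_system>",
                    '<coupling from="1" to="2">9.9</coupling></spin_system>',
                ),
                "conflicting duplicate",
            ),
            (('from="1"', 'from="7"'), "unknown spin"),
        ],
        ids=["bad-shift", "missing-index", "dup-coupling", "bad-ref"],
    )
    def test_malformed_documents_name_the_problem(self, mutation, match):
        old, new = mutation
        with pytest.raises(ParseError, match=match):
            parse_spin_matrix_xml(TWO_SPIN_XML.replace(old, new))

    def test_not_xml_at_all(self):
        with pytest.raises(ParseError):
            parse_spin_matrix_xml("this is not xml")


def minimal_entry() -> MetaboliteEntry:
    peaks = PeakList(
        [Peak(1.5, 1.0, 0.9, multiplet_id="M1", peak_id="P1")],
        source_kind="annotated",
    )
    return MetaboliteEntry(
        entry_id="MDB000001",
        inchi="InChI=1S/CH4/h1H4",
        name="methane-like",
        samples=[
            Sample(
                sample_id="S1",
                ph=None,
                solvent="D2O",
                spectra=[
                    Spectrum(
                        spectrum_id="SP1",
                        spectrometer_mhz=600.0,
                        peaklist=peaks,
                    )
                ],
            )
        ],
    )


class TestEntryRoundTrip:
    def test_minimal_entry_round_trips(self, tmp_path):
        entry = minimal_entry()
        path = tmp_path / "e.nef"
        write_entry(entry, path)
        back = read_entry(path)
        assert back.entry_id == entry.entry_id
        assert back.inchi == entry.inchi
        assert back.samples[0].ph is None  # explicit null survives
        peak = back.samples[0].spectra[0].peaklist.peaks[0]
        assert peak.position_ppm == 1.5
        assert peak.width_hz == 0.9

    def test_rich_entry_round_trips_bit_exactly(self, tmp_path):
        entry = make_entry(SyntheticSpec(seed=5, n_spins=4))
        path = tmp_path / "rich.nef"
        write_entry(entry, path)
        back = read_entry(path)
        sp0 = entry.samples[0].spectra[0]
        sp1 = back.samples[0].spectra[0]
        for a, b in zip(sp0.peaklist, sp1.peaklist):
            assert a.position_ppm == b.position_ppm  # full repr precision
            assert a.height == b.height
            assert a.width_hz == b.width_hz
            assert a.multiplet_id == b.multiplet_id
        np.testing.assert_array_equal(
            sp0.spin_system.shifts_ppm, sp1.spin_system.shifts_ppm
        )
        np.testing.assert_array_equal(
            sp0.spin_system.couplings_hz, sp1.spin_system.couplings_hz
        )
        assert [m.multiplet_id for m in sp0.multiplets] == [
            m.multiplet_id for m in sp1.multiplets
        ]
        assert back.accessions == entry.accessions

    def test_missing_metabolite_frame_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.nef"
        path.write_text(
            "data_x\nsave_other\n_foo.bar 1\nsave_\n", encoding="utf-8"
        )
        with pytest.raises(SchemaError, match="mdb_metabolite"):
            read_entry(path)

    def test_spectrum_referencing_unknown_sample_rejected(self, tmp_path):
        import re

        entry = minimal_entry()
        path = tmp_path / "e.nef"
        write_entry(entry, path)
        text = re.sub(
            r"(_mdb_spectrum\.sample_id\s+)S1", r"\1SX", path.read_text()
        )
        path.write_text(text, encoding="utf-8")
        with pytest.raises(SchemaError, match="SX"):
            read_entry(path)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_spins=st.integers(1, 5))
    def test_round_trip_stability_property(self, seed, n_spins):
        """write(read(write(e))) is a fixed point for random valid entries."""
        import pathlib
        import tempfile

        entry = make_entry(SyntheticSpec(seed=seed, n_spins=n_spins))
        with tempfile.TemporaryDirectory() as d:
            p1 = pathlib.Path(d) / "a.nef"
            p2 = pathlib.Path(d) / "b.nef"
            write_entry(entry, p1)
            write_entry(read_entry(p1), p2)
            assert p1.read_text() == p2.read_text()


class TestMergeByInchi:
    def _pair(self):
        a = make_entry(SyntheticSpec(seed=1))
        b = make_entry(SyntheticSpec(seed=2))
        b.inchi = a.inchi  # same compound from another source
        b.accessions = {"bmrb": "bmse000001"}
        b.samples[0].source_accession = "bmse000001"
        return a, b

    def test_same_inchi_merges_samples(self):
        a, b = self._pair()
        merged = merge_by_inchi([a, b])
        assert len(merged) == 1
        assert len(merged[0].samples) == 2
        # HMDB accession stays at metabolite level, BMRB travels on sample
        assert merged[0].accessions["hmdb"] == a.accessions["hmdb"]
        assert merged[0].samples[1].source_accession == "bmse000001"

    def test_disjoint_inchis_identity(self):
        entries = [make_entry(SyntheticSpec(seed=s)) for s in (1, 2, 3)]
        merged = merge_by_inchi(entries)
        assert [e.inchi for e in merged] == [e.inchi for e in entries]

    def test_output_count_and_synonym_union(self):
        """5 entries over 3 InChIs -> 3 outputs with brute-force synonym
        unions."""
        entries = [make_entry(SyntheticSpec(seed=s)) for s in range(5)]
        entries[3].inchi = entries[0].inchi
        entries[4].inchi = entries[1].inchi
        expected = {}
        for e in entries:
            bucket = expected.setdefault(e.inchi, set())
            bucket.update(e.synonyms)
            bucket.add(e.name)
        merged = merge_by_inchi(entries)
        assert len(merged) == 3
        for m in merged:
            got = set(m.synonyms) | {m.name}
            assert got == expected[m.inchi]

    def test_conflicting_primary_names_become_synonyms(self):
        a, b = self._pair()
        b.name = "another name"
        merged = merge_by_inchi([a, b])
        assert merged[0].name == a.name
        assert "another name" in merged[0].synonyms

    def test_idempotent_and_order_insensitive(self):
        a, b = self._pair()
        once = merge_by_inchi([a, b])
        twice = merge_by_inchi(once)
        assert len(twice) == len(once) == 1
        assert sorted(once[0].synonyms) == sorted(twice[0].synonyms)
        swapped = merge_by_inchi([b, a])
        assert sorted(swapped[0].synonyms + [swapped[0].name]) == sorted(
            once[0].synonyms + [once[0].name]
        )


class TestPlaceholderWidths:
    def _entry_with_missing_widths(self):
        entry = minimal_entry()
        pl = entry.samples[0].spectra[0].peaklist
        pl.peaks.append(Peak(2.5, 0.5, None, peak_id="P2"))
        pl.peaks.append(Peak(3.5, 0.5, None, peak_id="P3"))
        return entry

    def test_all_widths_present_is_identity(self):
        entry = minimal_entry()
        apply_placeholder_widths(entry)
        peak = entry.samples[0].spectra[0].peaklist.peaks[0]
        assert peak.width_hz == 0.9
        assert not peak.width_is_placeholder

    def test_missing_width_gets_one_hz_and_flag(self):
        entry = self._entry_with_missing_widths()
        apply_placeholder_widths(entry)
        peaks = entry.samples[0].spectra[0].peaklist.peaks
        assert peaks[1].width_hz == 1.0
        assert peaks[1].width_is_placeholder

    def test_flagged_set_is_exactly_the_missing_set(self):
        entry = self._entry_with_missing_widths()
        missing = {
            p.peak_id
            for p in entry.samples[0].spectra[0].peaklist
            if p.width_hz is None
        }
        apply_placeholder_widths(entry)
        flagged = {
            p.peak_id
            for p in entry.samples[0].spectra[0].peaklist
            if p.width_is_placeholder
        }
        assert flagged == missing


def test_entry_stats_counts_match_construction():
    entries = [make_entry(SyntheticSpec(seed=s, n_spins=2)) for s in range(4)]
    stats = entry_stats(entries)
    assert stats["metabolites"] == 4
    assert stats["samples"] == 4
    assert stats["spectra"] == 4
    assert stats["peaks"] == sum(
        len(e.samples[0].spectra[0].peaklist) for e in entries
    )
    assert stats["multiplets"] == sum(
        len(e.samples[0].spectra[0].multiplets) for e in entries
    )
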