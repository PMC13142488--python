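"""Domain-type invariants and format round-trips."""

import base64
import struct

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dialion.io import (
    SchemaError,
    filter_identification_records,
    read_identification_report,
    read_library,
    read_metadata,
    read_quant_matrix,
    read_spectra,
    write_identification_report,
    write_library,
    write_metadata,
    write_quant_matrix,
    write_spectra,
)
from dialion.model import (
    IdentificationRecord,
    LibraryEntry,
    QuantMatrix,
    SampleMetadata,
    SpectrumRecord,
    ValidationError,
)


def _ms1(rt, mz, inten, run="runA"):
    return SpectrumRecord(run_id=run, ms_level=1, rt=rt, mz_values=mz, intensities=inten)


class TestSpectrumRecord:
    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValidationError):
            _ms1(1.0, [500.0, 499.0], [1.0, 1.0])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValidationError):
            _ms1(1.0, [500.0], [1.0, 2.0])

    def test_ms2_requires_isolation_window(self):
        with pytest.raises(ValidationError):
            SpectrumRecord(
                run_id="r", ms_level=2, rt=1.0, mz_values=[300.0], intensities=[1.0]
            )

    def test_isolation_window_ordering(self):
        with pytest.raises(ValidationError):
            SpectrumRecord(
                run_id="r", ms_level=2, rt=1.0, mz_values=[300.0], intensities=[1.0],
                isolation_low=425.0, isolation_high=400.0,
            )


class TestInternalSpectra:
    def test_identity_readback(self, tmp_path):
        records = [_ms1(1.0, [400.0, 500.0], [10.0, 20.0]), _ms1(2.0, [450.0], [5.0])]
        path = tmp_path / "runA.scans"
        write_spectra(records, path)
        back = read_spectra(path, "internal")
        assert len(back) == 2
        assert [r.rt for r in back] == [1.0, 2.0]
        assert back == records

    def test_roundtrip_mixed_levels(self, tmp_path):
        rng = np.random.default_rng(5)
        records = []
        for i in range(4):
            mz = np.sort(rng.uniform(300, 1200, 7))
            records.append(_ms1(float(i), mz, rng.uniform(0, 1e5, 7)))
            records.append(
                SpectrumRecord(
                    run_id="runA", ms_level=2, rt=float(i), mz_values=mz,
                    intensities=rng.uniform(0, 1e5, 7),
                    isolation_low=400.0, isolation_high=425.0,
                )
            )
        path = tmp_path / "runA.scans"
        write_spectra(records, path)
        back = read_spectra(path, "internal")
        assert sorted(r.rt for r in back) == sorted(r.rt for r in records)
        ms1 = [r for r in back if r.ms_level == 1]
        assert ms1 == [r for r in records if r.ms_level == 1]

    def test_run_id_is_file_stem(self, tmp_path):
        path = tmp_path / "sample_B3.scans"
        write_spectra([_ms1(1.0, [500.0], [1.0], run="whatever")], path)
        assert read_spectra(path)[0].run_id == "sample_B3"


def _minimal_mzml(scans):
    """Hand-built minimal mzML document (text) for read-back tests."""
    spectra = []
    for i, (level, rt, iso, mz, inten) in enumerate(scans):
        def b64(values):
            return base64.b64encode(
                struct.pack(f"<{len(values)}d", *values)
            ).decode()

        precursor = ""
        if level == 2:
            target = (iso[0] + iso[1]) / 2
            off = (iso[1] - iso[0]) / 2
            precursor = f"""
      <precursorList count="1"><precursor><isolationWindow>
        <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{target}"/>
        <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{off}"/>
        <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{off}"/>
      </isolationWindow><selectedIonList count="1"><selectedIon>
        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{target}"/>
      </selectedIon></selectedIonList><activation/></precursor></precursorList>"""
        spectra.append(f"""
    <spectrum index="{i}" id="scan={i+1}" defaultArrayLength="{len(mz)}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
      <scanList count="1"><scan>
        <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitName="minute"/>
      </scan></scanList>{precursor}
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="{len(b64(mz))}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
          <binary>{b64(mz)}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="{len(b64(inten))}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
          <binary>{b64(inten)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>""")
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="testrun">
    <spectrumList count="{len(scans)}">{''.join(spectra)}
    </spectrumList>
  </run>
</mzML>
"""


class TestMzml:
    def test_ms2_isolation_window_readback(self, tmp_path):
        doc = _minimal_mzml(
            [
                (1, 1.5, None, [500.0, 501.0], [100.0, 50.0]),
                (2, 1.51, (400.0, 425.0), [310.0, 420.0], [30.0, 60.0]),
            ]
        )
        path = tmp_path / "tiny.mzML"
        path.write_text(doc)
        records = read_spectra(path, format="mzml")
        assert len(records) == 2
        ms2 = [r for r in records if r.ms_level == 2][0]
        assert ms2.isolation_low == pytest.approx(400.0)
        assert ms2.isolation_high == pytest.approx(425.0)
        assert ms2.run_id == "tiny"
        ms1 = [r for r in records if r.ms_level == 1][0]
        np.testing.assert_allclose(ms1.mz_values, [500.0, 501.0])
        np.testing.assert_allclose(ms1.intensities, [100.0, 50.0])


def _record(pid, run, q, rt=10.0):
    return IdentificationRecord(
        precursor_id=pid, run_id=run, protein_group="PG_HUMAN", q_value=q, observed_rt=rt
    )


class TestReportFilter:
    def test_all_pass(self):
        recs = [_record("P", f"r{i}", 0.001) for i in range(3)]
        assert len(filter_identification_records(recs, 0.01, 3)) == 3

    def test_q_filter_breaks_min_runs(self):
        recs = [
            _record("P", "r1", 0.001),
            _record("P", "r2", 0.02),
            _record("P", "r3", 0.001),
        ]
        assert filter_identification_records(recs, 0.01, 3) == []

    def test_empty_report(self):
        assert filter_identification_records([], 0.01, 3) == []

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        recs = [
            _record(f"P{i%7}", f"r{rng.integers(6)}", float(rng.uniform(0, 0.05)))
            for i in range(60)
        ]
        once = filter_identification_records(recs, 0.01, 3)
        twice = filter_identification_records(once, 0.01, 3)
        assert once == twice

    @settings(derandomize=True, max_examples=40)
    @given(
        q1=st.floats(0.001, 0.5),
        q2=st.floats(0.001, 0.5),
        m1=st.integers(1, 5),
        m2=st.integers(1, 5),
    )
    def test_retention_monotone_in_thresholds(self, q1, q2, m1, m2):
        rng = np.random.default_rng(99)
        recs = [
            _record(f"P{i % 10}", f"r{j}", float(rng.uniform(0, 0.4)))
            for i in range(10)
            for j in range(6)
        ]
        lo_q, hi_q = sorted([q1, q2])
        lo_m, hi_m = sorted([m1, m2])
        assert len(filter_identification_records(recs, lo_q, lo_m)) <= len(
            filter_identification_records(recs, hi_q, lo_m)
        )
        assert len(filter_identification_records(recs, lo_q, hi_m)) <= len(
            filter_identification_records(recs, lo_q, lo_m)
        )

    def test_file_roundtrip_and_schema_error(self, tmp_path):
        recs = [_record("P1", f"r{i}", 0.002) for i in range(3)]
        path = tmp_path / "report.tsv"
        write_identification_report(recs, path)
        back = read_identification_report(path, 0.01, 3)
        assert {r.precursor_id for r in back} == {"P1"}
        assert back[0].observed_rt == pytest.approx(10.0)
        bad = tmp_path / "bad.tsv"
        bad.write_text("precursor_id\trun_id\nP1\tr1\n")
        with pytest.raises(SchemaError):
            read_identification_report(bad, 0.01, 1)


class TestLibraryMetadataRoundtrip:
    def test_library_roundtrip(self, tmp_path):
        entries = [
            LibraryEntry(
                precursor_id="PEP1/2", precursor_mz=500.5, charge=2,
                mono_mass=999.0, irt=42.0,
                fragments=((700.1, 1.0, "y6"), (450.2, 0.5, "b4")),
            )
        ]
        path = tmp_path / "lib.tsv"
        write_library(entries, path)
        back = read_library(path)
        assert back == entries

    def test_metadata_roundtrip(self, tmp_path):
        meta = SampleMetadata(
            runs=("r1", "r2"), conditions=("A", "B"), batches=("b1", "b1")
        )
        path = tmp_path / "meta.tsv"
        write_metadata(meta, path)
        assert read_metadata(path) == meta

    def test_metadata_rejects_duplicate_runs(self):
        with pytest.raises(ValidationError):
            SampleMetadata(runs=("r1", "r1"), conditions=("A", "B"))


class TestQuantMatrix:
    def test_single_cell(self, tmp_path):
        m = QuantMatrix(values=pd.DataFrame({"r1": [42.0]}, index=["prot1"]))
        path = tmp_path / "m.tsv"
        write_quant_matrix(m, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[1].split("\t") == ["prot1", "42"]

    def test_missing_cell_is_empty_field(self, tmp_path):
        m = QuantMatrix(
            values=pd.DataFrame(
                {"r1": [1.0, np.nan], "r2": [2.0, 3.0]}, index=["a", "b"]
            )
        )
        path = tmp_path / "m.tsv"
        write_quant_matrix(m, path)
        rows = [l.split("\t") for l in path.read_text().strip().split("\n")]
        assert rows[2][1] == ""  # missing, not "0" and not "nan"
        back = read_quant_matrix(path)
        assert back == m

    def test_random_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 1e7, (3, 4))
        m = QuantMatrix(
            values=pd.DataFrame(vals, index=list("abc"), columns=[f"r{i}" for i in range(4)])
        )
        path = tmp_path / "m.tsv"
        write_quant_matrix(m, path)
        assert read_quant_matrix(path) == m
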