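import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specidx import spectra_io as sio
from specidx.spectra_io import Spectrum, SpectrumError


def make_spec(mz, inten, **kw):
    kw.setdefault("native_id", "s")
    kw.setdefault("precursor_mz", 500.0)
    kw.setdefault("charge", 2)
    return Spectrum.from_peaks(mz=mz, intensity=inten, **kw)


class TestSpectrumConstruction:
    def test_sorts_and_merges_coincident_mz(self):
        s = make_spec([300.0, 100.0, 300.0], [1.0, 2.0, 3.0])
        assert np.all(np.diff(s.mz) > 0)
        assert s.n_peaks == 2
        assert s.intensity[s.mz == 300.0] == pytest.approx(4.0)

    def test_drops_zero_intensity_peaks(self):
        s = make_spec([100.0, 200.0], [0.0, 5.0])
        assert s.n_peaks == 1 and s.mz[0] == 200.0

    def test_rejects_nonpositive_mz(self):
        with pytest.raises(SpectrumError):
            make_spec([0.0, 100.0], [1.0, 1.0])


class TestPreprocess:
    @pytest.mark.parametrize(
        "mz, raw, expected",
        [
            ([500.0], [100.0], [1.0]),
            ([100.0, 200.0], [9.0, 16.0], [3 / 5, 4 / 5]),
            ([1, 2, 3, 4], [7.0] * 4, [0.5] * 4),
        ],
    )
    def test_sqrt_then_unit_norm(self, mz, raw, expected):
        out = sio.preprocess(make_spec(mz, raw))
        assert out.intensity == pytest.approx(expected)

    def test_all_zero_intensities_error(self):
        s = make_spec([100.0], [1.0])
        s.intensity = np.zeros(1)
        with pytest.raises(SpectrumError, match="empty spectrum"):
            sio.preprocess(s)

    @given(
        st.lists(
            st.tuples(
                st.floats(50, 2000), st.floats(1e-6, 1e6)
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_output_always_unit_norm(self, peaks):
        s = make_spec([p[0] for p in peaks], [p[1] for p in peaks])
        out = sio.preprocess(s)
        assert float(np.dot(out.intensity, out.intensity)) == pytest.approx(
            1.0, abs=1e-9
        )


class TestDenoise:
    def test_keeps_top_k_per_window(self):
        s = make_spec([50.0, 60.0, 150.0], [5.0, 9.0, 2.0])
        out = sio.denoise_top_k_window(s, k=1, w=100.0)
        assert list(out.mz) == [60.0, 150.0]

    def test_identity_when_k_large(self):
        s = make_spec([50.0, 60.0, 150.0], [5.0, 9.0, 2.0])
        out = sio.denoise_top_k_window(s, k=10, w=100.0)
        assert np.array_equal(out.mz, s.mz)

    def test_single_peak_unchanged(self):
        s = make_spec([123.4], [1.0])
        out = sio.denoise_top_k_window(s, k=1, w=5.0)
        assert np.array_equal(out.mz, s.mz)

    @given(
        st.lists(
            st.tuples(st.floats(50, 1500), st.floats(0.01, 100)),
            min_size=1,
            max_size=40,
        ),
        st.integers(1, 5),
    )
    def test_never_grows_and_idempotent(self, peaks, k):
        s = make_spec([p[0] for p in peaks], [p[1] for p in peaks])
        once = sio.denoise_top_k_window(s, k, 50.0)
        twice = sio.denoise_top_k_window(once, k, 50.0)
        assert once.n_peaks <= s.n_peaks
        assert np.array_equal(once.mz, twice.mz)
        assert np.array_equal(once.intensity, twice.intensity)


class TestPpmToDa:
    @pytest.mark.parametrize(
        "ppm, mz, expected",
        [(10, 1500, 0.015), (0, 700, 0.0), (10, 500, 0.005)],
    )
    def test_linear_conversion(self, ppm, mz, expected):
        assert sio.ppm_to_da(ppm, mz) == pytest.approx(expected, abs=1e-12)


class TestMsp:
    def test_round_trip_field_by_field(self, small_fixture, tmp_path):
        """write(read(f)) re-read equals the stream of f field by field
        (1e-4 on m/z, 1e-6 relative on intensity). The first write
        canonicalizes the dialect (4-decimal m/z may merge peaks closer
        than the formatting tolerance); after that the round trip is
        exact."""
        raw = tmp_path / "raw.msp"
        sio.write_msp(small_fixture.target_spectra, raw)
        first = list(sio.read_msp(raw))
        again = tmp_path / "again.msp"
        sio.write_msp(first, again)
        second = list(sio.read_msp(again))
        assert len(first) == len(second) == len(small_fixture.target_spectra)
        for a, b in zip(first, second):
            assert (a.native_id, a.peptide, a.charge, a.is_decoy) == (
                b.native_id,
                b.peptide,
                b.charge,
                b.is_decoy,
            )
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-5)
            assert a.n_peaks == b.n_peaks
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-4)
            np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-6)
            assert a.ion_labels == b.ion_labels

    def test_write_preserves_stream_metadata(self, small_fixture, tmp_path):
        path = tmp_path / "t.msp"
        sio.write_msp(small_fixture.target_spectra, path)
        back = list(sio.read_msp(path))
        for a, b in zip(small_fixture.target_spectra, back):
            assert (a.peptide, a.charge, a.is_decoy) == (
                b.peptide, b.charge, b.is_decoy
            )
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-5)
            # peaks closer than the 4-decimal dialect can resolve merge
            assert b.n_peaks <= a.n_peaks
            assert b.n_peaks >= a.n_peaks - 4

    def test_annotation_column_parsed_to_label(self, tmp_path):
        path = tmp_path / "a.msp"
        path.write_text(
            "Name: PEPTIDEK/2\nPrecursorMZ: 450.1\nNum peaks: 1\n"
            '100.5\t12.0\t"y3/0.01"\n'
        )
        (spec,) = sio.read_msp(path)
        assert spec.ion_labels == ("y3",)

    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = tmp_path / "e.msp"
        path.write_text("")
        assert list(sio.read_msp(path)) == []

    def test_malformed_record_names_ordinal_and_line(self, tmp_path):
        path = tmp_path / "bad.msp"
        path.write_text(
            "Name: GOODPEPK/2\nPrecursorMZ: 450.1\nNum peaks: 1\n"
            "100.5 1.0\n\n"
            "Name: BADPEPK/2\nPrecursorMZ: 460.1\nNum peaks: 1\n"
            "oops nope\n"
        )
        with pytest.raises(SpectrumError, match="record 2.*oops"):
            list(sio.read_msp(path))

    def test_truncated_final_record_errors(self, tmp_path):
        path = tmp_path / "trunc.msp"
        path.write_text(
            "Name: PEPTIDEK/2\nPrecursorMZ: 450.1\nNum peaks: 3\n100.5 1.0\n"
        )
        with pytest.raises(SpectrumError, match="truncated"):
            list(sio.read_msp(path))

    def test_decoy_recognized_by_prefix_and_flag(self, tmp_path):
        path = tmp_path / "d.msp"
        path.write_text(
            "Name: DECOY_PEPTIDEK/2\nPrecursorMZ: 450.1\nNum peaks: 1\n"
            "100.5 1.0\n"
        )
        (by_prefix,) = sio.read_msp(path)
        assert by_prefix.is_decoy and by_prefix.peptide == "PEPTIDEK"
        path2 = tmp_path / "t.msp"
        path2.write_text(
            "Name: PEPTIDEK/2\nPrecursorMZ: 450.1\nNum peaks: 1\n100.5 1.0\n"
        )
        (by_flag,) = sio.read_msp(path2, is_decoy=True)
        assert by_flag.is_decoy


class TestMgf:
    def test_charge_conventions(self, tmp_path):
        path = tmp_path / "q.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=with\nPEPMASS=500.2\nCHARGE=2+\n"
            "100.1 10\nEND IONS\n"
            "BEGIN IONS\nTITLE=without\nPEPMASS=400.1\n"
            "200.2 5\nEND IONS\n"
        )
        specs = list(sio.read_mgf(path))
        assert [s.charge for s in specs] == [2, 0]
        assert [s.native_id for s in specs] == ["with", "without"]

    def test_missing_pepmass_errors(self, tmp_path):
        path = tmp_path / "q.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=x\n100.1 10\nEND IONS\n"
        )
        with pytest.raises(SpectrumError, match="PEPMASS"):
            list(sio.read_mgf(path))

    def test_nested_begin_ions_errors(self, tmp_path):
        path = tmp_path / "q.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=x\nPEPMASS=500.0\n100.1 10\n"
            "BEGIN IONS\n200.2 5\nEND IONS\n"
        )
        with pytest.raises(Exception, match="unexpected start"):
            list(sio.read_mgf(path))

    def test_round_trip_ids_from_title(self, small_fixture, tmp_path):
        path = tmp_path / "q.mgf"
        sio.write_mgf(small_fixture.queries[:5], path)
        back = list(sio.read_mgf(path))
        assert len(back) == 5
        for a, b in zip(small_fixture.queries, back):
            assert b.native_id == a.native_id
            assert b.charge == a.charge
            assert b.precursor_mz == pytest.approx(a.precursor_mz, rel=1e-9)
            np.testing.assert_allclose(b.mz, a.mz, atol=1e-4)
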