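import numpy as np
import pytest

from specidx import fixtures as fx
from specidx import index as idx
from specidx import scoring
from specidx import search as srch
from specidx.spectra_io import Spectrum, preprocess


def lib_spec(native_id, charge, premz, mz, inten, peptide="PEPTIDEK"):
    return Spectrum.from_peaks(
        native_id=native_id,
        precursor_mz=premz,
        charge=charge,
        mz=mz,
        intensity=inten,
        peptide=peptide,
    )


class TestSchedule:
    def test_boundary_query_hits_both_partitions(self):
        parts = srch.schedule([700.0], [0.01], [700.0], 2)
        assert parts == [[0], [0]]

    def test_zero_tol_interior_single_partition(self):
        parts = srch.schedule([650.0], [0.0], [700.0], 2)
        assert parts == [[0], []]

    def test_multiple_queries_partition_lists(self):
        parts = srch.schedule(
            [500.0, 900.0, 1300.0], [0.01, 0.01, 0.01], [700.0, 1100.0], 3
        )
        assert parts == [[0], [1], [2]]


class TestCandidateWindow:
    def _pindex(self, entries):
        lib = [
            lib_spec(f"s{i}", z, m, [100.0], [1.0])
            for i, (z, m) in enumerate(entries)
        ]
        return idx.build_precursor_index(lib)

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(7)
        entries = [
            (int(rng.integers(2, 5)), float(rng.uniform(400, 1500)))
            for _ in range(500)
        ]
        pi = self._pindex(entries)
        for _ in range(100):
            z = int(rng.integers(2, 5))
            qmz = float(rng.uniform(400, 1500))
            tol = float(rng.uniform(0, 0.5))
            win = srch.candidate_window(pi, z, qmz, tol)
            expected = {
                i
                for i, (zz, mm) in enumerate(entries)
                if zz == z and abs(mm - qmz) <= tol
            }
            got = {
                int(pi.ranked_ids[r])
                for r in range(win.lo_rank, win.hi_rank)
            }
            assert got == expected

    def test_tolerance_spanning_all_gives_full_block(self):
        pi = self._pindex([(2, 400.0), (2, 500.0), (2, 600.0)])
        win = srch.candidate_window(pi, 2, 500.0, 1000.0)
        assert len(win) == 3

    def test_absent_charge_empty_window(self):
        pi = self._pindex([(2, 400.0), (2, 500.0)])
        win = srch.candidate_window(pi, 5, 500.0, 10.0)
        assert len(win) == 0

    def test_tight_window_spans_single_entry(self):
        pi = self._pindex([(2, 400.0), (2, 500.0), (2, 600.0)])
        win = srch.candidate_window(pi, 2, 500.0, 0.015)
        ids = {int(pi.ranked_ids[r]) for r in range(win.lo_rank, win.hi_rank)}
        assert ids == {1}


class TestAccumulate:
    def _build(self, lib, tmp_path, n_partitions=1):
        out = tmp_path / "ix"
        idx.build_index(
            lib, idx.IndexConfig(n_partitions=n_partitions), out
        )
        manifest = idx.read_manifest(out)
        pi = idx.load_precursor_index(out, manifest)
        part = idx.load_partition(out, 0, pi, manifest)
        return pi, part, manifest["bin_width_da"]

    def test_self_query_unit_dot(self, tmp_path):
        lib = [
            lib_spec("a", 2, 500.0, [100.05, 300.11, 700.19], [1.0, 2.0, 3.0])
        ]
        pi, part, B = self._build(lib, tmp_path)
        q = preprocess(lib[0])
        acc = srch.accumulate(q, part, srch.CandidateWindow(0, 1), B)
        assert acc[0] == pytest.approx(1.0, abs=1e-6)

    def test_no_shared_bins_all_zero(self, tmp_path):
        lib = [lib_spec("a", 2, 500.0, [100.0, 300.0], [1.0, 1.0])]
        pi, part, B = self._build(lib, tmp_path)
        q = preprocess(lib_spec("q", 2, 500.0, [150.0, 350.0], [1.0, 1.0]))
        acc = srch.accumulate(q, part, srch.CandidateWindow(0, 1), B)
        assert np.all(acc == 0.0)

    def test_equals_brute_force_binned_dot(self, tmp_path):
        rng = np.random.default_rng(13)
        lib = [
            lib_spec(
                f"s{i}",
                2,
                500.0 + 0.001 * i,
                np.sort(rng.uniform(100, 1500, 25)),
                rng.uniform(0.1, 1.0, 25),
            )
            for i in range(20)
        ]
        pi, part, B = self._build(lib, tmp_path)
        q = preprocess(
            lib_spec(
                "q", 2, 500.0,
                np.sort(rng.uniform(100, 1500, 30)),
                rng.uniform(0.1, 1.0, 30),
            )
        )
        win = srch.CandidateWindow(0, len(lib))
        acc = srch.accumulate(q, part, win, B)
        cfg = idx.IndexConfig(n_partitions=1)
        for r in range(len(win)):
            ref = idx.stored_view(lib[int(pi.ranked_ids[r])], cfg)
            expected = scoring.binned_dot(q, ref, B)
            assert acc[r] == pytest.approx(expected, abs=1e-6)

    def test_accumulator_bounds(self, default_fixture, default_indexes):
        tdir, _ = default_indexes
        manifest = idx.read_manifest(tdir)
        pi = idx.load_precursor_index(tdir, manifest)
        part = idx.load_partition(tdir, 0, pi, manifest)
        for s in default_fixture.queries[:20]:
            q = preprocess(s)
            win = srch.candidate_window(pi, q.charge, q.precursor_mz, 0.5)
            acc = srch.accumulate(q, part, win, manifest["bin_width_da"])
            assert np.all(acc >= 0.0) and np.all(acc <= 1.0 + 1e-6)


class TestSearchRun:
    def test_self_search_rank1_is_self(self, small_fixture, small_index, tmp_path):
        from specidx.spectra_io import write_mgf

        queries = [
            Spectrum.from_peaks(
                native_id=f"self{i}",
                precursor_mz=s.precursor_mz,
                charge=s.charge,
                mz=s.mz,
                intensity=s.intensity,
            )
            for i, s in enumerate(small_fixture.target_spectra[:30])
        ]
        mgf_path = tmp_path / "self.mgf"
        write_mgf(queries, mgf_path)
        res = srch.search_run(mgf_path, small_index, srch.SearchParams())
        rank1 = {p.query_id: p.library_id for p in res.psms if p.rank == 1}
        assert rank1 == {i: i for i in range(30)}

    def test_top_x_larger_than_candidate_count(self, tmp_path):
        lib = [
            lib_spec(f"s{i}", 2, 500.0 + 0.0001 * i,
                     [100.0 + 10 * i, 200.0 + 10 * i], [1.0, 2.0],
                     peptide=f"PEP{i}K")
            for i in range(3)
        ]
        idx.build_index(lib, idx.IndexConfig(n_partitions=1), tmp_path / "ix")
        q = lib_spec("q", 2, 500.0, [100.0, 200.0], [1.0, 2.0])
        res = srch.search_spectra(
            [q], tmp_path / "ix", srch.SearchParams(top_x=5, n_rescore=50)
        )
        assert sorted(p.rank for p in res.psms) == [1, 2, 3]

    def test_query_below_all_precursors_gets_marker(self, tmp_path):
        lib = [lib_spec("a", 2, 900.0, [100.0], [1.0])]
        idx.build_index(lib, idx.IndexConfig(n_partitions=1), tmp_path / "ix")
        q = lib_spec("low", 2, 420.0, [100.0], [1.0])
        res = srch.search_spectra([q], tmp_path / "ix", srch.SearchParams())
        assert res.psms == [] and res.no_candidate_queries == [(0, "low")]
        srch.write_psm_tsv(res, tmp_path / "out.tsv")
        lines = (tmp_path / "out.tsv").read_text().splitlines()
        assert len(lines) == 2 and "\t-1\t" in lines[1]

    def test_index_agrees_with_oracle(self, small_fixture, small_index):
        params = srch.SearchParams()
        res = srch.search_spectra(small_fixture.queries, small_index, params)
        oracle = srch.oracle_search(
            small_fixture.queries,
            small_fixture.target_spectra,
            params,
            idx.IndexConfig(n_partitions=4),
        )
        b1 = {p.query_id: p for p in res.psms if p.rank == 1}
        b2 = {p.query_id: p for p in oracle.psms if p.rank == 1}
        assert set(b1) == set(b2)
        for qid in b1:
            assert b1[qid].library_id == b2[qid].library_id
            assert b1[qid].scores.final_score == pytest.approx(
                b2[qid].scores.final_score, abs=1e-6
            )

    def test_partition_invariance_small(self, small_fixture, tmp_path):
        tables = []
        for n in (1, 4):
            out = tmp_path / f"p{n}"
            idx.build_index(
                small_fixture.target_spectra,
                idx.IndexConfig(n_partitions=n),
                out,
            )
            res = srch.search_spectra(
                small_fixture.queries, out, srch.SearchParams()
            )
            tables.append(res)
        a, b = tables
        assert [(p.query_id, p.library_id, p.rank) for p in a.psms] == [
            (p.query_id, p.library_id, p.rank) for p in b.psms
        ]
        for x, y in zip(a.psms, b.psms):
            assert x.scores.final_score == pytest.approx(
                y.scores.final_score, abs=1e-6
            )

    def test_deterministic_output_bytes(self, small_fixture, small_index, tmp_path):
        params = srch.SearchParams()
        for name in ("a.tsv", "b.tsv"):
            res = srch.search_spectra(
                small_fixture.queries, small_index, params
            )
            srch.write_psm_tsv(res, tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (
            tmp_path / "b.tsv"
        ).read_bytes()

    def test_psm_tsv_round_trip(self, small_fixture, small_index, tmp_path):
        res = srch.search_spectra(
            small_fixture.queries, small_index, srch.SearchParams()
        )
        srch.write_psm_tsv(res, tmp_path / "x.tsv")
        back = srch.read_psm_tsv(tmp_path / "x.tsv")
        assert len(back.psms) == len(res.psms)
        for x, y in zip(res.psms, back.psms):
            assert (x.query_id, x.library_id, x.rank, x.peptide) == (
                y.query_id, y.library_id, y.rank, y.peptide
            )
            assert y.scores.final_score == pytest.approx(
                x.scores.final_score, rel=1e-6
            )

    def test_oracle_empty_library_no_psms(self):
        q = lib_spec("q", 2, 500.0, [100.0], [1.0])
        res = srch.oracle_search([q], [], srch.SearchParams())
        assert res.psms == []

    def test_oracle_single_candidate_is_rank1(self):
        lib = [lib_spec("a", 2, 500.0, [100.0], [1.0])]
        q = lib_spec("q", 2, 500.0, [700.0], [1.0])  # no spectral overlap
        res = srch.oracle_search([q], lib, srch.SearchParams())
        assert len(res.psms) == 1 and res.psms[0].rank == 1
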