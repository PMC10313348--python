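"""Query scheduling, fragment-index accumulation and candidate rescoring.

The search proceeds per partition: every query is scheduled to each
partition whose precursor interval intersects its tolerance window, the
partition is loaded once, and for every scheduled query

1. a binary search on the precursor index yields the half-open rank
   window of in-tolerance candidates (per charge block; an
   unknown-charge query visits every block);
2. a zeroed score accumulator over that window is allocated;
3. for each query peak only its own fragment bin is visited, and a
   binary search inside the bin locates the contiguous run of entries
   whose parent rank falls in the window;
4. the run's intensities are multiplied with the query peak intensity
   and added to the parent scores in one batched multiply-add.

The accumulator therefore equals the binned spectral dot product for
every candidate. The highest-accumulating candidates are then rescored
with the Gaussian bias-adjusted similarity, results from all partitions
are merged per query, and only the top X PSMs are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import index as idx
from . import scoring
from .spectra_io import (
    Spectrum,
    SpectrumError,
    denoise_top_k_window,
    ppm_to_da,
    preprocess,
    read_mgf,
)


@dataclass(frozen=True)
class SearchParams:
    """tol_ppm: precursor tolerance (applied on m/z, matching the
    index's m/z ordering); top_x: PSMs reported per query; n_rescore:
    accumulator-ranked candidates rescored per query and partition
    (must comfortably exceed top_x so the refined score can reorder);
    sigma defaults to the index bin width. Optional top-k/window-w
    denoising is off by default."""

    tol_ppm: float = 10.0
    top_x: int = 1
    n_rescore: int = 50
    sigma: Optional[float] = None
    match_cutoff_sigmas: float = 5.0
    denoise_k: Optional[int] = None
    denoise_w: float = 100.0

    def __post_init__(self):
        if self.top_x < 1:
            raise ValueError("top_x must be >= 1")
        if self.n_rescore < self.top_x:
            raise ValueError("n_rescore must be >= top_x")


@dataclass(frozen=True)
class CandidateWindow:
    """Half-open rank interval of candidates for one (charge, m/z +- tol)
    query."""

    lo_rank: int
    hi_rank: int

    def __len__(self) -> int:
        return max(0, self.hi_rank - self.lo_rank)


@dataclass
class PSM:
    query_id: int
    query_native_id: str
    library_id: int
    peptide: str
    is_decoy: bool
    rank: int
    scores: scoring.ScoreVector


@dataclass
class SearchResult:
    psms: List[PSM]
    no_candidate_queries: List[Tuple[int, str]]  # (query_id, native_id)
    n_queries: int = 0


def schedule(
    query_mzs: Sequence[float],
    tol_das: Sequence[float],
    boundaries: Sequence[float],
    n_partitions: int,
) -> List[List[int]]:
    """Per-partition query lists: a query lands in every partition whose
    precursor interval intersects [mz - tol, mz + tol]; a query sitting
    on a boundary is scheduled to both neighbours."""
    b = np.asarray(boundaries, dtype=np.float64)
    out: List[List[int]] = [[] for _ in range(n_partitions)]
    for qid, (mz, tol) in enumerate(zip(query_mzs, tol_das)):
        lo = int(np.searchsorted(b, mz - tol, side="right"))
        hi = int(np.searchsorted(b, mz + tol, side="left"))
        for p in range(lo, min(hi, n_partitions - 1) + 1):
            out[p].append(qid)
    return out


def candidate_window(
    pindex: idx.PrecursorIndex, charge: int, query_mz: float, tol_da: float
) -> CandidateWindow:
    """Binary-search bounds of in-tolerance candidates in one charge
    block; equals what a linear scan would produce."""
    blo, bhi = pindex.charge_block(charge)
    mzs = pindex.sorted_mz[blo:bhi]
    lo = blo + int(np.searchsorted(mzs, query_mz - tol_da, side="left"))
    hi = blo + int(np.searchsorted(mzs, query_mz + tol_da, side="right"))
    return CandidateWindow(lo, hi)


def accumulate(
    query: Spectrum,
    part: idx.Partition,
    win: CandidateWindow,
    B: float,
) -> np.ndarray:
    """Dense binned-dot-product accumulator over the window's ranks.

    For each query peak only the single bin ``floor(mz / B)`` is
    visited; within the bin the contiguous rank-run [lo, hi) is found by
    binary search and contributed via one batched multiply-add."""
    acc = np.zeros(len(win))
    if len(win) == 0:
        return acc
    qbins = idx.bins_of(query.mz, B)
    for qi in range(query.mz.size):
        sl = part.bin_slice(int(qbins[qi]))
        if sl.start == sl.stop:
            continue
        ranks = part.rank[sl]
        a = sl.start + int(np.searchsorted(ranks, win.lo_rank, side="left"))
        b = sl.start + int(np.searchsorted(ranks, win.hi_rank, side="left"))
        if a == b:
            continue
        np.add.at(
            acc,
            part.rank[a:b].astype(np.int64) - win.lo_rank,
            query.intensity[qi] * part.intensity[a:b].astype(np.float64),
        )
    return acc


def _prepare_query(s: Spectrum, params: SearchParams) -> Spectrum:
    if params.denoise_k is not None:
        s = denoise_top_k_window(s, params.denoise_k, params.denoise_w)
    return preprocess(s)


def _finalize_query_psms(
    cands: List[PSM], top_x: int
) -> List[PSM]:
    """Deduplicate per library id (best-scoring instance wins), order by
    final score with deterministic tie-breaks (higher shared peak count,
    then lower library id), keep top X, assign ranks and fill the
    rank-dependent features."""
    best: Dict[int, PSM] = {}
    for c in cands:
        prev = best.get(c.library_id)
        if prev is None or c.scores.final_score > prev.scores.final_score:
            best[c.library_id] = c
    ordered = sorted(
        best.values(),
        key=lambda c: (
            -c.scores.final_score,
            -c.scores.shared_peak_count,
            c.library_id,
        ),
    )[:top_x]
    for r, c in enumerate(ordered, start=1):
        c.rank = r
    for i, c in enumerate(ordered):
        nxt = ordered[i + 1].scores if i + 1 < len(ordered) else None
        c.scores.delta_final = c.scores.final_score - (
            nxt.final_score if nxt is not None else 0.0
        )
        c.scores.f_value = scoring.f_value(
            c.scores.dot, nxt.dot if nxt is not None else None
        )
    return ordered


def _rescore_candidates(
    query_pre: Spectrum,
    query_id: int,
    part: idx.Partition,
    pindex: idx.PrecursorIndex,
    win: CandidateWindow,
    acc: np.ndarray,
    params: SearchParams,
    sparams: scoring.ScoringParams,
    B: float,
) -> List[PSM]:
    n_take = min(params.n_rescore, len(win))
    if n_take == 0:
        return []
    order = np.lexsort((np.arange(len(win)), -acc))[:n_take]
    out: List[PSM] = []
    for local in order:
        rank = win.lo_rank + int(local)
        lib_id = int(pindex.ranked_ids[rank])
        rmz, rint = part.spectrum_peaks(lib_id)
        if rmz.size == 0:
            continue  # parent lives in another partition (or no in-range peaks)
        rec = pindex.records[lib_id]
        ref = Spectrum(
            native_id=rec.native_id,
            precursor_mz=rec.precursor_mz,
            charge=rec.charge,
            mz=rmz.astype(np.float64),
            intensity=rint.astype(np.float64),
            peptide=rec.peptide,
            is_decoy=rec.is_decoy,
        )
        sv = scoring.score_pair(query_pre, ref, sparams, B)
        out.append(
            PSM(
                query_id=query_id,
                query_native_id=query_pre.native_id,
                library_id=lib_id,
                peptide=rec.peptide,
                is_decoy=rec.is_decoy,
                rank=0,
                scores=sv,
            )
        )
    return out


def search_spectra(
    queries: Sequence[Spectrum], index_dir, params: SearchParams
) -> SearchResult:
    """Search an in-memory list of raw query spectra against an on-disk
    index. Queries are processed independently; results do not depend on
    processing order."""
    index_dir = Path(index_dir)
    manifest = idx.read_manifest(index_dir)
    B = manifest["bin_width_da"]
    sigma = params.sigma if params.sigma is not None else B
    sparams = scoring.ScoringParams(
        sigma=sigma, match_cutoff_sigmas=params.match_cutoff_sigmas
    )
    pindex = idx.load_precursor_index(index_dir, manifest)
    boundaries = manifest["partition_boundaries"]

    prepared: List[Optional[Spectrum]] = []
    for s in queries:
        try:
            prepared.append(_prepare_query(s, params))
        except SpectrumError:
            prepared.append(None)

    tol_das = [
        ppm_to_da(params.tol_ppm, s.precursor_mz) if s is not None else 0.0
        for s in prepared
    ]
    mzs = [s.precursor_mz if s is not None else -1.0 for s in prepared]
    per_part = schedule(mzs, tol_das, boundaries, manifest["n_partitions"])

    cand_by_query: Dict[int, List[PSM]] = {i: [] for i in range(len(queries))}
    for pid, qids in enumerate(per_part):
        qids = [q for q in qids if prepared[q] is not None]
        if not qids:
            continue
        part = idx.load_partition(index_dir, pid, pindex, manifest)
        for qid in qids:
            q = prepared[qid]
            charges = [q.charge] if q.charge > 0 else pindex.charges
            for charge in charges:
                win = candidate_window(
                    pindex, charge, q.precursor_mz, tol_das[qid]
                )
                if len(win) == 0:
                    continue
                acc = accumulate(q, part, win, B)
                cand_by_query[qid].extend(
                    _rescore_candidates(
                        q, qid, part, pindex, win, acc,
                        params, sparams, B,
                    )
                )
        del part

    psms: List[PSM] = []
    empty: List[Tuple[int, str]] = []
    for qid in range(len(queries)):
        finals = _finalize_query_psms(cand_by_query[qid], params.top_x)
        if finals:
            psms.extend(finals)
        else:
            empty.append((qid, queries[qid].native_id))
    return SearchResult(
        psms=psms, no_candidate_queries=empty, n_queries=len(queries)
    )


def search_run(queries_mgf, index_dir, params: SearchParams) -> SearchResult:
    """File-based entry point: read an MGF run and search it."""
    queries = list(read_mgf(queries_mgf))
    return search_spectra(queries, index_dir, params)


def oracle_search(
    queries: Sequence[Spectrum],
    library: Sequence[Spectrum],
    params: SearchParams,
    cfg: Optional[idx.IndexConfig] = None,
) -> SearchResult:
    """Exhaustive index-free reference search for equivalence testing.

    Scores every in-tolerance candidate directly through the scoring
    module against the canonical stored view of each library spectrum
    (preprocessed, range-filtered, float32-quantized), with the same
    tolerance, tie-break and ranking rules as the indexed path. Intended
    for small libraries."""
    cfg = cfg or idx.IndexConfig()
    B = cfg.bin_width_da
    sigma = params.sigma if params.sigma is not None else B
    sparams = scoring.ScoringParams(
        sigma=sigma, match_cutoff_sigmas=params.match_cutoff_sigmas
    )
    views = [idx.stored_view(s, cfg) for s in library]
    lib_mz = np.array([s.precursor_mz for s in library])
    lib_charge = np.array([s.charge for s in library])

    psms: List[PSM] = []
    empty: List[Tuple[int, str]] = []
    for qid, raw in enumerate(queries):
        try:
            q = _prepare_query(raw, params)
        except SpectrumError:
            empty.append((qid, raw.native_id))
            continue
        tol = ppm_to_da(params.tol_ppm, q.precursor_mz)
        in_tol = np.abs(lib_mz - q.precursor_mz) <= tol
        if q.charge > 0:
            in_tol &= lib_charge == q.charge
        cands: List[PSM] = []
        for lib_id in np.flatnonzero(in_tol):
            ref = views[int(lib_id)]
            if ref.n_peaks == 0:
                continue
            sv = scoring.score_pair(q, ref, sparams, B)
            cands.append(
                PSM(
                    query_id=qid,
                    query_native_id=q.native_id,
                    library_id=int(lib_id),
                    peptide=ref.peptide or "",
                    is_decoy=ref.is_decoy,
                    rank=0,
                    scores=sv,
                )
            )
        finals = _finalize_query_psms(cands, params.top_x)
        if finals:
            psms.extend(finals)
        else:
            empty.append((qid, raw.native_id))
    return SearchResult(
        psms=psms, no_candidate_queries=empty, n_queries=len(queries)
    )


PSM_TSV_COLUMNS = (
    "query_id",
    "title",
    "library_id",
    "peptide",
    "is_decoy",
    "rank",
) + scoring.ScoreVector.FEATURE_ORDER


def write_psm_tsv(result: SearchResult, path) -> None:
    """PSM table with one explicit marker row (library_id -1, rank 0)
    per query that produced no candidates."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PSM_TSV_COLUMNS) + "\n")
        rows = [
            (p.query_id, p.rank, p) for p in result.psms
        ] + [(qid, 0, None) for qid, _ in result.no_candidate_queries]
        titles = {p.query_id: p.query_native_id for p in result.psms}
        titles.update({qid: t for qid, t in result.no_candidate_queries})
        for qid, rank, p in sorted(rows, key=lambda r: (r[0], r[1])):
            if p is None:
                fh.write(
                    f"{qid}\t{titles[qid]}\t-1\t\t0\t0"
                    + "\t0" * len(scoring.ScoreVector.FEATURE_ORDER)
                    + "\n"
                )
                continue
            feats = p.scores.as_feature_dict()
            vals = "\t".join(
                f"{feats[name]:.9g}" if isinstance(feats[name], float)
                else str(feats[name])
                for name in scoring.ScoreVector.FEATURE_ORDER
            )
            fh.write(
                f"{p.query_id}\t{p.query_native_id}\t{p.library_id}\t"
                f"{p.peptide}\t{int(p.is_decoy)}\t{p.rank}\t{vals}\n"
            )


def read_psm_tsv(path) -> SearchResult:
    psms: List[PSM] = []
    empty: List[Tuple[int, str]] = []
    qids = set()
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PSM_TSV_COLUMNS:
            raise ValueError(f"unexpected PSM TSV header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            qid = int(f[0])
            qids.add(qid)
            if f[2] == "-1":
                empty.append((qid, f[1]))
                continue
            feat_vals = f[6:]
            sv = scoring.ScoreVector()
            for name, val in zip(scoring.ScoreVector.FEATURE_ORDER, feat_vals):
                cur = getattr(sv, name)
                setattr(sv, name, int(val) if isinstance(cur, int) else float(val))
            psms.append(
                PSM(
                    query_id=qid,
                    query_native_id=f[1],
                    library_id=int(f[2]),
                    peptide=f[3],
                    is_decoy=bool(int(f[4])),
                    rank=int(f[5]),
                    scores=sv,
                )
            )
    return SearchResult(
        psms=psms, no_candidate_queries=empty, n_queries=len(qids)
    )
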