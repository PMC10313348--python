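"""Partitioned precursor + fragment index over a spectral library.

Two auxiliary structures make the search fast:

* the *precursor index* ranks all library spectra by (charge,
  precursor m/z) and keeps the inverse permutation ``rank_of`` so a
  fragment's parent id maps to its rank in O(1);
* the *fragment index* stores every in-range library peak as a
  ``(mz, intensity, parent_id)`` triplet inside m/z bins of width ``B``;
  within a bin, triplets are sorted by parent rank so the candidates of
  one precursor window form a contiguous run.

The fragment index is split into partitions tied to non-overlapping
precursor m/z intervals: a triplet lives only in the partition whose
interval contains its parent's precursor m/z, and each partition carries
the full bin range, so it acts as a complete, independently loadable
fragment index for its slice of the library. Peak working memory during
a build is bounded by the largest single partition plus the precursor
table, never by total library size: phase 1 streams the library once and
spills provisional triplets to per-partition files, phase 2 rewrites one
partition at a time with bin/rank-sorted entries.

On disk an index directory holds, per partition, a little-endian record
file (float32 mz, float32 intensity, uint32 parent_id) and an int64 bin
offset file, plus a precursor TSV and a JSON manifest with the
configuration, boundaries, counts and SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .spectra_io import Spectrum, preprocess

MANIFEST_NAME = "manifest.json"
PRECURSORS_NAME = "precursors.tsv"
FORMAT_VERSION = 1

# (mz, intensity, parent id) triplet as stored on disk
ENTRY_DTYPE = np.dtype(
    [("mz", "<f4"), ("intensity", "<f4"), ("parent", "<u4")]
)
# phase-1 spill record carries the bin explicitly
SPILL_DTYPE = np.dtype(
    [("bin", "<u4"), ("mz", "<f4"), ("intensity", "<f4"), ("parent", "<u4")]
)

_SPILL_FLUSH = 1 << 15  # total buffered triplets before spilling to disk


class IndexError_(RuntimeError):
    """Index construction or loading failure."""


@dataclass(frozen=True)
class IndexConfig:
    """Build-time configuration.

    bin_width_da
        Fragment bin width ``B`` (Da); 0.2 by default, matching a typical
        ion-trap fragment tolerance.
    n_partitions
        Number of precursor m/z partitions; 64 by default.
    mz_min, mz_max
        Indexed fragment m/z range (half-open); fragments outside are
        dropped and counted.
    partition_boundaries
        Optional explicit precursor m/z cut points (strictly increasing,
        length ``n_partitions - 1``); computed from the library's
        precursor quantiles when absent.
    """

    bin_width_da: float = 0.2
    n_partitions: int = 64
    mz_min: float = 0.0
    mz_max: float = 2000.0
    partition_boundaries: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        if self.bin_width_da <= 0:
            raise ValueError("bin width must be positive")
        if self.n_partitions < 1:
            raise ValueError("need at least one partition")
        if self.partition_boundaries is not None:
            b = list(self.partition_boundaries)
            if any(x >= y for x, y in zip(b, b[1:])):
                raise ValueError("boundaries must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return int(math.ceil(self.mz_max / self.bin_width_da))


@dataclass(frozen=True)
class PrecursorRecord:
    id: int
    native_id: str
    charge: int
    precursor_mz: float
    peptide: str
    is_decoy: bool
    retention_time: Optional[float] = None


@dataclass
class PrecursorIndex:
    """Library spectra ranked by (charge, precursor m/z) with the inverse
    id -> rank lookup precomputed by a linear scan."""

    records: List[PrecursorRecord]
    ranked_ids: np.ndarray  # uint32, rank -> id
    rank_of: np.ndarray  # uint32, id -> rank
    sorted_charge: np.ndarray  # int32 along ranks
    sorted_mz: np.ndarray  # float64 along ranks

    def __len__(self) -> int:
        return len(self.records)

    @property
    def charges(self) -> list:
        return sorted(set(int(c) for c in self.sorted_charge))

    def charge_block(self, charge: int) -> Tuple[int, int]:
        """Half-open rank interval of one charge block (empty if the
        charge is absent from the library)."""
        lo = int(np.searchsorted(self.sorted_charge, charge, side="left"))
        hi = int(np.searchsorted(self.sorted_charge, charge, side="right"))
        return lo, hi


def build_precursor_index(library: Iterable) -> PrecursorIndex:
    """Rank library spectra by (charge, precursor m/z); ids are assigned
    in stream order, ties broken by id for determinism."""
    records: List[PrecursorRecord] = []
    for spec in library:
        if isinstance(spec, PrecursorRecord):
            rec = spec
            if rec.id != len(records):
                raise IndexError_(
                    f"precursor ids must be dense/in order, got {rec.id} "
                    f"at position {len(records)}"
                )
        else:
            if spec.peptide is None:
                raise IndexError_(
                    f"library spectrum {spec.native_id!r} lacks a peptide"
                )
            rec = PrecursorRecord(
                id=len(records),
                native_id=spec.native_id,
                charge=spec.charge,
                precursor_mz=spec.precursor_mz,
                peptide=spec.peptide,
                is_decoy=spec.is_decoy,
                retention_time=spec.retention_time,
            )
        records.append(rec)
    if not records:
        raise IndexError_("empty library")
    charges = np.array([r.charge for r in records], dtype=np.int32)
    mzs = np.array([r.precursor_mz for r in records], dtype=np.float64)
    ids = np.arange(len(records), dtype=np.uint32)
    order = np.lexsort((ids, mzs, charges))
    ranked_ids = ids[order].astype(np.uint32)
    rank_of = np.empty(len(records), dtype=np.uint32)
    rank_of[ranked_ids] = np.arange(len(records), dtype=np.uint32)
    return PrecursorIndex(
        records=records,
        ranked_ids=ranked_ids,
        rank_of=rank_of,
        sorted_charge=charges[order],
        sorted_mz=mzs[order],
    )


def bin_of(mz: float, B: float) -> int:
    """Fragment bin index under the half-open convention
    ``[b*B, (b+1)*B)``: ``floor(mz / B)``."""
    if mz < 0:
        raise ValueError("mz must be non-negative")
    if B <= 0:
        raise ValueError("bin width must be positive")
    return int(math.floor(mz / B))


def bins_of(mz: np.ndarray, B: float) -> np.ndarray:
    return np.floor(np.asarray(mz, dtype=np.float64) / B).astype(np.int64)


def make_partition_boundaries(
    precursor_mzs, n: int
) -> Tuple[float, ...]:
    """Equal-count (quantile) cut points splitting the precursor m/z
    multiset into ``n`` near-equal partitions.

    Returns up to ``n - 1`` strictly increasing boundaries; intervals are
    ``[0, b1), [b1, b2), ..., [b_last, inf)``. Degenerate inputs (fewer
    distinct m/z values than partitions) collapse to fewer non-empty
    partitions with a warning.
    """
    if n < 1:
        raise ValueError("need at least one partition")
    if isinstance(precursor_mzs, PrecursorIndex):
        mzs = np.sort(np.asarray(
            [r.precursor_mz for r in precursor_mzs.records], dtype=np.float64
        ))
    else:
        mzs = np.sort(np.asarray(precursor_mzs, dtype=np.float64))
    if n == 1 or mzs.size == 0:
        return ()
    bounds: List[float] = []
    for i in range(1, n):
        cut = (i * mzs.size) // n
        if cut <= 0 or cut >= mzs.size:
            continue
        lo, hi = mzs[cut - 1], mzs[cut]
        if hi > lo:
            bounds.append(0.5 * (lo + hi))
    bounds = sorted(set(bounds))
    if len(bounds) < n - 1:
        warnings.warn(
            f"only {len(bounds) + 1} non-empty partitions possible for "
            f"{n} requested (too few distinct precursor m/z values)",
            stacklevel=2,
        )
    return tuple(bounds)


def partition_of(precursor_mz, boundaries) -> np.ndarray:
    """Partition id(s) owning the given precursor m/z value(s)."""
    b = np.asarray(boundaries, dtype=np.float64)
    return np.searchsorted(b, np.asarray(precursor_mz), side="right")


# ---------------------------------------------------------------------------
# build
# ---------------------------------------------------------------------------


@dataclass
class BuildStats:
    n_spectra: int = 0
    n_fragments_indexed: int = 0
    n_fragments_dropped: int = 0
    peak_resident_entries: int = 0  # coarse in-memory triplet high-water mark


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_index(library, cfg: IndexConfig, out_dir) -> BuildStats:
    """Build the on-disk index from a stream of *raw* library spectra.

    The library is streamed exactly once; pre-processing (sqrt +
    unit-norm) is applied here, so the index stores post-preprocessing
    intensities and the accumulation phase of the search is a pure
    multiply-add. When ``cfg.partition_boundaries`` is unset the library
    must be an in-memory sequence (so precursor quantiles can be taken
    first); streaming callers pre-compute boundaries from a cheap
    precursor-only scan.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise IndexError_(f"output directory not writable: {out}") from exc

    boundaries = cfg.partition_boundaries
    if boundaries is None:
        if not isinstance(library, Sequence):
            raise IndexError_(
                "partition boundaries unset and library is not a sequence; "
                "precompute boundaries with make_partition_boundaries()"
            )
        boundaries = make_partition_boundaries(
            [s.precursor_mz for s in library], cfg.n_partitions
        )
    boundaries = tuple(boundaries)
    n_parts = len(boundaries) + 1
    B = cfg.bin_width_da
    stats = BuildStats()

    # phase 1: stream, preprocess, spill provisional triplets per partition
    spill_paths = [out / f"partition_{p:05d}.spill" for p in range(n_parts)]
    spill_fhs = [open(p, "wb") for p in spill_paths]
    buffers: List[List[np.ndarray]] = [[] for _ in range(n_parts)]
    buffered = [0] * n_parts
    records: List[PrecursorRecord] = []
    seen_target_ids = set()
    resident = 0

    def _flush(p: int):
        nonlocal resident
        if buffers[p]:
            np.concatenate(buffers[p]).tofile(spill_fhs[p])
            buffers[p].clear()
            buffered[p] = 0

    try:
        for spec in library:
            if spec.peptide is None:
                raise IndexError_(
                    f"library spectrum {spec.native_id!r} lacks a peptide"
                )
            if not spec.is_decoy:
                if spec.native_id in seen_target_ids:
                    raise IndexError_(
                        f"duplicate native id in target library: "
                        f"{spec.native_id!r}"
                    )
                seen_target_ids.add(spec.native_id)
            sid = len(records)
            records.append(
                PrecursorRecord(
                    id=sid,
                    native_id=spec.native_id,
                    charge=spec.charge,
                    precursor_mz=spec.precursor_mz,
                    peptide=spec.peptide,
                    is_decoy=spec.is_decoy,
                    retention_time=spec.retention_time,
                )
            )
            pre = preprocess(spec)
            in_range = (pre.mz >= cfg.mz_min) & (pre.mz < cfg.mz_max)
            n_in = int(in_range.sum())
            stats.n_fragments_dropped += pre.n_peaks - n_in
            stats.n_fragments_indexed += n_in
            if n_in == 0:
                continue
            part = int(partition_of(spec.precursor_mz, boundaries))
            chunk = np.empty(n_in, dtype=SPILL_DTYPE)
            chunk["bin"] = bins_of(pre.mz[in_range], B)
            chunk["mz"] = pre.mz[in_range]
            chunk["intensity"] = pre.intensity[in_range]
            chunk["parent"] = sid
            buffers[part].append(chunk)
            buffered[part] += n_in
            resident = max(resident, sum(buffered))
            if sum(buffered) >= _SPILL_FLUSH:
                for pp in range(n_parts):
                    _flush(pp)
        for p in range(n_parts):
            _flush(p)
    finally:
        for fh in spill_fhs:
            fh.close()

    if not records:
        for p in spill_paths:
            p.unlink(missing_ok=True)
        raise IndexError_("empty library")
    stats.n_spectra = len(records)

    # phase 2: precursor index, then rewrite each partition bin/rank sorted
    pindex = build_precursor_index(records)
    with open(out / PRECURSORS_NAME, "w", encoding="utf-8") as fh:
        fh.write(
            "id\tnative_id\tcharge\tprecursor_mz\tpeptide\tis_decoy"
            "\tretention_time\n"
        )
        for r in pindex.records:
            rt = "" if r.retention_time is None else f"{r.retention_time:.4f}"
            fh.write(
                f"{r.id}\t{r.native_id}\t{r.charge}\t{r.precursor_mz:.8f}"
                f"\t{r.peptide}\t{int(r.is_decoy)}\t{rt}\n"
            )

    n_bins = cfg.n_bins
    part_meta = []
    for p in range(n_parts):
        spill = np.fromfile(spill_paths[p], dtype=SPILL_DTYPE)
        resident = max(resident, spill.size)
        rank = pindex.rank_of[spill["parent"]]
        order = np.lexsort((rank, spill["bin"]))
        entries = np.empty(spill.size, dtype=ENTRY_DTYPE)
        entries["mz"] = spill["mz"][order]
        entries["intensity"] = spill["intensity"][order]
        entries["parent"] = spill["parent"][order]
        offsets = np.zeros(n_bins + 1, dtype=np.int64)
        counts = np.bincount(spill["bin"], minlength=n_bins)
        offsets[1:] = np.cumsum(counts)
        rec_path = out / f"partition_{p:05d}.bin"
        off_path = out / f"partition_{p:05d}.offsets"
        entries.tofile(rec_path)
        offsets.tofile(off_path)
        spill_paths[p].unlink()
        lo = 0.0 if p == 0 else boundaries[p - 1]
        hi = math.inf if p == n_parts - 1 else boundaries[p]
        part_meta.append(
            {
                "partition_id": p,
                "interval": [lo, None if math.isinf(hi) else hi],
                "n_entries": int(spill.size),
                "records_file": rec_path.name,
                "offsets_file": off_path.name,
                "records_sha256": _sha256(rec_path),
                "offsets_sha256": _sha256(off_path),
            }
        )
    stats.peak_resident_entries = resident

    manifest = {
        "format_version": FORMAT_VERSION,
        "bin_width_da": B,
        "mz_min": cfg.mz_min,
        "mz_max": cfg.mz_max,
        "n_bins": n_bins,
        "n_partitions": n_parts,
        "partition_boundaries": list(boundaries),
        "n_spectra": stats.n_spectra,
        "n_fragments_indexed": stats.n_fragments_indexed,
        "n_fragments_dropped": stats.n_fragments_dropped,
        "precursors_file": PRECURSORS_NAME,
        "precursors_sha256": _sha256(out / PRECURSORS_NAME),
        "partitions": part_meta,
    }
    tmp = out / (MANIFEST_NAME + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    tmp.replace(out / MANIFEST_NAME)
    return stats


# ---------------------------------------------------------------------------
# load
# ---------------------------------------------------------------------------


def read_manifest(index_dir) -> dict:
    path = Path(index_dir) / MANIFEST_NAME
    if not path.exists():
        raise IndexError_(f"no index manifest at {path}")
    return json.loads(path.read_text())


def load_precursor_index(index_dir, manifest: Optional[dict] = None) -> PrecursorIndex:
    index_dir = Path(index_dir)
    manifest = manifest or read_manifest(index_dir)
    path = index_dir / manifest["precursors_file"]
    if _sha256(path) != manifest["precursors_sha256"]:
        raise IndexError_(f"checksum mismatch for {path}")
    records: List[PrecursorRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)  # header
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                PrecursorRecord(
                    id=int(f[0]),
                    native_id=f[1],
                    charge=int(f[2]),
                    precursor_mz=float(f[3]),
                    peptide=f[4],
                    is_decoy=bool(int(f[5])),
                    retention_time=float(f[6]) if f[6] else None,
                )
            )
    return build_precursor_index(records)


@dataclass
class Partition:
    """One precursor interval's complete set of fragment bins, plus the
    per-parent view used to reconstruct candidate spectra at rescoring."""

    partition_id: int
    precursor_interval: Tuple[float, float]
    bin_width_da: float
    offsets: np.ndarray  # int64, len n_bins + 1
    mz: np.ndarray  # float32, stored order (bin, rank)
    intensity: np.ndarray  # float32
    parent: np.ndarray  # uint32
    rank: np.ndarray  # uint32, parallel to entries

    _parent_order: Optional[np.ndarray] = field(default=None, repr=False)
    _parent_starts: Optional[np.ndarray] = field(default=None, repr=False)
    _parent_ids: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_entries(self) -> int:
        return int(self.mz.shape[0])

    def bin_slice(self, b: int) -> slice:
        if b < 0 or b >= self.offsets.size - 1:
            return slice(0, 0)
        return slice(int(self.offsets[b]), int(self.offsets[b + 1]))

    def _ensure_parent_view(self):
        if self._parent_order is None:
            order = np.argsort(self.parent, kind="stable")
            sorted_parents = self.parent[order]
            ids, starts = np.unique(sorted_parents, return_index=True)
            self._parent_order = order
            self._parent_ids = ids
            self._parent_starts = np.append(starts, sorted_parents.size)

    def spectrum_peaks(self, library_id: int) -> Tuple[np.ndarray, np.ndarray]:
        """Stored (m/z, intensity) arrays of one parent spectrum, sorted
        by m/z — the canonical float32 view used for rescoring."""
        self._ensure_parent_view()
        i = int(np.searchsorted(self._parent_ids, library_id))
        if i >= self._parent_ids.size or self._parent_ids[i] != library_id:
            return (
                np.empty(0, dtype=np.float32),
                np.empty(0, dtype=np.float32),
            )
        sel = self._parent_order[
            self._parent_starts[i]: self._parent_starts[i + 1]
        ]
        mz = self.mz[sel]
        order = np.argsort(mz, kind="stable")
        return mz[order], self.intensity[sel][order]

    def to_bytes(self) -> Tuple[bytes, bytes]:
        """Re-serialize to the on-disk (records, offsets) byte strings."""
        entries = np.empty(self.n_entries, dtype=ENTRY_DTYPE)
        entries["mz"] = self.mz
        entries["intensity"] = self.intensity
        entries["parent"] = self.parent
        return entries.tobytes(), self.offsets.tobytes()


def load_partition(
    index_dir, pid: int, pindex: Optional[PrecursorIndex] = None,
    manifest: Optional[dict] = None,
) -> Partition:
    """Materialize one partition; never touches another partition's files.
    Checksums are verified; a corrupt or missing file raises."""
    index_dir = Path(index_dir)
    manifest = manifest or read_manifest(index_dir)
    if pid < 0 or pid >= manifest["n_partitions"]:
        raise IndexError_(
            f"partition id {pid} out of range "
            f"(index has {manifest['n_partitions']})"
        )
    meta = manifest["partitions"][pid]
    rec_path = index_dir / meta["records_file"]
    off_path = index_dir / meta["offsets_file"]
    for path, want in (
        (rec_path, meta["records_sha256"]),
        (off_path, meta["offsets_sha256"]),
    ):
        if not path.exists():
            raise IndexError_(f"missing partition file {path}")
        if _sha256(path) != want:
            raise IndexError_(f"checksum mismatch for {path}")
    entries = np.fromfile(rec_path, dtype=ENTRY_DTYPE)
    offsets = np.fromfile(off_path, dtype=np.int64)
    if entries.size != meta["n_entries"] or offsets.size != manifest["n_bins"] + 1:
        raise IndexError_(f"corrupt partition {pid}: size mismatch")
    if pindex is None:
        pindex = load_precursor_index(index_dir, manifest)
    lo, hi = meta["interval"]
    return Partition(
        partition_id=pid,
        precursor_interval=(lo, math.inf if hi is None else hi),
        bin_width_da=manifest["bin_width_da"],
        offsets=offsets,
        mz=entries["mz"].copy(),
        intensity=entries["intensity"].copy(),
        parent=entries["parent"].copy(),
        rank=pindex.rank_of[entries["parent"]],
    )


def stored_view(spec: Spectrum, cfg: IndexConfig) -> Spectrum:
    """The canonical stored form of a library spectrum: preprocessed,
    restricted to the indexed m/z range, quantized to the float32
    precision of the on-disk triplets. Exhaustive (index-free) search
    scores against this view so its scores are directly comparable to
    index-based search."""
    pre = preprocess(spec)
    keep = (pre.mz >= cfg.mz_min) & (pre.mz < cfg.mz_max)
    labels = (
        tuple(l for l, k in zip(pre.ion_labels, keep) if k)
        if pre.ion_labels is not None
        else None
    )
    from dataclasses import replace

    return replace(
        pre,
        mz=pre.mz[keep].astype(np.float32).astype(np.float64),
        intensity=pre.intensity[keep].astype(np.float32).astype(np.float64),
        ion_labels=labels,
    )
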