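"""Spectral file formats (MSP, MGF) and spectrum pre-processing.

The in-memory :class:`Spectrum` stores its peak list as parallel numpy
arrays sorted strictly ascending by m/z; coincident m/z values are merged
at construction by intensity summation and zero-intensity peaks are
dropped, so downstream scoring never has to special-case ties.

Pre-processing follows the square-root / unit-norm convention of
intensity-aware spectral matching: raw intensities are square-rooted to
de-emphasize dominant peaks and the resulting vector is scaled to unit
Euclidean norm, so a binned dot product of two identical spectra is 1.
``preprocess`` must be applied exactly once per spectrum — it is not
idempotent (a second application re-roots the already rooted values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from pyteomics import mgf as _mgf


class SpectrumError(ValueError):
    """Malformed spectral record or invalid spectrum operation."""


@dataclass(frozen=True)
class Peak:
    """One fragment peak: m/z (Thomson), non-negative intensity, optional
    ion annotation such as ``"b5"`` or ``"y7"``."""

    mz: float
    intensity: float
    ion_label: Optional[str] = None


@dataclass
class Spectrum:
    """One precursor plus its peak list.

    ``mz`` and ``intensity`` are parallel float arrays sorted strictly
    ascending by m/z. ``ion_labels`` is an optional tuple parallel to the
    peak arrays. ``charge == 0`` means "unknown" (allowed for query
    spectra only). Library spectra must carry ``peptide``.
    """

    native_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    ion_labels: Optional[tuple] = None
    peptide: Optional[str] = None
    is_decoy: bool = False
    retention_time: Optional[float] = None

    @property
    def n_peaks(self) -> int:
        return int(self.mz.shape[0])

    @property
    def peaks(self) -> list:
        labels = self.ion_labels or (None,) * self.n_peaks
        return [
            Peak(float(m), float(i), l)
            for m, i, l in zip(self.mz, self.intensity, labels)
        ]

    @classmethod
    def from_peaks(
        cls,
        native_id: str,
        precursor_mz: float,
        charge: int,
        mz: Sequence[float],
        intensity: Sequence[float],
        ion_labels: Optional[Sequence[Optional[str]]] = None,
        **kwargs,
    ) -> "Spectrum":
        """Build a spectrum enforcing the peak-list invariants: sort by
        m/z, merge coincident m/z by intensity summation (keeping the
        first non-empty annotation), drop zero-intensity peaks."""
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(intensity, dtype=np.float64)
        if mz.shape != inten.shape:
            raise SpectrumError("mz and intensity arrays differ in length")
        if np.any(mz <= 0):
            raise SpectrumError("peak m/z must be positive")
        if np.any(inten < 0):
            raise SpectrumError("peak intensity must be non-negative")
        labels = list(ion_labels) if ion_labels is not None else None

        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if labels is not None:
            labels = [labels[i] for i in order]

        if mz.size > 1 and np.any(np.diff(mz) == 0.0):
            umz, inverse = np.unique(mz, return_inverse=True)
            uint = np.zeros_like(umz)
            np.add.at(uint, inverse, inten)
            if labels is not None:
                ulab: list = [None] * umz.size
                for src, dst in enumerate(inverse):
                    if ulab[dst] is None:
                        ulab[dst] = labels[src]
                labels = ulab
            mz, inten = umz, uint

        keep = inten > 0.0
        if not np.all(keep):
            mz, inten = mz[keep], inten[keep]
            if labels is not None:
                labels = [l for l, k in zip(labels, keep) if k]

        return cls(
            native_id=native_id,
            precursor_mz=float(precursor_mz),
            charge=int(charge),
            mz=mz,
            intensity=inten,
            ion_labels=tuple(labels) if labels is not None else None,
            **kwargs,
        )


def preprocess(s: Spectrum) -> Spectrum:
    """Square-root transform intensities and scale to unit Euclidean norm.

    Apply exactly once per spectrum. Raises on an all-zero peak list.
    """
    if s.n_peaks == 0 or not np.any(s.intensity > 0):
        raise SpectrumError(
            f"empty spectrum after preprocessing: {s.native_id!r}"
        )
    rooted = np.sqrt(s.intensity)
    norm = math.sqrt(float(np.dot(rooted, rooted)))
    return replace(s, intensity=rooted / norm, mz=s.mz.copy())


def denoise_top_k_window(s: Spectrum, k: int, w: float) -> Spectrum:
    """Keep only the ``k`` most intense peaks within each consecutive
    m/z window ``[j*w, (j+1)*w)``. Optional noise reduction; off by
    default in the search pipeline. Peak order is preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if w <= 0:
        raise ValueError("window width must be positive")
    if s.n_peaks <= k:
        return s
    windows = np.floor(s.mz / w).astype(np.int64)
    keep = np.zeros(s.n_peaks, dtype=bool)
    for win in np.unique(windows):
        idx = np.flatnonzero(windows == win)
        if idx.size <= k:
            keep[idx] = True
        else:
            top = idx[np.argsort(s.intensity[idx], kind="stable")[-k:]]
            keep[top] = True
    labels = (
        tuple(l for l, kp in zip(s.ion_labels, keep) if kp)
        if s.ion_labels is not None
        else None
    )
    return replace(
        s, mz=s.mz[keep], intensity=s.intensity[keep], ion_labels=labels
    )


def ppm_to_da(tol_ppm: float, mz: float) -> float:
    """Convert a relative ppm tolerance to an absolute one at ``mz``
    (e.g. 10 ppm at m/z 1500 is 0.015 Da)."""
    if tol_ppm < 0:
        raise ValueError("ppm tolerance must be non-negative")
    if mz <= 0:
        raise ValueError("mz must be positive")
    return mz * tol_ppm * 1e-6


# ---------------------------------------------------------------------------
# MSP (NIST text dialect)
# ---------------------------------------------------------------------------

PROTON_MASS = 1.007276466879


def _parse_msp_record(
    lines: list, ordinal: int, is_decoy: bool, decoy_prefix: str
) -> Spectrum:
    name = None
    precursor_mz = None
    mw = None
    charge = None
    comment: dict = {}
    n_declared = None
    peak_start = None
    for i, line in enumerate(lines):
        low = line.lower()
        if low.startswith("name:"):
            name = line.split(":", 1)[1].strip()
        elif low.startswith("precursormz:"):
            precursor_mz = float(line.split(":", 1)[1])
        elif low.startswith("mw:"):
            mw = float(line.split(":", 1)[1])
        elif low.startswith("comment:"):
            for tok in line.split(":", 1)[1].split():
                if "=" in tok:
                    key, val = tok.split("=", 1)
                    comment[key] = val
        elif low.startswith("num peaks:"):
            n_declared = int(line.split(":", 1)[1])
            peak_start = i + 1
            break
        # other headers (MW variants, etc.) ignored

    if name is None:
        raise SpectrumError(f"MSP record {ordinal}: missing Name header")
    peptide = name
    if "/" in name:
        peptide, _, charge_part = name.rpartition("/")
        try:
            charge = int(charge_part)
        except ValueError as exc:
            raise SpectrumError(
                f"MSP record {ordinal}: unparseable charge in Name "
                f"line {name!r}"
            ) from exc
    if charge is None and "Charge" in comment:
        charge = int(comment["Charge"])
    if charge is None or charge < 1:
        raise SpectrumError(
            f"MSP record {ordinal}: no positive charge found"
        )
    if precursor_mz is None:
        if mw is None:
            raise SpectrumError(
                f"MSP record {ordinal}: neither PrecursorMZ nor MW given"
            )
        precursor_mz = (mw + charge * PROTON_MASS) / charge
    if n_declared is None or peak_start is None:
        raise SpectrumError(
            f"MSP record {ordinal}: missing 'Num peaks' header"
        )
    peak_lines = lines[peak_start:]
    if len(peak_lines) != n_declared:
        raise SpectrumError(
            f"MSP record {ordinal}: declared {n_declared} peaks but found "
            f"{len(peak_lines)}"
        )
    mzs, ints, labels = [], [], []
    for line in peak_lines:
        parts = line.replace("\t", " ").split()
        if len(parts) < 2:
            raise SpectrumError(
                f"MSP record {ordinal}: malformed peak line {line!r}"
            )
        try:
            mzs.append(float(parts[0]))
            ints.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumError(
                f"MSP record {ordinal}: malformed peak line {line!r}"
            ) from exc
        if len(parts) >= 3:
            ann = parts[2].strip('"')
            labels.append(ann.split("/", 1)[0] if ann else None)
        else:
            labels.append(None)

    decoy = is_decoy or peptide.startswith(decoy_prefix)
    if peptide.startswith(decoy_prefix):
        peptide = peptide[len(decoy_prefix):]
    native_id = comment.get("NativeID", name)
    rt = float(comment["RT"]) if "RT" in comment else None
    has_labels = any(l is not None for l in labels)
    return Spectrum.from_peaks(
        native_id=native_id,
        precursor_mz=precursor_mz,
        charge=charge,
        mz=mzs,
        intensity=ints,
        ion_labels=labels if has_labels else None,
        peptide=peptide,
        is_decoy=decoy,
        retention_time=rt,
    )


def read_msp(
    path, is_decoy: bool = False, decoy_prefix: str = "DECOY_"
) -> Iterator[Spectrum]:
    """Stream spectra from an MSP library file, one record at a time.

    ``is_decoy=True`` flags every spectrum in the file as decoy (the
    file-level convention for separately built decoy libraries);
    independently, a ``decoy_prefix`` on the Name is recognized and
    stripped from the peptide.
    """
    ordinal = 0
    record: list = []
    expecting = 0  # peak lines still owed to the open record
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.lower().startswith("name:") and record and expecting <= 0:
                ordinal += 1
                yield _parse_msp_record(record, ordinal, is_decoy, decoy_prefix)
                record = []
            record.append(line)
            if line.lower().startswith("num peaks:"):
                try:
                    expecting = int(line.split(":", 1)[1])
                except ValueError as exc:
                    raise SpectrumError(
                        f"MSP record {ordinal + 1}: bad 'Num peaks' "
                        f"line {line!r}"
                    ) from exc
            elif expecting > 0 and not line.lower().startswith(
                ("name:", "mw:", "precursormz:", "comment:")
            ):
                expecting -= 1
        if record:
            if expecting > 0:
                raise SpectrumError(
                    f"MSP record {ordinal + 1}: truncated final record "
                    f"({expecting} peak lines missing)"
                )
            ordinal += 1
            yield _parse_msp_record(record, ordinal, is_decoy, decoy_prefix)


def write_msp(spectra: Iterable[Spectrum], path) -> int:
    """Write spectra in the canonical fixture MSP dialect: m/z with 4
    decimals, intensities in scientific notation, annotation column
    ``label/0.00`` when ion labels are present. Returns the record count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            if s.peptide is None:
                raise SpectrumError(
                    f"library spectrum {s.native_id!r} lacks a peptide"
                )
            name = ("DECOY_" if s.is_decoy else "") + s.peptide
            fh.write(f"Name: {name}/{s.charge}\n")
            fh.write(f"PrecursorMZ: {s.precursor_mz:.6f}\n")
            comment = f"NativeID={s.native_id} Charge={s.charge}"
            if s.retention_time is not None:
                comment += f" RT={s.retention_time:.3f}"
            fh.write(f"Comment: {comment}\n")
            fh.write(f"Num peaks: {s.n_peaks}\n")
            labels = s.ion_labels or (None,) * s.n_peaks
            for m, i, l in zip(s.mz, s.intensity, labels):
                if l is not None:
                    fh.write(f"{m:.4f}\t{i:.6e}\t\"{l}/0.00\"\n")
                else:
                    fh.write(f"{m:.4f}\t{i:.6e}\n")
            fh.write("\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# MGF (via pyteomics)
# ---------------------------------------------------------------------------


def read_mgf(path) -> Iterator[Spectrum]:
    """Stream query spectra from an MGF file.

    CHARGE absent is recorded as charge 0, meaning "unknown"; such a
    query is later searched against every charge block. A missing
    PEPMASS raises, as does a nested BEGIN IONS (via pyteomics).
    """
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                title = params.get("title", f"index={i}")
                raise SpectrumError(
                    f"MGF spectrum {i + 1} ({title!r}): missing PEPMASS"
                )
            charge = 0
            if "charge" in params:
                charge = int(params["charge"][0])
            rt = params.get("rtinseconds")
            yield Spectrum.from_peaks(
                native_id=str(params.get("title", f"index={i}")),
                precursor_mz=float(params["pepmass"][0]),
                charge=charge,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                peptide=params.get("seq"),
                retention_time=float(rt) if rt is not None else None,
            )


def write_mgf(spectra: Iterable[Spectrum], path) -> int:
    """Write spectra as MGF with fixed-precision peak formatting so the
    output is byte-reproducible for a given input."""
    dicts = []
    for s in spectra:
        params = {"title": s.native_id, "pepmass": s.precursor_mz}
        if s.charge > 0:
            params["charge"] = s.charge
        if s.retention_time is not None:
            params["rtinseconds"] = f"{s.retention_time:.3f}"
        dicts.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        _mgf.write(dicts, fh, fragment_format="{:.5f} {:.8e}")
    return len(dicts)
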