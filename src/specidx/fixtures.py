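"""Deterministic synthetic spectral-library generator.

Everything the engine needs for development and testing is generated
here from a seed: random proteomes, tryptic digestion, toy b/y-ion
MS/MS "predictions" with deterministic intensity profiles,
pseudo-reversed decoys, an optional disjoint entrapment proteome, and
noisy query runs with a ground-truth map.

The generator emulates the conditions of a predicted-library search:
tryptic peptides of length 7-30 with up to two missed cleavages, charge
states 2-4, precursor m/z restricted to 400-1500, fixed cysteine
carbamidomethylation, and reference spectra containing only b/y-ion
peaks. What it does *not* emulate: learned (Prosit-like) fragment
intensities, retention time, isotope envelopes, or real chimeric noise
— see docs/methods.md for what that means for test conclusions.

A fraction of queries is generated from *foreign* peptides held out of
the library; those queries borrow the precursor m/z of a random
same-charge library entry so they draw in-tolerance candidates and
plant genuine false-match opportunities for the FDR machinery.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from pyteomics import mass as _pt_mass
from pyteomics import parser as _pt_parser

from .spectra_io import (
    PROTON_MASS,
    Spectrum,
    write_mgf,
    write_msp,
)

WATER_MONO = 18.0105646863
CARBAMIDOMETHYL = 57.02146
TRYPSIN_RULE = r"[KR](?!P)"  # cleave C-terminal to K/R except before P

_AA = "ACDEFGHIKLMNPQRSTVWY"
# baseline composition with K/R enriched so tryptic products land in the
# configured length range on average
_AA_WEIGHTS = np.array(
    [7.4, 1.5, 5.4, 6.1, 4.0, 7.2, 2.3, 5.5, 7.0, 9.0,
     2.3, 4.2, 4.5, 3.8, 7.0, 7.2, 5.7, 6.5, 1.3, 3.1]
)
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

_RESIDUE_MASS = {aa: _pt_mass.std_aa_mass[aa] for aa in _AA}
_RESIDUE_MASS["C"] += CARBAMIDOMETHYL  # fixed modification


@dataclass(frozen=True)
class FixtureConfig:
    """Generator settings; the defaults define the standard test
    conditions (2000-spectrum target library incl. an entrapment share,
    equally many decoys, 500 moderately noisy queries)."""

    seed: int
    n_proteins: int = 60
    protein_length: int = 360
    n_entrap_proteins: int = 20
    peptide_length: Tuple[int, int] = (7, 30)
    charges: Tuple[int, ...] = (2, 3, 4)
    precursor_mz_range: Tuple[float, float] = (400.0, 1500.0)
    missed_cleavages: int = 2
    n_library: int = 2000
    entrap_fraction: float = 0.25  # share of the target library
    n_queries: int = 500
    mz_jitter: float = 0.02  # Da, SD of fragment m/z noise
    int_cv: float = 0.2  # lognormal CV of intensity noise
    dropout: float = 0.1  # per-peak dropout probability
    n_contaminants: int = 5  # uniform random peaks added per query
    fraction_foreign: float = 0.1
    precursor_ppm_jitter: float = 5.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_proteins", "n_entrap_proteins", "n_library",
                     "n_queries", "n_contaminants", "missed_cleavages"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# proteome + digestion
# ---------------------------------------------------------------------------


def generate_proteome(
    n_proteins: int, length: int, rng: np.random.Generator, prefix: str = "P"
) -> List[Tuple[str, str]]:
    """Random (name, sequence) pairs over the 20-letter alphabet."""
    out = []
    for i in range(n_proteins):
        seq = "".join(
            rng.choice(list(_AA), size=length, p=_AA_WEIGHTS)
        )
        out.append((f"{prefix}{i:04d}", seq))
    return out


def write_fasta(proteome: Sequence[Tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in proteome:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def digest(
    protein: str,
    missed_cleavages: int = 2,
    length_range: Optional[Tuple[int, int]] = None,
) -> List[str]:
    """Tryptic digestion (cleave after K/R, not before P) with 0..mc
    missed cleavages, optionally filtered to a length range. Returns a
    deterministically sorted peptide list."""
    peps = _pt_parser.cleave(
        protein, TRYPSIN_RULE, missed_cleavages=missed_cleavages
    )
    if length_range is not None:
        lo, hi = length_range
        peps = {p for p in peps if lo <= len(p) <= hi}
    return sorted(peps)


def peptide_neutral_mass(peptide: str) -> float:
    """Monoisotopic neutral mass with fixed Cys carbamidomethylation."""
    try:
        return sum(_RESIDUE_MASS[aa] for aa in peptide) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"unknown residue in peptide {peptide!r}") from exc


def precursor_mz(peptide: str, charge: int) -> float:
    return (peptide_neutral_mass(peptide) + charge * PROTON_MASS) / charge


# ---------------------------------------------------------------------------
# toy spectrum prediction
# ---------------------------------------------------------------------------


def _stable_seed(*parts) -> int:
    h = hashlib.blake2b("|".join(map(str, parts)).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "little")


def toy_predict(peptide: str, charge: int) -> Spectrum:
    """Deterministic b/y-ion reference spectrum for one precursor.

    Singly charged b1..b(n-1) and y1..y(n-1) fragments always; doubly
    charged fragment series added when the precursor charge is >= 3.
    Intensities follow a smooth position-dependent bell profile
    modulated by a per-ion factor hashed on (peptide, charge), so
    distinct peptides get distinct but reproducible patterns; y ions
    run hotter than b ions, as is typical for collision-induced spectra.
    """
    n = len(peptide)
    if n < 2:
        raise ValueError("peptide too short to fragment")
    res = np.array([_RESIDUE_MASS[aa] for aa in peptide])  # KeyError -> below
    prefix = np.cumsum(res)[:-1]  # b fragments' residue sums
    suffix = np.cumsum(res[::-1])[:-1]  # y fragments
    rng = np.random.default_rng(_stable_seed("toy", peptide, charge))
    pos = np.arange(1, n)
    # bell over fragment length, peaking past the middle of the ladder
    bell = np.exp(-0.5 * ((pos - 0.55 * n) / (0.30 * n)) ** 2)

    mzs: List[float] = []
    ints: List[float] = []
    labels: List[str] = []
    frag_charges = (1, 2) if charge >= 3 else (1,)
    for z in frag_charges:
        zfac = 1.0 if z == 1 else 0.35
        b_mod = rng.uniform(0.25, 1.0, size=n - 1)
        y_mod = rng.uniform(0.25, 1.0, size=n - 1)
        for i in range(1, n):
            b_mz = (prefix[i - 1] + z * PROTON_MASS) / z
            y_mz = (suffix[i - 1] + WATER_MONO + z * PROTON_MASS) / z
            suff = "" if z == 1 else "^2"
            mzs.append(b_mz)
            ints.append(60.0 * bell[i - 1] * b_mod[i - 1] * zfac)
            labels.append(f"b{i}{suff}")
            mzs.append(y_mz)
            ints.append(100.0 * bell[i - 1] * y_mod[i - 1] * zfac)
            labels.append(f"y{i}{suff}")

    try:
        pre_mz = precursor_mz(peptide, charge)
    except ValueError:
        raise
    return Spectrum.from_peaks(
        native_id=f"{peptide}/{charge}",
        precursor_mz=pre_mz,
        charge=charge,
        mz=mzs,
        intensity=ints,
        ion_labels=labels,
        peptide=peptide,
    )


def make_decoys(
    peptides: Sequence[str], seed: int
) -> Dict[str, str]:
    """Pseudo-reversed decoy peptide per target (reverse all but the
    C-terminal residue). Collisions with the target set are reshuffled
    deterministically; irreducible cases are dropped with a warning.
    Returns target -> decoy mapping."""
    targets = set(peptides)
    taken: Set[str] = set()
    rng = np.random.default_rng(seed % (2 ** 31))
    out: Dict[str, str] = {}
    for pep in peptides:
        decoy = pep[-2::-1] + pep[-1]
        tries = 0
        while (decoy in targets or decoy in taken) and tries < 20:
            head = list(pep[:-1])
            rng.shuffle(head)
            decoy = "".join(head) + pep[-1]
            tries += 1
        if decoy in targets or decoy in taken:
            warnings.warn(
                f"could not derive a distinct decoy for {pep!r}; dropped",
                stacklevel=2,
            )
            continue
        taken.add(decoy)
        out[pep] = decoy
    return out


# ---------------------------------------------------------------------------
# full fixture
# ---------------------------------------------------------------------------


@dataclass
class FixtureSet:
    config: FixtureConfig
    proteome: List[Tuple[str, str]]
    target_spectra: List[Spectrum]  # true + entrapment, in library order
    decoy_spectra: List[Spectrum]
    queries: List[Spectrum]
    truth: Dict[int, str]  # query id -> generating peptide or "foreign"
    true_peptides: Set[str]
    entrapment_peptides: Set[str]
    foreign_peptides: Set[str]

    @property
    def entrapment_ratio(self) -> float:
        """R: target (sample-true) over entrapment peptide count."""
        if not self.entrapment_peptides:
            raise ValueError("fixture has no entrapment peptides")
        return len(self.true_peptides) / len(self.entrapment_peptides)


def _eligible_precursors(
    peptides: Sequence[str], cfg: FixtureConfig
) -> List[Tuple[str, int]]:
    lo, hi = cfg.precursor_mz_range
    out = []
    for pep in peptides:
        for z in cfg.charges:
            if lo <= precursor_mz(pep, z) <= hi:
                out.append((pep, z))
    return out


def make_fixture(cfg: FixtureConfig) -> FixtureSet:
    """Generate the complete, seed-reproducible fixture."""
    rng = np.random.default_rng(cfg.seed % (2 ** 31))

    proteome = generate_proteome(
        cfg.n_proteins, cfg.protein_length, rng, prefix="P"
    )
    peptides = sorted(
        {
            pep
            for _, seq in proteome
            for pep in digest(seq, cfg.missed_cleavages, cfg.peptide_length)
        }
    )
    entrap_proteome = generate_proteome(
        cfg.n_entrap_proteins, cfg.protein_length, rng, prefix="E"
    )
    entrap_peps = sorted(
        {
            pep
            for _, seq in entrap_proteome
            for pep in digest(seq, cfg.missed_cleavages, cfg.peptide_length)
        }
        - set(peptides)
    )

    pool = _eligible_precursors(peptides, cfg)
    trap_pool = _eligible_precursors(entrap_peps, cfg)
    n_trap = int(round(cfg.n_library * cfg.entrap_fraction))
    n_true = cfg.n_library - n_trap
    if len(pool) < n_true + 1 or (n_trap > 0 and len(trap_pool) < n_trap):
        raise ValueError(
            "proteome too small for the requested library size; increase "
            "n_proteins/protein_length"
        )

    sel_true = [pool[i] for i in rng.choice(len(pool), n_true, replace=False)]
    sel_trap = (
        [trap_pool[i] for i in rng.choice(len(trap_pool), n_trap, replace=False)]
        if n_trap
        else []
    )
    library_sel = sel_true + sel_trap
    target_spectra = [toy_predict(pep, z) for pep, z in library_sel]

    true_peps = {pep for pep, _ in sel_true}
    trap_peps = {pep for pep, _ in sel_trap}
    # foreign pool: digestible peptides excluded from the library
    foreign_candidates = sorted(set(p for p, _ in pool) - true_peps)

    decoy_map = make_decoys(
        sorted({pep for pep, _ in library_sel}), cfg.seed + 1
    )
    decoy_spectra = [
        toy_predict(decoy_map[pep], z)
        for pep, z in library_sel
        if pep in decoy_map
    ]
    for s in decoy_spectra:
        s.is_decoy = True

    # queries derive from the sample-true part of the library only;
    # entrapment spectra are bait and never generate a query
    queries, truth, foreign_used = _make_queries_internal(
        target_spectra[:n_true], target_spectra, foreign_candidates, cfg, rng
    )
    return FixtureSet(
        config=cfg,
        proteome=proteome + entrap_proteome,
        target_spectra=target_spectra,
        decoy_spectra=decoy_spectra,
        queries=queries,
        truth=truth,
        true_peptides=true_peps,
        entrapment_peptides=trap_peps,
        foreign_peptides=foreign_used,
    )


def _perturb(
    spec: Spectrum, qid: int, cfg: FixtureConfig, rng: np.random.Generator,
    precursor_override: Optional[float] = None,
) -> Spectrum:
    mz = spec.mz.copy()
    inten = spec.intensity.copy()
    if cfg.mz_jitter > 0:
        mz = mz + rng.normal(0.0, cfg.mz_jitter, size=mz.size)
    if cfg.int_cv > 0:
        sigma = math.sqrt(math.log1p(cfg.int_cv ** 2))
        inten = inten * rng.lognormal(-0.5 * sigma * sigma, sigma, inten.size)
    if cfg.dropout > 0:
        keep = rng.random(mz.size) >= cfg.dropout
        if not keep.any():
            keep[int(np.argmax(inten))] = True
        mz, inten = mz[keep], inten[keep]
    if cfg.n_contaminants > 0:
        cmz = rng.uniform(100.0, 1400.0, size=cfg.n_contaminants)
        cint = rng.uniform(0.02, 0.3, size=cfg.n_contaminants) * (
            float(inten.max()) if inten.size else 1.0
        )
        mz = np.concatenate([mz, cmz])
        inten = np.concatenate([inten, cint])
    pmz = (
        precursor_override
        if precursor_override is not None
        else spec.precursor_mz
    )
    if cfg.precursor_ppm_jitter > 0:
        pmz = pmz * (
            1.0
            + rng.uniform(-cfg.precursor_ppm_jitter, cfg.precursor_ppm_jitter)
            * 1e-6
        )
    mz = np.clip(mz, 1e-3, None)
    return Spectrum.from_peaks(
        native_id=f"Q{qid:05d}",
        precursor_mz=pmz,
        charge=spec.charge,
        mz=mz,
        intensity=inten,
    )


def _make_queries_internal(
    sources: List[Spectrum],
    host_library: List[Spectrum],
    foreign_candidates: List[str],
    cfg: FixtureConfig,
    rng: np.random.Generator,
) -> Tuple[List[Spectrum], Dict[int, str], Set[str]]:
    by_charge: Dict[int, List[Spectrum]] = {}
    for s in host_library:
        by_charge.setdefault(s.charge, []).append(s)

    queries: List[Spectrum] = []
    truth: Dict[int, str] = {}
    foreign_used: Set[str] = set()
    for qid in range(cfg.n_queries):
        if foreign_candidates and rng.random() < cfg.fraction_foreign:
            pep = foreign_candidates[rng.integers(len(foreign_candidates))]
            zs = [z for z in cfg.charges if by_charge.get(z)]
            z = zs[rng.integers(len(zs))]
            base = toy_predict(pep, z)
            # plant the precursor on a random same-charge library entry so
            # the foreign spectrum draws in-tolerance (false) candidates
            host = by_charge[z][rng.integers(len(by_charge[z]))]
            q = _perturb(base, qid, cfg, rng,
                         precursor_override=host.precursor_mz)
            truth[qid] = "foreign"
            foreign_used.add(pep)
        else:
            src = sources[rng.integers(len(sources))]
            q = _perturb(src, qid, cfg, rng)
            truth[qid] = src.peptide
        queries.append(q)
    return queries, truth, foreign_used


def write_truth_tsv(truth: Dict[int, str], queries: Sequence[Spectrum], path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("query_id\ttitle\tpeptide\n")
        for qid in sorted(truth):
            fh.write(f"{qid}\t{queries[qid].native_id}\t{truth[qid]}\n")


def read_truth_tsv(path) -> Dict[int, str]:
    truth: Dict[int, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            truth[int(f[0])] = f[2]
    return truth


def write_fixture(fx: FixtureSet, out_dir) -> dict:
    """Write FASTA, target/decoy MSP, query MGF, truth TSV and a
    manifest; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(fx.proteome, out / "proteome.fasta")
    write_msp(fx.target_spectra, out / "target.msp")
    write_msp(fx.decoy_spectra, out / "decoy.msp")
    write_mgf(fx.queries, out / "queries.mgf")
    write_truth_tsv(fx.truth, fx.queries, out / "truth.tsv")
    manifest = {
        "seed": fx.config.seed,
        "n_target_spectra": len(fx.target_spectra),
        "n_decoy_spectra": len(fx.decoy_spectra),
        "n_queries": len(fx.queries),
        "n_true_peptides": len(fx.true_peptides),
        "n_entrapment_peptides": len(fx.entrapment_peptides),
        "n_foreign_queries": sum(
            1 for v in fx.truth.values() if v == "foreign"
        ),
        "entrapment_ratio": (
            fx.entrapment_ratio if fx.entrapment_peptides else None
        ),
        "entrapment_peptides_file": "entrapment_peptides.txt",
    }
    (out / "entrapment_peptides.txt").write_text(
        "\n".join(sorted(fx.entrapment_peptides)) + "\n"
        if fx.entrapment_peptides
        else ""
    )
    (out / "fixture_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
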