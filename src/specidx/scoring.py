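"""Spectral similarity scoring: Gaussian-resolved dot product, dot bias,
reflection variants and auxiliary PSM features.

The primary similarity between a query spectrum Q and a reference
spectrum R (both preprocessed to unit Euclidean norm) resolves the m/z
dimension with a Gaussian bell curve instead of fixed bins::

    similarity(Q, R) = sum_k max_l  I_l * I_k * phi(mz_l, mz_k)
    phi(x, mu)       = exp(-((x - mu) / sigma)^2 / 2)

where k runs over reference peaks, l over query peaks, and sigma models
the fragment tolerance (by convention equal to the fragment bin width).
Mass shifts between matched peaks are thereby penalized as intensity
decay along the curve rather than lost at a bin edge.

The *dot bias* measures how much of the similarity is carried by few
peak pairs (the SpectraST dot-bias idea transplanted to the Gaussian
terms)::

    bias(Q, R) = sum_k t_k^2 / sum_k t_k,   t_k = max_l I_l I_k phi(...)

and the *bias-adjusted similarity* is ``similarity * (1 - bias)``, which
suppresses matches dominated by a single peak. Because predicted
reference libraries contain only b/y-ion peaks, a second, *reflection*
variant first discards query peaks with no reference peak within the
truncation radius (treating them as noise), renormalizes the survivors
to unit norm, and applies the same formulas. The final ranking score is
the arithmetic mean of the two bias-adjusted similarities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .index import bins_of
from .spectra_io import Spectrum


@dataclass(frozen=True)
class ScoringParams:
    """sigma: Gaussian spread in Da (defaults to the fragment bin width
    at the call site); match_cutoff_sigmas: truncation radius in units
    of sigma beyond which phi is exactly zero (contributions past 5
    sigma are below 4e-6 and ignoring them keeps the sorted-merge
    implementation exact to tolerance while bounding work)."""

    sigma: float = 0.2
    match_cutoff_sigmas: float = 5.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def cutoff_da(self) -> float:
        return self.sigma * self.match_cutoff_sigmas


@dataclass
class ScoreVector:
    """Full per-PSM score/feature vector."""

    dot: float = 0.0
    similarity: float = 0.0
    bias: float = 1.0
    bias_adjusted: float = 0.0
    reflection_similarity: float = 0.0
    reflection_bias: float = 1.0
    reflection_bias_adjusted: float = 0.0
    final_score: float = 0.0
    log_hyperscore: float = 0.0
    shared_peak_count: int = 0
    f_value: float = 0.0
    delta_final: float = 0.0
    mz_sd_matched: float = 0.0
    abs_mass_diff_precursor: float = 0.0
    peptide_length: int = 0

    FEATURE_ORDER = (
        "final_score",
        "bias_adjusted",
        "reflection_bias_adjusted",
        "similarity",
        "reflection_similarity",
        "dot",
        "bias",
        "reflection_bias",
        "log_hyperscore",
        "f_value",
        "delta_final",
        "shared_peak_count",
        "mz_sd_matched",
        "abs_mass_diff_precursor",
        "peptide_length",
    )

    def as_feature_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.FEATURE_ORDER}


def phi(x: float, mu: float, sigma: float,
        match_cutoff_sigmas: float = 5.0) -> float:
    """Gaussian mass-shift penalty factor in (0, 1]; exactly 0 beyond
    the truncation radius."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (x - mu) / sigma
    if abs(z) > match_cutoff_sigmas:
        return 0.0
    return math.exp(-0.5 * z * z)


def _flat_windows(
    qmz: np.ndarray, rmz: np.ndarray, cutoff: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each reference peak k, the half-open run of query-peak indices
    within the truncation window, flattened: returns (k_idx, l_idx,
    counts). Relies on both m/z arrays being sorted (the sorted-merge
    contract: O(|R| log |Q|) searches instead of the quadratic loop)."""
    lo = np.searchsorted(qmz, rmz - cutoff, side="left")
    hi = np.searchsorted(qmz, rmz + cutoff, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            counts,
        )
    k_idx = np.repeat(np.arange(rmz.size), counts)
    # within-run offsets 0..count-1 for each k, vectorized
    ends = np.cumsum(counts)
    within = np.arange(total) - np.repeat(ends - counts, counts)
    l_idx = np.repeat(lo, counts) + within
    return k_idx, l_idx, counts


def _best_terms(
    qmz: np.ndarray,
    qint: np.ndarray,
    rmz: np.ndarray,
    rint: np.ndarray,
    p: ScoringParams,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per reference peak k: the best Gaussian intensity-product term
    max_l I_l I_k phi, the m/z difference (mz_l - mz_k) of the winning
    pair, and the winning raw product I_l * I_k (no phi). Zero term
    means unmatched."""
    terms = np.zeros(rmz.size)
    dmz = np.zeros(rmz.size)
    raw = np.zeros(rmz.size)
    k_idx, l_idx, counts = _flat_windows(qmz, rmz, p.cutoff_da)
    if k_idx.size == 0:
        return terms, dmz, raw
    d = qmz[l_idx] - rmz[k_idx]
    prod_raw = qint[l_idx] * rint[k_idx]
    prod = prod_raw * np.exp(-0.5 * (d / p.sigma) ** 2)
    nz = counts > 0
    starts = (np.cumsum(counts) - counts)[nz]
    seg_max = np.maximum.reduceat(prod, starts)
    # first flat index attaining the segment max
    rep_max = np.repeat(seg_max, counts[nz])
    flat = np.where(prod >= rep_max, np.arange(prod.size), prod.size)
    winner = np.minimum.reduceat(flat, starts)
    terms[nz] = seg_max
    dmz[nz] = d[winner]
    raw[nz] = prod_raw[winner]
    return terms, dmz, raw


def similarity(Q: Spectrum, R: Spectrum, p: ScoringParams) -> float:
    """Gaussian-resolved similarity; both spectra must be preprocessed
    (unit norm) and their peak lists sorted by m/z."""
    terms, _, _ = _best_terms(Q.mz, Q.intensity, R.mz, R.intensity, p)
    return float(terms.sum())


def similarity_brute(Q: Spectrum, R: Spectrum, p: ScoringParams) -> float:
    """Reference quadratic double-loop evaluation of the similarity,
    kept deliberately independent of the sorted-merge path; used as the
    oracle in equivalence checks."""
    total = 0.0
    for k in range(R.mz.size):
        best = 0.0
        for l in range(Q.mz.size):
            v = (
                Q.intensity[l]
                * R.intensity[k]
                * phi(Q.mz[l], R.mz[k], p.sigma, p.match_cutoff_sigmas)
            )
            if v > best:
                best = v
        total += best
    return total


def bias(Q: Spectrum, R: Spectrum, p: ScoringParams) -> float:
    """Dot-bias analogue on the Gaussian terms: sum of squared per-k
    terms over their sum. By convention 1 (maximal) when the similarity
    is zero, so the bias-adjusted similarity is 0 there."""
    terms, _, _ = _best_terms(Q.mz, Q.intensity, R.mz, R.intensity, p)
    s = float(terms.sum())
    if s <= 0.0:
        return 1.0
    return float(np.square(terms).sum()) / s


def bias_adjusted(Q: Spectrum, R: Spectrum, p: ScoringParams) -> float:
    return similarity(Q, R, p) * (1.0 - bias(Q, R, p))


def _matched_query_mask(
    qmz: np.ndarray, rmz: np.ndarray, cutoff: float
) -> np.ndarray:
    lo = np.searchsorted(rmz, qmz - cutoff, side="left")
    hi = np.searchsorted(rmz, qmz + cutoff, side="right")
    return hi > lo


def reflection_scores(
    Q: Spectrum, R: Spectrum, p: ScoringParams
) -> Tuple[float, float, float]:
    """(similarity, bias, bias-adjusted) computed on the matched query
    sub-spectrum only: query peaks with no reference peak within the
    truncation radius are treated as noise and removed, the survivors
    renormalized to unit norm. All three are 0 when nothing matches."""
    mask = _matched_query_mask(Q.mz, R.mz, p.cutoff_da)
    if not mask.any():
        return 0.0, 0.0, 0.0
    qmz = Q.mz[mask]
    qint = Q.intensity[mask]
    norm = math.sqrt(float(np.dot(qint, qint)))
    if norm <= 0.0:
        return 0.0, 0.0, 0.0
    qint = qint / norm
    terms, _, _ = _best_terms(qmz, qint, R.mz, R.intensity, p)
    s = float(terms.sum())
    if s <= 0.0:
        return 0.0, 1.0, 0.0
    b = float(np.square(terms).sum()) / s
    return s, b, s * (1.0 - b)


def final_score(bias_adj: float, reflection_bias_adj: float) -> float:
    """The ranking score: arithmetic mean of the bias-adjusted
    similarity and its reflection variant."""
    return 0.5 * (bias_adj + reflection_bias_adj)


def binned_dot(Q: Spectrum, R: Spectrum, B: float) -> float:
    """Classic binned spectral dot product (what the fragment-index
    accumulation computes): sum over shared bins of the per-bin
    intensity-sum products."""
    qb = bins_of(Q.mz, B)
    rb = bins_of(R.mz, B)
    qs: dict = {}
    for b, i in zip(qb, Q.intensity):
        qs[int(b)] = qs.get(int(b), 0.0) + float(i)
    total = 0.0
    for b, i in zip(rb, R.intensity):
        total += qs.get(int(b), 0.0) * float(i)
    return total


def log_hyperscore(
    matched_labels: list, matched_raw_products: np.ndarray
) -> float:
    """X!Tandem-style log hyperscore over the matched reference peaks:
    ln(N_b!) + ln(N_y!) + ln(1 + sum of matched intensity products),
    with unlabeled matched peaks counted in a single extra series.
    Log-factorials via lgamma."""
    n_b = sum(1 for l in matched_labels if l and l.startswith("b"))
    n_y = sum(1 for l in matched_labels if l and l.startswith("y"))
    n_other = len(matched_labels) - n_b - n_y
    s = float(np.sum(matched_raw_products))
    return (
        math.lgamma(n_b + 1)
        + math.lgamma(n_y + 1)
        + math.lgamma(n_other + 1)
        + math.log1p(max(s, 0.0))
    )


def f_value(dot1: float, dot2: Optional[float]) -> float:
    """SpectraST-style discriminant combining the dot product with the
    delta to the next-best hit: 0.6*dot1 - 0.4*(dot1 - dot2); dot2 is 0
    when no runner-up exists. Emitted as a rescoring feature only."""
    d2 = 0.0 if dot2 is None else dot2
    return 0.6 * dot1 - 0.4 * (dot1 - d2)


def score_pair(
    Q: Spectrum, R: Spectrum, p: ScoringParams, bin_width: float
) -> ScoreVector:
    """Compute every per-pair score for one query/reference pair. Both
    spectra must be preprocessed. ``f_value`` and ``delta_final`` are
    rank-dependent and filled in after ranking."""
    terms, dmz, raw = _best_terms(Q.mz, Q.intensity, R.mz, R.intensity, p)
    sim = float(terms.sum())
    if sim > 0.0:
        b = float(np.square(terms).sum()) / sim
    else:
        b = 1.0
    badj = sim * (1.0 - b)
    rsim, rbias, rbadj = reflection_scores(Q, R, p)
    matched = terms > 0.0
    n_matched = int(matched.sum())
    labels = (
        [R.ion_labels[i] for i in np.flatnonzero(matched)]
        if R.ion_labels is not None
        else [None] * n_matched
    )
    sv = ScoreVector(
        dot=binned_dot(Q, R, bin_width),
        similarity=sim,
        bias=b,
        bias_adjusted=badj,
        reflection_similarity=rsim,
        reflection_bias=rbias,
        reflection_bias_adjusted=rbadj,
        final_score=final_score(badj, rbadj),
        log_hyperscore=log_hyperscore(labels, raw[matched]),
        shared_peak_count=n_matched,
        mz_sd_matched=float(np.std(dmz[matched])) if n_matched >= 2 else 0.0,
        abs_mass_diff_precursor=abs(Q.precursor_mz - R.precursor_mz),
        peptide_length=len(R.peptide) if R.peptide else 0,
    )
    return sv
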