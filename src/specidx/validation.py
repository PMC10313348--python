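"""Target-decoy competition, FDR / q-value estimation, entrapment FDR
and Percolator pin-tab export.

Targets and decoys are searched separately; per query only the single
best-scoring hit from either library survives the competition. With
``N_target(t)`` and ``N_decoy(t)`` the numbers of target and decoy
competition winners at score threshold ``t``, the estimated false
discovery rate is ``FDR(t) = N_decoy(t) / N_target(t)`` (the printed
form, without a +1 correction; switchable). q-values are the
monotonized minimum FDR over all thresholds at or below a PSM's score.

An orthogonal estimate uses entrapment sequences spiked into the target
library: with ``N_trap(t)`` entrapment winners among the targets and
``R`` the target/entrapment peptide-count ratio,
``FDR_trap(t) = N_trap(t) / N_target(t) * R``. When ground truth is
available (synthetic runs), the true FDR counts accepted targets whose
peptide differs from the generating one by exact string comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .scoring import ScoreVector
from .search import PSM, SearchResult

logger = logging.getLogger(__name__)


@dataclass
class CompetedPSM:
    query_id: int
    psm: PSM
    label: int  # +1 target, -1 decoy
    is_entrapment: bool = False
    q_value: float = math.nan

    @property
    def score(self) -> float:
        return self.psm.scores.final_score


@dataclass
class FdrCurve:
    """Score-threshold sweep: arrays aligned on descending thresholds."""

    thresholds: np.ndarray
    n_target: np.ndarray
    n_decoy: np.ndarray
    fdr: np.ndarray
    q: np.ndarray
    n_trap: Optional[np.ndarray] = None
    R: Optional[float] = None
    fdr_trap: Optional[np.ndarray] = None
    n_false: Optional[np.ndarray] = None
    fdr_true: Optional[np.ndarray] = None

    def threshold_at_q(self, q_max: float) -> Optional[float]:
        """Most permissive (lowest) threshold whose q-value is <= q_max;
        None when no threshold qualifies."""
        ok = np.flatnonzero(self.q <= q_max)
        if ok.size == 0:
            return None
        return float(self.thresholds[ok[-1]])


def compete(
    target_psms: Iterable[PSM],
    decoy_psms: Iterable[PSM],
    entrapment_peptides: Optional[set] = None,
    target_peptides: Optional[set] = None,
) -> Tuple[List[CompetedPSM], int]:
    """Merge separate target and decoy search results, keeping per query
    the single higher-scoring rank-1 hit. Exact ties go to the target
    (counted and returned so the effect is auditable). A target winner
    is flagged entrapment when its peptide occurs in the entrapment
    peptide set and not in the true-target peptide set."""
    best_t: Dict[int, PSM] = {}
    for p in target_psms:
        if p.rank == 1:
            best_t[p.query_id] = p
    best_d: Dict[int, PSM] = {}
    for p in decoy_psms:
        if p.rank == 1:
            best_d[p.query_id] = p

    n_ties = 0
    out: List[CompetedPSM] = []
    for qid in sorted(set(best_t) | set(best_d)):
        t, d = best_t.get(qid), best_d.get(qid)
        if t is not None and d is not None:
            if t.scores.final_score == d.scores.final_score:
                n_ties += 1
                winner, label = t, 1
            elif t.scores.final_score > d.scores.final_score:
                winner, label = t, 1
            else:
                winner, label = d, -1
        elif t is not None:
            winner, label = t, 1
        else:
            winner, label = d, -1
        is_trap = bool(
            label == 1
            and entrapment_peptides
            and winner.peptide in entrapment_peptides
            and (target_peptides is None or winner.peptide not in target_peptides)
        )
        out.append(
            CompetedPSM(
                query_id=qid, psm=winner, label=label, is_entrapment=is_trap
            )
        )
    if n_ties:
        logger.info("target/decoy competition: %d exact ties kept as target",
                    n_ties)
    return out, n_ties


def _sweep(competed: Sequence[CompetedPSM]):
    """Sorted descending scores with cumulative target/decoy/entrapment
    counts at every distinct threshold."""
    if not competed:
        raise ValueError("no competed PSMs")
    scores = np.array([c.score for c in competed])
    labels = np.array([c.label for c in competed])
    traps = np.array([c.is_entrapment for c in competed])
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    cum_t = np.cumsum(labels[order] == 1)
    cum_d = np.cumsum(labels[order] == -1)
    cum_trap = np.cumsum(traps[order])
    # keep the last row of each distinct score (full count at threshold)
    last = np.flatnonzero(np.append(np.diff(s) != 0.0, True))
    return s[last], cum_t[last], cum_d[last], cum_trap[last], order, scores


def tdc_fdr(
    competed: Sequence[CompetedPSM], plus_one: bool = False
) -> FdrCurve:
    """Target-decoy FDR curve over every distinct score threshold, with
    monotonized q-values. ``plus_one=True`` applies the conservative
    (N_decoy + 1) correction. Also annotates each CompetedPSM's
    q_value in place."""
    thr, n_t, n_d, _, _, scores = _sweep(competed)
    num = n_d + 1 if plus_one else n_d
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_t > 0, num / np.maximum(n_t, 1), 0.0)
    # q(t) = min FDR over thresholds at or below t (more permissive)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    curve = FdrCurve(
        thresholds=thr, n_target=n_t, n_decoy=n_d, fdr=fdr, q=q
    )
    pos = thr.size - 1 - np.searchsorted(thr[::-1], scores, side="left")
    for c, i in zip(competed, pos):
        c.q_value = float(q[i])
    return curve


def entrapment_fdr(
    competed: Sequence[CompetedPSM], R: float
) -> FdrCurve:
    """Entrapment-based FDR curve: N_trap / N_target * R per threshold,
    with R the target/entrapment peptide-count ratio."""
    if R <= 0:
        raise ValueError("R must be positive")
    thr, n_t, n_d, n_trap, _, _ = _sweep(competed)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1), 0.0)
        fdr_trap = np.where(n_t > 0, n_trap / np.maximum(n_t, 1) * R, 0.0)
    q = np.clip(np.minimum.accumulate(fdr[::-1])[::-1], 0.0, 1.0)
    return FdrCurve(
        thresholds=thr, n_target=n_t, n_decoy=n_d, fdr=fdr, q=q,
        n_trap=n_trap, R=R, fdr_trap=fdr_trap,
    )


def true_fdr(
    competed: Sequence[CompetedPSM], truth: Dict[int, str]
) -> FdrCurve:
    """Ground-truth FDR curve: N_false counts accepted target winners
    whose peptide is not the generating peptide (exact string match;
    I/L distinct). Queries missing from the truth map are excluded with
    a warning; foreign queries carry a marker that never matches."""
    known = [c for c in competed if c.query_id in truth]
    missing = len(competed) - len(known)
    if missing:
        logger.warning("true_fdr: %d queries missing from truth map", missing)
    if not known:
        return FdrCurve(
            thresholds=np.empty(0), n_target=np.empty(0, int),
            n_decoy=np.empty(0, int), fdr=np.empty(0), q=np.empty(0),
            n_false=np.empty(0, int), fdr_true=np.empty(0),
        )
    scores = np.array([c.score for c in known])
    is_target = np.array([c.label == 1 for c in known])
    wrong = np.array(
        [c.label == 1 and c.psm.peptide != truth[c.query_id] for c in known]
    )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    cum_t = np.cumsum(is_target[order])
    cum_f = np.cumsum(wrong[order])
    cum_d = np.cumsum(~is_target[order])
    last = np.flatnonzero(np.append(np.diff(s) != 0.0, True))
    thr, n_t, n_f, n_d = s[last], cum_t[last], cum_f[last], cum_d[last]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1), 0.0)
        fdr_true = np.where(n_t > 0, n_f / np.maximum(n_t, 1), 0.0)
    q = np.clip(np.minimum.accumulate(fdr[::-1])[::-1], 0.0, 1.0)
    return FdrCurve(
        thresholds=thr, n_target=n_t, n_decoy=n_d, fdr=fdr, q=q,
        n_false=n_f, fdr_true=fdr_true,
    )


PIN_RT_COLUMNS = ("rt_diff_abs", "rt_diff_sq", "rt_diff_log", "rt_diff_rel")


def write_pin(
    psms: Sequence[PSM],
    path,
    rt_distances: Optional[Dict[int, Tuple[float, float, float, float]]] = None,
) -> None:
    """Percolator pin-tab export: SpecId, Label (+-1), ScanNr, the full
    feature block, flanked Peptide and Proteins. Four retention-time
    distance feature columns (absolute, squared, log, relative) are
    reserved and included when ``rt_distances`` maps query ids to them.
    Raises on any non-finite feature value."""
    feat_names = list(ScoreVector.FEATURE_ORDER)
    if rt_distances is not None:
        feat_names += list(PIN_RT_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "SpecId\tLabel\tScanNr\t" + "\t".join(feat_names)
            + "\tPeptide\tProteins\n"
        )
        for p in psms:
            feats = p.scores.as_feature_dict()
            if rt_distances is not None:
                rt = rt_distances.get(p.query_id, (0.0, 0.0, 0.0, 0.0))
                feats.update(dict(zip(PIN_RT_COLUMNS, rt)))
            vals = []
            for name in feat_names:
                v = float(feats[name])
                if not math.isfinite(v):
                    raise ValueError(
                        f"non-finite value for feature {name!r} in PSM "
                        f"(query {p.query_id}, library {p.library_id})"
                    )
                vals.append(f"{v:.9g}")
            label = -1 if p.is_decoy else 1
            spec_id = f"q{p.query_id}_r{p.rank}_{'d' if p.is_decoy else 't'}"
            fh.write(
                f"{spec_id}\t{label}\t{p.query_id}\t" + "\t".join(vals)
                + f"\t-.{p.peptide}.-\t{'decoy' if p.is_decoy else 'library'}\n"
            )


def write_fdr_tsv(curve: FdrCurve, path) -> None:
    cols = ["threshold", "n_target", "n_decoy", "fdr", "q"]
    extra = []
    if curve.fdr_trap is not None:
        cols += ["n_trap", "fdr_trap"]
        extra.append((curve.n_trap, curve.fdr_trap))
    if curve.fdr_true is not None:
        cols += ["n_false", "fdr_true"]
        extra.append((curve.n_false, curve.fdr_true))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(curve.thresholds.size):
            row = [
                f"{curve.thresholds[i]:.9g}",
                str(int(curve.n_target[i])),
                str(int(curve.n_decoy[i])),
                f"{curve.fdr[i]:.9g}",
                f"{curve.q[i]:.9g}",
            ]
            for counts, rates in extra:
                row += [str(int(counts[i])), f"{rates[i]:.9g}"]
            fh.write("\t".join(row) + "\n")
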