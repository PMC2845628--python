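"""PWM scanning, discriminative evaluation, and motif comparison.

A motif's enrichment in a foreground promoter set against a matched
background set is summarized by the classification relative-error rate
(err): each sequence is called positive when its best log-odds site
score reaches a cutoff, the cutoff is chosen to minimize the average of
the false-positive and false-negative rates, and that minimum is err.
Significance comes from permuting the foreground/background indicator
over whole sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .pwm import PWM
from .sequences import MaskedSequence, MaskedSequenceSet

__all__ = [
    "EnrichmentResult",
    "MotifMatch",
    "best_site_scores",
    "scan_best_site",
    "classify_set",
    "library_significance",
    "denovo_significance",
    "compare_motifs",
    "merge_similar",
    "rerank_across_sets",
    "region_enrichment_fet",
]

NEG_INF = -np.inf


@dataclass
class EnrichmentResult:
    motif: str
    err: float
    cutoff: float
    p: float = 1.0
    source_set: str = ""
    rank: int = 0
    pwm: Optional[PWM] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.err <= 1.0):
            raise ValueError(f"err {self.err} outside [0, 1]")


@dataclass(frozen=True)
class MotifMatch:
    query: str
    reference: str
    divergence: float  # bits per aligned column
    offset: int
    orientation: str  # forward | reverse-complement
    is_match: bool


# --------------------------------------------------------------------------
# Scanning
# --------------------------------------------------------------------------

def _window_scores(W: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Scores of precomputed windows against a log-odds matrix (both handled
    by the caller passing forward and reverse-complement matrices)."""
    L = W.shape[1]
    return lod[np.arange(L)[:, None], W.T.astype(np.intp)].sum(axis=0)


def best_site_scores(
    seqs: MaskedSequenceSet,
    pwm: PWM,
    background: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Best double-stranded log-odds site score per sequence.

    Sequences without a fully-unmasked window of the motif's length get
    the -inf sentinel.
    """
    L = len(pwm)
    W, seq_idx, _ = seqs.windows(L)
    out = np.full(len(seqs), NEG_INF)
    if W.shape[0] == 0:
        return out
    lod = pwm.log_odds(background)
    lod_rc = pwm.reverse_complement().log_odds(background)
    scores = np.maximum(_window_scores(W, lod), _window_scores(W, lod_rc))
    # windows are emitted grouped by sequence: segment-max via reduceat
    boundaries = np.nonzero(np.diff(seq_idx))[0] + 1
    starts = np.concatenate([[0], boundaries])
    seq_ids = seq_idx[starts]
    out[seq_ids] = np.maximum.reduceat(scores, starts)
    return out


def scan_best_site(
    seq: MaskedSequence,
    pwm: PWM,
    background: Optional[np.ndarray] = None,
) -> float:
    """Maximum log-odds score over both strands and unmasked windows."""
    tmp = MaskedSequenceSet([seq.copy()])
    return float(best_site_scores(tmp, pwm, background)[0])


# --------------------------------------------------------------------------
# Classification relative error
# --------------------------------------------------------------------------

def min_err_cutoff(fg_scores: np.ndarray, bg_scores: np.ndarray) -> Tuple[float, float]:
    """Cutoff minimizing (FPR + FNR)/2 over attained scores.

    A sequence is positive iff score >= cutoff.  The all-negative cutoff
    (+inf) attains err 0.5, so the minimum never exceeds 0.5.  Ties are
    broken toward the largest cutoff (fewest positives).
    """
    fg = np.sort(np.asarray(fg_scores, float))
    bg = np.sort(np.asarray(bg_scores, float))
    n1, n0 = len(fg), len(bg)
    if n1 == 0 or n0 == 0:
        raise ValueError("foreground and background must be non-empty")
    cand = np.unique(np.concatenate([fg, bg]))
    fnr = np.searchsorted(fg, cand, side="left") / n1
    fpr = (n0 - np.searchsorted(bg, cand, side="left")) / n0
    err = (fpr + fnr) / 2.0
    best = float(err.min())
    if best >= 0.5:
        return 0.5, np.inf
    # largest cutoff among minimizers
    idx = np.nonzero(err == err.min())[0][-1]
    return best, float(cand[idx])


def classify_set(
    fg: MaskedSequenceSet,
    bg_set: MaskedSequenceSet,
    pwm: PWM,
    background: Optional[np.ndarray] = None,
) -> EnrichmentResult:
    """Evaluate one motif's discrimination of foreground vs background.

    The log-odds background composition defaults to the matched
    background set's base composition at the same processing stage.
    """
    if len(fg) == 0 or len(bg_set) == 0:
        raise ValueError("foreground and background sets must be non-empty")
    bg_comp = bg_set.base_composition() if background is None else background
    s_fg = best_site_scores(fg, pwm, bg_comp)
    s_bg = best_site_scores(bg_set, pwm, bg_comp)
    err, cutoff = min_err_cutoff(s_fg, s_bg)
    return EnrichmentResult(
        motif=pwm.id, err=err, cutoff=cutoff, source_set=fg.stage_label, pwm=pwm
    )


def _err_matrix_for_labels(
    sorted_scores_info: Tuple[np.ndarray, np.ndarray],
    labels: np.ndarray,
    n1: int,
    n0: int,
) -> np.ndarray:
    """Minimum err for each label row given one motif's score ordering.

    ``sorted_scores_info`` is (order, group_ends): indices sorting the
    pooled scores descending and the last index of each tied-score
    group.  ``labels`` is (n_rows, N) with 1 = foreground.
    """
    order, group_ends = sorted_scores_info
    arranged = labels[:, order]
    tp = arranged.cumsum(axis=1)[:, group_ends]
    pos = group_ends + 1
    fp = pos[None, :] - tp
    err = (fp / n0 + (n1 - tp) / n1) / 2.0
    return np.minimum(err.min(axis=1), 0.5)


def _score_order(scores: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    ends = np.nonzero(np.diff(s))[0]
    group_ends = np.concatenate([ends, [len(s) - 1]])
    return order, group_ends


def library_significance(
    library: Sequence[PWM],
    fg: MaskedSequenceSet,
    bg_set: MaskedSequenceSet,
    n_perm: int = 10000,
    rng: Optional[np.random.Generator] = None,
    null_mode: str = "library_min",
    background: Optional[np.ndarray] = None,
) -> List[EnrichmentResult]:
    """Permutation p-values for a motif library's enrichment errs.

    The indicator vector assigning sequences to foreground or background
    is permuted ``n_perm`` times; under ``null_mode='library_min'`` the
    null statistic is the per-permutation minimum err over the whole
    library (controls library-wide selection), under ``'per_motif'``
    each motif is tested against its own permutation errs.  p-values use
    the add-one estimator; results are sorted by err ascending.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not library:
        return []
    rng = rng or np.random.default_rng(0)
    bg_comp = bg_set.base_composition() if background is None else background
    n1, n0 = len(fg), len(bg_set)
    score_rows = []
    for pwm in library:
        row = np.concatenate(
            [best_site_scores(fg, pwm, bg_comp), best_site_scores(bg_set, pwm, bg_comp)]
        )
        score_rows.append(row)
    labels0 = np.concatenate([np.ones(n1, np.int32), np.zeros(n0, np.int32)])
    observed = np.array(
        [
            min_err_cutoff(row[:n1], row[n1:])[0]
            for row in score_rows
        ]
    )
    cutoffs = [min_err_cutoff(row[:n1], row[n1:])[1] for row in score_rows]

    perms = np.tile(labels0, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    null_per_motif = np.stack(
        [
            _err_matrix_for_labels(_score_order(row), perms, n1, n0)
            for row in score_rows
        ]
    )  # (n_motifs, n_perm)
    if null_mode == "library_min":
        null = null_per_motif.min(axis=0)
        ps = [(1 + int((null <= e).sum())) / (n_perm + 1) for e in observed]
    elif null_mode == "per_motif":
        ps = [
            (1 + int((null_per_motif[i] <= observed[i]).sum())) / (n_perm + 1)
            for i in range(len(library))
        ]
    else:
        raise ValueError("null_mode must be 'library_min' or 'per_motif'")

    results = [
        EnrichmentResult(
            motif=pwm.id,
            err=float(observed[i]),
            cutoff=float(cutoffs[i]),
            p=float(ps[i]),
            source_set=fg.stage_label,
            pwm=pwm,
        )
        for i, pwm in enumerate(library)
    ]
    results.sort(key=lambda r: (r.err, r.p, r.motif))
    for rank, r in enumerate(results, 1):
        r.rank = rank
    return results


def denovo_significance(
    fg: MaskedSequenceSet,
    bg_set: MaskedSequenceSet,
    discoverer: Callable[[MaskedSequenceSet, MaskedSequenceSet], List[EnrichmentResult]],
    n_perm: int = 100,
    rng: Optional[np.random.Generator] = None,
    alpha: float = 0.05,
) -> Tuple[float, np.ndarray]:
    """Null distribution of best de novo err under label permutation.

    Full discovery is re-run on ``n_perm`` random foreground/background
    reassignments; the best (lowest) err per permutation forms the null.
    Returns the err threshold below which a motif is significant at
    ``alpha`` (add-one permutation p <= alpha) and the null values.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 to resolve the significance percentile")
    rng = rng or np.random.default_rng(0)
    pool = [e for e in fg] + [e for e in bg_set]
    n1 = len(fg)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(len(pool))
        pfg = MaskedSequenceSet([pool[i].copy() for i in idx[:n1]], fg.stage_label)
        pbg = MaskedSequenceSet([pool[i].copy() for i in idx[n1:]], bg_set.stage_label)
        res = discoverer(pfg, pbg)
        null[b] = min((r.err for r in res), default=0.5)
    # err e is significant iff (1 + #{null <= e}) / (n_perm + 1) <= alpha
    k = int(np.floor(alpha * (n_perm + 1))) - 1
    srt = np.sort(null)
    threshold = float(srt[k]) if k >= 0 else -np.inf
    return threshold, null


def permutation_p(err: float, null: np.ndarray) -> float:
    return (1 + int((null <= err).sum())) / (len(null) + 1)


# --------------------------------------------------------------------------
# Motif comparison and merging
# --------------------------------------------------------------------------

def _sym_kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    return float(0.5 * ((p * np.log2(p / q)).sum() + (q * np.log2(q / p)).sum()))


def compare_motifs(a: PWM, b: PWM, cutoff_bits: float = 1.0, min_overlap: int = 4) -> MotifMatch:
    """Minimum mean per-column symmetrized KL divergence over alignments.

    All relative offsets with at least ``min_overlap`` aligned columns
    are scanned in both orientations.
    """
    best = (np.inf, 0, "forward")
    for orientation, bm in (("forward", b.matrix), ("reverse-complement", b.reverse_complement().matrix)):
        la, lb = len(a), len(bm)
        for offset in range(-(lb - min_overlap), la - min_overlap + 1):
            a_lo, a_hi = max(0, offset), min(la, offset + lb)
            if a_hi - a_lo < min_overlap:
                continue
            cols = [
                _sym_kl_bits(a.matrix[i], bm[i - offset]) for i in range(a_lo, a_hi)
            ]
            d = float(np.mean(cols))
            if d < best[0]:
                best = (d, offset, orientation)
    d, offset, orientation = best
    return MotifMatch(
        query=a.id,
        reference=b.id,
        divergence=d,
        offset=offset,
        orientation=orientation,
        is_match=bool(d <= cutoff_bits),
    )


def merge_similar(
    motifs: Sequence[PWM],
    errs: Sequence[float],
    cutoff_bits: float = 1.0,
) -> List[PWM]:
    """Greedy merge of similar motifs; each cluster keeps its best member.

    Motifs are visited in err order (ties by id); each unclaimed motif
    seeds a cluster and absorbs every later motif within the divergence
    cutoff.
    """
    order = sorted(range(len(motifs)), key=lambda i: (errs[i], motifs[i].id))
    taken = [False] * len(motifs)
    out: List[PWM] = []
    for i in order:
        if taken[i]:
            continue
        taken[i] = True
        out.append(motifs[i])
        for j in order:
            if not taken[j] and compare_motifs(motifs[i], motifs[j], cutoff_bits).is_match:
                taken[j] = True
    return out


def rerank_across_sets(
    results_by_set: Dict[str, Sequence[EnrichmentResult]]
) -> List[EnrichmentResult]:
    """Merge per-stage results: each motif keeps its best (minimum) err.

    Ties break by smaller p, then id; ``source_set`` records the stage
    achieving the minimum.
    """
    best: Dict[str, EnrichmentResult] = {}
    for stage, results in results_by_set.items():
        for r in results:
            cur = best.get(r.motif)
            cand = replace(r, source_set=stage)
            if cur is None or (cand.err, cand.p) < (cur.err, cur.p):
                best[r.motif] = cand
    merged = sorted(best.values(), key=lambda r: (r.err, r.p, r.motif))
    for rank, r in enumerate(merged, 1):
        r.rank = rank
    return merged


# --------------------------------------------------------------------------
# Region-set site enrichment
# --------------------------------------------------------------------------

def region_enrichment_fet(
    motifs: Sequence[PWM],
    fg_regions: MaskedSequenceSet,
    bg_regions: MaskedSequenceSet,
    cutoffs: Dict[str, float],
    background: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """One-sided Fisher exact enrichment of motif sites, Bonferroni-corrected.

    Site cutoffs must be fixed beforehand (from training classify_set).
    The 2x2 table counts sequences with/without a site in each region
    set; p-values are multiplied by the number of motifs tested (capped
    at 1).
    """
    if len(fg_regions) == 0 or len(bg_regions) == 0:
        raise ValueError("empty region set")
    bg_comp = bg_regions.base_composition() if background is None else background
    out: Dict[str, float] = {}
    m = len(motifs)
    for pwm in motifs:
        c = cutoffs[pwm.id]
        k_fg = int((best_site_scores(fg_regions, pwm, bg_comp) >= c).sum())
        k_bg = int((best_site_scores(bg_regions, pwm, bg_comp) >= c).sum())
        table = [
            [k_fg, len(fg_regions) - k_fg],
            [k_bg, len(bg_regions) - k_bg],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        out[pwm.id] = min(1.0, float(p) * m)
    return out
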