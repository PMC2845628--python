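"""Cross-species conserved promoter fragments.

Two complementary conservation calls are produced and then combined:

* alignment-based — per-base conservation probabilities (e.g. phastCons
  scores) thresholded so that a requested fraction of the DNA survives;
* pattern-discovery-based — deterministic enumeration of 8-base seed
  words from the reference promoter (fully-specified seeds, satisfying
  a 6-of-8 solid-density admissibility bound), whose specified positions
  must recur exactly in at least 4 species.  Position-independent
  matching tolerates binding-site turnover (reordering of conserved
  islands) that defeats linear alignment.

Patterns are ranked by a z-score comparing the number of supporting
species to its expectation under per-species 3rd-order Markov
backgrounds, and consumed greedily until a target DNA coverage is
reached.  The combined-conservation mask is the union of the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequences import MaskedSequenceSet, reverse_complement_codes

SEED_LENGTH = 8
MIN_SOLID = 6  # minimum specified positions per 8-base window of a seed

__all__ = [
    "CoverageCalibration",
    "PatternOccurrence",
    "SparsePattern",
    "threshold_for_coverage",
    "alignment_conserved_mask",
    "find_sparse_patterns",
    "pattern_conserved_mask",
    "combine_conservation",
]


@dataclass(frozen=True)
class CoverageCalibration:
    threshold: float
    achieved_fraction: float
    requested_fraction: float


@dataclass(frozen=True)
class PatternOccurrence:
    species: str
    offset: int
    matched: int  # matching positions out of SEED_LENGTH
    strand: str = "+"


@dataclass
class SparsePattern:
    seed: str
    gene: str
    occurrences: List[PatternOccurrence]
    support: int
    z: float
    covered: List[Tuple[str, int, int]]  # (sequence name, start, end) on reference


# --------------------------------------------------------------------------
# Alignment-based conservation
# --------------------------------------------------------------------------

def _pooled_scores(
    track: Dict[str, np.ndarray], seqs: Optional[MaskedSequenceSet]
) -> np.ndarray:
    if seqs is None:
        return np.concatenate([np.asarray(a, float) for a in track.values()])
    parts = []
    for entry in seqs:
        arr = track.get(entry.name)
        if arr is None:
            arr = np.zeros(len(entry))
        parts.append(np.asarray(arr, float)[~entry.mask[: len(arr)]])
    return np.concatenate(parts) if parts else np.empty(0)


def threshold_for_coverage(
    track: Dict[str, np.ndarray],
    fraction: float,
    seqs: Optional[MaskedSequenceSet] = None,
) -> CoverageCalibration:
    """Score threshold retaining the largest DNA fraction <= ``fraction``.

    Scores are pooled over all (unmasked, when ``seqs`` is given) bases;
    the returned threshold t is the smallest attained score whose
    retained fraction (#bases with score >= t / #bases) does not exceed
    the request (closest-from-below over the attainable fractions).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    scores = _pooled_scores(track, seqs)
    if scores.size == 0 or scores.max() <= 0.0:
        raise ValueError("all-zero conservation track: threshold undefined")
    uniq, counts = np.unique(scores, return_counts=True)  # ascending
    n = scores.size
    # retained fraction when thresholding at uniq[i]
    retained = counts[::-1].cumsum()[::-1] / n
    ok = retained <= fraction
    if not ok.any():
        warnings.warn(
            "no attainable coverage at or below the requested fraction; "
            "thresholding above the maximum score"
        )
        t = float(np.nextafter(uniq[-1], np.inf))
        return CoverageCalibration(t, 0.0, fraction)
    i = int(np.argmax(retained[ok]))  # retained is decreasing; first ok index is best
    idx = np.nonzero(ok)[0][i]
    return CoverageCalibration(float(uniq[idx]), float(retained[idx]), fraction)


def alignment_conserved_mask(
    seqs: MaskedSequenceSet,
    track: Dict[str, np.ndarray],
    fraction: float,
) -> MaskedSequenceSet:
    """Mask bases scoring below the coverage-calibrated threshold."""
    cal = threshold_for_coverage(track, fraction, seqs=seqs)
    out = seqs.copy(stage_label="alignment-conserved")
    for entry in out:
        arr = track.get(entry.name)
        scores = np.zeros(len(entry)) if arr is None else np.asarray(arr, float)
        if len(scores) < len(entry):
            scores = np.pad(scores, (0, len(entry) - len(scores)))
        entry.mask |= scores[: len(entry)] < cal.threshold
    return out


# --------------------------------------------------------------------------
# Sparse pattern discovery
# --------------------------------------------------------------------------

class MarkovBackground:
    """3rd-order Markov model of unmasked sequence, for word probabilities."""

    def __init__(self, order: int = 3, pseudocount: float = 0.5):
        self.order = order
        self.ctx_counts = np.full(4**order, pseudocount)
        self.trans_counts = np.full((4**order, 4), pseudocount)

    def fit(self, seq_sets: Sequence) -> "MarkovBackground":
        k = self.order
        for entry in seq_sets:
            codes, mask = entry.codes.astype(np.int64), entry.mask
            if len(codes) < k + 1:
                continue
            ctx = np.zeros(len(codes) - k, dtype=np.int64)
            for j in range(k):
                ctx = ctx * 4 + codes[j : len(codes) - k + j]
            nxt = codes[k:]
            ok = np.convolve(
                (~mask).astype(np.int32), np.ones(k + 1, dtype=np.int32), "valid"
            ) == (k + 1)
            np.add.at(self.ctx_counts, ctx[ok], 1.0)
            np.add.at(self.trans_counts, (ctx[ok], nxt[ok]), 1.0)
        return self

    def word_log_probs(self, words: np.ndarray) -> np.ndarray:
        """log P(word) for an (N, L) array of base-code words, L > order."""
        k = self.order
        ctx0 = np.zeros(words.shape[0], dtype=np.int64)
        for j in range(k):
            ctx0 = ctx0 * 4 + words[:, j]
        stat = self.ctx_counts / self.ctx_counts.sum()
        trans = self.trans_counts / self.trans_counts.sum(axis=1, keepdims=True)
        lp = np.log(stat[ctx0])
        ctx = ctx0
        for j in range(k, words.shape[1]):
            nxt = words[:, j].astype(np.int64)
            lp += np.log(trans[ctx, nxt])
            ctx = (ctx % (4 ** (k - 1))) * 4 + nxt
        return lp


def _encode_windows(codes: np.ndarray) -> np.ndarray:
    base = 4 ** np.arange(codes.shape[1] - 1, -1, -1, dtype=np.int64)
    return codes.astype(np.int64) @ base


def find_sparse_patterns(
    orthologs: Dict[str, MaskedSequenceSet],
    min_species: int = 4,
    backgrounds: Optional[Dict[str, MarkovBackground]] = None,
) -> List[SparsePattern]:
    """Enumerate conserved 8-base seed patterns across orthologous promoters.

    ``orthologs`` maps each gene to a set whose first entry is the
    reference promoter and remaining entries are per-species orthologs
    (entry names are species ids).  Seeds are the fully-specified 8-base
    windows of the reference (trivially satisfying the 6-of-8 solid
    density bound for seed admissibility), and a species supports a seed
    when any of its unmasked 8-base windows, on either strand, matches
    the seed's specified positions exactly; the reference trivially
    supports its own seeds.  Exact occurrence matching is what keeps the
    species-support statistic informative: allowing mismatched
    occurrences makes a chance hit near-certain in promoter-length
    sequence, saturating support for every seed.  Patterns supported by
    fewer than ``min_species`` species are dropped; the rest are ranked
    by z-score (observed supporting species against a per-species
    Markov-background expectation), ties broken by seed then gene.
    """
    # fit per-species backgrounds over all genes unless supplied
    if backgrounds is None:
        per_species: Dict[str, list] = {}
        for gene, sset in orthologs.items():
            for entry in sset:
                per_species.setdefault(entry.name, []).append(entry)
        backgrounds = {
            sp: MarkovBackground().fit(entries) for sp, entries in per_species.items()
        }

    patterns: List[SparsePattern] = []
    for gene in sorted(orthologs):
        sset = orthologs[gene]
        names = sset.names
        if len(names) < min_species:
            warnings.warn(f"gene {gene!r}: fewer than {min_species} species; skipped")
            continue
        ref_name = names[0]
        win_cache = {sp: sset.subset([sp]).windows(SEED_LENGTH) for sp in names}
        ref_W, _, ref_starts = win_cache[ref_name]
        if ref_W.shape[0] == 0:
            continue
        seeds, first_idx = np.unique(_encode_windows(ref_W), return_index=True)
        seed_mat = ref_W[np.sort(first_idx)]
        seeds = _encode_windows(seed_mat)
        n_seeds = seed_mat.shape[0]

        support = np.zeros(n_seeds, dtype=np.int64)
        best_occ: Dict[int, List[PatternOccurrence]] = {i: [] for i in range(n_seeds)}
        rc_mat = np.stack([reverse_complement_codes(s) for s in seed_mat])
        rc_codes = _encode_windows(rc_mat)
        palindrome = seeds == rc_codes

        for sp in names:
            W, _, starts = win_cache[sp]
            if W.shape[0] == 0:
                continue
            codes_sp = _encode_windows(W)
            order = np.argsort(codes_sp, kind="stable")
            sorted_codes = codes_sp[order]

            def lookup(queries: np.ndarray):
                pos = np.searchsorted(sorted_codes, queries)
                safe = np.minimum(pos, len(sorted_codes) - 1)
                ok = sorted_codes[safe] == queries
                return ok, order[safe]

            f_ok, f_idx = lookup(seeds)
            r_ok, r_idx = lookup(rc_codes)
            any_match = f_ok | r_ok
            support += any_match
            for i in np.nonzero(any_match)[0]:
                strand = "+" if f_ok[i] else "-"
                j = f_idx[i] if f_ok[i] else r_idx[i]
                best_occ[int(i)].append(
                    PatternOccurrence(sp, int(starts[j]), SEED_LENGTH, strand)
                )

        # expectation/variance of the support under the background model
        exp = np.zeros(n_seeds)
        var = np.zeros(n_seeds)
        for sp in names:
            W, _, _ = win_cache[sp]
            if W.shape[0] == 0:
                continue
            if sp == ref_name:
                exp += 1.0  # reference always matches its own seed
                continue
            bg = backgrounds[sp]
            p_f = np.exp(bg.word_log_probs(seed_mat))
            p_r = np.exp(bg.word_log_probs(rc_mat))
            p_win = np.minimum(np.where(palindrome, p_f, p_f + p_r), 1.0)
            q_sp = 1.0 - (1.0 - p_win) ** W.shape[0]
            exp += q_sp
            var += q_sp * (1.0 - q_sp)

        z = (support - exp) / np.sqrt(np.maximum(var, 1e-12))
        ref_codes = _encode_windows(ref_W)
        for i in range(n_seeds):
            if support[i] < min_species:
                continue
            word = "".join("ACGT"[c] for c in seed_mat[i])
            ref_hits = (ref_codes == seeds[i]) | (ref_codes == rc_codes[i])
            covered = [
                (ref_name, int(s), int(s) + SEED_LENGTH)
                for s in ref_starts[ref_hits]
            ]
            patterns.append(
                SparsePattern(
                    seed=word,
                    gene=gene,
                    occurrences=best_occ[i],
                    support=int(support[i]),
                    z=float(z[i]),
                    covered=covered,
                )
            )
    patterns.sort(key=lambda p: (-p.z, p.seed, p.gene))
    return patterns


def pattern_conserved_mask(
    seqs: MaskedSequenceSet,
    patterns: Sequence[SparsePattern],
    fraction: float,
    tolerance: float = 0.01,
) -> MaskedSequenceSet:
    """Unmask bases covered by top-z patterns up to a DNA coverage target.

    Patterns are consumed greedily in z order; consumption stops at the
    first pattern whose addition would push coverage past
    ``fraction + tolerance`` of the currently unmasked (MCR) bases.
    Everything not covered by a consumed pattern is masked.
    """
    if not patterns:
        warnings.warn("empty pattern list: output is fully masked")
    out = seqs.copy(stage_label="pattern-conserved")
    denom = sum(int((~e.mask).sum()) for e in out)
    keep = {name: np.zeros(len(out[name]), dtype=bool) for name in out.names}
    covered = 0
    if denom > 0:
        for pat in sorted(patterns, key=lambda p: (-p.z, p.seed, p.gene)):
            new = 0
            spans = []
            for name, s, e in pat.covered:
                # pattern genes are named after the reference promoter
                key = name if name in keep else pat.gene if pat.gene in keep else None
                if key is None:
                    continue
                sl = keep[key][s:e] | out[key].mask[s:e]
                new += int((~sl).sum())
                spans.append((key, s, e))
            if (covered + new) / denom > fraction + tolerance:
                break
            for key, s, e in spans:
                keep[key][s:e] = True
            covered += new
    for name in out.names:
        out[name].mask |= ~keep[name]
    return out


def combine_conservation(
    align: MaskedSequenceSet, pattern: MaskedSequenceSet
) -> MaskedSequenceSet:
    """Union of conserved (unmasked) regions from the two approaches."""
    if set(align.names) != set(pattern.names):
        raise ValueError("sequence name mismatch between conservation sets")
    out = align.copy(stage_label="combined-conservation")
    for name in out.names:
        a, b = align[name], pattern[name]
        if len(a) != len(b):
            raise ValueError(f"length mismatch for sequence {name!r}")
        if not np.array_equal(a.codes, b.codes):
            raise ValueError(f"underlying sequence mismatch for {name!r}")
        out[name].mask = a.mask & b.mask
    return out
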