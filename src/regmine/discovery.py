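"""Discriminative de novo PWM discovery.

The search optimizes classification relative error (err) of a candidate
motif on a foreground set against a matched background set.  It is a
two-stage deterministic procedure: a coarse enumeration over candidate
consensus words drawn from the most over-represented foreground words
(each projected onto a small discretized column lattice), followed by
coordinate-descent refinement over single-column replacements from the
lattice.  Errs are cutoff-coupled, so the site-score cutoff is
re-optimized at every evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import RunConfig
from .motifs import EnrichmentResult, denovo_significance, min_err_cutoff, permutation_p
from .pwm import PWM
from .sequences import MaskedSequenceSet, codes_to_string

__all__ = ["ColumnAlphabet", "DiscoveryResult", "coarse_search", "refine", "discover"]


@dataclass(frozen=True)
class ColumnAlphabet:
    """Discretized probability-column lattice for the coarse search.

    The default granularity-2 lattice holds the four point-mass
    columns, the six equal two-base mixtures, and the uniform column,
    all mixed with a small uniform component so log-odds stay finite.
    """

    granularity: int
    vectors: np.ndarray  # (K, 4), rows sum to 1, entries > 0

    @classmethod
    def default(cls, eps: float = 0.06) -> "ColumnAlphabet":
        rows = []
        for i in range(4):
            for j in range(i, 4):
                v = np.zeros(4)
                v[i] += 0.5
                v[j] += 0.5
                rows.append(v)
        rows.append(np.full(4, 0.25))
        vecs = (1 - eps) * np.stack(rows) + eps / 4.0
        return cls(granularity=2, vectors=vecs)

    def point_mass_index(self, base: int) -> int:
        # rows were built as (0,0),(0,1),(0,2),(0,3),(1,1),...
        offsets = [0, 4, 7, 9]
        return offsets[base]


@dataclass
class DiscoveryResult:
    motifs: List[EnrichmentResult]
    lengths_searched: Tuple[int, ...]
    refinement_iterations: int
    significance_threshold: Optional[float] = None
    null_errs: Optional[np.ndarray] = None


class _Evaluator:
    """Incremental err evaluation of PWMs on pooled fg+bg windows."""

    def __init__(
        self,
        fg: MaskedSequenceSet,
        bg_set: MaskedSequenceSet,
        length: int,
        background: Optional[np.ndarray] = None,
    ):
        self.length = length
        self.n1, self.n0 = len(fg), len(bg_set)
        self.background = (
            bg_set.base_composition() if background is None else np.asarray(background)
        )
        Wf, idf, _ = fg.windows(length)
        Wb, idb, _ = bg_set.windows(length)
        self.W = np.concatenate([Wf, Wb]).astype(np.intp)
        seq_idx = np.concatenate([idf, idb + self.n1])
        self.n_seqs = self.n1 + self.n0
        if self.W.shape[0] == 0:
            raise ValueError(f"no unmasked window of length {length} in either set")
        boundaries = np.nonzero(np.diff(seq_idx))[0] + 1
        self.group_starts = np.concatenate([[0], boundaries])
        self.group_seq = seq_idx[self.group_starts]
        # per-window background log-probability, shared by both strands
        self.bg_logsum = np.log2(self.background)[self.W].sum(axis=1).astype(np.float32)
        # state for the currently loaded PWM
        self._cf: Optional[np.ndarray] = None
        self._cr: Optional[np.ndarray] = None
        self._tf: Optional[np.ndarray] = None
        self._tr: Optional[np.ndarray] = None
        self._matrix: Optional[np.ndarray] = None

    # -- full evaluation ----------------------------------------------------

    def _fwd_lut(self, col: np.ndarray) -> np.ndarray:
        return np.log2(col / self.background).astype(np.float32)

    def _rc_lut(self, col: np.ndarray) -> np.ndarray:
        return np.log2(col[::-1] / self.background).astype(np.float32)

    def load(self, matrix: np.ndarray) -> None:
        L = self.length
        self._matrix = matrix.copy()
        self._cf = np.empty((self.W.shape[0], L), dtype=np.float32)
        self._cr = np.empty_like(self._cf)
        for k in range(L):
            self._cf[:, k] = self._fwd_lut(matrix[k])[self.W[:, k]]
            # reverse-complement: rc row j scores complement of column L-1-j
            self._cr[:, L - 1 - k] = self._rc_lut(matrix[k])[self.W[:, L - 1 - k]]
        self._tf = self._cf.sum(axis=1)
        self._tr = self._cr.sum(axis=1)

    def _err_from_window_scores(self, scores: np.ndarray) -> Tuple[float, float]:
        per_seq = np.full(self.n_seqs, -np.inf)
        per_seq[self.group_seq] = np.maximum.reduceat(scores, self.group_starts)
        return min_err_cutoff(per_seq[: self.n1], per_seq[self.n1 :])

    def current_err(self) -> Tuple[float, float]:
        return self._err_from_window_scores(np.maximum(self._tf, self._tr))

    def err_of(self, matrix: np.ndarray) -> Tuple[float, float]:
        self.load(matrix)
        return self.current_err()

    # -- incremental single-column replacement -------------------------------

    def err_all_columns(self, k: int, vectors: np.ndarray) -> List[Tuple[float, float]]:
        """(err, cutoff) for replacing column ``k`` with each row of ``vectors``."""
        L = self.length
        K = len(vectors)
        lut_f = np.log2(vectors / self.background).astype(np.float32)
        lut_r = np.log2(vectors[:, ::-1] / self.background).astype(np.float32)
        tf = lut_f[:, self.W[:, k]]  # (K, N)
        tf += self._tf - self._cf[:, k]
        tr = lut_r[:, self.W[:, L - 1 - k]]
        tr += self._tr - self._cr[:, L - 1 - k]
        np.maximum(tf, tr, out=tf)
        red = np.maximum.reduceat(tf, self.group_starts, axis=1)
        per_seq = np.full((K, self.n_seqs), -np.inf, dtype=np.float32)
        per_seq[:, self.group_seq] = red
        return [
            min_err_cutoff(per_seq[i, : self.n1], per_seq[i, self.n1 :])
            for i in range(K)
        ]

    def err_with_column(self, k: int, col: np.ndarray) -> Tuple[float, float]:
        L = self.length
        a = self._fwd_lut(col)[self.W[:, k]]
        b = self._rc_lut(col)[self.W[:, L - 1 - k]]
        tf = self._tf - self._cf[:, k] + a
        tr = self._tr - self._cr[:, L - 1 - k] + b
        return self._err_from_window_scores(np.maximum(tf, tr))

    def accept_column(self, k: int, col: np.ndarray) -> None:
        L = self.length
        a = self._fwd_lut(col)[self.W[:, k]]
        b = self._rc_lut(col)[self.W[:, L - 1 - k]]
        self._tf += a - self._cf[:, k]
        self._tr += b - self._cr[:, L - 1 - k]
        self._cf[:, k] = a
        self._cr[:, L - 1 - k] = b
        self._matrix[k] = col


# --------------------------------------------------------------------------
# Word seeding
# --------------------------------------------------------------------------

def _encode(W: np.ndarray) -> np.ndarray:
    base = 4 ** np.arange(W.shape[1] - 1, -1, -1, dtype=np.int64)
    return W.astype(np.int64) @ base


def _decode(codes: np.ndarray, length: int) -> np.ndarray:
    out = np.empty((len(codes), length), dtype=np.int8)
    c = codes.copy()
    for k in range(length - 1, -1, -1):
        out[:, k] = c % 4
        c //= 4
    return out


def overrepresented_words(
    fg: MaskedSequenceSet,
    bg_set: MaskedSequenceSet,
    length: int,
    top: int = 500,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Most over-represented foreground words, as (n, length) code rows.

    Words are scored by a Poisson log-likelihood of their foreground
    count against the expectation under the background occurrence rate
    (with pseudocounts), which rewards repeatedly-seen enriched words
    over sampling flukes seen once or twice.  Ties break by word code.
    """
    Wf, _, _ = fg.windows(length)
    Wb, _, _ = bg_set.windows(length)
    if Wf.shape[0] == 0:
        raise ValueError(f"no unmasked foreground window of length {length}")
    cf_codes, cf = np.unique(_encode(Wf), return_counts=True)
    if Wb.shape[0] > 0:
        cb_codes, cb_all = np.unique(_encode(Wb), return_counts=True)
        pos = np.searchsorted(cb_codes, cf_codes)
        pos = np.clip(pos, 0, len(cb_codes) - 1)
        cb = np.where(cb_codes[pos] == cf_codes, cb_all[pos], 0)
        expected = (cb + pseudocount) * (Wf.shape[0] / Wb.shape[0])
    else:
        expected = np.full(len(cf_codes), pseudocount)
    cf = cf.astype(float)
    llr = cf * np.log((cf + pseudocount) / (expected + pseudocount)) - (cf - expected)
    order = np.lexsort((cf_codes, -llr))[:top]
    return _decode(cf_codes[order], length)


# --------------------------------------------------------------------------
# Search
# --------------------------------------------------------------------------

def coarse_search(
    fg: MaskedSequenceSet,
    bg_set: MaskedSequenceSet,
    length: int,
    alphabet: Optional[ColumnAlphabet] = None,
    beam: int = 50,
    seed_words: int = 500,
    background: Optional[np.ndarray] = None,
    _evaluator: Optional[_Evaluator] = None,
) -> List[Tuple[PWM, float, float]]:
    """Deterministic coarse enumeration over word-seeded lattice PWMs.

    Candidate consensus words are the most over-represented foreground
    words; each becomes a PWM of lattice point-mass columns and is
    scored by err.  Returns the ``beam`` best as (pwm, err, cutoff),
    independent of sequence order.
    """
    if beam < 1:
        raise ValueError("beam must be >= 1")
    alphabet = alphabet or ColumnAlphabet.default()
    ev = _evaluator or _Evaluator(fg, bg_set, length, background)
    words = overrepresented_words(fg, bg_set, length, top=seed_words)
    point = [alphabet.vectors[alphabet.point_mass_index(b)] for b in range(4)]
    L = length
    # A point-mass-column PWM assigns probability hi to the consensus
    # base and lo to the other three, so its log-odds window score is
    # m*log2(hi) + (L-m)*log2(lo) - sum(log2 bg[base]) where m is the
    # match count to the consensus word -- and because the background
    # term uses the window's own bases, the same expression (with the
    # reverse-complement match count) gives the reverse-strand score.
    # Exact errs for all seed words therefore come from match counts,
    # obtained in bulk via one one-hot matrix product per strand.
    his = [point[b][b] for b in range(4)]
    los = [np.delete(point[b], b) for b in range(4)]
    fast = np.allclose(his, his[0]) and all(np.allclose(lo, los[0][0]) for lo in los)
    scored: List[Tuple[float, str, np.ndarray, float]] = []
    if fast:
        slope = float(np.log2(his[0]) - np.log2(los[0][0]))
        base = L * float(np.log2(los[0][0]))
        N = ev.W.shape[0]
        Woh = np.zeros((N, 4 * L), dtype=np.float32)
        Woh[np.arange(N)[:, None], np.arange(L) * 4 + ev.W] = 1.0
        cols = np.arange(L) * 4
        chunk = 64
        for lo_i in range(0, len(words), chunk):
            block = words[lo_i : lo_i + chunk]
            rc = 3 - block[:, ::-1]
            c = len(block)
            coh = np.zeros((2 * c, 4 * L), dtype=np.float32)
            coh[np.arange(c)[:, None], cols + block] = 1.0
            coh[c + np.arange(c)[:, None], cols + rc] = 1.0
            counts = coh @ Woh.T  # (2c, N) match counts
            s = np.maximum(counts[:c], counts[c:], out=counts[:c])
            s *= slope
            s -= ev.bg_logsum
            red = np.maximum.reduceat(s, ev.group_starts, axis=1)
            per_seq = np.full((c, ev.n_seqs), -np.inf, dtype=np.float32)
            per_seq[:, ev.group_seq] = red
            for j, w in enumerate(block):
                e, cut = min_err_cutoff(per_seq[j, : ev.n1], per_seq[j, ev.n1 :])
                scored.append((e, codes_to_string(w), w, cut + base))
    else:
        for w in words:
            matrix = np.stack([point[b] for b in w])
            err, cut = ev.err_of(matrix)
            scored.append((err, codes_to_string(w), w, cut))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [
        (PWM(f"denovo_w{length}_{word}", np.stack([point[b] for b in w])), err, cutoff)
        for err, word, w, cutoff in scored[:beam]
    ]


def refine(
    pwm: PWM,
    fg: MaskedSequenceSet,
    bg_set: MaskedSequenceSet,
    alphabet: Optional[ColumnAlphabet] = None,
    max_iter: int = 100,
    background: Optional[np.ndarray] = None,
    _evaluator: Optional[_Evaluator] = None,
) -> Tuple[PWM, float, float, int]:
    """Coordinate-descent refinement over single-column lattice swaps.

    Columns are visited cyclically; a replacement is accepted when it
    strictly lowers err (ties keep the incumbent, then prefer the
    lowest lattice index), so err is non-increasing and the endpoint is
    a local optimum of the single-column neighborhood.  Returns
    (refined pwm, err, cutoff, passes used).
    """
    alphabet = alphabet or ColumnAlphabet.default()
    ev = _evaluator or _Evaluator(fg, bg_set, len(pwm), background)
    ev.load(pwm.matrix)
    err, cutoff = ev.current_err()
    passes = 0
    for _ in range(max_iter):
        improved = False
        passes += 1
        for k in range(len(pwm)):
            best = (err, cutoff, None)
            candidates = ev.err_all_columns(k, alphabet.vectors)
            for vi, (e, c) in enumerate(candidates):
                if np.allclose(alphabet.vectors[vi], ev._matrix[k]):
                    continue
                if e < best[0] - 1e-12:
                    best = (e, c, vi)
            if best[2] is not None:
                ev.accept_column(k, alphabet.vectors[best[2]])
                err, cutoff = best[0], best[1]
                improved = True
        if not improved:
            break
    refined = PWM(pwm.id, ev._matrix.copy())
    return refined, err, cutoff, passes


def discover(
    fg: MaskedSequenceSet,
    bg_set: MaskedSequenceSet,
    config: Optional[RunConfig] = None,
    rng: Optional[np.random.Generator] = None,
    alphabet: Optional[ColumnAlphabet] = None,
    refine_top: int = 5,
    attach_significance: bool = True,
) -> DiscoveryResult:
    """Full de novo discovery across configured motif lengths.

    Coarse search + refinement per length, pooling, merging of similar
    motifs (best err represents each cluster), optional permutation
    significance, and ranking by err.
    """
    from .motifs import merge_similar  # local import avoids cycle at module load

    config = config or RunConfig()
    if len(fg) < 5:
        raise ValueError("foreground too small for discovery (need >= 5 sequences)")
    if len(fg) < config.min_targets:
        warnings.warn(
            f"foreground has {len(fg)} sequences; at least "
            f"{config.min_targets} are recommended for discovery"
        )
    alphabet = alphabet or ColumnAlphabet.default()
    bg_comp = bg_set.base_composition()

    def _run(f: MaskedSequenceSet, b: MaskedSequenceSet) -> List[EnrichmentResult]:
        pool: List[EnrichmentResult] = []
        total_passes = 0
        for length in config.motif_lengths:
            try:
                ev = _Evaluator(f, b, length, bg_comp)
            except ValueError:
                continue
            cands = coarse_search(
                f, b, length, alphabet,
                beam=config.beam_width, seed_words=config.seed_words,
                background=bg_comp, _evaluator=ev,
            )
            for pwm, _, _ in cands[:refine_top]:
                rp, err, cutoff, passes = refine(
                    pwm, f, b, alphabet,
                    max_iter=config.refine_max_iter,
                    background=bg_comp, _evaluator=ev,
                )
                total_passes += passes
                pool.append(
                    EnrichmentResult(
                        motif=rp.id, err=err, cutoff=cutoff,
                        source_set=f.stage_label, pwm=rp,
                    )
                )
        if not pool:
            return []
        merged = merge_similar([r.pwm for r in pool], [r.err for r in pool])
        keep_ids = {p.id for p in merged}
        out = [r for r in pool if r.motif in keep_ids]
        out.sort(key=lambda r: (r.err, r.motif))
        _run.passes = total_passes  # type: ignore[attr-defined]
        return out

    results = _run(fg, bg_set)
    threshold = None
    null = None
    if attach_significance and results:
        rng = rng or np.random.default_rng(config.rng_seed)
        threshold, null = denovo_significance(
            fg, bg_set,
            lambda f, b: _run(f, b),
            n_perm=config.denovo_permutations,
            rng=rng,
            alpha=config.significance_alpha,
        )
        for r in results:
            r.p = permutation_p(r.err, null)
    for rank, r in enumerate(results, 1):
        r.rank = rank
    return DiscoveryResult(
        motifs=results,
        lengths_searched=tuple(config.motif_lengths),
        refinement_iterations=getattr(_run, "passes", 0),
        significance_threshold=threshold,
        null_errs=null,
    )
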