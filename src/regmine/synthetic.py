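"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure the pipeline
assumes: expression matrices with planted TF->target edges and
TF->mediator->distal cascades (so DPI has indirect edges to prune);
promoters with sites planted from a known PWM over a 3rd-order Markov
background; and orthologous promoter sets in which the neighborhoods of
planted sites form conserved islands whose order across species can be
permuted ("binding-site turnover"), destroying linear alignability
while preserving island content.  Truth records make exact site-level
recall computable for any discovery output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pwm import PWM
from .sequences import MaskedSequence, MaskedSequenceSet

__all__ = [
    "SyntheticSpec",
    "default_planted_pwm",
    "simulate_expression",
    "simulate_promoters",
    "simulate_orthologs",
    "MarkovSampler",
]


def default_planted_pwm() -> PWM:
    """A CREB-like 10-column motif of realistic strength (~13 bits).

    Validated vertebrate TF matrices typically carry 10-16 bits of
    information; most columns here are strong (0.92) with two degenerate
    columns (0.70), giving sites that vary from the consensus the way
    genuine binding sites do.
    """
    consensus = "TGACGTCATC"
    dominant = [0.92, 0.92, 0.70, 0.92, 0.92, 0.92, 0.70, 0.92, 0.92, 0.92]
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.empty((10, 4))
    for i, (ch, d) in enumerate(zip(consensus, dominant)):
        rest = (1.0 - d) / 3.0
        m[i] = rest
        m[i, base_idx[ch]] = d
    return PWM("planted", m)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    n_samples: int = 254
    n_genes: int = 120
    planted_edges: List[Tuple[str, str, float]] = field(default_factory=list)
    cascade_chains: List[Tuple[str, str, str]] = field(default_factory=list)
    promoter_length: int = 1500
    planted_pwm: PWM = field(default_factory=default_planted_pwm)
    site_frequency: float = 0.9
    species: Tuple[str, ...] = ("human", "mouse", "rat", "chimpanzee", "rhesus", "dog")
    island_length: int = 50
    turnover_rate: float = 0.0
    noise_sd: float = 0.5
    island_substitution: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.site_frequency <= 1.0):
            raise ValueError("site_frequency must be in [0, 1]")
        if self.promoter_length < len(self.planted_pwm):
            raise ValueError("promoter shorter than planted motif")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def planted_network_spec(
    n_direct: int = 35,
    n_cascades: int = 10,
    n_samples: int = 254,
    n_genes: int = 120,
    noise_sd: float = 0.5,
    seed: int = 0,
    tf: str = "TF1",
) -> SyntheticSpec:
    """Convenience spec: one activator TF with direct targets and cascades."""
    edges = [(tf, f"T{i:03d}", 1.0) for i in range(1, n_direct + 1)]
    chains = [(tf, f"M{i:02d}", f"D{i:02d}") for i in range(1, n_cascades + 1)]
    return SyntheticSpec(
        n_samples=n_samples,
        n_genes=n_genes,
        planted_edges=edges,
        cascade_chains=chains,
        noise_sd=noise_sd,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Expression
# --------------------------------------------------------------------------

def simulate_expression(
    spec: SyntheticSpec, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Expression matrix with planted direct edges and cascades.

    TF profiles are i.i.d. standard normal; each direct target is a
    linear (hence monotone) function of its TF plus Gaussian noise of
    ``noise_sd``; cascade distal genes depend on the TF only through
    the mediator, so the TF-distal edge is indirect and DPI should
    prune it.  Remaining genes are independent noise.
    """
    rng = rng or spec.rng()
    n = spec.n_samples
    profiles: Dict[str, np.ndarray] = {}
    tfs = {e[0] for e in spec.planted_edges} | {c[0] for c in spec.cascade_chains}
    for tf in sorted(tfs):
        profiles[tf] = rng.standard_normal(n)
    for tf, target, effect in spec.planted_edges:
        profiles[target] = effect * profiles[tf] + spec.noise_sd * rng.standard_normal(n)
    for tf, mediator, distal in spec.cascade_chains:
        med = profiles[tf] + spec.noise_sd * rng.standard_normal(n)
        profiles[mediator] = med
        profiles[distal] = med + spec.noise_sd * rng.standard_normal(n)
    i = 0
    while len(profiles) < spec.n_genes:
        i += 1
        name = f"G{i:04d}"
        if name in profiles:
            continue
        profiles[name] = rng.standard_normal(n)
    genes = sorted(profiles)
    mat = np.stack([profiles[g] for g in genes])
    return pd.DataFrame(mat, index=genes, columns=[f"S{j + 1:03d}" for j in range(n)])


# --------------------------------------------------------------------------
# Promoters
# --------------------------------------------------------------------------

class MarkovSampler:
    """3rd-order Markov sequence sampler with seeded random parameters.

    The transition matrix is drawn once (Dirichlet with mild
    concentration) so background composition is non-uniform but
    homogeneous, matching the order of the conservation module's null.
    """

    def __init__(self, rng: np.random.Generator, order: int = 3, concentration: float = 5.0):
        self.order = order
        k = 4**order
        self.trans = rng.dirichlet(np.full(4, concentration), size=k)
        self.init = rng.dirichlet(np.full(k, concentration))

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        k = self.order
        out = np.empty(length, dtype=np.int8)
        if length == 0:
            return out
        ctx = rng.choice(4**k, p=self.init)
        first = []
        c = ctx
        for _ in range(k):
            first.append(c % 4)
            c //= 4
        first = first[::-1]
        for i in range(min(k, length)):
            out[i] = first[i]
        for i in range(k, length):
            b = rng.choice(4, p=self.trans[ctx])
            out[i] = b
            ctx = (ctx % (4 ** (k - 1))) * 4 + b
        return out

    def probabilities(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.init, self.trans


def simulate_promoters(
    spec: SyntheticSpec,
    n_fg: int,
    n_bg: int,
    rng: Optional[np.random.Generator] = None,
    markov: Optional[MarkovSampler] = None,
) -> Tuple[MaskedSequenceSet, MaskedSequenceSet, Dict[str, List[Tuple[int, int]]]]:
    """Foreground promoters with planted sites, background, and truth.

    Background promoters are 3rd-order Markov sequences; foreground
    promoters additionally carry one site sampled from the planted PWM,
    inserted at a uniform position on a uniform strand, in
    ``site_frequency`` of the sequences.  Truth maps each foreground
    name to its planted (start, end) intervals.
    """
    rng = rng or spec.rng()
    markov = markov or MarkovSampler(rng)
    L = spec.promoter_length
    pwm = spec.planted_pwm
    w = len(pwm)
    if w > L:
        raise ValueError("site longer than promoter")
    truth: Dict[str, List[Tuple[int, int]]] = {}
    fg = MaskedSequenceSet(stage_label="conservation-free")
    for i in range(n_fg):
        name = f"fg{i + 1:03d}"
        codes = markov.sample(L, rng)
        truth[name] = []
        if rng.random() < spec.site_frequency:
            pos = int(rng.integers(0, L - w + 1))
            site = pwm.sample_site(rng)
            if rng.random() < 0.5:
                site = (3 - site[::-1]).astype(np.int8)
            codes[pos : pos + w] = site
            truth[name].append((pos, pos + w))
        fg.add(MaskedSequence(name, codes, np.zeros(L, dtype=bool)))
    bg = MaskedSequenceSet(stage_label="background")
    for i in range(n_bg):
        codes = markov.sample(L, rng)
        bg.add(MaskedSequence(f"bg{i + 1:04d}", codes, np.zeros(L, dtype=bool)))
    return fg, bg, truth


# --------------------------------------------------------------------------
# Orthologs and conservation tracks
# --------------------------------------------------------------------------

def _islands_for(
    length: int,
    sites: Sequence[Tuple[int, int]],
    island_length: int,
    rng: np.random.Generator,
) -> List[Tuple[int, int]]:
    """Island intervals: one per planted site (or one random neutral island)."""
    islands: List[Tuple[int, int]] = []
    if sites:
        for s, e in sites:
            centre = (s + e) // 2
            lo = max(0, min(centre - island_length // 2, length - island_length))
            islands.append((lo, lo + island_length))
    else:
        lo = int(rng.integers(0, max(1, length - island_length)))
        islands.append((lo, lo + island_length))
    # merge overlaps to keep segmentation well-defined
    islands.sort()
    merged = [islands[0]]
    for s, e in islands[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


def simulate_orthologs(
    promoter: MaskedSequence,
    truth_sites: Sequence[Tuple[int, int]],
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    markov: Optional[MarkovSampler] = None,
) -> Tuple[MaskedSequenceSet, np.ndarray]:
    """Per-species ortholog sequences plus an alignment-style track.

    Conserved islands (planted-site neighborhoods, or one neutral
    island when the promoter carries no site) are copied into each
    species with a low per-base substitution rate; spacers between
    islands are regenerated independently per species.  With
    probability ``turnover_rate`` a species receives the islands in
    permuted order, which preserves island content but breaks linear
    alignability.  The emitted conservation track scores an island high
    only when at least half the ortholog species kept the original
    order — emulating the blindness of alignment-based conservation to
    turnover.
    """
    rng = rng or spec.rng()
    markov = markov or MarkovSampler(rng)
    L = len(promoter)
    islands = _islands_for(L, truth_sites, spec.island_length, rng)
    ref_name = spec.species[0]
    out = MaskedSequenceSet()
    out.add(MaskedSequence(ref_name, promoter.codes.copy(), promoter.mask.copy()))

    # spacer segmentation of the reference
    spacers: List[Tuple[int, int]] = []
    prev = 0
    for s, e in islands:
        if s > prev:
            spacers.append((prev, s))
        prev = e
    if prev < L:
        spacers.append((prev, L))

    n_keep_order = 0
    for sp in spec.species[1:]:
        permute = rng.random() < spec.turnover_rate
        if not permute:
            n_keep_order += 1
        order = list(range(len(islands)))
        if permute and len(islands) > 1:
            while True:
                perm = list(rng.permutation(len(islands)))
                if perm != order:
                    order = perm
                    break
        pieces: List[np.ndarray] = []
        island_seqs = []
        for s, e in islands:
            seg = promoter.codes[s:e].copy()
            subs = rng.random(len(seg)) < spec.island_substitution
            if subs.any():
                shift = rng.integers(1, 4, size=int(subs.sum()))
                seg[subs] = (seg[subs] + shift) % 4
            island_seqs.append(seg)
        # rebuild: spacer, island, spacer, island ... with islands re-ordered
        cursor = 0
        isl_i = 0
        pos = 0
        boundaries = sorted([(s, e, "i", k) for k, (s, e) in enumerate(islands)] +
                            [(s, e, "s", k) for k, (s, e) in enumerate(spacers)])
        for s, e, kind, k in boundaries:
            if kind == "s":
                pieces.append(markov.sample(e - s, rng))
            else:
                pieces.append(island_seqs[order[isl_i]])
                isl_i += 1
        out.add(MaskedSequence(sp, np.concatenate(pieces) if pieces else np.empty(0, np.int8),
                               np.zeros(L, dtype=bool)))

    track = np.clip(rng.beta(1.0, 20.0, size=L), 0.0, 1.0)
    n_orth = len(spec.species) - 1
    if n_keep_order * 2 >= n_orth:
        for s, e in islands:
            track[s:e] = np.clip(0.92 + 0.05 * rng.standard_normal(e - s), 0.0, 1.0)
    return out, track
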