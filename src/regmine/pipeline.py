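"""End-to-end discovery pipeline: network -> promoters -> conservation -> motifs.

The flow mirrors the study design: a bootstrap-consensus regulatory
network proposes activated targets per TF; target promoters (and a
matched random background, processed identically) are repeat/exon
masked; alignment-based and pattern-based conservation masks are
combined at matched DNA coverage; library enrichment and de novo
discovery run on both the conservation-free and combined-conservation
sets; and the per-stage results are merged, each motif keeping its best
(minimum) err, and re-ranked.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .config import RunConfig
from .conservation import (
    alignment_conserved_mask,
    combine_conservation,
    find_sparse_patterns,
    pattern_conserved_mask,
)
from .discovery import discover
from .io import (
    PathLike,
    read_bed,
    read_conservation_track,
    read_expression_matrix,
    read_genome,
    read_motif_library,
    read_sequences,
    read_tf_list,
    read_tss_table,
)
from .motifs import (
    EnrichmentResult,
    compare_motifs,
    library_significance,
    rerank_across_sets,
)
from .network import activated_targets, bootstrap_consensus
from .promoters import build_background, extract_promoters, mask_regions
from .pwm import PWM
from .sequences import MaskedSequenceSet

logger = logging.getLogger("regmine")

__all__ = ["PipelineInputs", "PipelineReport", "ReportRow", "run_pipeline"]


@dataclass
class PipelineInputs:
    """File paths consumed by :func:`run_pipeline`.

    ``conservation_track`` is a bedGraph/wiggle of per-base scores in
    promoter-local coordinates keyed by gene id; ``ortholog_dir``
    contains one FASTA per gene (``<gene>.fa``) whose first record is
    the reference promoter and remaining records are per-species
    orthologs.  Conservation stages run only when both are provided.
    """

    expression: PathLike
    tf_list: PathLike
    annotations: PathLike
    genome: PathLike
    repeat_masks: Optional[PathLike] = None
    conservation_track: Optional[PathLike] = None
    ortholog_dir: Optional[PathLike] = None
    motif_library: Optional[PathLike] = None


@dataclass
class ReportRow:
    """One ranked motif for one TF."""

    tf: str
    rank: int
    motif: str
    source_set: str
    err: float
    cutoff: float
    p: float
    matches_known: bool
    known_match: str = ""


@dataclass
class PipelineReport:
    """Ranked motifs per TF plus stage statistics and provenance."""

    rows: List[ReportRow] = field(default_factory=list)
    stage_stats: Dict[str, Dict[str, Dict[str, float]]] = field(default_factory=dict)
    skipped: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)
    results: Dict[str, List[EnrichmentResult]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "tf", "rank", "motif", "source_set", "err", "cutoff", "p",
            "matches_known", "known_match",
        ]
        return pd.DataFrame(
            [[getattr(r, c) for c in cols] for r in self.rows], columns=cols
        )

    def write(self, path: PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _tf_rng(seed: int, tf: str) -> np.random.Generator:
    """Per-TF substream so results do not depend on TF processing order."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(tf.encode())])
    )


def _conserve(
    seqs: MaskedSequenceSet,
    track_path: PathLike,
    ortholog_dir: PathLike,
    config: RunConfig,
) -> MaskedSequenceSet:
    """Combined-conservation masking of one promoter set."""
    seq_lengths = {e.name: len(e) for e in seqs}
    track = read_conservation_track(track_path, seq_lengths)
    align = alignment_conserved_mask(seqs, track, config.coverage_fraction)

    orthologs: Dict[str, MaskedSequenceSet] = {}
    for name in seqs.names:
        p = Path(ortholog_dir) / f"{name}.fa"
        if not p.exists():
            logger.info("gene %s: no ortholog file; excluded from patterns", name)
            continue
        oset = read_sequences(p)
        ref = next(iter(oset))
        if len(ref) == len(seqs[name]):
            ref.mask |= seqs[name].mask  # respect MCR masking of the reference
        orthologs[name] = oset
    patterns = find_sparse_patterns(orthologs, min_species=config.min_pattern_species)
    pattern = pattern_conserved_mask(seqs, patterns, config.coverage_fraction)
    return combine_conservation(align, pattern)


def _stage_stats(fg: MaskedSequenceSet, bg: MaskedSequenceSet) -> Dict[str, float]:
    return {
        "n_foreground": float(len(fg)),
        "n_background": float(len(bg)),
        "fg_unmasked_fraction": fg.unmasked_fraction(),
        "bg_unmasked_fraction": bg.unmasked_fraction(),
    }


def _known_match(pwm: Optional[PWM], library: List[PWM]) -> Tuple[bool, str]:
    if pwm is None or not library:
        return False, ""
    best = None
    for ref in library:
        if ref.id == pwm.id:
            return True, ref.id
        m = compare_motifs(pwm, ref)
        if best is None or m.divergence < best.divergence:
            best = m
    if best is not None and best.is_match:
        return True, best.reference
    return False, ""


def run_pipeline(
    config: RunConfig,
    inputs: PipelineInputs,
    run_denovo: bool = True,
    denovo_pvalues: bool = True,
) -> PipelineReport:
    """Run the full discovery workflow over all qualifying TFs.

    Deterministic given ``config.rng_seed``: network inference uses the
    global seed and every TF gets an order-independent substream.  TFs
    whose consensus target set is below ``config.min_targets`` are
    skipped with a logged reason, not an error.
    """
    report = PipelineReport(
        provenance={
            k: str(v)
            for k, v in vars(inputs).items()
            if v is not None
        }
    )
    expr = read_expression_matrix(inputs.expression)
    tfs = read_tf_list(inputs.tf_list)
    annotations = read_tss_table(inputs.annotations)
    genome = read_genome(inputs.genome)
    repeat_ivs = read_bed(inputs.repeat_masks) if inputs.repeat_masks else []
    library = (
        read_motif_library(inputs.motif_library) if inputs.motif_library else []
    )
    conserving = (
        inputs.conservation_track is not None and inputs.ortholog_dir is not None
    )

    edges = bootstrap_consensus(
        expr, tfs, config, rng=np.random.default_rng(config.rng_seed)
    )
    tsets = {t.tf: t for t in activated_targets(edges, expr, config.min_targets)}
    n_pos: Dict[str, int] = {}
    for e in edges:
        if e.sign == 1:
            n_pos[e.tf] = n_pos.get(e.tf, 0) + 1
    for tf in tfs:
        if tf not in tsets:
            report.skipped[tf] = (
                f"{n_pos.get(tf, 0)} activated consensus targets "
                f"(< min_targets={config.min_targets})"
            )
            logger.info("TF %s skipped: %s", tf, report.skipped[tf])

    for tf in sorted(tsets):
        targets = sorted(tsets[tf].targets)
        rng = _tf_rng(config.rng_seed, tf)
        fg_raw, fg_iv = extract_promoters(
            annotations, genome, targets, config.short_promoters
        )
        if len(fg_raw) < 5:
            report.skipped[tf] = (
                f"only {len(fg_raw)} target promoters extractable (< 5)"
            )
            logger.info("TF %s skipped: %s", tf, report.skipped[tf])
            continue
        bg_raw, bg_iv = build_background(
            annotations, genome, set(targets) | {tf}, config.n_background,
            rng, config.short_promoters,
        )
        fg = mask_regions(fg_raw, repeat_ivs, fg_iv, stage_label="conservation-free")
        bg = mask_regions(bg_raw, repeat_ivs, bg_iv, stage_label="background")

        stage_sets: Dict[str, Tuple[MaskedSequenceSet, MaskedSequenceSet]] = {
            "conservation-free": (fg, bg)
        }
        if conserving:
            # the background receives identical conservation processing
            comb_fg = _conserve(
                fg, inputs.conservation_track, inputs.ortholog_dir, config
            )
            comb_bg = _conserve(
                bg, inputs.conservation_track, inputs.ortholog_dir, config
            )
            comb_fg.stage_label = "combined-conservation"
            stage_sets["combined-conservation"] = (comb_fg, comb_bg)

        report.stage_stats[tf] = {
            stage: _stage_stats(f, b) for stage, (f, b) in stage_sets.items()
        }

        results_by_set: Dict[str, List[EnrichmentResult]] = {}
        for stage, (f, b) in stage_sets.items():
            stage_results: List[EnrichmentResult] = []
            if library:
                stage_results.extend(
                    library_significance(
                        library, f, b,
                        n_perm=config.library_permutations, rng=rng,
                    )
                )
            if run_denovo:
                f_labeled = f.copy(stage_label=stage)
                disc = discover(
                    f_labeled, b, config, rng=rng,
                    attach_significance=denovo_pvalues,
                )
                stage_results.extend(disc.motifs)
            results_by_set[stage] = stage_results

        merged = rerank_across_sets(results_by_set)
        report.results[tf] = merged
        lib_ids = {p.id for p in library}
        for r in merged:
            if r.motif in lib_ids:
                matched, known = True, r.motif
            else:
                matched, known = _known_match(r.pwm, library)
            report.rows.append(
                ReportRow(
                    tf=tf, rank=r.rank, motif=r.motif, source_set=r.source_set,
                    err=r.err, cutoff=r.cutoff, p=r.p,
                    matches_known=matched, known_match=known,
                )
            )
    return report
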