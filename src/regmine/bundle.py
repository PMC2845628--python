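"""Write a complete synthetic input bundle to disk.

The bundle contains every file :func:`~regmine.pipeline.run_pipeline`
consumes — expression matrix, TF list, TSS annotations, genome FASTA,
repeat masks, conservation bedGraph, per-gene ortholog FASTAs, and a
TRANSFAC motif library seeded with the planted PWM plus decoys — so
end-to-end runs exercise the real I/O paths.  Ground-truth sites and
edges are written alongside for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np

from .io import (
    write_conservation_track,
    write_motif_library,
    write_sequences,
)
from .pipeline import PipelineInputs
from .pwm import PWM
from .sequences import MaskedSequence, MaskedSequenceSet
from .synthetic import (
    MarkovSampler,
    SyntheticSpec,
    planted_network_spec,
    simulate_expression,
    simulate_orthologs,
    simulate_promoters,
)

__all__ = ["SyntheticBundle", "write_synthetic_bundle"]


@dataclass
class SyntheticBundle:
    """Paths plus the ground truth of a written synthetic dataset."""

    inputs: PipelineInputs
    truth_sites: Dict[str, List[Tuple[int, int]]]  # gene -> promoter-local sites
    direct_targets: List[str]
    mediators: List[str]
    distal_genes: List[str]
    planted_pwm: PWM
    tf: str


def _decoy_library(planted: PWM, n_decoys: int, rng: np.random.Generator) -> List[PWM]:
    lib = [PWM("planted", planted.matrix.copy())]
    for i in range(n_decoys):
        m = rng.dirichlet(np.full(4, 0.8), size=8)
        m = np.maximum(m, 1e-3)
        m /= m.sum(axis=1, keepdims=True)
        lib.append(PWM(f"decoy{i + 1}", m))
    return lib


def write_synthetic_bundle(
    outdir: Union[str, Path],
    n_direct: int = 15,
    n_cascades: int = 4,
    n_samples: int = 120,
    n_genes: int = 40,
    site_frequency: float = 0.9,
    turnover_rate: float = 0.0,
    repeat_prefix: int = 40,
    n_decoy_motifs: int = 4,
    seed: int = 0,
) -> SyntheticBundle:
    """Generate and write a synthetic dataset; returns paths and truth.

    Direct targets and cascade mediators carry planted PWM sites in
    their promoters (both are direct TF targets); cascade distal genes
    and filler genes do not.  Every gene gets its own contig (the
    promoter window exactly), a conservation track, and an ortholog
    FASTA, so background promoters receive the same conservation
    processing as the foreground.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "orthologs").mkdir(exist_ok=True)

    net_spec = planted_network_spec(
        n_direct=n_direct, n_cascades=n_cascades,
        n_samples=n_samples, n_genes=n_genes, seed=seed,
    )
    tf = net_spec.planted_edges[0][0]
    expr = simulate_expression(net_spec)
    expr.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")
    (outdir / "tfs.txt").write_text(tf + "\n")

    direct = sorted(t for _, t, _ in net_spec.planted_edges)
    mediators = sorted(m for _, m, _ in net_spec.cascade_chains)
    distal = sorted(d for _, _, d in net_spec.cascade_chains)
    sited_genes = sorted(set(direct) | set(mediators))
    other_genes = sorted(set(expr.index) - set(sited_genes))

    seq_spec = SyntheticSpec(
        promoter_length=1500,
        site_frequency=site_frequency,
        turnover_rate=turnover_rate,
        seed=seed,
    )
    rng = np.random.default_rng([seed, 1])
    markov = MarkovSampler(rng)
    fg, bg, raw_truth = simulate_promoters(
        seq_spec, len(sited_genes), len(other_genes), rng=rng, markov=markov
    )
    promoters: Dict[str, MaskedSequence] = {}
    truth: Dict[str, List[Tuple[int, int]]] = {}
    for gene, entry in zip(sited_genes, fg):
        promoters[gene] = MaskedSequence(gene, entry.codes, entry.mask)
        truth[gene] = raw_truth[entry.name]
    for gene, entry in zip(other_genes, bg):
        promoters[gene] = MaskedSequence(gene, entry.codes, entry.mask)

    # genome: one contig per gene, TSS at +1000 on the plus strand, so the
    # [-1000, +500) promoter window is exactly the contig
    genome = MaskedSequenceSet(
        [MaskedSequence(f"chr_{g}", promoters[g].codes, promoters[g].mask)
         for g in sorted(promoters)]
    )
    write_sequences(genome, outdir / "genome.fa")
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for g in sorted(promoters):
            fh.write(f"{g}\tchr_{g}\t1000\t+\n")

    with open(outdir / "masks.bed", "w") as fh:
        for g in sorted(promoters):
            fh.write(f"chr_{g}\t0\t{repeat_prefix}\trepeat\t0\t+\n")

    tracks: Dict[str, np.ndarray] = {}
    for g in sorted(promoters):
        oset, tr = simulate_orthologs(
            promoters[g], truth.get(g, []), seq_spec, rng=rng, markov=markov
        )
        write_sequences(oset, outdir / "orthologs" / f"{g}.fa")
        tracks[g] = tr
    write_conservation_track(tracks, outdir / "conservation.bedGraph")

    library = _decoy_library(
        seq_spec.planted_pwm, n_decoy_motifs, np.random.default_rng([seed, 2])
    )
    write_motif_library(library, outdir / "library.transfac")

    with open(outdir / "truth_sites.bed", "w") as fh:
        for g in sorted(truth):
            for s, e in truth[g]:
                fh.write(f"{g}\t{s}\t{e}\tplanted_site\t0\t+\n")
    with open(outdir / "truth_edges.tsv", "w") as fh:
        fh.write("tf\ttarget\tkind\n")
        for _, t, _ in net_spec.planted_edges:
            fh.write(f"{tf}\t{t}\tdirect\n")
        for _, m, d in net_spec.cascade_chains:
            fh.write(f"{tf}\t{m}\tmediator\n{tf}\t{d}\tdistal\n")

    inputs = PipelineInputs(
        expression=outdir / "expression.tsv",
        tf_list=outdir / "tfs.txt",
        annotations=outdir / "annotations.tsv",
        genome=outdir / "genome.fa",
        repeat_masks=outdir / "masks.bed",
        conservation_track=outdir / "conservation.bedGraph",
        ortholog_dir=outdir / "orthologs",
        motif_library=outdir / "library.transfac",
    )
    return SyntheticBundle(
        inputs=inputs,
        truth_sites=truth,
        direct_targets=direct,
        mediators=mediators,
        distal_genes=distal,
        planted_pwm=seq_spec.planted_pwm,
        tf=tf,
    )
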