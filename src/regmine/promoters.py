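"""Promoter extraction, repeat/coding-exon masking, and background sets.

Promoters are the window [-1000, +500) around each gene's transcription
start site, reverse-complemented for minus-strand genes so position 0
is always the -1000 point in transcription orientation.  Overlapping
promoters are resolved deterministically (the lexicographically
earlier gene id wins), and masking produces the MCR set (Masked
Coding-exons and Repeats) used by all conservation analysis.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .sequences import (
    GenomicInterval,
    MaskedSequence,
    MaskedSequenceSet,
    string_to_codes,
)

logger = logging.getLogger("regmine")

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500
PROMOTER_LENGTH = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def promoter_interval(tss: int, strand: str) -> Tuple[int, int]:
    """Genomic window covering 1000 bp upstream and 500 bp downstream."""
    if strand == "+":
        return tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    return tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM


def _select_tss(rows: pd.DataFrame) -> pd.Series:
    """For multi-isoform genes, take the 5'-most TSS in transcription orientation."""
    strand = rows.iloc[0]["strand"]
    idx = rows["tss"].idxmin() if strand == "+" else rows["tss"].idxmax()
    return rows.loc[idx]


def _eliminate_overlaps(
    chosen: Dict[str, GenomicInterval]
) -> Tuple[Dict[str, GenomicInterval], List[str]]:
    """Greedy, id-ordered elimination of intersecting promoter windows."""
    kept: Dict[str, GenomicInterval] = {}
    dropped: List[str] = []
    accepted: Dict[str, List[GenomicInterval]] = {}
    for gene in sorted(chosen):
        iv = chosen[gene]
        if any(iv.overlaps(o) for o in accepted.get(iv.chrom, [])):
            dropped.append(gene)
            continue
        kept[gene] = iv
        accepted.setdefault(iv.chrom, []).append(iv)
    return kept, dropped


def extract_promoters(
    annotations: pd.DataFrame,
    genome: Dict[str, str],
    genes: Sequence[str],
    short_promoters: str = "drop",
    stage_label: str = "conservation-free",
) -> Tuple[MaskedSequenceSet, Dict[str, GenomicInterval]]:
    """Extract 1500 bp promoters for the given genes.

    Returns the sequence set plus the genomic interval of each retained
    promoter (needed to map genomic masks into promoter-local
    coordinates).  Genes without an annotated TSS are skipped with a log
    entry; windows running off a contig end are dropped (default) or
    padded with masked N bases per ``short_promoters``.
    """
    if short_promoters not in ("drop", "pad"):
        raise ValueError("short_promoters must be 'drop' or 'pad'")
    wanted = set(genes)
    ann = annotations[annotations["gene"].isin(wanted)]
    chosen: Dict[str, GenomicInterval] = {}
    for gene, rows in ann.groupby("gene"):
        row = _select_tss(rows)
        start, end = promoter_interval(int(row["tss"]), row["strand"])
        if row["chrom"] not in genome:
            logger.info("gene %s: chromosome %s absent; skipped", gene, row["chrom"])
            continue
        clen = len(genome[row["chrom"]])
        if start < 0 or end > clen:
            if short_promoters == "drop":
                logger.info("gene %s: promoter window outside contig; dropped", gene)
                continue
        chosen[gene] = GenomicInterval(
            row["chrom"], max(0, start), min(end, clen), row["strand"]
        )
    missing = wanted - set(ann["gene"])
    for gene in sorted(missing):
        logger.info("gene %s: no annotated TSS; skipped", gene)

    kept, dropped = _eliminate_overlaps(chosen)
    for gene in dropped:
        logger.info("gene %s: promoter intersects another; eliminated", gene)

    out = MaskedSequenceSet(stage_label=stage_label)
    intervals: Dict[str, GenomicInterval] = {}
    for gene, iv in kept.items():
        seq = genome[iv.chrom][iv.start : iv.end]
        if len(seq) < PROMOTER_LENGTH:
            if short_promoters == "drop":
                logger.info("gene %s: truncated promoter; dropped", gene)
                continue
            # pad with masked Ns on the contig-edge side
            row = ann[ann["gene"] == gene].pipe(_select_tss)
            want_start, want_end = promoter_interval(int(row["tss"]), iv.strand)
            left = iv.start - want_start
            right = want_end - iv.end
            seq = "N" * max(0, left) + seq + "N" * max(0, right)
        if iv.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        out.add(MaskedSequence.from_string(gene, seq))
        intervals[gene] = iv
    return out, intervals


def genomic_to_local(
    mask: GenomicInterval, promoter: GenomicInterval
) -> Optional[Tuple[int, int]]:
    """Map a genomic mask interval into promoter-local coordinates.

    Accounts for reverse-complementation of minus-strand promoters.
    Returns None when there is no overlap; clips to promoter bounds.
    """
    if mask.chrom != promoter.chrom:
        return None
    s = max(mask.start, promoter.start)
    e = min(mask.end, promoter.end)
    if s >= e:
        return None
    if promoter.strand == "+":
        return s - promoter.start, e - promoter.start
    return promoter.end - e, promoter.end - s


def mask_regions(
    seqs: MaskedSequenceSet,
    masks: Sequence[GenomicInterval],
    promoter_intervals: Optional[Dict[str, GenomicInterval]] = None,
    local_masks: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    stage_label: str = "MCR",
) -> MaskedSequenceSet:
    """Mask repeats/coding exons; masks union with any existing mask.

    Masks may be genomic intervals (with ``promoter_intervals`` giving
    each promoter's genomic placement) or already promoter-local via
    ``local_masks`` (name -> list of (start, end)).  Intervals beyond
    sequence bounds are clipped with a warning.
    """
    out = seqs.copy(stage_label=stage_label)
    per_seq: Dict[str, List[Tuple[int, int]]] = {n: [] for n in out.names}
    if local_masks:
        for name, ivs in local_masks.items():
            if name in per_seq:
                per_seq[name].extend(ivs)
    if masks:
        if promoter_intervals is None:
            raise ValueError("genomic masks require promoter_intervals")
        for m in masks:
            for name, piv in promoter_intervals.items():
                if name not in per_seq:
                    continue
                loc = genomic_to_local(m, piv)
                if loc is not None:
                    per_seq[name].append(loc)
    for name, ivs in per_seq.items():
        entry = out[name]
        n = len(entry)
        for s, e in ivs:
            if s < 0 or e > n:
                warnings.warn(f"mask [{s},{e}) clipped to sequence {name!r} bounds")
            s, e = max(0, s), min(n, e)
            if s < e:
                entry.mask[s:e] = True
    return out


def build_background(
    annotations: pd.DataFrame,
    genome: Dict[str, str],
    excluded: Set[str],
    k: int,
    rng: np.random.Generator,
    short_promoters: str = "drop",
) -> Tuple[MaskedSequenceSet, Dict[str, GenomicInterval]]:
    """k non-overlapping promoters of random genes outside ``excluded``.

    The background is processed downstream exactly like the foreground
    (MCR masking, conservation) so classification statistics compare
    like with like.
    """
    eligible = sorted(set(annotations["gene"]) - set(excluded))
    if not eligible:
        warnings.warn("no eligible background genes")
        return MaskedSequenceSet(stage_label="background"), {}
    order = list(rng.permutation(len(eligible)))
    accepted: List[str] = []
    accepted_ivs: Dict[str, List[GenomicInterval]] = {}
    for j in order:
        gene = eligible[j]
        rows = annotations[annotations["gene"] == gene]
        row = _select_tss(rows)
        start, end = promoter_interval(int(row["tss"]), row["strand"])
        if row["chrom"] not in genome:
            continue
        clen = len(genome[row["chrom"]])
        if (start < 0 or end > clen) and short_promoters == "drop":
            continue
        iv = GenomicInterval(row["chrom"], max(0, start), min(end, clen), row["strand"])
        if any(iv.overlaps(o) for o in accepted_ivs.get(iv.chrom, [])):
            continue
        accepted.append(gene)
        accepted_ivs.setdefault(iv.chrom, []).append(iv)
        if len(accepted) == k:
            break
    if len(accepted) < k:
        warnings.warn(f"only {len(accepted)} background promoters available (wanted {k})")
    seqs, intervals = extract_promoters(
        annotations, genome, accepted, short_promoters=short_promoters,
        stage_label="background",
    )
    return seqs, intervals
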