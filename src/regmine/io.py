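"""Readers and writers for the external formats the pipeline consumes.

FASTA goes through Biopython; tabular data through pandas.  TRANSFAC
matrix flat files, MEME minimal format, BED and bedGraph/wiggle are
parsed here directly because the contracts (soft-mask semantics, score
range checks, count-to-probability smoothing) are specific to this
pipeline.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm import DEFAULT_PSEUDOCOUNT, PWM
from .sequences import GenomicInterval, MaskedSequence, MaskedSequenceSet

logger = logging.getLogger("regmine")

PathLike = Union[str, Path]


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_sequences(path: PathLike, stage_label: str = "conservation-free") -> MaskedSequenceSet:
    """Read a soft-masked FASTA file.

    Lowercase bases and ``N`` are treated as masked positions.  Duplicate
    record names and non-nucleotide symbols are rejected.
    """
    out = MaskedSequenceSet(stage_label=stage_label)
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        out.add(MaskedSequence.from_string(rec.id, str(rec.seq)))
    return out


def write_sequences(seqs: MaskedSequenceSet, path: PathLike) -> None:
    """Write as soft-masked FASTA (masked bases lowercase)."""
    records = [
        SeqRecord(Seq(entry.to_string()), id=entry.name, description="")
        for entry in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome(path: PathLike) -> Dict[str, str]:
    """Load a (small) genome FASTA into memory as name -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------------------------
# TRANSFAC matrix flat file
# --------------------------------------------------------------------------

def read_motif_library(
    path: PathLike, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> List[PWM]:
    """Parse a TRANSFAC-format matrix library into smoothed PWMs.

    Records are delimited by ``AC``/``ID`` ... ``//`` blocks with
    per-position A,C,G,T counts.  Counts are converted to probabilities
    with a pseudocount of ``pseudocount`` per base per column.
    """
    pwms: List[PWM] = []
    acc: Optional[str] = None
    rows: List[List[float]] = []
    in_record = False
    terminated = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tag = line[:2]
            if tag == "AC":
                acc = line[2:].strip()
                in_record = True
                terminated = False
            elif tag == "ID" and acc is None:
                acc = line[2:].strip()
                in_record = True
                terminated = False
            elif tag in ("P0", "PO"):
                continue
            elif tag == "//":
                if acc is None and not rows:
                    continue
                if not rows:
                    raise ValueError(f"{path}:{lineno}: record {acc!r} has no counts")
                counts = np.array(rows, dtype=float)
                if (counts < 0).any():
                    raise ValueError(f"{path}: record {acc!r} has a negative count")
                pwms.append(PWM.from_counts(acc or f"motif_{len(pwms)+1}", counts, pseudocount))
                acc, rows = None, []
                in_record, terminated = False, True
            elif in_record and line[:2].strip().isdigit():
                fields = line.split()
                vals = [float(v) for v in fields[1:5]]
                if any(v < 0 for v in vals):
                    raise ValueError(f"{path}:{lineno}: negative count in record {acc!r}")
                rows.append(vals)
            # other TRANSFAC tags (NA, DE, BF, XX, CC ...) are ignored
    if not terminated or rows:
        raise ValueError(f"{path}: missing '//' terminator for record {acc!r}")
    if not pwms:
        warnings.warn(f"{path}: empty motif library")
    return pwms


def write_motif_library(
    pwms: Sequence[PWM],
    path: PathLike,
    counts_scale: int = 100,
    comments: Optional[Dict[str, str]] = None,
) -> None:
    """Write PWMs as a TRANSFAC matrix flat file (probabilities × scale)."""
    comments = comments or {}
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"AC  {pwm.id}\nXX\nID  {pwm.id}\nXX\n")
            if pwm.id in comments:
                fh.write(f"CC  {comments[pwm.id]}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            cons = pwm.consensus()
            for i, col in enumerate(pwm.matrix, start=1):
                vals = "  ".join(f"{v * counts_scale:6.2f}" for v in col)
                fh.write(f"{i:02d}  {vals}  {cons[i - 1]}\n")
            fh.write("XX\n//\n")


# --------------------------------------------------------------------------
# MEME minimal format
# --------------------------------------------------------------------------

def write_meme(
    pwms: Sequence[PWM],
    path: PathLike,
    background: Optional[np.ndarray] = None,
    comments: Optional[Dict[str, str]] = None,
) -> None:
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    comments = comments or {}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.id}\n")
            if pwm.id in comments:
                fh.write(f"# {comments[pwm.id]}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 20 E= 0\n"
            )
            for col in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path: PathLike) -> List[PWM]:
    pwms: List[PWM] = []
    name = None
    rows: List[List[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("MOTIF"):
                name = s.split()[1]
            elif s.startswith("letter-probability matrix"):
                toks = s.split()
                parts = dict(zip(toks[2::2], toks[3::2]))  # 'alength=': '4', 'w=': ...
                expect = int(parts["w="])
                rows = []
            elif name is not None and s and s[0] in "0123456789.":
                rows.append([float(v) for v in s.split()])
                if len(rows) == expect:
                    m = np.array(rows)
                    m = m / m.sum(axis=1, keepdims=True)
                    m = np.clip(m, 1e-6, None)
                    m = m / m.sum(axis=1, keepdims=True)
                    pwms.append(PWM(name, m))
                    name, rows = None, []
    return pwms


# --------------------------------------------------------------------------
# BED
# --------------------------------------------------------------------------

def read_bed(path: PathLike) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "+"
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: PathLike,
    names: Optional[Sequence[str]] = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# --------------------------------------------------------------------------
# Conservation tracks (bedGraph / fixedStep wiggle)
# --------------------------------------------------------------------------

def read_conservation_track(
    path: PathLike, seq_lengths: Dict[str, int]
) -> Dict[str, np.ndarray]:
    """Read per-base conservation scores in [0, 1].

    Positions without a record get score 0.  Overlapping records follow
    last-writer-wins semantics (with a warning).  Scores outside [0, 1]
    are rejected with the offending line number.
    """
    tracks = {name: np.zeros(n) for name, n in seq_lengths.items()}
    written = {name: np.zeros(n, dtype=bool) for name, n in seq_lengths.items()}
    overlap_warned = False
    mode: Optional[Tuple[str, int, int]] = None  # fixedStep state
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            if s.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in s.split()[1:])
                mode = (kv["chrom"], int(kv["start"]) - 1, int(kv.get("step", 1)))
                continue
            if s.startswith("variableStep"):
                raise ValueError(f"{path}:{lineno}: variableStep wiggle not supported")
            fields = s.split()
            if mode is not None and len(fields) == 1:
                chrom, pos, step = mode
                score = float(fields[0])
                _check_score(score, path, lineno)
                if chrom in tracks and pos < len(tracks[chrom]):
                    if written[chrom][pos] and not overlap_warned:
                        warnings.warn(f"{path}: overlapping records; last writer wins")
                        overlap_warned = True
                    tracks[chrom][pos] = score
                    written[chrom][pos] = True
                mode = (chrom, pos + step, step)
                continue
            chrom, start, end, score = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            _check_score(score, path, lineno)
            if chrom not in tracks:
                continue
            end = min(end, len(tracks[chrom]))
            if start >= end:
                continue
            if written[chrom][start:end].any() and not overlap_warned:
                warnings.warn(f"{path}: overlapping records; last writer wins")
                overlap_warned = True
            tracks[chrom][start:end] = score
            written[chrom][start:end] = True
    return tracks


def _check_score(score: float, path, lineno: int) -> None:
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"{path}:{lineno}: conservation score {score} outside [0, 1]")


def write_conservation_track(tracks: Dict[str, np.ndarray], path: PathLike) -> None:
    """Write per-base scores as bedGraph, merging equal-score runs."""
    with open(path, "w") as fh:
        for name, arr in tracks.items():
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s] != 0.0:
                    fh.write(f"{name}\t{s}\t{e}\t{arr[s]:.6g}\n")


# --------------------------------------------------------------------------
# Tabular inputs
# --------------------------------------------------------------------------

def read_expression_matrix(path: PathLike) -> pd.DataFrame:
    """Genes × samples TSV with a header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    return df.astype(float)


def read_tf_list(path: PathLike) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_tss_table(path: PathLike) -> pd.DataFrame:
    """TSS table TSV with columns gene, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
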