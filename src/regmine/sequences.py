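"""Masked promoter sequence sets and genomic intervals.

Sequences carry an explicit per-base mask bitmap.  Masked bases (repeats,
coding exons, non-conserved regions, ambiguous ``N`` calls) are excluded
from every downstream scanning and discovery step; a motif window that
overlaps even one masked base is never scored, which prevents chimeric
sites from being assembled across mask boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = np.array(list("ACGT"))

#: stage labels in pipeline order
STAGES = (
    "conservation-free",
    "MCR",
    "alignment-conserved",
    "pattern-conserved",
    "combined-conservation",
    "background",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class MaskedSequence:
    """One nucleotide sequence plus a boolean mask (True = masked)."""

    __slots__ = ("name", "codes", "mask")

    def __init__(self, name: str, codes: np.ndarray, mask: np.ndarray):
        if codes.shape != mask.shape:
            raise ValueError("mask bitmap length must equal sequence length")
        self.name = name
        self.codes = codes  # int8 in {0..3}; masked positions may be any code
        self.mask = mask  # bool

    @classmethod
    def from_string(cls, name: str, seq: str) -> "MaskedSequence":
        """Build from a soft-masked string (lowercase / N = masked)."""
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        upper = np.char.upper(np.array(seq, dtype=str)).item()
        codes = np.empty(len(seq), dtype=np.int8)
        mask = np.zeros(len(seq), dtype=bool)
        lut = np.full(256, -1, dtype=np.int8)
        for b, c in _BASE_TO_CODE.items():
            lut[ord(b)] = c
        up = np.frombuffer(upper.encode("ascii"), dtype=np.uint8)
        codes[:] = lut[up]
        # lowercase letters in the original are soft-masked
        mask |= (arr >= ord("a")) & (arr <= ord("z"))
        is_n = up == ord("N")
        mask |= is_n
        codes[is_n] = 0  # placeholder; never scored because masked
        bad = np.nonzero(codes < 0)[0]
        if bad.size:
            raise ValueError(
                f"non-nucleotide symbol {chr(arr[bad[0]])!r} in sequence "
                f"{name!r} at position {int(bad[0])}"
            )
        return cls(name, codes, mask)

    def __len__(self) -> int:
        return len(self.codes)

    def to_string(self) -> str:
        """Soft-masked string: masked bases lowercase."""
        chars = _CODE_TO_BASE[self.codes].copy()
        if self.mask.any():
            low = np.char.lower(chars[self.mask])
            chars[self.mask] = low
        return "".join(chars)

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean()) if len(self.mask) else 0.0

    def copy(self) -> "MaskedSequence":
        return MaskedSequence(self.name, self.codes.copy(), self.mask.copy())


class MaskedSequenceSet:
    """An ordered, name-unique collection of masked sequences.

    ``stage_label`` records the masking provenance (one of :data:`STAGES`).
    """

    def __init__(
        self,
        entries: Optional[List[MaskedSequence]] = None,
        stage_label: str = "conservation-free",
    ):
        self._entries: Dict[str, MaskedSequence] = {}
        self.stage_label = stage_label
        for e in entries or []:
            self.add(e)
        self._window_cache: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def add(self, entry: MaskedSequence) -> None:
        if entry.name in self._entries:
            raise ValueError(f"duplicate sequence name {entry.name!r}")
        self._entries[entry.name] = entry
        self.__dict__.setdefault("_window_cache", {}).clear()

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[MaskedSequence]:
        return iter(self._entries.values())

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> MaskedSequence:
        return self._entries[name]

    @property
    def names(self) -> List[str]:
        return list(self._entries)

    def copy(self, stage_label: Optional[str] = None) -> "MaskedSequenceSet":
        return MaskedSequenceSet(
            [e.copy() for e in self],
            stage_label=stage_label or self.stage_label,
        )

    def subset(self, names, stage_label: Optional[str] = None) -> "MaskedSequenceSet":
        return MaskedSequenceSet(
            [self._entries[n].copy() for n in names],
            stage_label=stage_label or self.stage_label,
        )

    # ---- scanning support -------------------------------------------------

    def windows(self, length: int):
        """All fully-unmasked windows of ``length``, pooled over sequences.

        Returns ``(W, seq_idx, starts)`` where ``W`` is an
        ``(n_windows, length)`` int8 matrix of base codes, ``seq_idx`` maps
        each window to the index of its sequence in iteration order, and
        ``starts`` gives window start offsets.  Cached per length.
        """
        cached = self._window_cache.get(length)
        if cached is not None:
            return cached
        mats, idxs, starts = [], [], []
        for i, entry in enumerate(self):
            n = len(entry)
            if n < length:
                continue
            ok = ~entry.mask
            # window valid iff all `length` bases unmasked
            valid = (
                np.convolve(ok.astype(np.int32), np.ones(length, dtype=np.int32), "valid")
                == length
            )
            pos = np.nonzero(valid)[0]
            if pos.size == 0:
                continue
            win = np.lib.stride_tricks.sliding_window_view(entry.codes, length)
            mats.append(win[pos])
            idxs.append(np.full(pos.size, i, dtype=np.int32))
            starts.append(pos.astype(np.int32))
        if mats:
            out = (
                np.ascontiguousarray(np.concatenate(mats)),
                np.concatenate(idxs),
                np.concatenate(starts),
            )
        else:
            out = (
                np.empty((0, length), dtype=np.int8),
                np.empty(0, dtype=np.int32),
                np.empty(0, dtype=np.int32),
            )
        self._window_cache[length] = out
        return out

    def base_composition(self) -> np.ndarray:
        """Frequencies of A,C,G,T over unmasked bases (uniform if empty)."""
        counts = np.zeros(4, dtype=np.int64)
        for entry in self:
            vals = entry.codes[~entry.mask]
            if vals.size:
                counts += np.bincount(vals, minlength=4)
        total = counts.sum()
        if total == 0:
            warnings.warn("no unmasked bases; falling back to uniform composition")
            return np.full(4, 0.25)
        return counts / total

    def unmasked_fraction(self) -> float:
        total = sum(len(e) for e in self)
        if total == 0:
            return 0.0
        kept = sum(int((~e.mask).sum()) for e in self)
        return kept / total


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.int8)


def codes_to_string(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[codes])


def string_to_codes(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _BASE_TO_CODE[ch]
    return out
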