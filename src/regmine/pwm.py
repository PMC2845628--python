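"""Position-weight matrices.

A PWM models a transcription-factor binding site as an independent
per-position distribution over {A, C, G, T}.  Columns are stored
row-major as an ``(L, 4)`` matrix of probabilities; every column sums to
one and, after smoothing, every entry is strictly positive so log-odds
scores are finite.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .sequences import codes_to_string

DEFAULT_PSEUDOCOUNT = 0.5  # Laplace-style smoothing per base per column


class PWM:
    __slots__ = ("id", "matrix")

    def __init__(self, id: str, matrix: np.ndarray, *, validate: bool = True):
        matrix = np.asarray(matrix, dtype=float)
        if validate:
            if matrix.ndim != 2 or matrix.shape[1] != 4:
                raise ValueError("PWM matrix must be (length, 4)")
            if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"PWM {id!r}: columns must sum to 1")
            if (matrix <= 0).any():
                raise ValueError(f"PWM {id!r}: entries must be positive (smooth first)")
        self.id = id
        self.matrix = matrix

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __repr__(self) -> str:
        return f"PWM({self.id!r}, length={len(self)})"

    @classmethod
    def from_counts(
        cls,
        id: str,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError(f"PWM {id!r}: negative count")
        smoothed = counts + pseudocount
        return cls(id, smoothed / smoothed.sum(axis=1, keepdims=True))

    @classmethod
    def from_consensus(
        cls, id: str, word_codes: np.ndarray, dominant: float = 0.94
    ) -> "PWM":
        """Point-mass-like PWM from a word of base codes."""
        rest = (1.0 - dominant) / 3.0
        m = np.full((len(word_codes), 4), rest)
        m[np.arange(len(word_codes)), word_codes] = dominant
        return cls(id, m)

    def log_odds(self, background: Optional[np.ndarray] = None) -> np.ndarray:
        """(L, 4) matrix of log2(p / bg) scores."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return np.log2(self.matrix / bg)

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.matrix[::-1, ::-1].copy(), validate=False)

    def consensus(self) -> str:
        return codes_to_string(self.matrix.argmax(axis=1).astype(np.int8))

    def information_content(self, background: Optional[np.ndarray] = None) -> float:
        """Total relative entropy versus background, in bits."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return float((self.matrix * np.log2(self.matrix / bg)).sum())

    def max_score(self, background: Optional[np.ndarray] = None) -> float:
        return float(self.log_odds(background).max(axis=1).sum())

    def sample_site(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one site (base-code array) from the column distributions."""
        u = rng.random(len(self))
        cdf = self.matrix.cumsum(axis=1)
        return (u[:, None] > cdf).sum(axis=1).astype(np.int8)


def smooth(matrix: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Mix a column-stochastic matrix with the uniform column."""
    m = (1.0 - eps) * np.asarray(matrix, float) + eps / 4.0
    return m / m.sum(axis=1, keepdims=True)
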