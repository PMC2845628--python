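"""Shared test helpers."""

from typing import Dict, List, Optional, Sequence

import numpy as np
import pytest

from regmine.sequences import MaskedSequence, MaskedSequenceSet


def make_set(
    strings: Sequence[str],
    names: Optional[Sequence[str]] = None,
    stage_label: str = "conservation-free",
) -> MaskedSequenceSet:
    """Build a sequence set from soft-masked strings."""
    names = names or [f"s{i + 1}" for i in range(len(strings))]
    return MaskedSequenceSet(
        [MaskedSequence.from_string(n, s) for n, s in zip(names, strings)],
        stage_label=stage_label,
    )


def random_set(
    rng: np.random.Generator,
    n_seqs: int,
    length: int,
    stage_label: str = "conservation-free",
    mask_prob: float = 0.0,
    prefix: str = "s",
) -> MaskedSequenceSet:
    """Random base-code sequences with optional random masking."""
    entries = []
    for i in range(n_seqs):
        codes = rng.integers(0, 4, size=length).astype(np.int8)
        mask = rng.random(length) < mask_prob
        entries.append(MaskedSequence(f"{prefix}{i + 1}", codes, mask))
    return MaskedSequenceSet(entries, stage_label=stage_label)


def random_pwm(rng: np.random.Generator, length: int, name: str = "m") -> "PWM":
    from regmine.pwm import PWM

    m = rng.dirichlet(np.full(4, 0.8), size=length)
    m = np.maximum(m, 1e-3)
    m /= m.sum(axis=1, keepdims=True)
    return PWM(name, m)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
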