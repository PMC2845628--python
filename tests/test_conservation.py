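"""Conservation masking: coverage calibration, alignment and pattern masks."""

import numpy as np
import pytest

from regmine.conservation import (
    SEED_LENGTH,
    alignment_conserved_mask,
    combine_conservation,
    find_sparse_patterns,
    pattern_conserved_mask,
    threshold_for_coverage,
)
from regmine.sequences import (
    MaskedSequence,
    MaskedSequenceSet,
    reverse_complement_codes,
    string_to_codes,
)

from conftest import make_set, random_set


# ------------------------------------------------- coverage calibration

def test_threshold_closest_from_below():
    track = {"g": np.arange(0.1, 1.05, 0.1)}  # 0.1 .. 1.0
    cal = threshold_for_coverage(track, 0.25)
    assert cal.threshold == pytest.approx(0.9)
    assert cal.achieved_fraction == pytest.approx(0.2)


def test_threshold_high_fraction():
    track = {"g": np.arange(0.1, 1.05, 0.1)}
    cal = threshold_for_coverage(track, 0.95)
    assert cal.threshold == pytest.approx(0.2)
    assert cal.achieved_fraction == pytest.approx(0.9)


def test_threshold_never_exceeds_request(rng):
    for _ in range(20):
        track = {"g": rng.random(rng.integers(50, 500))}
        cal = threshold_for_coverage(track, 0.10)
        assert cal.achieved_fraction <= 0.10 + 1e-12


def test_threshold_rejects_bad_fraction():
    with pytest.raises(ValueError):
        threshold_for_coverage({"g": np.ones(5)}, 1.5)


def test_alignment_mask_respects_threshold():
    seqs = make_set(["ACGTACGTAC"])
    track = {"s1": np.array([0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])}
    out = alignment_conserved_mask(seqs, track, 0.3)
    assert list(~out["s1"].mask) == [True, True] + [False] * 8
    assert out.stage_label == "alignment-conserved"


# --------------------------------------------------- pattern discovery

SEED = "AAACCCGG"  # non-palindromic 8-mer


def _ortho_set(rng, planted_in, length=60, pos=10, mutate_in=(), rc_in=()):
    """Reference + 5 species; the seed is planted exactly in ``planted_in``."""
    names = ["ref", "sp1", "sp2", "sp3", "sp4", "sp5"]
    seed = string_to_codes(SEED)
    entries = []
    for name in names:
        codes = rng.integers(0, 4, size=length).astype(np.int8)
        if name in planted_in:
            codes[pos : pos + SEED_LENGTH] = seed
        if name in rc_in:
            codes[pos : pos + SEED_LENGTH] = reverse_complement_codes(seed)
        if name in mutate_in:
            mut = seed.copy()
            mut[0] = (mut[0] + 1) % 4
            mut[4] = (mut[4] + 1) % 4  # 2 mismatches
            codes[pos : pos + SEED_LENGTH] = mut
        entries.append(MaskedSequence(name, codes, np.zeros(length, dtype=bool)))
    return MaskedSequenceSet(entries)


def test_pattern_supported_by_exact_occurrences(rng):
    oset = _ortho_set(rng, planted_in=("ref", "sp1", "sp2", "sp3"))
    pats = find_sparse_patterns({"gene1": oset}, min_species=4)
    hit = [p for p in pats if p.seed == SEED]
    assert hit and hit[0].support >= 4
    assert hit[0].z > 0
    assert ("ref", 10, 18) in hit[0].covered


def test_mismatched_occurrences_do_not_support(rng):
    # exact in reference + 2 species, 2-mismatch copy in two more: support 3
    oset = _ortho_set(
        rng, planted_in=("ref", "sp1", "sp2"), mutate_in=("sp3", "sp4")
    )
    pats = find_sparse_patterns({"gene1": oset}, min_species=4)
    assert not [p for p in pats if p.seed == SEED]


def test_reverse_complement_occurrences_support(rng):
    oset = _ortho_set(rng, planted_in=("ref", "sp1"), rc_in=("sp2", "sp3"))
    pats = find_sparse_patterns({"gene1": oset}, min_species=4)
    hit = [p for p in pats if p.seed == SEED]
    assert hit and hit[0].support >= 4
    strands = {o.strand for o in hit[0].occurrences}
    assert "-" in strands


def test_pattern_mask_unmasks_covered_bases_only(rng):
    oset = _ortho_set(rng, planted_in=("ref", "sp1", "sp2", "sp3"))
    pats = find_sparse_patterns({"gene1": oset}, min_species=4)
    seqs = MaskedSequenceSet([oset["ref"].copy()])
    out = pattern_conserved_mask(seqs, pats, fraction=0.2)
    kept = ~out["ref"].mask
    assert kept[10:18].all()
    assert kept.mean() <= 0.2 + 0.01 + 1e-9


def test_pattern_mask_empty_patterns_warns(rng):
    seqs = random_set(rng, 2, 30)
    with pytest.warns(UserWarning, match="fully masked"):
        out = pattern_conserved_mask(seqs, [], fraction=0.1)
    assert all(e.mask.all() for e in out)


# -------------------------------------------------------------- combine

def test_combine_is_union_of_conserved():
    a = make_set(["ACGTACGT"])
    b = make_set(["ACGTACGT"])
    a["s1"].mask[:] = [True, True, False, False, True, True, False, False]
    b["s1"].mask[:] = [True, False, True, False, True, False, True, False]
    out = combine_conservation(a, b)
    # unmasked = unmasked in either input
    assert list(out["s1"].mask) == [True, False, False, False, True, False, False, False]
    assert out.stage_label == "combined-conservation"


def test_combine_rejects_mismatched_sets():
    a = make_set(["ACGT"], names=["x"])
    b = make_set(["ACGT"], names=["y"])
    with pytest.raises(ValueError, match="name mismatch"):
        combine_conservation(a, b)
    c = make_set(["TTTT"], names=["x"])
    with pytest.raises(ValueError, match="sequence mismatch"):
        combine_conservation(a, c)
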