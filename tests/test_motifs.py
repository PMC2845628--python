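"""Motif engine: scanning, err minimization, permutation tests, comparison."""

import numpy as np
import pytest

from regmine.motifs import (
    best_site_scores,
    classify_set,
    compare_motifs,
    denovo_significance,
    library_significance,
    merge_similar,
    min_err_cutoff,
    permutation_p,
    region_enrichment_fet,
    rerank_across_sets,
    scan_best_site,
    EnrichmentResult,
)
from regmine.pwm import PWM
from regmine.sequences import MaskedSequence, MaskedSequenceSet, string_to_codes

from conftest import make_set, random_pwm, random_set


def _consensus_pwm(word: str, dominant: float = 0.94) -> PWM:
    return PWM.from_consensus(word, string_to_codes(word), dominant)


# ------------------------------------------------------------- scanning

def test_scan_best_site_finds_planted_consensus(rng):
    pwm = _consensus_pwm("ACGTTGCA")
    seq = random_set(rng, 1, 100)["s1"]
    seq.codes[40:48] = string_to_codes("ACGTTGCA")
    score = scan_best_site(seq, pwm)
    assert score == pytest.approx(pwm.max_score(), abs=1e-9)


def test_scan_is_strand_symmetric(rng):
    pwm = random_pwm(rng, 6)
    seq = random_set(rng, 1, 50)["s1"]
    rc = MaskedSequence("rc", (3 - seq.codes[::-1]).astype(np.int8),
                        seq.mask[::-1].copy())
    assert scan_best_site(seq, pwm) == pytest.approx(scan_best_site(rc, pwm))


def test_masked_windows_never_scored(rng):
    pwm = _consensus_pwm("AAAAAA")
    seq = MaskedSequence(
        "s", string_to_codes("AAAAAACGCGCG"), np.zeros(12, dtype=bool)
    )
    unmasked = scan_best_site(seq, pwm)
    seq.mask[2] = True  # breaks every window containing the A-run
    assert scan_best_site(seq, pwm) < unmasked


def test_scan_no_valid_window_is_neg_inf():
    seq = MaskedSequence("s", string_to_codes("ACGT"), np.ones(4, dtype=bool))
    assert scan_best_site(seq, _consensus_pwm("ACGT")) == -np.inf


# ------------------------------------------------------------------ err

def test_min_err_cutoff_perfect_separation():
    err, cutoff = min_err_cutoff(np.array([5.0, 6.0]), np.array([1.0, 2.0]))
    assert err == 0.0 and cutoff == 5.0


def test_min_err_cutoff_worst_case_is_half():
    err, cutoff = min_err_cutoff(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    assert err == 0.5 and cutoff == np.inf


def test_min_err_cutoff_tie_breaks_to_largest_cutoff():
    # cutoffs 3 and 4 both attain err 0.25; the larger must win
    err, cutoff = min_err_cutoff(np.array([3.0, 4.0]), np.array([2.0, 3.5]))
    fg, bg = np.array([3.0, 4.0]), np.array([2.0, 3.5])
    e3 = ((bg >= 3.0).mean() + (fg < 3.0).mean()) / 2
    e4 = ((bg >= 4.0).mean() + (fg < 4.0).mean()) / 2
    assert e3 == e4 == err
    assert cutoff == 4.0


def test_classify_set_separates_planted(rng):
    pwm = _consensus_pwm("TGACGTCA")
    fg = random_set(rng, 10, 200, prefix="f")
    for e in fg:
        e.codes[20:28] = string_to_codes("TGACGTCA")
    bg = random_set(rng, 10, 200, stage_label="background", prefix="b")
    res = classify_set(fg, bg, pwm)
    assert res.err <= 0.1
    assert res.source_set == "conservation-free"


# ------------------------------------------------------- permutations

def test_permutation_p_add_one():
    assert permutation_p(0.1, np.array([0.05, 0.2, 0.3])) == pytest.approx(2 / 4)
    assert permutation_p(0.0, np.array([0.2, 0.3])) == pytest.approx(1 / 3)


def test_library_significance_enriched_vs_null(rng):
    pwm = _consensus_pwm("TGACGTCA")
    decoy = random_pwm(rng, 8, "decoy")
    fg = random_set(rng, 12, 150, prefix="f")
    for e in fg:
        e.codes[30:38] = string_to_codes("TGACGTCA")
    bg = random_set(rng, 18, 150, stage_label="background", prefix="b")
    res = library_significance([pwm, decoy], fg, bg, n_perm=199,
                               rng=np.random.default_rng(0))
    assert res[0].motif == "TGACGTCA"
    assert res[0].p <= 0.05 < res[1].p
    assert [r.rank for r in res] == [1, 2]


def test_library_significance_errs_independent_of_rng(rng):
    lib = [random_pwm(rng, 6, f"m{i}") for i in range(3)]
    fg = random_set(rng, 8, 80, prefix="f")
    bg = random_set(rng, 8, 80, prefix="b", stage_label="background")
    r1 = library_significance(lib, fg, bg, n_perm=100, rng=np.random.default_rng(1))
    r2 = library_significance(lib, fg, bg, n_perm=100, rng=np.random.default_rng(2))
    assert [(r.motif, r.err, r.cutoff) for r in r1] == \
           [(r.motif, r.err, r.cutoff) for r in r2]


def test_library_significance_enforces_min_permutations(rng):
    fg = random_set(rng, 5, 30)
    bg = random_set(rng, 5, 30)
    with pytest.raises(ValueError, match="n_perm"):
        library_significance([random_pwm(rng, 6)], fg, bg, n_perm=50)


def test_denovo_significance_threshold_semantics(rng):
    fg = random_set(rng, 6, 40, prefix="f")
    bg = random_set(rng, 10, 40, prefix="b", stage_label="background")
    calls = []

    def fake_discoverer(f, b):
        calls.append(1)
        e = 0.1 + 0.4 * len(calls) / 40
        return [EnrichmentResult(motif="x", err=min(e, 0.5), cutoff=0.0)]

    threshold, null = denovo_significance(fg, bg, fake_discoverer, n_perm=39,
                                          rng=np.random.default_rng(0))
    assert len(null) == 39
    # errs strictly below the threshold are significant; the next larger
    # attained null value would not be
    assert permutation_p(threshold - 1e-9, null) <= 0.05
    above = null[null > threshold].min()
    assert permutation_p(above, null) > 0.05


# ------------------------------------------------------------ compare

def test_compare_identical_motifs_zero_divergence(rng):
    a = random_pwm(rng, 8, "a")
    m = compare_motifs(a, PWM("b", a.matrix.copy()))
    assert m.divergence == pytest.approx(0.0, abs=1e-12)
    assert m.is_match and m.offset == 0 and m.orientation == "forward"


def test_compare_detects_reverse_complement(rng):
    a = random_pwm(rng, 8, "a")
    m = compare_motifs(a, a.reverse_complement())
    assert m.divergence == pytest.approx(0.0, abs=1e-12)
    assert m.orientation == "reverse-complement"


def test_compare_finds_shift_offset(rng):
    a = random_pwm(rng, 10, "a")
    b = PWM("b", a.matrix[2:8].copy())
    m = compare_motifs(a, b)
    assert m.divergence == pytest.approx(0.0, abs=1e-12)
    assert m.offset == 2


def test_compare_dissimilar_not_match():
    strong_a = _consensus_pwm("AAAAAAAA", 0.97)
    strong_c = _consensus_pwm("CCCCCCCC", 0.97)
    assert not compare_motifs(strong_a, strong_c).is_match


def test_merge_similar_keeps_best_of_cluster(rng):
    a = random_pwm(rng, 8, "a")
    twin = PWM("twin", a.matrix.copy())
    other = _consensus_pwm("GGGGCCCC", 0.97)
    kept = merge_similar([a, twin, other], [0.2, 0.1, 0.3])
    assert {p.id for p in kept} == {"twin", "other" if False else "GGGGCCCC"}


def test_rerank_keeps_minimum_err_and_labels_source():
    free = [EnrichmentResult(motif="m1", err=0.3, cutoff=0.0),
            EnrichmentResult(motif="m2", err=0.1, cutoff=0.0)]
    comb = [EnrichmentResult(motif="m1", err=0.2, cutoff=0.0)]
    merged = rerank_across_sets({
        "conservation-free": free, "combined-conservation": comb,
    })
    assert [(r.motif, r.err, r.source_set, r.rank) for r in merged] == [
        ("m2", 0.1, "conservation-free", 1),
        ("m1", 0.2, "combined-conservation", 2),
    ]
    errs = [r.err for r in merged]
    assert errs == sorted(errs)


# ----------------------------------------------------------------- FET

def test_region_enrichment_fet_detects_enrichment(rng):
    pwm = _consensus_pwm("TGACGTCA")
    fg = random_set(rng, 15, 120, prefix="f")
    for e in fg:
        e.codes[10:18] = string_to_codes("TGACGTCA")
    bg = random_set(rng, 15, 120, prefix="b")
    cutoff = pwm.max_score() - 2.0
    ps = region_enrichment_fet([pwm], fg, bg, {pwm.id: cutoff})
    assert ps[pwm.id] < 0.01
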