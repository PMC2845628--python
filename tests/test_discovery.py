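"""De novo discovery: word seeding, coarse search, refinement, discover()."""

import numpy as np
import pytest

from regmine.config import RunConfig
from regmine.discovery import (
    ColumnAlphabet,
    coarse_search,
    discover,
    overrepresented_words,
    refine,
)
from regmine.motifs import classify_set
from regmine.sequences import codes_to_string, string_to_codes

from conftest import random_set

WORD = "TGACGTCA"


def _planted_sets(rng, n_fg=12, n_bg=30, length=120, word=WORD):
    fg = random_set(rng, n_fg, length, prefix="f")
    for e in fg:
        pos = int(rng.integers(0, length - len(word)))
        e.codes[pos : pos + len(word)] = string_to_codes(word)
    bg = random_set(rng, n_bg, length, prefix="b", stage_label="background")
    return fg, bg


def test_overrepresented_words_ranks_planted_word_first(rng):
    fg, bg = _planted_sets(rng)
    words = overrepresented_words(fg, bg, 8, top=10)
    assert codes_to_string(words[0]) == WORD


def test_coarse_search_recovers_planted_word(rng):
    fg, bg = _planted_sets(rng)
    cands = coarse_search(fg, bg, 8, beam=5, seed_words=100)
    consensus = [pwm.consensus() for pwm, _, _ in cands]
    assert WORD in consensus
    errs = [e for _, e, _ in cands]
    assert errs == sorted(errs)
    assert errs[0] <= 0.05


def test_refine_never_increases_err(rng):
    fg, bg = _planted_sets(rng, n_fg=8, n_bg=16, length=80)
    cands = coarse_search(fg, bg, 8, beam=3, seed_words=50)
    pwm, coarse_err, _ = cands[0]
    refined, err, cutoff, passes = refine(pwm, fg, bg, max_iter=20)
    start = classify_set(fg, bg, pwm).err
    assert err <= start + 1e-9
    assert err == pytest.approx(classify_set(fg, bg, refined).err, abs=1e-6)


def test_discover_returns_ranked_planted_motif(rng):
    fg, bg = _planted_sets(rng)
    cfg = RunConfig(motif_lengths=(8,), seed_words=100, beam_width=10,
                    min_targets=5, refine_max_iter=10)
    res = discover(fg, bg, cfg, attach_significance=False)
    assert res.motifs
    errs = [r.err for r in res.motifs]
    assert errs == sorted(errs)
    assert [r.rank for r in res.motifs] == list(range(1, len(res.motifs) + 1))
    assert res.motifs[0].err <= 0.05
    assert WORD in res.motifs[0].pwm.consensus() or res.motifs[0].err < 0.05


def test_discover_deterministic(rng):
    fg, bg = _planted_sets(rng, n_fg=8, n_bg=12, length=80)
    cfg = RunConfig(motif_lengths=(6,), seed_words=40, beam_width=5,
                    min_targets=5, refine_max_iter=5)
    r1 = discover(fg, bg, cfg, attach_significance=False)
    r2 = discover(fg, bg, cfg, attach_significance=False)
    assert [(m.motif, m.err, m.cutoff) for m in r1.motifs] == \
           [(m.motif, m.err, m.cutoff) for m in r2.motifs]


def test_discover_rejects_tiny_foreground(rng):
    fg = random_set(rng, 3, 50)
    bg = random_set(rng, 5, 50)
    with pytest.raises(ValueError, match="foreground"):
        discover(fg, bg, RunConfig())


def test_discover_warns_below_min_targets(rng):
    fg, bg = _planted_sets(rng, n_fg=6, n_bg=8, length=60)
    cfg = RunConfig(motif_lengths=(6,), seed_words=20, beam_width=3,
                    refine_max_iter=3)
    with pytest.warns(UserWarning, match="recommended"):
        discover(fg, bg, cfg, attach_significance=False)


def test_column_alphabet_default_lattice():
    alpha = ColumnAlphabet.default()
    assert np.allclose(alpha.vectors.sum(axis=1), 1.0)
    assert (alpha.vectors > 0).all()
    assert len(alpha.vectors) == 11  # 4 point masses + 6 pairs + uniform
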