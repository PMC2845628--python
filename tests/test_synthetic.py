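"""Synthetic generators: determinism, truth records, planted structure."""

import numpy as np
import pytest
from scipy import stats

from regmine.network import estimate_mi
from regmine.synthetic import (
    MarkovSampler,
    SyntheticSpec,
    default_planted_pwm,
    planted_network_spec,
    simulate_expression,
    simulate_orthologs,
    simulate_promoters,
)


def test_expression_deterministic():
    spec = planted_network_spec(n_direct=5, n_cascades=2, n_samples=40,
                                n_genes=15, seed=7)
    assert simulate_expression(spec).equals(simulate_expression(spec))


def test_expression_zero_noise_rank_identical():
    spec = planted_network_spec(n_direct=3, n_cascades=0, n_samples=50,
                                n_genes=10, noise_sd=0.0, seed=1)
    expr = simulate_expression(spec)
    rho, _ = stats.spearmanr(expr.loc["TF1"], expr.loc["T001"])
    assert rho == pytest.approx(1.0)


def test_cascade_mi_satisfies_dpi_premise():
    ok = 0
    for seed in range(10):
        spec = planted_network_spec(n_direct=2, n_cascades=1, n_samples=150,
                                    n_genes=10, seed=seed)
        expr = simulate_expression(spec)
        tf, med, dist = expr.loc["TF1"], expr.loc["M01"], expr.loc["D01"]
        mi_td = estimate_mi(tf.values, dist.values)
        ok += mi_td < min(estimate_mi(tf.values, med.values),
                          estimate_mi(med.values, dist.values))
    assert ok >= 9


def test_promoters_site_frequency_extremes():
    spec1 = SyntheticSpec(promoter_length=200, site_frequency=1.0, seed=5)
    fg, _, truth = simulate_promoters(spec1, 15, 2)
    assert all(truth[e.name] for e in fg)
    w = len(spec1.planted_pwm)
    for sites in truth.values():
        for s, e in sites:
            assert 0 <= s and e <= 200 and e - s == w

    spec0 = SyntheticSpec(promoter_length=200, site_frequency=0.0, seed=5)
    _, _, truth0 = simulate_promoters(spec0, 15, 2)
    assert not any(truth0.values())


def test_promoters_deterministic():
    spec = SyntheticSpec(promoter_length=100, seed=3)
    fg1, bg1, t1 = simulate_promoters(spec, 4, 4)
    fg2, bg2, t2 = simulate_promoters(spec, 4, 4)
    assert t1 == t2
    for a, b in zip(fg1, fg2):
        assert np.array_equal(a.codes, b.codes)


def test_promoters_site_longer_than_promoter_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(promoter_length=5)


def test_orthologs_no_turnover_colinear_and_tracked():
    spec = SyntheticSpec(promoter_length=400, site_frequency=1.0,
                         turnover_rate=0.0, seed=2)
    fg, _, truth = simulate_promoters(spec, 1, 0)
    prom = next(iter(fg))
    oset, track = simulate_orthologs(prom, truth[prom.name], spec)
    assert oset.names[0] == spec.species[0]
    assert len(oset) == len(spec.species)
    (s, e), = truth[prom.name]
    # island around the site is conserved and scored high
    centre = (s + e) // 2
    assert track[centre] > 0.8
    for sp in oset.names[1:]:
        seg_ref = prom.codes[s:e]
        seg_sp = oset[sp].codes[s:e]
        assert (seg_ref == seg_sp).mean() > 0.8  # colinear, low substitution


def test_orthologs_full_turnover_track_blind():
    spec = SyntheticSpec(promoter_length=600, site_frequency=1.0,
                         turnover_rate=1.0, seed=4)
    fg, _, truth = simulate_promoters(spec, 1, 0)
    prom = next(iter(fg))
    _, track = simulate_orthologs(prom, truth[prom.name], spec)
    (s, e), = truth[prom.name]
    centre = (s + e) // 2
    assert track[centre] < 0.8  # alignment-style track misses relocated sites


def test_ortholog_substitution_rate_matches_configured():
    spec = SyntheticSpec(promoter_length=1500, site_frequency=1.0,
                         island_length=400, island_substitution=0.05,
                         turnover_rate=0.0, seed=8)
    fg, _, truth = simulate_promoters(spec, 1, 0)
    prom = next(iter(fg))
    oset, _ = simulate_orthologs(prom, truth[prom.name], spec)
    (s, e), = truth[prom.name]
    lo = max(0, (s + e) // 2 - 200)
    hi = lo + 400
    diffs, total = 0, 0
    for sp in oset.names[1:]:
        diffs += int((prom.codes[lo:hi] != oset[sp].codes[lo:hi]).sum())
        total += hi - lo
    observed = diffs / total
    # substituted bases change with prob 1; binomial 99% interval around 0.05
    se = np.sqrt(0.05 * 0.95 / total)
    assert abs(observed - 0.05) < 3 * se + 0.005


def test_markov_sampler_deterministic():
    mk = MarkovSampler(np.random.default_rng(0))
    a = mk.sample(50, np.random.default_rng(1))
    b = mk.sample(50, np.random.default_rng(1))
    assert np.array_equal(a, b)


def test_default_planted_pwm_is_informative():
    pwm = default_planted_pwm()
    assert len(pwm) == 10
    assert 10.0 <= pwm.information_content() <= 16.0
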