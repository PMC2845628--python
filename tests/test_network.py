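"""Network inference: MI estimation, DPI, bootstrap consensus, target sets."""

import numpy as np
import pandas as pd
import pytest

from regmine.config import RunConfig
from regmine.network import (
    NetworkEdge,
    TFTargetSet,
    activated_targets,
    apply_dpi,
    bootstrap_consensus,
    coexpression_star,
    coexpression_targets,
    estimate_mi,
    mi_significance_threshold,
)
from regmine.synthetic import planted_network_spec, simulate_expression


def _edge(a, b, mi):
    return NetworkEdge(tf=a, target=b, mi=mi)


# ------------------------------------------------------------------- MI

def test_mi_invariant_under_monotone_transform(rng):
    x = rng.standard_normal(120)
    y = x + 0.5 * rng.standard_normal(120)
    assert estimate_mi(x, y) == pytest.approx(estimate_mi(np.exp(x), 2 * y + 3))


def test_mi_dependent_exceeds_independent(rng):
    x = rng.standard_normal(150)
    y_dep = x + 0.3 * rng.standard_normal(150)
    y_ind = rng.standard_normal(150)
    assert estimate_mi(x, y_dep) > estimate_mi(x, y_ind)


def test_mi_symmetric(rng):
    x, y = rng.standard_normal(80), rng.standard_normal(80)
    assert estimate_mi(x, y) == pytest.approx(estimate_mi(y, x), abs=1e-10)


def test_mi_nonnegative(rng):
    for _ in range(5):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        assert estimate_mi(x, y) >= 0.0


def test_mi_threshold_decreases_with_alpha(rng):
    expr = pd.DataFrame(
        rng.standard_normal((20, 100)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(100)],
    )
    t_loose = mi_significance_threshold(expr, 0.5, rng=np.random.default_rng(0))
    t_tight = mi_significance_threshold(expr, 1e-3, rng=np.random.default_rng(0))
    assert t_tight > t_loose > 0


# ------------------------------------------------------------------ DPI

def test_dpi_prunes_weakest_triangle_edge():
    edges = [_edge("X", "Y", 0.9), _edge("Y", "Z", 0.8), _edge("X", "Z", 0.3)]
    kept = apply_dpi(edges)
    assert {e.key for e in kept} == {frozenset(("X", "Y")), frozenset(("Y", "Z"))}


def test_dpi_tolerance_keeps_near_ties():
    edges = [_edge("X", "Y", 1.0), _edge("Y", "Z", 1.0), _edge("X", "Z", 0.95)]
    assert len(apply_dpi(edges, tolerance=0.1)) == 3
    assert len(apply_dpi(edges, tolerance=0.0)) == 2


def test_dpi_no_triangle_is_noop():
    edges = [_edge("X", "Y", 0.5), _edge("X", "Z", 0.1)]
    assert apply_dpi(edges) == edges


def test_dpi_idempotent(rng):
    genes = [f"g{i}" for i in range(8)]
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < 0.5:
                edges.append(_edge(genes[i], genes[j], float(rng.random())))
    once = apply_dpi(edges)
    assert apply_dpi(once) == once


def test_dpi_rejects_negative_tolerance():
    with pytest.raises(ValueError):
        apply_dpi([], tolerance=-0.1)


# ---------------------------------------------------------------- sets

def test_tf_target_set_rejects_self_loop():
    with pytest.raises(ValueError):
        TFTargetSet(tf="A", targets=frozenset({"A", "B"}), method="aracne")


def test_activated_targets_filters_sign_and_size():
    edges = [
        NetworkEdge("T", f"g{i}", 0.5, sign=1) for i in range(4)
    ] + [NetworkEdge("T", "neg", 0.5, sign=-1)]
    assert activated_targets(edges, None, min_targets=4)[0].targets == frozenset(
        f"g{i}" for i in range(4)
    )
    assert activated_targets(edges, None, min_targets=5) == []


# ------------------------------------------------------ co-expression

def test_coexpression_noiseless_target(rng):
    n = 60
    tf = rng.standard_normal(n)
    expr = pd.DataFrame(
        np.stack([tf, 2 * tf + 1]),
        index=["TF", "TARGET"],
        columns=[f"S{j}" for j in range(n)],
    )
    ts = coexpression_targets(expr, "TF", alpha=1e-4)
    assert ts.targets == frozenset({"TARGET"})


def test_coexpression_star_size_and_order(rng):
    n = 80
    tf = rng.standard_normal(n)
    rows = [tf] + [tf + noise * rng.standard_normal(n)
                   for noise in (0.1, 0.5, 2.0, 8.0)]
    expr = pd.DataFrame(
        np.stack(rows),
        index=["TF", "g0", "g1", "g2", "g3"],
        columns=[f"S{j}" for j in range(n)],
    )
    star = coexpression_star(expr, "TF", 2)
    assert star.targets == frozenset({"g0", "g1"})


# ------------------------------------------------- bootstrap consensus

def test_bootstrap_consensus_recovers_planted_star():
    spec = planted_network_spec(
        n_direct=8, n_cascades=0, n_samples=120, n_genes=25, seed=3
    )
    expr = simulate_expression(spec)
    cfg = RunConfig(bootstraps=20, consensus_alpha=1e-4, min_targets=5)
    edges = bootstrap_consensus(expr, ["TF1"], cfg, rng=np.random.default_rng(3))
    found = {e.target for e in edges if e.tf == "TF1"}
    planted = {t for _, t, _ in spec.planted_edges}
    assert len(found & planted) >= 7
    assert all(e.sign == 1 for e in edges if e.target in planted)


def test_bootstrap_consensus_deterministic():
    spec = planted_network_spec(
        n_direct=6, n_cascades=0, n_samples=100, n_genes=18, seed=9
    )
    expr = simulate_expression(spec)
    cfg = RunConfig(bootstraps=12, consensus_alpha=1e-4, min_targets=5)
    e1 = bootstrap_consensus(expr, ["TF1"], cfg, rng=np.random.default_rng(1))
    e2 = bootstrap_consensus(expr, ["TF1"], cfg, rng=np.random.default_rng(1))
    assert e1 == e2


def test_bootstrap_consensus_requires_samples():
    expr = pd.DataFrame(np.zeros((3, 4)), index=list("abc"))
    with pytest.raises(ValueError, match="samples"):
        bootstrap_consensus(expr, ["a"], RunConfig())
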