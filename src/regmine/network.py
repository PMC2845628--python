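"""Regulatory-network inference from expression profiles.

Candidate TF-target interactions are scored by mutual information (MI)
between expression profiles, thresholded against a shuffle null with
Bonferroni correction, pruned of indirect edges with the Data
Processing Inequality (DPI), and aggregated over bootstrap resamples
into a consensus network.  Co-expression target sets (plain Spearman
and the size-matched "co-expression*" variant) are produced for
comparison.

MI estimator
------------
Profiles are first mapped to normal scores through their ranks (a
copula transform), which makes the estimate invariant under strictly
monotone transformations of either argument and deterministic.  MI is
then the resubstitution plug-in estimate under Gaussian kernel density
estimates with normal-reference bandwidths, minus the estimator's null
mean at that sample size (the null distribution of the plug-in on rank
data depends only on n, so the correction is a per-n constant),
clamped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig

__all__ = [
    "NetworkEdge",
    "TFTargetSet",
    "estimate_mi",
    "mi_significance_threshold",
    "apply_dpi",
    "bootstrap_consensus",
    "activated_targets",
    "coexpression_targets",
    "coexpression_star",
    "spearman_profile",
]


@dataclass(frozen=True)
class NetworkEdge:
    tf: str
    target: str
    mi: float
    sign: int = 0
    support: int = 0
    consensus_p: float = 1.0

    @property
    def key(self) -> FrozenSet[str]:
        return frozenset((self.tf, self.target))


@dataclass(frozen=True)
class TFTargetSet:
    tf: str
    targets: frozenset
    method: str  # aracne | coexpression | coexpression*

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError(f"TF {self.tf!r} cannot be its own target")

    @property
    def n(self) -> int:
        return len(self.targets)


# --------------------------------------------------------------------------
# MI estimation
# --------------------------------------------------------------------------

def _normal_scores(v: np.ndarray) -> Optional[np.ndarray]:
    """Rank-based normal scores; None when the vector is constant."""
    v = np.asarray(v, dtype=float)
    r = stats.rankdata(v)
    z = stats.norm.ppf(r / (len(v) + 1))
    if z.std() < 1e-12:
        return None
    return z


def _bandwidth(z: np.ndarray) -> float:
    # normal-reference rule for a univariate Gaussian kernel
    return 1.06 * z.std() * len(z) ** (-0.2)


def _kernel(z: np.ndarray) -> np.ndarray:
    h = _bandwidth(z)
    d = (z[:, None] - z[None, :]) / h
    return np.exp(-0.5 * d * d).astype(np.float32)


def _raw_mi_from_kernels(kx: np.ndarray, ky: np.ndarray) -> float:
    """Plug-in MI (nats) from precomputed kernel matrices."""
    n = kx.shape[0]
    joint = np.einsum("ij,ij->i", kx, ky)
    ratio = n * joint / (kx.sum(axis=1) * ky.sum(axis=1))
    return float(np.log(np.maximum(ratio, 1e-300)).mean())


@lru_cache(maxsize=32)
def _null_mean(n: int, n_draws: int = 200) -> float:
    """Null mean of the raw plug-in at sample size n (internal fixed MC).

    On rank data the null law depends only on n, so this constant is a
    property of the estimator, not of any particular dataset.
    """
    rng = np.random.default_rng(181818)
    z = stats.norm.ppf((np.arange(1, n + 1)) / (n + 1))
    kx = _kernel(z)
    vals = np.empty(n_draws)
    for i in range(n_draws):
        p = rng.permutation(n)
        vals[i] = _raw_mi_from_kernels(kx, kx[np.ix_(p, p)])
    return float(vals.mean())


def estimate_mi(x: np.ndarray, y: np.ndarray, bias_correct: bool = True) -> float:
    """Mutual information (nats) between two equal-length sample vectors.

    Symmetric, non-negative, and invariant under strictly monotone
    transforms of either argument.  Constant vectors give MI 0 with a
    warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 8:
        raise ValueError("need at least 8 samples for MI estimation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    zx, zy = _normal_scores(x), _normal_scores(y)
    if zx is None or zy is None:
        warnings.warn("constant vector: MI set to 0")
        return 0.0
    raw = _raw_mi_from_kernels(_kernel(zx), _kernel(zy))
    if bias_correct:
        raw -= _null_mean(len(x))
    return max(0.0, raw)


def _mi_block(
    tf_kernels: Dict[str, np.ndarray],
    gene_kernels: Dict[str, np.ndarray],
    pairs: Sequence[Tuple[str, str]],
    n: int,
    correction: float,
) -> Dict[FrozenSet[str], float]:
    """Corrected MI for many (tf, gene) pairs reusing kernel matrices."""
    out: Dict[FrozenSet[str], float] = {}
    sums = {g: k.sum(axis=1) for g, k in gene_kernels.items()}
    tf_sums = {t: k.sum(axis=1) for t, k in tf_kernels.items()}
    for tf, gene in pairs:
        kx, ky = tf_kernels[tf], gene_kernels[gene]
        joint = np.einsum("ij,ij->i", kx, ky)
        ratio = n * joint / (tf_sums[tf] * sums[gene])
        raw = float(np.log(np.maximum(ratio, 1e-300)).mean())
        out[frozenset((tf, gene))] = max(0.0, raw - correction)
    return out


# --------------------------------------------------------------------------
# MI significance threshold
# --------------------------------------------------------------------------

def mi_significance_threshold(
    expr: pd.DataFrame,
    alpha: float,
    n_null: int = 2000,
    tfs: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
    tail: str = "auto",
    resampled: bool = False,
) -> float:
    """Bonferroni-corrected MI threshold from a within-gene shuffle null.

    The null is MI between independently shuffled profiles; the
    threshold is the 1 - alpha / n_pairs quantile of that null.  When
    n_null cannot resolve the corrected quantile empirically, the upper
    tail is extrapolated with a generalized Pareto fit over the top
    decile of exceedances (``tail='gpd'`` forces this, ``'empirical'``
    forbids it).

    With ``resampled=True`` each null pair is additionally
    bootstrap-resampled with a shared index draw before estimation.
    Joint resampling duplicates whole samples, and duplicated points
    concentrate probability mass in rank space, inflating the kernel MI
    of even independent profiles -- so thresholds intended for networks
    inferred on bootstrap resamples must be calibrated on the same
    distribution.
    """
    if not (0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    n_genes = expr.shape[0]
    n = expr.shape[1]
    if tfs is None:
        n_pairs = n_genes * (n_genes - 1) // 2
    else:
        tfs = [t for t in tfs if t in expr.index]
        n_pairs = len({frozenset((t, g)) for t in tfs for g in expr.index if g != t})
    corrected = min(1.0, alpha / max(1, n_pairs))
    rng = rng or np.random.default_rng(0)

    # null MI on ranks depends only on n: permute a fixed normal-score grid
    z = stats.norm.ppf(np.arange(1, n + 1) / (n + 1))
    kx = _kernel(z)
    correction = _null_mean(n)
    null = np.empty(n_null)
    for i in range(n_null):
        p = rng.permutation(n)
        if resampled:
            idx = rng.integers(0, n, size=n)
            zx = _normal_scores(z[idx])
            zy = _normal_scores(z[p][idx])
            raw = _raw_mi_from_kernels(_kernel(zx), _kernel(zy))
        else:
            raw = _raw_mi_from_kernels(kx, kx[np.ix_(p, p)])
        null[i] = max(0.0, raw - correction)
    null.sort()

    if corrected >= 1.0:
        return float(null[0])
    resolvable = n_null * corrected >= 1.0
    if tail == "empirical" and not resolvable:
        raise ValueError(
            f"n_null={n_null} cannot resolve quantile 1-{corrected:.3g}; "
            "increase n_null or allow the generalized-Pareto tail fit"
        )
    if resolvable and tail != "gpd":
        k = int(np.ceil((1.0 - corrected) * n_null)) - 1
        k = min(max(k, 0), n_null - 1)
        return float(null[k])
    # peaks-over-threshold tail fit
    u = float(np.quantile(null, 0.9))
    exceed = null[null > u] - u
    if exceed.size < 20:
        raise ValueError("too few tail exceedances for a GPD fit; increase n_null")
    c, loc, scale = stats.genpareto.fit(exceed, floc=0.0)
    p_exceed = exceed.size / n_null
    q = corrected / p_exceed  # tail probability conditional on exceedance
    return float(u + stats.genpareto.ppf(1.0 - q, c, loc=0.0, scale=scale))


# --------------------------------------------------------------------------
# DPI
# --------------------------------------------------------------------------

def apply_dpi(edges: Sequence[NetworkEdge], tolerance: float = 0.0) -> List[NetworkEdge]:
    """Prune the weakest edge of every triangle (mark-and-sweep).

    For each triangle, the minimum-MI edge is marked for removal when
    its MI is strictly below (1 - tolerance) times the smaller of the
    other two; all marks are evaluated on the input graph, so the
    result is independent of edge order and idempotent.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    mi: Dict[FrozenSet[str], float] = {}
    adj: Dict[str, set] = {}
    for e in edges:
        mi[e.key] = e.mi
        adj.setdefault(e.tf, set()).add(e.target)
        adj.setdefault(e.target, set()).add(e.tf)
    doomed: set = set()
    for key in mi:
        u, v = sorted(key)
        for w in adj[u] & adj[v]:
            if w <= v:
                continue  # each triangle visited once via its two smallest nodes
            trio = [
                (mi[frozenset((u, v))], frozenset((u, v))),
                (mi[frozenset((u, w))], frozenset((u, w))),
                (mi[frozenset((v, w))], frozenset((v, w))),
            ]
            trio.sort(key=lambda t: (t[0], sorted(t[1])))
            weakest_mi, weakest_key = trio[0]
            if weakest_mi < (1.0 - tolerance) * trio[1][0]:
                doomed.add(weakest_key)
    return [e for e in edges if e.key not in doomed]


# --------------------------------------------------------------------------
# Bootstrap consensus
# --------------------------------------------------------------------------

def _poisson_binomial_sf(qs: np.ndarray) -> np.ndarray:
    """P(S >= s) for s = 0..B where S = sum of independent Bernoulli(qs)."""
    pmf = np.array([1.0])
    for q in qs:
        pmf = np.convolve(pmf, [1.0 - q, q])
    sf = pmf[::-1].cumsum()[::-1]
    return np.minimum(sf, 1.0)


def spearman_profile(expr: pd.DataFrame, tf: str) -> Tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of every gene against one TF."""
    vals = expr.values
    ranks = np.apply_along_axis(stats.rankdata, 1, vals)
    ranks = (ranks - ranks.mean(axis=1, keepdims=True))
    norms = np.sqrt((ranks**2).sum(axis=1))
    norms[norms == 0] = np.nan
    i = expr.index.get_loc(tf)
    rho = ranks @ ranks[i] / (norms * norms[i])
    rho = np.clip(rho, -1.0, 1.0)
    n = vals.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), np.where(np.abs(rho) >= 1.0, 0.0, 1.0), p)
    return rho, p


def _infer_single_network(
    expr_vals: np.ndarray,
    genes: List[str],
    tf_set: set,
    threshold: float,
    correction: float,
    dpi_tolerance: float,
) -> List[FrozenSet[str]]:
    """One network inference pass: MI threshold then DPI.  Returns TF-edge keys.

    MI is computed for every TF-gene pair, and additionally for pairs of
    genes adjacent to a common TF: those second-ring edges supply the
    triangles through which the Data Processing Inequality can prune
    indirect (cascade) TF-target edges.  Only TF-incident edges are
    returned; second-ring edges act as pruning evidence.
    """
    n = expr_vals.shape[1]
    kernels: Dict[str, np.ndarray] = {}
    const: set = set()
    for g, row in zip(genes, expr_vals):
        z = _normal_scores(row)
        if z is None:
            const.add(g)
        else:
            kernels[g] = _kernel(z)
    pairs = []
    seen = set()
    for t in genes:
        if t not in tf_set or t in const:
            continue
        for g in genes:
            if g == t or g in const:
                continue
            key = frozenset((t, g))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((t, g))
    mi = _mi_block(kernels, kernels, pairs, n, correction)
    edges = [
        NetworkEdge(tf=t, target=g, mi=mi[frozenset((t, g))])
        for t, g in pairs
        if mi[frozenset((t, g))] >= threshold
    ]
    neighbours: Dict[str, set] = {}
    for e in edges:
        neighbours.setdefault(e.tf, set()).add(e.target)
    ring_pairs = []
    ring_seen = set()
    for t, targets in neighbours.items():
        ordered = sorted(targets)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                key = frozenset((a, b))
                if key in ring_seen or a in tf_set or b in tf_set:
                    continue
                ring_seen.add(key)
                ring_pairs.append((a, b))
    if ring_pairs:
        mi2 = _mi_block(kernels, kernels, ring_pairs, n, correction)
        edges += [
            NetworkEdge(tf=a, target=b, mi=mi2[frozenset((a, b))])
            for a, b in ring_pairs
            if mi2[frozenset((a, b))] >= threshold
        ]
    kept = apply_dpi(edges, dpi_tolerance)
    return [e.key for e in kept if e.tf in tf_set or e.target in tf_set]


def bootstrap_consensus(
    expr: pd.DataFrame,
    tfs: Sequence[str],
    config: RunConfig,
    rng: Optional[np.random.Generator] = None,
    threshold: Optional[float] = None,
) -> List[NetworkEdge]:
    """Bootstrap-consensus network over TF-gene pairs.

    Each bootstrap resamples expression samples with replacement and
    runs MI-threshold + DPI inference.  Edge support counts are tested
    against the exact Poisson-binomial null of a same-size random
    network per bootstrap (the analytic limit of shuffled-network
    support nulls), and edges significant at ``consensus_alpha`` are
    kept.  Signs come from Spearman correlation on the full matrix.
    """
    n = expr.shape[1]
    if n < 8:
        raise ValueError("need at least 8 samples")
    rng = rng or np.random.default_rng(config.rng_seed)
    genes = list(expr.index)
    tf_set = {t for t in tfs if t in expr.index}
    if not tf_set:
        return []
    if threshold is None:
        threshold = mi_significance_threshold(
            expr, config.mi_alpha, tfs=sorted(tf_set), rng=rng, resampled=True
        )
    correction = _null_mean(n)
    m_possible = len(
        {frozenset((t, g)) for t in tf_set for g in genes if g != t}
    )
    vals = expr.values
    support: Dict[FrozenSet[str], int] = {}
    edge_counts = np.zeros(config.bootstraps, dtype=int)
    for b in range(config.bootstraps):
        idx = rng.integers(0, n, size=n)
        keys = _infer_single_network(
            vals[:, idx], genes, tf_set, threshold, correction, config.dpi_tolerance
        )
        edge_counts[b] = len(keys)
        for k in keys:
            support[k] = support.get(k, 0) + 1

    qs = edge_counts / m_possible
    sf = _poisson_binomial_sf(qs)

    # signs and full-data MI for retained edges
    rho_cache: Dict[str, np.ndarray] = {}
    kernels = {}
    for g in genes:
        z = _normal_scores(vals[genes.index(g)])
        if z is not None:
            kernels[g] = _kernel(z)
    out: List[NetworkEdge] = []
    for key, s in sorted(support.items(), key=lambda kv: sorted(kv[0])):
        p = float(sf[min(s, len(sf) - 1)])
        if p >= config.consensus_alpha:
            continue
        a, bnode = sorted(key)
        tf = a if a in tf_set else bnode
        target = bnode if tf == a else a
        if tf not in rho_cache:
            rho_cache[tf], _ = spearman_profile(expr, tf)
        rho = rho_cache[tf][genes.index(target)]
        sign = 0 if not np.isfinite(rho) or rho == 0 else (1 if rho > 0 else -1)
        if tf in kernels and target in kernels:
            mi_val = max(
                0.0,
                _raw_mi_from_kernels(kernels[tf], kernels[target]) - correction,
            )
        else:
            mi_val = 0.0
        out.append(
            NetworkEdge(tf=tf, target=target, mi=mi_val, sign=sign, support=s, consensus_p=p)
        )
    return out


def activated_targets(
    edges: Sequence[NetworkEdge],
    expr: pd.DataFrame,
    min_targets: int = 30,
) -> List[TFTargetSet]:
    """Per-TF sets of positively-signed consensus targets of size >= min."""
    by_tf: Dict[str, set] = {}
    for e in edges:
        if e.sign == 1:
            by_tf.setdefault(e.tf, set()).add(e.target)
    return [
        TFTargetSet(tf=tf, targets=frozenset(tg), method="aracne")
        for tf, tg in sorted(by_tf.items())
        if len(tg) >= min_targets
    ]


# --------------------------------------------------------------------------
# Co-expression target sets
# --------------------------------------------------------------------------

def coexpression_targets(
    expr: pd.DataFrame,
    tf: str,
    alpha: float = 1e-4,
    correction_scope: str = "genes",
    n_tfs: int = 1,
) -> TFTargetSet:
    """Positively Spearman-correlated genes at a Bonferroni-corrected level.

    ``correction_scope`` selects whether the Bonferroni factor counts
    candidate genes only ("genes") or gene x TF pairs ("pairs",
    multiplying by ``n_tfs``).
    """
    if tf not in expr.index:
        raise KeyError(f"TF {tf!r} not in expression matrix")
    rho, p = spearman_profile(expr, tf)
    n_tests = expr.shape[0] - 1
    if correction_scope == "pairs":
        n_tests *= max(1, n_tfs)
    corrected = np.minimum(1.0, p * n_tests)
    genes = expr.index.to_numpy()
    keep = (rho > 0) & (corrected <= alpha) & (genes != tf)
    return TFTargetSet(tf=tf, targets=frozenset(genes[keep]), method="coexpression")


def coexpression_star(expr: pd.DataFrame, tf: str, n: int) -> TFTargetSet:
    """The n most co-expressed (positively correlated) genes with the TF.

    Ranking is by Spearman p ascending (ties: rho descending, then gene
    id) among positively correlated genes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rho, p = spearman_profile(expr, tf)
    genes = expr.index.to_numpy()
    eligible = (rho > 0) & (genes != tf)
    cand = sorted(
        zip(p[eligible], -rho[eligible], genes[eligible]),
        key=lambda t: (t[0], t[1], t[2]),
    )
    if n > len(cand):
        warnings.warn(f"requested {n} targets but only {len(cand)} eligible genes")
    chosen = frozenset(g for _, _, g in cand[:n])
    return TFTargetSet(tf=tf, targets=chosen, method="coexpression*")
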