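"""Regularized partial-correlation networks and their stability diagnostics.

Networks are estimated by graphical lasso on a Spearman rank-correlation
matrix, with the regularization strength selected by the extended Bayesian
information criterion (EBIC) along a descending lambda path. Edge weights
are the regularized partial correlations ``-Theta_ij / sqrt(Theta_ii
Theta_jj)``. Stability diagnostics follow the case-dropping and
person-resampling bootstrap framework standard in network psychometrics:
CS coefficients for centrality orderings, edge retention/weight-correlation
summaries, and bootstrapped community-recovery frequencies against a
reference Louvain partition.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))


@dataclass
class NetworkModel:
    nodes: List[str]
    W: np.ndarray  # symmetric partial-correlation weights, zero diagonal
    lambda_selected: float
    gamma: float
    input_corr: np.ndarray
    n: int
    lambda_path: Optional[np.ndarray] = None
    ebic_path: Optional[np.ndarray] = None

    @property
    def p(self) -> int:
        return len(self.nodes)


@dataclass
class CommunityPartition:
    labels: Dict[str, int]
    Q: float
    resolution: float
    seed: int

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class StabilityReport:
    cs: Dict[str, float]
    edge_mean_retention: Optional[float]
    edge_median_weight_corr: Optional[float]
    n_boot: int
    drop_grid: Tuple[float, ...]
    recovery_frequency: Optional[float] = None
    edge_ci: Optional[Dict[Tuple[int, int], Tuple[float, float]]] = None


def spearman_matrix(data: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rank correlations with average-rank tie handling.

    Zero-variance columns get missing correlations (NaN) off the diagonal.
    """
    X = np.asarray(data, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    sds = X.std(axis=0)
    ranked = np.apply_along_axis(stats.rankdata, 0, X)  # average-rank ties
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(ranked, rowvar=False)
    for j in np.flatnonzero(sds == 0):
        logger.warning("column %d has zero variance; correlations set missing", j)
        R[j, :] = np.nan
        R[:, j] = np.nan
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def nearest_pd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair with unit diagonal.

    Already-PD inputs pass through unchanged.
    """
    R = np.asarray(R, dtype=float)
    A = (R + R.T) / 2.0
    if np.linalg.eigvalsh(A).min() >= eps and np.allclose(np.diag(A), 1.0, atol=1e-12):
        return R.copy()
    # rescaling to unit diagonal can push the smallest eigenvalue back
    # below the floor, so clip-and-rescale is iterated to a fixed point
    for _ in range(100):
        vals, vecs = np.linalg.eigh(A)
        if vals.min() >= eps:
            break
        vals = np.clip(vals, eps * 1.05, None)
        A = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        np.fill_diagonal(A, 1.0)
        A = (A + A.T) / 2.0
    return A


def _partials_from_precision(Theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(Theta))
    W = -Theta / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    W[np.abs(W) < 1e-10] = 0.0
    return (W + W.T) / 2.0


def ebic_glasso(
    R: np.ndarray,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    nodes: Optional[Sequence[str]] = None,
    tol: float = 1e-4,
    max_iter: int = 200,
    select: str = "ebic",
    patience: Optional[int] = None,
) -> NetworkModel:
    """Graphical lasso along a lambda path with EBIC model selection.

    The path runs log-spaced from lambda_max (smallest lambda giving an
    empty graph, i.e. the largest absolute input correlation) down to
    ``lambda_min_ratio * lambda_max``. EBIC(lambda) = -2 loglik +
    E log(n) + 4 E gamma log(p) with E the edge count. ``select`` may be
    "ebic" (default) or "min_lambda" (return the least-regularized
    solution on the path, approaching the exact partial correlations).

    ``patience`` (optional) stops the scan once EBIC has not improved for
    that many consecutive lambdas. The profile is usually but not always
    unimodal — it can wiggle near the sparse end as single edges enter and
    leave — so no early stopping happens by default; pass a generous
    patience only when the dense tail is known to be irrelevant.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if nodes is None:
        nodes = [f"V{j + 1}" for j in range(p)]
    off = np.abs(R - np.diag(np.diag(R)))
    lam_max = float(off.max())
    if lam_max == 0.0:
        W = np.zeros_like(R)
        return NetworkModel(list(nodes), W, 0.0, gamma, R, n)
    lams = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)

    if patience is None:
        patience = n_lambda  # no early stop
    best = None
    since_best = 0
    ebics = np.full(n_lambda, np.nan)
    for i, lam in enumerate(lams):
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                _, Theta = graphical_lasso(R, alpha=float(lam), tol=tol, max_iter=max_iter)
        except Exception:
            continue
        W = _partials_from_precision(Theta)
        iu = np.triu_indices(p, k=1)
        E = int(np.count_nonzero(W[iu]))
        sign, logdet = np.linalg.slogdet(Theta)
        if sign <= 0:
            continue
        loglik = (n / 2.0) * (logdet - np.trace(R @ Theta))
        ebic = -2.0 * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)
        ebics[i] = ebic
        if select == "min_lambda":
            best = (ebic, float(lam), W)
        elif best is None or ebic < best[0]:
            best = (ebic, float(lam), W)
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best is None:
        raise RuntimeError(
            f"graphical lasso failed along the whole path (lambda_max={lam_max:.4g})"
        )
    _, lam_sel, W_sel = best
    return NetworkModel(
        nodes=list(nodes),
        W=W_sel,
        lambda_selected=lam_sel,
        gamma=gamma,
        input_corr=R,
        n=n,
        lambda_path=lams,
        ebic_path=ebics,
    )


def estimate_network(
    data: np.ndarray,
    nodes: Optional[Sequence[str]] = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    tol: float = 1e-4,
) -> NetworkModel:
    """Spearman -> nearest-PD -> EBIC glasso convenience pipeline."""
    X = np.asarray(data, dtype=float)
    R = spearman_matrix(X)
    if np.isnan(R).any():
        keep = ~np.isnan(R).all(axis=0)
        raise ValueError(
            f"zero-variance nodes present; drop columns {list(np.flatnonzero(~keep))}"
        )
    R = nearest_pd(R)
    return ebic_glasso(R, n=X.shape[0], gamma=gamma, n_lambda=n_lambda, nodes=nodes, tol=tol)


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------

def _graph(net: NetworkModel) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(net.nodes)
    iu = np.triu_indices(net.p, k=1)
    for i, j in zip(*iu):
        w = abs(net.W[i, j])
        if w > 0:
            G.add_edge(net.nodes[i], net.nodes[j], weight=w, length=1.0 / w)
    return G


def centralities(net: NetworkModel) -> Dict[str, Dict[str, float]]:
    """Strength, betweenness and closeness per node.

    Strength sums absolute edge weights; betweenness and closeness use edge
    lengths 1/|w| (stronger edge = shorter path); closeness is harmonic, so
    disconnected pairs contribute zero.
    """
    G = _graph(net)
    n = len(net.nodes)
    strength = {v: 0.0 for v in net.nodes}
    for u, v, d in G.edges(data=True):
        strength[u] += d["weight"]
        strength[v] += d["weight"]
    if G.number_of_edges() == 0:
        return {v: {"strength": 0.0, "betweenness": 0.0, "closeness": 0.0} for v in net.nodes}
    btw = nx.betweenness_centrality(G, weight="length", normalized=True)
    harm = nx.harmonic_centrality(G, distance="length")
    scale = 1.0 / (n - 1) if n > 1 else 1.0
    return {
        v: {
            "strength": strength[v],
            "betweenness": btw.get(v, 0.0),
            "closeness": harm.get(v, 0.0) * scale,
        }
        for v in net.nodes
    }


def centrality_vector(net: NetworkModel, index: str) -> np.ndarray:
    cents = centralities(net)
    if index not in ("strength", "betweenness", "closeness"):
        raise ValueError(f"unknown centrality index {index!r}")
    return np.array([cents[v][index] for v in net.nodes])


# ---------------------------------------------------------------------------
# Case-dropping bootstrap (CS coefficient)
# ---------------------------------------------------------------------------

def case_drop_stability(
    data: np.ndarray,
    indices: Sequence[str] = ("strength", "betweenness", "closeness"),
    n_boot: int = 1000,
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    threshold: float = 0.7,
    confidence: float = 0.95,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 30,
    nodes: Optional[Sequence[str]] = None,
    boot_tol: float = 1e-4,
) -> Dict[str, float]:
    """CS coefficients for several centrality indices at once.

    For each drop proportion, networks are re-estimated on person
    subsamples (all indices share the same re-estimated networks); each
    index's CS is the largest drop proportion, scanning upward and stopping
    at the first failure, at which the correlation between original and
    subsample centralities stays >= threshold in >= confidence of
    resamples.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    for index in indices:
        if index not in ("strength", "betweenness", "closeness"):
            raise ValueError(f"unknown centrality index {index!r}")
    full = estimate_network(X, nodes=nodes, gamma=gamma, n_lambda=n_lambda)
    full_cents = centralities(full)
    c_full = {
        ix: np.array([full_cents[v][ix] for v in full.nodes]) for ix in indices
    }

    grid = [q for q in drop_grid if (1 - q) * n >= max(3 * p, 10)]
    if len(grid) < len(drop_grid):
        logger.info("drop grid truncated to %s (n=%d, p=%d)", grid, n, p)
    if not grid:
        return {ix: 0.0 for ix in indices}
    per_level = max(1, n_boot // len(drop_grid))

    cs = {ix: 0.0 for ix in indices}
    alive = set(indices)
    for li, q in enumerate(grid):
        if not alive:
            break
        m = int(round((1 - q) * n))
        ok = {ix: 0 for ix in alive}
        for b in range(per_level):
            rng = np.random.default_rng([seed, li, b])
            idx = rng.choice(n, size=m, replace=False)
            try:
                net_b = estimate_network(
                    X[idx], nodes=nodes, gamma=gamma, n_lambda=n_lambda, tol=boot_tol
                )
                cents_b = centralities(net_b)
            except Exception:
                continue
            for ix in alive:
                c_b = np.array([cents_b[v][ix] for v in full.nodes])
                if c_b.std() == 0 or c_full[ix].std() == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(c_full[ix], c_b)[0, 1])
                if r >= threshold:
                    ok[ix] += 1
        for ix in list(alive):
            if ok[ix] / per_level >= confidence:
                cs[ix] = q
            else:
                alive.discard(ix)
    return cs


def case_drop_cs(
    data: np.ndarray,
    index: str = "strength",
    n_boot: int = 1000,
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    threshold: float = 0.7,
    confidence: float = 0.95,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 30,
    nodes: Optional[Sequence[str]] = None,
    boot_tol: float = 1e-4,
) -> float:
    """Centrality-stability coefficient for one index (see case_drop_stability)."""
    return case_drop_stability(
        data,
        indices=(index,),
        n_boot=n_boot,
        drop_grid=drop_grid,
        threshold=threshold,
        confidence=confidence,
        seed=seed,
        gamma=gamma,
        n_lambda=n_lambda,
        nodes=nodes,
        boot_tol=boot_tol,
    )[index]


def edge_bootstrap(
    data: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 30,
    ci_level: float = 0.95,
    nodes: Optional[Sequence[str]] = None,
    boot_tol: float = 1e-4,
) -> Dict[str, object]:
    """Person-resampling bootstrap of edge weights.

    Reports the mean retention of full-sample edges across bootstraps, the
    median Pearson correlation between full-sample and bootstrap
    upper-triangle weights, and percentile CIs per edge.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    full = estimate_network(X, nodes=nodes, gamma=gamma, n_lambda=n_lambda)
    iu = np.triu_indices(p, k=1)
    w_full = full.W[iu]
    full_edges = np.flatnonzero(w_full != 0)
    if full_edges.size == 0:
        logger.warning("full-sample network is empty; retention undefined")
    boot_w = np.full((n_boot, w_full.size), np.nan)
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, n, size=n)
        try:
            net_b = estimate_network(
                X[idx], nodes=nodes, gamma=gamma, n_lambda=n_lambda, tol=boot_tol
            )
            boot_w[b] = net_b.W[iu]
        except Exception:
            continue
    valid = ~np.isnan(boot_w).any(axis=1)
    bw = boot_w[valid]

    retention = None
    if full_edges.size:
        retention = float(np.mean(bw[:, full_edges] != 0))
    corrs = []
    for row in bw:
        if row.std() > 0 and w_full.std() > 0:
            corrs.append(float(np.corrcoef(w_full, row)[0, 1]))
    median_corr = float(np.median(corrs)) if corrs else None
    alpha = (1 - ci_level) / 2
    lo, hi = np.percentile(bw, [100 * alpha, 100 * (1 - alpha)], axis=0)
    edge_ci = {
        (int(i), int(j)): (float(lo[e]), float(hi[e]))
        for e, (i, j) in enumerate(zip(*iu))
    }
    return {
        "edge_mean_retention": retention,
        "edge_median_weight_corr": median_corr,
        "edge_ci": edge_ci,
        "n_boot_valid": int(valid.sum()),
        "full_network": full,
    }


# ---------------------------------------------------------------------------
# Communities and global metrics
# ---------------------------------------------------------------------------

def louvain(
    net: NetworkModel,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
) -> CommunityPartition:
    """Seeded best-of-restarts Louvain on absolute edge weights."""
    G = _graph(net)
    if G.number_of_edges() == 0:
        labels = {v: i for i, v in enumerate(net.nodes)}
        return CommunityPartition(labels, 0.0, resolution, seed)
    best_q, best_comms = -np.inf, None
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed + r
        )
        q = nx.community.modularity(G, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_comms = q, comms
    ordered = sorted(best_comms, key=lambda c: min(net.nodes.index(v) for v in c))
    labels = {v: i for i, c in enumerate(ordered) for v in c}
    return CommunityPartition(labels, float(best_q), resolution, seed)


def global_metrics(net: NetworkModel) -> Dict[str, float]:
    """Global strength (sum of absolute upper-triangle weights) and density."""
    iu = np.triu_indices(net.p, k=1)
    w = net.W[iu]
    return {
        "global_strength": float(np.abs(w).sum()),
        "density": float(np.count_nonzero(w) / w.size) if w.size else 0.0,
    }


def structure_recovery_frequency(
    data: np.ndarray,
    reference: CommunityPartition,
    n_boot: int = 200,
    seed: int = 0,
    gamma: float = 0.5,
    n_lambda: int = 30,
    resolution: float = 1.0,
    restarts: int = 5,
    ari_threshold: float = 0.8,
    nodes: Optional[Sequence[str]] = None,
    boot_tol: float = 1e-4,
) -> float:
    """Fraction of person-resampled bootstraps recovering the reference partition.

    A bootstrap counts as a recovery when its Louvain partition has the same
    number of communities as the reference and adjusted Rand >= 0.8.
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    node_names = list(nodes) if nodes is not None else None
    ref_nodes = sorted(reference.labels)
    ref_vec = [reference.labels[v] for v in ref_nodes]
    hits = 0
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, n, size=n)
        try:
            net_b = estimate_network(
                X[idx], nodes=node_names, gamma=gamma, n_lambda=n_lambda, tol=boot_tol
            )
            part_b = louvain(net_b, resolution=resolution, seed=seed + b, restarts=restarts)
        except Exception:
            continue
        vec_b = [part_b.labels[v] for v in ref_nodes]
        if part_b.n_communities == reference.n_communities:
            if adjusted_rand_score(ref_vec, vec_b) >= ari_threshold:
                hits += 1
    return hits / n_boot
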