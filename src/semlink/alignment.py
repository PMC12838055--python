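"""Person-level convergence and configuration-level alignment indices.

Two distinct questions are served. Person-level convergence asks how
strongly two instruments' scores covary across people (full Pearson and
Spearman cross-correlation matrices, matched-domain diagonal summaries, and
a facet-level scan with pairwise-complete n per cell). Configuration-level
alignment asks whether the two instruments' facet spaces share the same
*geometry*, independent of person scores: the RV coefficient, Procrustes
similarity after optimal translation/scaling/rotation, distance
correlation, a Mantel permutation test on cosine-distance matrices, and
the first canonical correlation (reported descriptively, with explicit
degeneracy flags when the rank situation forces r1 = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from .scoring import AnchorLexicon, EmbeddingProvider

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Person-level convergence
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    domain_corr_pearson: pd.DataFrame
    domain_corr_spearman: pd.DataFrame
    matched_mean_abs_r: float
    matched_range: Tuple[float, float]
    matched_mean_abs_rho: float
    matching: Dict[str, str]
    n_overlap: int
    facet_corr: Optional[pd.DataFrame] = None
    facet_pairwise_n: Optional[pd.DataFrame] = None
    max_abs_facet_r: Optional[Tuple[float, str, str, int]] = None


def _cross_corr(A: pd.DataFrame, B: pd.DataFrame, method: str) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete cross-correlations and per-cell n."""
    corr = pd.DataFrame(index=A.columns, columns=B.columns, dtype=float)
    ns = pd.DataFrame(index=A.columns, columns=B.columns, dtype=int)
    for a in A.columns:
        for b in B.columns:
            pair = pd.concat([A[a], B[b]], axis=1).dropna()
            ns.loc[a, b] = len(pair)
            if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                corr.loc[a, b] = np.nan
                continue
            if method == "pearson":
                corr.loc[a, b] = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            else:
                corr.loc[a, b] = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
    return corr, ns


def convergence_matrix(
    dm_domains: pd.DataFrame,
    b5_domains: pd.DataFrame,
    matching: Optional[Dict[str, str]] = None,
    dm_facets: Optional[pd.DataFrame] = None,
    b5_facets: Optional[pd.DataFrame] = None,
    min_pairwise_n: int = 10,
) -> ConvergenceReport:
    """Cross-instrument correlation analysis on the overlap sample.

    Inputs are person-indexed DataFrames; persons are matched by index
    intersection and correlations use pairwise-complete observations per
    cell. ``matching`` maps each column of ``dm_domains`` to its counterpart
    in ``b5_domains`` (identity by name when omitted).
    """
    shared = dm_domains.index.intersection(b5_domains.index)
    if len(shared) == 0:
        raise ValueError("no overlapping persons between the two score sets")
    if len(shared) < min_pairwise_n:
        raise ValueError(f"only {len(shared)} overlapping persons (need >= {min_pairwise_n})")
    A = dm_domains.loc[shared]
    B = b5_domains.loc[shared]
    if matching is None:
        matching = {d: d for d in A.columns if d in B.columns}
        if not matching:
            raise ValueError("no shared domain names; supply an explicit matching")

    pear, _ = _cross_corr(A, B, "pearson")
    spear, _ = _cross_corr(A, B, "spearman")
    diag_r = np.array([pear.loc[d, matching[d]] for d in matching])
    diag_rho = np.array([spear.loc[d, matching[d]] for d in matching])

    report = ConvergenceReport(
        domain_corr_pearson=pear,
        domain_corr_spearman=spear,
        matched_mean_abs_r=float(np.nanmean(np.abs(diag_r))),
        matched_range=(float(np.nanmin(diag_r)), float(np.nanmax(diag_r))),
        matched_mean_abs_rho=float(np.nanmean(np.abs(diag_rho))),
        matching=dict(matching),
        n_overlap=int(len(shared)),
    )

    if dm_facets is not None and b5_facets is not None:
        sharedf = dm_facets.index.intersection(b5_facets.index)
        F1, F2 = dm_facets.loc[sharedf], b5_facets.loc[sharedf]
        fc, fn = _cross_corr(F1, F2, "pearson")
        report.facet_corr = fc
        report.facet_pairwise_n = fn
        best = None
        for a in fc.index:
            for b in fc.columns:
                n_cell = int(fn.loc[a, b])
                r = fc.loc[a, b]
                if n_cell < min_pairwise_n or np.isnan(r):
                    continue
                if best is None or abs(r) > abs(best[0]):
                    best = (float(r), str(a), str(b), n_cell)
        if best is not None:
            report.max_abs_facet_r = (abs(best[0]), best[1], best[2], best[3])
    return report


# ---------------------------------------------------------------------------
# Configuration-level alignment indices
# ---------------------------------------------------------------------------

def _center(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X - X.mean(axis=0, keepdims=True)


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV coefficient between two configurations (column-centered)."""
    Xc, Yc = _center(X), _center(Y)
    if Xc.shape[0] != Yc.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    Sx = Xc @ Xc.T
    Sy = Yc @ Yc.T
    denom = np.sqrt(np.sum(Sx * Sx) * np.sum(Sy * Sy))
    if denom == 0:
        raise ValueError("degenerate (all-zero) configuration")
    return float(np.sum(Sx * Sy) / denom)


def procrustes_similarity(X: np.ndarray, Y: np.ndarray) -> float:
    """1 - m^2 after optimal translation, scaling and rotation/reflection.

    The narrower configuration is padded with zero columns so shapes match.
    """
    Xc, Yc = _center(X), _center(Y)
    if Xc.shape[0] != Yc.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if np.allclose(Xc, 0) or np.allclose(Yc, 0):
        raise ValueError("degenerate (zero-variance) configuration")
    q = max(Xc.shape[1], Yc.shape[1])
    if Xc.shape[1] < q:
        Xc = np.hstack([Xc, np.zeros((Xc.shape[0], q - Xc.shape[1]))])
    if Yc.shape[1] < q:
        Yc = np.hstack([Yc, np.zeros((Yc.shape[0], q - Yc.shape[1]))])
    _, _, disparity = _scipy_procrustes(Xc, Yc)
    return float(1.0 - disparity)


def distance_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Sample distance correlation from doubly-centered Euclidean distances."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    if n != Y.shape[0]:
        raise ValueError("same row count required")
    if n < 4:
        raise ValueError("need at least 4 rows")

    def centered(D: np.ndarray) -> np.ndarray:
        return D - D.mean(axis=0) - D.mean(axis=1)[:, None] + D.mean()

    a = squareform(pdist(X))
    b = squareform(pdist(Y))
    if a.max() == 0 or b.max() == 0:
        raise ValueError("constant configuration: distances all zero")
    A, B = centered(a), centered(b)
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    denom = np.sqrt(dvarx * dvary)
    if denom == 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def cosine_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances (1 - cosine similarity) between rows."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm row")
    U = X / norms
    D = 1.0 - U @ U.T
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, None)


def mantel_test(
    D1: np.ndarray,
    D2: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> Tuple[float, float]:
    """One-sided Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the strict upper triangles; p counts
    permutations (simultaneous row/column relabelings of D2) with r at
    least as large as observed, with the +1 correction.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    m = D1.shape[0]
    if m < 4:
        raise ValueError("distance matrices must be at least 4 x 4")
    for D in (D1, D2):
        if D.shape != (m, m) or not np.allclose(D, D.T, atol=1e-10) or np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("inputs must be square symmetric with zero diagonal")
    iu = np.triu_indices(m, k=1)
    x = D1[iu]
    x = (x - x.mean()) / x.std()
    y0 = D2[iu]

    def r_of(y: np.ndarray) -> float:
        return float(np.mean(x * (y - y.mean()) / y.std()))

    r_obs = r_of(y0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        yp = D2[np.ix_(perm, perm)][iu]
        if r_of(yp) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p


def cca_first(
    X: np.ndarray,
    Y: np.ndarray,
    n_components_cap: Optional[int] = None,
) -> Tuple[float, List[str]]:
    """First canonical correlation with explicit rank-degeneracy flags.

    Each side is reduced by principal components to rank at most
    ``min(cap, n - 1, p)``; a flag is raised whenever the retained ranks
    make r1 = 1 a linear-algebra certainty (p_x + p_y >= n), so the value
    can only be read descriptively.
    """
    Xc, Yc = _center(X), _center(Y)
    n = Xc.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    if Yc.shape[0] != n:
        raise ValueError("same row count required")

    def reduce(M: np.ndarray) -> np.ndarray:
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
        r = min(rank, n - 1)
        if n_components_cap is not None:
            r = min(r, n_components_cap)
        return U[:, :r] * s[:r]

    Xr, Yr = reduce(Xc), reduce(Yc)
    px, py = Xr.shape[1], Yr.shape[1]
    flags: List[str] = []
    if px == 0 or py == 0:
        raise ValueError("degenerate configuration with zero rank")
    if px + py >= n:
        flags.append("cca_rank_degenerate: p_x + p_y >= n forces r1 = 1")
    Qx, _ = np.linalg.qr(Xr)
    Qy, _ = np.linalg.qr(Yr)
    s = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    r1 = float(np.clip(s[0], 0.0, 1.0))
    return r1, flags


# ---------------------------------------------------------------------------
# Facet configurations and the combined report
# ---------------------------------------------------------------------------

def facet_configurations(
    lexicon_dm: AnchorLexicon,
    lexicon_b5: AnchorLexicon,
    emb: EmbeddingProvider,
    correspondence: Optional[Dict[str, str]] = None,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Facet-configuration matrices: one row per facet, mean anchor embedding.

    Rows are aligned by the facet correspondence (identity by name when
    omitted); unmatched facets are an error.
    """
    if correspondence is None:
        missing = [f for f in lexicon_dm.facets if f not in lexicon_b5.anchors]
        if missing:
            raise ValueError(f"unmatched facets: {missing}")
        correspondence = {f: f for f in lexicon_dm.facets}
    else:
        missing = [f for f in correspondence.values() if f not in lexicon_b5.anchors]
        if missing:
            raise ValueError(f"unmatched facets: {missing}")
    rows_x, rows_y, names = [], [], []
    for f in lexicon_dm.facets:
        g = correspondence[f]
        rows_x.append(emb.embed_many(lexicon_dm.anchors[f]).mean(axis=0))
        rows_y.append(emb.embed_many(lexicon_b5.anchors[g]).mean(axis=0))
        names.append(f)
    return np.stack(rows_x), np.stack(rows_y), names


@dataclass
class AlignmentReport:
    cca_r1: float
    rv: float
    procrustes_sim: float
    dcor: float
    mantel_r: float
    mantel_p: float
    n_permutations: int
    degeneracy_flags: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, object]:
        return {
            "cca_r1": self.cca_r1,
            "rv": self.rv,
            "procrustes_sim": self.procrustes_sim,
            "dcor": self.dcor,
            "mantel_r": self.mantel_r,
            "mantel_p": self.mantel_p,
            "n_permutations": self.n_permutations,
            "degeneracy_flags": list(self.degeneracy_flags),
        }


def alignment_report(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    cca_cap: Optional[int] = None,
) -> AlignmentReport:
    """All five configuration-alignment indices on row-aligned configurations."""
    r1, flags = cca_first(X, Y, n_components_cap=cca_cap)
    rv = rv_coefficient(X, Y)
    proc = procrustes_similarity(X, Y)
    dc = distance_correlation(X, Y)
    r, p = mantel_test(cosine_distance_matrix(X), cosine_distance_matrix(Y), n_perm=n_perm, seed=seed)
    return AlignmentReport(
        cca_r1=r1,
        rv=rv,
        procrustes_sim=proc,
        dcor=dc,
        mantel_r=r,
        mantel_p=p,
        n_permutations=n_perm,
        degeneracy_flags=flags,
    )
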