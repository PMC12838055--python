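"""Reliability battery: omega coefficients, Schmid-Leiman, bootstrap CIs, ICC.

McDonald's omega total is the proportion of composite variance attributable
to all common factors; omega hierarchical is the share attributable to the
general factor alone, obtained through a Schmid-Leiman orthogonalization of
an oblique group-factor solution. Factor extraction is minimum-residual
(ULS) factoring of the correlation matrix; the oblique rotation is promax
over a varimax start. Percentile bootstrap confidence intervals resample
persons with counter-derived seeds so results are reproducible and
order-independent. The intraclass correlation for absolute agreement,
ICC(A,1)/(A,k), comes from the two-way random-effects ANOVA decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Minimum-residual (ULS) factor extraction
# ---------------------------------------------------------------------------

def minres_factor(R: np.ndarray, n_factors: int, max_iter: int = 500) -> Tuple[np.ndarray, np.ndarray]:
    """Minimum-residual factoring of a correlation matrix.

    Minimizes the sum of squared off-diagonal residuals of ``R - L L'`` over
    the uniquenesses. Returns (loadings k x n_factors, uniquenesses k,).
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if k < 2:
        raise ValueError("need at least 2 indicators")
    if n_factors < 1 or n_factors > k:
        raise ValueError("invalid number of factors")

    def loadings_given_psi(psi: np.ndarray) -> np.ndarray:
        Rs = R - np.diag(psi)
        vals, vecs = np.linalg.eigh(Rs)
        idx = np.argsort(vals)[::-1][:n_factors]
        lam = np.clip(vals[idx], 0.0, None)
        return vecs[:, idx] * np.sqrt(lam)

    def objective(psi: np.ndarray) -> float:
        L = loadings_given_psi(psi)
        resid = R - L @ L.T
        np.fill_diagonal(resid, 0.0)
        return float(np.sum(resid**2) / 2.0)

    # start from squared multiple correlations (bounded away from the edges)
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(k, 0.5)
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        objective,
        psi0,
        method="L-BFGS-B",
        bounds=[(1e-3, 1.0)] * k,
        options={"maxiter": max_iter},
    )
    if not res.success and res.fun > 1e-4:
        logger.warning("minres did not fully converge: %s", res.message)
    L = loadings_given_psi(res.x)
    # sign convention: dominant direction positive per factor
    for j in range(L.shape[1]):
        if L[:, j].sum() < 0:
            L[:, j] = -L[:, j]
    psi = np.clip(1.0 - np.sum(L**2, axis=1), 0.0, 1.0)
    return L, psi


def varimax(L: np.ndarray, eps: float = 1e-6, max_iter: int = 1000) -> Tuple[np.ndarray, np.ndarray]:
    """Kaiser-normalized varimax rotation; returns (rotated loadings, rotation)."""
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    sc = np.sqrt(np.sum(L**2, axis=1))
    sc[sc == 0] = 1.0
    X = L / sc[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Z = X @ T
        B = X.T @ (Z**3 - Z @ np.diag(np.sum(Z**2, axis=0)) / p)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d_old, d = d, float(s.sum())
        if d < d_old * (1 + eps):
            break
    Z = (X @ T) * sc[:, None]
    return Z, T


def promax(L: np.ndarray, power: int = 4) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Promax oblique rotation (varimax start, power-target procrustean fit).

    Returns (pattern loadings, rotation matrix, factor correlation Phi).
    """
    X, rotmat = varimax(np.asarray(L, dtype=float))
    k = X.shape[1]
    if k < 2:
        return X, np.eye(k), np.eye(k)
    Q = X * np.abs(X) ** (power - 1)
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = X @ U
    U_full = rotmat @ U
    Ui = np.linalg.inv(U_full)
    Phi = Ui @ Ui.T
    # orient each factor positively (flips propagate to Phi)
    signs = np.where(pattern.sum(axis=0) < 0, -1.0, 1.0)
    pattern = pattern * signs
    U_full = U_full * signs
    Phi = Phi * np.outer(signs, signs)
    return pattern, U_full, Phi


# ---------------------------------------------------------------------------
# Schmid-Leiman decomposition and omegas
# ---------------------------------------------------------------------------

@dataclass
class SchmidLeimanSolution:
    general_loadings: np.ndarray  # (k,)
    group_loadings: np.ndarray  # (k, n_groups)
    uniquenesses: np.ndarray  # (k,)
    n_groups: int
    factor_correlations: Optional[np.ndarray] = None


def schmid_leiman(R: np.ndarray, n_groups: int) -> SchmidLeimanSolution:
    """Schmid-Leiman orthogonalization of an oblique group-factor solution.

    Group factors are extracted by minres and obliquely rotated; a single
    higher-order factor is fitted to the group-factor correlation matrix;
    its loadings distribute each indicator's common variance into a general
    part and orthogonalized group parts.
    """
    if n_groups < 2:
        raise ValueError("hierarchical partitioning unstable: need >= 2 group factors")
    R = np.asarray(R, dtype=float)
    L, _ = minres_factor(R, n_groups)
    pattern, _, Phi = promax(L)

    # a null group factor (no appreciable loadings) collapses the hierarchy:
    # with a single viable group factor the higher-order factor coincides
    # with it, so all common variance is general
    ssq = np.sum(pattern**2, axis=0)
    viable = ssq > 0.05 * max(ssq.max(), 1e-12)
    if viable.sum() < 2:
        j = int(np.argmax(ssq))
        general = pattern[:, j]
        group = np.zeros_like(pattern)
        psi = np.clip(1.0 - general**2, 0.0, 1.0)
        return SchmidLeimanSolution(
            general_loadings=general,
            group_loadings=group,
            uniquenesses=psi,
            n_groups=n_groups,
            factor_correlations=Phi,
        )

    if n_groups == 2:
        # one factor from a 2x2 correlation matrix is indeterminate up to the
        # product constraint; use the symmetric convention g1 = g2 = sqrt(phi)
        phi12 = float(np.clip(Phi[0, 1], 0.0, 1.0))
        gload = np.full(2, np.sqrt(phi12))
    else:
        gL, _ = minres_factor(Phi, 1)
        gload = np.clip(gL[:, 0], -1.0, 1.0)

    general = pattern @ gload
    group = pattern * np.sqrt(np.clip(1.0 - gload**2, 0.0, 1.0))[None, :]
    common = general**2 + np.sum(group**2, axis=1)
    psi = np.clip(1.0 - common, 0.0, 1.0)
    return SchmidLeimanSolution(
        general_loadings=general,
        group_loadings=group,
        uniquenesses=psi,
        n_groups=n_groups,
        factor_correlations=Phi,
    )


def omega_total(R: np.ndarray, sl: Optional[SchmidLeimanSolution] = None) -> float:
    """McDonald's omega total.

    Single-factor case (default): omega = (sum lambda)^2 / ((sum lambda)^2 +
    sum psi) from a one-factor minres solution. With a Schmid-Leiman
    solution, all common factors (general + groups) count.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[0] < 2:
        raise ValueError("need at least 2 indicators")
    if sl is None:
        L, psi = minres_factor(R, 1)
        lam = L[:, 0]
        num = lam.sum() ** 2
        return float(num / (num + psi.sum()))
    g2 = sl.general_loadings.sum() ** 2
    s2 = float(np.sum(sl.group_loadings.sum(axis=0) ** 2))
    return float((g2 + s2) / (g2 + s2 + sl.uniquenesses.sum()))


def omega_hierarchical(sl: SchmidLeimanSolution) -> float:
    """Omega hierarchical: general-factor share of total composite variance."""
    g2 = sl.general_loadings.sum() ** 2
    s2 = float(np.sum(sl.group_loadings.sum(axis=0) ** 2))
    return float(g2 / (g2 + s2 + sl.uniquenesses.sum()))


# ---------------------------------------------------------------------------
# Bootstrap machinery
# ---------------------------------------------------------------------------

def bootstrap_ci(
    data: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile bootstrap CI over person resampling.

    Resample seeds are derived from the master seed by counter, so results
    do not depend on execution order. Failing resamples are dropped and
    counted; more than 10% failures is an error.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 10:
        raise ValueError("need at least 10 rows for a person bootstrap")
    stats: List[float] = []
    failures = 0
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, n, size=n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val = float(statistic(data[idx]))
            if not np.isfinite(val):
                raise ValueError("non-finite statistic")
            stats.append(val)
        except Exception:
            failures += 1
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"bootstrap failed on {failures}/{n_boot} resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Indicator-level diagnostics
# ---------------------------------------------------------------------------

def item_total_diagnostics(data: np.ndarray) -> Tuple[Dict[int, Optional[float]], Dict[int, float]]:
    """Corrected indicator-total correlations and leave-one-out delta-omega.

    r_it correlates each indicator with the sum of the remaining k-1
    indicators; delta-omega_j = omega(all) - omega(without j). Zero-variance
    indicators get a missing r_it with a warning.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k < 3:
        raise ValueError("need at least 3 indicators")
    r_it: Dict[int, Optional[float]] = {}
    total = data.sum(axis=1)
    for j in range(k):
        col = data[:, j]
        rest = total - col
        if col.std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            logger.warning("indicator %d has zero variance; r_it missing", j)
            r_it[j] = None
        else:
            r_it[j] = float(np.corrcoef(col, rest)[0, 1])

    R = np.corrcoef(data, rowvar=False)
    om_all = omega_total(R)
    loo: Dict[int, float] = {}
    for j in range(k):
        keep = [i for i in range(k) if i != j]
        loo[j] = om_all - omega_total(R[np.ix_(keep, keep)])
    return r_it, loo


# ---------------------------------------------------------------------------
# Intraclass correlation (two-way random effects, absolute agreement)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc_single: float  # ICC(A,1)
    icc_avg: float  # ICC(A,k)
    var_target: float
    var_rater: float
    var_error: float
    ms: Dict[str, float] = field(default_factory=dict)


def icc_absolute(ratings: np.ndarray) -> ICCResult:
    """ICC for absolute agreement under a two-way random-effects model.

    ICC(A,1) = (MS_t - MS_e) / (MS_t + (k-1) MS_e + (k/n)(MS_r - MS_e)).
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("need a targets x raters matrix with >= 2 of each")
    if np.isnan(Y).any():
        raise ValueError("missing cells are not supported")
    n, k = Y.shape
    grand = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ss_t = k * np.sum((row_m - grand) ** 2)
    ss_r = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_e = ss_tot - ss_t - ss_r
    ms_t = ss_t / (n - 1)
    ms_r = ss_r / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    icc1 = (ms_t - ms_e) / (ms_t + (k - 1) * ms_e + (k / n) * (ms_r - ms_e))
    icc_k = (ms_t - ms_e) / (ms_t + (ms_r - ms_e) / n)
    return ICCResult(
        icc_single=float(icc1),
        icc_avg=float(icc_k),
        var_target=float((ms_t - ms_e) / k),
        var_rater=float((ms_r - ms_e) / n),
        var_error=float(ms_e),
        ms={"ms_t": float(ms_t), "ms_r": float(ms_r), "ms_e": float(ms_e)},
    )


# ---------------------------------------------------------------------------
# Domain-level reporting
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityReport:
    domain: str
    k: int
    omega_total: float
    omega_h: Optional[float]
    ci_low: float
    ci_high: float
    n_boot: int
    item_total: Dict[str, Optional[float]]
    loo_delta_omega: Dict[str, float]


def domain_reliability(
    data: np.ndarray,
    indicator_names: Sequence[str],
    domain: str,
    n_groups: Optional[int] = 2,
    n_boot: int = 1000,
    seed: int = 0,
) -> ReliabilityReport:
    """Full per-domain reliability report on a person x indicator matrix.

    Omega hierarchical is refused (None) when the indicator set is too small
    to support at least two viable group factors of >= 3 indicators each.
    """
    data = np.asarray(data, dtype=float)
    k = data.shape[1]
    R = np.corrcoef(data, rowvar=False)
    om = omega_total(R)

    om_h: Optional[float] = None
    if n_groups is not None and n_groups >= 2 and k >= 3 * n_groups:
        try:
            sl = schmid_leiman(R, n_groups)
            om_h = omega_hierarchical(sl)
        except Exception as exc:  # pragma: no cover - diagnostic path
            logger.warning("omega_h not computed for %s: %s", domain, exc)
    else:
        logger.info("omega_h not reported for %s (k=%d too small)", domain, k)

    lo, hi = bootstrap_ci(
        data, lambda d: omega_total(np.corrcoef(d, rowvar=False)), n_boot=n_boot, seed=seed
    )
    r_it, loo = item_total_diagnostics(data)
    names = list(indicator_names)
    return ReliabilityReport(
        domain=domain,
        k=k,
        omega_total=om,
        omega_h=om_h,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        item_total={names[j]: v for j, v in r_it.items()},
        loo_delta_omega={names[j]: v for j, v in loo.items()},
    )
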