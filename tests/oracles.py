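"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive: dense matrices, all-pairs scans,
rank-then-Pearson correlation, exhaustive greedy enumeration. The
oracles share no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


# -- dense restricted-likelihood maximiser (random intercept) ---------------

def dense_restricted_loglik(
    y: np.ndarray,
    groups: np.ndarray,
    X: np.ndarray,
    lam: float,
    method: str = "reml",
) -> tuple[float, np.ndarray, float]:
    """Restricted (or full ML) log-likelihood at variance ratio ``lam``.

    Builds the full N x N covariance V* = I + lam * Z Z' and uses dense
    solves/determinants throughout.
    """
    n = len(y)
    labels, z_idx = np.unique(groups, return_inverse=True)
    Z = np.zeros((n, len(labels)))
    Z[np.arange(n), z_idx] = 1.0
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    A = XtVi @ X
    beta = np.linalg.solve(A, XtVi @ y)
    r = y - X @ beta
    q = float(r @ Vi @ r)
    p = X.shape[1]
    dof = n - p if method == "reml" else n
    s2e = q / dof
    _, logdet_v = np.linalg.slogdet(V)
    ll = -0.5 * (dof * (np.log(2 * np.pi) + np.log(s2e) + 1.0) + logdet_v)
    if method == "reml":
        _, logdet_a = np.linalg.slogdet(A)
        ll -= 0.5 * logdet_a
    return ll, beta, s2e


def dense_reml_fit(
    y: np.ndarray,
    groups: np.ndarray,
    X: np.ndarray,
    method: str = "reml",
    grid: int = 241,
) -> dict:
    """Grid over log10(lam) in [-8, 8] plus golden-section refinement."""
    lams = np.concatenate([[0.0], np.logspace(-8, 8, grid)])
    lls = np.array(
        [dense_restricted_loglik(y, groups, X, l, method)[0] for l in lams]
    )
    i = int(np.argmax(lls))
    lo = lams[max(i - 1, 0)]
    hi = lams[min(i + 1, len(lams) - 1)]
    if i == 0:
        best_lam = 0.0
    else:
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        for _ in range(200):
            c = b - phi * (b - a)
            d = a + phi * (b - a)
            if (
                dense_restricted_loglik(y, groups, X, c, method)[0]
                < dense_restricted_loglik(y, groups, X, d, method)[0]
            ):
                a = c
            else:
                b = d
        best_lam = 0.5 * (a + b)
        if dense_restricted_loglik(y, groups, X, 0.0, method)[0] >= (
            dense_restricted_loglik(y, groups, X, best_lam, method)[0]
        ):
            best_lam = 0.0
    ll, beta, s2e = dense_restricted_loglik(y, groups, X, best_lam, method)
    return {
        "lam": best_lam,
        "beta": beta,
        "sigma2_e": s2e,
        "sigma2_b": best_lam * s2e,
        "loglik": ll,
    }


# -- geometry ---------------------------------------------------------------

def brute_nearest_segment(px, py, geoms, seg_ids, max_dist):
    """All-pairs point-to-polyline distance; min distance then min id."""
    from shapely.geometry import Point

    best = None
    for g, sid in zip(geoms, seg_ids):
        d = g.distance(Point(px, py))
        if d > max_dist:
            continue
        key = (d, sid)
        if best is None or key < best:
            best = key
    return (None, None) if best is None else (best[1], best[0])


# -- statistics -------------------------------------------------------------

def brute_spearman(a, b) -> float:
    ra = stats.rankdata(a, method="average")
    rb = stats.rankdata(b, method="average")
    return float(np.corrcoef(ra, rb)[0, 1])


def brute_sem(values) -> float:
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return np.nan
    m = v.mean()
    sd = np.sqrt(((v - m) ** 2).sum() / (len(v) - 1))
    return sd / np.sqrt(len(v))


def brute_quantile_block(values) -> dict:
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return {
        "min": v[0],
        "q1": q(0.25),
        "median": q(0.5),
        "q3": q(0.75),
        "max": v[-1],
    }


# -- forward-stepwise enumeration ------------------------------------------

def greedy_stepwise_path(y, cov, expected_signs, gain_min=0.01):
    """Enumerate, at each step, every not-yet-entered candidate with a
    statsmodels OLS fit and apply the admissibility rules; return the
    greedy entry path."""
    import statsmodels.api as sm

    selected: list[str] = []
    current = 0.0
    while True:
        best = None
        for cand in cov.columns:
            if cand in selected or cand not in expected_signs:
                continue
            X = sm.add_constant(cov[selected + [cand]].to_numpy())
            res = sm.OLS(y, X).fit()
            coefs = dict(zip(selected + [cand], res.params[1:]))
            if any(
                np.sign(coefs[nm]) != np.sign(expected_signs[nm])
                for nm in selected + [cand]
            ):
                continue
            if res.rsquared_adj - current < gain_min:
                continue
            if best is None or res.rsquared_adj > best[0]:
                best = (res.rsquared_adj, cand)
        if best is None:
            return selected
        current = best[0]
        selected.append(best[1])
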