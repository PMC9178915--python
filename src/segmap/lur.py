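"""Supervised forward stepwise land-use regression (LUR).

Fits the fixed-effects surface: an OLS regression of per-segment
mean-of-means concentrations on land-use covariates, built by the
supervised forward procedure standard in the LUR literature — at each
step add the candidate giving the largest adjusted-R2 gain, subject to
the coefficient carrying its a-priori expected sign (pollution sources
must not enter with negative coefficients), a minimum adjusted-R2 gain,
and no sign flip among already-entered covariates; afterwards remove
covariates that are not statistically significant and refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OLSResult:
    names: list[str]                 # incl. "intercept"
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    fitted: np.ndarray
    r2: float
    adj_r2: float


@dataclass
class LURFit:
    """A fitted LUR surface."""

    selected: list[str]              # covariates in entry order
    beta: pd.Series                  # incl. "intercept"
    se: pd.Series
    pvalues: pd.Series
    fitted: pd.Series                # indexed by segment_id
    r2: float
    adj_r2: float
    n: int
    step_adj_r2: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> OLSResult:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # Identify offending columns via incremental rank.
        bad = []
        r = 0
        for j in range(p):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise np.linalg.LinAlgError(
            f"design matrix is rank-deficient; collinear column(s): {bad}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0  # constant response: nothing to explain
    dof = n - p
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    if dof > 0:
        sigma2 = rss / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    else:
        se = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    return OLSResult(names, beta, se, pvals, fitted, r2, adj_r2)


def _design(cov: pd.DataFrame, names: list[str]) -> np.ndarray:
    return np.column_stack([np.ones(len(cov))] + [cov[n].to_numpy(float) for n in names])


def _signs_ok(res: OLSResult, expected: dict[str, int]) -> bool:
    # Intercept exempt; a zero coefficient never satisfies a sign.
    for name, b in zip(res.names[1:], res.beta[1:]):
        if np.sign(b) != np.sign(expected[name]):
            return False
    return True


def fit_lur(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    expected_signs: dict[str, int],
    *,
    gain_min: float = 0.01,
    p_remove: float = 0.10,
    value_col: str = "mean_of_means",
) -> LURFit:
    """Supervised forward stepwise OLS of segment means on covariates.

    Parameters
    ----------
    summaries : frame with ``segment_id`` and ``value_col`` (the response).
    covariates : per-segment covariate table indexed by segment_id;
        columns listed in ``expected_signs`` are the candidates.
    expected_signs : a-priori coefficient sign (+1/-1) per candidate.
    gain_min : minimum adjusted-R2 gain to enter a covariate.
    p_remove : after selection, covariates with p >= this are dropped
        (iteratively, worst first) and the model refit.
    """
    df = summaries.set_index("segment_id") if "segment_id" in summaries else summaries
    ids = df.index
    cov = covariates.loc[ids]
    y = df[value_col].to_numpy(float)
    candidates = [c for c in covariates.columns if c in expected_signs]
    if len(y) < len(candidates) + 2:
        raise ValueError("need at least p + 2 segments to fit the LUR")

    notes: list[str] = []
    selected: list[str] = []
    current_adj = 0.0                       # intercept-only baseline
    path = [current_adj]
    while True:
        best: tuple[float, str] | None = None
        for cand in candidates:
            if cand in selected:
                continue
            try:
                res = _ols(_design(cov, selected + [cand]), y, ["intercept"] + selected + [cand])
            except np.linalg.LinAlgError:
                continue
            if not _signs_ok(res, expected_signs):
                continue
            if res.adj_r2 - current_adj < gain_min:
                continue
            if best is None or res.adj_r2 > best[0]:
                best = (res.adj_r2, cand)
        if best is None:
            break
        current_adj = best[0]
        selected.append(best[1])
        path.append(current_adj)

    if not selected:
        msg = "no admissible covariate at step 1; returning intercept-only model"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)

    # Backward significance pruning, then a sign-consistency sweep.
    res = _ols(_design(cov, selected), y, ["intercept"] + selected)
    while selected:
        pv = dict(zip(res.names[1:], res.pvalues[1:]))
        worst = max(selected, key=lambda c: pv[c])
        if pv[worst] < p_remove:
            break
        selected.remove(worst)
        notes.append(f"dropped {worst!r} (p = {pv[worst]:.3f} >= {p_remove})")
        res = _ols(_design(cov, selected), y, ["intercept"] + selected)
    while selected and not _signs_ok(res, expected_signs):
        viol = [
            nm
            for nm, b in zip(res.names[1:], res.beta[1:])
            if np.sign(b) != np.sign(expected_signs[nm])
        ]
        for nm in viol:
            selected.remove(nm)
            notes.append(f"dropped {nm!r} (sign flipped after pruning)")
        res = _ols(_design(cov, selected), y, ["intercept"] + selected)

    return LURFit(
        selected=list(selected),
        beta=pd.Series(res.beta, index=res.names),
        se=pd.Series(res.se, index=res.names),
        pvalues=pd.Series(res.pvalues, index=res.names),
        fitted=pd.Series(res.fitted, index=ids, name="lur_pred"),
        r2=res.r2,
        adj_r2=res.adj_r2,
        n=len(y),
        step_adj_r2=path,
        warnings=notes,
    )


def predict_lur(fit: LURFit, covariates: pd.DataFrame) -> pd.Series:
    """Evaluate the fitted surface x_i' beta on a covariate table."""
    missing = [c for c in fit.selected if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate column(s) missing for prediction: {missing}")
    X = _design(covariates, fit.selected)
    beta = fit.beta.loc[["intercept"] + fit.selected].to_numpy()
    return pd.Series(X @ beta, index=covariates.index, name="lur_pred")
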