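"""Random-intercept mixed-effects model on drive-pass segment means.

Model: for segment i with n_i drive-pass means,

    y_ik = x_i' beta + b_i + e_ik,   b_i ~ N(0, sigma2_b),  e_ik ~ N(0, sigma2_e)

with covariates constant within segment. REML (default) or ML
estimation is done by profiling: for a given variance ratio
lambda = sigma2_b / sigma2_e the GLS solution for beta and the
residual variance have closed forms driven by per-segment weights
w_i = n_i / (1 + n_i * lambda), so the restricted likelihood is a
one-dimensional function of lambda maximised by safeguarded bounded
search (boundary lambda = 0 admissible).

The BLUP of the segment intercept is the shrunken deviation

    b_hat_i = [n_i sigma2_b / (sigma2_e + n_i sigma2_b)] (ybar_i - x_i' beta)

so the per-segment prediction x_i' beta + b_hat_i is a convex
combination of the data-only segment mean and the regression surface:
many passes pull it toward the data, few passes toward the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from segmap.lur import LURFit
from segmap.synthetic import StreetNetwork

_LOG2PI = np.log(2.0 * np.pi)
_LAM_LO, _LAM_HI = 1e-8, 1e8


@dataclass
class MixedFit:
    """REML/ML fit of the random-intercept model."""

    beta: pd.Series                  # incl. "intercept"
    beta_se: pd.Series
    sigma2_b: float
    sigma2_e: float
    lam: float                       # sigma2_b / sigma2_e
    loglik: float                    # restricted (REML) or full (ML)
    method: str
    segments: pd.DataFrame           # per measured segment: n_passes, ybar,
                                     # fixed_pred, shrink_w, blup, pred
    selected: list[str]
    n_obs: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    @property
    def blups(self) -> pd.Series:
        return self.segments["blup"]


@dataclass
class _Profiled:
    """Sufficient statistics for the profiled (restricted) likelihood."""

    n: np.ndarray          # (m,) passes per segment
    ybar: np.ndarray       # (m,) segment means of pass means
    ssw: np.ndarray        # (m,) within-segment sum of squares
    X: np.ndarray          # (m, p) segment-level design
    N: int                 # total observations
    frozen_beta: np.ndarray | None = None

    def eval(self, lam: float, method: str) -> tuple[float, np.ndarray, float]:
        """Return (loglik, beta_hat, sigma2_e_hat) at this lambda."""
        w = self.n / (1.0 + self.n * lam)
        if self.frozen_beta is not None:
            beta = self.frozen_beta
            p_eff = 0
            logdet_a = 0.0
        else:
            A = (self.X * w[:, None]).T @ self.X
            c = (self.X * w[:, None]).T @ self.ybar
            beta = np.linalg.solve(A, c)
            p_eff = self.X.shape[1]
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return -np.inf, beta, np.nan
        resid = self.ybar - self.X @ beta
        q = float(self.ssw.sum() + (w * resid**2).sum())
        dof = self.N - p_eff if method == "reml" else self.N
        if q <= 0.0:
            return np.inf, beta, 0.0  # degenerate: zero residual variance
        s2e = q / dof
        log_v = float(np.log1p(self.n * lam).sum())
        ll = -0.5 * (dof * (_LOG2PI + np.log(s2e) + 1.0) + log_v)
        if method == "reml" and self.frozen_beta is None:
            ll -= 0.5 * logdet_a
        return ll, beta, s2e


def _profiled_stats(
    pass_means: pd.DataFrame,
    covariates: pd.DataFrame,
    selected: list[str],
    value_col: str,
) -> tuple[_Profiled, pd.Index]:
    g = pass_means.groupby("segment_id", sort=True)[value_col]
    n = g.count()
    ybar = g.mean()
    # sum of squared deviations from the segment mean: sum(y^2) - n*ybar^2
    sumsq = (
        pass_means[value_col].pow(2).groupby(pass_means["segment_id"]).sum()
        .reindex(n.index)
    )
    ssw = (sumsq - n * ybar**2).clip(lower=0.0)
    ids = n.index
    missing = [c for c in selected if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate column(s) missing: {missing}")
    cov = covariates.loc[ids]
    X = np.column_stack(
        [np.ones(len(ids))] + [cov[c].to_numpy(float) for c in selected]
    )
    prof = _Profiled(
        n=n.to_numpy(float),
        ybar=ybar.to_numpy(float),
        ssw=ssw.to_numpy(float),
        X=X,
        N=int(n.sum()),
    )
    return prof, ids


def fit_mixed(
    pass_means: pd.DataFrame,
    covariates: pd.DataFrame,
    selected: list[str],
    *,
    method: str = "reml",
    freeze_beta: pd.Series | None = None,
    fix_variance_components: tuple[float, float] | None = None,
    value_col: str = "mean_concentration",
) -> MixedFit:
    """Fit the random-intercept model on drive-pass means.

    Parameters
    ----------
    pass_means : frame with segment_id and ``value_col`` (one row per
        drive-pass; passes are the observation unit, unweighted by their
        duration in seconds).
    covariates : per-segment table indexed by segment_id.
    selected : fixed-effect covariate names (typically the LUR selection).
    method : "reml" (default, unbiased variance components) or "ml".
    freeze_beta : optionally freeze the fixed effects at given values
        (Series indexed like the fit's beta, e.g. LUR coefficients) and
        estimate only the variance components.
    fix_variance_components : optionally plug in known (sigma2_b,
        sigma2_e) instead of estimating them; beta is then the GLS
        solution at that variance ratio and BLUPs use the given
        components.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")
    prof, ids = _profiled_stats(pass_means, covariates, selected, value_col)
    m = len(ids)
    if m < 2:
        raise ValueError("need at least 2 segments")
    n_multi = int((prof.n >= 2).sum())
    if n_multi < 2:
        raise ValueError(
            "sigma2_e is not identifiable: need at least 2 segments with "
            f">= 2 drive-passes (found {n_multi})"
        )
    names = ["intercept"] + list(selected)
    if freeze_beta is not None:
        prof.frozen_beta = freeze_beta.reindex(names).to_numpy(float)
        if np.isnan(prof.frozen_beta).any():
            raise ValueError("freeze_beta must provide intercept and all selected names")

    notes: list[str] = []

    def neg_ll(theta: float) -> float:
        ll, _, _ = prof.eval(np.exp(theta), method)
        return -ll if np.isfinite(ll) else np.inf

    if fix_variance_components is not None:
        s2b_fix, s2e_fix = fix_variance_components
        if s2b_fix < 0 or s2e_fix <= 0:
            raise ValueError("need sigma2_b >= 0 and sigma2_e > 0")
        lam = s2b_fix / s2e_fix
        ll_best, beta, _ = prof.eval(lam, method)
        s2e = s2e_fix
        converged = True
        notes.append("variance components supplied, not estimated")
        return _assemble_fit(
            prof, ids, names, beta, lam, s2e, ll_best, method, converged, notes,
            selected, freeze_beta is not None,
        )

    ll0, _, _ = prof.eval(0.0, method)
    degenerate = np.isposinf(ll0)
    if degenerate:
        # All residuals are (numerically) zero: no-noise limit.
        lam, converged = 0.0, True
        notes.append("zero residual variance: degenerate noise-free fit")
        ll_best, beta, s2e = -np.inf, *prof.eval(0.0, method)[1:]
        s2e = 0.0
    else:
        res = minimize_scalar(
            neg_ll,
            bounds=(np.log(_LAM_LO), np.log(_LAM_HI)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        lam_opt = float(np.exp(res.x))
        ll_opt = -res.fun
        # Boundary lambda = 0 is admissible and must be compared.
        if ll0 >= ll_opt or lam_opt <= _LAM_LO * (1 + 1e-6):
            if ll0 >= ll_opt:
                lam, ll_best = 0.0, ll0
            else:
                lam, ll_best = 0.0, prof.eval(0.0, method)[0]
        else:
            lam, ll_best = lam_opt, ll_opt
        converged = bool(res.success)
        _, beta, s2e = prof.eval(lam, method)
        if not np.isfinite(ll_best):
            raise FloatingPointError(
                f"non-finite likelihood at lambda={lam:.3g} "
                f"(sigma2_e={s2e:.3g}, N={prof.N})"
            )

    return _assemble_fit(
        prof, ids, names, beta, lam, s2e, ll_best, method, converged, notes,
        selected, freeze_beta is not None,
    )


def _assemble_fit(
    prof: _Profiled,
    ids: pd.Index,
    names: list[str],
    beta: np.ndarray,
    lam: float,
    s2e: float,
    ll_best: float,
    method: str,
    converged: bool,
    notes: list[str],
    selected: list[str],
    beta_frozen: bool,
) -> MixedFit:
    s2b = lam * s2e
    w_shrink = prof.n * lam / (1.0 + prof.n * lam)  # n*s2b/(s2e + n*s2b)
    resid = prof.ybar - prof.X @ beta
    blups = np.where(lam == 0.0, 0.0, w_shrink * resid)
    preds = prof.X @ beta + blups

    if not beta_frozen and s2e > 0:
        w = prof.n / (1.0 + prof.n * lam)
        A = (prof.X * w[:, None]).T @ prof.X
        beta_se = np.sqrt(np.diag(s2e * np.linalg.inv(A)))
    else:
        beta_se = np.full(len(names), np.nan)

    seg = pd.DataFrame(
        {
            "n_passes": prof.n.astype(int),
            "ybar": prof.ybar,
            "fixed_pred": prof.X @ beta,
            "shrink_w": w_shrink,
            "blup": blups,
            "pred": preds,
        },
        index=ids,
    )
    return MixedFit(
        beta=pd.Series(beta, index=names),
        beta_se=pd.Series(beta_se, index=names),
        sigma2_b=float(s2b),
        sigma2_e=float(s2e),
        lam=float(lam),
        loglik=float(ll_best) if np.isfinite(ll_best) else np.inf,
        method=method,
        segments=seg,
        selected=list(selected),
        n_obs=prof.N,
        converged=converged,
        notes=notes,
    )


def blup(fit: MixedFit, segment_id) -> float:
    """Predicted random intercept b_hat_i for a measured segment."""
    try:
        return float(fit.segments.loc[segment_id, "blup"])
    except KeyError:
        raise KeyError(f"segment {segment_id!r} has no drive-passes in this fit")


def fit_mixed_from_lur(
    pass_means: pd.DataFrame,
    covariates: pd.DataFrame,
    lur_fit: LURFit,
    *,
    method: str = "reml",
    freeze_beta: bool = False,
    value_col: str = "mean_concentration",
) -> MixedFit:
    """Two-stage fit: LUR-selected covariates feed the mixed model.

    With ``freeze_beta`` the LUR coefficients are used as-is and only
    variance components are estimated; otherwise (default) the fixed
    effects are re-estimated by GLS inside the mixed fit.
    """
    return fit_mixed(
        pass_means,
        covariates,
        lur_fit.selected,
        method=method,
        freeze_beta=lur_fit.beta if freeze_beta else None,
        value_col=value_col,
    )


def predict_map(
    fit: MixedFit,
    network: StreetNetwork,
    *,
    facade_adjust: float | None = None,
) -> pd.DataFrame:
    """Per-segment mixed-map predictions for a whole network.

    Measured segments get x_i' beta + b_hat_i; segments without any
    drive-pass fall back to the regression surface alone and are flagged
    ``lur_only``. ``facade_adjust`` optionally scales all predictions
    (e.g. 0.8 to move on-road levels toward facade levels).
    """
    cov = network.covariates
    missing = [c for c in fit.selected if c not in cov.columns]
    if missing:
        raise KeyError(f"covariate column(s) missing: {missing}")
    X = np.column_stack(
        [np.ones(len(cov))] + [cov[c].to_numpy(float) for c in fit.selected]
    )
    lur_pred = X @ fit.beta.loc[["intercept"] + fit.selected].to_numpy()
    out = pd.DataFrame(
        {
            "segment_id": cov.index,
            "lur_pred": lur_pred,
            "blup": 0.0,
            "n_passes": 0,
            "shrink_w": 0.0,
            "lur_only": True,
        }
    ).set_index("segment_id")
    seg = fit.segments
    idx = out.index.intersection(seg.index)
    out.loc[idx, "blup"] = seg.loc[idx, "blup"]
    out.loc[idx, "n_passes"] = seg.loc[idx, "n_passes"]
    out.loc[idx, "shrink_w"] = seg.loc[idx, "shrink_w"]
    out.loc[idx, "lur_only"] = False
    out["mixed_pred"] = out["lur_pred"] + out["blup"]
    if facade_adjust is not None:
        out["lur_pred"] *= facade_adjust
        out["mixed_pred"] *= facade_adjust
    return out.reset_index()
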