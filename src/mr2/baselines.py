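"""Single-outcome reference methods: IVW, MV-MR and MV-MR-Egger.

These are the standard weighted-regression MR estimators fitted one
outcome at a time: the variant-outcome associations are regressed on the
variant-exposure associations with first-order weights se(beta_Y)^-2 and a
multiplicative overdispersion delta^2 >= 1 inflating the standard errors.
The Egger variant adds an intercept absorbing directional pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import SummaryData


@dataclass
class MvmrFit:
    theta: np.ndarray        # (p,) or (1,) causal effect estimates
    se: np.ndarray
    pvalues: np.ndarray
    delta2: float            # overdispersion, truncated at 1
    outcome: str
    exposure_names: list = field(default_factory=list)
    egger: bool = False
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None


def _wls(y, X, w, df_resid):
    fit = sm.WLS(y, X, weights=w).fit()
    scale = float(fit.scale)              # residual mean square (weighted)
    delta2 = max(1.0, scale)
    se = fit.bse * np.sqrt(delta2 / scale) if scale > 0 else fit.bse
    with np.errstate(divide="ignore"):
        tvals = np.where(se > 0, fit.params / np.where(se > 0, se, 1.0),
                         np.inf * np.sign(fit.params))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return fit.params, se, pvals, delta2


def fit_univariable_ivw(data: SummaryData, exposure: int = 0, outcome: int = 0
                        ) -> MvmrFit:
    """Classical univariable IVW MR of one outcome on one exposure.

    Weighted least squares without intercept, weights se(beta_Y)^-2;
    the overdispersion estimate is truncated below at 1 (the fixed-effect
    model is the floor).
    """
    if data.n < 3:
        raise ValueError("need at least 3 variants")
    x = data.beta_x[:, exposure]
    if np.var(x) == 0:
        raise ValueError(
            f"exposure column {data.exposure_names[exposure]!r} has zero "
            "variance")
    y = data.beta_y[:, outcome]
    w = data.se_y[:, outcome] ** -2.0
    params, se, pvals, delta2 = _wls(y, x[:, None], w, data.n - 1)
    return MvmrFit(theta=np.asarray(params), se=np.asarray(se),
                   pvalues=np.asarray(pvals), delta2=delta2,
                   outcome=data.outcome_names[outcome],
                   exposure_names=[data.exposure_names[exposure]])


def fit_mvmr(data: SummaryData, outcome: int = 0, egger: bool = False
             ) -> MvmrFit:
    """Multivariable MR (all exposures jointly) for one outcome.

    Weighted multivariable regression of the variant-outcome associations
    on the variant-exposure associations; ``egger=True`` adds an intercept
    capturing unmeasured directional pleiotropy.
    """
    p = data.p
    need = p + (2 if egger else 1)
    if data.n < need:
        raise ValueError(f"need n > p{' + 1 (Egger)' if egger else ''}: "
                         f"n={data.n}, p={p}")
    X = data.beta_x
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"exposure design is rank deficient (rank {rank} < {p}); most "
            f"collinear pair: {data.exposure_names[i]!r} / "
            f"{data.exposure_names[j]!r}")
    if egger:
        X = sm.add_constant(X, prepend=True)
    y = data.beta_y[:, outcome]
    w = data.se_y[:, outcome] ** -2.0
    df = data.n - X.shape[1]
    params, se, pvals, delta2 = _wls(y, X, w, df)
    if egger:
        return MvmrFit(theta=params[1:], se=se[1:], pvalues=pvals[1:],
                       delta2=delta2, outcome=data.outcome_names[outcome],
                       exposure_names=list(data.exposure_names), egger=True,
                       intercept=float(params[0]), intercept_se=float(se[0]),
                       intercept_pvalue=float(pvals[0]))
    return MvmrFit(theta=params, se=se, pvalues=pvals, delta2=delta2,
                   outcome=data.outcome_names[outcome],
                   exposure_names=list(data.exposure_names))


def fit_mvmr_all(data: SummaryData, egger: bool = False):
    """Fit every outcome; returns (theta_hat, pvalues) as (q, p) arrays
    plus the per-outcome fit objects."""
    fits = [fit_mvmr(data, k, egger=egger) for k in range(data.q)]
    theta = np.vstack([f.theta for f in fits])
    pvals = np.vstack([f.pvalues for f in fits])
    return theta, pvals, fits
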