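"""Correlated-instrument IVW and MR-Egger via generalized least squares.

With harmonized exposure effects ``bx``, outcome effects ``by`` with standard
errors ``sy`` and signed instrument correlation matrix ``r``, the outcome
effects are modelled as

    by ~ N(X theta, Omega),   Omega[j, l] = sy_j sy_l r[j, l],

with design X = [bx] (IVW) or X = [1, bx] (MR-Egger, after orienting all
exposure effects positive).  The GLS solution is

    theta_hat = (X' Omega^-1 X)^-1 X' Omega^-1 by,

with heterogeneity Q = (by - X theta)' Omega^-1 (by - X theta) and a
multiplicative overdispersion factor phi = max(1, Q / (k - p)) inflating the
coefficient covariance.  Whitened residuals e = L^-1 (by - X theta) for
Omega = L L' give per-variant chi^2(1)-scale outlier statistics, and the
whitened hat matrix gives leverages; instruments beyond 3x the mean leverage
or with e_j^2 above a chi^2 cut (default 10.83, the 0.001 tail) are pruned
one at a time with refitting.  Model choice between IVW and Egger uses the
heterogeneity difference Q_IVW - Q_Egger against a one-degree-of-freedom
cost (default 3.84).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .instruments import InstrumentSet
from .sumstats import CisMRError, ConfigError, VariantKey

logger = logging.getLogger("cismr")

Z95 = float(stats.norm.ppf(0.975))


class EstimationError(CisMRError):
    """GLS fit could not be computed."""


@dataclass
class FitConfig:
    """Pruning and model-selection settings for the MR estimators."""

    leverage_multiplier: float = 3.0
    outlier_chi2: float = 10.83
    q_select_crit: float = 3.84
    min_k_ivw: int = 2
    min_k_egger: int = 3
    max_prune_iter: int = 20
    condition_limit: float = 1e8

    def __post_init__(self) -> None:
        for name in ("leverage_multiplier", "outlier_chi2", "q_select_crit", "min_k_ivw", "min_k_egger", "max_prune_iter"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class GLSFit:
    """Raw GLS fit: coefficients, covariance and residual diagnostics."""

    theta: np.ndarray
    cov: np.ndarray  # overdispersion-inflated
    Q: float
    df: int
    phi: float
    resid_whitened: np.ndarray
    leverage: np.ndarray
    with_intercept: bool

    @property
    def slope(self) -> float:
        return float(self.theta[-1])

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.cov[-1, -1]))

    @property
    def intercept(self) -> float | None:
        return float(self.theta[0]) if self.with_intercept else None

    @property
    def intercept_se(self) -> float | None:
        return float(np.sqrt(self.cov[0, 0])) if self.with_intercept else None


def gls_design(bx: np.ndarray, with_intercept: bool) -> np.ndarray:
    x = np.asarray(bx, float)[:, None]
    return np.column_stack([np.ones(len(x)), x]) if with_intercept else x


def gls_fit(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    ld_r: np.ndarray,
    with_intercept: bool = False,
    condition_limit: float = 1e8,
) -> GLSFit:
    """Fit by ~ X theta with GLS under Omega = diag(sy) R diag(sy)."""
    bx, by, sy = (np.asarray(v, float) for v in (bx, by, sy))
    k = len(bx)
    p = 2 if with_intercept else 1
    if k < p + 1:
        raise EstimationError(f"need at least {p + 1} instruments for this fit, got {k}")
    X = gls_design(bx, with_intercept)
    omega = np.outer(sy, sy) * np.asarray(ld_r, float)
    try:
        L = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "instrument covariance is singular; increase the LD ridge regularization"
        ) from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, by, lower=True)
    if p > 1:
        cond = np.linalg.cond(Xw)
        if cond > condition_limit:
            raise EstimationError(f"design columns are collinear (condition number {cond:.3g})")
    xtx = Xw.T @ Xw
    xtx_inv = np.linalg.inv(xtx)
    theta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ theta
    Q = float(resid @ resid)
    df = k - p
    phi = max(1.0, Q / df) if df > 0 else 1.0
    leverage = np.einsum("ij,jk,ik->i", Xw, xtx_inv, Xw)
    return GLSFit(theta, xtx_inv * phi, Q, df, phi, resid, leverage, with_intercept)


def fit_instrument_set(iset: InstrumentSet, with_intercept: bool, config: FitConfig = FitConfig()) -> GLSFit:
    return gls_fit(iset.bx, iset.by, iset.sy, iset.ld.r, with_intercept, config.condition_limit)


def orient_for_egger(iset: InstrumentSet) -> InstrumentSet:
    """Flip instruments with negative exposure effects to the positive sign.

    Egger's intercept requires a sign convention; flipping bx_j, by_j and row
    and column j of the LD matrix is a pure re-orientation that leaves IVW
    invariant.  Idempotent; flipped variant keys are recorded in ``meta``.
    """
    flip = iset.bx < 0
    if not flip.any():
        return iset
    s = np.where(flip, -1.0, 1.0)
    keys = [
        VariantKey(v.chrom, v.pos, v.oa, v.ea, v.rsid) if fl else v
        for v, fl in zip(iset.variants, flip)
    ]
    ld = type(iset.ld)(keys, iset.ld.r * np.outer(s, s), iset.ld.n_ref)
    meta = dict(iset.meta)
    meta["egger_orientation_flips"] = [str(v) for v, fl in zip(iset.variants, flip) if fl]
    return InstrumentSet(
        iset.exposure_name,
        iset.outcome_name,
        keys,
        iset.bx * s,
        iset.sx,
        iset.by * s,
        iset.sy,
        iset.f_stats,
        ld,
        meta,
    )


def prune_instruments(
    iset: InstrumentSet,
    config: FitConfig = FitConfig(),
    with_intercept: bool = False,
) -> tuple[InstrumentSet, list[dict]]:
    """Iteratively remove high-leverage / outlying instruments.

    Each round fits the GLS model, flags variants with leverage above
    ``leverage_multiplier`` times the mean leverage or squared whitened
    residual above ``outlier_chi2``, and removes the single worst offender
    (largest squared residual, ties broken by leverage).  Stops when nothing
    is flagged, k reaches the method minimum, or ``max_prune_iter`` rounds.
    """
    min_k = config.min_k_egger if with_intercept else config.min_k_ivw
    pruned: list[dict] = []
    current = iset
    for _ in range(config.max_prune_iter):
        if current.k <= min_k:
            break
        fit = fit_instrument_set(current, with_intercept, config)
        e2 = fit.resid_whitened**2
        lev_cut = config.leverage_multiplier * fit.leverage.mean()
        flagged = (e2 > config.outlier_chi2) | (fit.leverage > lev_cut)
        if not flagged.any():
            break
        order = np.lexsort((fit.leverage, e2))  # last entry = worst
        worst = next(i for i in order[::-1] if flagged[i])
        reason = "outlier" if e2[worst] > config.outlier_chi2 else "leverage"
        pruned.append(
            {
                "variant": current.variants[worst],
                "reason": reason,
                "value": float(e2[worst] if reason == "outlier" else fit.leverage[worst]),
            }
        )
        current = current.subset([i for i in range(current.k) if i != worst])
    return current, pruned


@dataclass
class MREstimate:
    """Fitted causal effect with heterogeneity statistics and pruning audit trail."""

    method: str  # "IVW" or "Egger"
    alpha_hat: float
    alpha_se: float
    ci_low: float
    ci_high: float
    pvalue: float
    Q: float
    df: int
    phi: float
    k_used: int
    k_initial: int
    Q_ivw: float
    Q_egger: float | None
    b0: float | None = None
    b0_se: float | None = None
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    pruned: list[dict] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.alpha_se <= 0:
            raise EstimationError("alpha_se must be positive")
        if not (self.ci_low <= self.alpha_hat <= self.ci_high):
            raise EstimationError("confidence interval must bracket the estimate")


def _estimate_from_fit(fit: GLSFit) -> tuple[float, float, float, float, float]:
    a, se = fit.slope, fit.slope_se
    ci_low, ci_high = a - Z95 * se, a + Z95 * se
    p = float(np.clip(2 * stats.norm.sf(abs(a / se)), 5e-324, 1.0))
    return a, se, ci_low, ci_high, p


def run_cis_mr(
    iset: InstrumentSet,
    config: FitConfig = FitConfig(),
    binary: bool = False,
) -> MREstimate:
    """Pruned IVW / MR-Egger with Q-difference model selection.

    Pruning runs in the IVW parameterization; MR-Egger is then fitted on the
    sign-oriented pruned set when enough instruments remain, and selected iff
    Q_IVW - Q_Egger exceeds ``q_select_crit``.  For binary outcomes the
    estimate is also reported as an odds ratio per SD of exposure.
    """
    if iset.k < config.min_k_ivw:
        raise EstimationError(f"need at least {config.min_k_ivw} instruments, got {iset.k}")
    k_initial = iset.k
    pruned_set, pruned = prune_instruments(iset, config, with_intercept=False)

    ivw = fit_instrument_set(pruned_set, with_intercept=False, config=config)
    note = ""
    egger = None
    if pruned_set.k >= config.min_k_egger:
        egger = fit_instrument_set(orient_for_egger(pruned_set), with_intercept=True, config=config)
    else:
        note = "too few instruments for Egger; IVW reported without model selection"
        logger.info("%s vs %s: %s", iset.exposure_name, iset.outcome_name, note)

    use_egger = egger is not None and (ivw.Q - egger.Q) > config.q_select_crit
    fit = egger if use_egger else ivw
    a, se, lo, hi, p = _estimate_from_fit(fit)
    est = MREstimate(
        method="Egger" if use_egger else "IVW",
        alpha_hat=a,
        alpha_se=se,
        ci_low=lo,
        ci_high=hi,
        pvalue=p,
        Q=fit.Q,
        df=fit.df,
        phi=fit.phi,
        k_used=pruned_set.k,
        k_initial=k_initial,
        Q_ivw=ivw.Q,
        Q_egger=egger.Q if egger is not None else None,
        b0=fit.intercept,
        b0_se=fit.intercept_se,
        pruned=pruned,
        note=note,
    )
    if binary:
        est.odds_ratio = float(np.exp(a))
        est.or_ci_low = float(np.exp(lo))
        est.or_ci_high = float(np.exp(hi))
    return est
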