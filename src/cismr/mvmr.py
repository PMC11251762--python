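"""Two-exposure multivariable MR with GLS.

Joint regression of outcome effects on both exposures' effect vectors,
``by ~ alpha1 * bx1 + alpha2 * bx2 (+ intercept)``, under the same
LD-aware covariance as the univariable estimators.  The resulting effects
are mutually adjusted: when two co-located genes' signals are entangled by
LD, the multivariable slope for the non-causal protein is centred on zero
while its univariable estimate is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .estimators import EstimationError, FitConfig, GLSFit, Z95
from .instruments import SelectionConfig, SelectionError, compute_f_stats
from .meta import clump
from .sumstats import (
    ConfigError,
    GeneRegion,
    LDMatrix,
    MATCH_COLS,
    SummaryStats,
    VariantKey,
    harmonize,
)

logger = logging.getLogger("cismr")


@dataclass
class MVMRInput:
    """Harmonized two-exposure/outcome instrument data for one locus pair."""

    exposure_names: tuple[str, str]
    outcome_name: str
    variants: list[VariantKey]
    bx1: np.ndarray
    sx1: np.ndarray
    bx2: np.ndarray
    sx2: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    ld: LDMatrix

    def __post_init__(self) -> None:
        k = len(self.variants)
        for name in ("bx1", "sx1", "bx2", "sx2", "by", "sy", "f1", "f2"):
            v = np.asarray(getattr(self, name), float)
            setattr(self, name, v)
            if v.shape != (k,):
                raise ConfigError(f"{name} must have length {k}")
        if k < 3:
            raise ConfigError(f"multivariable MR needs at least 3 instruments, got {k}")
        if (self.sx1 <= 0).any() or (self.sx2 <= 0).any() or (self.sy <= 0).any():
            raise ConfigError("all standard errors must be > 0")
        if len(self.ld.variants) != k:
            raise ConfigError("LD matrix dimension must equal the number of instruments")

    @property
    def k(self) -> int:
        return len(self.variants)

    def subset(self, indices: Sequence[int]) -> "MVMRInput":
        idx = list(indices)
        keys = [self.variants[i] for i in idx]
        return MVMRInput(
            self.exposure_names,
            self.outcome_name,
            keys,
            self.bx1[idx],
            self.sx1[idx],
            self.bx2[idx],
            self.sx2[idx],
            self.by[idx],
            self.sy[idx],
            self.f1[idx],
            self.f2[idx],
            self.ld.aligned_submatrix(keys),
        )

    def swap_exposures(self) -> "MVMRInput":
        return MVMRInput(
            (self.exposure_names[1], self.exposure_names[0]),
            self.outcome_name,
            list(self.variants),
            self.bx2,
            self.sx2,
            self.bx1,
            self.sx1,
            self.by,
            self.sy,
            self.f2,
            self.f1,
            self.ld,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": [str(v) for v in self.variants],
                "bx1": self.bx1,
                "sx1": self.sx1,
                "bx2": self.bx2,
                "sx2": self.sx2,
                "by": self.by,
                "sy": self.sy,
                "f1": self.f1,
                "f2": self.f2,
            }
        )


def select_joint_instruments(
    meta1: SummaryStats,
    meta2: SummaryStats,
    region1: GeneRegion,
    region2: GeneRegion,
    outcome: SummaryStats,
    ld: LDMatrix,
    config: SelectionConfig = SelectionConfig(),
) -> MVMRInput:
    """Instrument selection over the union of the two gene windows.

    Candidates must be measured for both exposures; clumping uses the smaller
    of the two exposure p-values; a variant is retained when it is a strong
    instrument (F >= f_min) for at least one exposure.  All three datasets
    are harmonized to exposure 1's allele orientation.
    """
    if region1.chromosome != region2.chromosome:
        raise ConfigError("joint instrument selection requires both regions on one chromosome")
    lo1, hi1 = region1.window(config.flank_bp)
    lo2, hi2 = region2.window(config.flank_bp)

    def in_union(ss: SummaryStats) -> SummaryStats:
        df = ss.df
        m = (df["chrom"] == region1.chromosome) & (
            df["pos"].between(lo1, hi1) | df["pos"].between(lo2, hi2)
        )
        return SummaryStats(ss.study_name, df[m].reset_index(drop=True))

    w1 = in_union(meta1)
    if len(w1) == 0:
        raise SelectionError("window", "exposure 1 has no variants in the union window")
    w2_all = in_union(meta2)
    if len(w2_all) == 0:
        raise SelectionError("window", "exposure 2 has no variants in the union window")
    w2, _ = harmonize(w2_all, w1, config.palindrome_maf_limit)

    merged = w1.df.merge(
        w2.df[MATCH_COLS + ["beta", "se", "pvalue"]].rename(
            columns={"beta": "bx2", "se": "sx2", "pvalue": "p2"}
        ),
        on=MATCH_COLS,
        how="inner",
    )
    if merged.empty:
        raise SelectionError("exposure_overlap", "no variants measured for both exposures")

    maf = np.minimum(merged["eaf"], 1 - merged["eaf"])
    merged = merged[maf >= config.maf_min]
    if merged.empty:
        raise SelectionError("maf", f"no joint candidates with MAF >= {config.maf_min}")

    pmin = np.minimum(merged["pvalue"], merged["p2"])
    clump_table = SummaryStats(w1.study_name, merged.assign(pvalue=pmin).drop(columns=["bx2", "sx2", "p2"]))
    leads = {v.match_key for v in clump(clump_table, ld, p_threshold=1.0, r2_threshold=config.clump_r2)}
    merged = merged[[tuple(t) in leads for t in merged[MATCH_COLS].to_numpy()]]

    f1 = compute_f_stats(merged["beta"].to_numpy(), merged["se"].to_numpy())
    f2 = compute_f_stats(merged["bx2"].to_numpy(), merged["sx2"].to_numpy())
    keep = np.maximum(f1, f2) >= config.f_min
    merged, f1, f2 = merged[keep], f1[keep], f2[keep]
    if merged.empty:
        raise SelectionError("f_stat", f"no joint instruments with max(F1, F2) >= {config.f_min}")

    exposure_sel = SummaryStats(w1.study_name, merged.drop(columns=["bx2", "sx2", "p2"]).reset_index(drop=True))
    lo, hi = min(lo1, lo2), max(hi1, hi2)
    outcome_window = outcome.in_window(region1.chromosome, lo, hi)
    if len(outcome_window) == 0:
        raise SelectionError("outcome_window", f"outcome {outcome.study_name!r} has no variants in the window")
    outcome_h, _ = harmonize(outcome_window, exposure_sel, config.palindrome_maf_limit)
    final = merged.reset_index(drop=True).assign(f1=f1, f2=f2).merge(
        outcome_h.df[MATCH_COLS + ["beta", "se"]].rename(columns={"beta": "by", "se": "sy"}),
        on=MATCH_COLS,
        how="inner",
    )
    if len(final) < 3:
        raise SelectionError("outcome_overlap", f"only {len(final)} joint instruments shared with the outcome")

    keys = [
        VariantKey(r.chrom, int(r.pos), r.ea, r.oa, r.rsid if isinstance(r.rsid, str) else None)
        for r in final.itertuples()
    ]
    return MVMRInput(
        (meta1.study_name, meta2.study_name),
        outcome.study_name,
        keys,
        final["beta"].to_numpy(float),
        final["se"].to_numpy(float),
        final["bx2"].to_numpy(float),
        final["sx2"].to_numpy(float),
        final["by"].to_numpy(float),
        final["sy"].to_numpy(float),
        final["f1"].to_numpy(float),
        final["f2"].to_numpy(float),
        ld.aligned_submatrix(keys),
    )


@dataclass
class MVMREstimate:
    """Mutually adjusted causal effects of two exposures on one outcome."""

    method: str  # "MVMR" or "MVMR-Egger"
    exposure_names: tuple[str, str]
    outcome_name: str
    alpha1_hat: float
    alpha1_se: float
    alpha2_hat: float
    alpha2_se: float
    p1: float
    p2: float
    Q: float
    df: int
    phi: float
    k_used: int
    k_initial: int
    Q_mvmr: float
    Q_egger: float | None
    intercept: float | None = None
    intercept_se: float | None = None
    pruned: list[dict] = field(default_factory=list)
    note: str = ""


def _mvmr_design(inp: MVMRInput, with_intercept: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design, outcome and LD, oriented on exposure 1's effect signs for Egger."""
    if with_intercept:
        s = np.where(inp.bx1 < 0, -1.0, 1.0)
        X = np.column_stack([np.ones(inp.k), s * inp.bx1, s * inp.bx2])
        return X, s * inp.by, inp.ld.r * np.outer(s, s)
    return np.column_stack([inp.bx1, inp.bx2]), inp.by, inp.ld.r


def _gls_solve(X: np.ndarray, y: np.ndarray, sy: np.ndarray, r: np.ndarray, condition_limit: float) -> GLSFit:
    k, p = X.shape
    omega = np.outer(sy, sy) * r
    try:
        L = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("instrument covariance is singular; increase the LD ridge") from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    cond = np.linalg.cond(Xw)
    if cond > condition_limit:
        raise EstimationError(f"design columns are collinear (condition number {cond:.3g})")
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    theta = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ theta
    Q = float(resid @ resid)
    df = k - p
    phi = max(1.0, Q / df) if df > 0 else 1.0
    leverage = np.einsum("ij,jk,ik->i", Xw, xtx_inv, Xw)
    return GLSFit(theta, xtx_inv * phi, Q, df, phi, resid, leverage, with_intercept=(p == 3))


def gls_mvmr(
    inp: MVMRInput,
    with_intercept: bool = False,
    config: FitConfig = FitConfig(),
) -> GLSFit:
    """Raw multivariable GLS fit (intercept oriented on exposure 1's signs)."""
    p = 3 if with_intercept else 2
    if inp.k < p + 1:
        raise EstimationError(f"need at least {p + 1} instruments for this fit, got {inp.k}")
    X, y, r = _mvmr_design(inp, with_intercept)
    return _gls_solve(X, y, inp.sy, r, config.condition_limit)


def _prune_mvmr(inp: MVMRInput, config: FitConfig, with_intercept: bool) -> tuple[MVMRInput, list[dict]]:
    min_k = (3 if with_intercept else 2) + 1
    pruned: list[dict] = []
    current = inp
    for _ in range(config.max_prune_iter):
        if current.k <= min_k:
            break
        fit = gls_mvmr(current, with_intercept, config)
        e2 = fit.resid_whitened**2
        lev_cut = config.leverage_multiplier * fit.leverage.mean()
        flagged = (e2 > config.outlier_chi2) | (fit.leverage > lev_cut)
        if not flagged.any():
            break
        order = np.lexsort((fit.leverage, e2))
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


def run_mvmr(inp: MVMRInput, config: FitConfig = FitConfig()) -> MVMREstimate:
    """Pruned MVMR with Q-difference selection between plain and Egger variants."""
    k_initial = inp.k
    pruned_inp, pruned = _prune_mvmr(inp, config, with_intercept=False)
    plain = gls_mvmr(pruned_inp, with_intercept=False, config=config)
    egger = None
    note = ""
    if pruned_inp.k >= 4:
        try:
            egger = gls_mvmr(pruned_inp, with_intercept=True, config=config)
        except EstimationError as exc:
            note = f"MVMR-Egger not fitted: {exc}"
    else:
        note = "too few instruments for MVMR-Egger; MVMR reported without model selection"

    use_egger = egger is not None and (plain.Q - egger.Q) > config.q_select_crit
    fit = egger if use_egger else plain
    off = 1 if use_egger else 0
    a1, a2 = float(fit.theta[off]), float(fit.theta[off + 1])
    se1 = float(np.sqrt(fit.cov[off, off]))
    se2 = float(np.sqrt(fit.cov[off + 1, off + 1]))
    p1 = float(np.clip(2 * stats.norm.sf(abs(a1 / se1)), 5e-324, 1.0))
    p2 = float(np.clip(2 * stats.norm.sf(abs(a2 / se2)), 5e-324, 1.0))
    return MVMREstimate(
        method="MVMR-Egger" if use_egger else "MVMR",
        exposure_names=inp.exposure_names,
        outcome_name=inp.outcome_name,
        alpha1_hat=a1,
        alpha1_se=se1,
        alpha2_hat=a2,
        alpha2_se=se2,
        p1=p1,
        p2=p2,
        Q=fit.Q,
        df=fit.df,
        phi=fit.phi,
        k_used=pruned_inp.k,
        k_initial=k_initial,
        Q_mvmr=plain.Q,
        Q_egger=egger.Q if egger is not None else None,
        intercept=float(fit.theta[0]) if use_egger else None,
        intercept_se=float(np.sqrt(fit.cov[0, 0])) if use_egger else None,
        pruned=pruned,
        note=note,
    )
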