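"""DerSimonian–Laird random-effects meta-analysis, LD clumping, cis/trans assignment.

Per variant, study-specific effects are pooled with inverse-variance weights
after adding the moment-estimated between-study variance tau^2:

    w_s     = 1 / se_s^2
    beta_FE = sum(w beta) / sum(w)
    Q       = sum(w (beta - beta_FE)^2)
    tau^2   = max(0, (Q - (S - 1)) / (sum(w) - sum(w^2) / sum(w)))
    w*_s    = 1 / (se_s^2 + tau^2)

pooled beta = sum(w* beta) / sum(w*), pooled se = sqrt(1 / sum(w*)).
Variants present in only a subset of studies are pooled over the available
studies (k_studies recorded), matching standard METAL behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    CisMRError,
    ConfigError,
    GeneRegion,
    LDMatrix,
    MATCH_COLS,
    SummaryStats,
    VariantKey,
    harmonize,
)

logger = logging.getLogger("cismr")

META_COLUMNS = ("Q_het", "tau2", "i2", "k_studies")


@dataclass
class MetaRow:
    """Pooled result for a single variant."""

    pooled_beta: float
    pooled_se: float
    pvalue: float
    Q_het: float
    tau2: float
    i2: float
    k_studies: int


def _dl_pool(B: np.ndarray, SE: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized DL pooling over a (variants x studies) array with NaN gaps."""
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(np.isnan(B), 0.0, 1.0 / SE**2)
        Bz = np.where(np.isnan(B), 0.0, B)
        k = (W > 0).sum(axis=1)
        sumw = W.sum(axis=1)
        beta_fe = (W * Bz).sum(axis=1) / sumw
        Q = (W * (Bz - beta_fe[:, None]) ** 2 * (W > 0)).sum(axis=1)
        denom = sumw - (W**2).sum(axis=1) / sumw
        tau2 = np.where((k > 1) & (denom > 0), np.maximum(0.0, (Q - (k - 1)) / denom), 0.0)
        Wstar = np.where(W > 0, 1.0 / (SE**2 + tau2[:, None]), 0.0)
        Wstar = np.where(np.isnan(Wstar), 0.0, Wstar)
        pooled = (Wstar * Bz).sum(axis=1) / Wstar.sum(axis=1)
        pooled_se = np.sqrt(1.0 / Wstar.sum(axis=1))
        pvalue = np.clip(2 * stats.norm.sf(np.abs(pooled / pooled_se)), 5e-324, 1.0)
        i2 = np.where(Q > 0, np.maximum(0.0, (Q - (k - 1)) / Q), 0.0)
    return pooled, pooled_se, pvalue, Q, tau2, i2, k


def dl_meta(betas: Sequence[float], ses: Sequence[float]) -> MetaRow:
    """DerSimonian–Laird random-effects pooling for one variant.

    A single study passes through unchanged with Q = tau^2 = 0.
    """
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    if b.shape != s.shape or b.ndim != 1 or len(b) < 1:
        raise ConfigError("betas and ses must be equal-length 1-D vectors with >= 1 entry")
    if (s <= 0).any():
        raise ConfigError("all standard errors must be > 0")
    pooled, se, p, Q, tau2, i2, k = (x[0] for x in _dl_pool(b[None, :], s[None, :]))
    return MetaRow(float(pooled), float(se), float(p), float(Q), float(tau2), float(i2), int(k))


def meta_analyse(studies: Sequence[SummaryStats], study_name: str = "meta") -> SummaryStats:
    """Per-variant DL meta-analysis across studies.

    All studies are harmonized to the first study's allele orientation
    (variants absent from earlier studies adopt the orientation of the first
    study carrying them).  The output is a SummaryStats-shaped table ordered
    by chromosome and position, with extra columns Q_het, tau2, i2 and
    k_studies; its eaf is taken from the largest contributing study per
    variant, with a logged warning where studies disagree by more than 0.05.
    """
    if len(studies) == 0:
        raise ConfigError("meta_analyse requires at least one study")
    if sum(len(s) for s in studies) == 0:
        raise CisMRError("no variants in any study")

    # growing allele reference: first study's orientation wins, new keys append
    aligned: list[pd.DataFrame] = []
    ref_df = studies[0].df.copy()
    aligned.append(ref_df)
    ref = SummaryStats(studies[0].study_name, ref_df)
    for s in studies[1:]:
        known = s.df.merge(ref.df[MATCH_COLS], on=MATCH_COLS, how="inner")
        new = s.df.merge(ref.df[MATCH_COLS], on=MATCH_COLS, how="left", indicator=True)
        new = new[new["_merge"] == "left_only"].drop(columns="_merge")
        parts = []
        if len(known):
            h, _ = harmonize(SummaryStats(s.study_name, known), ref)
            parts.append(h.df)
        if len(new):
            parts.append(new)
        sdf = pd.concat(parts, ignore_index=True)
        aligned.append(sdf)
        if len(new):
            ref = SummaryStats(ref.study_name, pd.concat([ref.df, new], ignore_index=True))

    union = ref.df[MATCH_COLS + ["ea", "oa", "rsid"]].drop_duplicates(MATCH_COLS)
    union = union.sort_values(["chrom", "pos", "a1", "a2"], kind="stable").reset_index(drop=True)
    idx = {t: i for i, t in enumerate(map(tuple, union[MATCH_COLS].to_numpy()))}

    m, S = len(union), len(studies)
    B = np.full((m, S), np.nan)
    SE = np.full((m, S), np.nan)
    EAF = np.full((m, S), np.nan)
    N = np.zeros((m, S))
    for j, sdf in enumerate(aligned):
        rows = [idx[t] for t in map(tuple, sdf[MATCH_COLS].to_numpy())]
        B[rows, j] = sdf["beta"].to_numpy(float)
        SE[rows, j] = sdf["se"].to_numpy(float)
        EAF[rows, j] = sdf["eaf"].to_numpy(float)
        N[rows, j] = sdf["n"].to_numpy(float)

    pooled, pooled_se, pvalue, Q, tau2, i2, k = _dl_pool(B, SE)

    # eaf from the largest study carrying the variant; warn on large spread
    n_masked = np.where(np.isnan(B), -1.0, N)
    biggest = n_masked.argmax(axis=1)
    eaf = EAF[np.arange(m), biggest]
    with np.errstate(invalid="ignore"):
        spread = np.nanmax(EAF, axis=1) - np.nanmin(EAF, axis=1)
    n_disagree = int((spread > 0.05).sum())
    if n_disagree:
        logger.warning("%d variants with eaf spread > 0.05 across studies; using largest study", n_disagree)

    out = union.copy()
    out["eaf"] = eaf
    out["beta"] = pooled
    out["se"] = pooled_se
    out["pvalue"] = pvalue
    out["n"] = np.where(np.isnan(B), 0, N).sum(axis=1)
    out["Q_het"] = Q
    out["tau2"] = tau2
    out["i2"] = i2
    out["k_studies"] = k
    return SummaryStats(study_name, out)


def clump(
    stats_table: SummaryStats,
    ld: LDMatrix,
    p_threshold: float = 5.8e-8,
    r2_threshold: float = 0.01,
) -> list[VariantKey]:
    """Greedy p-value clumping.

    Among variants with p <= p_threshold, repeatedly take the smallest-p
    variant as a lead and discard remaining candidates with r^2 >=
    r2_threshold against it (r^2 uses the signed r squared, so allele
    orientation is irrelevant).  Ties are broken by position then allele
    order.  Retained leads are mutually below the threshold.
    """
    cand = stats_table.df[stats_table.df["pvalue"] <= p_threshold]
    if cand.empty:
        return []
    cand = cand.sort_values(["pvalue", "chrom", "pos", "ea"], kind="stable")
    keys = [
        VariantKey(r.chrom, int(r.pos), r.ea, r.oa, r.rsid if isinstance(r.rsid, str) else None)
        for r in cand.itertuples()
    ]
    sub = ld.aligned_submatrix(keys)  # raises naming any variant missing from ld
    r2 = sub.r**2

    leads: list[VariantKey] = []
    alive = np.ones(len(keys), bool)
    for i in range(len(keys)):
        if not alive[i]:
            continue
        leads.append(keys[i])
        alive &= r2[i] < r2_threshold
        alive[i] = False
    # post-condition: leads mutually below threshold
    li = [keys.index(l) for l in leads]
    assert (r2[np.ix_(li, li)][~np.eye(len(li), dtype=bool)] < r2_threshold).all()
    return leads


def assign_cis_trans(
    leads: Sequence[VariantKey],
    stats_table: SummaryStats,
    target: GeneRegion,
    flank_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Label lead variants cis/trans relative to ``target`` +/- ``flank_bp``.

    A lead is cis iff it lies on the target's chromosome with position inside
    the closed window [start - flank, end + flank].
    """
    if flank_bp < 0:
        raise ConfigError("flank_bp must be >= 0")
    lo, hi = target.window(flank_bp)
    rows = []
    stat_idx = {tuple(t): i for i, t in enumerate(stats_table.df[MATCH_COLS].to_numpy())}
    for v in leads:
        is_cis = v.chrom == target.chromosome and lo <= v.pos <= hi
        row = {
            "variant": str(v),
            "rsid": v.rsid,
            "chrom": v.chrom,
            "pos": v.pos,
            "locus_label": "cis" if is_cis else "trans",
            "assigned_region": target.gene_name if is_cis else None,
        }
        i = stat_idx.get(v.match_key)
        if i is not None:
            srow = stats_table.df.iloc[i]
            sign = 1.0 if srow["ea"] == v.ea else -1.0
            row.update(beta=sign * float(srow["beta"]), se=float(srow["se"]), pvalue=float(srow["pvalue"]))
        rows.append(row)
    return pd.DataFrame(rows)
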