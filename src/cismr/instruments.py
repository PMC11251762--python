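"""Cis-instrument selection for one exposure/outcome pair.

Pipeline order is fixed and auditable: (1) restrict exposure variants to the
gene window (gene body +/- flank); (2) minor-allele-frequency filter;
(3) p-value clumping at a permissive r^2 so correlated instruments are kept
(residual correlation is carried in the LD submatrix); (4) weak-instrument
filter on the per-variant F statistic; (5) harmonization with the outcome
GWAS; (6) LD submatrix attachment in final variant order.  If the outcome
intersection removes a clump lead the set is not re-clumped unless requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .meta import clump
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


class SelectionError(CisMRError):
    """Instrument selection emptied the candidate set at a named step."""

    def __init__(self, step: str, message: str):
        self.step = step
        super().__init__(f"[{step}] {message}")


@dataclass
class SelectionConfig:
    """Thresholds for cis-instrument selection.

    Defaults follow drug-target cis-MR practice: a +/-1 Mb flank around the
    gene body, MAF >= 0.01, clumping at r^2 = 0.40 (correlated instruments
    retained, modelled through the LD matrix downstream), and per-variant
    F >= 15 against weak-instrument bias.
    """

    flank_bp: int = 1_000_000
    maf_min: float = 0.01
    clump_r2: float = 0.40
    f_min: float = 15.0
    palindrome_maf_limit: float = 0.42
    reclump_after_intersection: bool = False

    def __post_init__(self) -> None:
        if self.flank_bp < 0 or self.maf_min < 0 or self.f_min < 0:
            raise ConfigError("selection thresholds must be non-negative")
        if not (0 < self.clump_r2 <= 1):
            raise ConfigError("clump_r2 must lie in (0, 1]")


def compute_f_stats(bx: np.ndarray, sx: np.ndarray) -> np.ndarray:
    """Per-variant instrument-strength F statistic, F_j = (bx_j / sx_j)^2."""
    bx = np.asarray(bx, float)
    sx = np.asarray(sx, float)
    if bx.shape != sx.shape:
        raise ConfigError("bx and sx must have the same length")
    if (sx <= 0).any():
        raise ConfigError("all exposure standard errors must be > 0")
    return (bx / sx) ** 2


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome betas, ses, F statistics and LD for one region."""

    exposure_name: str
    outcome_name: str
    variants: list[VariantKey]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    f_stats: np.ndarray
    ld: LDMatrix
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.variants)
        for name in ("bx", "sx", "by", "sy", "f_stats"):
            v = np.asarray(getattr(self, name), float)
            setattr(self, name, v)
            if v.shape != (k,):
                raise ConfigError(f"{name} must have length {k}")
        if k < 1:
            raise ConfigError("instrument set must contain at least one variant")
        if (self.sx <= 0).any() or (self.sy <= 0).any():
            raise ConfigError("all standard errors must be > 0")
        if (self.f_stats < 0).any():
            raise ConfigError("F statistics must be >= 0")
        if len(self.ld.variants) != k:
            raise ConfigError("LD matrix dimension must equal the number of instruments")

    @property
    def k(self) -> int:
        return len(self.variants)

    def subset(self, indices: Sequence[int]) -> "InstrumentSet":
        idx = list(indices)
        keys = [self.variants[i] for i in idx]
        return InstrumentSet(
            self.exposure_name,
            self.outcome_name,
            keys,
            self.bx[idx],
            self.sx[idx],
            self.by[idx],
            self.sy[idx],
            self.f_stats[idx],
            self.ld.aligned_submatrix(keys),
            dict(self.meta),
        )

    def to_files(self, table_path: str | Path, ld_path: str | Path) -> None:
        pd.DataFrame(
            {
                "variant": [str(v) for v in self.variants],
                "rsid": [v.rsid for v in self.variants],
                "bx": self.bx,
                "sx": self.sx,
                "by": self.by,
                "sy": self.sy,
                "f_stat": self.f_stats,
            }
        ).to_csv(table_path, sep="\t", index=False, float_format="%.10g")
        self.ld.to_file(ld_path)

    @classmethod
    def from_files(
        cls, table_path: str | Path, ld_path: str | Path, exposure_name: str = "exposure", outcome_name: str = "outcome"
    ) -> "InstrumentSet":
        df = pd.read_csv(table_path, sep="\t")
        keys = [VariantKey.parse(s) for s in df["variant"]]
        ld = LDMatrix.from_file(ld_path)
        return cls(
            exposure_name,
            outcome_name,
            keys,
            df["bx"].to_numpy(float),
            df["sx"].to_numpy(float),
            df["by"].to_numpy(float),
            df["sy"].to_numpy(float),
            df["f_stat"].to_numpy(float),
            ld.aligned_submatrix(keys),
        )


def select_instruments(
    exposure_meta: SummaryStats,
    outcome: SummaryStats,
    region: GeneRegion,
    ld: LDMatrix,
    config: SelectionConfig = SelectionConfig(),
) -> InstrumentSet:
    """Build the cis InstrumentSet for one exposure/outcome pair.

    Raises :class:`SelectionError` naming the step that emptied the set.
    """
    lo, hi = region.window(config.flank_bp)
    window = exposure_meta.in_window(region.chromosome, lo, hi)
    if len(window) == 0:
        raise SelectionError("window", f"no exposure variants within {region.gene_name} +/- {config.flank_bp} bp")

    maf = np.minimum(window.df["eaf"], 1 - window.df["eaf"])
    window = SummaryStats(window.study_name, window.df[maf >= config.maf_min].reset_index(drop=True))
    if len(window) == 0:
        raise SelectionError("maf", f"no variants with MAF >= {config.maf_min}")

    leads = clump(window, ld, p_threshold=1.0, r2_threshold=config.clump_r2)
    lead_keys = {v.match_key for v in leads}
    clumped = window.df[[tuple(t) in lead_keys for t in window.df[MATCH_COLS].to_numpy()]]
    exposure_sel = SummaryStats(window.study_name, clumped.reset_index(drop=True))

    f = compute_f_stats(exposure_sel.df["beta"].to_numpy(), exposure_sel.df["se"].to_numpy())
    exposure_sel = SummaryStats(
        exposure_sel.study_name, exposure_sel.df[f >= config.f_min].reset_index(drop=True)
    )
    if len(exposure_sel) == 0:
        raise SelectionError("f_stat", f"no instruments with F >= {config.f_min}")

    outcome_window = outcome.in_window(region.chromosome, lo, hi)
    if len(outcome_window) == 0:
        raise SelectionError("outcome_window", f"outcome {outcome.study_name!r} has no variants in the window")
    try:
        outcome_h, _ = harmonize(outcome_window, exposure_sel, config.palindrome_maf_limit)
    except CisMRError as exc:
        raise SelectionError("outcome_overlap", str(exc)) from exc

    merged = exposure_sel.df.merge(
        outcome_h.df[MATCH_COLS + ["beta", "se"]].rename(columns={"beta": "by", "se": "sy"}),
        on=MATCH_COLS,
        how="inner",
    )
    if merged.empty:
        raise SelectionError("outcome_overlap", "no instruments shared with the outcome GWAS")
    if len(merged) < len(exposure_sel) and config.reclump_after_intersection:
        logger.info("re-clumping %d instruments after outcome intersection", len(merged))
        reduced = SummaryStats(exposure_sel.study_name, merged.drop(columns=["by", "sy"]))
        return select_instruments(
            reduced, outcome, region, ld, SelectionConfig(
                config.flank_bp, 0.0, config.clump_r2, 0.0, config.palindrome_maf_limit, False
            ),
        )

    keys = [
        VariantKey(r.chrom, int(r.pos), r.ea, r.oa, r.rsid if isinstance(r.rsid, str) else None)
        for r in merged.itertuples()
    ]
    bx = merged["beta"].to_numpy(float)
    sx = merged["se"].to_numpy(float)
    iset = InstrumentSet(
        exposure_name=exposure_meta.study_name,
        outcome_name=outcome.study_name,
        variants=keys,
        bx=bx,
        sx=sx,
        by=merged["by"].to_numpy(float),
        sy=merged["sy"].to_numpy(float),
        f_stats=compute_f_stats(bx, sx),
        ld=ld.aligned_submatrix(keys),
        meta={"region": region.gene_name, "k_window": len(window)},
    )
    logger.info(
        "%s vs %s: %d instruments (window %d)", iset.exposure_name, iset.outcome_name, iset.k, len(window)
    )
    return iset
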