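"""Study orchestration: meta-analysis, lead variants, per-outcome cis-MR,
shared-outcome MVMR, multiple-testing rules and report tables.

The full study runs as a composition of the module operations — every number
in the results table can be reproduced by re-running the corresponding
operation on the serialized intermediate artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .estimators import EstimationError, FitConfig, MREstimate, run_cis_mr
from .instruments import InstrumentSet, SelectionConfig, select_instruments
from .meta import assign_cis_trans, clump, meta_analyse
from .mvmr import run_mvmr, select_joint_instruments
from .sumstats import (
    CisMRError,
    ConfigError,
    GeneRegion,
    LDMatrix,
    MATCH_COLS,
    SummaryStats,
    compute_ld,
    read_dosages,
    read_sumstats,
)

logger = logging.getLogger("cismr")


# ---------------------------------------------------------------------------
# Multiple-testing rules
# ---------------------------------------------------------------------------


def bonferroni_alpha(fwer: float, n_outcomes: int) -> float:
    """Family-wise corrected significance level, fwer / n_outcomes."""
    if n_outcomes < 1:
        raise ConfigError("n_outcomes must be >= 1")
    if not (0 < fwer < 1):
        raise ConfigError("fwer must lie in (0, 1)")
    return fwer / n_outcomes


def joint_null_probability(alpha: float, m_findings: int) -> float:
    """Probability of m independent findings under the null: alpha ** m."""
    if not (0 < alpha < 1):
        raise ConfigError("alpha must lie in (0, 1)")
    if m_findings < 1:
        raise ConfigError("m_findings must be >= 1")
    return alpha**m_findings


def find_shared_outcomes(
    results1: pd.DataFrame, results2: pd.DataFrame, p_liberal: float = 0.05
) -> list[str]:
    """Outcomes with p < p_liberal for both exposures (queued for MVMR)."""
    s1 = set(results1["outcome"])
    s2 = set(results2["outcome"])
    if s1 != s2:
        raise ConfigError(f"outcome sets differ: only-first={sorted(s1 - s2)}, only-second={sorted(s2 - s1)}")
    p1 = results1.set_index("outcome")["pvalue"]
    p2 = results2.set_index("outcome")["pvalue"]
    return sorted(o for o in s1 if p1[o] < p_liberal and p2[o] < p_liberal)


# ---------------------------------------------------------------------------
# Concordance statistics
# ---------------------------------------------------------------------------


def assay_concordance(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson and Spearman correlation between paired assay read-outs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ConfigError("need >= 3 complete pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ConfigError("missing values in paired data")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigError("correlation undefined for a constant vector")
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    return {
        "pearson": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
        "n": len(x),
    }


def compare_regional_signals(
    meta1: SummaryStats,
    meta2: SummaryStats,
    chrom: str,
    start: int,
    end: int,
) -> dict:
    """Pearson correlation of -log10(p) between two traits over a region.

    Computed over the intersection of variants inside the closed window; used
    to judge whether two co-located association signals are independent.
    """
    w1 = meta1.in_window(chrom, start, end)
    w2 = meta2.in_window(chrom, start, end)
    merged = w1.df[MATCH_COLS + ["pvalue"]].merge(
        w2.df[MATCH_COLS + ["pvalue"]], on=MATCH_COLS, suffixes=("_1", "_2")
    )
    if len(merged) < 3:
        raise CisMRError(f"only {len(merged)} shared variants in the window; need >= 3")
    l1 = -np.log10(merged["pvalue_1"].to_numpy())
    l2 = -np.log10(merged["pvalue_2"].to_numpy())
    r = sps.pearsonr(l1, l2)
    return {"pearson_log10p": float(r.statistic), "pvalue": float(r.pvalue), "n_variants": len(merged)}


# ---------------------------------------------------------------------------
# Study configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class OutcomeSpec:
    name: str
    path: str
    binary: bool = False


@dataclass
class ExposureSpec:
    name: str
    study_paths: list[str]
    region: GeneRegion


@dataclass
class StudyConfig:
    """Everything needed to run the full study from files on disk."""

    exposure: ExposureSpec
    outcomes: list[OutcomeSpec]
    ld_dosage_path: str
    exposure2: ExposureSpec | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    fwer: float = 0.05
    n_outcomes_for_bonferroni: int | None = None  # default: len(outcomes)
    shared_outcome_p: float = 0.05
    gwas_p_threshold: float = 5.8e-8
    lead_clump_r2: float = 0.01
    cis_trans_flank_bp: int = 2_000_000
    ld_ridge: float = 0.001
    seed: int = 0
    out_dir: str = "cismr_out"

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ConfigError("at least one outcome is required")
        if not (0 < self.fwer < 1):
            raise ConfigError("fwer must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def exposure(block: dict) -> ExposureSpec:
            r = block["region"]
            return ExposureSpec(
                name=block["name"],
                study_paths=list(block["studies"]),
                region=GeneRegion(r["gene_name"], str(r["chromosome"]), int(r["start"]), int(r["end"])),
            )

        kwargs = dict(
            exposure=exposure(raw["exposure"]),
            outcomes=[OutcomeSpec(o["name"], o["path"], bool(o.get("binary", False))) for o in raw["outcomes"]],
            ld_dosage_path=raw["ld_reference"],
        )
        if "exposure2" in raw:
            kwargs["exposure2"] = exposure(raw["exposure2"])
        if "selection" in raw:
            kwargs["selection"] = SelectionConfig(**raw["selection"])
        if "fit" in raw:
            kwargs["fit"] = FitConfig(**raw["fit"])
        for key in (
            "fwer",
            "n_outcomes_for_bonferroni",
            "shared_outcome_p",
            "gwas_p_threshold",
            "lead_clump_r2",
            "cis_trans_flank_bp",
            "ld_ridge",
            "seed",
            "out_dir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _estimate_row(exposure: str, outcome: OutcomeSpec, est: MREstimate) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome.name,
        "method": est.method,
        "k_initial": est.k_initial,
        "k_used": est.k_used,
        "estimate": est.alpha_hat,
        "se": est.alpha_se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pvalue": est.pvalue,
        "odds_ratio": est.odds_ratio,
        "or_ci_low": est.or_ci_low,
        "or_ci_high": est.or_ci_high,
        "Q_ivw": est.Q_ivw,
        "Q_egger": est.Q_egger,
        "phi": est.phi,
        "egger_intercept": est.b0,
        "n_pruned": len(est.pruned),
        "pruned": ";".join(f"{p['variant']}({p['reason']})" for p in est.pruned),
    }


@dataclass
class StudyResult:
    results: pd.DataFrame
    mvmr_results: pd.DataFrame
    leads: pd.DataFrame
    failures: pd.DataFrame
    corrected_alpha: float
    shared_outcomes: list[str]


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full cis-MR study and write all report tables.

    Stages: exposure meta-analysis; genome-wide lead variants with cis/trans
    assignment; per-outcome instrument selection and cis-MR (repeated for the
    second exposure when configured); MVMR for outcomes nominally associated
    with both exposures; Bonferroni significance flags.  Stage failures are
    isolated per outcome and reported in a failure table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dosages, panel_variants = read_dosages(config.ld_dosage_path)
    ld = compute_ld(dosages, panel_variants, ridge=config.ld_ridge)

    exposures = [config.exposure] + ([config.exposure2] if config.exposure2 else [])
    metas: dict[str, SummaryStats] = {}
    for exp in exposures:
        studies = [read_sumstats(p) for p in exp.study_paths]
        meta = meta_analyse(studies, study_name=exp.name)
        metas[exp.name] = meta
        meta.to_file(out / f"meta_{exp.name}.tsv")

    leads = clump(metas[config.exposure.name], ld, config.gwas_p_threshold, config.lead_clump_r2)
    lead_table = assign_cis_trans(
        leads, metas[config.exposure.name], config.exposure.region, config.cis_trans_flank_bp
    )
    lead_table.to_csv(out / "lead_variants.tsv", sep="\t", index=False)

    rows: list[dict] = []
    failures: list[dict] = []
    counts: dict[str, dict] = {}
    for exp in exposures:
        for oc in sorted(config.outcomes, key=lambda o: o.name):
            try:
                outcome_ss = read_sumstats(oc.path, study_name=oc.name)
                iset = select_instruments(metas[exp.name], outcome_ss, exp.region, ld, config.selection)
                iset.to_files(out / f"instruments_{exp.name}_{oc.name}.tsv", out / f"ld_{exp.name}_{oc.name}.tsv")
                est = run_cis_mr(iset, config.fit, binary=oc.binary)
                rows.append(_estimate_row(exp.name, oc, est))
                counts[f"{exp.name}/{oc.name}"] = {"k_selected": iset.k, "k_used": est.k_used}
            except CisMRError as exc:
                logger.error("stage failed for %s vs %s: %s", exp.name, oc.name, exc)
                failures.append({"exposure": exp.name, "outcome": oc.name, "error": str(exc)})

    results = pd.DataFrame(rows)
    n_bonf = config.n_outcomes_for_bonferroni or len(config.outcomes)
    corrected = bonferroni_alpha(config.fwer, n_bonf)
    if len(results):
        results["significant"] = results["pvalue"] <= corrected
        results = results.sort_values(["exposure", "outcome"], kind="stable").reset_index(drop=True)

    shared: list[str] = []
    mvmr_rows: list[dict] = []
    if config.exposure2 is not None and len(results):
        r1 = results[results["exposure"] == config.exposure.name]
        r2 = results[results["exposure"] == config.exposure2.name]
        common = set(r1["outcome"]) & set(r2["outcome"])
        shared = find_shared_outcomes(
            r1[r1["outcome"].isin(common)], r2[r2["outcome"].isin(common)], config.shared_outcome_p
        )
        for name in shared:
            oc = next(o for o in config.outcomes if o.name == name)
            try:
                outcome_ss = read_sumstats(oc.path, study_name=oc.name)
                inp = select_joint_instruments(
                    metas[config.exposure.name],
                    metas[config.exposure2.name],
                    config.exposure.region,
                    config.exposure2.region,
                    outcome_ss,
                    ld,
                    config.selection,
                )
                est = run_mvmr(inp, config.fit)
                mvmr_rows.append(
                    {
                        "exposure1": est.exposure_names[0],
                        "exposure2": est.exposure_names[1],
                        "outcome": name,
                        "method": est.method,
                        "k_used": est.k_used,
                        "alpha1": est.alpha1_hat,
                        "alpha1_se": est.alpha1_se,
                        "p1": est.p1,
                        "alpha2": est.alpha2_hat,
                        "alpha2_se": est.alpha2_se,
                        "p2": est.p2,
                        "Q_mvmr": est.Q_mvmr,
                        "Q_egger": est.Q_egger,
                    }
                )
            except CisMRError as exc:
                logger.error("MVMR failed for %s: %s", name, exc)
                failures.append({"exposure": "MVMR", "outcome": name, "error": str(exc)})

    mvmr_results = pd.DataFrame(mvmr_rows)
    failure_table = pd.DataFrame(failures, columns=["exposure", "outcome", "error"])
    results.to_csv(out / "mr_results.tsv", sep="\t", index=False)
    mvmr_results.to_csv(out / "mvmr_results.tsv", sep="\t", index=False)
    failure_table.to_csv(out / "failures.tsv", sep="\t", index=False)

    log = {
        "seed": config.seed,
        "corrected_alpha": corrected,
        "n_outcomes_for_bonferroni": n_bonf,
        "shared_outcomes": shared,
        "n_lead_variants": len(lead_table),
        "selection": vars(config.selection),
        "fit": vars(config.fit),
        "per_pair_counts": counts,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)

    return StudyResult(results, mvmr_results, lead_table, failure_table, corrected, shared)
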