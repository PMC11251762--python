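"""Synthetic GWAS summary statistics with known ground truth.

Emulates the statistical structure a cis-MR analysis consumes: an LD
reference panel with block-autoregressive correlation, several proteomic
studies of one protein with shared true cis effects plus study-level
heterogeneity, a second co-located gene's protein, and outcome GWAS
generated under a configurable causal effect and directional pleiotropy.

Summary statistics report *marginal* per-allele effects: with panel
correlation matrix R and joint (causal) effects gamma on the standardized
scale, the expected marginal effect vector is ``R @ gamma``, and the
sampling distribution of the estimates is MVN with covariance ``R / n`` —
exactly the structure the GLS estimators downstream assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    ConfigError,
    GeneRegion,
    LDMatrix,
    SummaryStats,
    VariantKey,
    compute_ld,
    write_dosages,
)

# Non-palindromic allele pairs used for synthetic variants (effect, other).
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"), ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]

_TINY_P = 5e-324  # smallest subnormal double; keeps p-values in (0, 1]


@dataclass
class PanelConfig:
    """Geometry of the simulated LD reference panel.

    Variants are laid out in LD blocks of ``block_size``; within a block the
    latent-Gaussian correlation between variants i and j is
    ``within_block_rho ** |i - j|``; blocks are independent.
    """

    n_individuals: int = 5000
    n_variants: int = 400
    block_size: int = 20
    within_block_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    chromosome: str = "1"
    start_bp: int = 1_000_000
    spacing_bp: int = 2_500
    seed: int = 0
    ld_ridge: float = 0.001

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ConfigError("n_variants must be >= 2")
        if not (0 <= self.within_block_rho < 1):
            raise ConfigError("within_block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")


@dataclass
class ReferencePanel:
    """Simulated dosage matrix plus derived quantities used by the generators."""

    dosages: np.ndarray
    variants: list[VariantKey]
    config: PanelConfig
    ld: LDMatrix = field(init=False)
    eaf: np.ndarray = field(init=False)
    _chol: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ld = compute_ld(self.dosages, self.variants, ridge=self.config.ld_ridge)
        self.eaf = self.dosages.mean(axis=0) / 2.0
        self._chol = np.linalg.cholesky(self.ld.r)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    def region_for(self, gene_name: str, first: int, last: int) -> GeneRegion:
        """Gene region spanning panel variant indices ``first``..``last`` inclusive."""
        return GeneRegion(
            gene_name, self.config.chromosome, int(self.variants[first].pos), int(self.variants[last].pos)
        )


def simulate_reference_panel(config: PanelConfig) -> ReferencePanel:
    """Simulate a diploid dosage panel with block-AR(1) LD.

    Per block, latent Gaussians with correlation ``rho^|i-j|`` are thresholded
    at per-variant MAF quantiles to give two haplotypes per individual;
    dosage is the haplotype sum.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.n_variants, config.n_individuals
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)
    rho = config.within_block_rho

    latent = np.empty((2 * n, m))
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        width = stop - start
        z = np.empty((2 * n, width))
        z[:, 0] = rng.standard_normal(2 * n)
        innov_sd = np.sqrt(1 - rho**2)
        for j in range(1, width):
            z[:, j] = rho * z[:, j - 1] + innov_sd * rng.standard_normal(2 * n)
        latent[:, start:stop] = z

    haplotypes = (latent < thresholds).astype(float)
    dosages = haplotypes[:n] + haplotypes[n:]

    pair_choice = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = [
        VariantKey(
            config.chromosome,
            config.start_bp + i * config.spacing_bp,
            *_ALLELE_PAIRS[pair_choice[i]],
            rsid=f"rs{900000 + i}",
        )
        for i in range(m)
    ]
    return ReferencePanel(dosages, variants, config)


@dataclass
class Architecture:
    """True cis genetic architecture of one protein.

    ``gamma`` holds joint per-allele effects of the causal variants on the
    standardized protein; marginal effects follow as ``R @ gamma``.
    """

    gene: GeneRegion
    causal_variants: list[int]
    gamma: np.ndarray
    flank_bp: int = 1_000_000
    heritability_cap: float = 0.5

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, float)
        if len(self.gamma) != len(self.causal_variants):
            raise ConfigError("gamma must have one entry per causal variant")
        if not np.all(np.isfinite(self.gamma)):
            raise ConfigError("gamma must be finite")

    def validate_against(self, panel: ReferencePanel) -> None:
        lo, hi = self.gene.window(self.flank_bp)
        pos = panel.positions
        for i in self.causal_variants:
            if not (0 <= i < panel.n_variants):
                raise ConfigError(f"causal index {i} outside the panel")
            if not (lo <= pos[i] <= hi):
                raise ConfigError(
                    f"causal variant {panel.variants[i]} outside {self.gene.gene_name} +/- flank"
                )
        g = self.joint_vector(panel.n_variants)
        h2 = float(g @ panel.ld.r @ g)
        if h2 > self.heritability_cap:
            raise ConfigError(
                f"{self.gene.gene_name}: explained variance {h2:.3f} exceeds cap {self.heritability_cap}"
            )

    def joint_vector(self, n_variants: int) -> np.ndarray:
        g = np.zeros(n_variants)
        g[self.causal_variants] = self.gamma
        return g


@dataclass
class OutcomeModel:
    """Generative model for one outcome GWAS.

    ``alpha`` is the causal effect per SD of protein; a sequence supplies one
    effect per architecture when two proteins act on the outcome.  ``delta``
    (direct, pleiotropic variant effects) are drawn Normal(pleiotropy_mean,
    pleiotropy_sd^2).  With the default scope ``"gene"`` every variant inside
    a causal gene's body receives a direct effect — the classical
    directional-pleiotropy setting an Egger intercept absorbs; scope
    ``"causal"`` restricts delta to the causal variants themselves, where the
    LD-smeared direct effects are nearly collinear with the exposure signal
    and no intercept can separate them.  Binary outcomes are simulated
    directly on the log-odds summary-statistic scale.
    """

    alpha: float | tuple[float, ...] = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_scope: str = "gene"
    n_outcome: int = 50_000
    binary: bool = False
    seed: int = 0
    name: str = "outcome"

    def __post_init__(self) -> None:
        if self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be >= 0")
        if self.pleiotropy_scope not in ("gene", "causal"):
            raise ConfigError("pleiotropy_scope must be 'gene' or 'causal'")
        if self.n_outcome < 2:
            raise ConfigError("n_outcome must be >= 2")

    def alphas(self, n_arch: int) -> np.ndarray:
        a = np.atleast_1d(np.asarray(self.alpha, float))
        if len(a) == 1:
            a = np.concatenate([a, np.zeros(n_arch - 1)])
        if len(a) != n_arch:
            raise ConfigError(f"alpha has {len(a)} entries for {n_arch} architectures")
        return a


def _finalize_sumstats(
    name: str,
    panel: ReferencePanel,
    bhat_std: np.ndarray,
    n: int,
    rng: np.random.Generator,
    flip_fraction: float = 0.0,
) -> SummaryStats:
    """Rescale standardized estimates to per-allele units and package them."""
    f = panel.eaf
    scale = 1.0 / np.sqrt(2 * f * (1 - f))
    beta = bhat_std * scale
    se = scale / np.sqrt(n)
    z = beta / se
    pvalue = np.clip(2 * stats.norm.sf(np.abs(z)), _TINY_P, 1.0)

    variants = panel.variants
    eaf = f.copy()
    if flip_fraction > 0:
        flip = rng.random(len(variants)) < flip_fraction
        variants = [
            VariantKey(v.chrom, v.pos, v.oa, v.ea, v.rsid) if fl else v
            for v, fl in zip(variants, flip)
        ]
        beta = np.where(flip, -beta, beta)
        eaf = np.where(flip, 1 - eaf, eaf)
    return SummaryStats.from_arrays(name, variants, eaf, beta, se, pvalue, n)


def simulate_protein_gwas(
    panel: ReferencePanel,
    arch: Architecture,
    n_study: int,
    study_noise_sd: float = 0.0,
    seed: int = 0,
    study_name: str = "protein_study",
    flip_fraction: float = 0.0,
) -> SummaryStats:
    """One study's marginal protein GWAS.

    Study-level heterogeneity enters as a Normal(0, study_noise_sd^2) shift of
    each causal effect; estimates are drawn MVN(R @ gamma_study, R / n) on the
    standardized scale and rescaled to per-allele units by 1 / sqrt(2f(1-f)).
    """
    if n_study < 50:
        raise ConfigError("n_study must be >= 50")
    arch.validate_against(panel)
    rng = np.random.default_rng(seed)
    gamma_study = arch.joint_vector(panel.n_variants)
    gamma_study[arch.causal_variants] += rng.normal(0.0, study_noise_sd, size=len(arch.causal_variants))
    beta_marg = panel.ld.r @ gamma_study
    bhat = beta_marg + (panel._chol @ rng.standard_normal(panel.n_variants)) / np.sqrt(n_study)
    return _finalize_sumstats(study_name, panel, bhat, n_study, rng, flip_fraction)


def simulate_outcome_gwas(
    panel: ReferencePanel,
    archs: Architecture | Sequence[Architecture],
    model: OutcomeModel,
    flip_fraction: float = 0.0,
) -> SummaryStats:
    """Outcome GWAS under a known causal effect and optional pleiotropy.

    True variant-outcome effects are ``sum_e alpha_e * (R @ gamma_e) + R @ delta``;
    estimates are MVN around them with covariance ``R / n_outcome``.
    """
    archs = [archs] if isinstance(archs, Architecture) else list(archs)
    for a in archs:
        a.validate_against(panel)
    alphas = model.alphas(len(archs))
    rng = np.random.default_rng(model.seed)

    b_y = np.zeros(panel.n_variants)
    for a, alpha in zip(archs, alphas):
        b_y += alpha * (panel.ld.r @ a.joint_vector(panel.n_variants))
    if model.pleiotropy_scope == "causal":
        pleio_idx = sorted({i for a in archs for i in a.causal_variants})
    else:
        pos = panel.positions
        pleio_idx = sorted(
            {
                i
                for a in archs
                for i in range(panel.n_variants)
                if a.gene.start <= pos[i] <= a.gene.end
            }
        )
    delta = np.zeros(panel.n_variants)
    if model.pleiotropy_mean != 0 or model.pleiotropy_sd > 0:
        delta[pleio_idx] = rng.normal(model.pleiotropy_mean, model.pleiotropy_sd, len(pleio_idx))
        b_y += panel.ld.r @ delta
    bhat = b_y + (panel._chol @ rng.standard_normal(panel.n_variants)) / np.sqrt(model.n_outcome)
    ss = _finalize_sumstats(model.name, panel, bhat, model.n_outcome, rng, flip_fraction)
    return ss


# ---------------------------------------------------------------------------
# Whole-scenario generation
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """Full study scenario: panel, two co-located gene architectures, outcomes.

    The default geometry mirrors the analysis setting: two genes ~200 kb
    apart on one chromosome, three proteomic studies of unequal size for
    exposure 1, the same three studies re-assayed for exposure 2, and one or
    more outcome GWAS.
    """

    panel: PanelConfig = field(default_factory=PanelConfig)
    architectures: list[Architecture] | None = None
    study_sizes: tuple[int, ...] = (3301, 5368, 35559)
    study_noise_sd: float = 0.02
    outcomes: list[OutcomeModel] = field(default_factory=lambda: [OutcomeModel(alpha=0.3, name="trait_q")])
    flip_fraction: float = 0.3
    allow_overlapping_causal: bool = False
    seed: int = 0


@dataclass
class ScenarioBundle:
    panel: ReferencePanel
    regions: list[GeneRegion]
    exposure_studies: list[list[SummaryStats]]  # one list per architecture
    outcome_studies: list[SummaryStats]
    outcome_models: list[OutcomeModel]
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write every table the pipeline reads; returns a path manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        write_dosages(out / "ld_reference_dosages.tsv", self.panel.dosages, self.panel.variants)
        manifest["ld_reference"] = str(out / "ld_reference_dosages.tsv")
        for g, studies in enumerate(self.exposure_studies, start=1):
            for s in studies:
                p = out / f"exposure{g}_{s.study_name}.tsv"
                s.to_file(p)
                manifest[f"exposure{g}/{s.study_name}"] = str(p)
        for s in self.outcome_studies:
            p = out / f"outcome_{s.study_name}.tsv"
            s.to_file(p)
            manifest[f"outcome/{s.study_name}"] = str(p)
        truth_rows = [
            {"quantity": f"alpha[{m.name}][{r.gene_name}]", "value": a}
            for m in self.outcome_models
            for r, a in zip(self.regions, m.alphas(len(self.regions)))
        ]
        pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
        manifest["truth"] = str(out / "truth.tsv")
        return manifest


def default_architectures(panel: ReferencePanel) -> list[Architecture]:
    """Two co-located genes ~200 kb apart, echoing adjacent pentraxin loci.

    Gene 2 carries two causal variants at its own locus and two inside gene
    1's LD block (shared regulatory region), so its marginal signal is
    partially confounded with gene 1's — the situation multivariable MR is
    meant to resolve.
    """
    gene1 = panel.region_for("GENE1", 120, 159)
    gene2 = panel.region_for("GENE2", 240, 279)
    arch1 = Architecture(gene1, [125, 133, 141, 148, 155], np.array([0.20, -0.10, 0.15, 0.08, 0.12]))
    arch2 = Architecture(gene2, [128, 136, 250, 262], np.array([0.12, 0.08, 0.15, 0.10]))
    return [arch1, arch2]


def generate_scenario(config: ScenarioConfig, panel: ReferencePanel | None = None) -> ScenarioBundle:
    """Generate the full multi-study two-gene scenario with a truth record.

    ``panel`` may be supplied to reuse one simulated LD reference across many
    replicates (the reference panel is fixed in a real analysis too); it must
    have been generated from the same PanelConfig geometry.
    """
    root = np.random.SeedSequence(config.seed)
    (panel_seed,) = root.spawn(1)
    if panel is None:
        pc = replace(config.panel, seed=int(panel_seed.generate_state(1)[0] % 2**31))
        panel = simulate_reference_panel(pc)

    archs = config.architectures or default_architectures(panel)
    study_seeds = root.spawn(len(archs) * len(config.study_sizes) + len(config.outcomes))
    seen: set[int] = set()
    for a in archs:
        overlap = seen & set(a.causal_variants)
        if overlap and not config.allow_overlapping_causal:
            raise ConfigError(
                f"causal sets overlap at indices {sorted(overlap)}; "
                "set allow_overlapping_causal=True if intended"
            )
        seen |= set(a.causal_variants)

    seed_iter = iter(int(s.generate_state(1)[0] % 2**31) for s in study_seeds)
    exposure_studies: list[list[SummaryStats]] = []
    for g, arch in enumerate(archs, start=1):
        studies = [
            simulate_protein_gwas(
                panel,
                arch,
                n_study=n,
                study_noise_sd=config.study_noise_sd,
                seed=next(seed_iter),
                study_name=f"study_{chr(64 + i)}",
                flip_fraction=config.flip_fraction,
            )
            for i, n in enumerate(config.study_sizes, start=1)
        ]
        exposure_studies.append(studies)

    outcome_studies = []
    for m in config.outcomes:
        m_run = replace(m, seed=next(seed_iter))
        outcome_studies.append(simulate_outcome_gwas(panel, archs, m_run, flip_fraction=config.flip_fraction))

    truth = {
        "alpha": {m.name: m.alphas(len(archs)).tolist() for m in config.outcomes},
        "gamma": {a.gene.gene_name: a.gamma.tolist() for a in archs},
        "causal_variants": {a.gene.gene_name: list(a.causal_variants) for a in archs},
    }
    return ScenarioBundle(
        panel=panel,
        regions=[a.gene for a in archs],
        exposure_studies=exposure_studies,
        outcome_studies=outcome_studies,
        outcome_models=list(config.outcomes),
        truth=truth,
    )
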