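"""GWAS summary-statistics data model, I/O, allele harmonization and LD handling.

The unit of all I/O is one study's per-variant association table
(:class:`SummaryStats`).  Variants are matched across tables on
(chromosome, position, unordered allele pair); rsids are carried for
reporting but never used for joins.  Coordinates are 1-based and all
genomic windows are closed intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cismr")


class CisMRError(Exception):
    """Base class for all package errors."""


class FormatError(CisMRError):
    """Malformed input file or table."""


class ConfigError(CisMRError):
    """Invalid configuration value."""


class HarmonizationError(CisMRError):
    """Exposure/outcome or study/study allele alignment failed."""


VALID_ALLELES = frozenset("ACGT")

#: Canonical on-disk column names (GWAS-SSF style).
SSF_COLUMNS = (
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
)

#: Internal (short) column names, in the same order as SSF_COLUMNS.
_INTERNAL = ("chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pvalue", "n")
_SSF_TO_INTERNAL = dict(zip(SSF_COLUMNS, _INTERNAL))
_INTERNAL_TO_SSF = dict(zip(_INTERNAL, SSF_COLUMNS))

#: Join columns identifying a variant irrespective of allele orientation.
MATCH_COLS = ["chrom", "pos", "a1", "a2"]


@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic SNV, oriented by its effect allele.

    The rsid is carried for reporting but excluded from equality and hashing;
    variants are identified positionally.
    """

    chrom: str
    pos: int
    ea: str
    oa: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.ea == self.oa:
            raise ConfigError(f"effect and other allele identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ConfigError(f"position must be >= 1, got {self.pos}")
        for a in (self.ea, self.oa):
            if a not in VALID_ALLELES:
                raise ConfigError(f"invalid allele {a!r} at {self.chrom}:{self.pos}")

    @property
    def match_key(self) -> tuple[str, int, str, str]:
        """Orientation-free identity: (chrom, pos, sorted allele pair)."""
        a1, a2 = sorted((self.ea, self.oa))
        return (self.chrom, self.pos, a1, a2)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ea}:{self.oa}"

    @classmethod
    def parse(cls, s: str) -> "VariantKey":
        parts = s.split(":")
        if len(parts) != 4:
            raise FormatError(f"cannot parse variant key {s!r}; expected chrom:pos:ea:oa")
        return cls(parts[0], int(parts[1]), parts[2], parts[3])


@dataclass(frozen=True)
class GeneRegion:
    """Gene body coordinates; ``start``/``end`` are 1-based inclusive."""

    gene_name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(f"{self.gene_name}: start {self.start} > end {self.end}")

    def window(self, flank_bp: int) -> tuple[int, int]:
        """Closed interval [start - flank, end + flank], clipped at 1."""
        return (max(1, self.start - flank_bp), self.end + flank_bp)


@dataclass
class HarmonizationReport:
    n_matched: int = 0
    n_flipped: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_unmatched: int = 0


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    # a1/a2 are sorted, so A/T presents as (A, T) and C/G as (C, G)
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "C") & (a2 == "G"))


def _canonicalize(df: pd.DataFrame, study_name: str) -> pd.DataFrame:
    """Uppercase alleles, drop unusable rows, deduplicate, add match columns."""
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("ea", "oa"):
        df[col] = df[col].astype(str).str.upper()
    if "rsid" not in df.columns:
        df["rsid"] = None
    df["rsid"] = df["rsid"].astype(object).where(pd.notna(df["rsid"]), None)

    bad_allele = (
        ~df["ea"].isin(VALID_ALLELES) | ~df["oa"].isin(VALID_ALLELES) | (df["ea"] == df["oa"])
    )
    bad_stats = df["beta"].isna() | df["se"].isna() | (df["se"] <= 0)
    n_drop = int((bad_allele | bad_stats).sum())
    if n_drop:
        logger.info("%s: dropped %d rows with invalid alleles or se <= 0", study_name, n_drop)
        df = df.loc[~(bad_allele | bad_stats)]

    both = np.sort(df[["ea", "oa"]].to_numpy(), axis=1)
    df = df.assign(a1=both[:, 0], a2=both[:, 1])

    dup = df.duplicated(subset=MATCH_COLS, keep=False)
    if dup.any():
        n_before = len(df)
        df = df.sort_values("pvalue", kind="stable").drop_duplicates(subset=MATCH_COLS, keep="first")
        logger.info(
            "%s: %d duplicated variant keys; kept smallest-p row each", study_name, n_before - len(df)
        )
    return df.sort_values(["chrom", "pos", "a1", "a2"], kind="stable").reset_index(drop=True)


@dataclass
class SummaryStats:
    """One study's per-variant association table.

    ``df`` holds columns chrom, pos, ea, oa, rsid, eaf, beta, se, pvalue, n
    plus the sorted-allele join columns a1, a2.  Construction canonicalizes
    (uppercased alleles, rows with se <= 0 or missing beta dropped with a
    logged count, duplicates resolved to the smallest p-value).
    """

    study_name: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _INTERNAL if c not in self.df.columns]
        if missing:
            raise FormatError(f"{self.study_name}: missing required columns {missing}")
        if "a1" not in self.df.columns:
            self.df = _canonicalize(self.df, self.study_name)
        eaf = self.df["eaf"].to_numpy(float)
        if ((eaf < 0) | (eaf > 1)).any():
            raise FormatError(f"{self.study_name}: effect-allele frequency outside [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variants(self) -> list[VariantKey]:
        return [
            VariantKey(r.chrom, int(r.pos), r.ea, r.oa, r.rsid if isinstance(r.rsid, str) else None)
            for r in self.df.itertuples()
        ]

    @classmethod
    def from_arrays(
        cls,
        study_name: str,
        variants: Sequence[VariantKey],
        eaf: np.ndarray,
        beta: np.ndarray,
        se: np.ndarray,
        pvalue: np.ndarray,
        n: np.ndarray | int,
    ) -> "SummaryStats":
        df = pd.DataFrame(
            {
                "chrom": [v.chrom for v in variants],
                "pos": [v.pos for v in variants],
                "ea": [v.ea for v in variants],
                "oa": [v.oa for v in variants],
                "rsid": [v.rsid for v in variants],
                "eaf": np.asarray(eaf, float),
                "beta": np.asarray(beta, float),
                "se": np.asarray(se, float),
                "pvalue": np.asarray(pvalue, float),
                "n": np.broadcast_to(np.asarray(n), (len(variants),)).astype(float),
            }
        )
        return cls(study_name, df)

    def to_file(self, path: str | Path) -> None:
        out = self.df.rename(columns=_INTERNAL_TO_SSF)
        extras = [c for c in out.columns if c not in SSF_COLUMNS and c not in ("rsid", "a1", "a2")]
        cols = list(SSF_COLUMNS) + ["rsid"] + extras
        out[cols].to_csv(path, sep="\t", index=False, na_rep="NA")

    def in_window(self, chrom: str, start: int, end: int) -> "SummaryStats":
        sub = self.df[(self.df["chrom"] == str(chrom)) & self.df["pos"].between(start, end)]
        return SummaryStats(self.study_name, sub.reset_index(drop=True))


def read_sumstats(
    path: str | Path,
    study_name: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps file column names to the canonical GWAS-SSF names
    (e.g. ``{"BP": "base_pair_location"}``) for files with nonstandard headers.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"summary statistics file not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "rsid": str})
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in SSF_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = raw.rename(columns=_SSF_TO_INTERNAL)
    return SummaryStats(study_name or path.stem, df)


def harmonize(
    target: SummaryStats,
    reference: SummaryStats,
    palindrome_maf_limit: float = 0.42,
) -> tuple[SummaryStats, HarmonizationReport]:
    """Align ``target`` effect alleles to ``reference``.

    Rows are matched on (chrom, pos, unordered allele pair).  Where target and
    reference disagree on which allele is the effect allele, the target beta
    sign is flipped and eaf replaced by 1 - eaf.  Palindromic variants (A/T,
    C/G) are aligned by allele frequency and dropped when the minor-allele
    frequency in either table exceeds ``palindrome_maf_limit``.
    """
    ref = reference.df[MATCH_COLS + ["ea", "eaf"]].rename(columns={"ea": "ea_ref", "eaf": "eaf_ref"})
    merged = target.df.merge(ref, on=MATCH_COLS, how="inner")
    report = HarmonizationReport(n_dropped_unmatched=len(target.df) - len(merged))
    if merged.empty:
        raise HarmonizationError(
            f"no overlapping variants between {target.study_name!r} and {reference.study_name!r}"
        )

    pal = _is_palindromic(merged["a1"], merged["a2"])
    maf_t = np.minimum(merged["eaf"], 1 - merged["eaf"])
    maf_r = np.minimum(merged["eaf_ref"], 1 - merged["eaf_ref"])
    ambiguous = pal & ((maf_t > palindrome_maf_limit) | (maf_r > palindrome_maf_limit))
    report.n_dropped_palindromic = int(ambiguous.sum())
    merged = merged.loc[~ambiguous].copy()
    pal = pal.loc[~ambiguous]

    # non-palindromic: orient by allele label; palindromic: orient by frequency
    flip_label = ~pal & (merged["ea"] != merged["ea_ref"])
    flip_freq = pal & ((merged["eaf"] - 0.5) * (merged["eaf_ref"] - 0.5) < 0)
    flip = (flip_label | flip_freq).to_numpy()

    merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    merged.loc[flip, "eaf"] = 1 - merged.loc[flip, "eaf"]
    ea = merged["ea"].to_numpy(object).copy()
    oa = merged["oa"].to_numpy(object).copy()
    ea[flip], oa[flip] = oa[flip].copy(), ea[flip].copy()
    merged["ea"], merged["oa"] = ea, oa

    report.n_matched = len(merged)
    report.n_flipped = int(flip.sum())
    out = merged.drop(columns=["ea_ref", "eaf_ref"]).reset_index(drop=True)
    return SummaryStats(target.study_name, out), report


# ---------------------------------------------------------------------------
# LD matrices
# ---------------------------------------------------------------------------


@dataclass
class LDMatrix:
    """Signed LD correlation matrix over an ordered variant list.

    ``r[j, l]`` is the correlation of effect-allele dosages of variants j and
    l; signs therefore follow each variant's effect-allele orientation.
    """

    variants: list[VariantKey]
    r: np.ndarray
    n_ref: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        k = len(self.variants)
        if self.r.shape != (k, k):
            raise ConfigError(f"LD matrix shape {self.r.shape} does not match {k} variants")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ConfigError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ConfigError("LD matrix diagonal must be 1")
        if np.abs(self.r).max() > 1 + 1e-10:
            raise ConfigError("LD correlations must lie in [-1, 1]")
        self._index = {v.match_key: i for i, v in enumerate(self.variants)}

    def __contains__(self, key: VariantKey) -> bool:
        return key.match_key in self._index

    def aligned_submatrix(self, keys: Sequence[VariantKey]) -> "LDMatrix":
        """Submatrix over ``keys``, sign-aligned to each key's effect allele."""
        idx, signs = [], []
        for k in keys:
            i = self._index.get(k.match_key)
            if i is None:
                raise ConfigError(f"variant {k} missing from LD reference")
            idx.append(i)
            signs.append(1.0 if self.variants[i].ea == k.ea else -1.0)
        s = np.asarray(signs)
        sub = self.r[np.ix_(idx, idx)] * np.outer(s, s)
        return LDMatrix(list(keys), sub, self.n_ref)

    def to_file(self, path: str | Path) -> None:
        header = [str(v) for v in self.variants]
        pd.DataFrame(self.r, columns=header).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_file(cls, path: str | Path, n_ref: int = 0) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t")
        variants = [VariantKey.parse(c) for c in df.columns]
        return cls(variants, df.to_numpy(float), n_ref)


def compute_ld(
    genotypes: np.ndarray,
    variants: Sequence[VariantKey],
    ridge: float = 0.001,
) -> LDMatrix:
    """Pearson correlation of effect-allele dosages, ridge-shrunk for invertibility.

    The raw correlation matrix is shrunk as ``(1 - ridge) * r + ridge * I`` so
    downstream GLS solves never face an exactly singular matrix; the diagonal
    is reset to exactly 1.
    """
    g = np.asarray(genotypes, float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ConfigError("genotype matrix must be 2-D with >= 2 individuals")
    if g.shape[1] != len(variants):
        raise ConfigError("genotype columns must match the variant list")
    if g.min() < -1e-9 or g.max() > 2 + 1e-9:
        raise ConfigError("dosages must lie in [0, 2]")
    sd = g.std(axis=0)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        raise ConfigError(f"monomorphic variant in LD reference: {variants[j]}")
    r = np.corrcoef(g, rowvar=False)
    r = (1 - ridge) * r + ridge * np.eye(len(variants))
    np.fill_diagonal(r, 1.0)
    return LDMatrix(list(variants), r, n_ref=g.shape[0])


# ---------------------------------------------------------------------------
# Dosage-matrix I/O (plain-text LD reference)
# ---------------------------------------------------------------------------


def write_dosages(path: str | Path, genotypes: np.ndarray, variants: Sequence[VariantKey]) -> None:
    """Write an individuals x variants dosage table; header holds variant keys."""
    header = [str(v) for v in variants]
    pd.DataFrame(np.asarray(genotypes, float), columns=header).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_dosages(path: str | Path) -> tuple[np.ndarray, list[VariantKey]]:
    df = pd.read_csv(path, sep="\t")
    variants = [VariantKey.parse(c) for c in df.columns]
    return df.to_numpy(float), variants


def read_dosages_vcf(path: str | Path) -> tuple[np.ndarray, list[VariantKey]]:
    """Derive dosages from GT fields of a biallelic-SNV VCF (requires cyvcf2)."""
    from cyvcf2 import VCF

    variants: list[VariantKey] = []
    rows: list[np.ndarray] = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        variants.append(VariantKey(str(rec.CHROM), rec.POS, rec.ALT[0], rec.REF, rec.ID))
        gt = np.asarray(rec.genotype.array())[:, :2]
        rows.append(np.clip(gt, 0, 1).sum(axis=1).astype(float))
    if not variants:
        raise FormatError(f"no biallelic SNVs found in {path}")
    return np.column_stack(rows), variants
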