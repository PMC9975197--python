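"""Reading, writing and transforming GWAS summary statistics.

Summary statistics arrive as per-phenotype delimited text files carrying, per
SNP, an effect/other allele pair and either a Z score or an effect estimate
with its standard error.  This module parses those files, converts between
the (beta, se), p-value and Z-score representations, and aligns several
phenotypes (plus an LD score table) onto a common SNP grid so that the K
single-trait scans become a single K x M Z-score matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DEFAULT_DIALECT",
    "LDSCORE_DIALECT",
    "SummaryStatsTable",
    "ZMatrix",
    "AlignmentReport",
    "read_sumstats",
    "read_ldscores",
    "z_from_beta",
    "adjusted_z",
    "score_statistic",
    "align_z_matrix",
    "write_results",
]

#: Column names of the default (LDSC-style) sumstats dialect.  A user dialect
#: maps these canonical keys to whatever the file's header actually says.
DEFAULT_DIALECT: dict[str, str] = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "z": "Z",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

#: LDSC ``.l2.ldscore`` column layout.
LDSCORE_DIALECT: dict[str, str] = {"snp": "SNP", "ldscore": "L2"}

_MANDATORY = ("snp",)
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumstatsError(ValueError):
    """Raised for malformed or inconsistent summary-statistic inputs."""


@dataclass
class SummaryStatsTable:
    """One phenotype's per-SNP association summary.

    ``data`` uses canonical column names (``snp, chrom, pos, a1, a2, z,
    beta, se, pvalue, n``); absent quantities are simply missing columns.
    """

    phenotype_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "snp" not in df.columns:
            raise SumstatsError("summary table needs a 'snp' column")
        if len(df) == 0:
            raise SumstatsError("empty summary-statistics table")
        dup = df["snp"][df["snp"].duplicated()]
        if len(dup):
            raise SumstatsError(f"duplicate SNP id(s): {', '.join(map(str, dup.unique()[:5]))}")
        has_z = "z" in df.columns and df["z"].notna().all()
        has_bse = (
            "beta" in df.columns
            and "se" in df.columns
            and df["beta"].notna().all()
            and df["se"].notna().all()
        )
        if not (has_z or has_bse):
            raise SumstatsError(
                f"phenotype {self.phenotype_id!r}: every record needs z or beta+se"
            )
        if "se" in df.columns and (df["se"].dropna() <= 0).any():
            raise SumstatsError("non-positive standard error")
        if "pvalue" in df.columns:
            p = df["pvalue"].dropna()
            if ((p <= 0) | (p > 1)).any():
                raise SumstatsError("p-values must lie in (0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def z_scores(self) -> pd.Series:
        """Z per SNP, computed from beta/se where no Z column is present."""
        if "z" in self.data.columns:
            return self.data["z"].astype(float)
        return z_from_beta(self.data["beta"].to_numpy(), self.data["se"].to_numpy())

    def mean_n(self) -> float | None:
        if "n" in self.data.columns and self.data["n"].notna().any():
            return float(self.data["n"].mean())
        return None


@dataclass
class AlignmentReport:
    """Bookkeeping from multi-phenotype SNP alignment."""

    n_input: dict[str, int]
    n_aligned: int
    n_dropped_incompatible: int = 0
    n_sign_flipped: int = 0
    ambiguous_snps: list[str] = field(default_factory=list)


@dataclass
class ZMatrix:
    """K x M matrix of Z scores on a shared, allele-harmonized SNP grid."""

    phenotype_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray
    mean_n: np.ndarray | None = None  # per-phenotype mean sample size
    ldscores: np.ndarray | None = None  # aligned to snp_ids when given
    report: AlignmentReport | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K, M = self.values.shape
        if K != len(self.phenotype_ids) or M != len(self.snp_ids):
            raise ValueError("ZMatrix shape does not match its labels")
        if K < 1 or M < 1:
            raise ValueError("ZMatrix needs at least one phenotype and one SNP")
        if not np.isfinite(self.values).all():
            raise ValueError("ZMatrix contains non-finite entries")

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]


def read_sumstats(
    path,
    dialect: dict[str, str] | None = None,
    phenotype_id: str | None = None,
) -> SummaryStatsTable:
    """Read one phenotype's summary statistics from a delimited text file.

    ``dialect`` maps canonical keys (see :data:`DEFAULT_DIALECT`) to the
    file's header names; unmapped canonical columns are looked up under their
    default names and silently skipped when absent.  Whitespace- and
    tab-delimited files are accepted; gzip is transparent.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise SumstatsError(f"{path}: empty file") from None
    if len(raw) == 0:
        raise SumstatsError(f"{path}: no data rows")
    rename = {v: k for k, v in colmap.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    for key in _MANDATORY:
        if key not in df.columns:
            raise SumstatsError(f"{path}: mandatory column {colmap[key]!r} missing")
    keep = [c for c in DEFAULT_DIALECT if c in df.columns]
    df = df[keep].copy()
    for col in ("pos", "n"):
        if col in df.columns:
            df[col] = _numeric(df, col, path).astype("Int64")
    for col in ("z", "beta", "se", "pvalue"):
        if col in df.columns:
            df[col] = _numeric(df, col, path)
    if phenotype_id is None:
        phenotype_id = str(path)
    return SummaryStatsTable(phenotype_id=phenotype_id, data=df.reset_index(drop=True))


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # 1-based + header line
        raise SumstatsError(f"{path}: malformed numeric field in column {col!r} at line {line}")
    return out


def read_ldscores(path) -> pd.DataFrame:
    """Read an LDSC ``.l2.ldscore``-style table -> DataFrame(snp, ldscore)."""
    raw = pd.read_csv(path, sep=r"\s+")
    rename = {v: k for k, v in LDSCORE_DIALECT.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    if "snp" not in df.columns or "ldscore" not in df.columns:
        raise SumstatsError(f"{path}: expected columns SNP and L2")
    df = df[["snp", "ldscore"]].copy()
    df["ldscore"] = pd.to_numeric(df["ldscore"], errors="raise")
    if df["snp"].duplicated().any():
        raise SumstatsError(f"{path}: duplicate SNP ids in LD score table")
    if not np.isfinite(df["ldscore"]).all():
        raise SumstatsError(f"{path}: non-finite LD score")
    return df.reset_index(drop=True)


def z_from_beta(beta, se):
    """Z score from an effect estimate and its standard error: beta / se."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard error must be positive")
    out = beta / se
    return float(out) if out.ndim == 0 else out


def adjusted_z(p=None, sign=1, log10p=None):
    """Z score reconstructed from a (possibly saddlepoint-adjusted) p-value.

    Returns ``sign * sqrt(q)`` with ``q`` the (1 - p) quantile of the 1-df
    chi-square distribution, i.e. the magnitude of the normal deviate whose
    two-sided p equals ``p``; the sign is taken from the score statistic.

    For p-values that underflow double precision pass ``log10p`` (the
    base-10 log of p) instead of ``p``; the quantile is then computed in log
    space.
    """
    if (p is None) == (log10p is None):
        raise ValueError("supply exactly one of p or log10p")
    sign = np.asarray(sign, dtype=float)
    if np.any(np.abs(sign) != 1):
        raise ValueError("sign must be -1 or +1")
    if log10p is not None:
        log10p = np.asarray(log10p, dtype=float)
        if np.any(log10p > 0):
            raise ValueError("log10 p-value must be <= 0")
        # |Z| = Phi^{-1}(1 - p/2) computed from log(p/2) without forming p
        logp2 = log10p * math.log(10.0) - math.log(2.0)
        mag = -special.ndtri_exp(logp2)
    else:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p must lie in (0, 1]; use log10p for underflowed values")
        mag = -special.ndtri(p / 2.0)
        mag = np.where(p == 1.0, 0.0, mag)
    out = sign * mag
    return float(out) if out.ndim == 0 else out


def score_statistic(y, g) -> float:
    """Marginal score statistic sum_i (y_i - ybar) g_i for one SNP/phenotype."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("y and g must be equal-length vectors")
    if y.size < 2:
        raise ValueError("need at least two observations")
    return float(np.dot(y - y.mean(), g))


def align_z_matrix(
    tables: list[SummaryStatsTable],
    ldscores: pd.DataFrame | None = None,
) -> ZMatrix:
    """Intersect tables on SNP id, harmonize alleles, and stack Z scores.

    The first table defines the reference allele orientation: a table whose
    effect/other alleles are swapped at a SNP has its Z negated there; SNPs
    whose allele pairs cannot be reconciled are dropped and counted.
    Strand-ambiguous pairs (A/T, C/G) are flagged but kept as-is.
    """
    if not tables:
        raise ValueError("need at least one summary table")
    report = AlignmentReport(
        n_input={t.phenotype_id: t.n_snps for t in tables}, n_aligned=0
    )
    ref = tables[0].data
    have_alleles = all(
        "a1" in t.data.columns and "a2" in t.data.columns for t in tables
    )
    common = ref["snp"]
    for t in tables[1:]:
        common = common[common.isin(set(t.data["snp"]))]
    if ldscores is not None:
        common = common[common.isin(set(ldscores["snp"]))]
    common = list(common)
    if not common:
        raise SumstatsError("empty SNP intersection across input tables")

    idx_ref = ref.set_index("snp").loc[common]
    if have_alleles:
        ref_a1 = idx_ref["a1"].str.upper().to_numpy()
        ref_a2 = idx_ref["a2"].str.upper().to_numpy()
        amb = [
            s
            for s, a, b in zip(common, ref_a1, ref_a2)
            if (a, b) in _AMBIGUOUS_PAIRS
        ]
        report.ambiguous_snps = amb

    rows = []
    keep_mask = np.ones(len(common), dtype=bool)
    for t in tables:
        sub = t.data.set_index("snp").loc[common]
        z = (
            sub["z"].to_numpy(dtype=float)
            if "z" in sub.columns
            else z_from_beta(sub["beta"].to_numpy(), sub["se"].to_numpy())
        )
        if have_alleles and t is not tables[0]:
            a1 = sub["a1"].str.upper().to_numpy()
            a2 = sub["a2"].str.upper().to_numpy()
            same = (a1 == ref_a1) & (a2 == ref_a2)
            swapped = (a1 == ref_a2) & (a2 == ref_a1)
            z = np.where(swapped, -z, z)
            report.n_sign_flipped += int(swapped.sum())
            keep_mask &= same | swapped
        rows.append(z)

    values = np.vstack(rows)[:, keep_mask]
    kept = [s for s, k in zip(common, keep_mask) if k]
    report.n_dropped_incompatible = int((~keep_mask).sum())
    report.n_aligned = len(kept)
    if not kept:
        raise SumstatsError("no SNPs left after allele harmonization")

    mean_n = None
    ns = [t.mean_n() for t in tables]
    if all(n is not None for n in ns):
        mean_n = np.asarray(ns, dtype=float)

    l_aligned = None
    if ldscores is not None:
        l_aligned = (
            ldscores.set_index("snp").loc[kept, "ldscore"].to_numpy(dtype=float)
        )

    return ZMatrix(
        phenotype_ids=[t.phenotype_id for t in tables],
        snp_ids=kept,
        values=values,
        mean_n=mean_n,
        ldscores=l_aligned,
        report=report,
    )


def _format_p(p: float) -> str:
    if p != p:  # NaN
        return "NA"
    if 0 < p < 1e-4:
        return f"{p:.6e}"
    return f"{p:.6g}"


def write_results(results: dict[str, list], path) -> None:
    """Write per-SNP test results as a delimited table.

    ``results`` maps SNP id -> list of TestResult; one (statistic, p) column
    pair per method, methods ordered as first encountered, SNPs in input
    order.  p-values carry >= 6 significant digits, scientific below 1e-4.
    """
    methods: list[str] = []
    for res_list in results.values():
        for r in res_list:
            if r.method not in methods:
                methods.append(r.method)
    cols = ["SNP"]
    for m in methods:
        cols += [f"{m}_stat", f"{m}_p"]
    lines = ["\t".join(cols)]
    for snp, res_list in results.items():
        by_method = {r.method: r for r in res_list}
        row = [str(snp)]
        for m in methods:
            r = by_method.get(m)
            if r is None:
                row += ["NA", "NA"]
            else:
                row += [f"{r.statistic:.6g}", _format_p(r.pvalue)]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
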