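"""Phenotype correlation matrix estimation via LD score regression intercepts.

Under polygenic inheritance the expected product of two phenotypes' Z scores
at SNP j decomposes as

    E(Z_sj * Z_kj) = G_g * l_j + rho_sk,

where l_j is SNP j's LD score, G_g carries the genetic covariance, and the
intercept rho_sk is the phenotypic correlation between traits s and k
(inclusive of confounding such as sample overlap).  Regressing the products
of aligned Z scores on LD scores therefore yields, through the fitted
intercepts, an estimate of the K x K phenotype correlation matrix R without
individual-level data.  Diagonal (univariate, Z^2) intercepts estimate
1 + inflation and are used for normalization and for a heritability-bounds
sanity filter; the released matrix is repaired to a valid correlation matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .sumstats import ZMatrix

__all__ = [
    "LdscFit",
    "CorrelationMatrix",
    "ldsc_regression",
    "estimate_R",
    "normalize_and_repair",
    "perturb_R",
    "save_correlation",
    "load_correlation",
]


@dataclass
class LdscFit:
    """Intercept/slope of the ordinary least-squares fit of Z-score products
    (or squares) on LD scores."""

    intercept: float
    slope: float
    n_snps: int

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise ValueError("LDSC regression needs at least 3 SNPs")


@dataclass
class CorrelationMatrix:
    """Symmetric positive-definite phenotype correlation matrix with labels."""

    phenotype_ids: list[str]
    values: np.ndarray
    provenance: str = "specified"  # {"specified", "ldsc", "perturbed"}

    #: smallest admissible eigenvalue after repair
    psd_floor: float = 1e-8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K = len(self.phenotype_ids)
        if self.values.shape != (K, K):
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10, rtol=0):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.linalg.eigvalsh(self.values)[0] < self.psd_floor * (1 - 1e-6):
            raise ValueError("correlation matrix is not positive definite")

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_values(cls, values, phenotype_ids=None, provenance="specified", psd_floor=1e-8):
        values = np.asarray(values, dtype=float)
        if phenotype_ids is None:
            phenotype_ids = [f"P{i + 1}" for i in range(values.shape[0])]
        return cls(list(phenotype_ids), values, provenance, psd_floor)


def as_matrix(R) -> np.ndarray:
    """Accept a CorrelationMatrix or a bare array; return the K x K array."""
    return np.asarray(getattr(R, "values", R), dtype=float)


def ldsc_regression(products, ldscores, weights=None) -> LdscFit:
    """OLS of per-SNP Z-score products on LD scores, with intercept.

    ``weights`` (optional) are per-SNP regression weights for an
    inverse-variance-style weighted fit; the default is the unweighted fit,
    which is unbiased for the intercept under the product model.
    """
    y = np.asarray(products, dtype=float)
    x = np.asarray(ldscores, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("products and ldscores must be equal-length vectors")
    M = y.size
    if M < 3:
        raise ValueError("need at least 3 SNPs")
    if np.ptp(x) == 0:
        raise ValueError("constant LD scores: slope unidentifiable")
    X = np.column_stack([np.ones(M), x])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        X = X * w[:, None]
        y = y * w
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return LdscFit(intercept=float(coef[0]), slope=float(coef[1]), n_snps=M)


def _h2_estimate(fit: LdscFit, mean_n: float | None) -> float:
    """Slope-implied heritability: slope * M / N, or the raw slope when the
    per-phenotype sample size is unknown."""
    if mean_n is None:
        return fit.slope
    return fit.slope * fit.n_snps / mean_n


def estimate_R(
    z: ZMatrix,
    ldscores=None,
    *,
    h2_bounds: tuple[float, float] = (0.0, 1.0),
    max_chisq: float | None = None,
    psd_floor: float = 1e-8,
):
    """Estimate the phenotype correlation matrix from aligned Z scores.

    Diagonal entries come from univariate fits of Z^2 on the LD scores,
    off-diagonals from bivariate fits of pairwise Z products.  Phenotypes
    whose slope-implied heritability falls outside ``h2_bounds`` are excluded
    before assembly (their estimators are out of the parameter space).  The
    assembled intercept matrix is passed through :func:`normalize_and_repair`.

    ``max_chisq`` optionally masks SNPs with any Z^2 above the cap from the
    regressions (outlier guard; off by default).

    Returns ``(CorrelationMatrix, excluded_ids, fits)`` where ``fits`` maps
    ``(s, k)`` phenotype-id pairs (s == k for univariate) to :class:`LdscFit`.
    """
    zv = z.values
    if ldscores is None:
        ldscores = z.ldscores
    if ldscores is None:
        raise ValueError("LD scores required: align with an LD score table or pass them")
    l = np.asarray(getattr(ldscores, "ldscore", ldscores), dtype=float)
    if l.shape != (z.M,):
        raise ValueError("LD scores are not aligned with the Z matrix")
    if z.K < 2:
        raise ValueError("need at least 2 phenotypes")

    mask = np.ones(z.M, dtype=bool)
    if max_chisq is not None:
        mask &= (zv**2 <= max_chisq).all(axis=0)
    zv = zv[:, mask]
    l = l[mask]

    fits: dict[tuple[str, str], LdscFit] = {}
    keep: list[int] = []
    excluded: list[str] = []
    for k, pid in enumerate(z.phenotype_ids):
        fit = ldsc_regression(zv[k] ** 2, l)
        fits[(pid, pid)] = fit
        n_k = float(z.mean_n[k]) if z.mean_n is not None else None
        h2 = _h2_estimate(fit, n_k)
        if h2_bounds[0] <= h2 <= h2_bounds[1]:
            keep.append(k)
        else:
            excluded.append(pid)
    if len(keep) < 2:
        raise ValueError("fewer than 2 phenotypes survive the heritability filter")

    ids = [z.phenotype_ids[k] for k in keep]
    K = len(keep)
    raw = np.zeros((K, K))
    for a, ka in enumerate(keep):
        raw[a, a] = fits[(z.phenotype_ids[ka], z.phenotype_ids[ka])].intercept
        for b in range(a + 1, K):
            kb = keep[b]
            fit = ldsc_regression(zv[ka] * zv[kb], l)
            fits[(z.phenotype_ids[ka], z.phenotype_ids[kb])] = fit
            raw[a, b] = raw[b, a] = fit.intercept
    R = normalize_and_repair(raw, psd_floor=psd_floor, phenotype_ids=ids)
    R = dataclasses.replace(R, provenance="ldsc")
    return R, excluded, fits


def normalize_and_repair(
    raw, psd_floor: float = 1e-8, phenotype_ids=None
) -> CorrelationMatrix:
    """Turn a raw symmetric intercept matrix into a valid correlation matrix.

    Rescales to unit diagonal with D^{-1/2} raw D^{-1/2}; if any eigenvalue
    then falls below ``psd_floor`` the spectrum is clipped at the floor and
    the matrix re-normalized, iterating until the floor holds.  Inputs that
    already satisfy the invariants are returned unchanged (idempotence).
    """
    A = np.asarray(as_matrix(raw), dtype=float).copy()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("expected a square matrix")
    asym = np.abs(A - A.T).max() if A.size else 0.0
    if asym >= 1e-8:
        raise ValueError(f"matrix is not symmetric (max asymmetry {asym:.2e})")
    A = (A + A.T) / 2.0
    d = np.diag(A)
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal entry")
    if phenotype_ids is None:
        phenotype_ids = getattr(raw, "phenotype_ids", None)

    scale = 1.0 / np.sqrt(d)
    A = A * np.outer(scale, scale)
    np.fill_diagonal(A, 1.0)
    for _ in range(100):
        w, U = np.linalg.eigh(A)
        if w[0] >= psd_floor * (1 - 1e-9):
            break
        w = np.clip(w, psd_floor, None)
        A = (U * w) @ U.T
        A = (A + A.T) / 2.0
        s = 1.0 / np.sqrt(np.diag(A))
        A = A * np.outer(s, s)
        np.fill_diagonal(A, 1.0)
    return CorrelationMatrix.from_values(
        A, phenotype_ids=phenotype_ids, provenance="specified", psd_floor=psd_floor
    )


def perturb_R(R: CorrelationMatrix, delta: float, seed=None) -> CorrelationMatrix:
    """Add white noise of variance ``delta`` to the off-diagonal entries.

    Emulates estimation error in R: each strict upper-triangle entry gets an
    independent N(0, delta) draw, mirrored below, diagonal kept at 1, then
    repaired to a valid correlation matrix.  ``delta = 0`` returns R itself.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0:
        return R
    rng = np.random.default_rng(seed)
    A = as_matrix(R).copy()
    K = A.shape[0]
    iu = np.triu_indices(K, k=1)
    noise = rng.normal(0.0, np.sqrt(delta), size=len(iu[0]))
    A[iu] += noise
    A.T[iu] = A[iu]
    out = normalize_and_repair(A, psd_floor=getattr(R, "psd_floor", 1e-8),
                               phenotype_ids=getattr(R, "phenotype_ids", None))
    return dataclasses.replace(out, provenance="perturbed")


def save_correlation(R: CorrelationMatrix, path) -> None:
    """Serialize as a delimited square matrix with id header row/column."""
    ids = R.phenotype_ids
    lines = ["\t".join(["ID"] + ids)]
    for pid, row in zip(ids, R.values):
        lines.append("\t".join([pid] + [f"{v:.10g}" for v in row]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_correlation(path, provenance="specified") -> CorrelationMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return CorrelationMatrix(list(df.columns), df.to_numpy(dtype=float), provenance)
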