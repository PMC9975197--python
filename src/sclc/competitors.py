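"""Comparison tests for multi-phenotype association from summary statistics.

All tests take a SNP's Z-score vector and the phenotype correlation matrix R
(Z ~ N(mu, R) under the working model) and return a :class:`TestResult`:

* SSU - sum of squared Z scores; its chi-square-mixture null is moment-
  matched by a scaled-shifted chi-square a*chi2_d + b.
* Hom - the optimal single linear combination under homogeneous effects,
  (e^T R^{-1} Z)^2 / (e^T R^{-1} e) ~ chi2_1 (one cohort).
* Wald - Z^T R^{-1} Z ~ chi2_K.
* PCFisher - Fisher combination of the K independent principal-component
  p-values, -2 sum log p_m ~ chi2_{2K}.
* MAT / aMAT - quadratic forms in truncated pseudoinverses R+_gamma keeping
  the singular values within a condition bound gamma; aMAT takes the minimum
  MAT p-value over gamma in (1, 10, 30, 50) and calibrates it through a
  Gaussian copula fitted to the null dependence of the MAT p-values.

:func:`weighted_chisq_pvalue` provides the exact weighted-chi-square upper
tail (Imhof's numerical inversion) used as the oracle for SSU's
approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clc import TestResult
from .phenocorr import as_matrix

__all__ = [
    "SpectralDecomposition",
    "ssu_test",
    "hom_test",
    "wald_test",
    "pcfisher_test",
    "mat_test",
    "amat_test",
    "AmatCalibrator",
    "weighted_chisq_pvalue",
]

DEFAULT_GAMMAS = (1.0, 10.0, 30.0, 50.0)


@dataclass
class SpectralDecomposition:
    """Eigenpairs of R sorted by descending eigenvalue."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are eigenvectors

    @classmethod
    def from_matrix(cls, R) -> "SpectralDecomposition":
        A = as_matrix(R)
        w, U = np.linalg.eigh(A)
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        recon = (U * w) @ U.T
        if np.abs(recon - A).max() >= 1e-10:
            raise ValueError("eigendecomposition failed to reconstruct R")
        return cls(eigenvalues=w, eigenvectors=U)


def _zvec(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError("expected a 1-d Z-score vector")
    return z


def ssu_test(z, R) -> TestResult:
    """Sum of squared Z scores with the moment-matched chi-square null."""
    z = _zvec(z)
    c = np.linalg.eigvalsh(as_matrix(R))
    a, b, d = _ssu_coefficients(c)
    T = float(z @ z)
    q = (T - b) / a
    p = 1.0 if q < 0 else float(stats.chi2.sf(q, df=d))
    return TestResult("ssu", T, p, detail={"a": a, "b": b, "df": d})


def _ssu_coefficients(eigenvalues: np.ndarray) -> tuple[float, float, float]:
    c2 = float(np.sum(eigenvalues**2))
    c3 = float(np.sum(eigenvalues**3))
    c1 = float(np.sum(eigenvalues))
    a = c3 / c2
    b = c1 - c2**2 / c3
    d = c2**3 / c3**2
    return a, b, d


def hom_test(z, R, n=None) -> TestResult:
    """Homogeneous-effect linear combination test (single cohort).

    ``n`` may be a scalar sample size or per-trait weights n_k; with one
    cohort the weight matrix V = diag(sqrt(n)) cancels when n is common,
    so the statistic reduces to (e^T R^{-1} Z)^2 / (e^T R^{-1} e) ~ chi2_1.
    """
    z = _zvec(z)
    A = as_matrix(R)
    K = z.size
    w = np.sqrt(np.full(K, float(n)) if np.isscalar(n) else np.asarray(n, dtype=float)) \
        if n is not None else np.ones(K)
    # e^T (RV)^{-1} Z = e^T V^{-1} R^{-1} Z; denominator e^T V^{-1} R^{-1} V^{-1} e
    ev = 1.0 / w
    rinv_z = np.linalg.solve(A, z)
    rinv_ev = np.linalg.solve(A, ev)
    num = float(ev @ rinv_z) ** 2
    den = float(ev @ rinv_ev)
    S = num / den
    return TestResult("hom", S, float(stats.chi2.sf(S, df=1)), detail={"df": 1})


def wald_test(z, R) -> TestResult:
    """Quadratic form Z^T R^{-1} Z against chi-square with K df."""
    z = _zvec(z)
    A = as_matrix(R)
    T = float(z @ np.linalg.solve(A, z))
    return TestResult("wald", T, float(stats.chi2.sf(T, df=z.size)), detail={"df": z.size})


def pcfisher_test(z, R) -> TestResult:
    """Fisher combination of the principal-component p-values.

    PC_m = u_m^T Z ~ N(0, lambda_m) independently under the null; each PC's
    two-sided normal p enters -2 sum log p_m ~ chi2_{2K}.  The log p are
    computed in log space so extreme PCs do not underflow.
    """
    z = _zvec(z)
    spec = SpectralDecomposition.from_matrix(R)
    if spec.eigenvalues[-1] <= 0:
        raise ValueError("PCFisher requires a positive-definite R")
    pc = spec.eigenvectors.T @ z
    standardized = np.abs(pc) / np.sqrt(spec.eigenvalues)
    logp = math.log(2.0) + stats.norm.logsf(standardized)
    T = float(-2.0 * logp.sum())
    p = float(stats.chi2.sf(T, df=2 * z.size))
    return TestResult("pcfisher", T, p, detail={"df": 2 * z.size})


def _mat_rank(sigma: np.ndarray, gamma: float) -> int:
    """Largest m with sigma_1 / sigma_m <= gamma (so gamma = 1 keeps the top
    singular value's multiplicity rather than nothing)."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    ratios = sigma[0] / sigma
    return int(np.searchsorted(ratios, gamma, side="right"))


def mat_test(z, R, gamma: float) -> TestResult:
    """Multi-trait quadratic form in the condition-bounded pseudoinverse.

    R+_gamma keeps the top m singular values with sigma_1/sigma_m <= gamma;
    T = Z^T R+_gamma Z is exactly chi-square with m df under the null since
    the kept subspace whitens.
    """
    z = _zvec(z)
    spec = SpectralDecomposition.from_matrix(R)
    sigma = spec.eigenvalues
    m = _mat_rank(sigma, gamma)
    pc = spec.eigenvectors.T @ z
    T = float(np.sum(pc[:m] ** 2 / sigma[:m]))
    return TestResult(
        f"mat({gamma:g})", T, float(stats.chi2.sf(T, df=m)), detail={"df": m, "gamma": gamma}
    )


def _tail_orthant(z: float, corr: np.ndarray, seed: int) -> float:
    """P(X_i >= z for all i) for X ~ N(0, corr), via the Genz algorithm
    (good relative accuracy in the tail thanks to sequential conditioning)."""
    dim = corr.shape[0]
    if dim == 1:
        return float(stats.norm.sf(z))
    dist = stats.multivariate_normal(mean=np.zeros(dim), cov=corr, allow_singular=True)
    return float(dist.cdf(np.full(dim, -z), rng=np.random.default_rng(seed)))


class AmatCalibrator:
    """Gaussian-copula calibration of the minimum MAT p-value for one R.

    The MAT statistics share the eigenbasis of R, so under the null the
    per-gamma p-values are deterministic functions of iid chi2_1 spectrum
    components; their probit-scale correlation is estimated once from seeded
    null simulations.  The aMAT p-value is then the union probability
    P(min_g p_g <= t) under that multivariate normal, evaluated by
    inclusion-exclusion over tail orthants and clipped into the Frechet
    bounds [t, G t].  A monotone log-log interpolation grid supports
    vectorized evaluation across a scan or simulation batch.
    """

    def __init__(self, R, gammas=DEFAULT_GAMMAS, null_draws: int = 100_000, seed=0,
                 grid_per_decade: int = 4, grid_min_p: float = 1e-40):
        if len(gammas) == 0:
            raise ValueError("need at least one gamma")
        self.gammas = tuple(float(g) for g in gammas)
        self.spec = SpectralDecomposition.from_matrix(R)
        sigma = self.spec.eigenvalues
        self.ranks = tuple(_mat_rank(sigma, g) for g in self.gammas)
        # gammas sharing a rank give identical MAT tests; the copula only
        # needs the distinct ones
        self._unique_ranks = sorted(set(self.ranks))
        self._seed = int(seed)
        self._null_draws = int(null_draws)
        self._copula_corr = self._estimate_copula_corr()
        self._grid_logp, self._grid_logu = self._build_grid(grid_per_decade, grid_min_p)

    @property
    def copula_corr(self) -> np.ndarray:
        return self._copula_corr

    def _null_min_p(self, zmat: np.ndarray) -> np.ndarray:
        """min over gamma of the MAT p-values for each column of K x n Z."""
        pc = self.spec.eigenvectors.T @ zmat
        comp = pc**2 / self.spec.eigenvalues[:, None]
        csum = np.cumsum(comp, axis=0)
        logps = [
            stats.chi2.logsf(csum[m - 1], df=m) for m in self._unique_ranks
        ]
        return np.exp(np.minimum.reduce(logps))

    def _per_gamma_logp(self, zmat: np.ndarray) -> np.ndarray:
        pc = self.spec.eigenvectors.T @ zmat
        comp = pc**2 / self.spec.eigenvalues[:, None]
        csum = np.cumsum(comp, axis=0)
        return np.vstack([stats.chi2.logsf(csum[m - 1], df=m) for m in self.ranks])

    def _estimate_copula_corr(self) -> np.ndarray:
        rng = np.random.default_rng(self._seed)
        # under the null the spectrum components are iid chi2_1
        comp = rng.chisquare(1.0, size=(self.spec.eigenvalues.size, self._null_draws))
        csum = np.cumsum(comp, axis=0)
        probits = []
        for m in self._unique_ranks:
            logp = stats.chi2.logsf(csum[m - 1], df=m)
            probits.append(-stats.norm.ppf(np.clip(np.exp(logp), 1e-15, 1 - 1e-15)))
        X = np.vstack(probits)
        if X.shape[0] == 1:
            return np.ones((1, 1))
        return np.corrcoef(X)

    def _union_probability(self, min_p: float) -> float:
        """P(min_g p_g <= min_p) by inclusion-exclusion over tail orthants."""
        if min_p >= 1.0:
            return 1.0
        if min_p <= 0.0:
            return 0.0
        G = len(self._unique_ranks)
        zthr = float(stats.norm.isf(min_p))
        total = 0.0
        for r in range(1, G + 1):
            for subset in itertools.combinations(range(G), r):
                sub = self._copula_corr[np.ix_(subset, subset)]
                term = _tail_orthant(zthr, sub, seed=self._seed + 7919 * r)
                total += (-1) ** (r + 1) * term
        return float(np.clip(total, min_p, min(1.0, G * min_p)))

    def _build_grid(self, per_decade: int, min_p: float):
        logs = np.linspace(0.0, math.log10(min_p), int(-math.log10(min_p) * per_decade) + 1)
        # extra resolution near 1 where the union probability bends sharply
        head = np.linspace(0.05, 0.999, 40)
        grid_p = np.unique(np.concatenate([10.0**logs, head]))
        grid_u = np.array([self._union_probability(p) for p in grid_p])
        # enforce monotonicity against quadrature noise
        order = np.argsort(grid_p)
        gp, gu = np.log(grid_p[order]), np.log(np.maximum.accumulate(grid_u[order]))
        return gp, gu

    def pvalues(self, min_p) -> np.ndarray:
        """Vectorized copula p-values by monotone log-log interpolation;
        below the grid the local log-log slope (asymptotically 1) is used."""
        mp = np.atleast_1d(np.asarray(min_p, dtype=float))
        logmp = np.log(np.clip(mp, 5e-324, 1.0))
        lo = self._grid_logp[0]
        slope = (self._grid_logu[1] - self._grid_logu[0]) / (
            self._grid_logp[1] - self._grid_logp[0]
        )
        out = np.interp(logmp, self._grid_logp, self._grid_logu)
        below = logmp < lo
        out[below] = self._grid_logu[0] + slope * (logmp[below] - lo)
        p = np.exp(out)
        G = len(self._unique_ranks)
        p = np.clip(p, mp, np.minimum(1.0, G * mp))
        return p if np.ndim(min_p) else float(p[0])

    def batch_pvalues(self, zmat: np.ndarray) -> np.ndarray:
        """aMAT p-values for each column of a K x n Z matrix."""
        return np.atleast_1d(self.pvalues(self._null_min_p(np.atleast_2d(zmat))))

    def test(self, z) -> TestResult:
        z = _zvec(z)
        logp = self._per_gamma_logp(z[:, None])[:, 0]
        min_p = float(np.exp(logp.min()))
        p = self._union_probability(min_p)
        return TestResult(
            "amat",
            min_p,
            p,
            detail={
                "per_gamma_p": dict(zip(self.gammas, np.exp(logp))),
                "ranks": dict(zip(self.gammas, self.ranks)),
            },
        )


def amat_test(z, R, gammas=DEFAULT_GAMMAS, null_draws: int = 100_000, seed=0) -> TestResult:
    """Adaptive MAT: minimum MAT p over gammas, Gaussian-copula calibrated."""
    return AmatCalibrator(R, gammas=gammas, null_draws=null_draws, seed=seed).test(z)


def weighted_chisq_pvalue(weights, q: float) -> float:
    """Exact upper tail of sum_i w_i chi2_1 at q by Imhof's inversion.

    P(Q > q) = 1/2 + (1/pi) Int_0^inf sin(theta(u)) / (u rho(u)) du with
    theta(u) = (1/2) sum arctan(w_i u) - q u / 2 and
    rho(u) = prod (1 + w_i^2 u^2)^{1/4}.  The head of the integral is
    evaluated adaptively and the oscillatory tail with an
    oscillation-aware quadrature (period 4 pi / q) in extended precision,
    giving absolute error well below 1e-8.
    """
    import mpmath as mp

    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0 or np.any(w <= 0):
        raise ValueError("weights must be positive")
    if q <= 0:
        return 1.0

    with mp.workdps(25):
        wm = [mp.mpf(float(x)) for x in w]
        qm = mp.mpf(float(q))

        def integrand(u):
            theta = mp.fsum(mp.atan(wi * u) for wi in wm) / 2 - qm * u / 2
            rho = mp.exp(mp.fsum(mp.log1p((wi * u) ** 2) for wi in wm) / 4)
            return mp.sin(theta) / (u * rho)

        period = 4 * mp.pi / qm
        head = mp.quad(integrand, [mp.mpf("1e-14"), period])
        tail = mp.quadosc(integrand, [period, mp.inf], period=period)
        value = mp.mpf(1) / 2 + (head + tail) / mp.pi
    return float(min(max(value, 0.0), 1.0))
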