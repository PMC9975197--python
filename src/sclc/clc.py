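"""The sCLC multiple-phenotype association test.

Given a SNP's vector of K association Z scores, Z ~ N(mu, R) under the
working model with R the phenotype correlation matrix, the clustering linear
combination (CLC) statistic for a partition of the K phenotypes into L
clusters (membership matrix B, K x L) is the quadratic form

    T_CLC^L = (W Z)^T (W R W^T)^{-1} (W Z),   W = B^T R^{-1},

which is chi-square with L degrees of freedom under the null.  Phenotype
partitions for every cluster count L = 1..K are read off one agglomerative
hierarchical tree built from the dissimilarity 1 - R, and the K resulting
p-values are aggregated with the Cauchy combination

    T_sCLC = (1/K) sum_L tan((0.5 - p_L) * pi),

whose null tail is approximately standard Cauchy, so the combined p-value is
0.5 - arctan(T_sCLC)/pi.  The heavy Cauchy tail makes the approximation
robust to the strong dependence among the p_L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .phenocorr import as_matrix

__all__ = [
    "TestResult",
    "ClusterPartitionSet",
    "hierarchical_partitions",
    "clc_statistic",
    "cauchy_combination",
    "sclc_test",
    "sclc_scan",
    "SclcEngine",
]

_LINKAGES = ("single", "complete", "average")

# tan((0.5 - p) pi) switches to its 1/(p pi) tail below this p (ACAT-style
# stabilization); symmetric clamp keeps p = 1 finite.
_TINY_P = 1e-15
_P_CLAMP = 1.0 - 1e-16


@dataclass
class TestResult:
    """Outcome of one association test at one SNP."""

    method: str
    statistic: float
    pvalue: float
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"{self.method}: non-finite statistic")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"{self.method}: p-value {self.pvalue} outside [0, 1]")


@dataclass
class ClusterPartitionSet:
    """Nested phenotype partitions for every cluster count L = 1..K.

    ``memberships[L]`` is the K x L binary membership matrix B of the
    L-cluster partition; columns are ordered by each cluster's smallest
    member index.  Successive partitions are nested (one agglomerative tree).
    """

    K: int
    memberships: dict[int, np.ndarray]
    linkage: str = "average"

    def __post_init__(self) -> None:
        if set(self.memberships) != set(range(1, self.K + 1)):
            raise ValueError("need one partition for every L in 1..K")
        prev_labels = None
        for L in range(self.K, 0, -1):
            B = np.asarray(self.memberships[L])
            if B.shape != (self.K, L):
                raise ValueError(f"membership matrix for L={L} has wrong shape")
            if not ((B == 0) | (B == 1)).all() or not (B.sum(axis=1) == 1).all():
                raise ValueError("rows must contain exactly one 1")
            if (B.sum(axis=0) < 1).any():
                raise ValueError("empty cluster")
            labels = B.argmax(axis=1)
            if prev_labels is not None:
                # merging from L+1 to L must only fuse clusters, never split
                pairs = set(zip(prev_labels.tolist(), labels.tolist()))
                if len({a for a, _ in pairs}) != len(pairs):
                    raise ValueError("partitions are not nested")
            prev_labels = labels

    def labels(self, L: int) -> np.ndarray:
        """Cluster label (0..L-1) of each phenotype at cluster count L."""
        return self.memberships[L].argmax(axis=1)


def _cluster_sequence(D: np.ndarray, linkage: str) -> list[np.ndarray]:
    """Agglomerate singletons under the given linkage; return per-level labels.

    Ties in the merge distance are broken by the lexicographically smallest
    (minimum member index, other minimum member index) pair, making the tree
    deterministic for fully tied inputs such as R = I.
    """
    K = D.shape[0]
    members: list[list[int]] = [[i] for i in range(K)]
    sizes = np.ones(K)
    dist = D.copy().astype(float)
    np.fill_diagonal(dist, np.inf)
    active = list(range(K))
    labels_by_level: dict[int, np.ndarray] = {}

    def record() -> None:
        L = len(active)
        # order clusters by smallest member
        order = sorted(active, key=lambda c: members[c][0])
        lab = np.empty(K, dtype=int)
        for j, c in enumerate(order):
            lab[np.array(members[c])] = j
        labels_by_level[L] = lab

    record()
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                mA, mB = members[a][0], members[b][0]
                key = (dist[a, b], min(mA, mB), max(mA, mB))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        # Lance-Williams update of cluster-to-cluster distances
        for c in active:
            if c in (a, b):
                continue
            if linkage == "single":
                d = min(dist[a, c], dist[b, c])
            elif linkage == "complete":
                d = max(dist[a, c], dist[b, c])
            else:  # average (UPGMA)
                d = (sizes[a] * dist[a, c] + sizes[b] * dist[b, c]) / (
                    sizes[a] + sizes[b]
                )
            dist[a, c] = dist[c, a] = d
        members[a] = sorted(members[a] + members[b])
        sizes[a] += sizes[b]
        active.remove(b)
        dist[b, :] = dist[:, b] = np.inf
        record()
    return labels_by_level


def hierarchical_partitions(R, linkage: str = "average") -> ClusterPartitionSet:
    """Build the nested partitions of K phenotypes from one hierarchical tree.

    Agglomerative clustering on the dissimilarity D = 1 - R (entrywise, zero
    diagonal): starting from singletons, the two closest clusters are merged
    until a single cluster remains; cutting the tree at every level yields
    the partitions for L = K..1.  Negative correlations simply give D > 1.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    A = as_matrix(R)
    K = A.shape[0]
    if K == 1:
        return ClusterPartitionSet(1, {1: np.ones((1, 1))}, linkage)
    D = 1.0 - A
    np.fill_diagonal(D, 0.0)
    labels_by_level = _cluster_sequence(D, linkage)
    memberships = {
        L: np.eye(L)[lab] for L, lab in labels_by_level.items()
    }
    return ClusterPartitionSet(K, memberships, linkage)


def _inverse_factor(R: np.ndarray):
    """Cholesky factor of R for solves; shrink toward I if R is numerically
    singular (duplicate phenotypes must not crash a scan)."""
    try:
        return linalg.cho_factor(R, lower=True)
    except linalg.LinAlgError:
        warnings.warn(
            "correlation matrix numerically singular; applying shrinkage "
            "(1-eps) R + eps I with eps = 1e-6",
            stacklevel=2,
        )
        eps = 1e-6
        return linalg.cho_factor((1 - eps) * R + eps * np.eye(R.shape[0]), lower=True)


def clc_statistic(z, R, B) -> tuple[float, float]:
    """CLC quadratic form and its chi-square(L) upper-tail p for one partition.

    With W = B^T R^{-1} the form collapses to
    (B^T R^{-1} Z)^T (B^T R^{-1} B)^{-1} (B^T R^{-1} Z).
    """
    z = np.asarray(z, dtype=float)
    A = as_matrix(R)
    B = np.asarray(B, dtype=float)
    L = B.shape[1]
    cho = _inverse_factor(A)
    u = B.T @ linalg.cho_solve(cho, z)
    C = B.T @ linalg.cho_solve(cho, B)
    try:
        c_cho = linalg.cho_factor((C + C.T) / 2, lower=True)
    except linalg.LinAlgError:
        raise ValueError(
            "cluster covariance W R W^T is singular (degenerate clustering)"
        ) from None
    stat = float(u @ linalg.cho_solve(c_cho, u))
    stat = max(stat, 0.0)
    pvalue = float(np.exp(stats.chi2.logsf(stat, df=L)))
    return stat, pvalue


def _cauchy_terms(p: np.ndarray, logp: np.ndarray | None = None) -> np.ndarray:
    """tan((0.5 - p) pi) with its 1/(p pi) tail for tiny p.

    ``logp`` (natural log of p), when given, extends the tail below the
    double-precision floor of p itself.
    """
    p = np.asarray(p, dtype=float)
    pc = np.minimum(p, _P_CLAMP)
    with np.errstate(over="ignore", divide="ignore"):
        terms = np.where(
            pc < _TINY_P,
            1.0 / (np.maximum(pc, 5e-324) * np.pi),
            np.tan((0.5 - pc) * np.pi),
        )
    if logp is not None:
        logp = np.asarray(logp, dtype=float)
        tiny = logp < math.log(_TINY_P)
        with np.errstate(over="ignore"):
            terms = np.where(tiny, np.exp(-logp) / np.pi, terms)
    return np.minimum(terms, 1e308)


def _cauchy_sf(T):
    """Upper-tail probability of a standard Cauchy variate, stable at both
    tails: 0.5 - arctan(T)/pi evaluated as arctan(1/T)/pi for T > 0."""
    T = np.asarray(T, dtype=float)
    with np.errstate(divide="ignore"):
        inv = np.where(T != 0, 1.0 / np.where(T != 0, T, 1.0), np.inf)
    p = np.where(
        T > 0,
        np.arctan(inv) / np.pi,
        np.where(T < 0, 1.0 - np.arctan(-inv) / np.pi, 0.5),
    )
    return np.clip(p, 5e-324, 1.0)


def _neg_log10_cauchy_sf(T):
    """-log10 of the combined p, computed in log space for the far tail."""
    T = np.asarray(T, dtype=float)
    out = np.empty(T.shape or (1,))
    flat = np.atleast_1d(T)
    res = np.empty_like(flat)
    big = flat > 1e15
    res[big] = np.log10(np.pi) + np.log10(flat[big])
    res[~big] = -np.log10(_cauchy_sf(flat[~big]))
    if T.ndim == 0:
        return float(res[0])
    return res.reshape(T.shape)


def cauchy_combination(pvalues) -> tuple[float, float]:
    """Combine dependent p-values via the Cauchy (ACAT-style) method.

    Returns (T, p) with T = mean of tan((0.5 - p) pi) and p its standard
    Cauchy upper-tail probability.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty vector")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("input p-values must lie strictly in (0, 1)")
    T = float(np.mean(_cauchy_terms(p)))
    return T, float(_cauchy_sf(T))


class SclcEngine:
    """Per-R precomputation for repeated sCLC evaluation.

    Factors the partitions, the whitened cluster loadings A_L = B_L^T R^{-1}
    and the cluster covariances C_L = B_L^T R^{-1} B_L once, so a genome scan
    costs only matrix products per SNP batch.
    """

    def __init__(self, R, linkage: str = "average", partitions: ClusterPartitionSet | None = None):
        self.R = as_matrix(R)
        self.K = self.R.shape[0]
        if partitions is None:
            partitions = hierarchical_partitions(R, linkage=linkage)
        if partitions.K != self.K:
            raise ValueError("partition set does not match R's dimension")
        self.partitions = partitions
        cho = _inverse_factor(self.R)
        self._A = {}
        self._C_cho = {}
        for L in range(1, self.K + 1):
            B = partitions.memberships[L]
            A_L = linalg.cho_solve(cho, B).T  # L x K, equals B^T R^{-1}
            C = A_L @ B
            try:
                self._C_cho[L] = linalg.cho_factor((C + C.T) / 2, lower=True)
            except linalg.LinAlgError:
                raise ValueError(
                    "cluster covariance singular (degenerate clustering)"
                ) from None
            self._A[L] = A_L

    def per_cluster_logp(self, zmat: np.ndarray) -> np.ndarray:
        """log p_L for every L; ``zmat`` is K x n, result K x n."""
        zmat = np.atleast_2d(np.asarray(zmat, dtype=float))
        if zmat.shape[0] != self.K:
            raise ValueError("Z matrix row count must equal K")
        logp = np.empty((self.K, zmat.shape[1]))
        for L in range(1, self.K + 1):
            U = self._A[L] @ zmat
            V = linalg.cho_solve(self._C_cho[L], U)
            statistic = np.maximum(np.einsum("ij,ij->j", U, V), 0.0)
            logp[L - 1] = stats.chi2.logsf(statistic, df=L)
        return logp

    def combine(self, logp: np.ndarray):
        """Cauchy-combine per-cluster-count log p columns -> (T, p, -log10 p)."""
        p = np.exp(logp)
        terms = _cauchy_terms(p, logp=logp)
        T = terms.mean(axis=0)
        return T, _cauchy_sf(T), _neg_log10_cauchy_sf(T)

    def test(self, z) -> TestResult:
        z = np.asarray(z, dtype=float)
        logp = self.per_cluster_logp(z[:, None])
        T, p, nlp = self.combine(logp)
        return TestResult(
            method="sclc",
            statistic=float(T[0]),
            pvalue=float(p[0]),
            detail={
                "per_cluster_p": np.exp(logp[:, 0]),
                "neg_log10_p": float(np.atleast_1d(nlp)[0]),
                "K": self.K,
                "linkage": self.partitions.linkage,
            },
        )


def sclc_test(z, R, partitions: ClusterPartitionSet | None = None, linkage: str = "average") -> TestResult:
    """Full sCLC test of one SNP's Z-score vector against R."""
    return SclcEngine(R, linkage=linkage, partitions=partitions).test(z)


def sclc_scan(zmat, R, partitions: ClusterPartitionSet | None = None, linkage: str = "average") -> list[TestResult]:
    """sCLC over an aligned K x M Z matrix; per-R factors computed once."""
    values = np.asarray(getattr(zmat, "values", zmat), dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a K x M matrix of Z scores")
    engine = SclcEngine(R, linkage=linkage, partitions=partitions)
    if values.shape[1] == 0:
        return []
    logp = engine.per_cluster_logp(values)
    T, p, nlp = engine.combine(logp)
    nlp = np.atleast_1d(nlp)
    results = []
    for j in range(values.shape[1]):
        results.append(
            TestResult(
                method="sclc",
                statistic=float(T[j]),
                pvalue=float(p[j]),
                detail={
                    "per_cluster_p": np.exp(logp[:, j]),
                    "neg_log10_p": float(nlp[j]),
                },
            )
        )
    return results
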