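"""Closed-form log-likelihood ratios for (E, A, B) triples.

Six nested-model tests on a genotype anchor E, its cis-gene A and a candidate
target B (expression supernormalized to zero mean / unit variance):

========  =========================  =====================================
test id   name                       statistic (nats)
========  =========================  =====================================
0         correlation                -(n/2) ln(1 - rho^2)
1         primary linkage            -(n/2) ln sigmaA^2
2         secondary linkage          -(n/2) ln sigmaB^2
3         conditional independence   -(n/2) ln(det) + (n/2) ln sigmaA^2
                                     + (n/2) ln(1 - rho^2)
4         relevance                  -(n/2) ln(det) + (n/2) ln sigmaA^2
5         controlled                 -(n/2) ln(det) + (n/2) ln(sigmaA^2 sigmaB^2)
========  =========================  =====================================

with ``rho = (1/n) sum A_i B_i``, per-genotype means ``mu_j`` (of A) and
``nu_j`` (of B), ``sigmaA^2 = 1 - sum_j (n_j/n) mu_j^2`` (likewise sigmaB^2),
``sigmaAB = 1 - sum_j (n_j/n) mu_j nu_j`` and
``det = sigmaA^2 sigmaB^2 - (rho + sigmaAB - 1)^2``.

All logarithm arguments are clamped below at 1e-300 so perfectly collinear
inputs give large finite statistics rather than infinities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .preprocess import GenotypeVector

__all__ = [
    "EPS",
    "GenotypeGroupStats",
    "group_stats",
    "llr_correlation",
    "llr_primary",
    "llr_secondary",
    "llr_independence",
    "llr_relevance",
    "llr_controlled",
    "LLRProfile",
    "llr_profile",
]

EPS = 1e-300
_NORM_TOL = 1e-6


def _check_supernormalized(x: np.ndarray, name: str) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] < 4:
        raise ValidationError(f"{name}: need at least 4 samples")
    mean = x.mean(axis=1)
    var = x.var(axis=1)
    if np.any(np.abs(mean) > _NORM_TOL) or np.any(np.abs(var - 1.0) > _NORM_TOL):
        raise ValidationError(
            f"{name}: rows must be supernormalized (zero mean, unit 1/n variance)"
        )
    return x


def _check_genotype(E: GenotypeVector, n: int, require_poly: bool = True) -> None:
    if E.n != n:
        raise ValidationError(f"genotype length {E.n} != sample count {n}")
    if require_poly and E.n_v < 2:
        raise DegenerateInputError("genotype has a single category (n_v = 1)")


def _safe_log(x: np.ndarray | float) -> np.ndarray | float:
    return np.log(np.maximum(x, EPS))


@dataclass
class GenotypeGroupStats:
    """Per-genotype sufficient statistics for one (E, A) against one or many B.

    ``nu_hat``, ``sigmaB2`` and ``sigmaAB`` are vectors over B rows;
    ``mu_hat`` and ``sigmaA2`` depend only on (E, A).
    """

    mu_hat: np.ndarray       # (n_v,)
    nu_hat: np.ndarray       # (m, n_v)
    sigmaA2: float
    sigmaB2: np.ndarray      # (m,)
    sigmaAB: np.ndarray      # (m,)
    rho_hat: np.ndarray      # (m,)
    n: int
    n_v: int


def group_stats(E: GenotypeVector, A: np.ndarray, B: np.ndarray) -> GenotypeGroupStats:
    """Compute all sufficient statistics in one pass over the data.

    ``B`` may be a single supernormalized vector or a matrix of rows.
    """
    A = _check_supernormalized(A, "A")[0]
    B2d = _check_supernormalized(B, "B")
    n = A.size
    if B2d.shape[1] != n:
        raise ValidationError("A and B sample counts differ")
    _check_genotype(E, n)
    ind = E.indicator_matrix()              # (n_v, n)
    counts = ind.sum(axis=1)                # (n_v,)
    w = counts / n
    mu = (ind @ A) / counts                 # (n_v,)
    nu = (B2d @ ind.T) / counts             # (m, n_v)
    sigmaA2 = float(1.0 - np.dot(w, mu**2))
    sigmaB2 = 1.0 - (nu**2 @ w)
    sigmaAB = 1.0 - (nu * mu) @ w
    rho = B2d @ A / n
    return GenotypeGroupStats(
        mu_hat=mu, nu_hat=nu, sigmaA2=sigmaA2, sigmaB2=sigmaB2,
        sigmaAB=sigmaAB, rho_hat=rho, n=n, n_v=E.n_v,
    )


def llr_correlation(A: np.ndarray, B: np.ndarray) -> float | np.ndarray:
    """Correlation-test LLR; ``B`` may be a vector or a matrix of rows."""
    A = _check_supernormalized(A, "A")[0]
    B2d = _check_supernormalized(B, "B")
    if B2d.shape[1] != A.size:
        raise ValidationError("A and B sample counts differ")
    n = A.size
    rho = B2d @ A / n
    out = -(n / 2) * _safe_log(1.0 - rho**2)
    return out if np.asarray(B).ndim == 2 else float(out[0])


def llr_primary(E: GenotypeVector, A: np.ndarray) -> float:
    """Primary-linkage LLR: does E shift the mean of A?"""
    A = _check_supernormalized(A, "A")[0]
    _check_genotype(E, A.size)
    ind = E.indicator_matrix()
    counts = ind.sum(axis=1)
    mu = (ind @ A) / counts
    sigmaA2 = 1.0 - np.dot(counts / A.size, mu**2)
    return float(-(A.size / 2) * _safe_log(sigmaA2))


def llr_secondary(E: GenotypeVector, B: np.ndarray) -> float | np.ndarray:
    """Secondary-linkage LLR: does E shift the mean of B?  Vectorized over rows."""
    B2d = _check_supernormalized(B, "B")
    _check_genotype(E, B2d.shape[1])
    ind = E.indicator_matrix()
    counts = ind.sum(axis=1)
    nu = (B2d @ ind.T) / counts
    sigmaB2 = 1.0 - nu**2 @ (counts / B2d.shape[1])
    out = -(B2d.shape[1] / 2) * _safe_log(sigmaB2)
    return out if np.asarray(B).ndim == 2 else float(out[0])


def _llr345(stats: GenotypeGroupStats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = stats.n
    det = stats.sigmaA2 * stats.sigmaB2 - (stats.rho_hat + stats.sigmaAB - 1.0) ** 2
    log_det = _safe_log(det)
    log_sA2 = _safe_log(stats.sigmaA2)
    log_sB2 = _safe_log(stats.sigmaB2)
    llr4 = -(n / 2) * log_det + (n / 2) * log_sA2
    llr3 = llr4 + (n / 2) * _safe_log(1.0 - stats.rho_hat**2)
    llr5 = -(n / 2) * log_det + (n / 2) * (log_sA2 + log_sB2)
    return llr3, llr4, llr5


def llr_independence(E: GenotypeVector, A: np.ndarray, B: np.ndarray) -> float | np.ndarray:
    """Conditional-independence LLR (small values support the chain E->A->B)."""
    st = group_stats(E, A, B)
    if st.n < st.n_v + 3:
        raise ValidationError("need n >= n_v + 3 samples")
    out = _llr345(st)[0]
    return out if np.asarray(B).ndim == 2 else float(out[0])


def llr_relevance(E: GenotypeVector, A: np.ndarray, B: np.ndarray) -> float | np.ndarray:
    """Relevance LLR: is B dependent on (E, A) jointly?"""
    out = _llr345(group_stats(E, A, B))[1]
    return out if np.asarray(B).ndim == 2 else float(out[0])


def llr_controlled(E: GenotypeVector, A: np.ndarray, B: np.ndarray) -> float | np.ndarray:
    """Controlled LLR: is the A-B correlation more than pleiotropy of E?"""
    out = _llr345(group_stats(E, A, B))[2]
    return out if np.asarray(B).ndim == 2 else float(out[0])


@dataclass
class LLRProfile:
    """All six LLRs for one (E, A) anchor against one or many B rows.

    ``llr1`` depends only on (E, A) and is a scalar; the others are scalars
    for a single B vector and arrays for a B matrix.
    """

    llr0: float | np.ndarray
    llr1: float
    llr2: float | np.ndarray
    llr3: float | np.ndarray
    llr4: float | np.ndarray
    llr5: float | np.ndarray
    n: int
    n_v: int

    def by_test(self, test_id: int) -> float | np.ndarray:
        return (self.llr0, self.llr1, self.llr2, self.llr3, self.llr4, self.llr5)[test_id]


def llr_profile(E: GenotypeVector, A: np.ndarray, B: np.ndarray) -> LLRProfile:
    """Batched driver: all six LLRs for one (E, A) against B row(s) at once."""
    st = group_stats(E, A, B)
    n = st.n
    llr0 = -(n / 2) * _safe_log(1.0 - st.rho_hat**2)
    llr1 = float(-(n / 2) * _safe_log(st.sigmaA2))
    llr2 = -(n / 2) * _safe_log(st.sigmaB2)
    llr3, llr4, llr5 = _llr345(st)
    if np.asarray(B).ndim != 2:
        llr0, llr2, llr3, llr4, llr5 = (float(x[0]) for x in (llr0, llr2, llr3, llr4, llr5))
    return LLRProfile(llr0=llr0, llr1=llr1, llr2=llr2, llr3=llr3, llr4=llr4,
                      llr5=llr5, n=n, n_v=st.n_v)
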