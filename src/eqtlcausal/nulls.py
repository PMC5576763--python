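"""Analytical null laws for the scaled statistics LLR/n.

Under each test's null hypothesis, LLR/n follows the distribution of
``Z = -0.5 * ln(1 - Y)`` with ``Y ~ Beta(k1/2, k2/2)`` — written D(k1, k2).
The (k1, k2) pair depends only on the test, the sample count n and the number
of observed genotype categories n_v:

=====  ==================
test   (k1, k2)
=====  ==================
0      (1, n - 2)
1, 2   (n_v - 1, n - n_v)
3      (n_v - 1, n - n_v - 1)
4      (n_v, n - n_v - 1)
5      (1, n - n_v - 1)
=====  ==================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .exceptions import InapplicableTestError

__all__ = ["NullSpec", "null_spec", "d_pdf", "d_cdf", "d_sf", "d_quantile", "d_sample"]


@dataclass(frozen=True)
class NullSpec:
    """D(k1, k2) parameters for one test at given (n, n_v)."""

    test_id: int
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise InapplicableTestError(
                f"test {self.test_id}: D({self.k1}, {self.k2}) has non-positive "
                "degrees of freedom at this (n, n_v)"
            )


def null_spec(test_id: int, n: int, n_v: int | None = None) -> NullSpec:
    """Map (test, n, n_v) to the D(k1, k2) null law of LLR/n.

    ``n_v`` is ignored for test 0 and required for tests 1-5.
    """
    if test_id == 0:
        return NullSpec(0, 1, n - 2)
    if n_v is None:
        raise InapplicableTestError(f"test {test_id} requires n_v")
    if test_id in (1, 2):
        return NullSpec(test_id, n_v - 1, n - n_v)
    if test_id == 3:
        return NullSpec(3, n_v - 1, n - n_v - 1)
    if test_id == 4:
        return NullSpec(4, n_v, n - n_v - 1)
    if test_id == 5:
        return NullSpec(5, 1, n - n_v - 1)
    raise ValueError(f"unknown test id {test_id}")


def d_pdf(z: np.ndarray | float, spec: NullSpec) -> np.ndarray | float:
    """Density of D(k1, k2): ``2/B(k1/2,k2/2) (1-e^{-2z})^{k1/2-1} e^{-k2 z}``
    for z > 0, zero otherwise."""
    z = np.asarray(z, dtype=float)
    a, b = spec.k1 / 2.0, spec.k2 / 2.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        log_p = (
            np.log(2.0)
            - special.betaln(a, b)
            + (a - 1.0) * np.log1p(-np.exp(-2.0 * z))
            - spec.k2 * z
        )
        out = np.where(z > 0, np.exp(log_p), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def d_cdf(z: np.ndarray | float, spec: NullSpec) -> np.ndarray | float:
    """CDF via the Beta substitution ``y = 1 - e^{-2z}``."""
    z = np.asarray(z, dtype=float)
    y = -np.expm1(-2.0 * np.maximum(z, 0.0))
    out = special.betainc(spec.k1 / 2.0, spec.k2 / 2.0, y)
    if out.ndim == 0:
        return float(out)
    return out


def d_sf(z: np.ndarray | float, spec: NullSpec) -> np.ndarray | float:
    """Survival function (upper-tail p-value) of D(k1, k2)."""
    z = np.asarray(z, dtype=float)
    y = -np.expm1(-2.0 * np.maximum(z, 0.0))
    out = special.betaincc(spec.k1 / 2.0, spec.k2 / 2.0, y)
    if out.ndim == 0:
        return float(out)
    return out


def d_quantile(q: np.ndarray | float, spec: NullSpec) -> np.ndarray | float:
    """Inverse CDF: ``z = -0.5 ln(1 - Beta^{-1}(q))``."""
    y = special.betaincinv(spec.k1 / 2.0, spec.k2 / 2.0, np.asarray(q, dtype=float))
    out = -0.5 * np.log1p(-y)
    if out.ndim == 0:
        return float(out)
    return out


def d_sample(spec: NullSpec, count: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``count`` variates from D(k1, k2), reproducibly under ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = stats.beta.rvs(spec.k1 / 2.0, spec.k2 / 2.0, size=count, random_state=rng)
    return -0.5 * np.log1p(-y)
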