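"""Empirical-Bayes conversion of observed LLR values into posterior
probabilities (local-FDR machinery).

The observed statistics for one test form a mixture of a known analytical
null (a :class:`~eqtlcausal.nulls.NullSpec`) and an unknown alternative.  The
null proportion ``pi0`` is estimated by aligning the null density with the
empirical density near zero, where the alternative is assumed absent; Bayes'
rule per histogram bin then yields the posterior probability of the
hypothesis of interest (alternative for tests 0, 1, 2, 4, 5; null for
test 3), clipped to [0, 1] and monotonized along the LLR axis.

All functions operate on the scaled statistic ``z = LLR / n``, the variate
whose null law is analytical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .nulls import NullSpec, d_cdf, d_sf

__all__ = ["LLRSample", "PosteriorMap", "estimate_pi0", "build_posterior_map", "posteriors"]

logger = logging.getLogger(__name__)

_MIN_PER_PAIR = 100


@dataclass
class LLRSample:
    """Observed LLR/n values for one test (one (E, A) row, or pooled)."""

    values: np.ndarray
    test_id: int
    spec: NullSpec

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValidationError("empty LLR sample")
        if np.any(v < -1e-9):
            raise ValidationError("LLR values must be non-negative")
        self.values = np.maximum(v, 0.0)


@dataclass
class PosteriorMap:
    """Piecewise-constant map from LLR/n to posterior probability."""

    pi0: float
    bin_edges: np.ndarray
    posterior_at_bin: np.ndarray
    direction: str  # "increasing" (tests 0,1,2,4,5) or "decreasing" (test 3)

    def __call__(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        idx = np.digitize(z, self.bin_edges) - 1
        idx = np.clip(idx, 0, self.posterior_at_bin.size - 1)
        out = np.where(np.isnan(z), np.nan, self.posterior_at_bin[idx])
        if out.ndim == 0:
            return float(out)
        return out


def _smooth(x: np.ndarray, passes: int = 2) -> np.ndarray:
    """3-bin moving average, repeated; edges padded by replication."""
    kernel = np.full(3, 1.0 / 3.0)
    for _ in range(passes):
        padded = np.concatenate(([x[0]], x, [x[-1]]))
        x = np.convolve(padded, kernel, mode="valid")
    return x


def _histogram(sample: LLRSample) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal-width bin edges on [0, max] with raw counts and null bin mass."""
    v = sample.values
    zmax = float(v.max())
    if zmax <= 0:
        zmax = 1.0 / max(sample.spec.k2, 1.0)  # all-zero sample: null-scale width
    n_bins = max(100, int(np.sqrt(v.size)))
    edges = np.linspace(0.0, zmax * (1 + 1e-12), n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    null_mass = np.diff(d_cdf(edges, sample.spec))
    return edges, counts, null_mass


def estimate_pi0(sample: LLRSample) -> float:
    """Estimate the null proportion from the low-LLR end of the mixture.

    Aligns the empirical and null distributions over the region holding the
    lowest decile of the observed values — where, by assumption, essentially
    all observations are null — as the ratio of empirical to null probability
    mass below that cutoff, capped at 1.  The ratio is computed on raw masses
    rather than smoothed histogram densities: the null density of D(k1, k2)
    diverges at 0+ for k1 < 2 and any smoothing there biases the estimate.
    """
    v = np.asarray(sample.values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise DegenerateInputError("cannot estimate pi0 from identical LLR values")
    cutoff = float(np.quantile(v, 0.1))
    if cutoff <= 0:
        positive = v[v > 0]
        if positive.size == 0:
            return 1.0
        cutoff = float(positive.min())
    data_mass = float(np.mean(v <= cutoff))
    null_mass = float(d_cdf(cutoff, sample.spec))
    if null_mass <= 0:
        return 1.0
    return min(1.0, data_mass / null_mass)


def build_posterior_map(sample: LLRSample, pi0: float | None = None) -> PosteriorMap:
    """Per-bin Bayes rule, monotonized and clipped to [0, 1].

    For tests 0, 1, 2, 4, 5 the posterior of the alternative,
    ``1 - pi0 * p_null / p_hat``, is made non-decreasing; for test 3 the
    posterior of the null, ``pi0 * p_null / p_hat``, is made non-increasing.
    Monotonization uses count-weighted isotonic regression (PAVA), which
    pools noisy bins with their neighbours instead of letting a single bin
    dominate.  Sparse far-tail bins, where the density ratio is driven by
    single observations, are additionally capped by the tail-mass bound
    ``1 - pi0 * SF0(z) / SF_hat(z)``: under a monotone likelihood ratio the
    local posterior never exceeds the posterior averaged over the tail, so
    the bound holds exactly and suppresses lone null outliers.
    """
    from scipy.optimize import isotonic_regression

    if pi0 is None:
        pi0 = estimate_pi0(sample)
    edges, counts, null_mass = _histogram(sample)
    n = counts.sum()
    data_mass = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(data_mass > 0, pi0 * null_mass / data_mass, 1.0)
    raw = _smooth(1.0 - ratio)
    weights = counts.astype(float) + 1e-9
    post_alt = np.clip(isotonic_regression(raw, weights=weights, increasing=True).x,
                       0.0, 1.0)
    tail_data = np.cumsum(counts[::-1])[::-1] / n
    tail_null = np.cumsum(null_mass[::-1])[::-1] + float(d_sf(edges[-1], sample.spec))
    with np.errstate(divide="ignore", invalid="ignore"):
        cap = np.where(tail_data > 0, 1.0 - pi0 * tail_null / tail_data, 1.0)
    post_alt = np.maximum.accumulate(np.clip(np.minimum(post_alt, cap), 0.0, 1.0))
    if sample.test_id == 3:
        return PosteriorMap(pi0=float(pi0), bin_edges=edges,
                            posterior_at_bin=1.0 - post_alt, direction="decreasing")
    return PosteriorMap(pi0=float(pi0), bin_edges=edges, posterior_at_bin=post_alt,
                        direction="increasing")


def posteriors(
    z_matrix: np.ndarray,
    spec: NullSpec,
    mode: str = "per-pair",
    min_targets: int = _MIN_PER_PAIR,
) -> np.ndarray:
    """Convert a matrix of LLR/n values (rows = (E, A) pairs, columns =
    candidate targets) into posterior probabilities.

    ``per-pair`` fits a separate mixture per row (recommended when each row
    has hundreds of candidates); ``pooled`` fits one mixture to all finite
    values.  Rows with fewer than ``min_targets`` finite values fall back to
    the pooled map with a logged warning.  NaN cells (e.g. excluded
    self-pairs) stay NaN.
    """
    z = np.atleast_2d(np.asarray(z_matrix, dtype=float))
    if mode not in ("per-pair", "pooled"):
        raise ValidationError(f"unknown mode {mode!r}")
    out = np.full_like(z, np.nan)
    finite = np.isfinite(z)

    pooled_map: PosteriorMap | None = None

    def get_pooled() -> PosteriorMap:
        nonlocal pooled_map
        if pooled_map is None:
            pooled_map = build_posterior_map(
                LLRSample(z[finite], spec.test_id, spec))
        return pooled_map

    if mode == "pooled":
        pm = get_pooled()
        out[finite] = pm(z[finite])
        return out

    for i in range(z.shape[0]):
        mask = finite[i]
        row = z[i, mask]
        if row.size < min_targets or np.ptp(row) == 0:
            logger.warning(
                "row %d: %d candidates < %d required for per-pair mode; "
                "falling back to pooled", i, row.size, min_targets)
            pm = get_pooled()
        else:
            pm = build_posterior_map(LLRSample(row, spec.test_id, spec))
        out[i, mask] = pm(row)
    return out
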