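"""Rank-based inverse-normal transformation of expression rows and
validation/encoding of genotype vectors.

Every continuous variable entering the likelihood-ratio machinery is first
*supernormalized*: mapped onto standard-normal quantiles of its ranks and then
re-standardized to exactly zero mean and unit (biased, 1/n) variance.  The
closed-form test statistics downstream assume this normalization exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "GenotypeVector",
    "supernormalize",
    "supernormalize_matrix",
    "zscore",
    "encode_genotypes",
]

_MIN_SAMPLES = 4


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with identifiers.

    Parameters
    ----------
    gene_ids
        One identifier per row.
    values
        Real matrix, shape ``(len(gene_ids), len(sample_ids))``.
    sample_ids
        One identifier per column.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene IDs")
        if self.values.shape[1] < _MIN_SAMPLES:
            raise ValidationError(f"need at least {_MIN_SAMPLES} samples")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("missing or non-finite expression values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def degenerate_rows(self) -> np.ndarray:
        """Boolean mask of rows whose values are all identical."""
        return np.ptp(self.values, axis=1) == 0


@dataclass
class GenotypeMatrix:
    """Variants x samples integer matrix with identifiers."""

    variant_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValidationError("genotype values must be a 2-D matrix")
        if vals.shape != (len(self.variant_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {vals.shape} does not match "
                f"{len(self.variant_ids)} variants x {len(self.sample_ids)} samples"
            )
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValidationError("duplicate variant IDs")
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = np.asarray(vals, dtype=float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                raise ValidationError("genotype values must be integers")
            vals = as_float.astype(np.int64)
        if np.any(vals < 0):
            raise ValidationError("genotype values must be non-negative")
        self.values = vals.astype(np.int64)

    def vector(self, variant_id: str) -> "GenotypeVector":
        idx = self.variant_ids.index(variant_id)
        return encode_genotypes(self.values[idx])


@dataclass
class GenotypeVector:
    """Integer-coded genotypes for one variant across samples.

    ``n_j`` counts samples per genotype category; only categories actually
    present (``n_j > 0``) participate in any per-genotype sum downstream.
    ``n_v`` is the number of such categories.
    """

    values: np.ndarray
    n_a: int = field(init=False)
    n_j: dict[int, int] = field(init=False)
    n_v: int = field(init=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 1:
            raise ValidationError("genotype vector must be 1-D")
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = np.asarray(vals, dtype=float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                raise ValidationError("genotype values must be integers")
            vals = as_float.astype(np.int64)
        if np.any(vals < 0):
            raise ValidationError("genotype values must be non-negative")
        self.values = vals.astype(np.int64)
        self.n = int(vals.size)
        categories, counts = np.unique(self.values, return_counts=True)
        self.n_a = int(categories.max()) if categories.size else 0
        self.n_j = {int(c): int(k) for c, k in zip(categories, counts)}
        self.n_v = int(categories.size)

    @property
    def categories(self) -> np.ndarray:
        """Sorted genotype values that actually occur in the samples."""
        return np.array(sorted(self.n_j), dtype=np.int64)

    def indicator_matrix(self) -> np.ndarray:
        """(n_v, n) one-hot matrix over the *present* categories only."""
        return (self.values[None, :] == self.categories[:, None]).astype(float)


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift/scale to exactly zero mean and unit biased variance."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)  # biased (1/n), matching the MLE forms
    if np.any(sd == 0):
        raise DegenerateInputError("cannot standardize a constant vector")
    return (x - mean) / sd


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain standardization to zero mean, unit (1/n) variance.

    Used in place of :func:`supernormalize` by the measurement-error
    simulation, and available as a pipeline switch.
    """
    return _standardize(x, axis=axis)


def supernormalize(row: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform of one vector.

    Ranks (average for ties) are mapped through the Blom offset
    ``(r - 3/8) / (n + 1/4)`` into standard-normal quantiles, then the result
    is re-standardized to exactly zero mean and unit biased variance, so the
    particular offset convention cannot leak into downstream statistics.

    Raises
    ------
    ValidationError
        On non-finite values or fewer than 4 samples.
    DegenerateInputError
        If all values are identical.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1:
        raise ValidationError("expected a 1-D vector")
    if row.size < _MIN_SAMPLES:
        raise ValidationError(f"need at least {_MIN_SAMPLES} samples, got {row.size}")
    if not np.all(np.isfinite(row)):
        raise ValidationError("missing or non-finite values")
    if np.ptp(row) == 0:
        raise DegenerateInputError("constant vector cannot be supernormalized")
    ranks = stats.rankdata(row, method="average")
    quantiles = stats.norm.ppf((ranks - 0.375) / (row.size + 0.25))
    return _standardize(quantiles)


def supernormalize_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply :func:`supernormalize` to every row of an expression matrix."""
    degenerate = matrix.degenerate_rows()
    if degenerate.any():
        bad = [g for g, d in zip(matrix.gene_ids, degenerate) if d]
        raise DegenerateInputError(f"constant expression rows: {', '.join(bad[:5])}")
    out = np.vstack([supernormalize(r) for r in matrix.values])
    return ExpressionMatrix(list(matrix.gene_ids), out, list(matrix.sample_ids))


def encode_genotypes(raw: np.ndarray) -> GenotypeVector:
    """Validate and summarize an integer genotype vector.

    Pure summary: applying it to the ``values`` field of its own result gives
    an identical object.
    """
    return GenotypeVector(np.asarray(raw))
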