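"""Composite causal scores and the dataset-level inference driver.

Two published score combinations over the per-test posteriors (with the
primary-test posterior P1 fixed to 1 for pre-validated eQTLs):

* traditional:  ``PT = P2 * P3``
* novel:        ``P  = (P2 * P5 + P4) / 2``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .lrt import llr_profile
from .nulls import null_spec
from .posterior import posteriors
from .preprocess import (
    ExpressionMatrix,
    GenotypeMatrix,
    encode_genotypes,
    supernormalize_matrix,
    zscore,
)

__all__ = ["InferenceConfig", "ScoreSet", "score_traditional", "score_novel", "infer_all"]

logger = logging.getLogger(__name__)

_SCORED_TESTS = (0, 2, 3, 4, 5)


@dataclass
class InferenceConfig:
    """Knobs for :func:`infer_all`.

    ``mode`` selects per-(E,A) or pooled posterior estimation;
    ``supernormalize`` switches between rank-based inverse-normal transform
    (default) and plain z-scoring; ``diagnostic_p1`` additionally reports the
    primary-test posterior instead of assuming validated eQTLs.
    """

    mode: str = "per-pair"
    min_targets: int = 100
    supernormalize: bool = True
    diagnostic_p1: bool = False
    seed: int = 0


@dataclass
class ScoreSet:
    """Posterior matrices ((E, A) pairs x candidate B genes) plus composites.

    The column of each row's own A gene is NaN (self-pairs are never scored).
    """

    pair_eqtl_ids: list[str]
    pair_gene_ids: list[str]
    target_gene_ids: list[str]
    P0: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    P4: np.ndarray
    P5: np.ndarray
    PT: np.ndarray = field(init=False)
    Pnew: np.ndarray = field(init=False)
    P1: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.PT = score_traditional(self.P2, self.P3)
        self.Pnew = score_novel(self.P2, self.P4, self.P5)

    def by_name(self, name: str) -> np.ndarray:
        try:
            return {"P0": self.P0, "P2": self.P2, "P3": self.P3, "P4": self.P4,
                    "P5": self.P5, "PT": self.PT, "Pnew": self.Pnew}[name]
        except KeyError:
            raise ValidationError(f"unknown score {name!r}") from None


def _check_probs(name: str, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    finite = p[np.isfinite(p)]
    if np.any(finite < 0) or np.any(finite > 1):
        raise ValidationError(f"{name}: entries must lie in [0, 1]")
    return p


def score_traditional(P2: np.ndarray, P3: np.ndarray) -> np.ndarray:
    """Elementwise ``P2 * P3`` (P1 assumed 1 for validated eQTLs)."""
    P2, P3 = _check_probs("P2", P2), _check_probs("P3", P3)
    if P2.shape != P3.shape:
        raise ValidationError("P2 and P3 shapes differ")
    return P2 * P3


def score_novel(P2: np.ndarray, P4: np.ndarray, P5: np.ndarray) -> np.ndarray:
    """Elementwise ``(P2 * P5 + P4) / 2``; reduces to ``P4 / 2`` when P2 = 0."""
    P2, P4, P5 = _check_probs("P2", P2), _check_probs("P4", P4), _check_probs("P5", P5)
    if not (P2.shape == P4.shape == P5.shape):
        raise ValidationError("P2/P4/P5 shapes differ")
    return 0.5 * (P2 * P5 + P4)


def infer_all(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    pairs: list[tuple[str, str]],
    config: InferenceConfig | None = None,
) -> ScoreSet:
    """Run the full pipeline: normalize once, batch the six LLRs for every
    (E, A) anchor against all other genes, convert to posteriors, and
    assemble the composite scores.

    ``pairs`` maps each A gene to its (pre-validated) best eQTL E as
    ``(eqtl_id, gene_id)`` tuples.  Pairs whose genotype shows a single
    category are dropped with a warning; unknown IDs raise a named error.
    Deterministic given inputs and config.
    """
    config = config or InferenceConfig()
    if expression.sample_ids != genotypes.sample_ids:
        raise ValidationError("expression and genotype sample IDs differ")

    gene_index = {g: i for i, g in enumerate(expression.gene_ids)}
    bad = [f"{e}->{a}" for e, a in pairs
           if e not in genotypes.variant_ids or a not in gene_index]
    if bad:
        raise ValidationError(f"pairs reference unknown IDs: {', '.join(bad)}")

    if config.supernormalize:
        norm = supernormalize_matrix(expression).values
    else:
        norm = zscore(expression.values, axis=1)

    kept_pairs: list[tuple[str, str]] = []
    evecs, nvs = [], []
    for eqtl_id, gene_id in pairs:
        evec = genotypes.vector(eqtl_id)
        if evec.n_v < 2:
            logger.warning("pair (%s, %s): single genotype category; dropped",
                           eqtl_id, gene_id)
            continue
        kept_pairs.append((eqtl_id, gene_id))
        evecs.append(evec)
        nvs.append(evec.n_v)
    if not kept_pairs:
        raise DegenerateInputError("no usable (E, A) pairs")

    n = expression.n_samples
    n_pairs, n_genes = len(kept_pairs), expression.n_genes
    z_by_test = {t: np.full((n_pairs, n_genes), np.nan) for t in _SCORED_TESTS}
    llr1_vals = np.empty(n_pairs)

    for i, ((_, gene_id), evec) in enumerate(zip(kept_pairs, evecs)):
        a_idx = gene_index[gene_id]
        prof = llr_profile(evec, norm[a_idx], norm)
        llr1_vals[i] = prof.llr1
        for t in _SCORED_TESTS:
            z = np.asarray(prof.by_test(t), dtype=float) / n
            z[a_idx] = np.nan
            z_by_test[t][i] = z

    prob: dict[int, np.ndarray] = {}
    nvs_arr = np.array(nvs)
    for t in _SCORED_TESTS:
        out = np.full((n_pairs, n_genes), np.nan)
        if t == 0:
            out[:] = posteriors(z_by_test[t], null_spec(0, n),
                                mode=config.mode, min_targets=config.min_targets)
        else:
            # null law depends on n_v, so rows are grouped by n_v
            for nv in np.unique(nvs_arr):
                rows = nvs_arr == nv
                out[rows] = posteriors(z_by_test[t][rows], null_spec(t, n, int(nv)),
                                       mode=config.mode, min_targets=config.min_targets)
        prob[t] = out

    scoreset = ScoreSet(
        pair_eqtl_ids=[e for e, _ in kept_pairs],
        pair_gene_ids=[a for _, a in kept_pairs],
        target_gene_ids=list(expression.gene_ids),
        P0=prob[0], P2=prob[2], P3=prob[3], P4=prob[4], P5=prob[5],
    )
    if config.diagnostic_p1:
        # primary-test p-value-free diagnostic: pool LLR(1)/n across pairs
        from .posterior import LLRSample, build_posterior_map
        p1 = np.full(n_pairs, np.nan)
        for nv in np.unique(nvs_arr):
            rows = np.flatnonzero(nvs_arr == nv)
            vals = llr1_vals[rows] / n
            if vals.size >= 2 and np.ptp(vals) > 0:
                pm = build_posterior_map(LLRSample(vals, 1, null_spec(1, n, int(nv))))
                p1[rows] = pm(vals)
            else:
                p1[rows] = 1.0
        scoreset.P1 = p1
    return scoreset
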