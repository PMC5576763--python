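"""Synthetic data generators.

Two families:

* the measurement-error causal model ``E -> A_true -> B`` with
  ``A_true -> A`` (observed A is a noisy readout of the latent A_true), plus
  a grid scan of the two A-variance parameters that maps where each test
  rejects its null;
* a desk-scale eQTL-network generator with known groundtruth edges and
  confounded-pair labels, for end-to-end benchmarking.

All generators are deterministic under their seed.  Continuous variables are
plain z-scored here (not rank-transformed): the closed-form statistics only
require zero mean and unit variance, and the grid scan relies on smooth
common-random-number behaviour across tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .lrt import llr_profile
from .nulls import d_sf, null_spec
from .preprocess import ExpressionMatrix, GenotypeMatrix, encode_genotypes, zscore

__all__ = [
    "MeasurementErrorConfig",
    "SimulatedTriple",
    "simulate_triple",
    "GridScanResult",
    "grid_scan",
    "NetworkConfig",
    "NetworkDataset",
    "generate_network_dataset",
]

EQTL_MASK_P = 1e-6
GRID_SIGMA_MIN = 1e-2
GRID_SIGMA_MAX = 1e2


@dataclass
class MeasurementErrorConfig:
    """Parameters of the latent-variable triple model.

    ``sigmaA1_sq`` is the variance of A_true beyond the genotype,
    ``sigmaA2_sq`` the measurement-noise variance of the observed A, and
    ``sigmaB_sq`` B's residual variance relative to the unit-variance
    (standardized) A_true signal.
    """

    n: int = 300
    maf: float = 0.1
    sigmaA1_sq: float = 1.0
    sigmaA2_sq: float = 1.0
    sigmaB_sq: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ValidationError("maf must lie in (0, 1)")
        if min(self.sigmaA1_sq, self.sigmaA2_sq, self.sigmaB_sq) <= 0:
            raise ValidationError("all variances must be positive")
        if self.n < 4:
            raise ValidationError("need at least 4 samples")


@dataclass
class SimulatedTriple:
    """One simulated (E, A, B) with the latent A_true kept aside.

    ``A_true`` exists only for diagnostics; inference code must never see it.
    ``degenerate`` flags a monomorphic genotype draw.
    """

    E: np.ndarray
    A_true: np.ndarray
    A: np.ndarray
    B: np.ndarray
    degenerate: bool


def _triple_from_draws(
    E: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    x3: np.ndarray,
    sigmaA1_sq: float,
    sigmaA2_sq: float,
    sigmaB_sq: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Build (A_true, A, B) from fixed standard-normal draws; None if E constant."""
    if np.ptp(E) == 0:
        return None
    e_std = zscore(E.astype(float))
    a_true = e_std + np.sqrt(sigmaA1_sq) * x1
    a_obs = a_true + np.sqrt(sigmaA2_sq) * x2
    b_obs = zscore(a_true) + np.sqrt(sigmaB_sq) * x3
    return a_true, a_obs, b_obs


def simulate_triple(config: MeasurementErrorConfig) -> SimulatedTriple:
    """Draw one triple: ``E ~ Bernoulli(maf)`` per sample, then
    ``A_true ~ N(std(E), sigmaA1_sq)``, ``A ~ N(A_true, sigmaA2_sq)``,
    ``B ~ N(std(A_true), sigmaB_sq)`` (std = z-scoring across samples)."""
    rng = np.random.default_rng(config.seed)
    E = (rng.random(config.n) < config.maf).astype(np.int64)
    x1, x2, x3 = rng.standard_normal((3, config.n))
    built = _triple_from_draws(E, x1, x2, x3, config.sigmaA1_sq,
                               config.sigmaA2_sq, config.sigmaB_sq)
    if built is None:
        nan = np.full(config.n, np.nan)
        return SimulatedTriple(E=E, A_true=nan, A=nan, B=nan, degenerate=True)
    a_true, a_obs, b_obs = built
    return SimulatedTriple(E=E, A_true=a_true, A=a_obs, B=b_obs, degenerate=False)


@dataclass
class GridScanResult:
    """P-value heatmaps over the (sigmaA1_sq, sigmaA2_sq) grid.

    ``pvalues[t][i, j]`` is the (median-over-replicate) p-value of test ``t``
    at ``sigmaA1_sq[i], sigmaA2_sq[j]``; ``masked`` marks tiles without a
    significant primary (E -> A) association.
    """

    sigmaA1_sq: np.ndarray
    sigmaA2_sq: np.ndarray
    pvalues: dict[int, np.ndarray]
    masked: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, grid in sorted(self.pvalues.items()):
            for i, s1 in enumerate(self.sigmaA1_sq):
                for j, s2 in enumerate(self.sigmaA2_sq):
                    rows.append((s1, s2, t, grid[i, j], bool(self.masked[i, j])))
        return pd.DataFrame(rows, columns=["sigmaA1_sq", "sigmaA2_sq", "test_id",
                                           "p_value", "masked"])


def grid_scan(
    base: MeasurementErrorConfig,
    grid_points: int = 25,
    n_replicates: int = 1,
) -> GridScanResult:
    """Scan ``sigmaA1_sq`` and ``sigmaA2_sq`` over ``grid_points`` log-spaced
    values in [1e-2, 1e2] and record the null p-values of tests 2-5 per tile.

    The same random draws (seeded from ``base.seed``) are reused for every
    tile within a replicate, so p-values vary smoothly across the grid; with
    ``n_replicates > 1`` the per-tile median over replicates is reported.
    Tiles whose primary-test p-value exceeds 1e-6 are masked.
    """
    if grid_points < 2:
        raise ValidationError("grid_points must be >= 2")
    sig = np.logspace(np.log10(GRID_SIGMA_MIN), np.log10(GRID_SIGMA_MAX), grid_points)
    n = base.n
    shape = (grid_points, grid_points, n_replicates)
    pvals = {t: np.full(shape, np.nan) for t in (1, 2, 3, 4, 5)}
    rng = np.random.default_rng(base.seed)

    for r in range(n_replicates):
        E = (rng.random(n) < base.maf).astype(np.int64)
        while np.ptp(E) == 0:  # monomorphic draws carry no eQTL signal at all
            E = (rng.random(n) < base.maf).astype(np.int64)
        x1, x2, x3 = rng.standard_normal((3, n))
        evec = encode_genotypes(E)
        specs = {t: null_spec(t, n, evec.n_v) for t in (1, 2, 3, 4, 5)}
        for i, s1 in enumerate(sig):
            for j, s2 in enumerate(sig):
                _, a_obs, b_obs = _triple_from_draws(E, x1, x2, x3, s1, s2,
                                                     base.sigmaB_sq)
                prof = llr_profile(evec, zscore(a_obs), zscore(b_obs))
                for t in (1, 2, 3, 4, 5):
                    pvals[t][i, j, r] = d_sf(prof.by_test(t) / n, specs[t])

    med = {t: np.median(pvals[t], axis=2) for t in pvals}
    masked = med[1] > EQTL_MASK_P
    return GridScanResult(sigmaA1_sq=sig, sigmaA2_sq=sig,
                          pvalues={t: med[t] for t in (2, 3, 4, 5)}, masked=masked)


@dataclass
class NetworkConfig:
    """Desk-scale eQTL-network generator settings.

    ``edge_density`` is the probability that a gene receives a backbone
    regulator; ``confounder_fraction`` is the fraction of backbone edges that
    get a planted common upstream regulator for both endpoints (making the
    regulated pair confounded); ``effect_size`` scales both cis (genotype)
    and trans (regulator) effects against ``noise_sd``.  Confounder genes get
    their cis effect scaled by ``confounder_cis_scale`` (< 1): a confounder
    with a weak anchor cannot be conditioned away and its own outgoing edges
    stay hard to detect, mimicking hidden-confounder behaviour.
    """

    n_genes: int = 1000
    n_samples: int = 300
    maf: float = 0.3
    edge_density: float = 0.4
    confounder_fraction: float = 0.3
    effect_size: float = 1.0
    noise_sd: float = 1.0
    confounder_cis_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.edge_density <= 1.0 and 0.0 <= self.confounder_fraction <= 1.0):
            raise ValidationError("edge_density and confounder_fraction must lie in [0, 1]")
        if not (0.0 < self.maf < 1.0):
            raise ValidationError("maf must lie in (0, 1)")


@dataclass
class NetworkDataset:
    """Generated dataset plus groundtruth.

    ``edges`` are directed true regulations (gene IDs); ``confounded_pairs``
    are the ordered gene pairs sharing at least one direct upstream regulator.
    """

    expression: ExpressionMatrix
    genotypes: GenotypeMatrix
    pairs: list[tuple[str, str]]
    edges: set[tuple[str, str]]
    confounded_pairs: set[tuple[str, str]] = field(repr=False)


def generate_network_dataset(config: NetworkConfig) -> NetworkDataset:
    """Random DAG with planted cis-eQTL effects and linear propagation.

    Construction (gene index = topological order):

    1. each gene, with probability ``edge_density``, picks one childless
       earlier gene as its regulator — out-degree stays <= 1, so no two genes
       share a parent yet;
    2. for ``confounder_fraction`` of those edges (p -> g), a childless
       earlier gene c is rewired into a common parent (c -> p and c -> g),
       making (p, g) a confounded pair;
    3. every gene gets its own biallelic eQTL (0/1/2, Binomial(2, maf)) with a
       categorical cis shift, and expression propagates linearly down the DAG
       with Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_samples
    gene_ids = [f"G{i:04d}" for i in range(G)]
    eqtl_ids = [f"E{i:04d}" for i in range(G)]

    parents: dict[int, list[int]] = {i: [] for i in range(G)}
    n_children = np.zeros(G, dtype=int)
    backbone: list[tuple[int, int]] = []
    for g in range(1, G):
        if rng.random() < config.edge_density:
            candidates = np.flatnonzero(n_children[:g] == 0)
            if candidates.size == 0:
                continue
            p = int(rng.choice(candidates))
            parents[g].append(p)
            n_children[p] += 1
            backbone.append((p, g))

    n_conf = int(round(config.confounder_fraction * len(backbone)))
    conf_parents: set[int] = set()
    if n_conf > 0:
        chosen = rng.choice(len(backbone), size=n_conf, replace=False)
        for k in chosen:
            p, g = backbone[k]
            candidates = np.flatnonzero(n_children[:p] == 0)
            candidates = candidates[candidates != p]
            if candidates.size == 0:
                continue
            c = int(rng.choice(candidates))
            parents[p].append(c)
            parents[g].append(c)
            n_children[c] += 2
            conf_parents.add(c)

    genotype = rng.binomial(2, config.maf, size=(G, n)).astype(np.int64)
    for i in range(G):
        tries = 0
        while np.ptp(genotype[i]) == 0 and tries < 100:
            genotype[i] = rng.binomial(2, config.maf, size=n)
            tries += 1

    expr = np.empty((G, n))
    for g in range(G):
        cis = config.effect_size
        if g in conf_parents:
            cis *= config.confounder_cis_scale
        x = cis * zscore(genotype[g].astype(float))
        for p in parents[g]:
            x = x + config.effect_size * zscore(expr[p])
        expr[g] = x + config.noise_sd * rng.standard_normal(n)

    edges = {(gene_ids[p], gene_ids[g]) for g in range(G) for p in parents[g]}
    children: dict[int, list[int]] = {}
    for g, ps in parents.items():
        for p in ps:
            children.setdefault(p, []).append(g)
    confounded: set[tuple[str, str]] = set()
    for sibs in children.values():
        for a in sibs:
            for b in sibs:
                if a != b:
                    confounded.add((gene_ids[a], gene_ids[b]))

    sample_ids = [f"S{j:03d}" for j in range(n)]
    return NetworkDataset(
        expression=ExpressionMatrix(gene_ids, expr, sample_ids),
        genotypes=GenotypeMatrix(eqtl_ids, genotype, sample_ids),
        pairs=list(zip(eqtl_ids, gene_ids)),
        edges=edges,
        confounded_pairs=confounded,
    )
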