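"""Evaluation of ranked predictions against groundtruth.

AUROC uses the midrank (Mann-Whitney) convention.  AUPR uses Davis-Goadrich
interpolation: between consecutive achievable PR points the false-positive
count is linear in the true-positive count, which induces the correct
nonlinear path in precision; the area under that path has a closed form and
is integrated exactly per segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedMetricError, ValidationError
from .scores import InferenceConfig, ScoreSet, infer_all

__all__ = [
    "RankedPredictions",
    "auroc",
    "aupr",
    "pr_curve",
    "roc_curve",
    "scoreset_predictions",
    "subsample_evaluate",
    "local_precision_by_confounding",
    "precision_vs_estimated",
    "RANK_BIN_PERCENTS",
]

# nine ranked-percentile bins used for top-prediction precision reports
RANK_BIN_PERCENTS = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 10.0, 100.0)

DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


@dataclass
class RankedPredictions:
    """Scored ordered gene pairs with binary labels and optional confounded
    flags, sorted by non-increasing score (ties broken by a seeded shuffle)."""

    scores: np.ndarray
    labels: np.ndarray
    confounded: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels)
        if s.shape != y.shape or s.ndim != 1:
            raise ValidationError("scores and labels must be matching 1-D arrays")
        if not np.all(np.isin(y, (0, 1))):
            raise ValidationError("labels must be binary")
        self.scores, self.labels = s, y.astype(bool)
        if self.confounded is not None:
            c = np.asarray(self.confounded)
            if c.shape != s.shape:
                raise ValidationError("confounded flags must match scores")
            self.confounded = c.astype(bool)

    def sorted(self, seed: int = 0) -> "RankedPredictions":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.scores.size)
        order = perm[np.argsort(-self.scores[perm], kind="stable")]
        conf = None if self.confounded is None else self.confounded[order]
        return RankedPredictions(self.scores[order], self.labels[order], conf)


def _check_classes(labels: np.ndarray, need_both: bool = True) -> None:
    pos = int(labels.sum())
    if pos == 0:
        raise UndefinedMetricError("no positive labels")
    if need_both and pos == labels.size:
        raise UndefinedMetricError("no negative labels")


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Midrank AUROC: probability a random positive outranks a random negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    _check_classes(labels)
    ranks = stats.rankdata(scores, method="average")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _pr_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (TP, FP) at each distinct score threshold, descending."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order].astype(float)
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # keep only the last index of each tied-score block: achievable points
    keep = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    return tp[keep], fp[keep]


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve, Davis-Goadrich interpolation.

    Between achievable points a and b, FP is linear in TP with slope
    ``s = (FP_b - FP_a) / (TP_b - TP_a)``; the area contribution is
    ``(1/P) * integral of t / ((1+s) t + c) dt`` with ``c = FP_a - s TP_a``,
    evaluated in closed form.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    _check_classes(labels, need_both=False)
    n_pos = int(labels.sum())
    tp, fp = _pr_points(scores, labels)
    tp = np.concatenate(([0.0], tp))
    fp = np.concatenate(([0.0], fp))
    area = 0.0
    for a in range(len(tp) - 1):
        dtp = tp[a + 1] - tp[a]
        if dtp <= 0:
            continue  # recall does not advance: no area
        slope = (fp[a + 1] - fp[a]) / dtp
        alpha = 1.0 + slope
        c = fp[a] - slope * tp[a]
        lo, hi = tp[a], tp[a + 1]
        if abs(c) <= 1e-12:
            # precision constant 1/alpha along the segment
            seg = (hi - lo) / alpha
        else:
            seg = (hi - lo) / alpha - (c / alpha**2) * np.log(
                (alpha * hi + c) / (alpha * lo + c))
        area += seg
    return float(area / n_pos)


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Recall/precision at each achievable threshold (no interpolation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    _check_classes(labels, need_both=False)
    tp, fp = _pr_points(scores, labels)
    return pd.DataFrame({"recall": tp / labels.sum(), "precision": tp / (tp + fp)})


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """FPR/TPR at each achievable threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    _check_classes(labels)
    tp, fp = _pr_points(scores, labels)
    return pd.DataFrame({"fpr": fp / (~labels).sum(), "tpr": tp / labels.sum()})


def scoreset_predictions(
    scoreset: ScoreSet,
    score_name: str,
    edges: set[tuple[str, str]],
    confounded: set[tuple[str, str]] | None = None,
) -> RankedPredictions:
    """Flatten a score matrix into per-ordered-pair predictions with labels
    from the groundtruth edge set (self-pairs and NaN cells excluded)."""
    mat = scoreset.by_name(score_name)
    scores, labels, conf = [], [], []
    for i, a in enumerate(scoreset.pair_gene_ids):
        row = mat[i]
        for j, b in enumerate(scoreset.target_gene_ids):
            if a == b or not np.isfinite(row[j]):
                continue
            scores.append(row[j])
            labels.append((a, b) in edges)
            if confounded is not None:
                conf.append((a, b) in confounded)
    return RankedPredictions(
        np.array(scores), np.array(labels, dtype=bool),
        np.array(conf, dtype=bool) if confounded is not None else None)


def subsample_evaluate(
    expression,
    genotypes,
    pairs,
    edges: set[tuple[str, str]],
    N: int,
    k: int = 100,
    seed: int = 0,
    score_names: tuple[str, ...] = ("PT", "Pnew", "P0"),
    config: InferenceConfig | None = None,
) -> pd.DataFrame:
    """Repeat k times: draw N samples without replacement, re-run inference on
    the subset, score AUROC/AUPR; report mean, SD and SE per score."""
    from .preprocess import ExpressionMatrix, GenotypeMatrix

    n = expression.n_samples
    if N > n:
        raise ValidationError(f"subsample size {N} exceeds sample count {n}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    records: dict[tuple[str, str], list[float]] = {}
    for _ in range(k):
        idx = np.sort(rng.choice(n, size=N, replace=False))
        sub_expr = ExpressionMatrix(
            list(expression.gene_ids), expression.values[:, idx],
            [expression.sample_ids[i] for i in idx])
        sub_geno = GenotypeMatrix(
            list(genotypes.variant_ids), genotypes.values[:, idx],
            [genotypes.sample_ids[i] for i in idx])
        scoreset = infer_all(sub_expr, sub_geno, pairs, config)
        for name in score_names:
            preds = scoreset_predictions(scoreset, name, edges)
            records.setdefault((name, "auroc"), []).append(
                auroc(preds.scores, preds.labels))
            records.setdefault((name, "aupr"), []).append(
                aupr(preds.scores, preds.labels))
    rows = []
    for (name, metric), vals in records.items():
        v = np.array(vals)
        rows.append((name, metric, v.mean(), v.std(ddof=1) if k > 1 else 0.0,
                     (v.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0))
    return pd.DataFrame(rows, columns=["score", "metric", "mean", "sd", "se"])


def local_precision_by_confounding(
    predictions: RankedPredictions,
    rank_bin_percents: tuple[float, ...] = RANK_BIN_PERCENTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Precision of top predictions per ranked-percentile bin, split by
    confounding status.

    All pairs are ranked globally; each percentile range (of the full
    prediction universe) is split into confounded/unconfounded subgroups,
    reporting true counts (x), totals (y) and precision (NaN when empty).
    """
    if predictions.confounded is None:
        raise ValidationError("confounded flags are required")
    ranked = predictions.sorted(seed=seed)
    total = ranked.scores.size
    bounds = [int(round(p / 100.0 * total)) for p in rank_bin_percents]
    rows = []
    for b in range(len(bounds) - 1):
        lo, hi = bounds[b], bounds[b + 1]
        for flag, sub in ((False, "unconfounded"), (True, "confounded")):
            in_bin = slice(lo, hi)
            mask = ranked.confounded[in_bin] == flag
            y = int(mask.sum())
            x = int(ranked.labels[in_bin][mask].sum())
            rows.append((rank_bin_percents[b], rank_bin_percents[b + 1], sub,
                         x, y, x / y if y else np.nan))
    return pd.DataFrame(rows, columns=["pct_lo", "pct_hi", "subgroup",
                                       "true_count", "total_count", "precision"])


def precision_vs_estimated(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Observed precision and prediction count among scores >= each cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    rows = []
    for c in thresholds:
        mask = scores >= c
        count = int(mask.sum())
        prec = float(labels[mask].sum() / count) if count else np.nan
        rows.append((c, count, prec))
    return pd.DataFrame(rows, columns=["cutoff", "count", "precision"])
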