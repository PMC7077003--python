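"""Compare paired experimental and predicted effect scores.

Metrics follow the field's standard toolkit: Spearman ρ and Pearson R
(scipy.stats), mean squared error, ordinary least-squares regression lines,
ROC/AUC and precision-recall (scikit-learn), all on the harmonized unit
scale with "effect" as the positive class and higher score = more effect.
Confidence intervals are 95% percentile bootstrap over variant pairs
(1000 resamples by default), seeded and reproducible.

Undefined statistics (constant vectors, single-class label sets) are
refusals, never silently reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.metrics import auc as _trapezoid_auc

from dmsbench.dms_io import VariantKey
from dmsbench.errors import RefusalError
from dmsbench.predictors import PredictionSet
from dmsbench.score_processing import NormalizedDataset

DEFAULT_REPS = 1000


@dataclass
class PairedScores:
    """Experimental and predicted score vectors aligned on one variant-key set."""

    x: np.ndarray  # experimental normalized scores, [0, 1]
    p: np.ndarray  # predicted unit scores, [0, 1]
    keys: list[VariantKey]
    side: str = "deleterious"
    labels: np.ndarray | None = None  # "neutral"/"effect" per variant

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.p = np.asarray(self.p, float)
        if len(self.x) != len(self.p) or len(self.x) != len(self.keys):
            raise ValueError("x, p and keys must be aligned")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class MetricResult:
    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    bootstrap_reps: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn)


@dataclass
class RocResult:
    points: list[tuple[float, float]]  # (FPR, TPR), monotone nondecreasing
    auc: float
    ci_low: float
    ci_high: float
    n: int
    operating_points: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class BinnedRecall:
    """Recall (fraction called "effect") per effect-strength bin.

    Variants are sorted by experimental score and split into ``n_bins``
    contiguous equal-count bins; ``adjusted_recall`` subtracts the first
    bin's recall to remove each method's over-prediction floor.
    """

    n_bins: int
    bin_mean_score: np.ndarray
    bin_count: np.ndarray
    recall: np.ndarray
    adjusted_recall: np.ndarray


def pair_scores(
    dataset: NormalizedDataset,
    pred: PredictionSet,
    side: str,
    scheme: str | None = None,
) -> PairedScores:
    """Align a dataset and a prediction set on their largest common SAV subset.

    Only SAVs on the requested effect side are kept; the key order is
    deterministic (position, then mutant residue).  With ``scheme`` given,
    neutral/effect labels from that synonymous-thresholding column ride
    along.  Raises :class:`RefusalError` on an empty intersection.
    """
    if not pred.unit_scores:
        raise RefusalError(f"{pred.method.name}: no unit scores; "
                           f"run rescale_to_unit first")
    sub = dataset.side(side)
    keys, x, p, labels = [], [], [], []
    label_col = f"label_{scheme}" if scheme else None
    if label_col and label_col not in sub.columns:
        raise RefusalError(f"dataset {dataset.dataset_id}: no {label_col} column")
    for row in sub.itertuples():
        key = (row.protein_id, row.position, row.wt_aa, row.mut_aa)
        if key not in pred.unit_scores:
            continue
        keys.append(key)
        x.append(row.normalized_score)
        p.append(pred.unit_scores[key])
        if label_col:
            labels.append(getattr(row, label_col))
    if not keys:
        raise RefusalError(
            f"dataset {dataset.dataset_id} x {pred.method.name}: empty "
            f"common SAV subset on side {side!r}"
        )
    order = sorted(range(len(keys)), key=lambda i: (keys[i][1], keys[i][3]))
    return PairedScores(
        x=np.array(x)[order],
        p=np.array(p)[order],
        keys=[keys[i] for i in order],
        side=side,
        labels=np.array(labels)[order] if label_col else None,
    )


def _require_nonconstant(paired: PairedScores, metric: str) -> None:
    if paired.n < 3:
        raise RefusalError(f"{metric}: need n >= 3, got {paired.n}")
    if np.ptp(paired.x) == 0 or np.ptp(paired.p) == 0:
        raise RefusalError(f"{metric}: undefined for a constant score vector")


def spearman(paired: PairedScores) -> MetricResult:
    """Spearman rank correlation (average ranks for ties)."""
    _require_nonconstant(paired, "spearman_rho")
    rho = stats.spearmanr(paired.x, paired.p).statistic
    return MetricResult("spearman_rho", float(rho), np.nan, np.nan, paired.n)


def pearson(paired: PairedScores) -> MetricResult:
    """Pearson product-moment correlation."""
    _require_nonconstant(paired, "pearson_r")
    r = stats.pearsonr(paired.x, paired.p).statistic
    return MetricResult("pearson_r", float(r), np.nan, np.nan, paired.n)


def mse(paired: PairedScores) -> MetricResult:
    """Mean squared error between experimental and predicted scores."""
    if paired.n < 1:
        raise RefusalError("mse: empty input")
    est = float(np.mean((paired.x - paired.p) ** 2))
    return MetricResult("mse", est, np.nan, np.nan, paired.n)


# --- bootstrap ------------------------------------------------------------

def _rows_pearson(X: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; NaN for zero-variance rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=1, keepdims=True)
    num = (Xc * Pc).sum(axis=1)
    den = np.sqrt((Xc ** 2).sum(axis=1) * (Pc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


_FAST_STATS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "mse": lambda X, P: ((X - P) ** 2).mean(axis=1),
    "pearson_r": _rows_pearson,
    "spearman_rho": lambda X, P: _rows_pearson(
        stats.rankdata(X, axis=1), stats.rankdata(P, axis=1)),
}

_METRIC_NAMES = {spearman: "spearman_rho", pearson: "pearson_r", mse: "mse"}


def bootstrap_ci(
    metric: Callable[[PairedScores], MetricResult] | str,
    paired: PairedScores,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float]:
    """95% percentile bootstrap CI for a paired-score metric.

    Index pairs are resampled with replacement ``reps`` times, the metric is
    recomputed on each resample, and the (1-ci)/2 and 1-(1-ci)/2 empirical
    percentiles are returned.  The three core metrics run on a vectorized
    path; any other callable is applied per resample.  If the metric is
    undefined (e.g. constant resample) on more than half of the resamples,
    the CI is refused.
    """
    if reps < 2:
        raise RefusalError("bootstrap_ci: need reps >= 2")
    if paired.n < 3:
        raise RefusalError("bootstrap_ci: need n >= 3")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, paired.n, size=(reps, paired.n))
    name = metric if isinstance(metric, str) else _METRIC_NAMES.get(metric)
    if name in _FAST_STATS:
        values = _FAST_STATS[name](paired.x[idx], paired.p[idx])
    else:
        values = np.empty(reps)
        for r in range(reps):
            sub = PairedScores(paired.x[idx[r]], paired.p[idx[r]],
                               [paired.keys[i] for i in idx[r]], paired.side)
            try:
                values[r] = metric(sub).estimate
            except RefusalError:
                values[r] = np.nan
    valid = np.isfinite(values)
    if valid.mean() <= 0.5:
        raise RefusalError(
            f"bootstrap_ci: metric undefined on {np.sum(~valid)}/{reps} resamples")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(values[valid], [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate_metric(
    metric: Callable[[PairedScores], MetricResult],
    paired: PairedScores,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> MetricResult:
    """Point estimate plus bootstrap CI in one :class:`MetricResult`."""
    point = metric(paired)
    lo, hi = bootstrap_ci(metric, paired, reps=reps, seed=seed)
    return MetricResult(point.metric, point.estimate, lo, hi,
                        point.n, bootstrap_reps=reps, seed=seed)


# --- binary classification ------------------------------------------------

def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == "effect").astype(int)
    return arr.astype(int)


def roc_and_auc(
    labels: Sequence,
    scores: Sequence[float],
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> RocResult:
    """ROC curve over all distinct score thresholds, trapezoidal AUC, and a
    percentile-bootstrap AUC confidence interval.

    "effect" is the positive class; higher score = more effect.  Refuses
    single-class inputs.  ``reps=0`` skips the bootstrap (NaN CI).
    """
    y = _as_binary(labels)
    s = np.asarray(scores, float)
    if len(set(y)) < 2:
        raise RefusalError("roc_and_auc: both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    area = float(_trapezoid_auc(fpr, tpr))
    if reps == 0:
        return RocResult(points=list(zip(fpr.tolist(), tpr.tolist())),
                         auc=area, ci_low=np.nan, ci_high=np.nan, n=len(y))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(y), size=(reps, len(y)))
    values = np.empty(reps)
    for r in range(reps):
        yr, sr = y[idx[r]], s[idx[r]]
        if yr.min() == yr.max():
            values[r] = np.nan
            continue
        f, t, _ = roc_curve(yr, sr)
        values[r] = _trapezoid_auc(f, t)
    valid = np.isfinite(values)
    if valid.mean() <= 0.5:
        raise RefusalError("roc_and_auc: AUC undefined on most resamples")
    lo, hi = np.quantile(values[valid], [0.025, 0.975])
    return RocResult(points=list(zip(fpr.tolist(), tpr.tolist())),
                     auc=area, ci_low=float(lo), ci_high=float(hi), n=len(y))


def pr_curve(labels: Sequence, scores: Sequence[float]) -> list[tuple[float, float]]:
    """Precision-recall points at every distinct score threshold.

    Returns (recall, precision) pairs; the zero-predicted-positive endpoint
    (precision undefined) is omitted.
    """
    y = _as_binary(labels)
    if y.sum() == 0:
        raise RefusalError("pr_curve: need at least one positive")
    precision, recall, _ = precision_recall_curve(y, np.asarray(scores, float))
    # sklearn appends a (recall=0, precision=1) sentinel for the threshold
    # above the maximum score, where no positives are predicted — drop it.
    return list(zip(recall[:-1].tolist(), precision[:-1].tolist()))


def confusion_at_threshold(
    labels: Sequence, scores: Sequence[float], threshold: float
) -> ConfusionCounts:
    """Confusion counts calling "effect" when score > threshold."""
    y = _as_binary(labels)
    call = np.asarray(scores, float) > threshold
    return ConfusionCounts(
        tp=int(np.sum(call & (y == 1))),
        fp=int(np.sum(call & (y == 0))),
        fn=int(np.sum(~call & (y == 1))),
        tn=int(np.sum(~call & (y == 0))),
    )


def binned_recall(
    paired: PairedScores,
    binary_calls: Sequence,
    n_bins: int = 20,
    binning: str = "count",
) -> BinnedRecall:
    """Recall as a function of experimental effect strength.

    SAVs are sorted by experimental normalized score (stable, so ties keep
    the deterministic key order) and split into ``n_bins`` contiguous
    equal-count bins; the remainder is spread over the lowest bins, so bin
    sizes differ by at most one.  ``binning="width"`` instead cuts the
    observed score range into equal-width intervals (bins may then be empty;
    their recall is NaN).  Per-bin recall is the fraction of SAVs called
    "effect"; ``adjusted_recall`` subtracts bin 1's recall.
    """
    calls = np.asarray(
        [c == "effect" if isinstance(c, str) else bool(c)
         for c in binary_calls])
    if len(calls) != paired.n:
        raise ValueError("binary_calls must align with paired scores")
    if paired.n < n_bins:
        raise RefusalError(
            f"binned_recall: n={paired.n} < n_bins={n_bins}")
    order = np.argsort(paired.x, kind="stable")
    x_sorted = paired.x[order]
    calls_sorted = calls[order]
    if binning == "count":
        base, rem = divmod(paired.n, n_bins)
        sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
        edges = np.cumsum([0] + sizes)
    elif binning == "width":
        cuts = np.linspace(x_sorted[0], x_sorted[-1], n_bins + 1)
        edges = np.searchsorted(x_sorted, cuts[1:-1], side="left")
        edges = np.concatenate([[0], edges, [paired.n]])
    else:
        raise ValueError(f"unknown binning {binning!r}")
    mean_score = np.empty(n_bins)
    count = np.empty(n_bins, dtype=int)
    recall = np.empty(n_bins)
    for b in range(n_bins):
        sl = slice(int(edges[b]), int(edges[b + 1]))
        count[b] = edges[b + 1] - edges[b]
        if count[b] == 0:
            mean_score[b] = np.nan
            recall[b] = np.nan
            continue
        mean_score[b] = x_sorted[sl].mean()
        recall[b] = calls_sorted[sl].mean()
    return BinnedRecall(
        n_bins=n_bins,
        bin_mean_score=mean_score,
        bin_count=count,
        recall=recall,
        adjusted_recall=recall - recall[0],
    )


def regression_line(paired: PairedScores) -> tuple[float, float]:
    """Ordinary least-squares line of predicted on experimental scores.

    Returns (slope, intercept); refuses constant experimental vectors.
    """
    if paired.n < 2:
        raise RefusalError("regression_line: need n >= 2")
    if np.ptp(paired.x) == 0:
        raise RefusalError("regression_line: constant experimental scores")
    fit = stats.linregress(paired.x, paired.p)
    return float(fit.slope), float(fit.intercept)
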