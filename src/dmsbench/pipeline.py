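"""End-to-end benchmark orchestration.

One :class:`RunConfig` drives the whole analysis: read score sets →
normalize and classify → harmonize predictors → evaluate every
dataset × predictor × side combination → agreement statistics across
same-protein experiment pairs.  Refusals (empty intersections,
single-class labels, undefined correlations) become status rows in the
output tables, never aborts — partial predictor coverage is the norm, not
an error.

Reproducibility: a single global seed deterministically derives a
per-stage seed from (stage, dataset, method) via SHA-256, so adding or
removing one combination never shifts the randomness of another.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dmsbench.dms_io import (
    DmsDataset,
    check_sequence_consistency,
    read_fasta,
    read_prediction_table,
    read_pssm,
    read_scoreset,
)
from dmsbench.errors import ConfigurationError, RefusalError
from dmsbench.evaluation import (
    binned_recall,
    evaluate_metric,
    mse,
    pair_scores,
    pearson,
    pr_curve,
    regression_line,
    roc_and_auc,
    spearman,
)
from dmsbench.agreement import common_pair, delta_mse, delta_rho
from dmsbench.predictors import (
    PredictionSet,
    binary_call,
    gaussian_baseline,
    load_method_registry,
    naive_conservation,
    rescale_to_unit,
    shuffle_baseline,
)
from dmsbench.score_processing import NormalizedDataset, normalize_dataset

logger = logging.getLogger(__name__)

METRIC_TABLE_COLUMNS = ["dataset_id", "method", "side", "metric", "estimate",
                        "ci_low", "ci_high", "n", "reps", "seed", "status"]


def derive_seed(global_seed: int, *parts: object) -> int:
    """Stable per-stage seed below 2**31 from the global seed and context."""
    digest = hashlib.sha256(
        ":".join([str(global_seed), *map(str, parts)]).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class DatasetEntry:
    path: str
    dataset_id: str | None = None
    sequence_path: str | None = None
    wt_score: float = 0.0
    orientation: str = "higher_is_fitter"
    provenance: str = ""
    column_map: dict = field(default_factory=dict)
    sep: str = "\t"


@dataclass
class PredictorEntry:
    """One predictor source.

    ``kind`` is one of ``table`` (a score file, with ``method`` naming a
    registry entry), ``naive_conservation`` (``path`` is a PSSM file),
    ``shuffle`` (permutes the scores of the predictor named ``source``), or
    ``gaussian`` (normal draws around each experiment's score mean).
    """

    name: str
    kind: str = "table"
    path: str | None = None
    method: str | None = None
    source: str | None = None
    protein_id: str | None = None  # PSSM files carry no id; set or inferred
    column_map: dict = field(default_factory=dict)
    sep: str = "\t"


@dataclass
class RunConfig:
    datasets: list[DatasetEntry]
    predictors: list[PredictorEntry]
    schemes: tuple[str, ...] = ("syn90", "syn95", "syn99")
    reps: int = 1000
    bins: int = 20
    binning: str = "count"  # or "width": equal-width effect bins
    seed: int = 0
    output_dir: str = "dmsbench_out"
    method_registry: str | None = None
    point_tables: bool = True  # write per-threshold ROC/PR tables to disk

    def __post_init__(self) -> None:
        if not self.datasets or not self.predictors:
            raise ConfigurationError("need >= 1 dataset and >= 1 predictor")
        if self.reps < 2:
            raise ConfigurationError("bootstrap reps must be >= 2")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(
            datasets=[DatasetEntry(**d) for d in raw.get("datasets", [])],
            predictors=[PredictorEntry(**p) for p in raw.get("predictors", [])],
            schemes=tuple(raw.get("schemes", ("syn90", "syn95", "syn99"))),
            reps=int(raw.get("reps", 1000)),
            bins=int(raw.get("bins", 20)),
            binning=str(raw.get("binning", "count")),
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "dmsbench_out")),
            method_registry=raw.get("method_registry"),
        )


def _load_datasets(config: RunConfig) -> list[DmsDataset]:
    datasets = []
    for entry in config.datasets:
        ds = read_scoreset(
            entry.path,
            column_map=entry.column_map,
            orientation=entry.orientation,  # type: ignore[arg-type]
            wt_score=entry.wt_score,
            dataset_id=entry.dataset_id,
            provenance=entry.provenance,
            sep=entry.sep,
        )
        if entry.sequence_path:
            seqs = read_fasta(entry.sequence_path)
            seq = seqs.get(ds.protein_id) or next(iter(seqs.values()))
            ds = check_sequence_consistency(ds, seq)
        datasets.append(ds)
    return datasets


def _static_predictors(config: RunConfig) -> dict[str, PredictionSet]:
    """Predictors that do not depend on a dataset (tables, PSSM baseline)."""
    registry = load_method_registry(config.method_registry)
    out: dict[str, PredictionSet] = {}
    for entry in config.predictors:
        if entry.kind == "table":
            if entry.method not in registry:
                raise ConfigurationError(
                    f"predictor {entry.name}: unknown method {entry.method!r}")
            pred = read_prediction_table(
                entry.path, registry[entry.method],
                column_map=entry.column_map, sep=entry.sep)
            out[entry.name] = rescale_to_unit(pred)
        elif entry.kind == "naive_conservation":
            profile = read_pssm(entry.path, protein_id=entry.protein_id)
            out[entry.name] = rescale_to_unit(naive_conservation(profile))
        elif entry.kind not in ("shuffle", "gaussian"):
            raise ConfigurationError(
                f"predictor {entry.name}: unknown kind {entry.kind!r}")
    return out


def _resolve_predictor(
    entry: PredictorEntry,
    static: dict[str, PredictionSet],
    norm: NormalizedDataset,
    global_seed: int,
) -> PredictionSet:
    if entry.kind == "table":
        return static[entry.name]
    if entry.kind == "naive_conservation":
        # The ASCII PSSM dialect carries no protein identifier; when the
        # profile's id (file stem by default) is not the dataset's protein,
        # rebind it — a profile always describes exactly one protein, and a
        # genuinely wrong pairing still fails the key intersection on
        # positions and wild-type residues.
        pred = static[entry.name]
        ids = {k[0] for k in pred.scores}
        if entry.protein_id is None and ids and ids != {norm.protein_id}:
            remap = {(norm.protein_id, *k[1:]): v
                     for k, v in pred.scores.items()}
            remap_unit = {(norm.protein_id, *k[1:]): v
                          for k, v in pred.unit_scores.items()}
            return PredictionSet(method=pred.method, scores=remap,
                                 unit_scores=remap_unit)
        return pred
    seed = derive_seed(global_seed, entry.kind, norm.dataset_id, entry.name)
    if entry.kind == "shuffle":
        source = entry.source or next(iter(static), None)
        if source is None or source not in static:
            raise RefusalError(
                f"shuffle baseline {entry.name}: no source predictor")
        return shuffle_baseline(static[source], seed)
    # gaussian: around this experiment's own normalized score distribution
    exp_scores = {
        (r.protein_id, r.position, r.wt_aa, r.mut_aa): r.normalized_score
        for r in norm.table.itertuples()
    }
    return gaussian_baseline(exp_scores, seed)


def run_benchmark(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full benchmark and write its tables and manifest.

    Returns the tables also as DataFrames keyed by name (``metrics``,
    ``roc_points``, ``pr_points``, ``binned_recall``, ``agreement``).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    datasets = _load_datasets(config)
    normalized = {ds.dataset_id: normalize_dataset(ds, config.schemes)
                  for ds in datasets}
    static = _static_predictors(config)

    metric_rows, roc_rows, pr_rows, bin_rows, agree_rows = [], [], [], [], []

    for ds in datasets:
        norm = normalized[ds.dataset_id]
        for entry in config.predictors:
            try:
                pred = _resolve_predictor(entry, static, norm, config.seed)
            except RefusalError as exc:
                metric_rows.append(_status_row(ds.dataset_id, entry.name,
                                               "", "", str(exc)))
                continue
            for side in ("deleterious", "beneficial"):
                _evaluate_combination(
                    norm, pred, entry.name, side, config,
                    metric_rows, roc_rows, pr_rows, bin_rows)

    # agreement across same-protein dataset pairs
    by_protein: dict[str, list[DmsDataset]] = {}
    for ds in datasets:
        by_protein.setdefault(ds.protein_id, []).append(ds)
    for protein, group in by_protein.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                n1, n2 = normalized[group[i].dataset_id], \
                    normalized[group[j].dataset_id]
                for entry in config.predictors:
                    for side in ("deleterious", "beneficial"):
                        agree_rows.append(_agreement_row(
                            protein, n1, n2, entry, static, config, side))

    tables = {
        "metrics": pd.DataFrame(metric_rows, columns=METRIC_TABLE_COLUMNS),
        "roc_points": pd.DataFrame(
            roc_rows, columns=["dataset_id", "method", "side", "scheme",
                               "fpr", "tpr"]),
        "pr_points": pd.DataFrame(
            pr_rows, columns=["dataset_id", "method", "side", "scheme",
                              "recall", "precision"]),
        "binned_recall": pd.DataFrame(
            bin_rows, columns=["dataset_id", "method", "side", "bin",
                               "mean_score", "count", "recall",
                               "adjusted_recall"]),
        "agreement": pd.DataFrame(
            agree_rows, columns=["protein", "dataset_1", "dataset_2",
                                 "method", "side", "n", "rho_x1x2",
                                 "delta_rho", "mse_x1x2", "delta_mse",
                                 "low_n", "status"]),
    }
    for name, frame in tables.items():
        if not config.point_tables and name in ("roc_points", "pr_points"):
            continue
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "schemes": list(config.schemes),
        "datasets": {ds.dataset_id: {"protein_id": ds.protein_id,
                                     "n_variants": len(ds.variants),
                                     "n_savs": len(ds.savs)}
                     for ds in datasets},
        "row_counts": {name: len(frame) for name, frame in tables.items()},
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return tables


def _versions() -> dict[str, str]:
    import sklearn
    import scipy

    import dmsbench
    return {"dmsbench": dmsbench.__version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "sklearn": sklearn.__version__}


def _status_row(dataset_id, method, side, metric, status):
    return {"dataset_id": dataset_id, "method": method, "side": side,
            "metric": metric, "estimate": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "n": 0, "reps": 0, "seed": 0,
            "status": status}


def _evaluate_combination(norm, pred, method_name, side, config,
                          metric_rows, roc_rows, pr_rows, bin_rows):
    try:
        paired = pair_scores(norm, pred, side)
    except RefusalError as exc:
        metric_rows.append(_status_row(norm.dataset_id, method_name, side,
                                       "", str(exc)))
        return

    for fn in (spearman, pearson, mse):
        seed = derive_seed(config.seed, "bootstrap", norm.dataset_id,
                           method_name, side, fn.__name__)
        try:
            res = evaluate_metric(fn, paired, reps=config.reps, seed=seed)
            metric_rows.append({
                "dataset_id": norm.dataset_id, "method": method_name,
                "side": side, "metric": res.metric,
                "estimate": res.estimate, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "n": res.n,
                "reps": res.bootstrap_reps, "seed": seed, "status": "ok"})
        except RefusalError as exc:
            metric_rows.append(_status_row(norm.dataset_id, method_name,
                                           side, fn.__name__, str(exc)))

    try:
        slope, intercept = regression_line(paired)
        for metric, value in (("ols_slope", slope),
                              ("ols_intercept", intercept)):
            metric_rows.append({
                "dataset_id": norm.dataset_id, "method": method_name,
                "side": side, "metric": metric, "estimate": value,
                "ci_low": np.nan, "ci_high": np.nan, "n": paired.n,
                "reps": 0, "seed": 0, "status": "ok"})
    except RefusalError:
        pass

    # binned recall against the predictor's default-threshold calls
    try:
        calls = binary_call(pred)
        aligned_calls = [calls[k] for k in paired.keys]
        br = binned_recall(paired, aligned_calls, n_bins=config.bins,
                           binning=config.binning)
        for b in range(br.n_bins):
            bin_rows.append({
                "dataset_id": norm.dataset_id, "method": method_name,
                "side": side, "bin": b + 1,
                "mean_score": br.bin_mean_score[b],
                "count": int(br.bin_count[b]), "recall": br.recall[b],
                "adjusted_recall": br.adjusted_recall[b]})
    except (RefusalError, KeyError):
        pass

    # ROC / PR per synonymous-thresholding scheme
    for scheme in config.schemes:
        try:
            labeled = pair_scores(norm, pred, side, scheme=scheme)
        except RefusalError:
            continue
        if labeled.labels is None or "unlabeled" in labeled.labels:
            continue
        seed = derive_seed(config.seed, "roc", norm.dataset_id, method_name,
                           side, scheme)
        try:
            roc = roc_and_auc(labeled.labels, labeled.p, reps=config.reps,
                              seed=seed)
        except RefusalError as exc:
            metric_rows.append(_status_row(norm.dataset_id, method_name,
                                           side, f"auc_{scheme}", str(exc)))
            continue
        metric_rows.append({
            "dataset_id": norm.dataset_id, "method": method_name,
            "side": side, "metric": f"auc_{scheme}", "estimate": roc.auc,
            "ci_low": roc.ci_low, "ci_high": roc.ci_high, "n": roc.n,
            "reps": config.reps, "seed": seed, "status": "ok"})
        for fpr, tpr in roc.points:
            roc_rows.append({"dataset_id": norm.dataset_id,
                             "method": method_name, "side": side,
                             "scheme": scheme, "fpr": fpr, "tpr": tpr})
        try:
            for recall, precision in pr_curve(labeled.labels, labeled.p):
                pr_rows.append({"dataset_id": norm.dataset_id,
                                "method": method_name, "side": side,
                                "scheme": scheme, "recall": recall,
                                "precision": precision})
        except RefusalError:
            pass


def _agreement_row(protein, n1, n2, entry, static, config, side):
    from scipy import stats as _st

    row = {"protein": protein, "dataset_1": n1.dataset_id,
           "dataset_2": n2.dataset_id, "method": entry.name, "side": side,
           "n": 0, "rho_x1x2": np.nan, "delta_rho": np.nan,
           "mse_x1x2": np.nan, "delta_mse": np.nan, "low_n": False,
           "status": "ok"}
    try:
        pred = _resolve_predictor(entry, static, n1, config.seed)
        pair = common_pair(n1, n2, pred, side)
        row["n"] = pair.n
        row["low_n"] = pair.low_n
        row["rho_x1x2"] = float(_st.spearmanr(pair.x1, pair.x2).statistic)
        row["mse_x1x2"] = float(np.mean((pair.x1 - pair.x2) ** 2))
        row["delta_rho"] = delta_rho(pair)
        row["delta_mse"] = delta_mse(pair)
    except RefusalError as exc:
        row["status"] = str(exc)
    return row
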