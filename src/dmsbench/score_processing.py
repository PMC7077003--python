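"""Normalize raw DMS scores and derive neutral/effect labels from synonymous variants.

Raw assay scores are anchored so the wild type sits at 0 and oriented so
that negative values mean reduced fitness (deleterious) and positive values
mean gained fitness (beneficial).  Because assays are not symmetric around
wild type, the two sides are normalized and analyzed separately: within a
side, |signed score| is divided by the side's maximum so the strongest
observed effect maps to 1 and wild type to 0.

Synonymous variants leave the protein unchanged, so their score spread is a
direct readout of experimental noise around wild type.  The middle 90/95/99%
of the synonymous score distribution defines a neutral interval (schemes
syn90/syn95/syn99); any SAV scoring outside it is labeled "effect".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from dmsbench.dms_io import DmsDataset, VariantKey, VariantRecord
from dmsbench.errors import RefusalError

logger = logging.getLogger(__name__)

EffectSide = Literal["deleterious", "beneficial", "zero"]
Label = Literal["neutral", "effect", "unlabeled"]

SYN_SCHEMES = {"syn90": 0.90, "syn95": 0.95, "syn99": 0.99}

#: Minimum number of synonymous variants required to fit a neutral interval.
MIN_SYNONYMOUS = 10


@dataclass(frozen=True)
class AnchoredScore:
    """A variant's score on the signed, wild-type-anchored scale.

    ``signed_score`` is negative for deleterious variants, positive for
    beneficial ones, and 0 exactly at the wild-type anchor.
    """

    variant: VariantRecord
    signed_score: float

    @property
    def effect_side(self) -> EffectSide:
        if self.signed_score < 0:
            return "deleterious"
        if self.signed_score > 0:
            return "beneficial"
        return "zero"

    @property
    def key(self) -> VariantKey:
        return self.variant.key


@dataclass(frozen=True)
class SynThreshold:
    """Neutral interval from the synonymous-score distribution.

    ``lower_bound``/``upper_bound`` are the (1-coverage)/2 and
    1-(1-coverage)/2 empirical quantiles (linear interpolation between order
    statistics) of the synonymous signed scores.  The interval is closed at
    both ends: the synonymous variants defining the bounds are themselves
    neutral.
    """

    coverage: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound must not exceed upper_bound")

    def contains(self, signed_score: float | np.ndarray):
        return (self.lower_bound <= signed_score) & (signed_score <= self.upper_bound)


@dataclass
class NormalizedDataset:
    """A dataset on the normalized scale, as a tidy per-SAV table.

    Columns: protein_id, position, wt_aa, mut_aa, signed_score, effect_side,
    normalized_score, and one ``label_<scheme>`` column per applied scheme.
    Synonymous records are excluded (labels apply to SAVs only).
    """

    dataset_id: str
    protein_id: str
    table: pd.DataFrame
    thresholds: dict[str, SynThreshold]
    provenance: str = ""

    def side(self, side: str) -> pd.DataFrame:
        return self.table[self.table["effect_side"] == side]

    def keys(self) -> list[VariantKey]:
        return [tuple(t) for t in self.table[
            ["protein_id", "position", "wt_aa", "mut_aa"]].itertuples(index=False)]

    def write(self, path) -> None:
        cols = ["dataset_id", "protein_id", "position", "wt_aa", "mut_aa",
                "signed_score", "effect_side", "normalized_score"]
        cols += [c for c in self.table.columns if c.startswith("label_")]
        out = self.table.copy()
        out.insert(0, "dataset_id", self.dataset_id)
        out[cols].to_csv(path, sep="\t", index=False)


def anchor_and_orient(dataset: DmsDataset) -> list[AnchoredScore]:
    """Anchor raw scores at the wild-type score and orient the sign.

    For a ``higher_is_fitter`` assay, signed = raw - wt_score; for a
    ``lower_is_fitter`` assay the difference is negated, so that negative
    always means loss of fitness.
    """
    sign = 1.0 if dataset.orientation == "higher_is_fitter" else -1.0
    return [AnchoredScore(v, sign * (v.raw_score - dataset.wt_score))
            for v in dataset.variants]


def interpolate_unit(
    anchored: Sequence[AnchoredScore], side: str
) -> dict[VariantKey, float]:
    """Map one side's effect magnitudes onto [0, 1].

    normalized = |signed| / max(|signed| on this side).  Strictly monotone in
    |signed|, so per-side rank statistics are unchanged.  Variants with
    signed score exactly 0 ("zero" side) map to 0.0 on either side.
    """
    on_side = [a for a in anchored if a.effect_side == side]
    if not on_side:
        logger.warning("no variants on side %r; empty normalization", side)
        return {}
    scale = max(abs(a.signed_score) for a in on_side)
    result = {a.key: abs(a.signed_score) / scale for a in on_side}
    result.update({a.key: 0.0 for a in anchored if a.effect_side == "zero"})
    return result


def synonymous_threshold(
    dataset: DmsDataset,
    coverage: float = 0.95,
    min_synonymous: int = MIN_SYNONYMOUS,
) -> SynThreshold:
    """Fit the neutral interval from a dataset's synonymous variants.

    Raises :class:`RefusalError` when fewer than ``min_synonymous``
    synonymous records are available — such datasets are excluded from
    classification analyses rather than thresholded unreliably.
    """
    syn = dataset.synonymous
    if len(syn) < min_synonymous:
        raise RefusalError(
            f"dataset {dataset.dataset_id}: {len(syn)} synonymous variants "
            f"(< {min_synonymous}); cannot derive a neutral interval"
        )
    anchored = anchor_and_orient(dataset)
    syn_keys = {v.key for v in syn}
    signed = np.array([a.signed_score for a in anchored if a.key in syn_keys])
    alpha = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(signed, [alpha, 1.0 - alpha])
    return SynThreshold(coverage=coverage, lower_bound=float(lo),
                        upper_bound=float(hi))


def classify_variants(
    anchored: Iterable[AnchoredScore], threshold: SynThreshold
) -> dict[VariantKey, Label]:
    """Label SAVs neutral/effect against a synonymous-derived interval.

    Closed interval: scores exactly at a bound are neutral.  Synonymous
    records are skipped (they define the interval; labels are for SAVs).
    """
    labels: dict[VariantKey, Label] = {}
    for a in anchored:
        if a.variant.is_synonymous:
            continue
        labels[a.key] = (
            "neutral" if threshold.contains(a.signed_score) else "effect"
        )
    return labels


def normalize_dataset(
    dataset: DmsDataset,
    schemes: Sequence[str] = ("syn90", "syn95", "syn99"),
    min_synonymous: int = MIN_SYNONYMOUS,
) -> NormalizedDataset:
    """Run the full per-dataset normalization: anchor, per-side unit
    interpolation, and synonymous thresholding for each requested scheme.

    Schemes that cannot be fitted (too few synonymous variants) yield
    all-"unlabeled" columns instead of aborting the dataset.
    """
    anchored = [a for a in anchor_and_orient(dataset)
                if not a.variant.is_synonymous]
    unit: dict[VariantKey, float] = {}
    for side in ("deleterious", "beneficial"):
        unit.update(interpolate_unit(anchored, side))

    rows = []
    for a in anchored:
        rows.append({
            "protein_id": a.variant.protein_id,
            "position": a.variant.position,
            "wt_aa": a.variant.wt_aa,
            "mut_aa": a.variant.mut_aa,
            "signed_score": a.signed_score,
            "effect_side": a.effect_side,
            "normalized_score": unit.get(a.key, 0.0),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            ["position", "mut_aa"], kind="stable").reset_index(drop=True)

    thresholds: dict[str, SynThreshold] = {}
    for scheme in schemes:
        coverage = SYN_SCHEMES[scheme]
        try:
            thr = synonymous_threshold(dataset, coverage, min_synonymous)
        except RefusalError:
            logger.info("dataset %s: scheme %s unavailable",
                        dataset.dataset_id, scheme)
            table[f"label_{scheme}"] = "unlabeled"
            continue
        thresholds[scheme] = thr
        labels = classify_variants(anchored, thr)
        table[f"label_{scheme}"] = [
            labels[(r.protein_id, r.position, r.wt_aa, r.mut_aa)]
            for r in table.itertuples()
        ] if len(table) else []
    return NormalizedDataset(
        dataset_id=dataset.dataset_id,
        protein_id=dataset.protein_id,
        table=table,
        thresholds=thresholds,
        provenance=dataset.provenance,
    )
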