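"""Harmonize predictor scores onto the unit effect scale, plus baselines.

External methods score variants on heterogeneous scales (some where lower
means more effect, e.g. SIFT).  Each method is described by a
:class:`MethodSpec` — theoretical score bounds, orientation, default binary
cutoff — held in a small editable YAML registry rather than in code, and its
scores are linearly mapped onto [0, 1] with 1 = highest effect.

Three baselines need no external tool:

* **Naïve conservation** — sign-flipped per-position log-odds from an
  iterative profile search (PSSM): the rarer a substitution among homologs,
  the higher its predicted effect.
* **Shuffled scores** — a predictor's own scores permuted across variants;
  preserves the score distribution while destroying all association.
* **Gaussian around the experimental mean** — draws from a normal fit to
  the experimental score vector; tests how far matching the score
  distribution alone gets a method on error metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from dmsbench.dms_io import PSSM_AA_ORDER, PssmProfile, VariantKey
from dmsbench.errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Default theoretical bounds for the naive-conservation (flipped PSSM) scale.
#: Integer log-odds emitted by PSI-BLAST stay well inside +-17 in practice;
#: pinned here (configurable) so unit rescaling is reproducible.
NAIVE_CONSERVATION_BOUNDS = (-17.0, 17.0)


@dataclass(frozen=True)
class MethodSpec:
    """Metadata describing one prediction method's score conventions."""

    name: str
    raw_min: float
    raw_max: float
    reversed: bool = False  # True when a LOWER raw score means MORE effect
    default_threshold: float = 0.0  # raw units
    beneficial_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.raw_min < self.raw_max:
            raise ConfigurationError(
                f"{self.name}: raw_min must be < raw_max "
                f"({self.raw_min} vs {self.raw_max})"
            )
        if not (self.raw_min <= self.default_threshold <= self.raw_max):
            raise ConfigurationError(
                f"{self.name}: default_threshold {self.default_threshold} "
                f"outside [{self.raw_min}, {self.raw_max}]"
            )

    def orient(self, scores: np.ndarray) -> np.ndarray:
        """Flip reversed scales so that higher always means more effect."""
        if self.reversed:
            return self.raw_max + self.raw_min - np.asarray(scores, float)
        return np.asarray(scores, float)


@dataclass
class PredictionSet:
    """One method's raw scores per variant key, plus harmonized unit scores."""

    method: MethodSpec
    scores: dict[VariantKey, float]
    unit_scores: dict[VariantKey, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scores)

    def keys(self) -> set[VariantKey]:
        return set(self.scores)


def load_method_registry(path: str | Path | None = None) -> dict[str, MethodSpec]:
    """Load method specs from YAML (the bundled registry by default)."""
    if path is None:
        text = (resources.files("dmsbench") / "data" / "methods.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    registry = {}
    for name, spec in raw.items():
        br = spec.get("beneficial_range")
        registry[name] = MethodSpec(
            name=name,
            raw_min=float(spec["raw_min"]),
            raw_max=float(spec["raw_max"]),
            reversed=bool(spec.get("reversed", False)),
            default_threshold=float(spec.get("default_threshold", 0.0)),
            beneficial_range=tuple(br) if br else None,
        )
    return registry


def naive_conservation(
    pssm: PssmProfile,
    bounds: tuple[float, float] = NAIVE_CONSERVATION_BOUNDS,
) -> PredictionSet:
    """Baseline predictor: sign-flipped PSSM log-odds.

    For every position and every one of the 19 non-native residues, the raw
    prediction is ``-log_odds``; substitutions rarely seen among homologs
    (negative log-odds) therefore score as high effect.  The binary cutoff
    is 0 on this flipped scale.
    """
    scores: dict[VariantKey, float] = {}
    for pos in range(1, len(pssm.sequence) + 1):
        wt = pssm.sequence[pos - 1]
        for j, aa in enumerate(PSSM_AA_ORDER):
            if aa == wt:
                continue
            scores[(pssm.protein_id, pos, wt, aa)] = float(
                -pssm.log_odds[pos - 1, j])
    spec = MethodSpec(
        name="naive_conservation",
        raw_min=bounds[0],
        raw_max=bounds[1],
        reversed=False,
        default_threshold=0.0,
    )
    return PredictionSet(method=spec, scores=scores)


def binary_call(pred: PredictionSet) -> dict[VariantKey, str]:
    """Default-threshold effect/neutral calls.

    A variant is called "effect" iff its oriented score strictly exceeds the
    oriented default threshold (for naive conservation: flipped score above
    0).  Scores exactly at the cutoff are neutral.
    """
    m = pred.method
    cut = m.orient(np.array([m.default_threshold]))[0]
    keys = list(pred.scores)
    oriented = m.orient(np.array([pred.scores[k] for k in keys]))
    return {k: ("effect" if s > cut else "neutral")
            for k, s in zip(keys, oriented)}


def rescale_to_unit(pred: PredictionSet) -> PredictionSet:
    """Linearly map raw scores onto [0, 1] using the method's theoretical
    bounds (reversed methods are flipped first).  Out-of-range values are
    clamped with a logged count."""
    m = pred.method
    keys = list(pred.scores)
    if not keys:
        return replace(pred, unit_scores={})
    oriented = m.orient(np.array([pred.scores[k] for k in keys]))
    unit = (oriented - m.raw_min) / (m.raw_max - m.raw_min)
    n_clamped = int(np.sum((unit < 0) | (unit > 1)))
    if n_clamped:
        logger.warning("%s: clamped %d unit scores to [0, 1]",
                       m.name, n_clamped)
    unit = np.clip(unit, 0.0, 1.0)
    return replace(pred, unit_scores=dict(zip(keys, unit.tolist())))


def map_beneficial_range(
    pred: PredictionSet, target: tuple[float, float] | None = None
) -> PredictionSet:
    """Min-max map a beneficial-side prediction subset onto a target interval.

    Used for methods whose beneficial-effect scores live on a different part
    of their scale (Envision-style): the subset's observed range is mapped
    onto ``target`` (the method's ``beneficial_range``, e.g. [0, 0.2]),
    preserving rank order.  If all scores are identical they map to the
    interval midpoint.
    """
    m = pred.method
    if target is None:
        if m.beneficial_range is None:
            raise ConfigurationError(
                f"{m.name}: no beneficial_range configured")
        target = m.beneficial_range
    lo, hi = target
    keys = list(pred.scores)
    if not keys:
        return replace(pred, unit_scores={})
    vals = np.array([pred.scores[k] for k in keys], float)
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        unit = np.full_like(vals, (lo + hi) / 2.0)
    else:
        unit = lo + (vals - vmin) / (vmax - vmin) * (hi - lo)
    return replace(pred, unit_scores=dict(zip(keys, unit.tolist())))


def shuffle_baseline(pred: PredictionSet, seed: int) -> PredictionSet:
    """Permute unit scores uniformly at random across variant keys.

    The multiset of scores is unchanged; any association with the
    experiment is destroyed.  Deterministic given the seed.
    """
    if not pred.unit_scores:
        raise ConfigurationError("shuffle_baseline needs unit_scores; "
                                 "run rescale_to_unit first")
    rng = np.random.default_rng(seed)
    keys = sorted(pred.unit_scores)  # deterministic order before permuting
    values = np.array([pred.unit_scores[k] for k in keys])
    permuted = values[rng.permutation(len(values))]
    spec = replace(pred.method, name=f"{pred.method.name}_shuffled")
    return PredictionSet(method=spec, scores=dict(pred.scores),
                         unit_scores=dict(zip(keys, permuted.tolist())))


def gaussian_baseline(
    experimental_scores: dict[VariantKey, float], seed: int
) -> PredictionSet:
    """Draw predictions from a normal distribution fitted to the
    experimental unit scores (mean and SD of the vector), clamped to [0, 1].
    """
    if len(experimental_scores) < 2:
        raise ConfigurationError("gaussian_baseline needs >= 2 scores")
    rng = np.random.default_rng(seed)
    keys = sorted(experimental_scores)
    x = np.array([experimental_scores[k] for k in keys])
    draws = np.clip(rng.normal(x.mean(), x.std(), size=len(x)), 0.0, 1.0)
    spec = MethodSpec(name="gaussian_baseline", raw_min=0.0, raw_max=1.0,
                      default_threshold=0.5)
    return PredictionSet(method=spec, scores=dict(zip(keys, draws.tolist())),
                         unit_scores=dict(zip(keys, draws.tolist())))
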