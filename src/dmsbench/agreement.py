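"""Agreement between repeated DMS experiments versus predictions.

When two independent experiments measure the same protein, their mutual
concordance is a ceiling for what any predictor can be expected to reach.
Two contrasts quantify this on the largest SAV set common to both
experiments and the predictor:

* ``delta_rho``  = 0.5*(ρ(x1,p1) + ρ(x2,p2)) - ρ(x1,x2)
* ``delta_mse``  = MSE(x1,x2) - 0.5*(MSE(x1,p1) + MSE(x2,p2))

Negative values of either mean the experiments agree more with each other
than with the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from dmsbench.errors import RefusalError
from dmsbench.predictors import PredictionSet
from dmsbench.score_processing import NormalizedDataset

#: Below this common-subset size, beneficial-side pairs are flagged low-n.
LOW_N_THRESHOLD = 10


@dataclass
class ExperimentPair:
    """Two experiments and a prediction aligned on one common SAV set.

    ``p1``/``p2`` are the predictor restricted to the pairing with each
    experiment; for a single harmonized predictor they coincide on the
    common set.
    """

    x1: np.ndarray
    x2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    dataset_1: str = ""
    dataset_2: str = ""
    method: str = ""
    side: str = "deleterious"
    low_n: bool = False

    def __post_init__(self) -> None:
        self.x1, self.x2 = np.asarray(self.x1, float), np.asarray(self.x2, float)
        self.p1, self.p2 = np.asarray(self.p1, float), np.asarray(self.p2, float)
        lengths = {len(self.x1), len(self.x2), len(self.p1), len(self.p2)}
        if len(lengths) != 1:
            raise ValueError("all four vectors must be aligned")
        if self.n < 3:
            raise RefusalError(
                f"experiment pair needs n >= 3 common SAVs, got {self.n}")

    @property
    def n(self) -> int:
        return len(self.x1)


def common_pair(
    exp1: NormalizedDataset,
    exp2: NormalizedDataset,
    pred: PredictionSet,
    side: str,
    min_n_flag: int = LOW_N_THRESHOLD,
    allow_same_provenance: bool = False,
) -> ExperimentPair:
    """Intersect two same-protein experiments and a prediction on one side.

    Pairs whose provenance tags mark a shared publication are excluded
    (set ``allow_same_provenance`` to override).  Refuses when fewer than 3
    SAVs are common to all three; small beneficial-side intersections are
    returned flagged ``low_n``.
    """
    if exp1.protein_id != exp2.protein_id:
        raise RefusalError(
            f"{exp1.dataset_id} and {exp2.dataset_id} target different "
            f"proteins ({exp1.protein_id} vs {exp2.protein_id})"
        )
    if (not allow_same_provenance and exp1.provenance and
            exp1.provenance == exp2.provenance):
        raise RefusalError(
            f"{exp1.dataset_id} and {exp2.dataset_id} share provenance "
            f"{exp1.provenance!r}; same-publication pairs are excluded"
        )
    if not pred.unit_scores:
        raise RefusalError(f"{pred.method.name}: no unit scores")

    def side_map(exp: NormalizedDataset) -> dict:
        sub = exp.side(side)
        return {(r.protein_id, r.position, r.wt_aa, r.mut_aa):
                r.normalized_score for r in sub.itertuples()}

    m1, m2 = side_map(exp1), side_map(exp2)
    common = sorted(set(m1) & set(m2) & set(pred.unit_scores),
                    key=lambda k: (k[1], k[3]))
    if len(common) < 3:
        raise RefusalError(
            f"{exp1.dataset_id} x {exp2.dataset_id} x {pred.method.name}: "
            f"only {len(common)} common SAVs on side {side!r}"
        )
    p = np.array([pred.unit_scores[k] for k in common])
    return ExperimentPair(
        x1=np.array([m1[k] for k in common]),
        x2=np.array([m2[k] for k in common]),
        p1=p, p2=p.copy(),
        dataset_1=exp1.dataset_id, dataset_2=exp2.dataset_id,
        method=pred.method.name, side=side,
        low_n=len(common) < min_n_flag,
    )


def _rho(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise RefusalError("delta_rho: undefined correlation "
                           "(constant vector)")
    return float(stats.spearmanr(a, b).statistic)


def delta_rho(pair: ExperimentPair) -> float:
    """Mean experiment-prediction ρ minus inter-experiment ρ (negative ⇒
    experiments agree better with each other)."""
    return 0.5 * (_rho(pair.x1, pair.p1) + _rho(pair.x2, pair.p2)) \
        - _rho(pair.x1, pair.x2)


def delta_mse(pair: ExperimentPair) -> float:
    """Inter-experiment MSE minus mean experiment-prediction MSE (negative ⇒
    experiments numerically closer to each other)."""
    def _mse(a, b):
        return float(np.mean((a - b) ** 2))
    return _mse(pair.x1, pair.x2) - 0.5 * (_mse(pair.x1, pair.p1)
                                           + _mse(pair.x2, pair.p2))
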