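"""Synthetic DMS datasets, replicates, predictors and PSSM profiles.

Real DMS score sets share a handful of statistical signatures: scores are
anchored at the wild type, synonymous variants cluster tightly around it,
deleterious variants outnumber (and reach further than) beneficial ones,
and repeated experiments on one protein agree only partially.  This module
generates data with exactly those signatures and *controlled* strength —
target rank correlations for predictors and replicates are hit via a
Gaussian copula — so every pipeline stage can be tested quantitatively
without any external data.

Effect-size defaults: per-side Gamma-distributed magnitudes (heavy-tailed,
strictly positive) with the deleterious scale larger than the beneficial
one, mirroring the deleterious skew of published scans; near-neutral SAVs
and synonymous variants draw from the same Normal(0, syn_noise_sd) noise.

Rank-correlation targeting: for a bivariate Gaussian copula with latent
Pearson correlation r, the population Spearman correlation is
ρ_S = (6/π)·arcsin(r/2), so the mixing weight is solved exactly as
r = 2·sin(π·ρ_S/6).  Everything is reproducible bit-for-bit from
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from dmsbench.dms_io import (
    PSSM_AA_ORDER,
    DmsDataset,
    PssmProfile,
    VariantRecord,
)
from dmsbench.errors import ConfigurationError
from dmsbench.predictors import MethodSpec, PredictionSet
from dmsbench.score_processing import anchor_and_orient

TRUTH_COLUMNS = ["protein_id", "position", "wt_aa", "mut_aa", "true_effect"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic DMS experiment.

    Defaults emulate a mid-sized scan: a 500-residue protein with full
    19·N SAV coverage, a deleterious:beneficial imbalance of ~3.7:1 among
    effect SAVs, 300 synonymous variants, and tight synonymous noise
    (sd 0.1 in raw score units where the strongest deleterious effects
    reach several units).
    """

    protein_length: int = 500
    fraction_deleterious: float = 0.55
    fraction_beneficial: float = 0.15
    n_synonymous: int = 300
    syn_noise_sd: float = 0.1
    deleterious_gamma: tuple[float, float] = (2.0, 1.0)  # (shape, scale)
    beneficial_gamma: tuple[float, float] = (2.0, 0.4)
    predictor_target_rho: float = 0.4
    replicate_target_rho: float = 0.93
    missingness: float = 0.0
    wt_score: float = 0.0
    orientation: str = "higher_is_fitter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length < 5:
            raise ConfigurationError("protein_length must be >= 5")
        fsum = self.fraction_deleterious + self.fraction_beneficial
        if not (0 <= self.fraction_deleterious <= 1
                and 0 <= self.fraction_beneficial <= 1 and fsum <= 1):
            raise ConfigurationError(
                "side fractions must lie in [0,1] and sum to <= 1")
        if not -1 < self.predictor_target_rho < 1:
            raise ConfigurationError("predictor_target_rho must be in (-1, 1)")
        if not -1 < self.replicate_target_rho < 1:
            raise ConfigurationError("replicate_target_rho must be in (-1, 1)")


def latent_pearson(target_spearman: float) -> float:
    """Latent Gaussian correlation that yields a target Spearman ρ
    (closed form for the bivariate normal copula)."""
    return 2.0 * np.sin(np.pi * target_spearman / 6.0)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Map values to standard-normal scores through their (average) ranks."""
    ranks = stats.rankdata(values)
    return stats.norm.ppf(ranks / (len(values) + 1.0))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(PSSM_AA_ORDER), size=length))


def generate_dms(config: SimulationConfig) -> tuple[DmsDataset, pd.DataFrame]:
    """Generate one DMS-like dataset plus its ground-truth effect table.

    Every one of the 19·N non-native SAVs is scored.  Each SAV is
    deleterious (signed effect = -Gamma draw), beneficial (+Gamma draw) or
    near-neutral (Normal(0, syn_noise_sd)) according to the configured
    fractions; synonymous records draw from the same noise distribution.
    Raw scores are true effect + wt_score under the configured orientation.

    Returns the dataset and a truth table (one row per SAV) with the signed
    ``true_effect`` retained for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.protein_length
    protein_id = f"synt{config.seed}"
    sequence = random_sequence(n, rng)

    records: list[VariantRecord] = []
    truth_rows = []
    sides = rng.choice(
        3,
        size=n * 19,
        p=[config.fraction_deleterious, config.fraction_beneficial,
           1.0 - config.fraction_deleterious - config.fraction_beneficial],
    )
    d_shape, d_scale = config.deleterious_gamma
    b_shape, b_scale = config.beneficial_gamma
    i = 0
    sign = 1.0 if config.orientation == "higher_is_fitter" else -1.0
    for pos in range(1, n + 1):
        wt = sequence[pos - 1]
        for aa in PSSM_AA_ORDER:
            if aa == wt:
                continue
            side = sides[i]
            i += 1
            if side == 0:
                effect = -rng.gamma(d_shape, d_scale)
            elif side == 1:
                effect = rng.gamma(b_shape, b_scale)
            else:
                effect = rng.normal(0.0, config.syn_noise_sd)
            raw = config.wt_score + sign * effect
            records.append(VariantRecord(protein_id, pos, wt, aa, raw))
            truth_rows.append((protein_id, pos, wt, aa, effect))

    syn_positions = rng.integers(1, n + 1, size=config.n_synonymous)
    syn_noise = rng.normal(0.0, config.syn_noise_sd,
                           size=config.n_synonymous)
    for pos, eps in zip(syn_positions, syn_noise):
        wt = sequence[pos - 1]
        records.append(VariantRecord(protein_id, int(pos), wt, wt,
                                     config.wt_score + sign * eps,
                                     is_synonymous=True))

    dataset = DmsDataset(
        dataset_id=f"{protein_id}_exp1",
        protein_id=protein_id,
        sequence=sequence,
        variants=records,
        wt_score=config.wt_score,
        orientation=config.orientation,  # type: ignore[arg-type]
        provenance=f"sim:{config.seed}:exp1",
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return dataset, truth


def generate_predictor(
    truth: pd.DataFrame,
    target_rho: float,
    seed: int,
    name: str = "synthetic_predictor",
    missingness: float = 0.0,
) -> PredictionSet:
    """Predictor scores with a controlled Spearman ρ to true effect strength.

    The truth's |effect| magnitudes are mapped to normal scores, mixed with
    independent Gaussian noise at the copula weight for ``target_rho``, and
    pushed through the normal CDF, yielding unit-interval scores whose
    realized Spearman against |true effect| matches the target up to
    sampling error.  A ``missingness`` fraction of SAVs is dropped
    (predictors failing for some residues).
    """
    if not -1 < target_rho < 1:
        raise ConfigurationError("target_rho must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    magnitude = np.abs(truth["true_effect"].to_numpy())
    z = _normal_scores(magnitude)
    r = latent_pearson(target_rho)
    z_pred = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(len(z))
    unit = stats.norm.cdf(z_pred)

    keys = [(row.protein_id, row.position, row.wt_aa, row.mut_aa)
            for row in truth.itertuples()]
    if missingness > 0:
        keep = rng.random(len(keys)) >= missingness
        keys = [k for k, kp in zip(keys, keep) if kp]
        unit = unit[keep]
    spec = MethodSpec(name=name, raw_min=0.0, raw_max=1.0,
                      default_threshold=0.5)
    scores = dict(zip(keys, unit.tolist()))
    return PredictionSet(method=spec, scores=scores, unit_scores=dict(scores))


def generate_replicate(
    dataset: DmsDataset, target_rho: float, seed: int
) -> DmsDataset:
    """A second experiment on the same protein at a controlled agreement.

    SAV scores: the original signed scores are mapped to normal scores,
    mixed with fresh noise at the copula weight for ``target_rho``, and the
    resulting ranks are mapped back onto the original score values
    (empirical quantile transform) — so the replicate has the *same*
    marginal score distribution but inter-experiment Spearman ρ ≈ target.
    Synonymous records are redrawn from the original synonymous noise.
    """
    if not -1 < target_rho < 1:
        raise ConfigurationError("target_rho must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    anchored = anchor_and_orient(dataset)
    sav_scores = np.array([a.signed_score for a in anchored
                           if not a.variant.is_synonymous])
    savs = [a.variant for a in anchored if not a.variant.is_synonymous]

    z = _normal_scores(sav_scores)
    r = latent_pearson(target_rho)
    z2 = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(len(z))
    # quantile-map the perturbed ranks back onto the observed marginal
    new_ranks = stats.rankdata(z2, method="ordinal") - 1
    new_signed = np.sort(sav_scores)[new_ranks]

    sign = 1.0 if dataset.orientation == "higher_is_fitter" else -1.0
    records = [
        dc_replace(v, raw_score=dataset.wt_score + sign * s)
        for v, s in zip(savs, new_signed)
    ]
    syn = dataset.synonymous
    if syn:
        syn_signed = np.array([sign * (v.raw_score - dataset.wt_score)
                               for v in syn])
        redraw = rng.normal(syn_signed.mean(), syn_signed.std(ddof=1),
                            size=len(syn))
        records += [
            dc_replace(v, raw_score=dataset.wt_score + sign * s)
            for v, s in zip(syn, redraw)
        ]
    return DmsDataset(
        dataset_id=f"{dataset.dataset_id}_rep{seed}",
        protein_id=dataset.protein_id,
        sequence=dataset.sequence,
        variants=records,
        wt_score=dataset.wt_score,
        orientation=dataset.orientation,
        provenance=f"{dataset.provenance}:rep{seed}",
    )


def generate_pssm(
    truth: pd.DataFrame,
    sequence: str,
    seed: int,
    noise_sd: float = 0.0,
    protein_id: str | None = None,
) -> PssmProfile:
    """A PSSM whose log-odds are anti-correlated with true effect strength.

    High-effect substitutions get low (negative) integer log-odds — the
    conservation signal a profile search would find if the assayed function
    were under selection.  ``noise_sd`` blurs the relationship (in log-odds
    units) to emulate imperfect conservation; values are rounded to
    integers and clipped to [-16, 16].  Wild-type residues score positive.
    """
    rng = np.random.default_rng(seed)
    if protein_id is None:
        protein_id = str(truth["protein_id"].iloc[0])
    n = len(sequence)
    magnitude = np.abs(truth["true_effect"].to_numpy())
    scale = magnitude.max() or 1.0
    log_odds = np.zeros((n, 20))
    log_odds[:, :] = np.nan
    for row, mag in zip(truth.itertuples(), magnitude):
        j = PSSM_AA_ORDER.index(row.mut_aa)
        value = 5.0 - 12.0 * (mag / scale)
        log_odds[row.position - 1, j] = value
    # unassigned cells (wild type, uncovered substitutions): mildly positive
    wt_default = 5.0
    log_odds = np.where(np.isnan(log_odds), wt_default, log_odds)
    if noise_sd > 0:
        log_odds = log_odds + rng.normal(0.0, noise_sd, size=log_odds.shape)
    log_odds = np.clip(np.rint(log_odds), -16, 16).astype(int)
    return PssmProfile(protein_id=protein_id, sequence=sequence,
                       log_odds=log_odds)
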