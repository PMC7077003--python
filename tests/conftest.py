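"""Shared fixtures: small in-memory datasets and independent metric oracles."""

import numpy as np
import pytest

from dmsbench.dms_io import DmsDataset, VariantRecord
from dmsbench.synthetic_data import SimulationConfig, generate_dms


def make_dataset(variant_tuples, dataset_id="ds1", protein_id="P1",
                 sequence="", wt_score=0.0, orientation="higher_is_fitter",
                 provenance=""):
    """Build a DmsDataset from (pos, wt, mut, score[, is_syn]) tuples."""
    variants = []
    for t in variant_tuples:
        pos, wt, mut, score = t[:4]
        is_syn = t[4] if len(t) > 4 else (wt == mut)
        variants.append(VariantRecord(protein_id, pos, wt, mut, score,
                                      is_synonymous=is_syn))
    return DmsDataset(dataset_id=dataset_id, protein_id=protein_id,
                      sequence=sequence, variants=variants,
                      wt_score=wt_score, orientation=orientation,
                      provenance=provenance)


@pytest.fixture
def small_sim():
    """A small but fully featured synthetic scan (30 residues, 80 synonymous)."""
    config = SimulationConfig(protein_length=30, n_synonymous=80, seed=42)
    dataset, truth = generate_dms(config)
    return config, dataset, truth


# ---- independent oracles (never call the implementation path) ------------

def pairwise_auc_oracle(labels, scores):
    """AUC as the exhaustive pairwise statistic P(s_eff > s_neut) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def spearman_bruteforce(x, p):
    """Tie-free Spearman via 1 - 6*sum(d^2)/(n*(n^2-1)) with hand-built ranks."""
    x, p = list(x), list(p)
    n = len(x)
    rank_x = [sorted(x).index(v) + 1 for v in x]
    rank_p = [sorted(p).index(v) + 1 for v in p]
    d2 = sum((rx - rp) ** 2 for rx, rp in zip(rank_x, rank_p))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))
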