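#!/usr/bin/env python
"""Generate the synthetic study inputs for the benchmark.

Simulates one mid-sized DMS experiment (500 residues, all 19*N SAVs, 300
synonymous variants), a replicate experiment targeted at inter-experiment
Spearman rho = 0.93, a predictor targeted at rho = 0.4 to true effect
strength, and a conservation profile (PSSM) whose log-odds track true
effects with moderate noise.  The generated files are bulky working data:
they land in scratch/inputs/ (regenerable, not versioned) and are fully
determined by the seed.

Run from the repository root:  python analysis/01_simulate_inputs.py
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from dmsbench.dms_io import write_pssm, write_scoreset
from dmsbench.pipeline import derive_seed
from dmsbench.synthetic_data import (
    SimulationConfig,
    generate_dms,
    generate_predictor,
    generate_pssm,
    generate_replicate,
)

SEED = 2026
OUT = Path("scratch/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(protein_length=500, seed=SEED)
    dataset, truth = generate_dms(config)
    write_scoreset(dataset, OUT / "scoreset.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    (OUT / "sequence.fasta").write_text(
        f">{dataset.protein_id}\n{dataset.sequence}\n")

    replicate = generate_replicate(dataset, config.replicate_target_rho,
                                   derive_seed(SEED, "replicate"))
    write_scoreset(replicate, OUT / "scoreset_replicate.tsv")

    pred = generate_predictor(truth, config.predictor_target_rho,
                              derive_seed(SEED, "predictor"))
    rows = [(k[0], k[1], k[2], k[3], v)
            for k, v in sorted(pred.scores.items())]
    pd.DataFrame(rows, columns=["protein_id", "position", "wt_aa", "mut_aa",
                                "raw_score"]).to_csv(
        OUT / "predictor.tsv", sep="\t", index=False)

    profile = generate_pssm(truth, dataset.sequence,
                            derive_seed(SEED, "pssm"), noise_sd=2.0)
    write_pssm(profile, OUT / "profile.pssm")

    (OUT / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True)
        + "\n")
    print(f"simulated {len(dataset.savs)} SAVs "
          f"({len(dataset.synonymous)} synonymous records) for "
          f"{dataset.protein_id}; replicate, predictor and PSSM written "
          f"to {OUT}/")


if __name__ == "__main__":
    main()
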