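#!/usr/bin/env python
"""Shift-guided ranking of candidate structural models.

Builds one example candidate set — the generating structure plus four
coordinate-jittered decoys — scores each against a noisy synthetic
experimental table, and then repeats the exercise over 100 seeds to measure
how often the true model wins at 0.2 ppm experimental noise.

Writes results/model_ranking.tsv and results/model_recovery.json.
"""

import json
from pathlib import Path

import numpy as np

from prshift import (
    CandidateModel,
    FragmentationParams,
    MockShieldingEngine,
    SyntheticSpec,
    assemble_shifts,
    fragment_all,
    make_structure,
    perturb_structure,
    rank_models,
    studies,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
ROOT.mkdir(exist_ok=True)
engine = MockShieldingEngine(3.0)
params = FragmentationParams()

# one worked example
truth = make_structure(SyntheticSpec(seed=0, n_residues=15))
rng = np.random.default_rng(1)
candidates = [CandidateModel("truth", truth, "generating structure")] + [
    CandidateModel(f"decoy_{k}", perturb_structure(truth, 0.3, rng), "0.3 A jitter")
    for k in range(1, 5)
]
experimental = assemble_shifts(fragment_all(truth, params), engine)
for key in experimental.keys():
    experimental[key].iso += rng.normal(0.0, 0.2)
    experimental[key].csa = None
ranking = rank_models(candidates, experimental, engine, params, key="iso")
ranking.to_csv(ROOT / "model_ranking.tsv", sep="\t", index=False)
print(ranking.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# recovery rate over seeds
res = studies.model_recovery_study(seed=0, n_reps=100)
(ROOT / "model_recovery.json").write_text(json.dumps(res, indent=2))
print(
    f"generating model ranked first in {100 * res['recovery_fraction']:.0f}% "
    f"of {res['n_reps']} repetitions at sigma = {res['noise_sigma_ppm']} ppm"
)
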