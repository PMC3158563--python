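#!/usr/bin/env python
"""The three-stage modular estimation workflow on the reference profiles.

Stage 1 fits the downstream IκBα/NF-κB module to the NF-κB reference
data with the measured-IKK profile (scaled to µM) as a fixed input;
stage 2 fits the upstream IKK/A20 module to the IKK reference data with
the stage-1 model's regenerated nuclear NF-κB as input; stage 3
re-integrates the modules and re-estimates only the loop-coupling rates
(A20 feedback strengths, IKK recycling, IκBα nuclear import) against
both datasets.

Writes results/staged_workflow.json.
"""

import argparse
import json
from pathlib import Path

from nfkbmicro.estimation import FREE_PARAMS, staged_workflow
from nfkbmicro.model import DEFAULT_PARAMS, NEW_MODEL
from nfkbmicro.synthetic import reference_profiles

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--starts", type=int, default=8)
args = ap.parse_args()

OUT = Path("results")
OUT.mkdir(exist_ok=True)

datasets = {"nfkb": reference_profiles("nfkb"), "ikk": reference_profiles("ikk")}
final, results = staged_workflow(
    NEW_MODEL, DEFAULT_PARAMS, datasets,
    seeds={"downstream": args.seed, "upstream": args.seed + 1,
           "full": args.seed + 2},
    n_starts={"downstream": args.starts, "upstream": args.starts,
              "full": max(args.starts // 2, 1)})

payload = {"final_parameters": dict(final.values), "stages": {}}
for stage, fits in results.items():
    best = fits[0]
    payload["stages"][stage] = {
        "best_objective": best.objective_value,
        "best_pF": best.p_F,
        "free_parameters": {n: best.params[n] for n in FREE_PARAMS[
            "downstream" if stage == "downstream" else stage]},
    }
    print(f"stage {stage:10s}: best objective {best.objective_value:.4g}, "
          f"p_F {best.p_F:.3g}")

with open(OUT / "staged_workflow.json", "w") as fh:
    json.dump(payload, fh, indent=2)
print(f"wrote {OUT}/staged_workflow.json")
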