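"""Monte-Carlo parameter recovery: regenerate large cohorts over many
seeds, push them through the full pipeline, and compare the refitted
standardized slopes of log10 HOMA-IR on the weekly exposures with the
planted truth.

Writes results/parameter_recovery.csv.
"""

import argparse

import numpy as np
import pandas as pd

import chronomeal as cm
from chronomeal.config import CohortConfig, Conventions
from chronomeal.pipeline import derive_participant_table

parser = argparse.ArgumentParser()
parser.add_argument("--n", type=int, default=4000, help="participants per seed (half men)")
parser.add_argument("--seeds", type=int, default=20)
parser.add_argument("--base-seed", type=int, default=100)
parser.add_argument("--out", default="results/parameter_recovery.csv")
args = parser.parse_args()

rows = []
for i in range(args.seeds):
    seed = args.base_seed + i
    cohort = cm.generate_cohort(
        CohortConfig(n_participants=args.n, seed=seed, fraction_women=0.5)
    )
    derived, _ = derive_participant_table(
        cohort.recall_events, cohort.sleep_nights, cohort.participants, Conventions()
    )
    analysis = cm.transform_outcomes(derived)
    for sex, label in (("man", "men"), ("woman", "women")):
        sub = analysis[analysis["sex"] == sex]
        for exposure, col in (("eating_window", "eating_window"), ("msp_to_first", "msp_to_first")):
            truth = cohort.truth[(label, exposure, "log10_homa_ir")]
            res = cm.simple_regression(sub[col], sub["homa_ir"])
            rows.append({"seed": seed, "stratum": label, "exposure": exposure,
                         "planted": truth, "refitted": res.beta_std})

table = pd.DataFrame(rows)
table.to_csv(args.out, index=False, float_format="%.6g")
summary = table.groupby(["stratum", "exposure"]).agg(
    planted=("planted", "first"),
    refit_mean=("refitted", "mean"),
    refit_sd=("refitted", "std"),
)
summary["bias"] = summary["refit_mean"] - summary["planted"]
print(f"{args.seeds} seeds x {args.n} participants (half per sex):")
print(summary.round(4).to_string())
print("\nSmall negative bias toward zero reflects day-level measurement noise")
print("(meal-time jitter, breakfast-skip deletions) attenuating the latent exposure.")
print(f"wrote {args.out}")
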