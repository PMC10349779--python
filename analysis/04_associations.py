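"""Sex-stratified simple and confounder-adjusted regressions of the five
meal-timing exposures on body-composition and cardiometabolic outcomes,
with Benjamini-Hochberg multiplicity control per table and stratum.

Writes long- and wide-format association tables under results/ and
prints the rows surviving multiplicity adjustment.
"""

import argparse

import pandas as pd

from chronomeal import associations as assoc
from chronomeal.pipeline import BODYCOMP_OUTCOMES, CARDIO_OUTCOMES, EXPOSURES

parser = argparse.ArgumentParser()
parser.add_argument("--derived", default="results/derived_participants.csv")
parser.add_argument("--out", default="results")
parser.add_argument("--multiplicity", default="bh", choices=["bh", "hochberg"])
args = parser.parse_args()

df = assoc.transform_outcomes(pd.read_csv(args.derived))
for label, outcomes in (
    ("body_composition", BODYCOMP_OUTCOMES),
    ("cardiometabolic", CARDIO_OUTCOMES),
):
    present = [o for o in outcomes if o in df.columns]
    for kind, adjusted in (("simple", False), ("adjusted", True)):
        table = assoc.association_table(
            df, list(EXPOSURES), present, adjusted=adjusted, multiplicity=args.multiplicity
        )
        table.to_csv(f"{args.out}/associations_{label}_{kind}_long.csv",
                     index=False, float_format="%.6g")
        assoc.table_to_wide(table).to_csv(
            f"{args.out}/associations_{label}_{kind}_wide.csv",
            index=False, float_format="%.6g")
        hits = table[table["significant_adj"]]
        print(f"\n{label} / {kind}: {len(hits)} of {len(table)} associations "
              f"survive {args.multiplicity.upper()} adjustment")
        if len(hits):
            print(hits[["stratum", "exposure", "outcome", "n", "adj_r2",
                        "beta_std", "p", "p_adj"]].round(4).to_string(index=False))
print(f"\nwrote association tables under {args.out}/")
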