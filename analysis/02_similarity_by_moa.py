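"""Distribution of the diet-max similarity index per mode-of-action class.

The table this writes is what a grouped boxplot of insecticide-diet
chemical similarity would draw: per MoA class min/quartiles/max of the
maximum Tanimoto similarity between each insecticide and the phytochemicals
of each pest's diet.
"""

import argparse
from pathlib import Path

import pandas as pd

from resistsurv.chemsim import similarity_by_moa_summary


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--records", type=Path, default=Path("results/synthetic/records.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = pd.read_csv(args.records)
    sim = records.rename(columns={"similarity": "score"})[
        ["pest_id", "insecticide_id", "score"]
    ].assign(closest_phytochemical_id="")
    moa_map = records.set_index("insecticide_id")["moa_class"].to_dict()
    table = similarity_by_moa_summary(sim, moa_map)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "similarity_by_moa.csv", index=False)
    glob = table[table.moa_class == "__all__"].iloc[0]
    print(table.to_string(index=False))
    print(f"\nglobal similarity range {glob['min']:.3f} - {glob['max']:.3f} "
          f"across {int(glob['n'])} pest x insecticide pairs")


if __name__ == "__main__":
    main()
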