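"""Generate the synthetic multi-cohort study and write it to scratch.

Large matrices (betas, metabolites) go under scratch/; small summaries
and the ground-truth sidecar under results/.
"""

import json

import pandas as pd

from config import RESULTS, SCRATCH, study_config
from dnamet.simulate import simulate_dataset


def main():
    cfg = study_config()
    data, truth = simulate_dataset(cfg)
    out = SCRATCH / "data"
    data.write_dir(out)
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)

    summary = data.phenotypes.groupby("cohort").agg(
        n=("age", "size"), age_mean=("age", "mean"), age_sd=("age", "std"),
        bmi_mean=("bmi", "mean"), male_fraction=("sex", "mean"))
    summary["deaths"] = data.survival.groupby(data.cohort_labels)["event"].sum()
    summary.round(2).to_csv(RESULTS / "cohort_summary.tsv", sep="\t")
    print(summary.round(2))
    print(f"\nwrote {len(data.phenotypes)} samples x "
          f"{data.betas.shape[1]} CpGs / {data.metabolites.shape[1]} metabolites -> {out}")


if __name__ == "__main__":
    main()
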