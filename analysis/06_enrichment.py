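"""Characterise the CpGs the surrogate models selected.

Positions and CpG-island intervals are synthetic (deterministic layout
on one chromosome), labelled as such; the mechanics — CGI-context
classification, Fisher enrichment with BH, ground-truth causal-CpG
enrichment, model overlap and recurrent CpGs — are the real pipeline.
"""

import json

import numpy as np
import pandas as pd

from config import RESULTS, SCRATCH
from dnamet.enrichment import (annotate_cgi_context, fisher_enrichment, genes_in_cis,
                               model_overlap, recurrent_cpgs)
from dnamet.training import SurrogateModel


def synthetic_genome(cpgs, rng):
    """Synthetic 1-chromosome annotation: island tiling and gene intervals."""
    pos = pd.DataFrame({"chrom": "chr1",
                        "pos": np.sort(rng.choice(80_000_000, len(cpgs),
                                                  replace=False)) + 1}, index=cpgs)
    starts = np.arange(400) * 200_000 + 50_000
    islands = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 1_500})
    gstarts = rng.choice(79_000_000, 300, replace=False)
    genes = pd.DataFrame({"chrom": "chr1", "start": gstarts,
                          "end": gstarts + rng.integers(5_000, 200_000, 300),
                          "name": [f"GENE{i:03d}" for i in range(300)]})
    return pos, islands, genes


def main():
    rng = np.random.default_rng(9)
    models = [SurrogateModel.from_json(p)
              for p in sorted((RESULTS / "models").glob("*.json"))]
    models = [m for m in models if m.weights]
    betas_cols = pd.read_csv(SCRATCH / "data" / "betas.tsv", sep="\t", index_col=0,
                             nrows=1).columns
    universe = set(betas_cols)
    truth = json.load(open(RESULTS / "ground_truth.json"))

    pos, islands, genes = synthetic_genome(list(betas_cols), rng)
    context = annotate_cgi_context(pos, islands)
    ann_sets = {lab: set(context.index[context == lab]) for lab in context.unique()}

    union = set().union(*(set(m.weights) for m in models))
    print(f"{len(models)} models select {len(union)} distinct CpGs "
          f"(median {int(np.median([len(m.weights) for m in models]))} per model)")

    enr = fisher_enrichment(union, universe, ann_sets)
    enr.to_csv(RESULTS / "cgi_context_enrichment.tsv", sep="\t")

    causal_union = set().union(*(set(v) for v in truth["causal_cpg_sets"].values()))
    causal = fisher_enrichment(union, universe, {"ground_truth_causal": causal_union})
    causal.to_csv(RESULTS / "causal_enrichment.tsv", sep="\t")
    print(f"ground-truth causal CpGs: OR = "
          f"{causal.loc['ground_truth_causal', 'odds_ratio']:.1f}, "
          f"p = {causal.loc['ground_truth_causal', 'p']:.2e}")

    overlap = model_overlap(models)
    overlap.round(3).to_csv(RESULTS / "model_overlap.tsv", sep="\t")
    off_diag = overlap.to_numpy()[~np.eye(len(overlap), dtype=bool)]
    print(f"pairwise CpG overlap: median {np.median(off_diag):.2f}, "
          f"max {off_diag.max():.2f} — models draw largely distinct CpG sets")

    rec = recurrent_cpgs(models, min_models=2)
    rec.head(50).to_csv(RESULTS / "recurrent_cpgs.tsv", sep="\t", index=False)
    if len(rec):
        print(f"{len(rec)} CpGs recur in >2 models; top sign agreement "
              f"{rec['sign_agreement'].iloc[0]:.2f}")

    cis = genes_in_cis(pos.loc[sorted(union)], genes)
    n_linked = sum(bool(v) for v in cis.values())
    print(f"{n_linked}/{len(union)} selected CpGs lie within 100 kb of a gene")


if __name__ == "__main__":
    main()
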