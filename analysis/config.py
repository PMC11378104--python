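"""Shared study configuration for the analysis scripts.

Three synthetic cohorts stand in for the multi-cohort design: two
(A, B) train the DNAm surrogates, the third (C) is held out for
validation and mortality evaluation.  Sizes keep the full pipeline in
minutes on one CPU while preserving the structure of an array-scale
study; batch distortions are injected in B and C so calibration has
real work to do.
"""

import pathlib

import numpy as np

from dnamet.simulate import CohortSpec, SimulationConfig, effect_sd_for_r2

ROOT = pathlib.Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

TRAIN_COHORTS = ("A", "B")
HELDOUT_COHORT = "C"
REFERENCE_COHORT = "A"


def study_config(seed: int = 2020) -> SimulationConfig:
    w = effect_sd_for_r2(0.5, 150, 0.3)
    hazard = np.zeros(8)
    hazard[:3] = [0.4, 0.3, 0.2]
    return SimulationConfig(
        cohort_specs=[CohortSpec("A", 500, 45, 11, 25, 3.5, 0.50),
                      CohortSpec("B", 500, 40, 10, 24, 3.2, 0.45),
                      CohortSpec("C", 900, 62, 9, 28, 4.0, 0.55)],
        n_metabolites=8, n_cpgs=8000, causal_cpgs_per_metabolite=150,
        cpg_effect_sd=w, missing_rate=0.002,
        batch_shift={"A": (0.0, 1.0), "B": (0.4, 1.25), "C": (0.2, 0.9)},
        hazard_coefs=hazard, censor_rate=0.65, seed=seed)
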