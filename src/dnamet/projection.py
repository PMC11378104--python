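"""Application of pretrained linear scores.

Two families share the affine mechanics: metabolite-based scores (a
weighted sum of log + z-scaled concentrations, MetaboHealth-style) and
CpG-based scores (surrogates and clock-style predictors applied to beta
matrices).  CpGs absent from a beta matrix are imputed with reference
mean betas, mirroring the gold-standard-mean imputation used when
projecting published clocks onto partially overlapping arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LinearScore:
    """Generic pretrained linear score over named features.

    ``preprocessing`` controls how the raw feature matrix is prepared:
    ``log`` takes natural logs first; ``zscale_scope`` is one of
    ``none``, ``per_dataset`` (z within each dataset label — the
    per-study standardisation mode) or ``pooled`` (across all samples —
    the calibrated-data mode).
    """

    name: str
    weights: dict[str, float]
    intercept: float = 0.0
    preprocessing: dict = field(default_factory=lambda: {"log": False, "zscale_scope": "none"})

    def __post_init__(self):
        if len(set(self.weights)) != len(self.weights):
            raise ValueError("duplicate feature ids")
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValueError("non-finite weights")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "intercept": self.intercept,
                       "preprocessing": self.preprocessing, "weights": self.weights}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LinearScore":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["name"], d["weights"], d.get("intercept", 0.0),
                   d.get("preprocessing", {"log": False, "zscale_scope": "none"}))

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "LinearScore":
        """Two-column (feature, weight) TSV; no intercept, no preprocessing."""
        tbl = pd.read_csv(path, sep="\t", header=None, names=["feature", "weight"],
                          comment="#")
        return cls(name or str(path), dict(zip(tbl["feature"].astype(str), tbl["weight"])))


def apply_metabolite_score(score: LinearScore, metabolites: pd.DataFrame,
                           dataset_labels: pd.Series | None = None,
                           scope: str | None = None) -> pd.Series:
    """Project a metabolite-based score after its declared preprocessing.

    ``scope`` overrides the score's ``zscale_scope``; ``per_dataset``
    requires ``dataset_labels``.
    """
    missing = [f for f in score.weights if f not in metabolites.columns]
    if missing:
        raise KeyError(f"score {score.name}: features absent from matrix: {missing}")
    x = metabolites[list(score.weights)].to_numpy(float)
    if score.preprocessing.get("log", False):
        if (x <= 0).any():
            raise ValueError("log preprocessing requires strictly positive concentrations")
        x = np.log(x)
    scope = scope or score.preprocessing.get("zscale_scope", "none")
    if scope == "pooled":
        x = (x - x.mean(0)) / x.std(0, ddof=0)
    elif scope == "per_dataset":
        if dataset_labels is None:
            raise ValueError("per_dataset scaling needs dataset labels")
        labels = dataset_labels.loc[metabolites.index].to_numpy()
        for lab in np.unique(labels):
            m = labels == lab
            x[m] = (x[m] - x[m].mean(0)) / x[m].std(0, ddof=0)
    elif scope != "none":
        raise ValueError(f"unknown zscale scope {scope!r}")
    w = np.array(list(score.weights.values()))
    return pd.Series(score.intercept + x @ w, index=metabolites.index, name=score.name)


def project_surrogates(models: list, betas: pd.DataFrame,
                       reference: dict[str, float] | None = None
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Project CpG-weight models onto a beta matrix.

    CpGs absent from ``betas`` take their reference mean beta; a CpG in
    neither raises.  Returns the sample-by-model score frame and the
    per-model count of reference-imputed CpGs.
    """
    reference = reference or {}
    cols = {}
    imputed_counts = {}
    beta_cols = set(betas.columns)
    for model in models:
        present = [c for c in model.weights if c in beta_cols]
        absent = [c for c in model.weights if c not in beta_cols]
        orphan = [c for c in absent if c not in reference]
        if orphan:
            raise KeyError(
                f"model {model.target}: CpG(s) {orphan[:5]} absent from betas and reference")
        w = np.array([model.weights[c] for c in present])
        score = model.intercept + betas[present].to_numpy(float) @ w
        score += sum(model.weights[c] * reference[c] for c in absent)
        cols[model.target] = score
        imputed_counts[model.target] = len(absent)
    return pd.DataFrame(cols, index=betas.index), imputed_counts


def zscale_within_dataset(scores: pd.DataFrame, dataset_labels: pd.Series) -> pd.DataFrame:
    """z-scale every score column within each dataset label (ddof=0)."""
    out = scores.copy().astype(float)
    labels = dataset_labels.loc[scores.index].to_numpy()
    for lab in np.unique(labels):
        m = labels == lab
        if m.sum() < 2:
            raise ValueError(f"dataset {lab!r} has fewer than 2 samples")
        block = out.loc[m].to_numpy(float)
        sd = block.std(0, ddof=0)
        if (sd == 0).any():
            bad = scores.columns[np.flatnonzero(sd == 0)[0]]
            raise ValueError(f"zero-variance score {bad!r} within dataset {lab!r}")
        out.loc[m] = (block - block.mean(0)) / sd
    return out
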