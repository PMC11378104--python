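"""Cross-cohort calibration of metabolite matrices.

Cohorts assayed in separate batches show systematic per-feature shifts in
location and scale.  Under the assumption that phenotypically similar
individuals have similar metabolomes, we match each target cohort to a
reference cohort on sex (exact), age and BMI, estimate per-feature affine
maps from the matched-subset moments, and apply them to every sample of
the target cohort.  Residual batch structure is quantified with a
k-nearest-neighbour mixing test and a principal-variance-component
decomposition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors


@dataclass
class MatchedPairs:
    """Phenotype-matched (reference, target) sample pairs per cohort."""

    reference_cohort: str
    pairs: dict[str, list[tuple[str, str]]]
    distances: dict[str, list[float]]
    counts_by_sex: dict[str, dict[int, int]] = field(default_factory=dict)


@dataclass
class CalibrationMap:
    """Per-cohort per-feature matched-subset moments (mu_t, sd_t, mu_r, sd_r)."""

    reference_cohort: str
    table: dict[str, dict[str, tuple[float, float, float, float]]]

    def to_json(self, path) -> None:
        payload = {"reference_cohort": self.reference_cohort,
                   "table": {c: {f: list(map(float, v)) for f, v in feats.items()}
                             for c, feats in self.table.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationMap":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(payload["reference_cohort"],
                   {c: {f: tuple(v) for f, v in feats.items()}
                    for c, feats in payload["table"].items()})


@dataclass
class BatchMixingReport:
    rejection_rate: float
    k: int
    n_tested: int


@dataclass
class VarianceComponentsReport:
    fractions: dict[str, float]
    n_components: int
    variance_kept: float


def match_samples(ref_pheno: pd.DataFrame, target_pheno: pd.DataFrame,
                  caliper: float = 0.5) -> tuple[list[tuple[str, str]], list[float]]:
    """Greedy sex-exact nearest-neighbour matching without replacement.

    Age and BMI are standardised by the reference cohort's SDs; within
    each sex stratum, available (reference, target) pairs are accepted in
    order of increasing Euclidean distance subject to ``caliper`` (in
    pooled-SD units); each sample is used at most once.  The final list
    is truncated so male and female pair counts are equal, dropping the
    worst-distance excess pairs.
    """
    for tbl, name in [(ref_pheno, "reference"), (target_pheno, "target")]:
        if tbl[["age", "sex", "bmi"]].isna().to_numpy().any():
            raise ValueError(f"missing age/sex/BMI in {name} phenotypes")
    sd_age = ref_pheno["age"].std() or 1.0
    sd_bmi = ref_pheno["bmi"].std() or 1.0
    per_sex: dict[int, list[tuple[float, str, str]]] = {}
    for sex in (0, 1):
        ref = ref_pheno[ref_pheno["sex"] == sex]
        tgt = target_pheno[target_pheno["sex"] == sex]
        if ref.empty or tgt.empty:
            per_sex[sex] = []
            continue
        rx = np.column_stack([ref["age"] / sd_age, ref["bmi"] / sd_bmi])
        tx = np.column_stack([tgt["age"] / sd_age, tgt["bmi"] / sd_bmi])
        d = np.sqrt(((rx[:, None, :] - tx[None, :, :]) ** 2).sum(-1))
        order = np.argsort(d, axis=None, kind="stable")
        used_r: set[int] = set()
        used_t: set[int] = set()
        accepted: list[tuple[float, str, str]] = []
        for flat in order:
            i, j = divmod(int(flat), d.shape[1])
            if d[i, j] > caliper:
                break
            if i in used_r or j in used_t:
                continue
            used_r.add(i)
            used_t.add(j)
            accepted.append((float(d[i, j]), str(ref.index[i]), str(tgt.index[j])))
        per_sex[sex] = accepted
    n_keep = min(len(per_sex[0]), len(per_sex[1]))
    if n_keep == 0:
        raise ValueError("no acceptable matched pairs in at least one sex stratum")
    pairs, dists = [], []
    for sex in (0, 1):
        kept = sorted(per_sex[sex])[:n_keep]
        pairs += [(r, t) for _, r, t in kept]
        dists += [dd for dd, _, _ in kept]
    return pairs, dists


def match_cohorts(phenotypes: pd.DataFrame, reference_cohort: str,
                  caliper: float = 0.5) -> MatchedPairs:
    """Match every non-reference cohort against the reference."""
    cohorts = phenotypes["cohort"].unique()
    if reference_cohort not in cohorts:
        raise ValueError(f"reference cohort {reference_cohort!r} not present")
    ref = phenotypes[phenotypes["cohort"] == reference_cohort]
    result = MatchedPairs(reference_cohort, {}, {}, {})
    for cohort in cohorts:
        if cohort == reference_cohort:
            continue
        tgt = phenotypes[phenotypes["cohort"] == cohort]
        pairs, dists = match_samples(ref, tgt, caliper=caliper)
        result.pairs[cohort] = pairs
        result.distances[cohort] = dists
        sexes = phenotypes.loc[[t for _, t in pairs], "sex"]
        result.counts_by_sex[cohort] = {int(s): int(c) for s, c in sexes.value_counts().items()}
    return result


def fit_calibration(metabolites: pd.DataFrame, matched: MatchedPairs,
                    cohort_labels: pd.Series) -> CalibrationMap:
    """Per-feature matched-subset moments for each target cohort.

    The reference cohort maps to the identity transform.  Raises when a
    matched subset has zero SD for any feature (the affine map would be
    degenerate).
    """
    table: dict[str, dict[str, tuple[float, float, float, float]]] = {}
    features = list(metabolites.columns)
    for cohort in cohort_labels.unique():
        if cohort == matched.reference_cohort:
            table[cohort] = {f: (0.0, 1.0, 0.0, 1.0) for f in features}
            continue
        pairs = matched.pairs[cohort]
        ref_ids = [r for r, _ in pairs]
        tgt_ids = [t for _, t in pairs]
        ref_block = metabolites.loc[ref_ids].to_numpy(float)
        tgt_block = metabolites.loc[tgt_ids].to_numpy(float)
        if np.isnan(ref_block).any() or np.isnan(tgt_block).any():
            raise ValueError("matched subsets must be complete (impute first)")
        mu_t, sd_t = tgt_block.mean(0), tgt_block.std(0, ddof=1)
        mu_r, sd_r = ref_block.mean(0), ref_block.std(0, ddof=1)
        degenerate = np.flatnonzero((sd_t <= 0) | (sd_r <= 0))
        if degenerate.size:
            raise ValueError(
                f"zero matched-subset SD for feature {features[degenerate[0]]} in cohort {cohort}")
        table[cohort] = {f: (float(a), float(b), float(c), float(d))
                         for f, a, b, c, d in zip(features, mu_t, sd_t, mu_r, sd_r)}
    return CalibrationMap(matched.reference_cohort, table)


def apply_calibration(metabolites: pd.DataFrame, cal_map: CalibrationMap,
                      cohort_labels: pd.Series,
                      clip_floor: str | float | None = None) -> pd.DataFrame:
    """Apply x' = (x - mu_t)/sd_t * sd_r + mu_r to all samples of each cohort.

    The affine map can push the extreme low tail of a concentration
    below zero, which would break a downstream log transform.
    ``clip_floor="auto"`` clips calibrated values at half the smallest
    reference-cohort value per feature (a detection-limit-style floor);
    a float clips at that value; None (default) leaves values untouched.
    """
    out = metabolites.copy()
    for cohort in cohort_labels.unique():
        if cohort not in cal_map.table:
            raise KeyError(f"no calibration entry for cohort {cohort}")
        entry = cal_map.table[cohort]
        missing = [f for f in metabolites.columns if f not in entry]
        if missing:
            raise KeyError(f"no calibration entry for features {missing} in cohort {cohort}")
        mask = (cohort_labels.loc[metabolites.index] == cohort).to_numpy()
        block = out.loc[mask].to_numpy(float)
        mu_t = np.array([entry[f][0] for f in metabolites.columns])
        sd_t = np.array([entry[f][1] for f in metabolites.columns])
        mu_r = np.array([entry[f][2] for f in metabolites.columns])
        sd_r = np.array([entry[f][3] for f in metabolites.columns])
        out.loc[mask] = (block - mu_t) / sd_t * sd_r + mu_r
    if clip_floor is not None:
        if clip_floor == "auto":
            ref_mask = (cohort_labels.loc[metabolites.index]
                        == cal_map.reference_cohort).to_numpy()
            floor = metabolites.loc[ref_mask].min(axis=0) * 0.5
        else:
            floor = float(clip_floor)
        out = out.clip(lower=floor, axis=1 if clip_floor == "auto" else None)
    return out


def batch_mixing_test(matrix: pd.DataFrame | np.ndarray, cohort_labels: pd.Series,
                      k: int = 50, n_draws: int = 500, seed: int = 0,
                      alpha: float = 0.05) -> BatchMixingReport:
    """kBET-style local-vs-global cohort composition test.

    For ``n_draws`` randomly chosen samples, the cohort composition of
    the sample's k nearest Euclidean neighbours (self included) is
    compared with the global cohort proportions by a chi-square
    goodness-of-fit test; the rejection rate is the fraction of
    neighbourhoods with p < alpha.  Well-mixed data reject at about the
    nominal level; batch-separated data reject almost everywhere.
    """
    x = np.asarray(matrix, float)
    labels = np.asarray(cohort_labels)
    classes, y = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        warnings.warn("single cohort: batch mixing rejection rate defined as 0")
        return BatchMixingReport(0.0, k, 0)
    if k >= len(labels):
        raise ValueError("k must be smaller than the number of samples")
    global_prop = y / y.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(labels), size=min(n_draws, len(labels)), replace=False)
    nn = NearestNeighbors(n_neighbors=k).fit(x)
    _, neigh = nn.kneighbors(x[idx])
    label_codes = np.searchsorted(classes, labels)
    rejected = 0
    for row in neigh:
        counts = np.bincount(label_codes[row], minlength=len(classes))
        _, p = stats.chisquare(counts, f_exp=global_prop * k)
        if p < alpha:
            rejected += 1
    return BatchMixingReport(rejected / len(idx), k, len(idx))


def variance_components(matrix: pd.DataFrame | np.ndarray, factor_table: pd.DataFrame,
                        variance_kept: float = 0.9) -> VarianceComponentsReport:
    """Eigenvalue-weighted attribution of principal components to factors.

    PCs are retained up to ``variance_kept`` cumulative variance.  Each
    PC score vector is regressed on each factor separately (categorical
    factors one-hot encoded, continuous as-is); its variance is split
    proportionally to the per-factor R^2 with residual = 1 - sum(R^2)
    (clipped at 0), renormalised, then averaged over PCs with eigenvalue
    weights.  A fixed-effects approximation of random-effects PVCA.
    """
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0,1]")
    x = np.asarray(matrix, float)
    xc = x - x.mean(0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    ev = s ** 2
    ev_frac = ev / ev.sum()
    n_keep = int(np.searchsorted(np.cumsum(ev_frac), variance_kept) + 1)
    n_keep = min(n_keep, len(ev))
    scores = u[:, :n_keep] * s[:n_keep]
    weights = ev_frac[:n_keep] / ev_frac[:n_keep].sum()

    factor_r2 = {}
    for name in factor_table.columns:
        col = factor_table[name]
        if col.dtype == object or str(col.dtype) == "category" or col.nunique() <= 2:
            levels = pd.get_dummies(col)
            if levels.shape[1] < 2:
                warnings.warn(f"factor {name} has a single level; contributes 0")
                factor_r2[name] = np.zeros(n_keep)
                continue
            z = levels.to_numpy(float)
        else:
            if col.nunique() < 2:
                warnings.warn(f"factor {name} is constant; contributes 0")
                factor_r2[name] = np.zeros(n_keep)
                continue
            z = col.to_numpy(float)[:, None]
        z = np.column_stack([np.ones(len(z)), z])
        r2 = np.empty(n_keep)
        for c in range(n_keep):
            y_pc = scores[:, c]
            coef, *_ = np.linalg.lstsq(z, y_pc, rcond=None)
            resid = y_pc - z @ coef
            tot = ((y_pc - y_pc.mean()) ** 2).sum()
            r2[c] = 1.0 - resid @ resid / tot if tot > 0 else 0.0
        factor_r2[name] = np.clip(r2, 0.0, 1.0)

    names = list(factor_r2)
    fractions = {}
    per_pc = np.array([factor_r2[n] for n in names])  # factors x PCs
    resid = np.clip(1.0 - per_pc.sum(0), 0.0, None)
    total = per_pc.sum(0) + resid
    per_pc = per_pc / total
    resid = resid / total
    for i, name in enumerate(names):
        fractions[name] = float((per_pc[i] * weights).sum())
    fractions["residual"] = float((resid * weights).sum())
    return VarianceComponentsReport(fractions, n_keep, variance_kept)
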