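"""Synthetic multi-cohort generator with known ground truth.

Emulates the data constellation needed to exercise the full surrogate
pipeline: several population cohorts with distinct age/BMI/sex profiles,
positive right-skewed metabolite concentrations driven by phenotype,
DNA-methylation beta values in [0, 1] carrying sparse linear encodings of
the metabolites on the logit scale, per-cohort batch distortions of the
metabolite matrix, and Weibull proportional-hazards survival whose
log-hazard depends on a subset of metabolites.

Every draw flows from a single :class:`numpy.random.Generator` seeded by
``SimulationConfig.seed``, so identical configs produce byte-identical
datasets.  The :class:`GroundTruth` sidecar records the causal CpG sets,
the injected batch shifts, the hazard coefficients and the analytic
variance fraction each metabolite's causal CpGs explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit


class ConfigurationError(ValueError):
    """Raised when a simulation config field is invalid; names the field."""


@dataclass(frozen=True)
class CohortSpec:
    """Marginal phenotype distribution of one cohort."""

    name: str
    n_samples: int
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    male_fraction: float


@dataclass
class SimulationConfig:
    """Knobs of the generator.

    Parameters
    ----------
    cohort_specs
        One :class:`CohortSpec` per cohort; the first cohort is the
        calibration reference (its batch shift is identity).
    n_metabolites, n_cpgs
        Universe sizes.  Defaults keep a full pipeline run on one CPU in
        minutes while preserving the structure of an array-scale study.
    causal_cpgs_per_metabolite
        Number of CpGs whose logit carries each metabolite's signal.
        Causal sets are disjoint across metabolites.
    cpg_effect_sd
        SD of the per-CpG weight linking a z-scaled log-metabolite to the
        CpG logit.  See :func:`effect_sd_for_r2` to pick a value giving a
        target explainable variance fraction.
    metabolite_pheno_effects
        (n_metabolites, 3) array of coefficients of (z-age, sex, z-BMI) on
        the log-metabolite; drawn N(0, 0.2) when None.
    batch_shift
        Mapping cohort name -> (delta, factor): additive mean shift and
        multiplicative SD factor per feature (scalars broadcast).  The
        reference cohort must map to (0, 1); missing mapping means no
        distortion anywhere.
    metab_noise_sd, latent_sd, cpg_noise_sd
        Residual SD of the log-metabolite, SD of the shared latent factor
        inducing inter-metabolite correlation, and residual SD on the CpG
        logit scale.
    hazard_coefs
        Per-metabolite log hazard ratio per SD of log-concentration;
        default gives four true mortality drivers (0.4, 0.3, 0.3, 0.2)
        and zeros elsewhere.
    weibull_shape, weibull_scale
        Baseline event-time distribution (years); shape > 1 encodes an
        ageing-like increasing hazard.
    censor_rate
        Target fraction of administratively censored subjects (uniform
        censoring on [0, T_max] with T_max solved to approximate it).
    missing_rate
        Fraction of metabolite cells set missing completely at random.
    """

    cohort_specs: list[CohortSpec]
    n_metabolites: int = 16
    n_cpgs: int = 20_000
    causal_cpgs_per_metabolite: int = 200
    cpg_effect_sd: float = 0.021
    metabolite_pheno_effects: np.ndarray | None = None
    batch_shift: dict[str, tuple] | None = None
    metab_noise_sd: float = 0.6
    latent_sd: float = 0.3
    cpg_noise_sd: float = 0.3
    age_sex_cpg_fraction: float = 0.05
    age_sex_effect_sd: float = 0.15
    hazard_coefs: np.ndarray | None = None
    weibull_shape: float = 1.5
    weibull_scale: float = 30.0
    censor_rate: float = 0.7
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.cohort_specs:
            raise ConfigurationError("cohort_specs: at least one cohort required")
        for spec in self.cohort_specs:
            if spec.n_samples <= 0:
                raise ConfigurationError(f"n_samples: must be > 0 for cohort {spec.name}")
            if not 0.0 <= spec.male_fraction <= 1.0:
                raise ConfigurationError(f"male_fraction: must be in [0,1] for cohort {spec.name}")
        for name, value in [("n_metabolites", self.n_metabolites),
                            ("n_cpgs", self.n_cpgs),
                            ("causal_cpgs_per_metabolite", self.causal_cpgs_per_metabolite)]:
            if value <= 0:
                raise ConfigurationError(f"{name}: must be > 0")
        if self.causal_cpgs_per_metabolite * self.n_metabolites > self.n_cpgs:
            raise ConfigurationError("n_cpgs: too small for disjoint causal sets")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ConfigurationError("weibull_shape/weibull_scale: must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate: must be in [0,1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate: must be in [0,1)")


@dataclass
class MultiCohortDataset:
    """Aligned phenotype, metabolite, methylation and survival tables.

    All tables share an identical sample-id index.  ``metabolites`` holds
    positive concentrations (NaN where missing), ``betas`` values in
    [0, 1], ``survival`` strictly positive follow-up times with a binary
    event indicator.
    """

    phenotypes: pd.DataFrame
    metabolites: pd.DataFrame
    betas: pd.DataFrame
    survival: pd.DataFrame
    cohort_labels: pd.Series

    def write_dir(self, outdir) -> None:
        """Write the component tables as TSV under ``outdir``."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
        self.metabolites.to_csv(out / "metabolites.tsv", sep="\t")
        self.betas.to_csv(out / "betas.tsv", sep="\t", float_format="%.5f")
        self.survival.to_csv(out / "survival.tsv", sep="\t")


@dataclass
class GroundTruth:
    causal_cpg_sets: dict[str, list[str]]
    true_batch_shifts: dict[str, tuple]
    true_log_hrs: dict[str, float]
    generating_r2: dict[str, float]
    pheno_effects: np.ndarray = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "causal_cpg_sets": self.causal_cpg_sets,
            "true_batch_shifts": {c: [float(np.atleast_1d(d)[0]), float(np.atleast_1d(f)[0])]
                                  for c, (d, f) in self.true_batch_shifts.items()},
            "true_log_hrs": self.true_log_hrs,
            "generating_r2": self.generating_r2,
        }


def effect_sd_for_r2(target_r2: float, n_causal: int, cpg_noise_sd: float) -> float:
    """Per-CpG weight SD giving an expected causal-CpG R^2 of ``target_r2``.

    Under the linearised generative model the variance fraction of a
    metabolite explainable from its m causal CpGs is S/(1+S) with
    S = sum_j w_j^2 / sigma^2, so E[S] = m * w_sd^2 / sigma^2.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0,1)")
    s = target_r2 / (1.0 - target_r2)
    return cpg_noise_sd * np.sqrt(s / n_causal)


def _simulate_phenotypes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for spec in config.cohort_specs:
        n = spec.n_samples
        age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 100.0)
        bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), 15.0, 55.0)
        sex = (rng.random(n) < spec.male_fraction).astype(int)  # 1 = male
        ids = [f"{spec.name}_{i:05d}" for i in range(n)]
        frames.append(pd.DataFrame(
            {"cohort": spec.name, "age": age, "sex": sex, "bmi": bmi}, index=ids))
    pheno = pd.concat(frames)
    pheno.index.name = "sample_id"
    return pheno


def inject_batch_effects(metabolites: pd.DataFrame, cohort_labels: pd.Series,
                         batch_shift: dict[str, tuple]) -> pd.DataFrame:
    """Distort per-cohort feature distributions by an affine map.

    For cohort c and feature f with cohort-feature mean m_cf the value x
    becomes ``(x - m_cf) * factor_cf + m_cf + delta_cf``: the cohort mean
    moves by delta and the cohort SD is multiplied by factor.  Cohorts
    with delta=0, factor=1 are untouched.
    """
    unknown = set(cohort_labels.unique()) - set(batch_shift)
    if unknown:
        raise KeyError(f"no batch_shift defined for cohorts: {sorted(unknown)}")
    out = metabolites.copy()
    for cohort, (delta, factor) in batch_shift.items():
        mask = (cohort_labels == cohort).to_numpy()
        if not mask.any():
            continue
        block = out.loc[mask].to_numpy(float)
        m = np.nanmean(block, axis=0, keepdims=True)
        block = (block - m) * np.asarray(factor, float) + m + np.asarray(delta, float)
        out.loc[mask] = block
    return out


def make_survival(metab_z: np.ndarray, hazard_coefs: np.ndarray, weibull_shape: float,
                  weibull_scale: float, censor_rate: float,
                  rng: np.random.Generator | int) -> pd.DataFrame:
    """Draw follow-up times from a Weibull-baseline proportional-hazards model.

    Event times invert S(t | x) = exp(-(t/scale)^shape * exp(x'beta)) at a
    uniform quantile; ``metab_z`` must already be z-scaled so the
    coefficients read as log hazard ratios per SD.  Censoring is
    administrative, uniform on [0, T_max] and independent of covariates,
    with T_max solved by bisection so the expected censored fraction
    approximates ``censor_rate``.
    """
    if weibull_shape <= 0 or weibull_scale <= 0:
        raise ValueError("weibull shape and scale must be > 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    metab_z = np.asarray(metab_z, float)
    lp = metab_z @ np.asarray(hazard_coefs, float)
    u = rng.uniform(size=len(lp))
    t_event = weibull_scale * (-np.log(u) * np.exp(-lp)) ** (1.0 / weibull_shape)

    if censor_rate <= 0:
        time, event = t_event, np.ones(len(lp), dtype=int)
    else:
        # P(censored | T=t, C~U(0,Tmax)) = min(t/Tmax, 1); solve for Tmax.
        def frac_censored(tmax):
            return float(np.mean(np.minimum(t_event / tmax, 1.0)))

        lo, hi = 1e-6, float(t_event.max()) * 4 + 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if frac_censored(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        t_max = 0.5 * (lo + hi)
        c = rng.uniform(0.0, t_max, size=len(lp))
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-8)
    return pd.DataFrame({"time": time, "event": event})


def simulate_dataset(config: SimulationConfig) -> tuple[MultiCohortDataset, GroundTruth]:
    """Generate a full multi-cohort dataset plus its ground-truth sidecar.

    Log-metabolites are a linear function of z-age, sex and z-BMI plus a
    shared latent factor and noise, then exponentiated, so the raw
    concentrations are positive and right-skewed and a downstream
    log + z-score transform recovers Gaussian structure.  Causal CpG
    logits read ``b0_j + w_j * z_metab + eps``; a disjoint subset of the
    remaining CpGs carries age/sex signal; the rest are pure noise.
    Batch effects are injected on the raw concentration scale, after
    which ``missing_rate`` cells are blanked at random.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pheno = _simulate_phenotypes(config, rng)
    n = len(pheno)
    n_met, n_cpg = config.n_metabolites, config.n_cpgs
    met_names = [f"met_{k:03d}" for k in range(n_met)]
    cpg_names = np.array([f"cg{j:08d}" for j in range(n_cpg)])

    age_z = (pheno["age"] - pheno["age"].mean()).to_numpy() / pheno["age"].std()
    bmi_z = (pheno["bmi"] - pheno["bmi"].mean()).to_numpy() / pheno["bmi"].std()
    sex = pheno["sex"].to_numpy(float)
    design = np.column_stack([age_z, sex, bmi_z])

    if config.metabolite_pheno_effects is None:
        pheno_eff = rng.normal(0.0, 0.2, size=(n_met, 3))
    else:
        pheno_eff = np.asarray(config.metabolite_pheno_effects, float)
        if pheno_eff.shape != (n_met, 3):
            raise ConfigurationError("metabolite_pheno_effects: shape must be (n_metabolites, 3)")

    latent = rng.normal(0.0, 1.0, size=n)
    loadings = rng.normal(0.0, config.latent_sd, size=n_met)
    log_met = (design @ pheno_eff.T
               + np.outer(latent, loadings)
               + rng.normal(0.0, config.metab_noise_sd, size=(n, n_met)))
    z_met = (log_met - log_met.mean(0)) / log_met.std(0)

    # disjoint causal CpG blocks, then age/sex CpGs from the leftover pool
    perm = rng.permutation(n_cpg)
    m = config.causal_cpgs_per_metabolite
    causal_sets = {met_names[k]: perm[k * m:(k + 1) * m] for k in range(n_met)}
    n_causal_total = n_met * m
    n_agesex = int(config.age_sex_cpg_fraction * (n_cpg - n_causal_total))
    agesex_idx = perm[n_causal_total:n_causal_total + n_agesex]

    b0 = rng.normal(0.0, 1.0, size=n_cpg)
    logits = np.tile(b0, (n, 1))
    weights = {}
    gen_r2 = {}
    for k, met in enumerate(met_names):
        idx = causal_sets[met]
        w = rng.normal(0.0, config.cpg_effect_sd, size=m)
        weights[met] = w
        logits[:, idx] += np.outer(z_met[:, k], w)
        s = float(np.sum(w ** 2) / config.cpg_noise_sd ** 2)
        gen_r2[met] = s / (1.0 + s)
    a = rng.normal(0.0, config.age_sex_effect_sd, size=n_agesex)
    s_eff = rng.normal(0.0, config.age_sex_effect_sd, size=n_agesex)
    logits[:, agesex_idx] += np.outer(age_z, a) + np.outer(sex, s_eff)
    logits += rng.normal(0.0, config.cpg_noise_sd, size=(n, n_cpg))
    betas = expit(logits)

    concentrations = np.exp(log_met)
    metab = pd.DataFrame(concentrations, index=pheno.index, columns=met_names)
    shifts = config.batch_shift or {spec.name: (0.0, 1.0) for spec in config.cohort_specs}
    metab = inject_batch_effects(metab, pheno["cohort"], shifts)
    if config.missing_rate > 0:
        mask = rng.random(metab.shape) < config.missing_rate
        metab = metab.mask(mask)

    if config.hazard_coefs is None:
        hz = np.zeros(n_met)
        hz[:4] = [0.4, 0.3, 0.3, 0.2][: min(4, n_met)]
    else:
        hz = np.asarray(config.hazard_coefs, float)
        if hz.shape != (n_met,):
            raise ConfigurationError("hazard_coefs: length must equal n_metabolites")
    surv = make_survival(z_met, hz, config.weibull_shape, config.weibull_scale,
                         config.censor_rate, rng)
    surv.index = pheno.index

    dataset = MultiCohortDataset(
        phenotypes=pheno,
        metabolites=metab,
        betas=pd.DataFrame(betas, index=pheno.index, columns=cpg_names),
        survival=surv,
        cohort_labels=pheno["cohort"],
    )
    truth = GroundTruth(
        causal_cpg_sets={met: list(cpg_names[idx]) for met, idx in causal_sets.items()},
        true_batch_shifts=dict(shifts),
        true_log_hrs={met: float(h) for met, h in zip(met_names, hz)},
        generating_r2=gen_r2,
        pheno_effects=pheno_eff,
    )
    return dataset, truth
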