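"""Matching, affine calibration identities, mixing test, variance components."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnamet.calibration import (CalibrationMap, MatchedPairs, apply_calibration,
                                batch_mixing_test, fit_calibration, match_cohorts,
                                match_samples, variance_components)


def _pheno(ages, bmis, sexes, prefix):
    return pd.DataFrame({"age": ages, "bmi": bmis, "sex": sexes},
                        index=[f"{prefix}{i}" for i in range(len(ages))])


class TestMatching:
    def test_identical_tables_self_match(self, rng):
        ages = rng.uniform(30, 70, 40)
        bmis = rng.uniform(20, 32, 40)
        sexes = np.r_[np.zeros(20, int), np.ones(20, int)]
        ref = _pheno(ages, bmis, sexes, "r")
        tgt = ref.copy()
        pairs, dists = match_samples(ref, tgt)
        assert all(r[1:] == t[1:] for r, t in pairs)  # same positional id
        assert np.allclose(dists, 0)

    def test_nearest_age_wins(self):
        ref = _pheno([40, 60, 40, 60], [25] * 4, [1, 1, 0, 0], "r")
        tgt = _pheno([41, 41], [25, 25], [1, 0], "t")
        pairs, _ = match_samples(ref, tgt, caliper=5.0)
        matched_ref = {t: r for r, t in pairs}
        assert matched_ref["t0"] == "r0" and matched_ref["t1"] == "r2"

    def test_equal_sex_counts(self, rng):
        # 10 matchable men, 7 matchable women -> 7 + 7
        ref = _pheno(rng.uniform(40, 50, 40), rng.uniform(24, 27, 40),
                     np.r_[np.ones(20, int), np.zeros(20, int)], "r")
        tgt = _pheno(rng.uniform(40, 50, 17), rng.uniform(24, 27, 17),
                     np.r_[np.ones(10, int), np.zeros(7, int)], "t")
        pairs, _ = match_samples(ref, tgt, caliper=10)
        sexes = [1] * 10 + [0] * 7
        matched_sex = [sexes[int(t[1:])] for _, t in pairs]
        assert matched_sex.count(1) == 7 and matched_sex.count(0) == 7

    def test_no_target_reused(self, rng):
        ref = _pheno(rng.uniform(30, 70, 30), rng.uniform(20, 32, 30),
                     rng.integers(0, 2, 30), "r")
        tgt = _pheno(rng.uniform(30, 70, 30), rng.uniform(20, 32, 30),
                     rng.integers(0, 2, 30), "t")
        pairs, _ = match_samples(ref, tgt, caliper=3)
        tgts = [t for _, t in pairs]
        refs = [r for r, _ in pairs]
        assert len(set(tgts)) == len(tgts) and len(set(refs)) == len(refs)

    def test_impossible_stratum_errors(self):
        ref = _pheno([40, 45], [25, 25], [1, 1], "r")
        tgt = _pheno([41, 44], [25, 25], [0, 0], "t")  # no male targets
        with pytest.raises(ValueError):
            match_samples(ref, tgt)


def _calibration_fixture(seed=5):
    rng = np.random.default_rng(seed)
    n = 700
    ref = _pheno(rng.uniform(35, 65, n), rng.uniform(22, 30, n),
                 np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)], "r")
    tgt = _pheno(rng.uniform(35, 65, n), rng.uniform(22, 30, n),
                 np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)], "t")
    pheno = pd.concat([ref.assign(cohort="REF"), tgt.assign(cohort="TGT")])
    base = np.exp(0.05 * (pheno["age"].to_numpy()[:, None] - 50) / 10
                  + rng.normal(0, 0.1, (2 * n, 3)))
    metab = pd.DataFrame(base, index=pheno.index, columns=["m1", "m2", "m3"])
    tmask = pheno["cohort"] == "TGT"
    block = metab.loc[tmask.to_numpy()]
    metab.loc[tmask.to_numpy()] = (block - block.mean()) * 1.3 + block.mean() + 0.5
    return pheno, metab


class TestCalibration:
    def test_reference_identity(self):
        pheno, metab = _calibration_fixture()
        matched = match_cohorts(pheno, "REF")
        cmap = fit_calibration(metab, matched, pheno["cohort"])
        assert cmap.table["REF"]["m1"] == (0.0, 1.0, 0.0, 1.0)

    def test_recovers_injected_shift(self):
        pheno, metab = _calibration_fixture()
        matched = match_cohorts(pheno, "REF")
        cmap = fit_calibration(metab, matched, pheno["cohort"])
        for f in ["m1", "m2", "m3"]:
            mu_t, sd_t, mu_r, sd_r = cmap.table["TGT"][f]
            assert abs((mu_t - mu_r) - 0.5) < 0.05
            assert abs(sd_t / sd_r - 1.3) < 0.1

    def test_apply_identity_map(self):
        pheno, metab = _calibration_fixture()
        cmap = CalibrationMap("REF", {c: {f: (0.0, 1.0, 0.0, 1.0) for f in metab.columns}
                                      for c in ["REF", "TGT"]})
        out = apply_calibration(metab, cmap, pheno["cohort"])
        pd.testing.assert_frame_equal(out, metab)

    def test_apply_affine_arithmetic(self):
        metab = pd.DataFrame({"m": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        labels = pd.Series(["X"] * 3, index=metab.index)
        cmap = CalibrationMap("R", {"X": {"m": (1.0, 1.0, 10.0, 2.0)}})
        out = apply_calibration(metab, cmap, labels)
        assert np.allclose(out["m"], [8.0, 10.0, 12.0])

    def test_matched_moments_equal_after_calibration(self):
        pheno, metab = _calibration_fixture()
        matched = match_cohorts(pheno, "REF")
        cmap = fit_calibration(metab, matched, pheno["cohort"])
        out = apply_calibration(metab, cmap, pheno["cohort"])
        ref_ids = [r for r, _ in matched.pairs["TGT"]]
        tgt_ids = [t for _, t in matched.pairs["TGT"]]
        assert np.abs(out.loc[tgt_ids].mean().to_numpy()
                      - out.loc[ref_ids].mean().to_numpy()).max() < 1e-10
        assert np.abs(out.loc[tgt_ids].std().to_numpy()
                      - out.loc[ref_ids].std().to_numpy()).max() < 1e-10

    def test_degenerate_sd_errors(self):
        pheno, metab = _calibration_fixture()
        metab["m1"] = 1.0
        matched = match_cohorts(pheno, "REF")
        with pytest.raises(ValueError, match="m1"):
            fit_calibration(metab, matched, pheno["cohort"])

    def test_missing_map_entry_errors(self):
        pheno, metab = _calibration_fixture()
        cmap = CalibrationMap("REF", {"REF": {f: (0, 1, 0, 1) for f in metab.columns}})
        with pytest.raises(KeyError):
            apply_calibration(metab, cmap, pheno["cohort"])

    @settings(max_examples=20, deadline=None)
    @given(mu_t=st.floats(-2, 2), sd_t=st.floats(0.2, 3), mu_r=st.floats(-2, 2),
           sd_r=st.floats(0.2, 3))
    def test_calibration_is_monotone(self, mu_t, sd_t, mu_r, sd_r):
        metab = pd.DataFrame({"m": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        labels = pd.Series(["X"] * 3, index=metab.index)
        cmap = CalibrationMap("R", {"X": {"m": (mu_t, sd_t, mu_r, sd_r)}})
        out = apply_calibration(metab, cmap, labels)["m"].to_numpy()
        assert out[0] < out[1] < out[2]

    def test_map_json_roundtrip(self, tmp_path):
        pheno, metab = _calibration_fixture()
        matched = match_cohorts(pheno, "REF")
        cmap = fit_calibration(metab, matched, pheno["cohort"])
        cmap.to_json(tmp_path / "map.json")
        loaded = CalibrationMap.from_json(tmp_path / "map.json")
        assert loaded.table == cmap.table


class TestBatchMixing:
    def test_same_distribution_low_rejection(self, rng):
        x = rng.normal(size=(1000, 5))
        labels = pd.Series(rng.permutation(["A"] * 500 + ["B"] * 500))
        rep = batch_mixing_test(x, labels, k=50, n_draws=300, seed=1)
        assert rep.rejection_rate <= 0.15

    def test_separated_cohorts_high_rejection(self, rng):
        x = rng.normal(size=(600, 5))
        x[300:] += 5.0
        labels = pd.Series(["A"] * 300 + ["B"] * 300)
        rep = batch_mixing_test(x, labels, k=50, n_draws=300, seed=1)
        assert rep.rejection_rate >= 0.9

    def test_single_cohort_defined_zero(self, rng):
        x = rng.normal(size=(50, 3))
        with pytest.warns(UserWarning):
            rep = batch_mixing_test(x, pd.Series(["A"] * 50), k=10)
        assert rep.rejection_rate == 0.0


class TestVarianceComponents:
    def test_pure_cohort_shift(self, rng):
        x = rng.normal(0, 0.1, size=(400, 6))
        x[200:] += 3.0
        factors = pd.DataFrame({"cohort": ["A"] * 200 + ["B"] * 200,
                                "age": rng.uniform(30, 70, 400)})
        rep = variance_components(x, factors)
        assert rep.fractions["cohort"] >= 0.8

    def test_isotropic_noise_mostly_residual(self, rng):
        x = rng.normal(size=(1000, 8))
        factors = pd.DataFrame({"cohort": rng.choice(["A", "B"], 1000),
                                "age": rng.uniform(30, 70, 1000)})
        rep = variance_components(x, factors)
        assert rep.fractions["residual"] >= 0.8

    def test_single_level_factor_zero(self, rng):
        x = rng.normal(size=(100, 4))
        factors = pd.DataFrame({"cohort": ["A"] * 100, "age": rng.uniform(30, 70, 100)})
        with pytest.warns(UserWarning):
            rep = variance_components(x, factors)
        assert rep.fractions["cohort"] == 0.0

    def test_fractions_sum_to_one(self, rng):
        x = rng.normal(size=(200, 5))
        factors = pd.DataFrame({"cohort": rng.choice(list("ABC"), 200),
                                "age": rng.uniform(30, 70, 200),
                                "sex": rng.integers(0, 2, 200)})
        rep = variance_components(x, factors)
        assert abs(sum(rep.fractions.values()) - 1.0) < 1e-6
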