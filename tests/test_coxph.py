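"""Cox machinery: partial-likelihood oracle, concordance enumeration, scans, AUC, PH."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from dnamet.coxph import (CoxConvergenceError, bh_adjust, compare_concordance,
                          concordance, fit_cox, schoenfeld_test, stepwise_select,
                          td_auc, univariate_scan)
from dnamet.simulate import make_survival


def naive_efron_loglik(beta, x, time, event):
    """Textbook Efron partial likelihood, written out with explicit loops."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d_idx = np.nonzero((time == t) & (event == 1))[0]
        risk = np.nonzero(time >= t)[0]
        d = len(d_idx)
        s0r = np.exp(x[risk] * beta).sum()
        s0d = np.exp(x[d_idx] * beta).sum()
        ll += (x[d_idx] * beta).sum()
        for l in range(d):
            ll -= np.log(s0r - l / d * s0d)
    return ll


def naive_concordance(risk, time, event):
    """Exhaustive pairwise Harrell C."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (event[i] == 1) and (time[i] < time[j]
                                          or (time[i] == time[j] and event[j] == 0))
            if not usable:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    return num / den


class TestFitCox:
    def test_eight_subject_oracle(self):
        """Newton solution equals brute-force maximization of the written-out likelihood."""
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        time = np.array([2.0, 4, 6, 9, 1, 5, 7, 8])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        fit = fit_cox(pd.DataFrame({"x": x}),
                      pd.DataFrame({"time": time, "event": event}))
        res = optimize.minimize_scalar(lambda b: -naive_efron_loglik(b, x, time, event),
                                       bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        assert abs(fit.beta[0] - res.x) < 1e-6

    def test_tied_fixture_oracle(self):
        x = np.array([0.5, -1.0, 0.0, 2.0, 1.0, -0.5, 0.3])
        time = np.array([3.0, 3.0, 3.0, 5.0, 5.0, 7.0, 9.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0])
        fit = fit_cox(pd.DataFrame({"x": x}),
                      pd.DataFrame({"time": time, "event": event}))
        res = optimize.minimize_scalar(lambda b: -naive_efron_loglik(b, x, time, event),
                                       bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        assert abs(fit.beta[0] - res.x) < 1e-6

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        surv = make_survival(X.to_numpy(), np.array([0.5, -0.3, 0.0]), 1.4, 20, 0.4, rng)
        surv.index = X.index
        fit = fit_cox(X, surv)
        cph = CoxPHFitter().fit(X.assign(T=surv["time"], E=surv["event"]), "T", "E")
        assert np.abs(fit.beta - cph.params_.to_numpy()).max() < 1e-5
        assert np.abs(fit.se - cph.standard_errors_.to_numpy()).max() < 1e-6

    def test_constant_covariate_errors(self):
        X = pd.DataFrame({"x": np.ones(10)})
        surv = pd.DataFrame({"time": np.arange(1.0, 11), "event": [1] * 10})
        with pytest.raises(ValueError, match="constant"):
            fit_cox(X, surv)

    def test_monotone_likelihood_detected(self):
        # perfectly separating covariate -> diverging coefficient
        X = pd.DataFrame({"x": np.r_[np.ones(10), np.zeros(10)]})
        surv = pd.DataFrame({"time": np.r_[np.arange(1.0, 11), np.arange(20.0, 30)],
                             "event": np.ones(20, int)})
        with pytest.raises(CoxConvergenceError):
            fit_cox(X, surv)

    def test_hr_ci_contains_hr(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=200)})
        surv = make_survival(X.to_numpy(), np.array([0.4]), 1.5, 25, 0.3, rng)
        surv.index = X.index
        s = fit_cox(X, surv).summary()
        assert (s["hr_lo95"] <= s["hr"]).all() and (s["hr"] <= s["hr_hi95"]).all()


class TestConcordance:
    def test_perfect_ranking(self):
        surv = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1]})
        assert concordance(np.array([4.0, 3, 2, 1]), surv) == 1.0

    def test_censored_fixture_matches_enumeration(self, tiny_survival):
        rng = np.random.default_rng(1)
        risk = rng.normal(size=6)
        c = concordance(risk, tiny_survival)
        expect = naive_concordance(risk, tiny_survival["time"].to_numpy(),
                                   tiny_survival["event"].to_numpy())
        assert c == expect

    def test_random_fixtures_match_enumeration_exactly(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 50
            time = np.round(rng.exponential(5, n), 1) + 0.1
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            risk = np.round(rng.normal(size=n), 1)  # induces score ties
            surv = pd.DataFrame({"time": time, "event": event})
            assert concordance(risk, surv) == naive_concordance(risk, time, event)

    def test_no_usable_pairs_errors(self):
        surv = pd.DataFrame({"time": [1.0, 1.0], "event": [1, 1]})
        with pytest.raises(ValueError):
            concordance(np.array([1.0, 2.0]), surv)


class TestCompareConcordance:
    def test_self_comparison(self, rng, tiny_survival):
        risk = rng.normal(size=6)
        assert compare_concordance(risk, risk, tiny_survival) == (0.0, 1.0)

    def test_sign_contract(self, rng):
        n = 300
        x = rng.normal(size=n)
        surv = make_survival(x[:, None], np.array([0.8]), 1.5, 20, 0.3, rng)
        noise = rng.normal(size=n)
        d, _ = compare_concordance(x, noise, surv)
        c_a = concordance(x, surv)
        c_b = concordance(noise, surv)
        assert (d > 0) == (c_a > c_b)
        assert abs(d - (c_a - c_b)) < 1e-12


class TestScanAndBH:
    def test_bh_textbook_example(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.5])), [0.03, 0.03, 0.5])

    def test_bh_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_scan_reports_collinear_feature(self, rng):
        n = 200
        age = rng.uniform(50, 80, n)
        covars = pd.DataFrame({"age": age, "sex": rng.integers(0, 2, n)})
        scores = pd.DataFrame({"dup": age, "ok": rng.normal(size=n)})
        surv = make_survival(rng.normal(size=(n, 1)), np.array([0.3]), 1.5, 25, 0.3, rng)
        surv.index = scores.index = covars.index = pd.RangeIndex(n)
        out = univariate_scan(scores, covars, surv)
        assert out.loc["dup", "error"] != ""
        assert np.isfinite(out.loc["ok", "p"])

    def test_scan_flags_true_driver(self, rng):
        n = 800
        z = rng.normal(size=(n, 6))
        surv = make_survival(z[:, :1], np.array([0.6]), 1.5, 25, 0.4, rng)
        scores = pd.DataFrame(z, columns=[f"s{i}" for i in range(6)])
        surv.index = scores.index
        out = univariate_scan(scores, None, surv)
        assert out.loc["s0", "significant"]
        assert (out["p_adj"] >= out["p"] - 1e-15).all()


class TestStepwise:
    def test_no_qualifying_candidate_returns_base(self, rng):
        n = 300
        cand = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        base = pd.DataFrame({"age": rng.uniform(50, 80, n)})
        surv = make_survival(base[["age"]].to_numpy() * 0.0, np.array([0.0]), 1.5, 25,
                             0.3, rng)
        surv.index = cand.index = base.index = pd.RangeIndex(n)
        trace = stepwise_select(cand, base, surv, tol_c=0.05)
        assert trace.steps == [] and trace.final_variables == []

    def test_deterministic_replay(self, rng):
        n = 400
        z = rng.normal(size=(n, 5))
        surv = make_survival(z[:, :1], np.array([0.6]), 1.5, 25, 0.4, rng)
        cand = pd.DataFrame(z, columns=[f"s{i}" for i in range(5)])
        base = pd.DataFrame({"age": rng.uniform(50, 80, n)}, index=cand.index)
        surv.index = cand.index
        t1 = stepwise_select(cand, base, surv)
        t2 = stepwise_select(cand, base, surv)
        assert t1.steps == t2.steps and t1.final_variables == t2.final_variables


class TestTdAuc:
    def test_perfect_separator(self):
        time = np.array([1.0, 2, 3, 10, 11, 12])
        event = np.array([1, 1, 1, 0, 0, 0])
        surv = pd.DataFrame({"time": time, "event": event})
        score = np.array([3.0, 2.5, 2.0, 1.0, 0.5, 0.2])
        assert td_auc(score, surv, 5.0) == pytest.approx(1.0)

    def test_no_censoring_equals_binary_auc(self, rng):
        from sklearn.metrics import roc_auc_score
        n = 400
        x = rng.normal(size=n)
        surv = make_survival(x[:, None], np.array([0.7]), 1.5, 20, 0.0, rng)
        horizon = float(np.median(surv["time"]))
        cases = (surv["time"] <= horizon).to_numpy()
        auc = td_auc(x, surv, horizon)
        assert abs(auc - roc_auc_score(cases, x)) < 1e-10

    def test_precondition_errors(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            td_auc(np.array([1.0, 2.0]), surv, 5.0)


class TestSchoenfeld:
    def test_single_event_errors(self):
        X = pd.DataFrame({"x": [0.1, 0.4, 0.9]})
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 0, 0]})
        with pytest.raises(ValueError):
            schoenfeld_test(X, surv)

    def test_ph_data_large_p(self, rng):
        n = 400
        X = pd.DataFrame({"x": rng.normal(size=n)})
        surv = make_survival(X.to_numpy(), np.array([0.5]), 1.5, 20, 0.3, rng)
        surv.index = X.index
        p = schoenfeld_test(X, surv)
        assert p.index.tolist() == ["x"] and 0 <= p["x"] <= 1
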