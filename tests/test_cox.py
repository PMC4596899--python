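"""Left-truncated Cox fits against grid-search and lifelines oracles."""

import numpy as np
import pandas as pd
import pytest

import mrscore as m
from mrscore.models import LeftTruncatedCox, ph_check


def _survival_fixture(seed, n=120, beta=-0.4, censor_at=12.0):
    rng = np.random.default_rng(seed)
    entry = rng.uniform(50, 70, n)
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    exit_ = entry + np.minimum(t, censor_at)
    event = (t < censor_at).astype(int)
    return entry, exit_, event, x


def breslow_partial_loglik(beta, entry, exit_, event, x):
    """Independent direct evaluation of the Breslow partial likelihood."""
    ll = 0.0
    for t in np.unique(exit_[event == 1]):
        d = (exit_ == t) & (event == 1)
        risk = (entry < t) & (t <= exit_)
        ll += beta * x[d].sum() - d.sum() * np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestCoxFit:
    def test_matches_grid_search_oracle(self):
        entry, exit_, event, x = _survival_fixture(0, n=30)
        res = LeftTruncatedCox(entry, exit_, event, x).fit()
        grid = np.arange(-2.0, 2.0, 1e-3)
        lls = [breslow_partial_loglik(b, entry, exit_, event, x) for b in grid]
        assert abs(res.params[0] - grid[int(np.argmax(lls))]) <= 1e-3 + 1e-9

    def test_matches_lifelines_with_entry_col(self):
        entry, exit_, event, x = _survival_fixture(1, n=250)
        res = LeftTruncatedCox(entry, exit_, event, x).fit()
        import lifelines

        df = pd.DataFrame({"entry": entry, "t": exit_, "e": event, "x": x})
        cph = lifelines.CoxPHFitter().fit(
            df, duration_col="t", event_col="e", entry_col="entry"
        )
        # no tied event times, so Efron (lifelines) == Breslow (ours)
        assert res.params[0] == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)

    def test_robust_variance_matches_brute_force_definition(self):
        entry, exit_, event, x = _survival_fixture(2, n=60)
        res = LeftTruncatedCox(entry, exit_, event, x).fit(small_sample=False)
        beta = res.params
        w = np.exp(x * beta[0])
        times = np.unique(exit_[event == 1])
        U = np.zeros(len(x))
        for i in range(len(x)):
            if event[i] == 1:
                risk = (entry < exit_[i]) & (exit_[i] <= exit_)
                U[i] += x[i] - (w[risk] * x[risk]).sum() / w[risk].sum()
            for t in times:
                if entry[i] < t <= exit_[i]:
                    risk = (entry < t) & (t <= exit_)
                    s0 = w[risk].sum()
                    xbar = (w[risk] * x[risk]).sum() / s0
                    d_k = ((exit_ == t) & (event == 1)).sum()
                    U[i] -= d_k * w[i] / s0 * (x[i] - xbar)
        info_inv = float(np.linalg.inv(res.information)[0, 0])
        se = float(np.sqrt(info_inv**2 * (U @ U)))
        assert res.bse[0] == pytest.approx(se, rel=1e-10)

    def test_breslow_tie_handling_against_direct_likelihood(self):
        # integer exit times force ties
        rng = np.random.default_rng(3)
        n = 80
        entry = np.zeros(n)
        x = rng.normal(size=n)
        exit_ = 1.0 + np.floor(rng.exponential(4, n)).clip(0, 8)
        event = (rng.random(n) < 0.7).astype(int)
        res = LeftTruncatedCox(entry, exit_, event, x).fit()
        grid = np.arange(-1.5, 1.5, 1e-3)
        lls = [breslow_partial_loglik(b, entry, exit_, event, x) for b in grid]
        assert abs(res.params[0] - grid[int(np.argmax(lls))]) <= 1e-3 + 1e-9

    def test_left_truncation_changes_risk_sets(self):
        """Ignoring delayed entry biases the estimate; the fit must not."""
        entry, exit_, event, x = _survival_fixture(4, n=400)
        lt = LeftTruncatedCox(entry, exit_, event, x).fit()
        naive = LeftTruncatedCox(np.zeros_like(entry), exit_, event, x).fit()
        assert lt.params[0] != pytest.approx(naive.params[0], abs=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(m.MrscoreError, match="events"):
            LeftTruncatedCox([0, 0], [1, 2], [0, 0], [1.0, 2.0]).fit()

    def test_entry_after_exit_rejected(self):
        with pytest.raises(m.MrscoreError, match="entry"):
            LeftTruncatedCox([5, 0], [1, 2], [1, 0], [1.0, 2.0])


class TestCohortSurvival:
    def test_missing_followup_excluded_and_counted(self, desk_data, height_score):
        spec = m.SimulationSpec(seed=7)
        res = m.fit_cox_cluster(
            m.SurvivalSpec(event="all-cause"), desk_data.cohort, height_score
        )
        n_cases = desk_data.cohort.n_cases
        expected_missing = round(spec.missing_followup_frac * n_cases)
        assert res.n_excluded == expected_missing
        assert res.nobs == n_cases - expected_missing

    def test_disease_specific_censors_other_causes(self, desk_data, height_score):
        all_cause = m.fit_cox_cluster(
            m.SurvivalSpec(event="all-cause"), desk_data.cohort, height_score
        )
        specific = m.fit_cox_cluster(
            m.SurvivalSpec(event="disease-specific"), desk_data.cohort, height_score
        )
        df = desk_data.cohort.cases()
        kept, _ = m.complete_followup(df)
        assert all_cause.n_events == int((kept["died"] == 1).sum())
        assert specific.n_events == int((kept["death_cause"] == "disease").sum())
        assert specific.n_events < all_cause.n_events


class TestPhCheck:
    def test_shape_contract(self):
        entry, exit_, event, x = _survival_fixture(5, n=150)
        res = LeftTruncatedCox(entry, exit_, event, x, exog_names=["score"]).fit()
        out = ph_check(res)
        assert set(out) == {"global_stat", "global_p", "covariates"}
        assert "score" in out["covariates"]
        assert 0 <= out["global_p"] <= 1

    def test_null_calibration(self):
        rejections = 0
        for s in range(100):
            entry, exit_, event, x = _survival_fixture(100 + s, n=150)
            res = LeftTruncatedCox(entry, exit_, event, x).fit()
            rejections += ph_check(res)["global_p"] < 0.05
        assert 1 <= rejections <= 12

    def test_detects_time_varying_effect(self):
        """Effect that reverses over follow-up is flagged."""
        rejections = 0
        for s in range(50):
            rng = np.random.default_rng(200 + s)
            n = 300
            entry = np.zeros(n)
            x = rng.normal(size=n)
            # hazard depends on x only early in follow-up, strongly
            t1 = rng.exponential(1.0 / (0.5 * np.exp(1.5 * x)))
            t = np.where(t1 < 1.0, t1, 1.0 + rng.exponential(1.0 / 0.5, n))
            event = (t < 6.0).astype(int)
            exit_ = np.minimum(t, 6.0) + 1e-9
            res = LeftTruncatedCox(entry, exit_, event, x).fit()
            rejections += ph_check(res)["global_p"] < 0.05
        assert rejections / 50 > 0.8
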