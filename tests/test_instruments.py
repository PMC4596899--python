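import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

import mrscore as m


class TestFirstStage:
    def test_hand_computed_fixture(self):
        # Sxy=6.5, Sxx=5, Syy=8.75 -> r2=42.25/43.75, F=(n-2)r2/(1-r2)
        d = m.first_stage(np.array([0.0, 1, 2, 3]), np.array([0.0, 1, 2, 4]))
        assert d.r2 == pytest.approx(0.9657142857, abs=1e-9)
        assert d.f_stat == pytest.approx(56.3333333, abs=1e-6)

    def test_perfect_fit_reports_infinite_f(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="perfect"):
            d = m.first_stage(x, x)
        assert d.r2 == 1.0 and np.isinf(d.f_stat)

    def test_constant_score_rejected(self):
        with pytest.raises(m.MrscoreError, match="constant"):
            m.first_stage(np.ones(10), np.arange(10.0))

    def test_independent_inputs_tiny_r2(self):
        rng = np.random.default_rng(0)
        hits = sum(
            m.first_stage(rng.normal(size=10_000), rng.normal(size=10_000)).r2 < 0.001
            for _ in range(20)
        )
        assert hits >= 19

    def test_f_r2_identity(self, desk_data, height_score):
        ph = desk_data.cohort.data.set_index("subject_id")["height"]
        z = (ph - ph.mean()) / ph.std(ddof=1)
        d = m.first_stage(height_score.as_series().loc[z.index].to_numpy(), z.to_numpy())
        assert d.f_stat == pytest.approx((d.n - 2) * d.r2 / (1 - d.r2), rel=1e-12)


class TestPower:
    def test_consortium_scale_power_values(self):
        p1 = m.mr_power_binary(m.PowerInput(20848, 20214, 0.0631, 1.12))
        p2 = m.mr_power_binary(m.PowerInput(20848, 20214, 0.0146, 1.25))
        assert round(p1, 2) == 0.82
        assert round(p2, 2) == 0.78

    def test_null_alternative_equals_half_alpha(self):
        p = m.mr_power_binary(m.PowerInput(100, 100, 0.05, 1.0))
        assert p == pytest.approx(0.025, abs=1e-10)

    def test_zero_r2_warns(self):
        with pytest.warns(UserWarning, match="no information"):
            p = m.mr_power_binary(m.PowerInput(100, 100, 0.0, 1.5))
        assert p == pytest.approx(0.025, abs=1e-10)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.integers(min_value=100, max_value=50_000),
        st.floats(min_value=0.001, max_value=0.3),
        st.floats(min_value=1.0, max_value=2.0),
    )
    def test_monotone_in_n_r2_and_effect(self, n, r2, or_alt):
        base = m.mr_power_binary(m.PowerInput(n, n, r2, or_alt))
        assert m.mr_power_binary(m.PowerInput(2 * n, 2 * n, r2, or_alt)) >= base - 1e-12
        assert m.mr_power_binary(m.PowerInput(n, n, min(r2 * 1.5, 0.9), or_alt)) >= base - 1e-12
        assert m.mr_power_binary(m.PowerInput(n, n, r2, or_alt * 1.1)) >= base - 1e-12


class TestGenotypePCs:
    def _two_population_panel(self):
        w = m.simulate_weights(40, seed=8)
        rng = np.random.default_rng(8)
        f = rng.uniform(0.2, 0.8, 40)
        a = m.simulate_dosages(150, w, np.clip(f - 0.15, 0.02, 0.98), seed=1)
        b = m.simulate_dosages(150, w, np.clip(f + 0.15, 0.02, 0.98), seed=2)
        df = pd.concat(
            [a.dosages, b.dosages.set_index(pd.Index([f"T{i}" for i in range(150)]))]
        )
        return m.DosagePanel(df), np.r_[np.zeros(150), np.ones(150)]

    def test_pc1_separates_subpopulations(self):
        panel, label = self._two_population_panel()
        pcs, _ = m.genotype_pcs(panel, k=4)
        r = np.corrcoef(pcs["PC1"], label)[0, 1]
        assert abs(r) > 0.8

    def test_explained_variance_non_increasing_and_orthogonal(self, desk_data):
        pcs, ev = m.genotype_pcs(desk_data.panel, k=8)
        assert np.all(np.diff(ev) <= 1e-12)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.diag(gram))

    def test_no_structure_no_dominant_axis(self):
        w = m.simulate_weights(60, seed=9)
        f = np.random.default_rng(9).uniform(0.2, 0.8, 60)
        panel = m.simulate_dosages([200, 200], w, f, drift=0.0, seed=3)
        _, ev = m.genotype_pcs(panel, k=5)
        assert ev[0] < 5.0 / min(panel.n_subjects, panel.n_variants)

    def test_k_beyond_rank_rejected(self, tiny_panel):
        with pytest.raises(m.MrscoreError, match="rank"):
            m.genotype_pcs(tiny_panel, k=3)


class TestCovariateScan:
    def _cohort(self, n, rng, extra=None):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "study_id": np.repeat(np.arange(10), n // 10),
                "case": rng.integers(0, 2, n),
                "grade_class": "unknown",
                "stage_class": "unknown",
                "age_entry": np.nan,
                "age_exit": np.nan,
                "died": 0,
                "death_cause": "alive",
            }
        )
        df.loc[df["case"] == 1, "grade_class"] = "low"
        df.loc[df["case"] == 1, "stage_class"] = "localized"
        covars = []
        for name, vals in (extra or {}).items():
            df[name] = vals
            covars.append(name)
        return m.CohortTable(df, covariate_cols=covars)

    def test_score_as_its_own_covariate(self):
        rng = np.random.default_rng(5)
        n = 500
        score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        z = (score - score.mean()) / score.std(ddof=1)
        cohort = self._cohort(n, rng, {"self": z.to_numpy()})
        out = m.covariate_scan(z, cohort, ["self"])
        assert out.loc[0, "type"] == "mean_difference"
        assert out.loc[0, "estimate"] == pytest.approx(1.0, abs=1e-10)

    def test_single_level_covariate_skipped(self):
        rng = np.random.default_rng(5)
        n = 200
        score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        cohort = self._cohort(n, rng, {"flat": np.zeros(n)})
        with pytest.warns(UserWarning, match="single level"):
            out = m.covariate_scan(score, cohort, ["flat"])
        assert len(out) == 0

    def test_null_p_values_uniform(self):
        """Independent covariates give uniform scan p-values (KS test)."""
        rng = np.random.default_rng(6)
        n = 400
        ps = []
        for _ in range(200):
            score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            cohort = self._cohort(n, rng, {"x": rng.normal(size=n)})
            out = m.covariate_scan(score, cohort, ["x"], cluster=False)
            ps.append(out.loc[0, "p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_binary_covariate_coverage(self):
        """CI covers a known log-OR of 0.3 in at least 93/100 replicates."""
        rng = np.random.default_rng(7)
        n = 800
        covered = 0
        from scipy.special import expit

        for _ in range(100):
            score = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            y = (rng.random(n) < expit(-1.0 + 0.3 * score.to_numpy())).astype(int)
            cohort = self._cohort(n, rng, {"y": y})
            out = m.covariate_scan(score, cohort, ["y"], cluster=False)
            covered += out.loc[0, "ci_low"] <= np.exp(0.3) <= out.loc[0, "ci_high"]
        assert covered >= 93
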