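import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mrscore as m


def _panel_from_matrix(D, weights):
    df = pd.DataFrame(D, columns=weights.variant_ids,
                      index=[f"s{i}" for i in range(len(D))])
    coded = {v.variant_id: v.effect_allele for v in weights}
    other = {v.variant_id: v.other_allele for v in weights}
    return m.DosagePanel(df, coded, other)


class TestBuildScore:
    def test_weighted_arithmetic(self, tiny_panel, tiny_weights):
        sc = m.build_score(tiny_panel, tiny_weights)
        assert sc.raw[0] == pytest.approx(1.5 * 0.10 + 0.5 * 0.05)

    def test_zero_dosages_score_zero(self, tiny_weights):
        panel = _panel_from_matrix(np.zeros((3, 2)), tiny_weights)
        assert np.all(m.build_score(panel, tiny_weights).raw == 0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(11)
        weights = m.simulate_weights(10, seed=11)
        D = rng.uniform(0, 2, size=(20, 10))
        panel = _panel_from_matrix(D, weights)
        sc = m.build_score(panel, weights)
        # independent brute-force summation, element by element
        expected = [
            sum(D[i, j] * weights.variants[j].weight for j in range(10))
            for i in range(20)
        ]
        np.testing.assert_allclose(sc.raw, expected, atol=1e-12)

    def test_unweighted_mode_counts_alleles(self, tiny_panel, tiny_weights):
        sc = m.build_score(tiny_panel, tiny_weights, mode="unweighted")
        assert sc.raw[0] == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=-5, max_value=5, allow_nan=False).filter(lambda c: abs(c) > 1e-3))
    def test_linearity_in_weights(self, c):
        weights = m.simulate_weights(6, seed=3)
        rng = np.random.default_rng(3)
        panel = _panel_from_matrix(rng.uniform(0, 2, size=(15, 6)), weights)
        base = m.build_score(panel, weights).raw
        scaled = m.build_score(panel, weights.scaled(c)).raw
        np.testing.assert_allclose(scaled, c * base, rtol=1e-12)


class TestStandardize:
    def test_forced_values(self):
        sc = m.ScoreVector(pd.Index(["a", "b", "c"]), np.array([1.0, 2.0, 3.0]))
        out = m.standardize(sc)
        np.testing.assert_allclose(out.standardized, [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        sc = m.ScoreVector(pd.RangeIndex(100), rng.normal(size=100))
        once = m.standardize(sc)
        twice = m.standardize(
            m.ScoreVector(sc.subject_ids, once.standardized)
        )
        np.testing.assert_allclose(twice.standardized, once.standardized, atol=1e-12)

    def test_sample_moments(self):
        rng = np.random.default_rng(1)
        sc = m.ScoreVector(pd.RangeIndex(10_000), rng.gamma(2, 1, size=10_000))
        out = m.standardize(sc)
        assert abs(out.standardized.mean()) < 1e-10
        assert abs(out.standardized.std(ddof=1) - 1) < 1e-10

    def test_outside_sample_uses_same_constants(self):
        sc = m.ScoreVector(pd.Index(list("abcd")), np.array([1.0, 2.0, 3.0, 10.0]))
        out = m.standardize(sc, sample=["a", "b", "c"])
        np.testing.assert_allclose(out.standardized[:3], [-1, 0, 1])
        assert out.standardized[3] == pytest.approx(8.0)

    def test_zero_sd_rejected(self):
        sc = m.ScoreVector(pd.RangeIndex(3), np.ones(3))
        with pytest.raises(m.MrscoreError, match="SD"):
            m.standardize(sc)


class TestQuintiles:
    def test_forced_assignment(self):
        sc = m.ScoreVector(pd.RangeIndex(10), np.arange(1.0, 11.0))
        q = m.quintile_groups(sc)
        assert list(q[:2]) == [1, 1] and list(q[-2:]) == [5, 5]

    def test_ties_go_to_lower_group(self):
        vals = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        sc = m.ScoreVector(pd.RangeIndex(10), vals)
        q = m.quintile_groups(sc)
        cut20 = np.quantile(vals, 0.2)
        at_cut = vals == cut20
        assert np.all(q[at_cut] == 1)

    def test_balanced_sizes_on_distinct_values(self):
        rng = np.random.default_rng(2)
        sc = m.ScoreVector(pd.RangeIndex(1000), rng.permutation(1000).astype(float))
        q = m.quintile_groups(sc)
        assert [int((q == g).sum()) for g in range(1, 6)] == [200] * 5

    def test_too_few_distinct_rejected(self):
        sc = m.ScoreVector(pd.RangeIndex(6), np.array([1.0, 1, 2, 2, 3, 3]))
        with pytest.raises(m.MrscoreError, match="distinct"):
            m.quintile_groups(sc)


class TestSplits:
    def test_random_halves_sizes_179(self):
        weights = m.simulate_weights(179, seed=9)
        a, b = m.split_weights(weights, "random_halves", seed=1)
        assert sorted([len(a), len(b)]) == [89, 90]
        assert set(a.variant_ids) | set(b.variant_ids) == set(weights.variant_ids)
        assert not set(a.variant_ids) & set(b.variant_ids)

    def test_named_variant_vs_rest_32(self):
        weights = m.simulate_weights(32, seed=9)
        top = max(weights, key=lambda v: v.weight).variant_id
        a, b = m.split_weights(weights, "named_variant_vs_rest", named_variant=top)
        assert len(a) == 1 and len(b) == 31
        assert a.variant_ids == [top]

    def test_missing_named_variant_rejected(self, tiny_weights):
        with pytest.raises(m.MrscoreError, match="rs999"):
            m.split_weights(tiny_weights, "named_variant_vs_rest", named_variant="rs999")

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_partition_additivity(self, seed):
        """Raw weighted sub-scores of any random split sum to the full score."""
        weights = m.simulate_weights(13, seed=41)
        rng = np.random.default_rng(41)
        panel = _panel_from_matrix(rng.uniform(0, 2, size=(25, 13)), weights)
        a, b = m.split_weights(weights, "random_halves", seed=seed)
        full = m.build_score(panel, weights).raw
        part = (
            m.build_score(m.harmonize(panel, a), a).raw
            + m.build_score(m.harmonize(panel, b), b).raw
        )
        np.testing.assert_allclose(part, full, atol=1e-12)
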