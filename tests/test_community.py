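import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from micasm import community, synthio
from micasm.errors import DegenerateDataError, ValidationError
from micasm.io import CommunityTable


class TestBrayCurtis:
    def test_hand_value(self):
        assert community.bray_curtis([1, 2, 3], [3, 2, 1]) == pytest.approx(1 / 3)

    def test_identity_and_disjoint(self):
        assert community.bray_curtis([4, 0, 1], [4, 0, 1]) == 0
        assert community.bray_curtis([1, 0], [0, 2]) == 1

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            community.bray_curtis([0, 0], [0, 0])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=20),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_bounded_semimetric(self, xs, data):
        ys = data.draw(st.lists(st.floats(0, 100), min_size=len(xs),
                                max_size=len(xs)))
        x, y = np.array(xs), np.array(ys)
        if (x + y).sum() == 0:
            return
        bc = community.bray_curtis(x, y)
        assert 0 <= bc <= 1
        assert bc == pytest.approx(community.bray_curtis(y, x))
        # independent oracle: scipy's implementation
        from scipy.spatial.distance import braycurtis
        assert bc == pytest.approx(float(braycurtis(x, y)), abs=1e-12)


def _table(counts, prefix="s"):
    counts = pd.DataFrame(counts)
    counts.index = [f"{prefix}{i}" for i in range(len(counts))]
    counts.columns = [f"o{j}" for j in range(counts.shape[1])]
    md = pd.DataFrame({"treatment": "T", "batch": "B1", "replicate": 1,
                       "day": 5}, index=counts.index)
    return CommunityTable(counts, md)


class TestRarefy:
    def test_full_depth_is_identity(self):
        table = _table([[3, 7], [5, 5]])
        out = community.rarefy(table, 10, seed=0)
        pd.testing.assert_frame_equal(out.counts, table.counts)

    def test_forced_outcome(self):
        out = community.rarefy(_table([[10, 0, 0]]), 5, seed=0)
        assert out.counts.iloc[0].tolist() == [5, 0, 0]

    def test_depth_error_lists_samples(self):
        with pytest.raises(ValidationError, match="s1"):
            community.rarefy(_table([[10, 10], [1, 1]]), 5, seed=0)

    def test_hypergeometric_mean(self):
        # 10^4 seeded draws of (5,5) at depth 4: mean of the first entry
        # must match the hypergeometric mean 2 within 3 standard errors
        table = _table(np.tile([5, 5], (10_000, 1)))
        out = community.rarefy(table, 4, seed=42)
        first = out.counts.iloc[:, 0].to_numpy()
        assert (out.counts.sum(axis=1) == 4).all()
        var = 4 * 0.5 * 0.5 * (10 - 4) / (10 - 1)
        se = np.sqrt(var / 10_000)
        assert abs(first.mean() - 2.0) < 3 * se

    def test_preserves_zeros(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(20, 30))
        counts[:, 5] = 0
        table = _table(counts)
        out = community.rarefy(table, int(counts.sum(axis=1).min()), seed=2)
        assert (out.counts.to_numpy()[counts == 0] == 0).all()


class TestRemovalRate:
    def _chem(self, c0, c5):
        return pd.DataFrame(
            [("m1", "T", 1, "B1", "BPA", 0, c0),
             ("m1", "T", 1, "B1", "BPA", 5, c5)],
            columns=["microcosm_id", "treatment", "replicate", "batch",
                     "compound", "day", "concentration_ugL"])

    @pytest.mark.parametrize("c0,c5,expected", [(1.0, 0.2, 80.0),
                                                (1.0, 1.1, -10.0)])
    def test_arithmetic(self, c0, c5, expected):
        out = community.removal_rate(self._chem(c0, c5))
        assert out["removal_percent"].iloc[0] == pytest.approx(expected)

    def test_zero_day0_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = community.removal_rate(self._chem(0.0, 0.0))
        assert out.empty
        assert "day-0 concentration is zero" in caplog.text

    def test_unit_invariance(self):
        a = community.removal_rate(self._chem(1.0, 0.25))
        b = community.removal_rate(self._chem(1000.0, 250.0))
        assert a["removal_percent"].iloc[0] == pytest.approx(
            b["removal_percent"].iloc[0])


class TestRankSum:
    def test_identical_samples(self):
        _, p = community.rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_enumeration_hand_value(self):
        u, p = community.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_one_sided_reversal_identity(self):
        # exact test: p_greater + p_less = 1 + P(U = u_obs)
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, 5).astype(float)
            b = rng.integers(0, 4, 6).astype(float)
            _, pg = community.rank_sum_test(a, b, "greater")
            _, pl = community.rank_sum_test(a, b, "less")
            assert pg + pl >= 1 - 1e-12

    def test_asymptotic_tracks_exact(self):
        # average agreement of the tie-corrected normal approximation
        # with exhaustive enumeration at n=6 per group
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(100):
            a, b = rng.normal(size=6), rng.normal(size=6)
            _, exact = community.rank_sum_test(a, b)
            asym = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
            diffs.append(abs(exact - asym))
        assert np.mean(diffs) <= 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            community.rank_sum_test([], [1.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        assert community.kruskal_wallis([[1, 1], [1, 1]]) == (0.0, 1.0)

    def test_hand_computed_h(self):
        h, _ = community.kruskal_wallis([[1], [2], [3]])
        assert h == pytest.approx(2.0)

    def test_two_groups_consistent_with_rank_sum(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(0.5, 1, size=20)
        _, p_kw = community.kruskal_wallis([a, b])
        p_mw = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic",
                                  use_continuity=False).pvalue
        assert p_kw == pytest.approx(p_mw, abs=1e-9)


class TestTurnoverRegression:
    def _linear_table(self):
        rows, meta = [], []
        for b in range(1, 8):
            k = 10 * b
            rows.append(pd.Series({"o0": 100 - k, "o1": k},
                                  name=f"T_r1_B{b}"))
            meta.append((f"T_r1_B{b}", "T", f"B{b}", 1, 5 * b))
            rows.append(pd.Series({"o0": 100, "o1": 0}, name=f"C_r1_B{b}"))
            meta.append((f"C_r1_B{b}", "Control", f"B{b}", 1, 5 * b))
        counts = pd.DataFrame(rows)
        md = pd.DataFrame(meta, columns=["sample_id", "treatment", "batch",
                                         "replicate", "day"]).set_index("sample_id")
        return CommunityTable(counts, md)

    def test_perfect_linear_fit(self):
        ts = community.turnover_regression(self._linear_table(), "T")
        assert ts.slope == pytest.approx(0.02)  # dissimilarity per day
        assert ts.slope_pvalue < 1e-6

    def test_constant_dissimilarity(self):
        table = self._linear_table()
        counts = table.counts.copy()
        for b in range(1, 8):  # same composition every batch
            counts.loc[f"T_r1_B{b}"] = [50, 50]
        ts = community.turnover_regression(
            CommunityTable(counts, table.metadata), "T")
        assert ts.slope == 0.0

    def test_too_few_days(self):
        table = self._linear_table()
        keep = [s for s in table.sample_ids if s.endswith(("B1", "B2"))]
        with pytest.raises(DegenerateDataError):
            community.turnover_regression(table.subset_samples(keep), "T")

    def test_selection_regime_increases_turnover(self):
        # simulation oracle: under selection the treated community drifts
        # away from its control, so the dissimilarity slope is positive
        wins = 0
        for seed in range(20):
            cfg = synthio.SimConfig(
                seed=seed, n_otus=60, sequencing_depth=2000,
                treatments=[synthio.Treatment("Control", {}),
                            synthio.Treatment("TCS", {"TCS": 1.0})])
            table, _, _ = synthio.simulate_experiment(cfg)
            ts = community.turnover_regression(table, "TCS")
            wins += (ts.slope > 0) and (ts.slope_pvalue < 0.05)
        assert wins > 10
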