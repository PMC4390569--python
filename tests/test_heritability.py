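import numpy as np
import pandas as pd
import pytest

from ethoscan import (
    VarianceComponents,
    bonferroni,
    copulation_duration_means,
    decompose_table,
    decompose_trait,
    line_mean_correlation,
)
from ethoscan.heritability import block_partition, heritability
from ethoscan.simulate import simulate_traits


class TestBlockPartition:
    def test_all_variance_between_blocks(self):
        bp = block_partition([0, 0, 2, 2], ["b1", "b1", "b2", "b2"])
        assert bp.pct_block == pytest.approx(100.0)
        assert np.allclose(bp.residuals, 0.0)

    def test_identical_block_means(self):
        bp = block_partition([1, 3, 1, 3], ["b1", "b1", "b2", "b2"])
        assert bp.pct_block == pytest.approx(0.0)
        assert bp.F == pytest.approx(0.0)

    def test_single_block_flagged(self):
        with pytest.warns(UserWarning, match="single block"):
            bp = block_partition([1.0, 2.0, 3.0], ["b"] * 3)
        assert bp.pct_block == 0.0 and np.isnan(bp.F)

    def test_simulated_block_share_recovered(self, rng):
        # 5 blocks x 1000 males; block effects rescaled so their realized
        # variance is exactly 3% of the total (simulation oracle)
        shares = []
        for _ in range(200):
            b = rng.normal(size=5)
            b = (b - b.mean()) / b.std() * np.sqrt(0.03)
            blocks = np.resize(np.arange(5), 5000)
            vals = b[blocks] + rng.normal(0, np.sqrt(0.97), 5000)
            shares.append(block_partition(vals, blocks).pct_block)
        assert np.mean(shares) == pytest.approx(3.0, abs=0.3)


class TestHeritability:
    def test_perfect_line_separation(self):
        lh = heritability([0, 0, 2, 2], ["l1", "l1", "l2", "l2"])
        assert lh.H2 == pytest.approx(1.0)

    def test_no_variance_at_all(self):
        lh = heritability([1.0] * 6, ["l1", "l1", "l2", "l2", "l3", "l3"])
        assert lh.H2 == 0.0

    def test_balanced_matches_intraclass_correlation(self, rng):
        # closed form for a balanced design, computed independently
        y = rng.normal(size=40)
        lines = np.repeat(np.arange(8), 5)
        lh = heritability(y, lines)
        n = 5
        means = y.reshape(8, 5).mean(axis=1)
        ms_line = n * means.var(ddof=1)
        ms_err = np.mean([y.reshape(8, 5)[i].var(ddof=1) for i in range(8)])
        s2l = (ms_line - ms_err) / n
        assert lh.H2 == pytest.approx(s2l / (s2l + ms_err), abs=1e-10)
        assert lh.n0 == pytest.approx(n)

    def test_unbalanced_coefficient(self):
        # n0 = (N - sum(n_i^2)/N) / (a-1) with n = (2, 4): n0 = (6-20/6)/1
        y = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        lines = ["a", "a", "b", "b", "b", "b"]
        lh = heritability(y, lines)
        assert lh.n0 == pytest.approx((6 - 20 / 6) / 1)

    def test_all_singletons_error(self):
        with pytest.raises(ValueError, match="singleton"):
            heritability([1.0, 2.0, 3.0], ["a", "b", "c"])

    def test_single_line_error(self):
        with pytest.raises(ValueError, match="2 lines"):
            heritability([1.0, 2.0], ["a", "a"])

    def test_negative_estimates_occur_under_null(self, rng):
        vals, lines, _ = simulate_traits(
            166, 12, 5, sigma2_line=0.0, sigma2_block=0.0,
            sigma2_error=1.0, n_traits=100, rng=rng,
        )
        h2s = [heritability(v, lines).H2 for v in vals]
        assert min(h2s) < 0.0  # untruncated estimator goes negative
        assert abs(np.mean(h2s)) < 0.01

    def test_recovery_at_generating_value(self, rng):
        vals, lines, blocks = simulate_traits(
            166, 12, 5, sigma2_line=0.1, sigma2_block=0.0,
            sigma2_error=0.9, n_traits=100, rng=rng,
        )
        h2s = [heritability(block_partition(v, blocks).residuals, lines).H2
               for v in vals]
        assert np.mean(h2s) == pytest.approx(0.10, abs=0.01)

    def test_monotone_in_generating_line_variance(self, rng):
        means = []
        for s2l in (0.02, 0.08, 0.2):
            vals, lines, _ = simulate_traits(
                166, 12, 5, sigma2_line=s2l, sigma2_block=0.0,
                sigma2_error=1.0 - s2l, n_traits=60, rng=rng,
            )
            means.append(np.mean([heritability(v, lines).H2 for v in vals]))
        assert means[0] < means[1] < means[2]


class TestDecompose:
    def test_model_results_roundtrip(self, rng):
        vals, lines, blocks = simulate_traits(
            20, 8, 4, 0.3, 0.05, 0.65, n_traits=1, rng=rng)
        res = VarianceComponents(vals[0], lines, blocks, trait="demo").fit()
        row = res.as_row()
        assert set(row) == {"trait", "pct_block", "F_B", "P_B", "H2_pct",
                            "F_L", "P_L", "mean"}
        assert 0.0 <= row["P_L"] <= 1.0 and row["F_L"] >= 0.0
        assert "demo" in res.summary()
        assert len(res.line_means()) == 20

    def test_deterministic_line_effect_gives_tiny_p(self):
        df = pd.DataFrame({
            "trait": np.repeat([0.0, 1.0, 2.0, 3.0], 4)
            + np.tile([0, 1e-6, -1e-6, 0], 4),
            "line": np.repeat(list("abcd"), 4),
            "block": np.tile(["b1", "b2"], 8),
        })
        res = decompose_trait(df, "trait")
        assert res.line.P < 1e-12
        assert res.H2 > 0.99

    def test_null_p_values_approximately_uniform(self, rng):
        vals, lines, blocks = simulate_traits(
            100, 10, 5, 0.0, 0.0, 1.0, n_traits=200, rng=rng)
        ps = []
        for v in vals:
            ps.append(heritability(
                block_partition(v, blocks).residuals, lines).P)
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.04)

    def test_decompose_table_stars_significant_traits(self, rng):
        vals, lines, blocks = simulate_traits(
            50, 10, 5, 0.4, 0.02, 0.58, n_traits=2, rng=rng)
        df = pd.DataFrame({"t1": vals[0], "t2": rng.normal(size=vals[0].size),
                           "line": lines, "block": blocks})
        out = decompose_table(df, ["t1", "t2"], alpha=0.05, n_tests=25)
        assert out.loc["t1", "sig"] == "*"
        assert list(out.columns[:7]) == [
            "pct_block", "F_B", "P_B", "H2_pct", "F_L", "P_L", "mean"]

    def test_arcsin_switch_changes_scale_not_design(self, small_panel):
        from ethoscan import transition_table

        df = transition_table(small_panel.observations).reset_index()
        raw = decompose_trait(df, "E_E")
        tr = decompose_trait(df, "E_E", arcsin=True)
        assert raw.trait_mean != pytest.approx(tr.trait_mean)
        assert raw.line.df_line == tr.line.df_line


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 25, 0.002), (0.05, 1, 0.05), (0.01, 100, 0.0001)],
    )
    def test_critical_values(self, alpha, n, expected):
        assert bonferroni(alpha, n) == pytest.approx(expected)

    def test_genomewide_threshold_to_printed_precision(self):
        crit = bonferroni(0.05, 2_400_000)
        assert f"{crit:.3g}" == "2.08e-08"

    @pytest.mark.parametrize("alpha,n", [(0.0, 10), (1.0, 10), (0.05, 0)])
    def test_invalid_inputs(self, alpha, n):
        with pytest.raises(ValueError):
            bonferroni(alpha, n)


class TestLineMeanCorrelation:
    def test_identical_vectors(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        r, p, n = line_mean_correlation(a, a)
        assert r == pytest.approx(1.0) and n == 4

    def test_orthogonal_vectors(self):
        a = pd.Series([1.0, -1.0, 1.0, -1.0], index=list("abcd"))
        b = pd.Series([1.0, 1.0, -1.0, -1.0], index=list("abcd"))
        r, _, _ = line_mean_correlation(a, b)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_shared_lines(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            line_mean_correlation(a, a)

    def test_recovers_generating_negative_relationship(self, rng):
        p_ea = pd.Series(rng.uniform(0, 0.1, 200),
                         index=[f"L{i}" for i in range(200)])
        noise = rng.normal(0, 0.05, 200)
        dur = pd.Series(20.0 - 40.0 * p_ea.to_numpy() + noise,
                        index=p_ea.index)
        r, p, n = line_mean_correlation(dur, p_ea)
        assert r < -0.8 and p < 1e-6 and n == 200

    def test_duration_correlation_on_simulated_panel(self, default_panel):
        dur = copulation_duration_means(default_panel.durations)
        ea = pd.Series(default_panel.truth.line_ea_rate,
                       index=default_panel.truth.line_ids)
        r, p, n = line_mean_correlation(dur["mean"], ea)
        assert r < 0  # generator ties duration negatively to E->A
        assert n == len(dur)


class TestCopulationDuration:
    def test_short_copulations_filtered(self):
        events = pd.DataFrame({"line": ["x"] * 3,
                               "duration": [4.9, 10.0, 20.0]})
        out = copulation_duration_means(events)
        assert out.loc["x", "mean"] == pytest.approx(15.0)
        assert out.loc["x", "n"] == 2

    def test_line_with_no_surviving_events_excluded(self):
        events = pd.DataFrame({"line": ["x", "x", "y"],
                               "duration": [1.0, 2.0, 30.0]})
        with pytest.warns(UserWarning, match="x"):
            out = copulation_duration_means(events)
        assert list(out.index) == ["y"]

    def test_negative_durations_rejected(self):
        events = pd.DataFrame({"line": ["x"], "duration": [-1.0]})
        with pytest.raises(ValueError):
            copulation_duration_means(events)

    def test_panel_durations_have_enough_pairs(self, default_panel):
        out = copulation_duration_means(default_panel.durations)
        assert (out["n"] >= 10).all()
        assert len(out) == 35
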