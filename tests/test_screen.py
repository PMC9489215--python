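"""Parameter sampler, two-step screen primitives and statistics layer."""

import numpy as np
import pandas as pd
import pytest

import oscreen as oc
from oscreen.screen import (
    SamplerConfig,
    category_analysis,
    fit_exponential_mean,
    sample_parameter_set,
    search_oscillatory_sets,
    spearman_correlation,
    wilcoxon_rank_sum_one_tailed,
)


class TestSampler:
    def test_deterministic_under_seed(self, repressilator):
        cfg = SamplerConfig()
        a = sample_parameter_set(cfg, repressilator, np.random.default_rng(5))
        b = sample_parameter_set(cfg, repressilator, np.random.default_rng(5))
        assert np.array_equal(a.K, b.K) and np.array_equal(a.r, b.r)

    def test_log_uniform_median(self, repressilator):
        cfg = SamplerConfig()
        rng = np.random.default_rng(0)
        rs = np.array(
            [sample_parameter_set(cfg, repressilator, rng).r[0] for _ in range(10_000)]
        )
        # geometric mean of the bounds of the log-uniform r range
        assert np.median(rs) == pytest.approx(np.sqrt(0.01 * 1.0), rel=0.05)

    def test_delta_zero_iff_activated(self, activator_inhibitor, repressilator):
        rng = np.random.default_rng(1)
        p = sample_parameter_set(SamplerConfig(), activator_inhibitor, rng)
        assert p.delta[0] == 0.0  # A activates itself
        assert p.delta[1] == 0.0  # B activated by A
        q = sample_parameter_set(SamplerConfig(), repressilator, rng)
        assert np.all(q.delta > 0)  # nobody has an activator

    def test_ranges_respected(self, repressilator):
        rng = np.random.default_rng(2)
        cfg = SamplerConfig()
        for _ in range(100):
            p = sample_parameter_set(cfg, repressilator, rng)
            for i in range(3):
                for j in range(3):
                    if repressilator.sign(i, j) != 0:
                        assert cfg.K_range[0] <= p.K[i, j] <= cfg.K_range[1]
            assert np.all((p.r >= cfg.r_range[0]) & (p.r <= cfg.r_range[1]))

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            SamplerConfig(v_range=(10.0, 0.1))

    def test_thresholds(self, repressilator, activator_inhibitor):
        cfg = SamplerConfig()
        assert cfg.threshold_for(activator_inhibitor, 10_000) == 80
        assert cfg.threshold_for(repressilator, 10_000) == 10
        # proportional scaling, rounded up
        assert cfg.threshold_for(activator_inhibitor, 500) == 4
        assert cfg.threshold_for(repressilator, 500) == 1

    def test_basal_is_much_smaller_than_production(self, repressilator):
        p = sample_parameter_set(
            SamplerConfig(), repressilator, np.random.default_rng(3)
        )
        p.validate_basal()  # does not raise at the default ranges


class TestSearch:
    def test_finds_oscillatory_sets_and_they_reproduce(self, repressilator):
        sets, drawn = search_oscillatory_sets(
            repressilator, SamplerConfig(), 5, seed=17, max_draws=2000
        )
        assert len(sets) == 5 and drawn <= 2000
        for s in sets[:2]:
            traj = oc.simulate_deterministic(repressilator, s.params)
            feats = oc.detect_oscillation(traj)
            assert feats.oscillatory
            assert feats.period_T == pytest.approx(s.period_T, rel=0.02)
            assert feats.amplitude == pytest.approx(s.amplitude, rel=0.05)

    def test_search_is_deterministic(self, repressilator):
        a, _ = search_oscillatory_sets(repressilator, SamplerConfig(), 3, seed=23, max_draws=2000)
        b, _ = search_oscillatory_sets(repressilator, SamplerConfig(), 3, seed=23, max_draws=2000)
        assert len(a) == len(b)
        for s, t in zip(a, b):
            assert np.array_equal(s.params.K, t.params.K)
            assert s.period_T == t.period_T

    def test_no_negative_feedback_never_oscillates(self):
        # mutual activation with autoregulation: no negative feedback loop
        t = oc.parse_topology("A A +1\nA B +1\nB A +1\nB B +1")
        assert not oc.contains_negative_feedback(t)
        sets, _ = search_oscillatory_sets(t, SamplerConfig(), 1, seed=3, max_draws=1500)
        assert sets == []


class TestStatistics:
    def test_exponential_mean(self):
        assert fit_exponential_mean([5.0, 5.0, 5.0]) == 5.0
        assert fit_exponential_mean([7.0]) == 7.0
        rng = np.random.default_rng(0)
        draws = rng.exponential(7.0, 100_000)
        assert fit_exponential_mean(draws) == pytest.approx(7.0, rel=0.01)
        with pytest.raises(ValueError, match="positive"):
            fit_exponential_mean([1.0, -2.0])

    def test_spearman(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_correlation(x, -x**3) == pytest.approx(-1.0)
        # hand-computed: 1 - 6 * sum(d^2) / (n (n^2-1)) with d = (0,1,1,0)
        assert spearman_correlation(
            [1, 2, 3, 4], [1, 3, 2, 4]
        ) == pytest.approx(0.8)
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_wilcoxon_exact_small_sample(self):
        # a=(1,2), b=(3,4): only 1 of C(4,2)=6 rank splits is as extreme
        assert wilcoxon_rank_sum_one_tailed(
            [1.0, 2.0], [3.0, 4.0], "a<b"
        ) == pytest.approx(1.0 / 6.0)

    def test_wilcoxon_identical_samples(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        p = wilcoxon_rank_sum_one_tailed(x, x.copy(), "a>b")
        assert 0.45 < p < 0.55

    def test_wilcoxon_separated_samples(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        assert wilcoxon_rank_sum_one_tailed(a, b, "a>b") < 1e-4
        assert wilcoxon_rank_sum_one_tailed(a, b, "a<b") > 0.999

    def test_wilcoxon_input_validation(self):
        with pytest.raises(ValueError, match="direction"):
            wilcoxon_rank_sum_one_tailed([1], [2], "sideways")
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum_one_tailed([], [2], "a>b")


class TestCategoryAnalysis:
    def make_table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        centers = {"C1": 20.0, "C2": 15.0, "C3": 10.0, "C4": 6.0, "C5": 3.0}
        tid = 0
        for cat, mu in centers.items():
            for _ in range(15):
                score = mu * rng.lognormal(0, 0.15)
                rows.append(
                    {
                        "topology_id": tid,
                        "category": cat,
                        "score": score,
                        "T_opt": score * 2 + rng.normal(0, 0.5),
                        "A_opt": 10 + rng.normal(0, 3),
                    }
                )
                tid += 1
        for _ in range(10):  # combined category between C1 and C3
            score = 14.0 * rng.lognormal(0, 0.15)
            rows.append(
                {
                    "topology_id": tid,
                    "category": "C13",
                    "score": score,
                    "T_opt": score * 2,
                    "A_opt": 10.0,
                }
            )
            tid += 1
        return pd.DataFrame(rows)

    def test_ordering_detected(self):
        report = category_analysis(self.make_table(), "extrinsic")
        assert report["skipped_categories"] == []
        for entry in report["adjacent_tests"]:
            assert entry["score"]["direction"] == "a>b"
            assert entry["score"]["p_value"] < 0.05

    def test_spearman_reported(self):
        report = category_analysis(self.make_table(), "extrinsic")
        assert report["spearman_score_vs_T_opt"] > 0.9
        assert abs(report["spearman_score_vs_A_opt"]) < 0.5

    def test_combined_category_intermediate(self):
        report = category_analysis(self.make_table(), "extrinsic")
        assert report["combined_categories"]["C13"]["intermediate"]

    def test_small_categories_flagged(self):
        table = self.make_table()
        table = table[~((table.category == "C4") & (table.index % 15 < 13))]
        report = category_analysis(table, "extrinsic")
        assert "C4" in report["skipped_categories"]


class TestFixtureLibrary:
    def test_fixture_motifs_and_categories(self, fixtures):
        t, _ = fixtures["repressilator"]
        assert set(oc.find_core_motifs(t)) == {4}
        t, _ = fixtures["activator_inhibitor"]
        assert oc.assign_category(t).label == "C3"
        for k in (1, 2, 3, 4, 5):
            t, _ = fixtures[f"C{k}"]
            assert oc.assign_category(t).label == f"C{k}"

    def test_every_fixture_parameter_set_oscillates(self, fixtures):
        for name, (t, p) in fixtures.items():
            traj = oc.simulate_deterministic(t, p)
            assert oc.detect_oscillation(traj).oscillatory, name

    def test_fixtures_have_negative_feedback(self, fixtures):
        for name, (t, _p) in fixtures.items():
            assert oc.contains_negative_feedback(t), name
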