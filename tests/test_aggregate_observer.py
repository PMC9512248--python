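"""Aggregate observer: proportions, confusion, bias test, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shadowedge.aggregate_observer import (
    ao_confusion,
    bias_test,
    bootstrap_compare,
    build_ao,
    model_human_correlation,
    observer_inclusion,
    responses_from_table,
)
from shadowedge.synthetic_data import simulate_observers


def _ao(pi, labels, n_observers=10):
    from shadowedge.aggregate_observer import AggregateObserver

    return AggregateObserver(
        pi=np.asarray(pi, float),
        labels=np.asarray(labels, int),
        n_observers=n_observers,
    )


class TestBuildAO:
    def test_unanimous_occlusion_responses(self):
        R = np.ones((7, 5), dtype=int)
        ao = build_ao(R, labels=[1, 1, 0, 0, 1])
        np.testing.assert_array_equal(ao.pi, 1.0)

    def test_single_observer_proportions_are_responses(self, rng):
        R = rng.integers(0, 2, size=(1, 12))
        ao = build_ao(R, labels=rng.integers(0, 2, size=12))
        np.testing.assert_array_equal(ao.pi, R[0])

    def test_simulated_observers_converge(self):
        probs = np.linspace(0.05, 0.95, 25)
        obs = simulate_observers(probs, 10000, seed=3)
        ao = build_ao(obs.responses, labels=np.zeros(25, int))
        assert np.max(np.abs(ao.pi - probs)) < 0.02

    def test_missing_responses_rejected(self):
        R = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            build_ao(R, labels=[0, 1])


class TestConfusion:
    def test_exact_half_counts_as_occlusion(self):
        ao = _ao([0.5, 0.49], labels=[1, 1])
        cm = ao_confusion(ao)
        # pi = 0.5 -> predicted occlusion (correct); 0.49 -> shadow (error)
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1

    def test_perfect_observers_diagonal(self):
        ao = _ao([0.9, 0.8, 0.1, 0.2], labels=[1, 1, 0, 0])
        cm = ao_confusion(ao)
        assert cm.counts[0, 1] == 0 and cm.counts[1, 0] == 0

    def test_matches_brute_force_tabulation(self, rng):
        pi = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        cm = ao_confusion(_ao(pi, labels))
        pred = (pi >= 0.5).astype(int)
        brute = np.zeros((2, 2), int)
        for actual, p in zip(labels, pred):
            brute[1 - actual, 1 - p] += 1
        np.testing.assert_array_equal(cm.counts, brute)

    def test_row_sums_equal_category_counts(self, rng):
        labels = rng.integers(0, 2, size=77)
        cm = ao_confusion(_ao(rng.random(77), labels))
        assert cm.counts[0].sum() == (labels == 1).sum()
        assert cm.counts[1].sum() == (labels == 0).sum()


class TestBiasTest:
    @pytest.mark.parametrize(
        "errors,expected_p",
        [((12, 19), 0.281), ((12, 24), 0.065), ((31, 27), 0.694)],
    )
    def test_known_error_splits(self, errors, expected_p):
        """Spot checks of the exact two-sided p at 3-decimal precision."""
        assert bias_test(errors).p == pytest.approx(expected_p, abs=5e-4)

    def test_equal_split_clamped_to_one(self):
        assert bias_test((9, 9)).p == 1.0

    def test_no_errors_undefined(self):
        res = bias_test((0, 0))
        assert res.p == 1.0 and not res.defined

    def test_matches_pmf_summation_oracle(self):
        """For every split with N <= 60 the p-value equals brute-force
        summation of the Binomial(N, 1/2) pmf over the rejection tails."""
        for n in range(1, 61):
            for e1 in range(0, n + 1):
                e2 = n - e1
                k = min(e1, e2)
                tail = sum(stats.binom.pmf(j, n, 0.5) for j in range(k + 1))
                expected = min(1.0, 2.0 * tail)
                assert bias_test((e1, e2)).p == pytest.approx(
                    expected, abs=1e-10
                )


class TestCorrelations:
    def test_perfect_agreement(self, rng):
        pi = rng.random(50)
        ao = _ao(pi, rng.integers(0, 2, 50))
        assert model_human_correlation(ao, pi) == pytest.approx(1.0)

    def test_perfect_disagreement(self, rng):
        pi = rng.random(50)
        ao = _ao(pi, rng.integers(0, 2, 50))
        assert model_human_correlation(ao, 1 - pi) == pytest.approx(-1.0)

    def test_equals_rank_pearson_oracle(self, rng):
        """Spearman rho equals the Pearson correlation of mid-ranks
        computed with an independent ranking routine."""
        for _ in range(10):
            pi = np.round(rng.random(60), 1)  # ties on purpose
            p = np.round(rng.random(60), 1)
            ao = _ao(pi, rng.integers(0, 2, 60))
            rho = model_human_correlation(ao, p)
            oracle = stats.pearsonr(
                stats.rankdata(pi), stats.rankdata(p)
            ).statistic
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self, rng):
        ao = _ao(np.full(30, 0.5), rng.integers(0, 2, 30))
        with pytest.raises(ValueError):
            model_human_correlation(ao, rng.random(30))


class TestBootstrapCompare:
    def test_identical_models_centered_on_zero(self, rng):
        pi = rng.random(100)
        ao = _ao(pi, rng.integers(0, 2, 100))
        preds = rng.random(100)
        out = bootstrap_compare(ao, preds, preds, n_boot=200, seed=0)
        assert out["median_delta_rho"] == 0.0
        assert out["ci_low"] <= 0.0 <= out["ci_high"]

    def test_perfect_vs_noise_excludes_zero(self, rng):
        pi = rng.random(200)
        ao = _ao(pi, rng.integers(0, 2, 200))
        noise = rng.random(200)
        out = bootstrap_compare(ao, pi, noise, n_boot=300, seed=1)
        assert out["ci_low"] > 0.0
        assert out["median_delta_rho"] > 0.5

    def test_seeded_reproducibility(self, rng):
        pi = rng.random(60)
        ao = _ao(pi, rng.integers(0, 2, 60))
        a = rng.random(60)
        b = rng.random(60)
        o1 = bootstrap_compare(ao, a, b, n_boot=100, seed=7)
        o2 = bootstrap_compare(ao, a, b, n_boot=100, seed=7)
        assert o1 == o2

    def test_ci_width_shrinks_with_more_images(self, rng):
        widths = {}
        for n in (50, 400):
            pi = rng.random(n)
            ao = _ao(pi, rng.integers(0, 2, n))
            a = np.clip(pi + 0.3 * rng.standard_normal(n), 0, 1)
            b = np.clip(pi + 0.3 * rng.standard_normal(n), 0, 1)
            out = bootstrap_compare(ao, a, b, n_boot=300, seed=2)
            widths[n] = out["ci_high"] - out["ci_low"]
        assert widths[400] < widths[50]


class TestResponseTable:
    def test_round_trip_from_long_table(self, rng):
        n_obs, n_img = 6, 10
        R = rng.integers(0, 2, size=(n_obs, n_img))
        labels = rng.integers(0, 2, size=n_img)
        rows = []
        for o in range(n_obs):
            for i in range(n_img):
                rows.append(
                    {
                        "observer_id": f"obs{o}",
                        "image_id": f"img{i:02d}",
                        "response": R[o, i],
                        "true_label": int(labels[i]),
                    }
                )
        table = pd.DataFrame(rows)
        R2, labels2 = responses_from_table(table)
        np.testing.assert_array_equal(R2, R)
        np.testing.assert_array_equal(labels2, labels)

    def test_inclusion_threshold(self):
        assert observer_inclusion(114)
        assert not observer_inclusion(113)
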