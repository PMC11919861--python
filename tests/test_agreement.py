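"""Quality/agreement metrics and cohort nonparametric statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from vrdistress import agreement as agr


class TestSnr:
    def test_zero_mean_square_wave(self):
        assert agr.snr_db([1, -1, 1, -1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        x = [10, 10, 10, 14]
        expected = 10 * np.log10(np.mean(np.square(x)) / np.var(x))
        assert agr.snr_db(x) == pytest.approx(expected)
        assert agr.snr_db(x) == pytest.approx(10 * np.log10(124 / 3))

    def test_constant_series_infinite_with_warning(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert agr.snr_db([60, 60, 60]) == np.inf

    def test_scale_invariance_and_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(70, 5, size=50)
            s = agr.snr_db(x)
            assert agr.snr_db(3.7 * x) == pytest.approx(s)
            identity = 10 * np.log10(1 + x.mean() ** 2 / np.var(x))
            assert s == pytest.approx(identity)


class TestCorrelations:
    def test_affine_relation(self):
        x = np.arange(10.0)
        r, rho = agr.correlations(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        r, rho = agr.correlations(x, x**3)
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_rank_formula_by_hand(self):
        _, rho = agr.correlations([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            agr.correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestErrorMetrics:
    def test_identical_series(self):
        assert agr.error_metrics([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)

    def test_hand_computed(self):
        ref = np.zeros(3)
        mae, rmse = agr.error_metrics(ref, [1, -1, 3])
        assert mae == pytest.approx(5 / 3)
        assert rmse == pytest.approx(np.sqrt(11 / 3))

    def test_constant_offset_equality_case(self):
        ref = np.arange(5.0)
        mae, rmse = agr.error_metrics(ref, ref + 4.0)
        assert mae == rmse == pytest.approx(4.0)

    def test_bruteforce_oracle_and_ordering(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            ref = rng.normal(size=20)
            test = rng.normal(size=20)
            mae, rmse = agr.error_metrics(ref, test)
            d = [t - r for r, t in zip(ref, test)]
            assert mae == pytest.approx(sum(abs(v) for v in d) / len(d))
            assert rmse == pytest.approx(
                (sum(v * v for v in d) / len(d)) ** 0.5
            )
            assert rmse >= mae - 1e-12


class TestBlandAltman:
    def test_identical_series(self):
        bias, lo, hi, _ = agr.bland_altman([1, 2, 3], [1, 2, 3])
        assert bias == lo == hi == 0.0

    def test_constant_offset_zero_spread(self):
        bias, lo, hi, _ = agr.bland_altman([1, 2, 3], [6, 7, 8])
        assert bias == pytest.approx(5.0)
        assert lo == hi == pytest.approx(5.0)

    def test_hand_computed_limits(self):
        bias, lo, hi, pts = agr.bland_altman([0.0, 0.0], [0.0, 2.0])
        sd = np.sqrt(2.0)  # sample sd of [0, 2]
        assert bias == pytest.approx(1.0)
        assert lo == pytest.approx(1.0 - 1.96 * sd)
        assert hi == pytest.approx(1.0 + 1.96 * sd)
        assert pts.shape == (2, 2)
        assert lo <= bias <= hi


class TestWilcoxon:
    def test_all_positive_differences(self):
        w, p = agr.wilcoxon_signed_rank([2, 3, 4], [1, 1, 1])
        assert w == 0.0
        assert p == pytest.approx(0.25)

    def test_mixed_signs_by_enumeration(self):
        w, p = agr.wilcoxon_signed_rank([1, -2, 3], [0, 0, 0])
        assert w == 2.0
        assert p == pytest.approx(0.75)

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError):
            agr.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(2)
        for n in range(3, 11):
            d = rng.normal(size=n)
            d[d == 0] = 0.5
            w, p = agr.wilcoxon_signed_rank(d, np.zeros(n))
            ranks = stats.rankdata(np.abs(d))
            stats_all = []
            for signs in itertools.product([1, -1], repeat=n):
                wm = sum(r for r, s in zip(ranks, signs) if s < 0)
                stats_all.append(min(wm, ranks.sum() - wm))
            w_obs = min(
                ranks[d < 0].sum(), ranks[d > 0].sum()
            )
            # two-sided: doubled lower tail of the W- distribution
            wm_all = [
                sum(r for r, s in zip(ranks, signs) if s < 0)
                for signs in itertools.product([1, -1], repeat=n)
            ]
            p_exact = min(
                1.0,
                2.0 * sum(1 for v in wm_all if v <= w_obs) / len(wm_all),
            )
            assert w == pytest.approx(w_obs)
            assert p == pytest.approx(p_exact)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        w, p = agr.wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="exact")
        assert w == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.3, 1.0, size=60)
        b = np.zeros(60)
        w, p = agr.wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, mode="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestCliffsDelta:
    def test_identical_multisets(self):
        delta, mag = agr.cliffs_delta([1, 2, 2, 3], [3, 2, 1, 2])
        assert delta == 0.0
        assert mag == "negligible"

    def test_complete_separation(self):
        delta, mag = agr.cliffs_delta([1, 2], [3, 4])
        assert delta == -1.0
        assert mag == "large"

    def test_interleaved_groups(self):
        delta, mag = agr.cliffs_delta([1, 3], [2, 4])
        assert delta == -0.5
        assert mag == "large"

    @pytest.mark.parametrize(
        "delta,label",
        [(0.1, "negligible"), (0.2, "small"), (0.4, "medium"),
         (0.474, "large"), (-0.6, "large")],
    )
    def test_magnitude_labels(self, delta, label):
        # construct groups realizing the requested delta on 1000 pairs
        n = 1000
        k = int(round((delta + 1) / 2 * n))  # wins among n cross pairs
        a = np.zeros(1)
        b = np.concatenate([-np.ones(k), np.ones(n - k)])
        got, mag = agr.cliffs_delta(a, b)
        assert got == pytest.approx(delta, abs=1e-9)
        assert mag == label

    def test_antisymmetry_and_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.integers(0, 10, size=rng.integers(1, 12))
            b = rng.integers(0, 10, size=rng.integers(1, 12))
            delta, _ = agr.cliffs_delta(a, b)
            wins = sum(1 for x in a for y in b if x > y)
            losses = sum(1 for x in a for y in b if x < y)
            assert delta == pytest.approx(
                (wins - losses) / (len(a) * len(b))
            )
            rev, _ = agr.cliffs_delta(b, a)
            assert rev == pytest.approx(-delta)
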