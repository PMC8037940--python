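import numpy as np
import pytest

from fluoropanel import (
    compare_roc_bootstrap,
    delong_test,
    mann_whitney_auc,
    min_detectable_auc,
    roc_auc,
    roc_power,
)
from fluoropanel.roc import roc_curve_points


def pair_counting_auc(scores, outcome):
    """Brute-force oracle: concordant pairs + half the ties, over all pairs."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    cases = scores[outcome]
    controls = scores[~outcome]
    wins = ties = 0
    for c in cases:
        for k in controls:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def random_fixture(rng, max_n=50):
    n = int(rng.integers(4, max_n + 1))
    scores = rng.integers(0, 3, size=n)
    outcome = np.zeros(n, dtype=bool)
    outcome[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
    return scores, outcome


class TestMannWhitneyAuc:
    def test_constant_score_gives_half(self):
        assert mann_whitney_auc([1] * 10, [True] * 3 + [False] * 7) == 0.5

    def test_perfect_separation_gives_one(self):
        scores = [2, 2, 2, 0, 0, 0]
        outcome = [True, True, True, False, False, False]
        assert mann_whitney_auc(scores, outcome) == 1.0

    def test_twelve_sample_toy_matches_pair_counting(self):
        scores = [0, 1, 2, 0, 1, 2, 1, 0, 2, 1, 0, 0]
        outcome = [True] * 5 + [False] * 7
        assert mann_whitney_auc(scores, outcome) == pytest.approx(
            pair_counting_auc(scores, outcome), abs=1e-15
        )

    def test_matches_pair_counting_on_random_fixtures(self, rng):
        for _ in range(200):
            scores, outcome = random_fixture(rng)
            assert mann_whitney_auc(scores, outcome) == pytest.approx(
                pair_counting_auc(scores, outcome), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            scores, outcome = random_fixture(rng)
            assert mann_whitney_auc(scores, outcome) == pytest.approx(
                roc_auc_score(outcome, scores), abs=1e-12
            )

    def test_score_negation_complements_auc(self, rng):
        for _ in range(50):
            scores, outcome = random_fixture(rng)
            total = mann_whitney_auc(scores, outcome) + mann_whitney_auc(
                -scores, outcome
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_class_raises_naming_the_class(self):
        with pytest.raises(ValueError, match="positive"):
            mann_whitney_auc([1, 2], [False, False])
        with pytest.raises(ValueError, match="negative"):
            mann_whitney_auc([1, 2], [True, True])


class TestRocCurve:
    def test_curve_endpoints_and_monotonicity(self, rng):
        for _ in range(50):
            scores, outcome = random_fixture(rng)
            points = roc_curve_points(scores, outcome)
            assert tuple(points[0]) == (0.0, 0.0)
            assert tuple(points[-1]) == (1.0, 1.0)
            assert (np.diff(points[:, 0]) >= 0).all()
            assert (np.diff(points[:, 1]) >= 0).all()

    def test_trapezoid_area_equals_mann_whitney(self, rng):
        for _ in range(100):
            scores, outcome = random_fixture(rng)
            points = roc_curve_points(scores, outcome)
            area = np.trapezoid(points[:, 1], points[:, 0])
            assert area == pytest.approx(
                mann_whitney_auc(scores, outcome), abs=1e-12
            )

    def test_roc_auc_ci_brackets_estimate(self, rng):
        scores = rng.integers(0, 3, size=60)
        outcome = rng.random(60) < 0.4
        result = roc_auc(scores, outcome, model_id="toy")
        assert result.ci[0] <= result.auc <= result.ci[1]
        assert result.n_pos + result.n_neg == 60


class TestBootstrapComparison:
    def test_self_comparison_is_null(self, rng):
        scores = rng.integers(0, 3, size=40)
        outcome = rng.random(40) < 0.5
        comparison = compare_roc_bootstrap(scores, scores, outcome, n_boot=50, seed=1)
        assert comparison.delta == 0.0
        assert comparison.wald_p == 1.0

    def test_fixed_seed_is_reproducible(self, rng):
        a = rng.integers(0, 3, size=100)
        b = rng.integers(0, 3, size=100)
        y = rng.random(100) < 0.3
        c1 = compare_roc_bootstrap(a, b, y, n_boot=100, seed=42)
        c2 = compare_roc_bootstrap(a, b, y, n_boot=100, seed=42)
        assert c1 == c2

    def test_ci_contains_full_sample_delta(self, rng):
        a = rng.integers(0, 3, size=200)
        b = rng.integers(0, 3, size=200)
        y = rng.random(200) < 0.3
        c = compare_roc_bootstrap(a, b, y, n_boot=200, seed=7)
        assert c.ci[0] <= c.delta <= c.ci[1]

    def test_planted_informative_variant_detected(self):
        # model B adds an outcome-informative variant to model A at trial scale
        rng = np.random.default_rng(2024)
        n = 888
        informative = rng.binomial(2, 0.3, size=n)
        noise = rng.binomial(2, 0.01, size=n)
        from scipy.special import expit, logit

        outcome = rng.random(n) < expit(logit(0.15) + informative * np.log(3.0))
        score_a = noise
        score_b = noise + informative
        c = compare_roc_bootstrap(
            score_a, score_b, outcome, n_boot=500, seed=5, model_a="a", model_b="b"
        )
        assert c.delta > 0
        assert c.wald_p < 0.05
        # analytic cross-check agrees
        delta_delong, p_delong = delong_test(score_a, score_b, outcome)
        assert delta_delong == pytest.approx(c.delta, abs=1e-12)
        assert p_delong < 0.05

    def test_ci_endpoints_stable_across_seeds(self):
        rng = np.random.default_rng(11)
        n = 888
        a = rng.binomial(2, 0.2, size=n)
        b = rng.binomial(2, 0.3, size=n)
        y = rng.random(n) < 0.2
        cis = [
            compare_roc_bootstrap(a, b, y, n_boot=1000, seed=s).ci for s in (1, 2, 3)
        ]
        lows, highs = zip(*cis)
        assert max(lows) - min(lows) < 0.01
        assert max(highs) - min(highs) < 0.01

    def test_stratified_resampling_never_degenerates(self, rng):
        a = rng.integers(0, 3, size=50)
        b = rng.integers(0, 3, size=50)
        y = np.zeros(50, dtype=bool)
        y[:2] = True  # very rare outcome
        c = compare_roc_bootstrap(a, b, y, n_boot=200, seed=3, stratified=True)
        assert c.n_redraws == 0

    def test_too_few_iterations_rejected(self, rng):
        with pytest.raises(ValueError, match="n_boot"):
            compare_roc_bootstrap([1, 0], [0, 1], [True, False], n_boot=1)


class TestPower:
    def test_null_limit_tends_to_alpha(self):
        result = roc_power(0.5 + 1e-9, 50, 50, alpha=0.05)
        assert result.power == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_auc_and_class_size(self):
        grid = np.linspace(0.55, 0.95, 9)
        powers = [roc_power(a, 20, 200).power for a in grid]
        assert all(b >= a for a, b in zip(powers, powers[1:]))
        sizes = [2, 4, 8, 16, 32]
        powers_n = [roc_power(0.8, n, 884).power for n in sizes]
        assert all(b >= a for a, b in zip(powers_n, powers_n[1:]))

    def test_invalid_alternatives_rejected(self):
        with pytest.raises(ValueError):
            roc_power(0.5, 10, 10)
        with pytest.raises(ValueError):
            roc_power(0.4, 10, 10)

    def test_rare_outcome_power_high_at_strong_auc(self):
        # 4 cases vs 884 controls: strong separation is still detectable
        assert roc_power(0.95, 4, 884).power > 0.80

    def test_min_detectable_auc_inverts_power(self):
        auc = min_detectable_auc(30, 300, power=0.8)
        assert roc_power(auc, 30, 300).power == pytest.approx(0.8, abs=1e-6)

    def test_common_outcome_detects_modest_auc(self):
        # roughly a quarter of 888 patients with a grade >= 3 event: the
        # study is powered for AUCs only modestly above chance
        auc = min_detectable_auc(222, 666, power=0.8)
        assert 0.5 < auc < 0.57
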