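"""Rasch probability model, calibration and person estimation."""

import numpy as np
import pytest

from macetools import (
    ItemBank,
    estimate_item_difficulties,
    estimate_person_theta,
    icc_probability,
    item_information,
    theta_by_raw_score,
)
from macetools import test_information as information_at  # avoid pytest collection
from macetools.rasch import ResponseMatrix, _pattern_groups, conditional_log_likelihood

from conftest import make_rasch_data


class TestIcc:
    def test_half_probability_at_item_location(self):
        assert icc_probability(0.0, 0.0) == pytest.approx(0.5)
        for b in (-3.1, -0.4, 0.0, 2.7):
            assert icc_probability(b, b) == pytest.approx(0.5)

    def test_logistic_evaluation(self):
        # person just above the parental-physical threshold vs the easiest item
        assert icc_probability(1.06, -3.27) == pytest.approx(0.987, abs=5e-4)

    def test_monotone_in_theta_and_b(self):
        thetas = np.linspace(-4, 4, 41)
        p = icc_probability(thetas, 0.3)
        assert np.all(np.diff(p) > 0)
        bs = np.linspace(-4, 4, 41)
        p = icc_probability(0.3, bs)
        assert np.all(np.diff(p) < 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            icc_probability(np.nan, 0.0)
        with pytest.raises(ValueError):
            icc_probability(0.0, np.inf)


class TestInformation:
    def test_maximum_quarter_at_item_location(self):
        assert item_information(1.3, 1.3) == pytest.approx(0.25)
        assert item_information(0.0, 8.0) < 1e-3  # vanishes far from the item

    def test_test_information_is_sum(self, defn):
        bank = defn.subscales["EN"].bank
        ti = information_at(0.0, bank)
        parts = [item_information(0.0, b) for b in bank.difficulty]
        assert ti == pytest.approx(sum(parts), rel=1e-12)

    def test_matches_negative_second_derivative_of_loglik(self, rng, defn):
        # TI(theta) == -d2/dtheta2 log L(theta | x) for any response vector,
        # since the Bernoulli curvature does not depend on x
        bank = defn.subscales["SA"].bank
        h = 1e-4
        for theta in rng.uniform(-3, 3, 20):
            x = rng.integers(0, 2, bank.n_items)

            def ll(t):
                p = icc_probability(t, bank.difficulty)
                return float(np.sum(x * np.log(p) + (1 - x) * np.log(1 - p)))

            num = -(ll(theta + h) - 2 * ll(theta) + ll(theta - h)) / h**2
            assert information_at(theta, bank) == pytest.approx(num, rel=1e-3)


class TestPersonTheta:
    def test_reproduces_published_threshold_logits(self, defn):
        # every subscale's exposure-threshold logit to 2 dp
        for sub in defn.subscales.values():
            est = estimate_person_theta(sub.threshold_raw, sub.bank)
            assert round(est.theta, 2) == pytest.approx(sub.threshold_logit)

    @pytest.mark.parametrize("d", [0.25, 1.0, 2.5])
    def test_symmetric_pair_gives_zero(self, d):
        bank = ItemBank(["hi", "lo"], [d, -d])
        assert estimate_person_theta(1, bank).theta == pytest.approx(0.0, abs=1e-7)

    def test_strictly_monotone_in_raw_score(self, defn):
        for sub in defn.subscales.values():
            thetas = [estimate_person_theta(r, sub.bank).theta
                      for r in range(sub.n_items + 1)]
            assert np.all(np.diff(thetas) > 0)

    def test_se_is_reciprocal_root_information(self, defn):
        bank = defn.subscales["PeerE"].bank
        est = estimate_person_theta(3, bank)
        assert est.theta_se == pytest.approx(
            1.0 / np.sqrt(information_at(est.theta, bank)))

    def test_extreme_scores_use_anchors_when_present(self, defn):
        sub = defn.subscales["EN"]
        lo = estimate_person_theta(0, sub.bank)
        hi = estimate_person_theta(sub.n_items, sub.bank)
        assert (lo.theta, hi.theta) == sub.anchors
        assert lo.extreme and lo.convention == "anchor"

    def test_extreme_scores_adjusted_without_anchors(self):
        bank = ItemBank(list("abc"), [-1.0, 0.0, 1.0])
        lo = estimate_person_theta(0, bank)
        hi = estimate_person_theta(3, bank)
        assert lo.convention == "adjusted" and hi.convention == "adjusted"
        # solves sum P = 0.25 (resp. k - 0.25)
        assert icc_probability(lo.theta, bank.difficulty).sum() == pytest.approx(0.25)
        assert icc_probability(hi.theta, bank.difficulty).sum() == pytest.approx(2.75)

    def test_rejects_out_of_range_scores(self, defn):
        bank = defn.subscales["EN"].bank
        for r in (-1, 6):
            with pytest.raises(ValueError):
                estimate_person_theta(r, bank)

    def test_theta_table_covers_all_scores(self, defn):
        bank = defn.subscales["NVEA"].bank
        table = theta_by_raw_score(bank)
        assert sorted(table) == list(range(7))


class TestItemBank:
    def test_normalized_bank_must_center(self):
        with pytest.raises(ValueError, match="sum to 0"):
            ItemBank(list("ab"), [1.0, 0.5], normalized=True)

    def test_positive_se_required(self):
        with pytest.raises(ValueError, match="positive"):
            ItemBank(list("ab"), [0.5, -0.5], difficulty_se=[0.1, -0.1])


class TestConditionalMl:
    def test_identical_columns_get_equal_difficulty(self, rng):
        data, _ = make_rasch_data(rng, [-0.8, 0.8], 300)
        vals = np.column_stack([data.values, data.values[:, 0]])
        rm = ResponseMatrix(data.persons, ["a", "b", "a2"], vals)
        bank = estimate_item_difficulties(rm)
        ia, ia2 = bank.item_ids.index("a"), bank.item_ids.index("a2")
        assert bank.difficulty[ia] == pytest.approx(bank.difficulty[ia2], abs=1e-6)

    def test_flipping_responses_negates_difficulties(self, rng):
        data, _ = make_rasch_data(rng, [-1.0, 0.2, 0.8], 400)
        bank = estimate_item_difficulties(data)
        flipped = ResponseMatrix(data.persons, data.items, 1.0 - data.values)
        bank_f = estimate_item_difficulties(flipped)
        assert bank_f.difficulty == pytest.approx(-bank.difficulty, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        # brute-force maximization of the conditional likelihood on a
        # sum-zero 3-item bank: coarse 0.05 grid refined to a 0.001 grid
        data, _ = make_rasch_data(rng, [-0.7, 0.1, 0.6], 30)
        groups = _pattern_groups(data)

        def cll(b1, b2):
            return conditional_log_likelihood(
                np.array([b1, b2, -b1 - b2]), groups)

        coarse = np.arange(-3, 3.0001, 0.05)
        best = max(((cll(b1, b2), b1, b2) for b1 in coarse for b2 in coarse))
        _, c1, c2 = best
        fine1 = np.arange(c1 - 0.06, c1 + 0.0601, 0.001)
        fine2 = np.arange(c2 - 0.06, c2 + 0.0601, 0.001)
        best = max(((cll(b1, b2), b1, b2) for b1 in fine1 for b2 in fine2))
        _, g1, g2 = best
        bank = estimate_item_difficulties(data)
        assert bank.difficulty[:2] == pytest.approx([g1, g2], abs=0.01)

    def test_person_distribution_invariance(self, rng):
        # hallmark of conditional estimation: the person distribution drops out
        b = np.array([-1.0, -0.3, 0.3, 1.0])
        low, _ = make_rasch_data(rng, b, 1500, theta_mean=-1.0, theta_sd=1.0)
        high, _ = make_rasch_data(rng, b, 1500, theta_mean=1.0, theta_sd=1.0)
        bl = estimate_item_difficulties(low)
        bh = estimate_item_difficulties(high)
        combined_se = np.sqrt(bl.difficulty_se**2 + bh.difficulty_se**2)
        assert np.all(np.abs(bl.difficulty - bh.difficulty) < 2 * combined_se)

    def test_parameter_recovery_within_two_se(self, rng):
        # simulation study: 100 replicates, 1000 persons, 6-item bank;
        # >= 95% of item estimates within 2 SE of truth
        b = np.array([-2.0, -1.2, -0.4, 0.4, 1.2, 2.0])
        hits = total = 0
        for _ in range(100):
            data, _ = make_rasch_data(rng, b, 1000)
            bank = estimate_item_difficulties(data)
            hits += int(np.sum(np.abs(bank.difficulty - b) < 2 * bank.difficulty_se))
            total += b.size
        assert hits / total >= 0.95

    def test_missing_responses_are_skipped_not_imputed(self, rng):
        data, _ = make_rasch_data(rng, [-0.5, 0.0, 0.5], 800)
        vals = data.values.copy()
        drop = rng.random(vals.shape) < 0.15
        vals[drop] = np.nan
        rm = ResponseMatrix(data.persons, data.items, vals)
        bank_full = estimate_item_difficulties(data)
        bank_miss = estimate_item_difficulties(rm)
        assert np.all(np.abs(bank_miss.difficulty - bank_full.difficulty)
                      < 3 * np.sqrt(bank_miss.difficulty_se**2
                                    + bank_full.difficulty_se**2))
        assert rm.item_observation_counts().tolist() == (~drop).sum(0).tolist()

    def test_constant_item_rejected_by_name(self, rng):
        data, _ = make_rasch_data(rng, [-0.5, 0.5], 50)
        vals = np.column_stack([data.values, np.ones(50)])
        rm = ResponseMatrix(data.persons, ["a", "b", "always"], vals)
        with pytest.raises(ValueError, match="always"):
            estimate_item_difficulties(rm)

    def test_needs_at_least_two_items(self, rng):
        rm = ResponseMatrix(["p1", "p2"], ["a"], np.array([[1.0], [0.0]]))
        with pytest.raises(ValueError):
            estimate_item_difficulties(rm)


class TestJointMl:
    def test_agrees_with_conditional_on_ordering_and_sign(self, rng):
        data, _ = make_rasch_data(rng, [-1.5, -0.5, 0.5, 1.5], 1000)
        cml = estimate_item_difficulties(data, method="conditional_ml")
        jml = estimate_item_difficulties(data, method="joint_ml")
        assert np.all(np.argsort(jml.difficulty) == np.argsort(cml.difficulty))
        assert jml.difficulty.sum() == pytest.approx(0.0, abs=1e-8)
        # joint ML carries the classic k/(k-1)-style outward bias; the
        # deflated estimates should land near the conditional ones
        k = 4
        assert jml.difficulty * (k - 1) / k == pytest.approx(
            cml.difficulty, abs=0.25)
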