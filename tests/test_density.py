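import numpy as np
import pytest
from hypothesis import given, strategies as st

from arnet.density import (
    alter_score,
    circle_composition,
    network_alter_density,
    network_size_summary,
    percentage,
)
from arnet.model import aggregate_cohort


def brute_force_densities(cohort):
    """Independent oracle: loop over raw placements, no closed-form counts."""
    scores = {}
    for placement in cohort.placements:
        w = cohort.n_circles + 1 - placement.circle
        scores[placement.alter.code] = scores.get(placement.alter.code, 0) + w
    total = sum(scores.values())
    return {code: 100 * s / total for code, s in scores.items()}


class TestPercentage:
    @pytest.mark.parametrize(
        "count,total,dp,expected",
        [
            (20, 41, 1, 48.8),
            (41, 47, 0, 87.0),
            (0, 41, 1, 0.0),
            (1, 8, 0, 13.0),  # 12.5 rounds half-away-from-zero, not to even
            (1, 41, 1, 2.4),
        ],
    )
    def test_values(self, count, total, dp, expected):
        assert percentage(count, total, dp) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percentage(1, 0)

    def test_count_above_total_rejected(self):
        with pytest.raises(ValueError):
            percentage(5, 4)

    @given(st.integers(0, 1000), st.integers(1, 1000), st.integers(0, 3))
    def test_bounds(self, count, total, dp):
        count = min(count, total)
        p = percentage(count, total, dp)
        assert 0.0 <= p <= 100.0


class TestAlterScore:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 0, 0, 0), 4), ((0, 0, 0, 1), 1), ((2, 1, 0, 3), 14), ((0, 0, 0, 0), 0)],
    )
    def test_weighted_sum(self, counts, expected):
        assert alter_score(*counts) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            alter_score(1, -1, 0, 0)

    def test_custom_weights(self):
        assert alter_score(1, 1, 1, 1, weights=(10, 0, 0, 0)) == 10

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_matches_dot_product(self, counts):
        assert alter_score(*counts) == int(np.dot(counts, (4, 3, 2, 1)))


class TestNetworkAlterDensity:
    def test_single_alter_density_100(self, make_participant):
        cohort = aggregate_cohort([make_participant("p1", [("gp", 3)])])
        table = network_alter_density(cohort)
        assert table.loc["gp", "density"] == 100.0

    def test_two_alter_split(self, make_participant):
        cohort = aggregate_cohort([make_participant("p1", [("gp", 1), ("media", 4)])])
        table = network_alter_density(cohort)
        assert table.loc["gp", "density"] == 80.0
        assert table.loc["media", "density"] == 20.0

    def test_derived_three_alter_densities(self, make_participant):
        # scores 14 / 4 / 2 -> densities 70 / 20 / 10 (hand-enumerated oracle)
        egos = [
            make_participant("p1", [("gp", 1), ("pharmacist", 1)]),
            make_participant("p2", [("gp", 1), ("media", 3)]),
            make_participant("p3", [("gp", 2)]),
            make_participant("p4", [("gp", 2)]),
        ]
        table = network_alter_density(aggregate_cohort(egos))
        assert table.loc["gp", "alter_score"] == 14
        assert table.loc["pharmacist", "alter_score"] == 4
        assert table.loc["media", "alter_score"] == 2
        assert table["density"].tolist() == [70.0, 20.0, 10.0]

    def test_sorted_descending_with_alpha_ties(self, make_participant):
        cohort = aggregate_cohort(
            [make_participant("p1", [("media", 2), ("internet", 2), ("gp", 1)])]
        )
        assert network_alter_density(cohort).index.tolist() == ["gp", "internet", "media"]

    def test_oracle_equivalence_random(self, make_random_cohort):
        rng = np.random.default_rng(42)
        for _ in range(100):
            cohort = make_random_cohort(rng)
            table = network_alter_density(cohort)
            oracle = brute_force_densities(cohort)
            assert set(table.index) == set(oracle)
            for code, expected in oracle.items():
                assert table.loc[code, "density"] == expected

    def test_normalisation(self, make_random_cohort):
        rng = np.random.default_rng(7)
        for _ in range(50):
            table = network_alter_density(make_random_cohort(rng))
            assert abs(table["density"].sum() - 100.0) < 1e-9

    def test_monotone_inward_move(self, make_participant):
        base = [
            make_participant("p1", [("gp", 2), ("media", 3)]),
            make_participant("p2", [("pharmacist", 2)]),
        ]
        moved = [
            make_participant("p1", [("gp", 1), ("media", 3)]),
            make_participant("p2", [("pharmacist", 2)]),
        ]
        t0 = network_alter_density(aggregate_cohort(base))
        t1 = network_alter_density(aggregate_cohort(moved))
        assert t1.loc["gp", "density"] > t0.loc["gp", "density"]
        for other in ("media", "pharmacist"):
            assert t1.loc[other, "density"] < t0.loc[other, "density"]

    def test_scale_invariance(self, small_cohort):
        table = network_alter_density(small_cohort)
        scaled_counts = {c: tuple(3 * n for n in ns) for c, ns in small_cohort.placement_counts.items()}

        class Scaled:
            placement_counts = scaled_counts
            n_circles = 4
            egos = small_cohort.egos

        t2 = network_alter_density(Scaled())
        for code in table.index:
            assert t2.loc[code, "density"] == pytest.approx(table.loc[code, "density"], abs=1e-12)

    def test_subgroup_score_additivity(self, calibrated_participants):
        from arnet.instruments import QolCategory
        from arnet.model import filter_by_qol

        cohort = aggregate_cohort(calibrated_participants)
        total = network_alter_density(cohort)["alter_score"]
        summed = {}
        for q in QolCategory:
            sub = filter_by_qol(cohort, q)
            if not sub.egos:
                continue
            for code, score in network_alter_density(sub)["alter_score"].items():
                summed[code] = summed.get(code, 0) + score
        assert dict(total) == summed

    def test_empty_rejected(self, small_cohort):
        class Empty:
            placement_counts = {}
            n_circles = 4
            egos = ()

        with pytest.raises(ValueError):
            network_alter_density(Empty())


class TestCircleComposition:
    def test_counts_and_denominators(self, make_participant):
        egos = [make_participant(f"p{i}", [("gp", 1)]) for i in range(3)]
        egos.append(make_participant("p9", [("pharmacist", 1), ("gp", 2)]))
        table = circle_composition(aggregate_cohort(egos), 1)
        assert table.loc["gp", "count"] == 3
        assert table.loc["gp", "pct_of_cohort"] == 75.0
        assert table.loc["gp", "pct_of_circle_placements"] == 75.0
        assert table.loc["pharmacist", "pct_of_cohort"] == 25.0

    def test_paper_calibrated_gp_row(self, make_participant):
        egos = []
        for i in range(41):
            placements = []
            if i < 15:
                placements.append(("gp", 1))
            if i < 9:
                placements.append(("pharmacist", 1))
            if not placements:
                placements.append(("internet", 3))
            egos.append(make_participant(f"p{i:02d}", placements))
        table = circle_composition(aggregate_cohort(egos), 1)
        assert table.loc["gp", "pct_of_cohort"] == 37.0
        assert table.loc["pharmacist", "pct_of_cohort"] == 22.0

    def test_empty_circle(self, make_participant):
        cohort = aggregate_cohort([make_participant("p1", [("gp", 1)])])
        assert circle_composition(cohort, 4).empty

    def test_sole_alter_on_circle(self, make_participant):
        cohort = aggregate_cohort([make_participant("p1", [("gp", 2), ("media", 4)])])
        table = circle_composition(cohort, 4)
        assert table.loc["media", "pct_of_circle_placements"] == 100.0

    def test_invalid_circle_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            circle_composition(small_cohort, 5)


class TestNetworkSizeSummary:
    def test_min_max_mean(self, make_participant, taxonomy):
        codes = [c.code for c in taxonomy]
        egos = [
            make_participant("p1", [("gp", 1)]),
            make_participant("p2", [(codes[i], 1 + i % 4) for i in range(11)]),
        ]
        s = network_size_summary(aggregate_cohort(egos))
        assert (s.minimum, s.maximum, s.mean) == (1, 11, 6)

    def test_median_and_mode(self, make_participant, taxonomy):
        codes = [c.code for c in taxonomy]

        def ego(pid, k):
            return make_participant(pid, [(codes[i], 1) for i in range(k)])

        s = network_size_summary(aggregate_cohort([ego("a", 5), ego("b", 5), ego("c", 3)]))
        assert s.modes == (5,)
        assert s.median == 5

    def test_multimodal(self, make_participant, taxonomy):
        codes = [c.code for c in taxonomy]

        def ego(pid, k):
            return make_participant(pid, [(codes[i], 1) for i in range(k)])

        s = network_size_summary(
            aggregate_cohort([ego("a", 2), ego("b", 2), ego("c", 3), ego("d", 3)])
        )
        assert s.modes == (2, 3)
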