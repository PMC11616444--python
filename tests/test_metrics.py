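import numpy as np
import pandas as pd
import pytest

from batforage import metrics, synthetic
from batforage.hmm import COMMUTING, FORAGING, StateSequence
from conftest import make_series


def seq_from_letters(letters: str) -> StateSequence:
    """'F'/'C' string → StateSequence with full posteriors."""
    s = np.array([FORAGING if c == "F" else COMMUTING for c in letters])
    return StateSequence(
        states=s, posteriors=np.eye(2)[s], imputed=np.zeros(len(s), bool)
    )


class TestStraightness:
    def test_right_angle_legs(self):
        s = metrics.straightness_index([0, 1000, 1000], [0, 0, 1000])
        assert s == pytest.approx(np.sqrt(2) / 2)

    def test_closed_loop_zero(self):
        s = metrics.straightness_index([0, 1000, 1000, 0], [0, 0, 1000, 0])
        assert s == 0.0

    def test_straight_line_one(self):
        s = metrics.straightness_index(np.arange(5) * 100.0, np.zeros(5))
        assert s == pytest.approx(1.0)

    def test_bounded_on_synthetic_commutes(
        self, small_series, truth_sequences, landscape_cfg
    ):
        land, _ = landscape_cfg
        sis = []
        for series, seq in zip(small_series, truth_sequences):
            roost = land.roosts[series.track.colony_id]
            for seg in metrics.extract_commutes(series, seq, roost):
                assert 0.0 <= seg.straightness_index <= 1.0
                sis.append(seg.straightness_index)
        assert sis, "no commutes extracted from synthetic nights"
        # biased correlated walks produce near-straight commutes
        assert np.median(sis) > 0.9


class TestForagingLocations:
    def test_bout_rule_worked_example(self, square_landscape):
        # C,C,F,F,C,F,C,F,F,F → bouts at slots 3–4 and 8–10; singleton dropped
        letters = "CCFFCFCFFF"
        x = 1000.0 * np.arange(1, 11)
        series = make_series(x, np.full(10, 5000.0))
        locs = metrics.extract_foraging_locations(
            series, seq_from_letters(letters), square_landscape
        )
        assert len(locs) == 2
        np.testing.assert_allclose([l.x for l in locs], [3000.0, 8000.0])

    def test_all_commuting_no_locations(self, square_landscape):
        series = make_series(1000.0 * np.arange(8), np.zeros(8))
        locs = metrics.extract_foraging_locations(
            series, seq_from_letters("C" * 8), square_landscape
        )
        assert locs == []

    def test_invariant_to_trailing_commute_padding(self, square_landscape):
        x = 1000.0 * np.arange(1, 11)
        base = metrics.extract_foraging_locations(
            make_series(x, np.full(10, 5000.0)),
            seq_from_letters("CCFFCFCFFF"),
            square_landscape,
        )
        x2 = 1000.0 * np.arange(1, 14)
        padded = metrics.extract_foraging_locations(
            make_series(x2, np.full(13, 5000.0)),
            seq_from_letters("CCFFCFCFFF" + "CCC"),
            square_landscape,
        )
        assert [(l.x, l.y) for l in base] == [(l.x, l.y) for l in padded]

    def test_matches_generator_truth(
        self, small_dataset, small_series, truth_sequences, landscape_cfg
    ):
        """Off-island anchors sit near the generator's target area."""
        land, _ = landscape_cfg
        truth = small_dataset.truth.set_index(["individual_id", "night_date"])
        checked = 0
        for series, seq in zip(small_series, truth_sequences):
            locs = [
                l
                for l in metrics.extract_foraging_locations(series, seq, land)
                if not l.on_home_island
            ]
            if not locs:
                continue
            row = truth.loc[(series.track.individual_id, series.track.night_date)]
            d = np.hypot(locs[0].x - row["anchor_x"], locs[0].y - row["anchor_y"])
            assert d < 100.0  # first off-island bout is the truth anchor
            checked += 1
        assert checked >= 4


class TestAngleDistance:
    def test_due_south_anchor(self):
        d, a = metrics.angle_distance_to_roost(0.0, -10_000.0, (0.0, 0.0))
        assert (d, a) == (10.0, 0.0)
        assert pytest.approx(180.0) == a * 180 / np.pi + 180

    def test_due_west_anchor(self):
        _, a = metrics.angle_distance_to_roost(-5000.0, 0.0, (0.0, 0.0))
        assert a == pytest.approx(np.pi / 2)

    def test_roost_itself_undefined(self):
        with pytest.raises(ValueError):
            metrics.angle_distance_to_roost(10.0, 20.0, (10.0, 20.0))


class TestProportions:
    def test_sum_to_one_and_match_generator(
        self, small_series, truth_sequences, landscape_cfg
    ):
        land, _ = landscape_cfg
        props = metrics.foraging_time_proportions(
            small_series, truth_sequences, land
        )
        np.testing.assert_allclose(props["p_on"] + props["p_off"], 1.0)
        # generator allocates ~30% of foraging time to the home island
        assert props["p_on"].mean() == pytest.approx(0.3, abs=0.1)

    def test_all_mainland_night(self, square_landscape):
        from shapely.geometry import MultiPolygon, box

        from batforage.data_io import Landscape

        # home island is a tiny corner; all foraging happens off it
        land = Landscape(
            land_polygons=MultiPolygon([box(-30_000, -30_000, 30_000, 30_000)]),
            home_island_polygon=box(-30_000, -30_000, -29_000, -29_000),
            roosts={"c": (-29_500.0, -29_500.0)},
            bounding_box=(-30_000, -30_000, 30_000, 30_000),
        )
        series = make_series(1000.0 * np.arange(6), np.zeros(6))
        props = metrics.foraging_time_proportions(
            [series], [seq_from_letters("FFFFFF")], land
        )
        assert (props["p_on"].iloc[0], props["p_off"].iloc[0]) == (0.0, 1.0)

    def test_zero_foraging_night_excluded(self, square_landscape):
        series = make_series(1000.0 * np.arange(6), np.zeros(6))
        with pytest.warns(UserWarning, match="no foraging"):
            props = metrics.foraging_time_proportions(
                [series], [seq_from_letters("CCCCCC")], square_landscape
            )
        assert props.empty


class TestBinomialGlm:
    @staticmethod
    def _nights(rng, n, logit0, effect=0.0):
        period = rng.integers(0, 2, n)
        p = 1 / (1 + np.exp(-(logit0 + effect * period)))
        tot = rng.integers(40, 80, n)
        on = rng.binomial(tot, p)
        return pd.DataFrame(
            {
                "on_count": on,
                "off_count": tot - on,
                "tracking_period": np.where(period == 0, "p1", "p2"),
            }
        )

    def test_identical_groups_zero_contrast(self):
        df = pd.DataFrame(
            {
                "on_count": [30, 30, 30, 30],
                "off_count": [70, 70, 70, 70],
                "tracking_period": ["p1", "p1", "p2", "p2"],
            }
        )
        res = metrics.fit_binomial_glm(
            df, "on_count + off_count ~ tracking_period"
        )
        assert res.params["tracking_period[T.p2]"] == pytest.approx(0.0, abs=1e-8)

    def test_type_one_error_calibrated(self):
        """Under the null the Wald test rejects at ~the nominal 5% rate."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            df = self._nights(rng, 40, logit0=-0.5, effect=0.0)
            res = metrics.fit_binomial_glm(
                df, "on_count + off_count ~ tracking_period"
            )
            rejections += res.pvalues["tracking_period[T.p2]"] <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.08

    def test_injected_effect_recovered(self):
        rng = np.random.default_rng(1)
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            df = self._nights(rng, 60, logit0=-0.5, effect=1.5)
            res = metrics.fit_binomial_glm(
                df, "on_count + off_count ~ tracking_period"
            )
            est = res.params["tracking_period[T.p2]"]
            se = res.bse["tracking_period[T.p2]"]
            ok += abs(est - 1.5) <= 2 * se
        assert ok / n_rep >= 0.90

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame(
            {"on_count": [1, 2], "off_count": [3, 4], "tracking_period": ["a", "a"]}
        )
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            metrics.fit_binomial_glm(df, "on_count + off_count ~ tracking_period")


class TestBalsaTrees:
    def test_colony_of_five_hundred(self):
        assert metrics.balsa_tree_requirement(500, 3, 7) == (72, 166)

    def test_exact_fit(self):
        assert metrics.balsa_tree_requirement(7, 7, 7) == (1, 1)

    def test_hand_arithmetic(self):
        assert metrics.balsa_tree_requirement(100, 4, 5) == (20, 25)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            metrics.balsa_tree_requirement(100, 8, 3)
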