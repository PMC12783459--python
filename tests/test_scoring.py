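import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arcade_dmx.catalog import CatalogError
from arcade_dmx.scoring import (
    N_GAMES,
    ProfitabilityState,
    ScoringError,
    decision_timeline,
    decision_value,
    dmx_score,
    observed_profitability,
    profitability_vector,
    rank_with_ties,
    sum_normalize,
)
from conftest import make_log, oracle_dmx

# The eight observed per-game rates of the worked example (games 1..8).
EIGHT_RATES = [0.024, 0.050, 0.070, 0.001, 0.003, 0.030, 0.082, 0.010]


def state_from_rates(rates, game_ids):
    """Profitability state in which game i was played 100 s at rates[i]."""
    n = len(game_ids)
    tickets = [r * 100.0 for r in rates] + [0.0] * (n - len(rates))
    seconds = [100.0] * len(rates) + [0.0] * (n - len(rates))
    return ProfitabilityState(tuple(game_ids), tuple(tickets), tuple(seconds))


class TestObservedProfitability:
    def test_tickets_per_second(self):
        log = make_log([("a", 0, 500, 30.0)])
        assert observed_profitability(log, "a", 600) == pytest.approx(0.06)

    def test_unplayed_is_undefined(self):
        log = make_log([("a", 0, 500, 30.0)])
        assert observed_profitability(log, "b", 600) is None

    def test_zero_tickets_gives_zero_rate(self):
        log = make_log([("a", 0, 100, 0.0)])
        assert observed_profitability(log, "a", 200) == 0.0

    def test_strictly_before_t(self):
        # at t=250, half the segment has elapsed: half the tickets count
        log = make_log([("a", 0, 500, 30.0)])
        assert observed_profitability(log, "a", 250) == pytest.approx(0.06)
        assert observed_profitability(log, "a", 0) is None

    def test_unknown_game_with_catalog(self, catalog):
        log = make_log([("mental_rotation", 0, 100, 5.0)])
        with pytest.raises(CatalogError, match="unknown"):
            observed_profitability(log, "not_a_game", 200, catalog=catalog)

    def test_t_out_of_range(self):
        log = make_log([("a", 0, 100, 5.0)])
        with pytest.raises(ScoringError):
            observed_profitability(log, "a", 1801)


class TestProfitabilityVector:
    def test_eight_game_worked_example(self, game_ids):
        state = state_from_rates(EIGHT_RATES, game_ids)
        vec = profitability_vector(state)
        assert vec[:8] == pytest.approx(EIGHT_RATES)
        assert sum(EIGHT_RATES) == pytest.approx(0.270)
        assert vec[8:] == pytest.approx([0.03375] * 13)

    def test_single_game_imputes_everywhere(self, game_ids):
        state = state_from_rates([0.06], game_ids)
        vec = profitability_vector(state)
        assert vec == pytest.approx([0.06] * 21)

    def test_two_game_mean(self, game_ids):
        state = state_from_rates([0.02, 0.04], game_ids)
        vec = profitability_vector(state)
        assert vec[2:] == pytest.approx([0.03] * 19)

    def test_no_play_rejected(self, game_ids):
        state = state_from_rates([], game_ids)
        assert not state.any_played
        with pytest.raises(ScoringError):
            profitability_vector(state)


class TestRankWithTies:
    def test_eight_game_worked_example(self, game_ids):
        vec = profitability_vector(state_from_rates(EIGHT_RATES, game_ids))
        ranks = rank_with_ties(vec)
        # games 1..8 -> printed ranks; games 9..21 tie over positions 4..16
        assert list(ranks[:8]) == [18, 3, 2, 21, 20, 17, 1, 19]
        assert list(ranks[8:]) == [10.0] * 13

    def test_all_tied_rank_11(self):
        ranks = rank_with_ties([0.06] * 21)
        assert list(ranks) == [11.0] * 21

    def test_two_way_tie_positions_12_13(self):
        values = [1.0 - 0.01 * i for i in range(11)] + [0.5, 0.5] + [0.4 - 0.01 * i for i in range(8)]
        ranks = rank_with_ties(values)
        assert ranks[11] == ranks[12] == 12.5

    def test_rank_sum_is_231(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = rng.choice([0.0, 0.01, 0.05, 0.1], size=21)
            assert rank_with_ties(values).sum() == pytest.approx(231.0)

    def test_non_finite_rejected(self):
        values = [0.1] * 20 + [float("nan")]
        with pytest.raises(ValueError, match="finite"):
            rank_with_ties(values)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            rank_with_ties([1.0] * 20)


class TestSumNormalize:
    def test_all_equal_example(self):
        shares = sum_normalize([0.06] * 21)
        assert shares[0] == pytest.approx(0.06 / 1.26)
        # the published figure 0.047 truncates 0.047619... at 3 decimals
        assert int(shares[0] * 1000) / 1000 == 0.047

    def test_dominant_game(self):
        values = [1.0] + [0.0] * 20
        shares = sum_normalize(values)
        assert shares[0] == 1.0

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            values = rng.random(21)
            assert sum_normalize(values).sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ScoringError):
            sum_normalize([0.0] * 21)


class TestDecisionValue:
    @pytest.mark.parametrize("rank,expected", [(11, 50.0), (1, 100.0), (21, 0.0), (12.5, 42.5)])
    def test_affine_map(self, rank, expected):
        assert decision_value(rank) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            decision_value(0.5)
        with pytest.raises(ValueError):
            decision_value(21.5)


class TestDmxScore:
    def test_single_game_session_scores_50(self, catalog):
        # one game all session: every second is in the all-tie state
        log = make_log([(catalog.game_ids[0], 0, 1800, 90.0)])
        result = dmx_score(log, catalog)
        assert result.dmx_score == pytest.approx(50.0)
        assert result.decision_values.shape == (1800,)

    def test_empty_log_scores_50(self, catalog):
        result = dmx_score(make_log([]), catalog)
        assert result.dmx_score == pytest.approx(50.0)

    def test_two_game_log_matches_oracle(self, catalog, two_game_log):
        expected, _ = oracle_dmx(two_game_log, catalog.game_ids)
        result = dmx_score(two_game_log, catalog)
        assert result.dmx_score == pytest.approx(expected, abs=1e-9)

    def test_reversed_order_scores_strictly_higher(self, catalog):
        a, b = catalog.game_ids[0], catalog.game_ids[1]
        # A is the 0.10/s game, B the 0.01/s game
        a_then_b = make_log([(a, 0, 600, 60.0), (b, 600, 1800, 12.0)])
        b_then_a = make_log([(b, 0, 1200, 12.0), (a, 1200, 1800, 60.0)])
        s_ab = dmx_score(a_then_b, catalog).dmx_score
        s_ba = dmx_score(b_then_a, catalog).dmx_score
        # staying with the discovered-better game scores higher
        assert s_ba > s_ab

    def test_uncleaned_log_rejected(self, catalog):
        log = make_log([(catalog.game_ids[0], 1500, 1900, 10.0)])
        with pytest.raises(ScoringError, match="clean"):
            dmx_score(log, catalog)

    def test_unknown_game_rejected(self, catalog):
        log = make_log([("mystery_machine", 0, 100, 1.0)])
        with pytest.raises(CatalogError):
            dmx_score(log, catalog)

    def test_bounds_and_exploit_floor(self, catalog):
        # discover the best game early then exploit it
        ids = catalog.game_ids
        log = make_log(
            [(ids[3], 0, 60, 0.6), (ids[0], 60, 120, 6.0), (ids[0], 120, 1800, 160.0)]
        )
        score = dmx_score(log, catalog).dmx_score
        assert 50.0 <= score <= 100.0

    def test_scale_invariance_of_rank_variant(self, catalog, two_game_log):
        scaled = make_log(
            [(s.game_id, s.start_s, s.end_s, s.tickets * 37.5) for s in two_game_log.segments]
        )
        assert dmx_score(scaled, catalog).dmx_score == pytest.approx(
            dmx_score(two_game_log, catalog).dmx_score, abs=1e-9
        )

    def test_sum_variant_all_tie_baseline(self, catalog):
        log = make_log([(catalog.game_ids[0], 0, 1800, 90.0)])
        result = dmx_score(log, catalog, normalization="sum")
        assert result.normalization == "sum"
        assert result.dmx_score == pytest.approx(50.0)

    def test_sum_variant_values_bounded(self, catalog, two_game_log):
        timeline = decision_timeline(two_game_log, catalog, normalization="sum")
        assert timeline.values.min() >= 0.0 and timeline.values.max() <= 100.0

    def test_invalid_normalization(self, catalog, two_game_log):
        with pytest.raises(ValueError):
            dmx_score(two_game_log, catalog, normalization="softmax")


class TestTimeline:
    def test_rank_conservation_every_second(self, catalog, two_game_log):
        timeline = decision_timeline(two_game_log, catalog)
        assert np.allclose(timeline.ranks.sum(axis=1), 231.0)

    def test_travel_seconds_attributed_to_destination(self, catalog):
        a, b = catalog.game_ids[0], catalog.game_ids[1]
        log = make_log([(a, 0, 600, 60.0), (b, 610, 1800, 12.0)])
        timeline = decision_timeline(log, catalog)
        assert timeline.occupied_game(605) == b

    def test_trailing_idle_keeps_previous_game(self, catalog):
        a = catalog.game_ids[0]
        log = make_log([(a, 0, 900, 30.0)])
        timeline = decision_timeline(log, catalog)
        assert timeline.occupied_game(1700) == a


@st.composite
def tiny_logs(draw):
    """Sessions of <= 60 s over <= 3 games, integer boundaries."""
    n = draw(st.integers(1, 4))
    games = ["mental_rotation", "hanoi_intermediate", "hanoi_expert"]
    t = 0
    segments = []
    for _ in range(n):
        t += draw(st.integers(0, 3))
        dur = draw(st.integers(1, 15))
        if t + dur > 60:
            break
        gid = draw(st.sampled_from(games))
        tickets = draw(st.integers(0, 40)) / 10.0
        segments.append((gid, t, t + dur, tickets))
        t += dur
    return make_log(segments, duration_s=60.0)


class TestOracleEquivalence:
    @settings(max_examples=80, deadline=None)
    @given(tiny_logs())
    def test_engine_equals_brute_force(self, catalog, log):
        expected_score, expected_values = oracle_dmx(log, catalog.game_ids)
        result = dmx_score(log, catalog)
        assert np.allclose(result.decision_values, expected_values)
        assert result.dmx_score == pytest.approx(expected_score, abs=1e-12)
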