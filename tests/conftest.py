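import numpy as np
import pytest

from arcade_dmx import GameCatalog, GameSpec, PlaySegment, SessionLog, default_catalog


@pytest.fixture(scope="session")
def catalog() -> GameCatalog:
    return default_catalog()


@pytest.fixture(scope="session")
def game_ids(catalog) -> tuple[str, ...]:
    return catalog.game_ids


def make_log(segments, participant_id="p001", summary=None, duration_s=1800.0) -> SessionLog:
    """Build a SessionLog from (game_id, start, end, tickets) tuples."""
    return SessionLog(
        participant_id=participant_id,
        segments=tuple(PlaySegment(g, s, e, t) for g, s, e, t in segments),
        summary_rows=tuple(summary or ()),
        duration_s=duration_s,
    )


@pytest.fixture
def two_game_log(game_ids) -> SessionLog:
    """Hand-scripted session: a good game first, then a poor one."""
    a, b = game_ids[0], game_ids[1]
    return make_log([(a, 0, 600, 60.0), (b, 600, 1800, 12.0)])


# ---------------------------------------------------------------------------
# Independent per-second oracle: recomputes everything from scratch, one
# second at a time, with its own tie-rank arithmetic. Deliberately naive.
# ---------------------------------------------------------------------------


def oracle_occupied(log: SessionLog, t: int):
    """Game occupying integer second t; gaps go to the switch destination,
    trailing idle keeps the previous game."""
    for seg in log.segments:
        if seg.start_s <= t < seg.end_s:
            return seg.game_id
    for seg in log.segments:  # destination of in-progress travel
        if seg.start_s > t:
            return seg.game_id
    prev = None
    for seg in log.segments:
        if seg.end_s <= t:
            prev = seg.game_id
    return prev


def oracle_rank(values, target_index):
    """Tie-averaged descending rank of one entry, by direct counting."""
    v = values[target_index]
    greater = sum(1 for x in values if x > v)
    equal = sum(1 for x in values if x == v)
    return greater + (equal + 1) / 2.0


def oracle_dmx(log: SessionLog, game_ids) -> tuple[float, list]:
    """Brute-force decision-quality score: per-second recomputation."""
    values = []
    for t in range(int(log.duration_s)):
        occ = oracle_occupied(log, t)
        if occ is None:
            values.append(50.0)
            continue
        tickets = dict.fromkeys(game_ids, 0.0)
        seconds = dict.fromkeys(game_ids, 0.0)
        for seg in log.segments:
            overlap = min(seg.end_s, t) - seg.start_s
            if overlap > 0:
                seconds[seg.game_id] += overlap
                tickets[seg.game_id] += seg.tickets * overlap / (seg.end_s - seg.start_s)
        played = [g for g in game_ids if seconds[g] > 0]
        if not played:
            values.append(50.0)
            continue
        rates = {g: tickets[g] / seconds[g] for g in played}
        imputed = sum(rates.values()) / len(rates)
        vec = [rates.get(g, imputed) for g in game_ids]
        rank = oracle_rank(vec, list(game_ids).index(occ))
        values.append(100.0 * (len(game_ids) - rank) / (len(game_ids) - 1))
    return sum(values) / len(values), values
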