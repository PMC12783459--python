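"""Per-participant derived measures: tickets, games, switches, questionnaires."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .logs import SessionLog

CRT_N_ITEMS = 7
AOMTB_N_ITEMS = 11
AOMTB_MIN, AOMTB_MAX = 1, 6  # six anchors per item -> totals 11..66
NCS_N_ITEMS = 18
NCS_MIN, NCS_MAX = -2, 2  # zero-anchored midpoint -> totals -36..36


class ResponseError(ValueError):
    """An item response is missing or outside its scale."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's derived session scores and questionnaire totals."""

    participant_id: str
    age: float | None = None
    tickets: float | None = None
    dmx: float | None = None
    games: int | None = None
    switches: int | None = None
    crt: int | None = None
    aomtb: int | None = None
    ncs: int | None = None

    def __post_init__(self) -> None:
        if self.games is not None and not 0 <= self.games <= 21:
            raise ValueError(f"games must be in 0..21, got {self.games}")
        if self.switches is not None and self.switches < 0:
            raise ValueError(f"switches must be >= 0, got {self.switches}")
        if self.crt is not None and not 0 <= self.crt <= CRT_N_ITEMS:
            raise ValueError(f"crt must be in 0..{CRT_N_ITEMS}, got {self.crt}")
        if self.aomtb is not None and not AOMTB_N_ITEMS * AOMTB_MIN <= self.aomtb <= AOMTB_N_ITEMS * AOMTB_MAX:
            raise ValueError(f"aomtb must be in 11..66, got {self.aomtb}")
        if self.ncs is not None and not NCS_N_ITEMS * NCS_MIN <= self.ncs <= NCS_N_ITEMS * NCS_MAX:
            raise ValueError(f"ncs must be in -36..36, got {self.ncs}")


# ----------------------------------------------------------------- session


def total_tickets(log: SessionLog) -> float:
    """Sum of tickets earned across all play segments of a cleaned log."""
    return float(sum(seg.tickets for seg in log.segments))


def count_games(log: SessionLog) -> int:
    """Number of unique games played."""
    return len({seg.game_id for seg in log.segments})


def count_switches(log: SessionLog) -> int:
    """Number of transitions between consecutive distinct games.

    Revisiting an earlier game counts as a switch; two back-to-back segments
    of the same game do not.
    """
    ids = [seg.game_id for seg in log.segments]
    return sum(1 for a, b in zip(ids, ids[1:]) if a != b)


# ----------------------------------------------------------- questionnaires


def _check_items(responses: Sequence[float], n: int, low: float, high: float, scale: str) -> None:
    if len(responses) != n:
        raise ResponseError(f"{scale} requires {n} responses, got {len(responses)}")
    for i, r in enumerate(responses, start=1):
        if not low <= r <= high:
            raise ResponseError(f"{scale} item {i}: response {r} outside [{low}, {high}]")


def score_crt(responses: Sequence[int], answer_key: Sequence[int] | None = None) -> int:
    """Cognitive-reflection total: number of the 7 items answered correctly.

    With ``answer_key`` given, ``responses`` are chosen options compared
    against the key; otherwise they are 0/1 correctness indicators.
    """
    if len(responses) != CRT_N_ITEMS:
        raise ResponseError(f"CRT requires {CRT_N_ITEMS} responses, got {len(responses)}")
    if answer_key is not None:
        if len(answer_key) != CRT_N_ITEMS:
            raise ResponseError(f"CRT answer key requires {CRT_N_ITEMS} entries")
        return sum(1 for r, k in zip(responses, answer_key) if r == k)
    _check_items(responses, CRT_N_ITEMS, 0, 1, "CRT")
    return int(sum(responses))


def score_aomtb(responses: Sequence[int], reverse_items: Iterable[int] = ()) -> int:
    """Open-minded-thinking total over 11 items on 1..6 anchors (range 11..66).

    ``reverse_items`` are 1-based indices reflected about the scale midpoint
    (x -> 7 - x) before summation. Which items are reverse-keyed is supplied
    by configuration.
    """
    _check_items(responses, AOMTB_N_ITEMS, AOMTB_MIN, AOMTB_MAX, "AOMTB")
    rev = set(reverse_items)
    if not rev <= set(range(1, AOMTB_N_ITEMS + 1)):
        raise ResponseError(f"AOMTB reverse_items must be 1..{AOMTB_N_ITEMS}, got {sorted(rev)}")
    return int(
        sum(
            (AOMTB_MIN + AOMTB_MAX - r) if i in rev else r
            for i, r in enumerate(responses, start=1)
        )
    )


def score_ncs(responses: Sequence[int], reverse_items: Iterable[int] = ()) -> int:
    """Need-for-cognition total over 18 items on -2..2 anchors (range -36..36).

    Reverse-keyed items are negated (the midpoint is 0), per configuration.
    """
    _check_items(responses, NCS_N_ITEMS, NCS_MIN, NCS_MAX, "NCS")
    rev = set(reverse_items)
    if not rev <= set(range(1, NCS_N_ITEMS + 1)):
        raise ResponseError(f"NCS reverse_items must be 1..{NCS_N_ITEMS}, got {sorted(rev)}")
    return int(sum(-r if i in rev else r for i, r in enumerate(responses, start=1)))
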