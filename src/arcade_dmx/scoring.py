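"""Decision-quality (DMX) scoring from cleaned session logs.

The score treats every second of a session as a decision: stay with the
current game or be at another one. Each second is valued by how profitable
the occupied game looks *given only the evidence accumulated strictly before
that second*:

1. For every game the participant has played, estimate its profitability as
   cumulative tickets earned divided by cumulative seconds played (tickets
   per second), interpolating tickets uniformly within each segment.
2. Assign every unplayed game the arithmetic mean of the observed rates —
   the participant can only assume unseen games resemble the ones sampled.
3. Rank the 21 per-game values with tie-averaged ranks (rank 1 = most
   profitable; any tie gets the average of the ranks it spans).
4. Value the occupied game's rank on a 0-100 scale via the affine map
   ``v = 100 * (21 - rank) / 20``, so the best-ranked game is worth 100, the
   worst 0, and the all-tie state (rank 11 everywhere) is worth 50.
5. The final score is the mean of the 1800 per-second values, i.e. the sum
   of the decision values rescaled by the fixed decision count onto 0-100.

The affine rank-to-value map and the mean aggregation are this package's
documented convention (an order-preserving choice whose all-tie baseline of
50 matches the published score scale); see README for discussion.

A rejected "sum" normalization variant (per-second profitability shares
summing to 1) is retained for comparison plots and is never the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .catalog import N_GAMES, CatalogError, GameCatalog
from .logs import SessionLog

#: Decisions per session: one per second of the 30-minute run.
N_DECISIONS = 1800

Normalization = Literal["rank", "sum"]

#: Scale factor for the sum variant: a share of 1/21 (the all-tie state)
#: maps to the same 50-point baseline as rank 11 under the rank variant.
_SUM_VARIANT_SCALE = 100.0 * N_GAMES / 2.0


class ScoringError(ValueError):
    """Raised when a log violates a scoring precondition."""


# --------------------------------------------------------------------------
# Profitability state
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfitabilityState:
    """Per-game cumulative evidence available at one instant.

    ``observed_rate`` is defined only for games with positive cumulative
    play time; every unplayed game is imputed the arithmetic mean of the
    observed rates. Before any play at all, the state is an all-tie
    sentinel: every game shares one common (undefined-magnitude) value.
    """

    game_ids: tuple[str, ...]
    cumulative_tickets: tuple[float, ...]
    cumulative_play_seconds: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.game_ids)
        if len(self.cumulative_tickets) != n or len(self.cumulative_play_seconds) != n:
            raise ValueError("state arrays must align with game_ids")

    @property
    def any_played(self) -> bool:
        return any(s > 0 for s in self.cumulative_play_seconds)

    def observed_rate(self, game_id: str) -> float | None:
        """Tickets/second for one game, or ``None`` when never played."""
        i = self.game_ids.index(game_id)
        seconds = self.cumulative_play_seconds[i]
        if seconds <= 0:
            return None
        return self.cumulative_tickets[i] / seconds

    @classmethod
    def from_log(cls, log: SessionLog, t: float, game_ids: Sequence[str]) -> "ProfitabilityState":
        """Accumulate evidence from all play strictly before time ``t``.

        Tickets are interpolated uniformly within each segment, so a segment
        half-elapsed at ``t`` contributes half its tickets.
        """
        idx = {g: i for i, g in enumerate(game_ids)}
        tickets = [0.0] * len(game_ids)
        seconds = [0.0] * len(game_ids)
        for seg in log.segments:
            try:
                i = idx[seg.game_id]
            except KeyError:
                raise CatalogError(f"log references unknown game_id: {seg.game_id!r}") from None
            overlap = min(seg.end_s, t) - seg.start_s
            if overlap <= 0:
                continue
            seconds[i] += overlap
            tickets[i] += seg.tickets * overlap / seg.duration_s
        return cls(tuple(game_ids), tuple(tickets), tuple(seconds))


def observed_profitability(
    log: SessionLog, game_id: str, t: float, catalog: GameCatalog | None = None
) -> float | None:
    """Cumulative tickets/second earned in ``game_id`` strictly before ``t``.

    Returns ``None`` (undefined) when the game has no play time before ``t``.
    """
    if not 0 <= t <= log.duration_s:
        raise ScoringError(f"t must lie in [0, {log.duration_s}], got {t}")
    if catalog is not None and game_id not in catalog:
        raise CatalogError(f"unknown game_id: {game_id!r}")
    game_ids = [game_id] + sorted({s.game_id for s in log.segments} - {game_id})
    state = ProfitabilityState.from_log(log, t, game_ids)
    return state.observed_rate(game_id)


def profitability_vector(state: ProfitabilityState) -> np.ndarray:
    """Full per-game profitability vector: observed rates with mean imputation.

    Requires at least one played game; the no-play sentinel state has no
    well-defined magnitudes and is handled by the caller as an all-tie.
    """
    seconds = np.asarray(state.cumulative_play_seconds, dtype=float)
    tickets = np.asarray(state.cumulative_tickets, dtype=float)
    played = seconds > 0
    if not played.any():
        raise ScoringError("profitability_vector requires at least one played game")
    rates = np.zeros_like(seconds)
    rates[played] = tickets[played] / seconds[played]
    rates[~played] = rates[played].mean()
    return rates


# --------------------------------------------------------------------------
# Normalizations and per-decision values
# --------------------------------------------------------------------------


def rank_with_ties(values: Sequence[float]) -> np.ndarray:
    """Tie-averaged descending ranks over the 21 games (1 = most profitable).

    Tied values receive the average of the rank positions they span, so the
    ranks always sum to 231 (= 21 * 22 / 2).
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_GAMES,):
        raise ValueError(f"expected exactly {N_GAMES} values, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("rank_with_ties requires finite values")
    return rankdata(-arr, method="average")


def sum_normalize(values: Sequence[float]) -> np.ndarray:
    """Divide each profitability by the total so shares sum to 1."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_GAMES,):
        raise ValueError(f"expected exactly {N_GAMES} values, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("sum_normalize requires non-negative values")
    total = arr.sum()
    if total <= 0:
        raise ScoringError("sum_normalize undefined for an all-zero vector")
    return arr / total


def decision_value(rank: float | np.ndarray) -> float | np.ndarray:
    """Map a tie-averaged rank in [1, 21] to a value in [0, 100].

    Strictly decreasing affine map ``100 * (21 - rank) / 20``: rank 1 -> 100,
    rank 11 (all-tie) -> 50, rank 21 -> 0.
    """
    rank_arr = np.asarray(rank, dtype=float)
    if ((rank_arr < 1) | (rank_arr > N_GAMES)).any():
        raise ValueError(f"rank must lie in [1, {N_GAMES}]")
    out = 100.0 * (N_GAMES - rank_arr) / (N_GAMES - 1.0)
    return float(out) if np.isscalar(rank) or out.ndim == 0 else out


# --------------------------------------------------------------------------
# Timeline reconstruction
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DecisionTimeline:
    """Per-second reconstruction of the session's 1800 decisions.

    ``occupied`` holds, for each second, the index of the game whose value
    the decision is credited with (-1 when the log is empty), ``ranks`` the
    21-game tie-averaged rank vector, and ``values`` the decision values.
    """

    game_ids: tuple[str, ...]
    occupied: np.ndarray  # (T,) int game indices, -1 = none
    ranks: np.ndarray  # (T, 21) tie-averaged ranks
    values: np.ndarray  # (T,) decision values in [0, 100]

    def occupied_game(self, t: int) -> str | None:
        i = int(self.occupied[t])
        return None if i < 0 else self.game_ids[i]


@dataclass(frozen=True)
class DmxResult:
    """Final score plus the per-decision values that produced it."""

    dmx_score: float
    decision_values: np.ndarray
    normalization: Normalization
    timeline: DecisionTimeline | None = field(default=None, repr=False, compare=False)


def _cumulative_before(log: SessionLog, game_index: dict[str, int], n_seconds: int) -> tuple[np.ndarray, np.ndarray]:
    """(T, 21) cumulative tickets and play-seconds strictly before each second."""
    n = len(game_index)
    cum_tickets = np.zeros((n_seconds, n))
    cum_seconds = np.zeros((n_seconds, n))
    ts = np.arange(n_seconds, dtype=float)
    # direct closed form per segment (not a running cumsum) so exactly equal
    # observed rates stay exactly tied after accumulation
    for seg in log.segments:
        try:
            j = game_index[seg.game_id]
        except KeyError:
            raise CatalogError(f"log references unknown game_id: {seg.game_id!r}") from None
        overlap = np.clip(ts - seg.start_s, 0.0, seg.duration_s)
        cum_seconds[:, j] += overlap
        cum_tickets[:, j] += seg.tickets * overlap / seg.duration_s
    return cum_tickets, cum_seconds


def _occupied_indices(log: SessionLog, game_index: dict[str, int], n_seconds: int) -> np.ndarray:
    """Game index occupied at each second.

    A second inside a play segment belongs to that game. Travel/idle seconds
    between segments are attributed to the destination game of the
    in-progress switch (switch cost is part of the decision); trailing idle
    seconds with no destination keep the previous game.
    """
    occ = np.full(n_seconds, -1, dtype=int)
    for seg in log.segments:
        t0 = max(int(math.ceil(seg.start_s)), 0)
        t1 = min(int(math.ceil(seg.end_s)), n_seconds)
        occ[t0:t1] = game_index[seg.game_id]
    # gaps -> destination game (backward fill), trailing gap -> previous game
    last = -1
    for t in range(n_seconds - 1, -1, -1):
        if occ[t] >= 0:
            last = occ[t]
        elif last >= 0:
            occ[t] = last
    prev = -1
    for t in range(n_seconds):
        if occ[t] >= 0:
            prev = occ[t]
        elif prev >= 0:
            occ[t] = prev
    return occ


def decision_timeline(
    log: SessionLog,
    catalog: GameCatalog,
    normalization: Normalization = "rank",
) -> DecisionTimeline:
    """Reconstruct every second's profitability ranks and decision value.

    The value at second ``t`` uses evidence strictly before ``t``, so the
    first played second is valued under the pre-play (all-tie) state.
    """
    if normalization not in ("rank", "sum"):
        raise ValueError(f"normalization must be 'rank' or 'sum', got {normalization!r}")
    if not log.is_within_limit:
        raise ScoringError(
            "log extends past the session limit; apply clean_session_log first"
        )
    game_ids = catalog.game_ids
    game_index = {g: i for i, g in enumerate(game_ids)}
    n_seconds = int(round(log.duration_s))

    cum_tickets, cum_seconds = _cumulative_before(log, game_index, n_seconds)
    occ = _occupied_indices(log, game_index, n_seconds)

    played = cum_seconds > 0
    any_played = played.any(axis=1)
    safe_seconds = np.where(played, cum_seconds, 1.0)
    obs = np.where(played, cum_tickets / safe_seconds, np.nan)
    with np.errstate(invalid="ignore"):
        row_mean = np.nanmean(np.where(any_played[:, None], obs, 0.0), axis=1)
    rates = np.where(np.isnan(obs), row_mean[:, None], obs)
    rates[~any_played] = 0.0  # placeholder rows; valued as all-tie below

    ranks = rankdata(-rates, method="average", axis=1)
    ranks[~any_played] = (N_GAMES + 1) / 2.0  # all-tie: every rank 11

    valid = occ >= 0
    occ_safe = np.where(valid, occ, 0)
    rows = np.arange(n_seconds)
    if normalization == "rank":
        values = 100.0 * (N_GAMES - ranks[rows, occ_safe]) / (N_GAMES - 1.0)
    else:
        totals = rates.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            shares = np.where(totals[:, None] > 0, rates / totals[:, None], 1.0 / N_GAMES)
        values = np.clip(_SUM_VARIANT_SCALE * shares[rows, occ_safe], 0.0, 100.0)
        values[~any_played] = 50.0
    values = np.where(valid, values, 50.0)  # empty log: neutral all-tie value
    values[~any_played & valid] = 50.0

    return DecisionTimeline(
        game_ids=game_ids, occupied=occ, ranks=ranks, values=values
    )


def dmx_score(
    log: SessionLog,
    catalog: GameCatalog,
    normalization: Normalization = "rank",
    keep_timeline: bool = False,
) -> DmxResult:
    """Score a cleaned session log on the 0-100 decision-quality scale.

    Deterministic given the log: the mean of the 1800 per-second decision
    values (summing the decisions and rescaling by the fixed count).
    """
    timeline = decision_timeline(log, catalog, normalization=normalization)
    score = float(timeline.values.mean()) if timeline.values.size else 50.0
    return DmxResult(
        dmx_score=score,
        decision_values=timeline.values,
        normalization=normalization,
        timeline=timeline if keep_timeline else None,
    )
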