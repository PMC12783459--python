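"""Arcade catalog: the 21-game machine layout and per-game reward dynamics.

A catalog describes the structure the scoring and simulation layers share:
which games exist, which room hosts each machine, how fast a reference-skill
player earns tickets in each game, and the structural constraints (play-count
caps, diminishing yields) that make persistence alone a losing strategy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

#: Number of active machines in the arcade.
N_GAMES = 21

#: Rooms are numbered 1..5.
N_ROOMS = 5


class CatalogError(ValueError):
    """Raised for structurally invalid catalogs or unknown game ids."""


@dataclass(frozen=True)
class GameSpec:
    """One arcade machine.

    Parameters
    ----------
    game_id:
        Stable string key used in session logs.
    display_name:
        Human-readable machine label.
    room:
        Room number hosting the machine (1..5).
    base_rate:
        Expected tickets per second for a reference-skill player on the
        first play.
    max_plays:
        Play-count cap, or ``None`` for unlimited plays.
    yield_decay:
        Multiplicative factor applied to the expected rate after each
        completed play; 1.0 means no diminishing yield.
    play_duration:
        Typical seconds one play lasts.
    """

    game_id: str
    display_name: str
    room: int
    base_rate: float
    max_plays: int | None = None
    yield_decay: float = 1.0
    play_duration: float = 60.0

    def __post_init__(self) -> None:
        if not self.game_id:
            raise CatalogError("game_id must be a non-empty string")
        if not 1 <= self.room <= N_ROOMS:
            raise CatalogError(f"room must be in 1..{N_ROOMS}, got {self.room}")
        if self.base_rate < 0:
            raise CatalogError(f"base_rate must be >= 0, got {self.base_rate}")
        if self.max_plays is not None and self.max_plays < 1:
            raise CatalogError(f"max_plays must be positive, got {self.max_plays}")
        if not 0.0 <= self.yield_decay <= 1.0:
            raise CatalogError(f"yield_decay must be in [0, 1], got {self.yield_decay}")
        if self.play_duration <= 0:
            raise CatalogError(f"play_duration must be > 0, got {self.play_duration}")


@dataclass(frozen=True)
class GameCatalog:
    """Immutable collection of exactly :data:`N_GAMES` machines."""

    games: tuple[GameSpec, ...]
    _index: dict[str, GameSpec] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        games = tuple(self.games)
        object.__setattr__(self, "games", games)
        if len(games) != N_GAMES:
            raise CatalogError(f"catalog must contain exactly {N_GAMES} games, got {len(games)}")
        index = {g.game_id: g for g in games}
        if len(index) != len(games):
            seen: set[str] = set()
            dupes = sorted({g.game_id for g in games if g.game_id in seen or seen.add(g.game_id)})
            raise CatalogError(f"duplicate game_ids: {dupes}")
        object.__setattr__(self, "_index", index)

    def __iter__(self) -> Iterator[GameSpec]:
        return iter(self.games)

    def __len__(self) -> int:
        return len(self.games)

    def __contains__(self, game_id: str) -> bool:
        return game_id in self._index

    def __getitem__(self, game_id: str) -> GameSpec:
        try:
            return self._index[game_id]
        except KeyError:
            raise CatalogError(f"unknown game_id: {game_id!r}") from None

    @property
    def game_ids(self) -> tuple[str, ...]:
        return tuple(g.game_id for g in self.games)

    # ------------------------------------------------------------------ i/o

    def to_dict(self) -> dict:
        return {
            "games": [
                {
                    "game_id": g.game_id,
                    "display_name": g.display_name,
                    "room": g.room,
                    "base_rate": g.base_rate,
                    "max_plays": g.max_plays,
                    "yield_decay": g.yield_decay,
                    "play_duration": g.play_duration,
                }
                for g in self.games
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GameCatalog":
        try:
            raw = data["games"]
        except (KeyError, TypeError):
            raise CatalogError("catalog config must contain a top-level 'games' list") from None
        return cls(tuple(GameSpec(**entry) for entry in raw))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "GameCatalog":
        """Load a catalog from a YAML or JSON config file."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"catalog file not found: {path}")
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


# Default instantiation: base rates spread over roughly an order of magnitude
# (the worked-example rates span 0.001..0.082 tickets/s), two machines capped
# at two plays, geometric yield decay on a subset.
_DEFAULT_GAMES: tuple[tuple[str, str, int, float, int | None, float, float], ...] = (
    ("mental_rotation", "Mental Rotation", 1, 0.080, 2, 1.0, 75.0),
    ("hanoi_intermediate", "Tower of Hanoi - Intermediate", 1, 0.055, None, 0.8, 90.0),
    ("hanoi_expert", "Tower of Hanoi - Expert", 1, 0.070, 2, 1.0, 120.0),
    ("go_no_go", "Go / No-Go", 1, 0.030, None, 1.0, 45.0),
    ("mackworth_clock", "Mackworth Clock", 1, 0.012, None, 1.0, 60.0),
    ("n_back", "N-Back", 2, 0.045, None, 0.8, 60.0),
    ("stroop", "Stroop Colours", 2, 0.025, None, 1.0, 45.0),
    ("visual_search", "Visual Search", 2, 0.060, None, 0.8, 50.0),
    ("digit_span", "Digit Span", 2, 0.018, None, 1.0, 40.0),
    ("corsi_blocks", "Corsi Blocks", 3, 0.035, None, 1.0, 55.0),
    ("pattern_match", "Pattern Match", 3, 0.050, None, 0.8, 50.0),
    ("reaction_race", "Reaction Race", 3, 0.022, None, 1.0, 35.0),
    ("target_tracking", "Target Tracking", 3, 0.040, None, 1.0, 60.0),
    ("quick_estimate", "Quick Estimate", 4, 0.008, None, 1.0, 40.0),
    ("anagram_rush", "Anagram Rush", 4, 0.028, None, 0.8, 55.0),
    ("mental_arithmetic", "Mental Arithmetic", 4, 0.015, None, 1.0, 45.0),
    ("memory_pairs", "Memory Pairs", 4, 0.048, None, 1.0, 65.0),
    ("card_sort", "Card Sort", 5, 0.020, None, 1.0, 50.0),
    ("spot_difference", "Spot the Difference", 5, 0.033, None, 0.8, 55.0),
    ("maze_runner", "Maze Runner", 5, 0.065, None, 0.8, 70.0),
    ("whack_a_mole", "Whack-a-Mole", 5, 0.010, None, 1.0, 30.0),
)


def default_catalog() -> GameCatalog:
    """Build the package's default 21-game catalog.

    Rates are heterogeneous (log-spread over ~one order of magnitude), two
    games allow only two plays, and a subset of games loses 20% of its
    expected yield after each completed play.
    """
    return GameCatalog(
        tuple(
            GameSpec(
                game_id=gid,
                display_name=name,
                room=room,
                base_rate=rate,
                max_plays=cap,
                yield_decay=decay,
                play_duration=dur,
            )
            for gid, name, room, rate, cap, decay, dur in _DEFAULT_GAMES
        )
    )
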