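"""Agent-based session and cohort simulator.

Stands in for the VR arcade: agents of configurable decision quality
allocate a 30-minute budget over the 21-game catalog, honouring play-count
caps, diminishing yields, and travel time between machines. Cohorts draw
correlated latent traits (game skill, selection ability, age, questionnaire
dispositions) so downstream scoring can be exercised against a known
generating process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .catalog import GameCatalog
from .logs import SESSION_DURATION_S, PlaySegment, SessionLog

PolicyKind = Literal[
    "explore_then_exploit", "uniform_random_switcher", "sticky_first_game", "oracle"
]

#: Latent trait order used by cohort covariance matrices.
COHORT_TRAITS = ("skill", "selection", "age", "crt", "ncs", "aomtb")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class AgentPolicy:
    """How an agent chooses games and how noisily it earns tickets.

    ``skill_vector`` multiplies each game's base rate (a scalar applies to
    all games). ``selection_ability`` in [0, 1] is the probability that an
    exploit-phase choice is the greedy best rather than random; 1.0 is a
    fully greedy agent.
    """

    policy_kind: PolicyKind = "explore_then_exploit"
    skill_vector: float | Mapping[str, float] = 1.0
    selection_ability: float = 1.0
    exploration_budget_s: float = 450.0
    switch_cost_s: float = 8.0
    ticket_noise_sd: float = 0.25  # sigma of the lognormal multiplicative noise
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.policy_kind not in (
            "explore_then_exploit", "uniform_random_switcher", "sticky_first_game", "oracle"
        ):
            raise SimulationError(f"unknown policy_kind: {self.policy_kind!r}")
        if not 0.0 <= self.selection_ability <= 1.0:
            raise SimulationError("selection_ability must lie in [0, 1]")
        if self.switch_cost_s < 0:
            raise SimulationError("switch_cost_s must be >= 0")
        if self.exploration_budget_s < 0:
            raise SimulationError("exploration_budget_s must be >= 0")
        if isinstance(self.skill_vector, Mapping):
            if any(v <= 0 for v in self.skill_vector.values()):
                raise SimulationError("skill multipliers must be > 0")
        elif self.skill_vector <= 0:
            raise SimulationError("skill multipliers must be > 0")

    def skill_for(self, game_id: str) -> float:
        if isinstance(self.skill_vector, Mapping):
            return float(self.skill_vector.get(game_id, 1.0))
        return float(self.skill_vector)


def _choose_game(
    policy: AgentPolicy,
    catalog: GameCatalog,
    rng: np.random.Generator,
    t: float,
    current: str | None,
    plays: dict[str, int],
    obs_tickets: dict[str, float],
    obs_seconds: dict[str, float],
) -> str | None:
    available = [
        g.game_id
        for g in catalog
        if g.max_plays is None or plays[g.game_id] < g.max_plays
    ]
    if not available:
        return None

    kind = policy.policy_kind
    if kind == "sticky_first_game":
        if current is not None and current in available:
            return current
        # prefer an uncapped machine so the agent can truly stay put
        uncapped = [g for g in available if catalog[g].max_plays is None]
        return str(rng.choice(uncapped or available))

    if kind == "uniform_random_switcher":
        pool = [g for g in available if g != current] or available
        return str(rng.choice(pool))

    if kind == "oracle":
        # true current expected rate, including decay already incurred
        def true_rate(gid: str) -> float:
            spec = catalog[gid]
            return spec.base_rate * policy.skill_for(gid) * spec.yield_decay ** plays[gid]

        if rng.random() <= policy.selection_ability:
            return max(available, key=true_rate)
        return str(rng.choice(available))

    # explore_then_exploit
    unplayed = [g for g in available if plays[g] == 0]
    if t < policy.exploration_budget_s and unplayed:
        return str(rng.choice(unplayed))
    sampled = [g for g in available if obs_seconds[g] > 0]
    if not sampled:
        return str(rng.choice(available))
    if rng.random() <= policy.selection_ability:
        return max(sampled, key=lambda g: obs_tickets[g] / obs_seconds[g])
    # poor selection: persist in the current game regardless of evidence
    if current is not None and current in available:
        return current
    return str(rng.choice(available))


def simulate_session(
    catalog: GameCatalog,
    policy: AgentPolicy,
    seed: int | None = None,
    participant_id: str = "sim",
    duration_s: float = SESSION_DURATION_S,
) -> SessionLog:
    """Simulate one 30-minute session under the given policy.

    Per play, tickets are drawn as expected rate x duration with lognormal
    multiplicative noise (non-negative tickets, skill-proportional spread).
    The expected rate honours the game's yield decay and play cap. Switching
    to a different machine consumes ``switch_cost_s`` travel seconds, which
    appear as gaps between segments. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(policy.rng_seed if seed is None else seed)
    plays = {g.game_id: 0 for g in catalog}
    obs_tickets = {g.game_id: 0.0 for g in catalog}
    obs_seconds = {g.game_id: 0.0 for g in catalog}

    segments: list[PlaySegment] = []
    t = 0.0
    current: str | None = None
    while t < duration_s:
        gid = _choose_game(policy, catalog, rng, t, current, plays, obs_tickets, obs_seconds)
        if gid is None:
            break
        if current is not None and gid != current:
            t += policy.switch_cost_s
            if t >= duration_s:
                break
        spec = catalog[gid]
        dur = min(spec.play_duration, duration_s - t)
        if dur <= 0:
            break
        expected_rate = spec.base_rate * policy.skill_for(gid) * spec.yield_decay ** plays[gid]
        noise = math.exp(rng.normal(0.0, policy.ticket_noise_sd)) if policy.ticket_noise_sd > 0 else 1.0
        tickets = round(expected_rate * dur * noise, 4)
        segments.append(PlaySegment(game_id=gid, start_s=t, end_s=t + dur, tickets=tickets))
        t += dur
        plays[gid] += 1
        obs_tickets[gid] += tickets
        obs_seconds[gid] += dur
        current = gid

    total = round(sum(s.tickets for s in segments), 4)
    return SessionLog(
        participant_id=participant_id,
        segments=tuple(segments),
        summary_rows=(("end_time", float(duration_s)), ("total_tickets", total)),
        duration_s=duration_s,
    )


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for a synthetic participant cohort.

    ``correlation`` is the 6x6 target correlation matrix among the latent
    traits in :data:`COHORT_TRAITS` (identity when omitted). Latents map to
    observables monotonically: skill -> per-game rate multiplier, selection
    -> greedy-choice probability, and the questionnaire latents -> item
    responses.
    """

    n_participants: int
    correlation: np.ndarray | None = None
    rng_seed: int | None = None
    mean_age: float = 23.0
    sd_age: float = 6.0
    skill_spread: float = 0.30
    selection_scale: float = 2.5
    selection_offset: float = 0.0
    exploration_budget_s: float = 450.0
    switch_cost_s: float = 8.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise SimulationError("cohort requires n_participants >= 2")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(COHORT_TRAITS)
            if corr.shape != (k, k):
                raise SimulationError(f"correlation must be {k}x{k}")
            if not np.allclose(corr, corr.T):
                raise SimulationError("correlation must be symmetric")
            eigvals = np.linalg.eigvalsh(corr)
            if eigvals.min() < -1e-10:
                raise SimulationError("correlation must be positive semi-definite")
            object.__setattr__(self, "correlation", corr)


@dataclass(frozen=True)
class CohortMember:
    participant_id: str
    session: SessionLog
    age: float
    crt_responses: tuple[int, ...]
    aomtb_responses: tuple[int, ...]
    ncs_responses: tuple[int, ...]
    latents: dict[str, float] = field(default_factory=dict)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(
    spec: CohortSpec,
    catalog: GameCatalog,
    seed: int | None = None,
) -> list[CohortMember]:
    """Draw a cohort of correlated agents and simulate each one's session."""
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    k = len(COHORT_TRAITS)
    corr = np.eye(k) if spec.correlation is None else spec.correlation
    latents = rng.multivariate_normal(np.zeros(k), corr, size=spec.n_participants, method="cholesky")
    z = {trait: latents[:, i] for i, trait in enumerate(COHORT_TRAITS)}

    skill = np.exp(spec.skill_spread * z["skill"])
    selection = _sigmoid(spec.selection_scale * z["selection"] + spec.selection_offset)
    age = np.clip(spec.mean_age + spec.sd_age * z["age"], 18.0, 80.0)

    # item-level questionnaire responses, monotone in each latent
    p_correct = _sigmoid(0.9 * z["crt"] - 0.6)
    crt_items = (rng.random((spec.n_participants, 7)) < p_correct[:, None]).astype(int)
    aomtb_items = np.clip(
        np.rint(4.3 + 1.1 * z["aomtb"][:, None] + rng.normal(0, 0.8, (spec.n_participants, 11))),
        1, 6,
    ).astype(int)
    ncs_items = np.clip(
        np.rint(0.35 + 0.9 * z["ncs"][:, None] + rng.normal(0, 0.7, (spec.n_participants, 18))),
        -2, 2,
    ).astype(int)

    members: list[CohortMember] = []
    width = max(3, len(str(spec.n_participants)))
    for i in range(spec.n_participants):
        pid = f"p{i + 1:0{width}d}"
        policy = AgentPolicy(
            policy_kind="explore_then_exploit",
            skill_vector=float(skill[i]),
            selection_ability=float(selection[i]),
            exploration_budget_s=spec.exploration_budget_s,
            switch_cost_s=spec.switch_cost_s,
        )
        session = simulate_session(
            catalog, policy, seed=int(rng.integers(0, 2**63 - 1)), participant_id=pid
        )
        members.append(
            CohortMember(
                participant_id=pid,
                session=session,
                age=float(age[i]),
                crt_responses=tuple(int(x) for x in crt_items[i]),
                aomtb_responses=tuple(int(x) for x in aomtb_items[i]),
                ncs_responses=tuple(int(x) for x in ncs_items[i]),
                latents={trait: float(z[trait][i]) for trait in COHORT_TRAITS},
            )
        )
    return members
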