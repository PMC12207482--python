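"""Monte-Carlo simulator of the iterated partner-choice protocol.

Each episode, a focal individual plays ``n_races`` back-and-forth races
with a fixed roster of coplayers (default 5, so 6 players per episode).
Every race has four phases: free mixing, partner choice, interaction
(one Stag hunt round per boat), and outcome.  Coplayers play
unconditional strategies; the focal always cooperates and its partner
choice follows the cascade

1. if the previous partner cooperated, re-pair with probability ``s``;
2. otherwise, with probability ``omega`` pick uniformly among known
   cooperators — ground truth in oracle mode, crown-flagged agents when
   a perceptual intervention is configured;
3. otherwise pick a color (purple with probability ``b``) and a uniform
   agent of that color, falling back to the other color if empty.

The perceptual intervention is an honest signal ("crown") set on every
agent that cooperated in the last interaction; each crown survives to
the next partner-choice phase independently with probability
``q(beta)``, a monotone decreasing function of the decay ``beta``.

``infinite`` mode bypasses rosters entirely and draws the partner *type*
from the analytic ingredients (P(0) and nu), so the simulated process is
exactly the recursion of :mod:`partnerchoice.model`; it exists as the
Monte-Carlo cross-check of the closed-form machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .model import (
    PC,
    TC,
    FocalParams,
    PopulationParams,
    initial_distribution,
    new_partner_distribution,
)

__all__ = [
    "PURPLE",
    "TEAL",
    "COOPERATE",
    "DEFECT",
    "Agent",
    "CommunitySpec",
    "StagHuntPayoffs",
    "InterventionSpec",
    "EpisodeConfig",
    "EpisodeRecord",
    "make_community",
    "focal_choose",
    "run_episode",
    "simulate_episodes",
    "infinite_type_frequencies",
    "effective_awareness",
]

PURPLE, TEAL = "purple", "teal"
COOPERATE, DEFECT = "cooperator", "defector"


@dataclass(frozen=True)
class Agent:
    """One coplayer: badge id (unique within an episode), color, strategy."""

    id: int
    color: str
    strategy: str

    @property
    def is_cooperator(self) -> bool:
        return self.strategy == COOPERATE

    @property
    def type_index(self) -> int:
        """Canonical partner-type slot of this agent."""
        return (0 if self.color == PURPLE else 2) + (0 if self.is_cooperator else 1)


@dataclass(frozen=True)
class CommunitySpec:
    """Roster recipe: half purple / half teal, half cooperators / defectors.

    ``training_bias`` is the color-strategy correlation ``c``; within
    colors the cooperator fractions are ``rho = (1 + c) / 2`` (purple)
    and ``tau = (1 - c) / 2`` (teal) — the only linear map preserving
    the half/half marginals.  Explicit ``(rho, tau)`` may be given
    instead.
    """

    size: int = 12
    training_bias: float | None = None
    rho: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.size < 2 or self.size % 2:
            raise ValueError("community size must be a positive even integer")
        has_bias = self.training_bias is not None
        has_rt = self.rho is not None or self.tau is not None
        if has_bias == has_rt:
            raise ValueError("give either training_bias or (rho, tau), not both")
        if has_bias and not 0.0 <= self.training_bias <= 1.0:
            raise ValueError("training_bias must lie in [0, 1]")
        if has_rt and (self.rho is None or self.tau is None):
            raise ValueError("rho and tau must be given together")

    def population(self) -> PopulationParams:
        if self.training_bias is not None:
            c = self.training_bias
            return PopulationParams(rho=(1.0 + c) / 2.0, tau=(1.0 - c) / 2.0)
        return PopulationParams(rho=self.rho, tau=self.tau)


@dataclass(frozen=True)
class StagHuntPayoffs:
    """Stag hunt payoff matrix with the ordering R > T >= P > S.

    R: mutual cooperation; S: cooperate against a defector; T: defect
    against a cooperator; P: mutual defection.  The defaults satisfy the
    ordering; the values never enter the discrimination index.
    """

    R: float = 4.0
    T: float = 3.0
    P: float = 3.0
    S: float = 1.0

    def __post_init__(self) -> None:
        if not (self.R > self.T >= self.P > self.S):
            raise ValueError("Stag hunt requires R > T >= P > S")

    def payoff(self, own_coop: bool, other_coop: bool) -> float:
        if own_coop:
            return self.R if other_coop else self.S
        return self.T if other_coop else self.P


# Crown-availability knots: decay beta -> probability the crown survives
# to the next partner-choice phase.  Calibrated to the qualitative decay
# descriptions (gone at the outcome phase, half way through it, half way
# through free mixing, never).
_Q_BETAS = np.array([0.0, 0.002, 0.005, 0.02])
_Q_VALUES = np.array([1.0, 0.75, 0.5, 0.0])


@dataclass(frozen=True)
class InterventionSpec:
    """Perceptual-intervention ("crown") settings.

    ``beta`` is the decay of the crown sprite; ``availability``, when
    given, overrides the default monotone mapping ``q(beta)``.
    ``coop_threshold`` is the cooperation fraction that earns a crown —
    trivially met by unconditional cooperators.
    """

    beta: float = 0.0
    coop_threshold: float = 0.75
    availability: float | None = None

    def __post_init__(self) -> None:
        if self.beta < 0.0:
            raise ValueError("beta must be nonnegative")
        if not 0.0 <= self.coop_threshold <= 1.0:
            raise ValueError("coop_threshold must lie in [0, 1]")
        if self.availability is not None and not 0.0 <= self.availability <= 1.0:
            raise ValueError("availability must lie in [0, 1]")

    @property
    def q(self) -> float:
        """Probability that a crown survives to the next partner choice."""
        if self.availability is not None:
            return self.availability
        return float(np.interp(self.beta, _Q_BETAS, _Q_VALUES))


@dataclass(frozen=True)
class EpisodeConfig:
    """Episode protocol: players, races, payoffs, optional intervention."""

    n_coplayers: int = 5
    n_races: int = 8
    payoffs: StagHuntPayoffs = field(default_factory=StagHuntPayoffs)
    intervention: InterventionSpec | None = None

    def __post_init__(self) -> None:
        if self.n_coplayers < 1 or (self.n_coplayers + 1) % 2:
            raise ValueError("n_coplayers + 1 (total players) must be even")
        if self.n_races < 1:
            raise ValueError("n_races must be positive")


@dataclass
class EpisodeRecord:
    """Everything measured about one episode, race by race."""

    partner_id: list[int | None] = field(default_factory=list)
    partner_type: list[int | None] = field(default_factory=list)
    partner_cooperated: list[bool | None] = field(default_factory=list)
    repaired: list[bool] = field(default_factory=list)
    payoff: list[float] = field(default_factory=list)
    roster: tuple[Agent, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "partner_id": self.partner_id,
            "partner_type": self.partner_type,
            "partner_cooperated": self.partner_cooperated,
            "repaired": self.repaired,
            "payoff": self.payoff,
            "roster": [
                {"id": a.id, "color": a.color, "strategy": a.strategy}
                for a in self.roster
            ],
        }


def make_community(spec: CommunitySpec, rng: np.random.Generator) -> list[Agent]:
    """Build a roster with exact half/half color and strategy counts.

    Within each color the cooperator count is the rounded fraction
    (``rho`` for purple, ``tau`` for teal); the teal count is the
    complement so the strategy marginal stays exactly half/half.  Badge
    ids are a random permutation of ``0..size-1``.
    """
    pop = spec.population()
    n_color = spec.size // 2
    n_pc = int(round(pop.rho * n_color))
    if spec.training_bias is not None:
        # rho + tau = 1 here; the complement keeps the strategy marginal
        # at exactly half the roster
        n_tc = n_color - n_pc
    else:
        n_tc = int(round(pop.tau * n_color))
    if not 0 <= n_tc <= n_color:
        raise ValueError(f"infeasible cooperator counts for size {spec.size}")
    cells = (
        [(PURPLE, COOPERATE)] * n_pc
        + [(PURPLE, DEFECT)] * (n_color - n_pc)
        + [(TEAL, COOPERATE)] * n_tc
        + [(TEAL, DEFECT)] * (n_color - n_tc)
    )
    ids = rng.permutation(spec.size)
    return [
        Agent(id=int(i), color=c, strategy=s)
        for i, (c, s) in zip(ids, cells)
    ]


def focal_choose(
    coplayers: Sequence[Agent],
    prev_partner: Agent | None,
    prev_partner_cooperated: bool,
    flags: set[int] | None,
    focal: FocalParams,
    rng: np.random.Generator,
) -> Agent:
    """Apply the stickiness -> awareness -> color-bias cascade.

    ``flags`` selects the awareness source: ``None`` means oracle mode
    (true cooperators are known); a set of badge ids means intervention
    mode (only crowned agents are known).  An empty known set falls
    through to the color-bias step.
    """
    if not coplayers:
        raise ValueError("empty coplayer roster")
    if prev_partner is not None and prev_partner_cooperated:
        if rng.random() < focal.s:
            return prev_partner
    if focal.omega > 0.0 and rng.random() < focal.omega:
        if flags is None:
            known = [a for a in coplayers if a.is_cooperator]
        else:
            known = [a for a in coplayers if a.id in flags]
        if known:
            return known[rng.integers(len(known))]
    want = PURPLE if rng.random() < focal.b else TEAL
    pool = [a for a in coplayers if a.color == want]
    if not pool:
        pool = [a for a in coplayers if a.color != want]
    return pool[rng.integers(len(pool))]


def _uniform_choose(coplayers: Sequence[Agent], rng: np.random.Generator) -> Agent:
    return coplayers[rng.integers(len(coplayers))]


def run_episode(
    coplayers: Sequence[Agent],
    config: EpisodeConfig,
    focal: FocalParams | None,
    rng: np.random.Generator,
    *,
    mode: Literal["finite", "infinite"] = "finite",
    pop: PopulationParams | None = None,
    policy: Literal["parametric", "uniform"] = "parametric",
) -> EpisodeRecord:
    """Play one episode and record partner identities, actions and payoffs.

    ``policy="uniform"`` replaces the focal cascade with a uniform
    choice among coplayers (the random-baseline focal).  In infinite
    mode the partner's type is drawn from the analytic distributions
    (``pop`` required) and ``coplayers`` is ignored.
    """
    if mode == "infinite":
        if pop is None or focal is None:
            raise ValueError("infinite mode needs focal and population parameters")
        return _run_episode_infinite(config, focal, pop, rng)
    if mode != "finite":
        raise ValueError(f"unknown mode {mode!r}")
    if policy == "parametric" and focal is None:
        raise ValueError("parametric policy needs focal parameters")

    rec = EpisodeRecord(roster=tuple(coplayers))
    ids = {a.id: a for a in coplayers}
    if len(ids) != len(coplayers):
        raise ValueError("badge ids must be unique within the episode")
    flags: set[int] = set()
    interv = config.intervention
    prev: Agent | None = None
    prev_coop = False
    for race in range(config.n_races):
        if policy == "uniform":
            partner = _uniform_choose(coplayers, rng)
        else:
            # Awareness needs observed interactions, so at race 0 the
            # known-cooperator set is empty in every mode and the choice
            # reduces to the color bias, matching the analytic P(0).
            if race == 0:
                known: set[int] | None = set()
            elif interv is not None:
                known = flags
            else:
                known = None
            partner = focal_choose(
                coplayers,
                prev,
                prev_coop,
                known,
                focal,
                rng,
            )
        # remaining coplayers pair uniformly at random among themselves
        rest = [a for a in coplayers if a.id != partner.id]
        rng.shuffle(rest)
        # interaction: focal cooperates; coplayers play their fixed strategy
        p_coop = partner.is_cooperator
        rec.partner_id.append(partner.id)
        rec.partner_type.append(partner.type_index)
        rec.partner_cooperated.append(p_coop)
        rec.repaired.append(prev is not None and partner.id == prev.id)
        rec.payoff.append(config.payoffs.payoff(True, p_coop))
        # outcome: crowns on everyone who cooperated this race, each
        # surviving to the next partner choice with probability q(beta)
        if interv is not None:
            q = interv.q
            flags = {
                a.id
                for a in coplayers
                if a.is_cooperator and rng.random() < q
            }
        prev, prev_coop = partner, p_coop
    return rec


def _run_episode_infinite(
    config: EpisodeConfig,
    focal: FocalParams,
    pop: PopulationParams,
    rng: np.random.Generator,
) -> EpisodeRecord:
    """Infinite-population episode: partner types straight from P(0)/nu."""
    p0 = initial_distribution(focal, pop)
    nu = new_partner_distribution(focal, pop)
    rec = EpisodeRecord()
    fresh = itertools.count()
    ptype = int(rng.choice(4, p=p0))
    pid = next(fresh)
    for r in range(config.n_races):
        if r > 0:
            coop = ptype in (PC, TC)
            if not (coop and rng.random() < focal.s):
                ptype = int(rng.choice(4, p=nu))
                pid = next(fresh)
        rec.partner_id.append(pid)
        rec.partner_type.append(ptype)
        rec.partner_cooperated.append(ptype in (PC, TC))
        rec.repaired.append(r > 0 and rec.partner_id[r - 1] == pid)
        rec.payoff.append(config.payoffs.payoff(True, ptype in (PC, TC)))
    return rec


def episode_rng(seed: int, episode_index: int) -> np.random.Generator:
    """Child generator for one episode; stable under episode-count changes."""
    return np.random.default_rng([seed, episode_index])


def simulate_episodes(
    community: Sequence[Agent],
    config: EpisodeConfig,
    focal: FocalParams | None,
    n_episodes: int,
    seed: int,
    *,
    mode: Literal["finite", "infinite"] = "finite",
    pop: PopulationParams | None = None,
    policy: Literal["parametric", "uniform"] = "parametric",
) -> list[EpisodeRecord]:
    """Run many episodes, each sampling ``n_coplayers`` from the community.

    Each episode gets its own child generator derived from ``seed`` and
    the episode index, so growing ``n_episodes`` never perturbs earlier
    episodes.
    """
    records = []
    n = config.n_coplayers
    for i in range(n_episodes):
        rng = episode_rng(seed, i)
        if mode == "finite":
            if len(community) < n:
                raise ValueError("community smaller than the coplayer sample")
            idx = rng.choice(len(community), size=n, replace=False)
            coplayers = [community[j] for j in idx]
        else:
            coplayers = ()
        records.append(
            run_episode(
                coplayers, config, focal, rng, mode=mode, pop=pop, policy=policy
            )
        )
    return records


def infinite_type_frequencies(
    focal: FocalParams,
    pop: PopulationParams,
    n_episodes: int,
    n_races: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised infinite-mode partner-type counts, shape ``(n_races, 4)``.

    Implements the same per-race transition as infinite-mode
    :func:`run_episode` across all episodes at once: keep a cooperating
    partner with probability ``s``, otherwise redraw the type from
    ``nu``.  Used for large Monte-Carlo cross-checks of the recursion.
    """
    p0 = initial_distribution(focal, pop)
    nu = new_partner_distribution(focal, pop)
    types = rng.choice(4, size=n_episodes, p=p0)
    counts = np.zeros((n_races, 4), dtype=np.int64)
    counts[0] = np.bincount(types, minlength=4)
    for r in range(1, n_races):
        coop = (types % 2) == 0  # even canonical index <=> cooperator
        keep = coop & (rng.random(n_episodes) < focal.s)
        redraw = rng.choice(4, size=n_episodes, p=nu)
        types = np.where(keep, types, redraw)
        counts[r] = np.bincount(types, minlength=4)
    return counts


def effective_awareness(
    base_omega: float, intervention: InterventionSpec | None
) -> float:
    """Awareness once the crown signal is folded in.

    A cooperator is identified either by the focal's own awareness or by
    a surviving crown: ``1 - (1 - omega) * (1 - q(beta))``.  Crowns only
    exist after an interaction, so this applies from race 1 onward;
    race 0 always uses ``base_omega``.
    """
    if not 0.0 <= base_omega <= 1.0:
        raise ValueError("base_omega must lie in [0, 1]")
    if intervention is None:
        return base_omega
    return 1.0 - (1.0 - base_omega) * (1.0 - intervention.q)
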