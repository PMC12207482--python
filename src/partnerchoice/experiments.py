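"""Parameter sweeps and calibration experiments.

Reproduces, at desk scale, the model's headline surfaces: the (s, omega)
contour of the discrimination index averaged over the color bias b, the
training-bias sweep against an unbiased evaluation community, and the
random-choice baselines (awareness 1/2, stickiness 1/5 with five
coplayers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import abm, metrics, model

__all__ = [
    "SweepSpec",
    "SweepResult",
    "contour_sweep",
    "bias_sweep",
    "random_baselines",
    "intervention_trajectory",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid over (s, omega), averaged over a set of b values.

    ``race_index`` selects which P(i) the index is computed from
    (default 8, i.e. after eight recursion steps from P(0));
    ``populations`` defaults to the unbiased evaluation community
    ``rho = tau = 1/2``.  ``mode`` picks the exact recursion
    ("analytic") or the infinite-population Monte-Carlo ("simulated").
    """

    s_grid: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 21))
    omega_grid: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 21))
    b_grid: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 11))
    populations: tuple[model.PopulationParams, ...] = (
        model.PopulationParams(0.5, 0.5),
    )
    race_index: int = 8
    mode: str = "analytic"
    n_episodes: int = 10_000
    n_boot: int = 200

    def __post_init__(self) -> None:
        for name, grid in (("s", self.s_grid), ("omega", self.omega_grid),
                           ("b", self.b_grid)):
            vals = np.asarray(grid, dtype=float)
            if vals.size < 1 or np.any(vals < 0.0) or np.any(vals > 1.0):
                raise ValueError(f"{name}_grid values must lie in [0, 1]")
        if len(self.s_grid) < 2 or len(self.omega_grid) < 2:
            raise ValueError("s and omega grids need at least 2 points")
        if self.race_index < 0:
            raise ValueError("race_index must be nonnegative")
        if self.mode not in ("analytic", "simulated"):
            raise ValueError("mode must be 'analytic' or 'simulated'")


@dataclass(frozen=True)
class SweepResult:
    """Long-format per-(s, omega, b) table plus the b-averaged summary."""

    table: pd.DataFrame
    summary: pd.DataFrame
    spec: SweepSpec
    seed: int | None = None

    def pivot(self, column: str = "mean_d") -> pd.DataFrame:
        """Summary reshaped to an omega-by-s matrix (rows = omega)."""
        return self.summary.pivot(index="omega", columns="s", values=column)


def _cell_d_analytic(
    focal: model.FocalParams, pop: model.PopulationParams, race_index: int
) -> float:
    traj = model.trajectory(focal, pop, race_index)
    return metrics.discrimination_index(traj[race_index])


def _cell_d_simulated(
    focal: model.FocalParams,
    pop: model.PopulationParams,
    race_index: int,
    n_episodes: int,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    n_races = race_index + 1
    counts = abm.infinite_type_frequencies(focal, pop, n_episodes, n_races, rng)
    row = counts[race_index]
    d = metrics.discrimination_index(row / row.sum())
    boot = rng.multinomial(n_episodes, row / row.sum(), size=n_boot)
    boot_d = [metrics.discrimination_index(c / n_episodes) for c in boot]
    return d, float(np.std(boot_d, ddof=1))


def contour_sweep(spec: SweepSpec, seed: int | None = None) -> SweepResult:
    """Discrimination index over the (s, omega) grid, averaged over b.

    Analytic mode is deterministic; simulated mode runs the
    infinite-population Monte-Carlo per cell and reports a bootstrap SE.
    """
    rng = np.random.default_rng(seed) if spec.mode == "simulated" else None
    rows = []
    for s in spec.s_grid:
        for omega in spec.omega_grid:
            for b in spec.b_grid:
                for pop in spec.populations:
                    focal = model.FocalParams(omega=omega, s=s, b=b)
                    if spec.mode == "analytic":
                        d = _cell_d_analytic(focal, pop, spec.race_index)
                        rows.append(
                            {"s": s, "omega": omega, "b": b,
                             "rho": pop.rho, "tau": pop.tau, "d": d}
                        )
                    else:
                        d, se = _cell_d_simulated(
                            focal, pop, spec.race_index,
                            spec.n_episodes, spec.n_boot, rng,
                        )
                        rows.append(
                            {"s": s, "omega": omega, "b": b,
                             "rho": pop.rho, "tau": pop.tau, "d": d, "se": se}
                        )
    table = pd.DataFrame(rows)
    agg = {"mean_d": ("d", "mean")}
    summary = (
        table.groupby(["s", "omega"], as_index=False)
        .agg(**agg)
        .sort_values(["s", "omega"], ignore_index=True)
    )
    if spec.mode == "simulated":
        se = (
            table.groupby(["s", "omega"], as_index=False)
            .agg(se=("se", lambda v: float(np.sqrt(np.mean(np.square(v))))))
        )
        summary = summary.merge(se, on=["s", "omega"])
    return SweepResult(table=table, summary=summary, spec=spec, seed=seed)


def intervention_trajectory(
    focal: model.FocalParams,
    pop: model.PopulationParams,
    intervention: abm.InterventionSpec | None,
    n_iters: int,
) -> list[np.ndarray]:
    """Analytic trajectory with the crown folded into awareness.

    The crown raises awareness to ``1 - (1 - omega)(1 - q(beta))`` from
    race 1 onward; P(0) is independent of awareness, so the whole
    trajectory is the plain recursion at the effective awareness —
    race 0 is untouched by construction.
    """
    omega_eff = abm.effective_awareness(focal.omega, intervention)
    boosted = model.FocalParams(omega=omega_eff, s=focal.s, b=focal.b)
    return model.trajectory(boosted, pop, n_iters)


def bias_sweep(
    biases: list[float],
    focal: model.FocalParams,
    n_episodes: int,
    config: abm.EpisodeConfig,
    seed: int,
    community_size: int = 12,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Per-race D (with bootstrap CIs) against the unbiased community.

    For each training bias ``c`` the focal keeps its (omega, s) but its
    color bias is set to ``b = (1 + c) / 2`` — the same linear map that
    sends ``c`` to the training-community (rho, tau).  Evaluation always
    uses a zero-correlation community.
    """
    eval_spec = abm.CommunitySpec(size=community_size, training_bias=0.0)
    rows = []
    for k, c in enumerate(biases):
        if not 0.0 <= c <= 1.0:
            raise ValueError("training bias must lie in [0, 1]")
        focal_c = model.FocalParams(
            omega=focal.omega, s=focal.s, b=(1.0 + c) / 2.0
        )
        rng = np.random.default_rng([seed, k])
        community = abm.make_community(eval_spec, rng)
        records = abm.simulate_episodes(
            community, config, focal_c, n_episodes, seed=int(rng.integers(2**31))
        )
        trace = metrics.discrimination_trace(records, n_boot=n_boot, rng=rng)
        for r in range(config.n_races):
            rows.append(
                {
                    "bias": c,
                    "race_index": r,
                    "d": trace.d[r],
                    "ci_low": trace.ci_low[r],
                    "ci_high": trace.ci_high[r],
                    "n_episodes": n_episodes,
                }
            )
    return pd.DataFrame(rows)


def random_baselines(
    config: abm.EpisodeConfig,
    n_episodes: int,
    seed: int,
    community_size: int = 12,
) -> metrics.EmpiricalBehavior:
    """Awareness/stickiness of a uniform-random focal in an unbiased community.

    With five coplayers and a balanced community the analytic targets
    are awareness 1/2 and stickiness 1/5.
    """
    spec = abm.CommunitySpec(size=community_size, training_bias=0.0)
    community = abm.make_community(spec, np.random.default_rng([seed, 2**30]))
    records = abm.simulate_episodes(
        community, config, focal=None, n_episodes=n_episodes,
        seed=seed, policy="uniform",
    )
    return metrics.empirical_behavior(records)
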