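"""Discrimination index and behavioral estimators.

The association distribution ``P`` over the four partner types can be
read as a 2x2 matrix (rows = color, columns = strategy).  The
discrimination index contrasts association by behavior with association
by color:

    D = (|P_pc - P_pd| + |P_tc - P_td|) - (|P_pc - P_tc| + |P_pd - P_td|)

``D > 0``: the focal sorts partners by what they do; ``D < 0``: by what
they look like; ``D = 0``: neither a row nor a column dominates
element-wise.  D always lies in [-1, 1].

Episode records from the simulator are tallied into per-race association
counts, from which pooled per-race D values and percentile-bootstrap
confidence intervals (episode-level resampling) are computed, together
with the empirical awareness / stickiness estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import PC, PD, TC, TD, as_distribution

__all__ = [
    "discrimination_index",
    "AssociationTally",
    "tally_from_episodes",
    "DiscriminationTrace",
    "discrimination_trace",
    "EmpiricalBehavior",
    "empirical_behavior",
    "bootstrap_ci",
]


def discrimination_index(P) -> float:
    """Behavior-association minus color-association of a type distribution."""
    P = as_distribution(P)
    by_behavior = abs(P[PC] - P[PD]) + abs(P[TC] - P[TD])
    by_color = abs(P[PC] - P[TC]) + abs(P[PD] - P[TD])
    return float(by_behavior - by_color)


def _counts_d(counts: np.ndarray) -> float:
    """D of a raw count vector; NaN when the race had no paired episodes."""
    total = counts.sum()
    if total == 0:
        return float("nan")
    return discrimination_index(counts / total)


@dataclass(frozen=True)
class AssociationTally:
    """Partner-type counts per race, aggregated across episodes.

    ``counts`` has shape ``(n_races, 4)`` in canonical type order; races
    in which the focal had no partner do not contribute to that race's
    row, so row sums may differ across races.
    """

    counts: np.ndarray
    n_races: int

    def distributions(self) -> np.ndarray:
        """Row-normalised association proportions (NaN rows where empty)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    def discrimination(self) -> np.ndarray:
        """Pooled discrimination index per race index."""
        return np.array([_counts_d(row) for row in self.counts])


def _episode_counts(records: Sequence) -> np.ndarray:
    """Per-episode one-hot tallies, shape ``(n_episodes, n_races, 4)``."""
    if not records:
        return np.zeros((0, 0, 4), dtype=np.int64)
    n_races = len(records[0].partner_type)
    out = np.zeros((len(records), n_races, 4), dtype=np.int64)
    for e, rec in enumerate(records):
        if len(rec.partner_type) != n_races:
            raise ValueError(
                "episode records disagree on the number of races: "
                f"{len(rec.partner_type)} != {n_races}"
            )
        for r, t in enumerate(rec.partner_type):
            if t is not None:
                out[e, r, t] = 1
    return out


def tally_from_episodes(records: Sequence) -> AssociationTally:
    """Aggregate per-race partner-type counts across episode records."""
    per_ep = _episode_counts(records)
    n_races = per_ep.shape[1]
    return AssociationTally(counts=per_ep.sum(axis=0), n_races=n_races)


@dataclass(frozen=True)
class DiscriminationTrace:
    """Pooled per-race D with episode-level bootstrap confidence intervals."""

    d: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    n_episodes: int
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "race_index": np.arange(len(self.d)),
                "d": self.d,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_episodes": self.n_episodes,
            }
        )


def discrimination_trace(
    records: Sequence,
    n_boot: int = 5000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> DiscriminationTrace:
    """Pooled per-race D with percentile-bootstrap CIs.

    The point estimate pools counts across episodes; the bootstrap
    resamples whole episodes with replacement (multinomial weighting,
    which is equivalent and avoids materialising the resamples).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 episodes to bootstrap")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    per_ep = _episode_counts(records)  # (E, R, 4)
    n_ep, n_races, _ = per_ep.shape
    pooled = AssociationTally(per_ep.sum(axis=0), n_races)
    d = pooled.discrimination()

    flat = per_ep.reshape(n_ep, n_races * 4).astype(float)
    weights = rng.multinomial(n_ep, np.full(n_ep, 1.0 / n_ep), size=n_boot)
    boot_counts = (weights @ flat).reshape(n_boot, n_races, 4)
    boot_d = np.empty((n_boot, n_races))
    for i in range(n_boot):
        for r in range(n_races):
            boot_d[i, r] = _counts_d(boot_counts[i, r])
    lo = (1.0 - level) / 2.0
    ci_low = np.nanquantile(boot_d, lo, axis=0)
    ci_high = np.nanquantile(boot_d, 1.0 - lo, axis=0)
    return DiscriminationTrace(
        d=d, ci_low=ci_low, ci_high=ci_high, n_boot=n_boot,
        n_episodes=n_ep, level=level,
    )


@dataclass(frozen=True)
class EmpiricalBehavior:
    """Observed awareness and stickiness proportions.

    ``awareness_hat``: fraction of partnered races whose partner is a
    cooperator.  ``stickiness_hat``: fraction of consecutive partnered
    race pairs in which the focal kept the same partner.  The count
    fields hold the denominators actually used.
    """

    awareness_hat: float
    stickiness_hat: float
    n_awareness: int = 0
    n_stickiness: int = 0
    n_episodes: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "awareness_hat": [self.awareness_hat],
                "stickiness_hat": [self.stickiness_hat],
                "n_episodes": [self.n_episodes],
            }
        )


def empirical_behavior(records: Sequence) -> EmpiricalBehavior:
    """Estimate awareness and stickiness from episode records.

    Races without a partner drop out of the awareness denominator; a
    consecutive race pair enters the stickiness denominator only when
    both races had a partner.
    """
    if not records:
        raise ValueError("empty episode sequence")
    coop = part = same = pairs = 0
    for rec in records:
        ids = rec.partner_id
        types = rec.partner_type
        for r, t in enumerate(types):
            if t is None:
                continue
            part += 1
            if t in (PC, TC):
                coop += 1
            if r >= 1 and ids[r - 1] is not None:
                pairs += 1
                if ids[r] == ids[r - 1]:
                    same += 1
    return EmpiricalBehavior(
        awareness_hat=coop / part if part else float("nan"),
        stickiness_hat=same / pairs if pairs else float("nan"),
        n_awareness=part,
        n_stickiness=pairs,
        n_episodes=len(records),
    )


def bootstrap_ci(
    per_episode_d: Iterable[float],
    n_boot: int = 5000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap interval for the mean of per-episode D values."""
    values = np.asarray(list(per_episode_d), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return float(np.quantile(means, lo)), float(np.quantile(means, 1.0 - lo))
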