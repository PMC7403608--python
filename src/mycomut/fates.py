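"""Temporal fate of called mutations across sampling points.

Each called mutation has a frequency trajectory ordered by mycelium
length at sampling.  Fates form a three-way partition:

* ``fixed`` — the frequency reaches the fixation threshold (default 0.90,
  "all or nearly all reads") at some point and stays at or above it at
  every later non-missing point, through the last;
* ``reached_lost`` — the frequency exceeded the reach threshold (default
  0.70) at some point but the mutation is not fixed;
* ``never_reached`` — the frequency never exceeded the reach threshold.

Trajectories ending above the loss threshold without sustaining the
fixation threshold are still ``reached_lost`` (the partition has no
fourth class) but are flagged ``unresolved`` so borderline calls can be
audited.  Missing frequencies (zero depth) are skipped, not interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

FATES = ("never_reached", "reached_lost", "fixed")


@dataclass(frozen=True)
class Trajectory:
    """A mutation's frequency ordered by mycelium length at sampling."""

    mutation_id: str
    lengths_m: tuple[float, ...]
    frequencies: tuple[float, ...]  # NaN = missing (zero depth)

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.lengths_m, self.lengths_m[1:])):
            raise ValueError("sampling lengths must be strictly increasing")
        for f in self.frequencies:
            if not math.isnan(f) and not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} outside [0, 1]")
        if len(self.lengths_m) != len(self.frequencies):
            raise ValueError("lengths and frequencies differ in size")

    def observed(self) -> list[tuple[int, float]]:
        return [(i, f) for i, f in enumerate(self.frequencies) if not math.isnan(f)]


@dataclass(frozen=True)
class FateConfig:
    reach_threshold: float = 0.70
    fix_threshold: float = 0.90
    loss_threshold: float = 0.70

    def __post_init__(self):
        if not 0.0 < self.loss_threshold <= self.reach_threshold:
            raise ValueError("need 0 < loss_threshold <= reach_threshold")
        if not self.reach_threshold <= self.fix_threshold <= 1.0:
            raise ValueError("need reach_threshold <= fix_threshold <= 1")


@dataclass(frozen=True)
class FateCall:
    mutation_id: str
    fate: str
    first_reach_index: int | None
    unresolved: bool = False


def classify_fate(traj: Trajectory, config: FateConfig | None = None) -> FateCall:
    """Assign one of the three fates to a trajectory.

    Requires at least two non-missing points; raises ``ValueError``
    otherwise.
    """
    if config is None:
        config = FateConfig()
    obs = traj.observed()
    if len(obs) < 2:
        raise ValueError(
            f"trajectory {traj.mutation_id}: need >=2 observed frequencies"
        )
    freqs = [f for _, f in obs]
    max_f = max(freqs)
    final_f = freqs[-1]

    first_reach = None
    for i, f in obs:
        if f >= config.reach_threshold:
            first_reach = i
            break

    # fixed: >= fix_threshold sustained from some point through the last
    # observed point, which reduces to the last observed point itself
    if final_f >= config.fix_threshold:
        return FateCall(traj.mutation_id, "fixed", first_reach)
    if max_f > config.reach_threshold:
        unresolved = final_f >= config.loss_threshold
        return FateCall(traj.mutation_id, "reached_lost", first_reach,
                        unresolved=unresolved)
    return FateCall(traj.mutation_id, "never_reached", first_reach)


def accumulation_curve(trajectories: list[Trajectory],
                       config: FateConfig | None = None) -> pd.DataFrame:
    """Count mutations at or above the reach threshold at each sampling point.

    All trajectories must share one sampling grid.  Returns a frame with
    columns ``length_m`` and ``n_reached``.
    """
    if config is None:
        config = FateConfig()
    if not trajectories:
        return pd.DataFrame({"length_m": [], "n_reached": []})
    grid = trajectories[0].lengths_m
    for t in trajectories[1:]:
        if t.lengths_m != grid:
            raise ValueError("trajectories do not share a sampling grid")
    counts = []
    for i, length in enumerate(grid):
        n = sum(
            1 for t in trajectories
            if not math.isnan(t.frequencies[i])
            and t.frequencies[i] >= config.reach_threshold
        )
        counts.append((length, n))
    return pd.DataFrame(counts, columns=["length_m", "n_reached"])


def trajectories_from_calls(calls, line_id: str | None = None) -> list[Trajectory]:
    """Build trajectories from :class:`~mycomut.calling.VariantCall` records."""
    out = []
    for c in calls:
        mid = f"{line_id or 'var'}:{c.position}:{c.alt_allele}"
        out.append(Trajectory(
            mutation_id=mid,
            lengths_m=tuple(c.sampling_lengths_m),
            frequencies=tuple(c.frequencies),
        ))
    return out


FATE_LABELS = {
    "never_reached": "Never reached frequency of 70%",
    "reached_lost": "Reached frequency of 70% but then lost",
    "fixed": "Fixed",
}
TYPE_ORDER = ("nonsense", "nonsynonymous", "synonymous", "frameshift",
              "intronic", "other_noncoding")


def tabulate_fates_and_types(records: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of mutation counts by fate and by type.

    ``records`` needs one row per mutation with columns ``fate``,
    ``effect``, ``founder`` and ``tube``.  The result has one column per
    (tube, founder) group plus a grand-total column; rows are the group
    total, the three fates, and the six effect types.  Fate rows and type
    rows each sum to the per-group totals.
    """
    required = {"fate", "effect", "founder", "tube"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")

    tubes = sorted(records["tube"].unique()) if len(records) else []
    founders = sorted(records["founder"].unique()) if len(records) else []
    group_cols = [f"{t}:{f}" for t in tubes for f in founders]

    index = ["total", *FATES, *TYPE_ORDER]
    table = pd.DataFrame(0, index=index, columns=[*group_cols, "total"])
    if not len(records):
        return table

    for (t, f), grp in records.groupby(["tube", "founder"]):
        col = f"{t}:{f}"
        table.loc["total", col] = len(grp)
        for fate, n in grp["fate"].value_counts().items():
            table.loc[fate, col] = n
        for eff, n in grp["effect"].value_counts().items():
            table.loc[eff, col] = n
    table["total"] = table[group_cols].sum(axis=1)
    return table
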