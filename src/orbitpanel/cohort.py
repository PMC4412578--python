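"""Population-level analytics over sets of orbits.

Capacity counts how many orbits occupy each state at each time; density
accumulates transition counts between ordered state pairs (including
idle self-transitions).  Region visit percentages, cluster and hole
detection summarize where a cohort lives in S_p: a *cluster* is a
depth-1 region (leading significant variable + its answer) holding a
large share of all orbit points, signalling a stable variable; a *hole*
is a region never visited, signalling a volatile leading variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import Orbit, edge_class
from .errors import CompletenessError, DimensionError, StratificationError
from .panel_io import BinaryPanel
from .space import Region, State, fitness_value

__all__ = [
    "CapacityTable",
    "DensityTable",
    "capacity_table",
    "density_table",
    "region_percentages",
    "find_holes",
    "find_clusters",
    "unfavourable_percentages",
    "population_change_frequencies",
    "stratify",
    "fitness_label",
    "group_proportion_by_fitness",
]


def _check_shared_shape(orbits: Sequence[Orbit]) -> tuple[int, int]:
    ps = {o.p for o in orbits}
    Ts = {o.T for o in orbits}
    if len(ps) > 1 or len(Ts) > 1:
        raise DimensionError(
            f"orbits mix dimensions: p in {sorted(ps)}, T in {sorted(Ts)}"
        )
    return ps.pop(), Ts.pop()


@dataclass(frozen=True)
class CapacityTable:
    """c[s, t] — number of orbits at state s at time t.

    ``counts`` is indexed by canonical state index (visited states
    only) with one column per time; ``n`` is the cohort size, so each
    column sums to n.
    """

    counts: pd.DataFrame = field(repr=False)
    n: int
    p: int

    def accumulated(self) -> pd.Series:
        """Total visits per state over all times (histogram heights)."""
        return self.counts.sum(axis=1)

    def filtered(self, threshold: int) -> pd.DataFrame:
        """Reporting filter: states whose capacity reaches ``threshold``
        at some time.  The stored table is never altered."""
        return self.counts[(self.counts >= threshold).any(axis=1)]


@dataclass(frozen=True)
class DensityTable:
    """d(s, s') — accumulated transition counts as an edge list.

    Columns: ``from_index, to_index, count, color``; self-transitions
    are the idle (blue) edges.  Counts sum to n*T.
    """

    edges: pd.DataFrame = field(repr=False)
    n: int
    T: int
    p: int

    @property
    def total(self) -> int:
        return int(self.edges["count"].sum())

    def filtered(self, threshold: int) -> pd.DataFrame:
        """Reporting filter: pairs with count >= threshold."""
        return self.edges[self.edges["count"] >= threshold]


def capacity_table(orbits: Sequence[Orbit]) -> CapacityTable:
    """Exact occupancy counts c[s, t] for a cohort of orbits."""
    orbits = list(orbits)
    if not orbits:
        raise DimensionError("capacity of an empty cohort is undefined")
    p, T = _check_shared_shape(orbits)
    counts: dict[int, np.ndarray] = {}
    for o in orbits:
        for t, s in enumerate(o.states):
            row = counts.setdefault(s.index, np.zeros(T + 1, dtype=int))
            row[t] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=range(T + 1))
    frame = frame.sort_index()
    frame.index.name = "state_index"
    return CapacityTable(frame, n=len(orbits), p=p)


def density_table(orbits: Sequence[Orbit]) -> DensityTable:
    """Accumulated transition counts d(s, s') over all subjects and times."""
    orbits = list(orbits)
    if not orbits:
        return DensityTable(
            pd.DataFrame(columns=["from_index", "to_index", "count", "color"]),
            n=0, T=0, p=0,
        )
    p, T = _check_shared_shape(orbits)
    counts: dict[tuple[State, State], int] = {}
    for o in orbits:
        for s, s2 in zip(o.states, o.states[1:]):
            counts[(s, s2)] = counts.get((s, s2), 0) + 1
    rows = [
        {
            "from_index": s.index,
            "to_index": s2.index,
            "count": c,
            "color": edge_class(s, s2),
        }
        for (s, s2), c in counts.items()
    ]
    edges = pd.DataFrame(rows, columns=["from_index", "to_index", "count", "color"])
    edges = edges.sort_values(["from_index", "to_index"]).reset_index(drop=True)
    return DensityTable(edges, n=len(orbits), T=T, p=p)


def _depth_regions(p: int, depth: int) -> list[Region]:
    regions = []
    for sig in permutations(range(p), depth):
        for fit in product((0, 1), repeat=depth):
            regions.append(Region(sig, fit))
    return regions


def region_percentages(orbits: Sequence[Orbit], depth: int = 1) -> pd.DataFrame:
    """Share of all orbit points falling in each depth-k region.

    The denominator is the total number of orbit points n*(T+1); the
    regions at a given depth partition S_p, so percentages sum to 100.
    Columns: ``region, sig_prefix, fit_prefix, visits, percent``.
    """
    orbits = list(orbits)
    if not orbits:
        raise DimensionError("region percentages of an empty cohort are undefined")
    p, T = _check_shared_shape(orbits)
    if not 0 <= depth <= p:
        raise DimensionError(f"depth {depth} outside [0, p={p}]")
    visits: dict[tuple[tuple, tuple], int] = {}
    for o in orbits:
        for s in o.states:
            key = (s.order[:depth], s.bits[:depth])
            visits[key] = visits.get(key, 0) + 1
    total = len(orbits) * (T + 1)
    rows = []
    for region in _depth_regions(p, depth):
        v = visits.get((region.sig_prefix, region.fit_prefix), 0)
        rows.append(
            {
                "region": region.label(p),
                "sig_prefix": "".join(map(str, region.sig_prefix)),
                "fit_prefix": "".join(map(str, region.fit_prefix)),
                "visits": v,
                "percent": 100.0 * v / total,
            }
        )
    return pd.DataFrame(rows)


def find_holes(orbits: Sequence[Orbit]) -> set[Region]:
    """Depth-1 regions that no orbit ever visits."""
    table = region_percentages(orbits, depth=1)
    return {
        Region((int(r.sig_prefix),), (int(r.fit_prefix),))
        for r in table.itertuples()
        if r.visits == 0
    }


def find_clusters(orbits: Sequence[Orbit], min_share: float = 0.10) -> dict[Region, float]:
    """Depth-1 regions holding at least ``min_share`` of all orbit points.

    The threshold is a tunable screening device (clusters are a visual
    notion); the share of each detected cluster is returned with it.
    """
    table = region_percentages(orbits, depth=1)
    return {
        Region((int(r.sig_prefix),), (int(r.fit_prefix),)): r.percent / 100.0
        for r in table.itertuples()
        if r.percent / 100.0 >= min_share
    }


def unfavourable_percentages(panel: BinaryPanel) -> pd.Series:
    """Percent of 0 (unfavourable) responses per variable, over all
    n*(T+1) observation points."""
    zeros = (panel.values == 0).sum(axis=(0, 2))
    share = 100.0 * zeros / (panel.n * (panel.T + 1))
    return pd.Series(share, index=list(panel.variables), name="percent_unfavourable")


def population_change_frequencies(panel: BinaryPanel) -> pd.Series:
    """Total answer-change counts per variable, summed over subjects."""
    flips = np.abs(np.diff(panel.values.astype(int), axis=2)).sum(axis=(0, 2))
    return pd.Series(flips, index=list(panel.variables), name="change_frequency")


def stratify(
    panel: BinaryPanel, strata: pd.DataFrame | Mapping[str, object]
) -> dict[str, BinaryPanel]:
    """Split a panel into disjoint sub-panels by constant subject attributes.

    ``strata`` maps subject_id to one or more attributes (a DataFrame
    indexed by subject_id, or a plain mapping to labels).  Multi-column
    attributes are joined with '/' to form the stratum label.  Every
    panel subject must be labelled; orbits are then computed per
    stratum, so there are no transitions between strata.
    """
    if isinstance(strata, pd.DataFrame):
        labels = {
            str(idx): "/".join(str(v) for v in row)
            for idx, row in zip(strata.index, strata.to_numpy())
        }
    else:
        labels = {str(k): str(v) for k, v in strata.items()}
    missing = [s for s in panel.subject_ids if s not in labels]
    if missing:
        raise StratificationError(
            f"{len(missing)} subjects without stratum label, e.g. {missing[:3]}"
        )
    groups: dict[str, list[str]] = {}
    for s in panel.subject_ids:
        groups.setdefault(labels[s], []).append(s)
    return {label: panel.subset(ids) for label, ids in groups.items()}


def fitness_label(bits: Sequence[int]) -> int:
    """1-based label of a fitness string in ascending lexicographic
    order: 00...0 -> 1, 11...1 -> 2^p."""
    return fitness_value(bits) + 1


def group_proportion_by_fitness(
    panel: BinaryPanel,
    group_flag: Mapping[str, int] | pd.Series,
    times: Sequence | None = None,
) -> pd.DataFrame:
    """Proportion of flagged subjects at each (fitness label, time) cell.

    Answers are read in the fixed variable order 0..p-1 (no significance
    permutation) and mapped to their fitness label; at each time the
    proportion of subjects with flag = 1 among those at the label is
    reported.  Cells with no subjects are NaN (absent).
    """
    flags = {str(k): int(v) for k, v in dict(group_flag).items()}
    bad = [v for v in flags.values() if v not in (0, 1)]
    if bad:
        raise DimensionError(f"group flags must be 0/1, got {bad[:3]}")
    missing = [s for s in panel.subject_ids if s not in flags]
    if missing:
        raise CompletenessError(
            f"{len(missing)} subjects without group flag, e.g. {missing[:3]}"
        )
    if times is None:
        times = panel.times
    tpos = {t: i for i, t in enumerate(panel.times)}
    unknown = [t for t in times if t not in tpos]
    if unknown:
        raise DimensionError(f"times {unknown} not observed in panel")
    table = pd.DataFrame(
        np.nan, index=range(1, 2**panel.p + 1), columns=list(times)
    )
    table.index.name = "fitness_label"
    for t in times:
        at_label: dict[int, list[int]] = {}
        for l, sid in enumerate(panel.subject_ids):
            label = fitness_label(panel.values[l, :, tpos[t]])
            at_label.setdefault(label, []).append(flags[sid])
        for label, fl in at_label.items():
            table.loc[label, t] = float(np.mean(fl))
    return table.dropna(how="all")
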