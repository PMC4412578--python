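"""Per-subject orbit construction: frequencies, initial placement, transitions.

A subject observed at times t = 0..T on p binary variables traces a
walk (its *orbit*) on the change space S_p.  The initial significance
order ranks variables by how often they change over the whole series
(stable variables left / most significant); afterwards the order is
rearranged dynamically: whenever a set of variables changes answer, the
swap-and-flip rule moves them to the rightmost significance positions
and negates their fitness digits.  The encoding is lossless — the raw
series is recovered exactly by un-permuting each fitness string by its
significance order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CodingError,
    CompletenessError,
    DimensionError,
    OrbitCorruptionError,
)
from .space import State, apply_change

__all__ = [
    "SubjectSeries",
    "Orbit",
    "change_frequencies",
    "initial_significance",
    "initial_state",
    "step",
    "edge_class",
    "encode_orbit",
    "decode_orbit",
    "encode_panel",
    "orbits_to_frame",
    "orbits_from_frame",
]

#: edge colors: red = fitness decreases, green = increases, blue = unchanged
RED, GREEN, BLUE = "red", "green", "blue"


@dataclass(frozen=True)
class SubjectSeries:
    """Complete binary answers of one subject: ``answers[i, t]`` for
    variable i = 0..p-1 and time t = 0..T."""

    subject_id: str
    answers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.answers)
        if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
            raise DimensionError(
                f"answers must be a (p, T+1) matrix, got shape {a.shape}"
            )
        if np.isnan(a.astype(float)).any():
            raise CompletenessError(
                f"subject {self.subject_id!r} has missing observations"
            )
        if not np.isin(a, (0, 1)).all():
            bad = a[~np.isin(a, (0, 1))][0]
            raise CodingError(
                f"subject {self.subject_id!r} has non-binary value {bad!r}"
            )
        object.__setattr__(self, "answers", a.astype(np.int8))

    @property
    def p(self) -> int:
        return self.answers.shape[0]

    @property
    def T(self) -> int:
        return self.answers.shape[1] - 1

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SubjectSeries)
            and self.subject_id == other.subject_id
            and np.array_equal(self.answers, other.answers)
        )


@dataclass(frozen=True)
class Orbit:
    """The state sequence of one subject with classified edges.

    ``states[t]`` is the point occupied at time t; ``edges[t]`` colors
    the transition t -> t+1 (red: fitness decreased, green: increased,
    blue: same fitness).
    """

    subject_id: str
    states: tuple[State, ...]
    edges: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.states) - 1:
            raise DimensionError(
                f"{len(self.states)} states need {len(self.states) - 1} edges, "
                f"got {len(self.edges)}"
            )

    @property
    def p(self) -> int:
        return self.states[0].p

    @property
    def T(self) -> int:
        return len(self.states) - 1

    @property
    def indices(self) -> tuple[int, ...]:
        """Canonical state indices along the orbit."""
        return tuple(s.index for s in self.states)


def change_frequencies(series: SubjectSeries) -> np.ndarray:
    """Per-variable change counts f_i = #{t : a[i,t] != a[i,t+1]}."""
    a = series.answers
    return np.abs(np.diff(a.astype(int), axis=1)).sum(axis=1)


def initial_significance(
    f_subject: Sequence[int], f_population: Sequence[int] | None = None
) -> tuple[int, ...]:
    """Initial question order: variables sorted by ascending change count.

    Subject-level counts rank first; population-level counts break
    subject ties; the ascending variable index breaks remaining ties.
    When no population counts are supplied they default to zero, so
    subject ties fall through to the variable index.
    """
    f_subject = np.asarray(f_subject)
    p = len(f_subject)
    if f_population is None:
        f_population = np.zeros(p, dtype=int)
    f_population = np.asarray(f_population)
    if len(f_population) != p:
        raise DimensionError(
            f"population frequencies have length {len(f_population)}, expected {p}"
        )
    return tuple(
        sorted(range(p), key=lambda i: (f_subject[i], f_population[i], i))
    )


def initial_state(
    series: SubjectSeries, f_population: Sequence[int] | None = None
) -> State:
    """Initial point of the orbit: t=0 answers permuted into the initial order."""
    order = initial_significance(change_frequencies(series), f_population)
    bits = tuple(int(series.answers[v, 0]) for v in order)
    return State(bits, order)


def step(state: State, changed: Iterable[int]) -> State:
    """Swap-and-flip transition (re-export of the S_p rule).

    Changed variables move to the rightmost significance positions (in
    reverse of their previous position order) and their fitness digits
    are negated; an empty change set is the idle transition.
    """
    return apply_change(state, changed)


def edge_class(s: State, s_next: State) -> str:
    """Color of the edge s -> s_next by the move along the fitness axis."""
    v0, v1 = s.value, s_next.value
    if v1 < v0:
        return RED
    if v1 > v0:
        return GREEN
    return BLUE


def encode_orbit(
    series: SubjectSeries, f_population: Sequence[int] | None = None
) -> Orbit:
    """Encode a complete subject series as its orbit in S_p."""
    states = [initial_state(series, f_population)]
    a = series.answers
    for t in range(series.T):
        changed = np.nonzero(a[:, t] != a[:, t + 1])[0]
        states.append(apply_change(states[-1], changed))
    edges = tuple(edge_class(s, s2) for s, s2 in zip(states, states[1:]))
    return Orbit(series.subject_id, tuple(states), edges)


def decode_orbit(orbit: Orbit) -> SubjectSeries:
    """Exact inverse of :func:`encode_orbit`.

    Un-permutes each fitness string by its significance order and
    verifies that consecutive states are related by the transition rule
    for the implied change set (otherwise the orbit is corrupt).
    """
    p = orbit.p
    answers = np.empty((p, orbit.T + 1), dtype=np.int8)
    for t, s in enumerate(orbit.states):
        for v, b in zip(s.order, s.bits):
            answers[v, t] = b
    for t in range(orbit.T):
        changed = np.nonzero(answers[:, t] != answers[:, t + 1])[0]
        if apply_change(orbit.states[t], changed) != orbit.states[t + 1]:
            raise OrbitCorruptionError(
                f"orbit {orbit.subject_id!r}: states at t={t} and t={t + 1} "
                "are not related by the transition rule"
            )
    return SubjectSeries(orbit.subject_id, answers)


def encode_panel(panel, f_population: Sequence[int] | None = None) -> list[Orbit]:
    """Encode every subject of a panel.

    Population change counts (used only for tie-breaking the initial
    orders) default to the totals of the panel itself, so when called on
    a stratum the tie-break is stratum-local.
    """
    series = [panel.subject(l) for l in panel.subject_ids]
    if f_population is None:
        f_population = np.sum([change_frequencies(s) for s in series], axis=0)
    return [encode_orbit(s, f_population) for s in series]


def orbits_to_frame(orbits: Iterable[Orbit]) -> pd.DataFrame:
    """Serialize orbits as a table.

    Columns (in order): ``subject_id, t, x, y, state_index, edge_color``
    where ``x``/``y`` are digit strings and ``edge_color`` colors the
    transition leaving time t (empty on the last row of each subject).
    """
    rows = []
    for o in orbits:
        for t, s in enumerate(o.states):
            rows.append(
                {
                    "subject_id": o.subject_id,
                    "t": t,
                    "x": "".join(map(str, s.bits)),
                    "y": "".join(map(str, s.order)),
                    "state_index": s.index,
                    "edge_color": o.edges[t] if t < o.T else "",
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "t", "x", "y", "state_index", "edge_color"]
    )


def orbits_from_frame(frame: pd.DataFrame) -> list[Orbit]:
    """Rebuild orbits from the serialized table (bit-exact round trip)."""
    orbits = []
    for subject_id, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("t")
        states = tuple(
            State.from_strings(str(x), str(y)) for x, y in zip(grp["x"], grp["y"])
        )
        edges = tuple(str(c) for c in grp["edge_color"][:-1])
        orbits.append(Orbit(str(subject_id), states, edges))
    return orbits
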