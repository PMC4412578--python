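"""The change space S_p: fitness states x significance permutations.

A binary panel in p variables is encoded per subject as a walk on the
change space

    S_p = X_p x Y_p,   |S_p| = 2**p * p!

where ``X_p`` is the set of length-p binary strings (*fitness states*,
leftmost digit most significant) and ``Y_p`` the set of permutations of
the variable indices (*significance states*, ranking variables from
least frequently changing on the left to most frequently changing on the
right).  Each state carries a canonical 1-based index that scans the
space left to right, top to bottom: rows are significance permutations
in descending lexicographic order (so the row of ``y = 01...(p-1)`` is
the bottom one), columns are fitness strings in ascending binary order.
The closed form is

    index(x, y) = (p! - 1 - lex_rank(y)) * 2**p + value(x) + 1.

The row orientation is not stated in prose anywhere; it is pinned down
by the worked-example indices it must reproduce (see the package docs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations, product
from typing import Iterable, Iterator, Sequence

from .errors import BoundsError, DimensionError, SizeError

#: largest p for which the full space is enumerated (2^8 * 8! ~ 10.3e6)
MAX_ENUM_P = 8

__all__ = [
    "MAX_ENUM_P",
    "State",
    "Region",
    "ChangeSpace",
    "fitness_value",
    "perm_lex_rank",
    "perm_lex_unrank",
    "state_index",
    "index_to_state",
    "apply_change",
    "admissible_successors",
    "region_states",
    "build_space",
]


def fitness_value(bits: Sequence[int]) -> int:
    """Integer denoted by a fitness string, leftmost digit most significant."""
    value = 0
    for b in bits:
        if b not in (0, 1):
            raise DimensionError(f"fitness digit must be 0 or 1, got {b!r}")
        value = (value << 1) | b
    return value


def perm_lex_rank(order: Sequence[int]) -> int:
    """0-based lexicographic rank of a permutation of 0..p-1.

    The identity order ``01...(p-1)`` has rank 0 and ``(p-1)...10`` has
    rank p!-1.
    """
    p = len(order)
    if sorted(order) != list(range(p)):
        raise DimensionError(f"{order!r} is not a permutation of 0..{p - 1}")
    available = list(range(p))
    rank = 0
    for pos, v in enumerate(order):
        j = available.index(v)
        rank += j * math.factorial(p - 1 - pos)
        available.pop(j)
    return rank


def perm_lex_unrank(rank: int, p: int) -> tuple[int, ...]:
    """Inverse of :func:`perm_lex_rank`."""
    if not 0 <= rank < math.factorial(p):
        raise BoundsError(f"rank {rank} outside [0, {p}!-1]")
    available = list(range(p))
    order = []
    for pos in range(p):
        f = math.factorial(p - 1 - pos)
        j, rank = divmod(rank, f)
        order.append(available.pop(j))
    return tuple(order)


@dataclass(frozen=True)
class State:
    """A point s = (x, y) of the change space S_p.

    ``bits`` is the fitness string (answers in significance order, most
    significant leftmost) and ``order`` the significance permutation
    (variable indices, most significant leftmost).  ``bits[j]`` is the
    current answer to variable ``order[j]``.
    """

    bits: tuple[int, ...]
    order: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))
        object.__setattr__(self, "order", tuple(int(i) for i in self.order))
        if len(self.bits) != len(self.order):
            raise DimensionError(
                f"fitness length {len(self.bits)} != significance length {len(self.order)}"
            )
        fitness_value(self.bits)  # digit check
        perm_lex_rank(self.order)  # permutation check

    @property
    def p(self) -> int:
        return len(self.bits)

    @property
    def value(self) -> int:
        """Integer value of the fitness string (position on the fitness axis)."""
        return fitness_value(self.bits)

    @property
    def sig_rank(self) -> int:
        """Lexicographic rank of the significance permutation."""
        return perm_lex_rank(self.order)

    @property
    def index(self) -> int:
        """Canonical 1-based index of the state in S_p."""
        return state_index(self.bits, self.order)

    def answers(self) -> dict[int, int]:
        """Map variable index -> current answer (undoes the permutation)."""
        return {v: b for v, b in zip(self.order, self.bits)}

    @classmethod
    def from_strings(cls, bits: str, order: str) -> "State":
        """Build a state from digit strings, e.g. ``State.from_strings("111", "120")``."""
        return cls(tuple(int(c) for c in bits), tuple(int(c) for c in order))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        x = "".join(map(str, self.bits))
        y = "".join(map(str, self.order))
        return f"({x}, {y})"


def state_index(bits: Sequence[int], order: Sequence[int]) -> int:
    """Canonical 1-based index of the state (bits, order) in S_p.

    Indices scan rows top to bottom (descending lexicographic order of
    the significance permutation) and, within a row, fitness strings in
    ascending binary order.
    """
    if len(bits) != len(order):
        raise DimensionError(
            f"fitness length {len(bits)} != significance length {len(order)}"
        )
    p = len(bits)
    row = math.factorial(p) - 1 - perm_lex_rank(order)
    return row * (1 << p) + fitness_value(bits) + 1


def index_to_state(k: int, p: int) -> State:
    """State with canonical index ``k`` in S_p (inverse of :func:`state_index`)."""
    if p < 1:
        raise SizeError(f"p must be >= 1, got {p}")
    total = (1 << p) * math.factorial(p)
    if not 1 <= k <= total:
        raise BoundsError(f"index {k} outside [1, {total}] for p={p}")
    row, col = divmod(k - 1, 1 << p)
    order = perm_lex_unrank(math.factorial(p) - 1 - row, p)
    bits = tuple((col >> (p - 1 - j)) & 1 for j in range(p))
    return State(bits, order)


def apply_change(state: State, changed: Iterable[int]) -> State:
    """One step of the swap-and-flip transition rule.

    The variables in ``changed`` flipped their answers between two
    consecutive observations.  Unchanged variables keep their relative
    significance order on the left; changed variables are appended on
    the right in reverse of their previous position order (the one that
    sat rightmost among them ends up leftmost of the appended block),
    each with its fitness digit negated.  An empty change set returns
    the state unchanged.
    """
    changed = frozenset(int(i) for i in changed)
    if not changed:
        return state
    unknown = changed.difference(state.order)
    if unknown:
        raise DimensionError(f"variables {sorted(unknown)} not in state of p={state.p}")
    kept = [(v, b) for v, b in zip(state.order, state.bits) if v not in changed]
    moved = [(v, 1 - b) for v, b in zip(state.order, state.bits) if v in changed]
    moved.reverse()
    pairs = kept + moved
    return State(tuple(b for _, b in pairs), tuple(v for v, _ in pairs))


@dataclass(frozen=True)
class Region:
    """A subset of S_p fixed by a prefix of significant variables and answers.

    ``sig_prefix`` lists the leading k significance positions (variable
    indices) and ``fit_prefix`` their fixed answers; the remaining
    positions are free.  Depth 0 is the whole space.
    """

    sig_prefix: tuple[int, ...] = ()
    fit_prefix: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sig_prefix", tuple(int(i) for i in self.sig_prefix))
        object.__setattr__(self, "fit_prefix", tuple(int(b) for b in self.fit_prefix))
        if len(self.sig_prefix) != len(self.fit_prefix):
            raise DimensionError(
                f"significance prefix length {len(self.sig_prefix)} != "
                f"fitness prefix length {len(self.fit_prefix)}"
            )
        if len(set(self.sig_prefix)) != len(self.sig_prefix):
            raise DimensionError(f"duplicate variables in prefix {self.sig_prefix}")
        if any(b not in (0, 1) for b in self.fit_prefix):
            raise DimensionError(f"fitness prefix must be binary: {self.fit_prefix}")

    @property
    def depth(self) -> int:
        return len(self.sig_prefix)

    def contains(self, state: State) -> bool:
        """Whether the state's leading significance/fitness entries match."""
        k = self.depth
        return (
            state.order[:k] == self.sig_prefix and state.bits[:k] == self.fit_prefix
        )

    def label(self, p: int) -> str:
        """Wildcard notation, e.g. ``x=11***, y=01***``."""
        stars = "*" * (p - self.depth)
        x = "".join(map(str, self.fit_prefix)) + stars
        y = "".join(map(str, self.sig_prefix)) + stars
        return f"x={x}, y={y}"


def region_states(region: Region, p: int) -> frozenset[State]:
    """All states of S_p belonging to ``region`` (explicit enumeration)."""
    k = region.depth
    if k > p:
        raise DimensionError(f"region depth {k} exceeds p={p}")
    if any(v >= p for v in region.sig_prefix):
        raise DimensionError(f"prefix variables {region.sig_prefix} exceed p={p}")
    _check_enumerable(p)
    free_vars = [v for v in range(p) if v not in region.sig_prefix]
    out = set()
    for tail_order in permutations(free_vars):
        for tail_bits in product((0, 1), repeat=p - k):
            out.add(
                State(region.fit_prefix + tail_bits, region.sig_prefix + tail_order)
            )
    return frozenset(out)


def admissible_successors(state: State, within: Region | None = None) -> frozenset[State]:
    """States reachable from ``state`` in one step of the transition rule.

    Enumerates every subset of changing variables, so the full result
    has exactly 2^p elements (each subset flips a distinct set of
    digits) and always contains ``state`` itself (empty change set).
    Not every state pair is realizable this way: transitions are
    *admissible* only to this image.

    ``within`` optionally restricts the result to a region of S_p.
    This answers reachability questions for orbits known to stay inside
    a region — e.g. a subject whose leading variable never changes has
    only the successors lying in the depth-1 region of that variable.
    """
    succ = set()
    for r in range(state.p + 1):
        for changed in combinations(range(state.p), r):
            nxt = apply_change(state, changed)
            if within is None or within.contains(nxt):
                succ.add(nxt)
    return frozenset(succ)


@dataclass(frozen=True)
class ChangeSpace:
    """Full enumeration of S_p with canonical index order."""

    p: int
    states: tuple[State, ...] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.states)

    @property
    def n_fitness(self) -> int:
        return 1 << self.p

    @property
    def n_significance(self) -> int:
        return math.factorial(self.p)

    def __iter__(self) -> Iterator[State]:
        return iter(self.states)

    def __getitem__(self, index: int) -> State:
        """State with canonical 1-based ``index``."""
        if not 1 <= index <= self.size:
            raise BoundsError(f"index {index} outside [1, {self.size}]")
        return self.states[index - 1]


def _check_enumerable(p: int, max_p: int = MAX_ENUM_P) -> None:
    if p < 1:
        raise SizeError(f"p must be >= 1, got {p}")
    if p > max_p:
        raise SizeError(
            f"refusing to enumerate S_{p} ({(1 << p) * math.factorial(p)} states); "
            f"maximum enumerable p is {max_p}"
        )


def build_space(p: int, max_p: int = MAX_ENUM_P) -> ChangeSpace:
    """Enumerate all 2^p * p! states of S_p in canonical index order."""
    _check_enumerable(p, max_p)
    total = (1 << p) * math.factorial(p)
    states = tuple(index_to_state(k, p) for k in range(1, total + 1))
    return ChangeSpace(p=p, states=states)
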