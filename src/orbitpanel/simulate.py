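"""Synthetic binary panels with controlled change dynamics.

The generator draws each variable's initial answer from an independent
Bernoulli(pi_i) and then evolves it by independent per-step flips with
probability phi_i — the simplest dynamics expressed directly in the
frequency-of-change vocabulary the orbit analytics rank variables by:
small phi makes a stable variable (clusters), large phi a volatile one
(holes).  Optional strata carry per-stratum overrides of n, pi and phi,
emulating subpopulations with constant labels; an optional shared
latent flip event couples a chosen set of variables so correlated
dynamics can be screened for.

Also provides the built-in demonstration subjects used throughout the
docs and tests: three 5-observation subjects on p = 3 variables and one
8-observation subject whose orbit exercises every edge color.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .engine import SubjectSeries
from .panel_io import BinaryPanel

__all__ = ["StratumSpec", "PanelSpec", "generate_panel", "example_subjects"]


def _as_probs(x, p: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (p,)).copy()
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1], got {arr}")
    return arr


@dataclass(frozen=True)
class StratumSpec:
    """Per-stratum overrides: subject count and optional pi/phi."""

    name: str
    n: int
    pi: Sequence[float] | float | None = None
    phi: Sequence[float] | float | None = None


@dataclass(frozen=True)
class PanelSpec:
    """Generator parameters.

    pi_i  — probability the initial answer to variable i is favourable.
    phi_i — probability variable i flips between consecutive times.
    strata — optional list of :class:`StratumSpec`; their n's replace
    the top-level n and each subject carries its stratum label.
    coupling — optional (variables, probability): a shared latent event
    that flips all listed variables together, on top of the
    independent flips.
    """

    n: int
    p: int
    T: int
    pi: Sequence[float] | float = 0.5
    phi: Sequence[float] | float = 0.1
    seed: int = 0
    strata: tuple[StratumSpec, ...] = ()
    coupling: tuple[Sequence[int], float] | None = None

    def __post_init__(self) -> None:
        if self.p < 1 or self.T < 0:
            raise ValueError(f"need p >= 1 and T >= 0, got p={self.p}, T={self.T}")
        if not self.strata and self.n < 1:
            raise ValueError(f"need n >= 1, got n={self.n}")
        _as_probs(self.pi, self.p, "pi")
        _as_probs(self.phi, self.p, "phi")
        if self.coupling is not None:
            vars_, rho = self.coupling
            if not 0 <= rho <= 1:
                raise ValueError(f"coupling probability must lie in [0, 1], got {rho}")
            if any(not 0 <= v < self.p for v in vars_):
                raise ValueError(f"coupled variables {vars_} outside 0..{self.p - 1}")


def _simulate_block(
    rng: np.random.Generator,
    n: int,
    p: int,
    T: int,
    pi: np.ndarray,
    phi: np.ndarray,
    coupling: tuple[Sequence[int], float] | None,
) -> np.ndarray:
    values = np.empty((n, p, T + 1), dtype=np.int8)
    values[:, :, 0] = rng.random((n, p)) < pi
    for t in range(T):
        flips = rng.random((n, p)) < phi
        if coupling is not None:
            vars_, rho = coupling
            shared = rng.random(n) < rho
            flips[np.ix_(shared, list(vars_))] ^= True
        values[:, :, t + 1] = values[:, :, t] ^ flips
    return values


def generate_panel(spec: PanelSpec) -> tuple[BinaryPanel, dict[str, str]]:
    """Generate a complete panel from a :class:`PanelSpec`.

    Returns the panel and a subject_id -> stratum label mapping (label
    ``"all"`` when no strata are specified).  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pi = _as_probs(spec.pi, spec.p, "pi")
    phi = _as_probs(spec.phi, spec.p, "phi")
    blocks, subject_ids, labels = [], [], {}
    strata = spec.strata or (StratumSpec("all", spec.n),)
    for st in strata:
        st_pi = pi if st.pi is None else _as_probs(st.pi, spec.p, f"pi[{st.name}]")
        st_phi = phi if st.phi is None else _as_probs(st.phi, spec.p, f"phi[{st.name}]")
        blocks.append(
            _simulate_block(rng, st.n, spec.p, spec.T, st_pi, st_phi, spec.coupling)
        )
        ids = [f"{st.name}-{k:05d}" for k in range(st.n)]
        subject_ids.extend(ids)
        labels.update({i: st.name for i in ids})
    panel = BinaryPanel(
        np.concatenate(blocks, axis=0),
        subject_ids,
        [f"Q{i}" for i in range(spec.p)],
        list(range(spec.T + 1)),
    )
    return panel, labels


def example_subjects() -> dict[str, SubjectSeries]:
    """Built-in demonstration subjects (p = 3).

    ``trio_a``/``trio_b``/``trio_c`` are three subjects observed at 5
    times; a and b have a constant answer to variable 0 (unfavourable
    and favourable respectively) while c is constantly favourable in
    variable 2, so their initial orders differ.  ``demo`` is a subject
    observed at 8 times whose orbit revisits states and shows all three
    edge colors.  Answer matrices are indexed ``[variable, time]``.
    """
    return {
        "trio_a": SubjectSeries(
            "trio_a",
            np.array(
                [
                    [0, 0, 0, 0, 0],
                    [1, 0, 0, 0, 0],
                    [0, 1, 0, 1, 0],
                ]
            ),
        ),
        "trio_b": SubjectSeries(
            "trio_b",
            np.array(
                [
                    [1, 1, 1, 1, 1],
                    [0, 0, 0, 1, 0],
                    [0, 0, 1, 0, 1],
                ]
            ),
        ),
        "trio_c": SubjectSeries(
            "trio_c",
            np.array(
                [
                    [1, 0, 0, 1, 0],
                    [1, 0, 0, 0, 0],
                    [1, 1, 1, 1, 1],
                ]
            ),
        ),
        "demo": SubjectSeries(
            "demo",
            np.array(
                [
                    [1, 1, 0, 0, 0, 0, 1, 0],
                    [1, 1, 1, 1, 1, 1, 1, 1],
                    [1, 1, 1, 0, 1, 1, 1, 1],
                ]
            ),
        ),
    }
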