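"""Plot families for orbits in S_p and cohort summaries.

Every plotting function renders to a file and returns ``(path, table)``
where ``table`` is the exact numeric data behind the figure, so the
mapped values can be exported and asserted independently of appearance.
Edge-color semantics are fixed: red = move left on the fitness axis
(a variable turned unfavourable), green = move right, blue = same
fitness (idle or pure reordering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; figures only ever go to files

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from .cohort import CapacityTable
from .engine import Orbit
from .errors import DimensionError

__all__ = [
    "PlotConfig",
    "plot_orbits",
    "plot_timeseries",
    "plot_capacity",
    "plot_heatmap",
]


@dataclass(frozen=True)
class PlotConfig:
    """Display options shared by the plot families.

    ``show_all_rows`` forces every significance permutation onto the
    y-axis of S_p scatter plots (by default only visited rows are
    shown, since p! rows quickly become unreadable).  Thresholds are
    reporting filters for capacity/density displays and never alter the
    underlying tables.
    """

    show_all_rows: bool = False
    capacity_threshold: int = 0
    density_threshold: int = 0
    figsize: tuple[float, float] = (8.0, 6.0)
    dpi: int = 120

    def __post_init__(self) -> None:
        if self.capacity_threshold < 0 or self.density_threshold < 0:
            raise ValueError("thresholds must be nonnegative")


def _row_of(state) -> int:
    """Row number of a state, counted from the top of the canonical layout."""
    return math.factorial(state.p) - 1 - state.sig_rank


def _orbit_points(orbits: Sequence[Orbit]) -> pd.DataFrame:
    rows = []
    for o in orbits:
        for t, s in enumerate(o.states):
            rows.append(
                {
                    "subject_id": o.subject_id,
                    "t": t,
                    "fitness": s.value + 1,
                    "row": _row_of(s),
                    "y": "".join(map(str, s.order)),
                    "state_index": s.index,
                    "edge_color": o.edges[t] if t < o.T else "",
                }
            )
    return pd.DataFrame(rows)


def plot_orbits(
    orbits: Sequence[Orbit], path: str | Path, config: PlotConfig = PlotConfig()
) -> tuple[Path, pd.DataFrame]:
    """Scatter of visited states in S_p with colored transition edges.

    x-axis: fitness states in ascending binary order (1..2^p); y-axis:
    significance permutations in canonical row order (top row first).
    """
    orbits = list(orbits)
    if not orbits:
        raise DimensionError("cannot plot an empty orbit set")
    p = orbits[0].p
    table = _orbit_points(orbits)
    if config.show_all_rows:
        rows_shown = list(range(math.factorial(p)))
    else:
        rows_shown = sorted(table["row"].unique())
    ypos = {r: i for i, r in enumerate(rows_shown)}

    fig, ax = plt.subplots(figsize=config.figsize)
    for o in orbits:
        for s, s2, color in zip(o.states, o.states[1:], o.edges):
            ax.plot(
                [s.value + 1, s2.value + 1],
                [ypos[_row_of(s)], ypos[_row_of(s2)]],
                color=color, lw=0.8, alpha=0.6, zorder=1,
            )
    ax.scatter(table["fitness"], table["row"].map(ypos), s=18, color="black", zorder=2)
    ax.set_xlim(0.5, 2**p + 0.5)
    ax.set_xlabel("fitness state (binary order)")
    ax.set_ylabel("significance state")
    row_labels = {r: y for r, y in zip(table["row"], table["y"])}
    ax.set_yticks(range(len(rows_shown)))
    ax.set_yticklabels([row_labels.get(r, "") for r in rows_shown])
    ax.invert_yaxis()  # top row of the canonical layout on top
    fig.savefig(path, dpi=config.dpi, bbox_inches="tight")
    plt.close(fig)
    return Path(path), table


def plot_timeseries(
    orbits: Sequence[Orbit], path: str | Path, config: PlotConfig = PlotConfig()
) -> tuple[Path, pd.DataFrame]:
    """State index against time, one polyline per orbit, edges colored."""
    orbits = list(orbits)
    if not orbits:
        raise DimensionError("cannot plot an empty orbit set")
    table = _orbit_points(orbits)
    fig, ax = plt.subplots(figsize=config.figsize)
    for o in orbits:
        idx = o.indices
        for t, color in enumerate(o.edges):
            ax.plot([t, t + 1], [idx[t], idx[t + 1]], color=color, lw=1.0)
        ax.scatter(range(len(idx)), idx, s=12, color="black", zorder=2)
    ax.set_xlabel("time")
    ax.set_ylabel("state index")
    fig.savefig(path, dpi=config.dpi, bbox_inches="tight")
    plt.close(fig)
    return Path(path), table


def plot_capacity(
    capacity: CapacityTable,
    path: str | Path,
    mode: str = "histogram",
    config: PlotConfig = PlotConfig(),
) -> tuple[Path, pd.DataFrame]:
    """Capacity displays: accumulated histogram, (state, t) bubbles, or
    per-state curves for states passing the capacity threshold."""
    fig, ax = plt.subplots(figsize=config.figsize)
    if mode == "histogram":
        acc = capacity.accumulated()
        table = acc.rename("visits").reset_index()
        ax.bar(acc.index.astype(str), acc.to_numpy(), color="steelblue")
        ax.set_xlabel("state index")
        ax.set_ylabel("accumulated visits")
        ax.tick_params(axis="x", rotation=90)
    elif mode == "bubble":
        long = (
            capacity.counts.stack().rename("capacity").reset_index()
            .rename(columns={"level_1": "t"})
        )
        table = long[long["capacity"] > 0].reset_index(drop=True)
        ax.scatter(
            table["t"], table["state_index"], s=8.0 * table["capacity"],
            alpha=0.5, color="steelblue",
        )
        ax.set_xlabel("time")
        ax.set_ylabel("state index")
    elif mode == "curves":
        table = capacity.filtered(config.capacity_threshold)
        if table.empty:
            import warnings

            warnings.warn(
                f"no state reaches capacity {config.capacity_threshold}; empty plot",
                stacklevel=2,
            )
        for idx, row in table.iterrows():
            ax.plot(row.index, row.to_numpy(), marker="o", label=str(idx))
        if not table.empty:
            ax.legend(title="state", fontsize="small")
        ax.set_xlabel("time")
        ax.set_ylabel("capacity")
        table = table.reset_index()
    else:
        raise ValueError(f"mode must be histogram|bubble|curves, got {mode!r}")
    fig.savefig(path, dpi=config.dpi, bbox_inches="tight")
    plt.close(fig)
    return Path(path), table


def plot_heatmap(
    proportions: pd.DataFrame, path: str | Path, config: PlotConfig = PlotConfig()
) -> tuple[Path, pd.DataFrame]:
    """Heat map of group proportions by fitness label (rows) and time
    (columns); absent cells get a distinct no-data color."""
    fig, ax = plt.subplots(figsize=config.figsize)
    cmap = sns.color_palette("viridis", as_cmap=True).copy()
    cmap.set_bad("lightgrey")
    sns.heatmap(
        proportions, ax=ax, cmap=cmap, vmin=0.0, vmax=1.0,
        cbar_kws={"label": "proportion flagged"},
    )
    ax.set_xlabel("time")
    ax.set_ylabel("fitness label")
    fig.savefig(path, dpi=config.dpi, bbox_inches="tight")
    plt.close(fig)
    return Path(path), proportions
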