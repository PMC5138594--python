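"""Seeded factorial trial designs for the three experiments.

Experiment 1 (visual search): 5 edge conditions — control plus the full
``both`` profile at widths {8, 16} px crossed with offsets {20, 40} —
× 2 shadow backgrounds × 8 display cells = 80 trials.

Experiment 2 (component knock-out): control plus {no_high, no_low, square}
× offsets {20, 40} at a fixed 16-px width — 7 edge conditions × 2 shadow
backgrounds × 8 cells = 112 trials (the balanced factorial; the trial
total is configurable through ``repeats``).

Experiment 3 (depth judgement): {none, both, no_high, no_low} × 2 shadow
backgrounds × 25 repetitions = 200 trials, target central and vertical,
edge width fixed at 0.53° (17 px at the default display scale).

Each design is an ordered list of :class:`TrialSpec`; order and per-trial
seeds are deterministic functions of the supplied random generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .background import deg_to_px
from .texture import EdgeProfile

__all__ = [
    "Condition",
    "TrialSpec",
    "EXP1_EDGES",
    "EXP2_EDGES",
    "EXP3_EDGES",
    "design_exp1",
    "design_exp2",
    "design_exp3",
    "design_to_frame",
    "design_from_frame",
]

_MAX_SEED = 2**31 - 1

EXP1_EDGES: tuple[EdgeProfile, ...] = (
    EdgeProfile("none"),
    EdgeProfile("both", offset=20, width=8),
    EdgeProfile("both", offset=40, width=8),
    EdgeProfile("both", offset=20, width=16),
    EdgeProfile("both", offset=40, width=16),
)

EXP2_EDGES: tuple[EdgeProfile, ...] = (EdgeProfile("none"),) + tuple(
    EdgeProfile(variant, offset=offset, width=16)
    for variant in ("no_high", "no_low", "square")
    for offset in (20, 40)
)

#: 0.53 degrees at the default 0.62°/20 px display scale.
EXP3_EDGE_WIDTH_PX = round(deg_to_px(0.53))

EXP3_EDGES: tuple[EdgeProfile, ...] = (
    EdgeProfile("none"),
    EdgeProfile("both", offset=40, width=EXP3_EDGE_WIDTH_PX),
    EdgeProfile("no_high", offset=40, width=EXP3_EDGE_WIDTH_PX),
    EdgeProfile("no_low", offset=40, width=EXP3_EDGE_WIDTH_PX),
)


@dataclass(frozen=True)
class Condition:
    """An experimental condition: edge profile × shadow background."""

    edge: EdgeProfile
    shadows: bool

    @property
    def label(self) -> str:
        return f"{self.edge.label}|{'shadow' if self.shadows else 'plain'}"


@dataclass(frozen=True)
class TrialSpec:
    """One trial of a design, with its own stimulus seed."""

    experiment: int
    index: int
    condition: Condition
    cell: int | str
    orientation: float
    seed: int


def _assemble(
    experiment: int,
    cells: list[int | str],
    edges: tuple[EdgeProfile, ...],
    repeats: int,
    rng: np.random.Generator,
) -> list[TrialSpec]:
    combos = [
        (edge, shadows, cell)
        for edge in edges
        for shadows in (False, True)
        for cell in cells
        for _ in range(repeats)
    ]
    order = rng.permutation(len(combos))
    trials = []
    for index, j in enumerate(order):
        edge, shadows, cell = combos[j]
        trials.append(
            TrialSpec(
                experiment=experiment,
                index=index,
                condition=Condition(edge, shadows),
                cell=cell,
                orientation=float(rng.uniform(0.0, 2.0 * np.pi)),
                seed=int(rng.integers(0, _MAX_SEED)),
            )
        )
    return trials


def design_exp1(rng: np.random.Generator) -> list[TrialSpec]:
    """80 search trials: 5 edge conditions × 2 shadow levels × 8 cells."""
    return _assemble(1, list(range(1, 9)), EXP1_EDGES, 1, rng)


def design_exp2(rng: np.random.Generator, repeats: int = 1) -> list[TrialSpec]:
    """112 search trials: 7 edge conditions × 2 shadow levels × 8 cells."""
    return _assemble(2, list(range(1, 9)), EXP2_EDGES, repeats, rng)


def design_exp3(rng: np.random.Generator, repeats: int = 25) -> list[TrialSpec]:
    """200 depth-judgement trials: 4 edge types × 2 backgrounds × 25 reps.

    The target is central and vertical (orientation π/2 by convention of a
    row-major canvas)."""
    trials = _assemble(3, ["center"], EXP3_EDGES, repeats, rng)
    return [
        TrialSpec(
            t.experiment, t.index, t.condition, t.cell, float(np.pi / 2), t.seed
        )
        for t in trials
    ]


def design_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """Flatten a design to a table (one row per trial) for CSV round-trips."""
    rows = []
    for t in trials:
        rows.append(
            {
                "experiment": t.experiment,
                "index": t.index,
                "variant": t.condition.edge.variant,
                "offset": t.condition.edge.offset,
                "width": t.condition.edge.width,
                "shadows": t.condition.shadows,
                "cell": t.cell,
                "orientation": t.orientation,
                "seed": t.seed,
            }
        )
    return pd.DataFrame(rows)


def design_from_frame(df: pd.DataFrame) -> list[TrialSpec]:
    trials = []
    for _, r in df.iterrows():
        edge = EdgeProfile(str(r["variant"]), float(r["offset"]), float(r["width"]))
        cell = r["cell"]
        cell = cell if cell == "center" else int(cell)
        trials.append(
            TrialSpec(
                int(r["experiment"]),
                int(r["index"]),
                Condition(edge, bool(r["shadows"])),
                cell,
                float(r["orientation"]),
                int(r["seed"]),
            )
        )
    return trials
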