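"""Experimental design for the media-optimisation loop.

The design space is two-dimensional: glucose concentration (% w/v, carbon
source) and ammonium chloride concentration (mM, nitrogen source), varied
against an M9 minimal-medium background.  This module generates the initial
centred Latin-hypercube design and the block-randomised 96-well plate
layouts used to run each batch with replication.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: treatment label for wells with M9 salts but no added carbon/nitrogen
CONTROL = "control"
#: treatment label for wells with the complete baseline M9 medium
M9_REFERENCE = "M9_reference"

_ROW_LETTERS = "ABCDEFGH"


@dataclass(frozen=True)
class MediaComposition:
    """A point in the design space: glucose (% w/v) and NH4Cl (mM)."""

    glucose_pct: float
    nh4cl_mM: float

    def as_array(self) -> np.ndarray:
        return np.array([self.glucose_pct, self.nh4cl_mM], dtype=float)


@dataclass(frozen=True)
class DesignSpace:
    """Axis-aligned bounds of the glucose/NH4Cl composition space.

    Defaults span [0.1, 2.0] % glucose and [5, 120] mM NH4Cl, containing
    both the baseline M9 composition and the known high-titre region.
    """

    glucose_lo: float = 0.1
    glucose_hi: float = 2.0
    nh4cl_lo: float = 5.0
    nh4cl_hi: float = 120.0

    def __post_init__(self) -> None:
        if not (self.glucose_lo < self.glucose_hi):
            raise ValueError("glucose bounds must satisfy lo < hi")
        if not (self.nh4cl_lo < self.nh4cl_hi):
            raise ValueError("nh4cl bounds must satisfy lo < hi")

    @property
    def lo(self) -> np.ndarray:
        return np.array([self.glucose_lo, self.nh4cl_lo])

    @property
    def hi(self) -> np.ndarray:
        return np.array([self.glucose_hi, self.nh4cl_hi])

    def contains(self, comp: "MediaComposition | np.ndarray", atol: float = 1e-9) -> bool:
        x = comp.as_array() if isinstance(comp, MediaComposition) else np.asarray(comp, float)
        return bool(np.all(x >= self.lo - atol) and np.all(x <= self.hi + atol))

    def to_unit(self, X: np.ndarray) -> np.ndarray:
        """Map compositions (m, 2) to the unit square."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.lo) / (self.hi - self.lo)

    def from_unit(self, U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        return self.lo + U * (self.hi - self.lo)

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(np.atleast_2d(np.asarray(X, float)), self.lo, self.hi)

    def grid(self, shape: tuple[int, int] = (101, 101)) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (glucose axis, nh4cl axis, stacked grid points (m, 2))."""
        gx = np.linspace(self.glucose_lo, self.glucose_hi, shape[0])
        gn = np.linspace(self.nh4cl_lo, self.nh4cl_hi, shape[1])
        GG, NN = np.meshgrid(gx, gn, indexing="ij")
        pts = np.column_stack([GG.ravel(), NN.ravel()])
        return gx, gn, pts


def compositions_to_array(comps: Sequence[MediaComposition]) -> np.ndarray:
    return np.array([[c.glucose_pct, c.nh4cl_mM] for c in comps], dtype=float).reshape(-1, 2)


def latin_hypercube(n: int, space: DesignSpace | None = None, seed: int = 0) -> list[MediaComposition]:
    """Centred Latin-hypercube design with ``n`` points.

    Each axis is divided into ``n`` equal bins and points sit at bin
    centres; the bin-to-bin pairing across axes is a seeded uniform
    permutation, so every axis projection occupies each bin exactly once.
    """
    if n < 1:
        raise ValueError(f"latin_hypercube requires n >= 1, got {n}")
    space = space or DesignSpace()
    rng = np.random.default_rng(seed)
    centres = (np.arange(n) + 0.5) / n
    U = np.column_stack([centres[rng.permutation(n)], centres[rng.permutation(n)]])
    X = space.from_unit(U)
    return [MediaComposition(float(g), float(a)) for g, a in X]


@dataclass(frozen=True)
class WellAssignment:
    well: str
    row: int
    col: int
    treatment: str
    block: int
    composition: Optional[MediaComposition]
    batch: str


@dataclass
class PlateLayout:
    """Assignment of treatments to wells of an 8x12 microplate.

    Treatments are replicated once per block (randomized complete block
    design); the number of blocks equals the replication level.
    """

    wells: list[WellAssignment]
    batch: str = "batch0"
    n_rows: int = 8
    n_cols: int = 12

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.treatment, None)
        return list(seen)

    @property
    def n_blocks(self) -> int:
        return len({w.block for w in self.wells})

    def composition_of(self, treatment: str) -> Optional[MediaComposition]:
        for w in self.wells:
            if w.treatment == treatment:
                return w.composition
        raise KeyError(treatment)

    def wells_of(self, treatment: str) -> list[WellAssignment]:
        return [w for w in self.wells if w.treatment == treatment]

    def treatment_of_well(self, well: str) -> str:
        for w in self.wells:
            if w.well == well:
                return w.treatment
        raise KeyError(well)

    def validate(self) -> None:
        names = [w.well for w in self.wells]
        if len(names) != len(set(names)):
            raise ValueError("a well was assigned more than once")
        inc: dict[tuple[str, int], int] = {}
        for w in self.wells:
            inc[(w.treatment, w.block)] = inc.get((w.treatment, w.block), 0) + 1
        blocks = sorted({b for _, b in inc})
        for t in self.treatments:
            for b in blocks:
                if inc.get((t, b), 0) != 1:
                    raise ValueError(
                        f"treatment {t!r} appears {inc.get((t, b), 0)} times in block {b}"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            rows.append(
                {
                    "well": w.well,
                    "row": w.row,
                    "col": w.col,
                    "treatment": w.treatment,
                    "block": w.block,
                    "glucose_pct": w.composition.glucose_pct if w.composition else np.nan,
                    "nh4cl_mM": w.composition.nh4cl_mM if w.composition else np.nan,
                    "batch": w.batch,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    def to_csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue().encode()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateLayout":
        wells = []
        batch = str(df["batch"].iloc[0]) if len(df) else "batch0"
        for _, r in df.iterrows():
            comp = None
            if np.isfinite(r["glucose_pct"]) and np.isfinite(r["nh4cl_mM"]):
                comp = MediaComposition(float(r["glucose_pct"]), float(r["nh4cl_mM"]))
            wells.append(
                WellAssignment(
                    well=str(r["well"]),
                    row=int(r["row"]),
                    col=int(r["col"]),
                    treatment=str(r["treatment"]),
                    block=int(r["block"]),
                    composition=comp,
                    batch=str(r["batch"]),
                )
            )
        return cls(wells=wells, batch=batch)

    @classmethod
    def from_csv(cls, path_or_buf) -> "PlateLayout":
        # round_trip parsing keeps composition floats byte-stable across
        # write/read/write cycles
        return cls.from_frame(pd.read_csv(path_or_buf, float_precision="round_trip"))


def treatment_map(
    combinations: Sequence[MediaComposition],
    baseline: Optional[MediaComposition] = None,
    include_control: bool = True,
    include_m9_reference: bool = True,
) -> dict[str, Optional[MediaComposition]]:
    """Build the label -> composition mapping for one batch.

    ``combination_1..q`` carry the proposed compositions; ``control`` is M9
    salts with no added carbon/nitrogen (no composition in the space) and
    ``M9_reference`` is the complete baseline medium used for normalisation.
    """
    treatments: dict[str, Optional[MediaComposition]] = {
        f"combination_{i + 1}": c for i, c in enumerate(combinations)
    }
    if include_control:
        treatments[CONTROL] = None
    if include_m9_reference:
        treatments[M9_REFERENCE] = baseline or MediaComposition(0.4, 18.7)
    return treatments


def block_randomised_layout(
    treatments: Mapping[str, Optional[MediaComposition]],
    n_blocks: int = 6,
    seed: int = 0,
    batch: str = "batch0",
    order: str = "row-major",
) -> PlateLayout:
    """Randomized-complete-block assignment of treatments to plate wells.

    Wells are taken in ``order`` ('row-major' or 'column-major') and
    partitioned into ``n_blocks`` contiguous groups; within each block the
    treatment order is an independent seeded permutation, so every
    treatment occurs exactly once per block.  Per-block random streams are
    spawned from one root seed, keeping layouts stable under block-count
    changes.
    """
    labels = list(treatments)
    n_t = len(labels)
    if n_t < 1:
        raise ValueError("at least one treatment is required")
    needed = n_t * n_blocks
    capacity = 96
    if needed > capacity:
        raise ValueError(
            f"layout needs {needed} wells ({n_t} treatments x {n_blocks} blocks) "
            f"but the plate has only {capacity}"
        )
    if order == "row-major":
        seq = [(r, c) for r in range(8) for c in range(12)]
    elif order == "column-major":
        seq = [(r, c) for c in range(12) for r in range(8)]
    else:
        raise ValueError(f"unknown order {order!r}")

    children = np.random.SeedSequence(seed).spawn(n_blocks)
    wells: list[WellAssignment] = []
    pos = 0
    for b in range(n_blocks):
        rng = np.random.default_rng(children[b])
        for label_idx in rng.permutation(n_t):
            label = labels[int(label_idx)]
            r, c = seq[pos]
            pos += 1
            wells.append(
                WellAssignment(
                    well=f"{_ROW_LETTERS[r]}{c + 1}",
                    row=r,
                    col=c,
                    treatment=label,
                    block=b,
                    composition=treatments[label],
                    batch=batch,
                )
            )
    layout = PlateLayout(wells=wells, batch=batch)
    layout.validate()
    return layout
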