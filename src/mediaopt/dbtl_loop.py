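"""Design-Build-Test-Learn loop orchestration.

Runs the closed active-learning loop: iteration 0 uses a centred Latin
hypercube; later iterations propose batches by qNEI.  Each iteration
simulates (or ingests) a block-randomised plate, processes the traces into
relative titres, refits the heteroskedastic GP on all data so far, and
records the predicted landscape, its uncertainty map and the cumulative
best observed titre.  Post-hoc summaries include the mean grid
uncertainty, the performance-cliff region (predicted relative titre below
threshold) and the best improvement over the M9 baseline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from . import __version__
from .acquisition import AcquisitionConfig, propose_batch
from .design import (
    DesignSpace,
    MediaComposition,
    PlateLayout,
    block_randomised_layout,
    latin_hypercube,
    treatment_map,
)
from .ms_processing import (
    AsLSConfig,
    DriftConfig,
    OutlierConfig,
    RelativeAbundanceTable,
    process_plate,
)
from .surrogate import GPConfig, GPDataset, GPModel, fit_gp
from .synthetic_data import (
    TITRE_SIGNAL,
    BaselineComposition,
    GrowthSpec,
    NoiseSpec,
    SurfaceFunction,
    SurfaceSpec,
    TraceSpec,
    growth_features,
    make_landscape,
    simulate_growth,
    simulate_plate,
)


class LoopError(RuntimeError):
    """A loop stage failed; message names the iteration and stage."""


@dataclass(frozen=True)
class LoopConfig:
    n_iterations: int = 3
    batch_q: int = 7
    n_blocks: int = 6
    grid_shape: tuple[int, int] = (101, 101)
    seed: int = 0
    space: DesignSpace = field(default_factory=DesignSpace)
    gp: GPConfig = field(default_factory=GPConfig)
    # smaller MC/pool sizes than the standalone acquisition default keep a
    # full three-iteration run in the seconds range without changing the
    # proposals appreciably (documented in the methods note)
    acq: AcquisitionConfig = field(default_factory=lambda: AcquisitionConfig(mc_samples=1024, pool_size=256))
    asls: AsLSConfig = field(default_factory=AsLSConfig)
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    simulate_growth_curves: bool = True
    fallback_cv: float = 0.15  # noise guess when a condition has < 2 kept replicates

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class CliffConfig:
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class LandscapeGrid:
    """Posterior mean and latent-mean sd on a rectangular composition grid."""

    glucose: np.ndarray
    nh4cl: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.glucose), len(self.nh4cl))
        if self.mean.shape != shape or self.sd.shape != shape:
            raise ValueError("mean/sd shapes must match the grid axes")
        if np.any(self.sd < -1e-12):
            raise ValueError("sd must be non-negative")

    @property
    def points(self) -> np.ndarray:
        GG, NN = np.meshgrid(self.glucose, self.nh4cl, indexing="ij")
        return np.column_stack([GG.ravel(), NN.ravel()])

    def argmax_composition(self) -> MediaComposition:
        i, j = np.unravel_index(int(np.argmax(self.mean)), self.mean.shape)
        return MediaComposition(float(self.glucose[i]), float(self.nh4cl[j]))

    def to_frame(self) -> pd.DataFrame:
        pts = self.points
        return pd.DataFrame(
            {
                "glucose_pct": pts[:, 0],
                "nh4cl_mM": pts[:, 1],
                "mean": self.mean.ravel(),
                "sd": self.sd.ravel(),
            }
        )

    def same_grid(self, other: "LandscapeGrid") -> bool:
        return (
            self.glucose.shape == other.glucose.shape
            and self.nh4cl.shape == other.nh4cl.shape
            and np.allclose(self.glucose, other.glucose)
            and np.allclose(self.nh4cl, other.nh4cl)
        )


@dataclass
class IterationRecord:
    index: int
    compositions: list[MediaComposition]
    layout: PlateLayout
    table: RelativeAbundanceTable
    stats: pd.DataFrame
    model: GPModel
    grid: LandscapeGrid
    mean_sd: float
    growth: Optional[pd.DataFrame] = None


@dataclass
class LoopState:
    config_seed: int
    space: DesignSpace
    iterations: list[IterationRecord] = field(default_factory=list)

    def all_stats(self) -> pd.DataFrame:
        frames = []
        for rec in self.iterations:
            df = rec.stats.copy()
            df.insert(0, "iteration", rec.index)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def best_observed(self) -> tuple[float, MediaComposition]:
        """Best replicate-mean relative titre seen so far and its composition."""
        df = self.all_stats().dropna(subset=["mean"])
        if df.empty:
            raise ValueError("loop state holds no observations")
        row = df.loc[df["mean"].idxmax()]
        return float(row["mean"]), MediaComposition(float(row["glucose_pct"]), float(row["nh4cl_mM"]))

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for rec in self.iterations:
            h.update(rec.stats.round(12).to_csv(index=False).encode())
        return h.hexdigest()

    # -- persistence --------------------------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.config_seed,
            "version": __version__,
            "space": {
                "glucose_lo": self.space.glucose_lo,
                "glucose_hi": self.space.glucose_hi,
                "nh4cl_lo": self.space.nh4cl_lo,
                "nh4cl_hi": self.space.nh4cl_hi,
            },
            "n_iterations": len(self.iterations),
            "state_hash": self.state_hash(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for rec in self.iterations:
            d = out / f"iter_{rec.index:02d}"
            d.mkdir(exist_ok=True)
            rec.layout.to_csv(d / "layout.csv")
            rec.table.data.to_csv(d / "relative_abundance.csv")
            rec.stats.to_csv(d / "stats.csv", index=False)
            (d / "model.json").write_text(rec.model.to_json())
            rec.grid.to_frame().to_csv(d / "grid.csv", index=False)
            if rec.growth is not None:
                rec.growth.to_csv(d / "growth.csv", index=False)
            (d / "summary.json").write_text(
                json.dumps({"mean_sd": rec.mean_sd, "index": rec.index}, indent=1)
            )

    @classmethod
    def load(cls, out_dir) -> "LoopState":
        out = Path(out_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        space = DesignSpace(**manifest["space"])
        state = cls(config_seed=manifest["seed"], space=space)
        for i in range(manifest["n_iterations"]):
            d = out / f"iter_{i:02d}"
            layout = PlateLayout.from_csv(d / "layout.csv")
            table = RelativeAbundanceTable(
                data=pd.read_csv(d / "relative_abundance.csv", index_col=0), batch=layout.batch
            )
            stats = pd.read_csv(d / "stats.csv")
            model = GPModel.from_json((d / "model.json").read_text())
            gdf = pd.read_csv(d / "grid.csv")
            gx = np.unique(gdf["glucose_pct"])
            gn = np.unique(gdf["nh4cl_mM"])
            grid = LandscapeGrid(
                glucose=gx,
                nh4cl=gn,
                mean=gdf["mean"].to_numpy().reshape(len(gx), len(gn)),
                sd=gdf["sd"].to_numpy().reshape(len(gx), len(gn)),
            )
            summary = json.loads((d / "summary.json").read_text())
            growth = pd.read_csv(d / "growth.csv") if (d / "growth.csv").exists() else None
            comps = [
                MediaComposition(float(r["glucose_pct"]), float(r["nh4cl_mM"]))
                for _, r in stats.iterrows()
                if str(r["treatment"]).startswith("combination_")
            ]
            state.iterations.append(
                IterationRecord(
                    index=i,
                    compositions=comps,
                    layout=layout,
                    table=table,
                    stats=stats,
                    model=model,
                    grid=grid,
                    mean_sd=float(summary["mean_sd"]),
                    growth=growth,
                )
            )
        return state


class SyntheticSimulator:
    """Build+Test stage emulator: plates, traces and growth from ground truth."""

    def __init__(
        self,
        landscape: SurfaceFunction | None = None,
        extra_surfaces: Optional[dict[str, SurfaceFunction]] = None,
        noise: NoiseSpec | None = None,
        trace: TraceSpec | None = None,
        growth: GrowthSpec | None = None,
        space: DesignSpace | None = None,
        baseline: BaselineComposition | None = None,
        n_blocks: int = 6,
    ):
        self.space = space or DesignSpace()
        self.landscape = landscape if landscape is not None else make_landscape(SurfaceSpec(), space=self.space)
        self.surfaces: dict[str, SurfaceFunction] = {TITRE_SIGNAL: self.landscape}
        if extra_surfaces:
            self.surfaces.update(extra_surfaces)
        self.noise = noise or NoiseSpec()
        self.trace = trace or TraceSpec()
        self.growth = growth or GrowthSpec()
        self.baseline = baseline or BaselineComposition()
        self.n_blocks = n_blocks

    def run_batch(self, compositions: Sequence[MediaComposition], iteration: int, seed: int):
        batch = f"batch{iteration}"
        treatments = treatment_map(compositions, baseline=self.baseline.as_composition())
        ss = np.random.SeedSequence(seed)
        s_layout, s_plate, s_growth = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
        layout = block_randomised_layout(treatments, n_blocks=self.n_blocks, seed=s_layout, batch=batch)
        traces = simulate_plate(
            layout,
            self.surfaces,
            noise=self.noise,
            seed=s_plate,
            trace=self.trace,
            baseline=self.baseline,
        )
        growth_df = self._simulate_growth(layout, s_growth)
        return layout, traces, growth_df

    def _simulate_growth(self, layout: PlateLayout, seed: int) -> pd.DataFrame:
        rows = []
        rng_seeds = np.random.SeedSequence(seed).spawn(len(layout.wells))
        for w, s in zip(layout.wells, rng_seeds):
            if w.treatment == "M9_reference":
                comp = self.baseline.as_composition()
            elif w.composition is None:
                continue
            else:
                comp = w.composition
            curve = simulate_growth(comp, seed=int(s.generate_state(1)[0] % 2**31), spec=self.growth)
            mx, fin = growth_features(curve)
            rows.append(
                {
                    "well": w.well,
                    "treatment": w.treatment,
                    "glucose_pct": comp.glucose_pct,
                    "nh4cl_mM": comp.nh4cl_mM,
                    "max_od": mx,
                    "final_od": fin,
                }
            )
        return pd.DataFrame(rows)


def _training_rows(stats_frames: Sequence[pd.DataFrame], fallback_cv: float) -> pd.DataFrame:
    df = pd.concat(stats_frames, ignore_index=True).dropna(subset=["mean"])
    sem = df["sem"].to_numpy(float)
    mean = df["mean"].to_numpy(float)
    bad = ~np.isfinite(sem)
    sem = np.where(bad, fallback_cv * np.abs(mean), sem)
    out = df.copy()
    out["noise_var"] = sem**2
    return out


def run_loop(
    simulator: SyntheticSimulator,
    cfg: LoopConfig | None = None,
    out_dir=None,
) -> LoopState:
    """Run the full active-learning loop against a simulator.

    Iteration 0 designs by centred Latin hypercube; iterations >= 1 by
    greedy qNEI batches.  Every source of randomness derives from
    ``cfg.seed``.  On a stage failure the partial state is persisted (when
    ``out_dir`` is given) and a :class:`LoopError` naming the iteration
    and stage is raised.
    """
    cfg = cfg or LoopConfig()
    space = simulator.space
    state = LoopState(config_seed=cfg.seed, space=space)
    root = np.random.SeedSequence(cfg.seed)
    iter_seeds = root.spawn(cfg.n_iterations)
    stats_frames: list[pd.DataFrame] = []
    model: Optional[GPModel] = None

    for i in range(cfg.n_iterations):
        s_design, s_batch = [int(s.generate_state(1)[0] % 2**31) for s in iter_seeds[i].spawn(2)]
        stage = "design"
        try:
            if i == 0 or model is None:
                comps = latin_hypercube(cfg.batch_q, space, seed=s_design)
            else:
                acq_cfg = replace(cfg.acq, q=cfg.batch_q, seed=s_design, grid_shape=cfg.grid_shape)
                comps = propose_batch(model, space, acq_cfg).compositions

            stage = "build/test"
            layout, traces, growth_df = simulator.run_batch(comps, i, s_batch)
            table = process_plate(
                traces, layout, asls=cfg.asls, outlier=cfg.outlier, drift=cfg.drift
            )
            stats = table.condition_stats(layout, TITRE_SIGNAL)
            stats_frames.append(stats)

            stage = "learn"
            train = _training_rows(stats_frames, cfg.fallback_cv)
            dataset = GPDataset.from_observations(
                train[["glucose_pct", "nh4cl_mM"]].to_numpy(float),
                train["mean"].to_numpy(float),
                train["noise_var"].to_numpy(float),
                space=space,
            )
            model = fit_gp(dataset, replace(cfg.gp, seed=cfg.seed + i))
            grid = uncertainty_map(model, space, cfg.grid_shape)
            state.iterations.append(
                IterationRecord(
                    index=i,
                    compositions=comps,
                    layout=layout,
                    table=table,
                    stats=stats,
                    model=model,
                    grid=grid,
                    mean_sd=mean_uncertainty(grid),
                    growth=growth_df if cfg.simulate_growth_curves else None,
                )
            )
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            if out_dir is not None:
                state.save(out_dir)
            raise LoopError(f"iteration {i}, stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        state.save(out_dir)
    return state


# ---------------------------------------------------------------------------
# uncertainty and summaries


def uncertainty_map(
    model: GPModel,
    space: DesignSpace | None = None,
    grid_shape: tuple[int, int] = (101, 101),
) -> LandscapeGrid:
    """Posterior mean and latent-mean sd on a dense composition grid."""
    space = space or model.space
    gx, gn, pts = space.grid(grid_shape)
    mean, sd = model.predict(pts)
    return LandscapeGrid(
        glucose=gx,
        nh4cl=gn,
        mean=mean.reshape(grid_shape),
        sd=sd.reshape(grid_shape),
    )


def mean_uncertainty(grid: LandscapeGrid) -> float:
    """Arithmetic mean of the posterior sd over the grid."""
    return float(np.mean(grid.sd))


def compare_uncertainty(models: Sequence[GPModel], space: DesignSpace, grid_shape=(101, 101)) -> list[float]:
    """Mean grid uncertainty for several models at identical grid points."""
    grids = [uncertainty_map(m, space, grid_shape) for m in models]
    for g in grids[1:]:
        if not g.same_grid(grids[0]):
            raise ValueError("uncertainty comparison requires identical grids")
    return [mean_uncertainty(g) for g in grids]


@dataclass
class CliffResult:
    mask: np.ndarray
    area_fraction: float
    boundary: list[np.ndarray]  # polylines in (glucose_pct, nh4cl_mM) coords


def performance_cliff(grid: LandscapeGrid, cfg: CliffConfig | None = None) -> CliffResult:
    """Region of the landscape with predicted relative titre below threshold.

    The boundary polyline comes from marching squares at the threshold
    level, mapped back to composition coordinates.
    """
    cfg = cfg or CliffConfig()
    mask = grid.mean < cfg.threshold
    frac = float(mask.mean())
    contours = []
    lo, hi = float(grid.mean.min()), float(grid.mean.max())
    if lo < cfg.threshold < hi:
        for c in measure.find_contours(grid.mean, cfg.threshold):
            g = np.interp(c[:, 0], np.arange(len(grid.glucose)), grid.glucose)
            n = np.interp(c[:, 1], np.arange(len(grid.nh4cl)), grid.nh4cl)
            contours.append(np.column_stack([g, n]))
    return CliffResult(mask=mask, area_fraction=frac, boundary=contours)


def best_improvement(state: LoopState) -> tuple[float, MediaComposition]:
    """Percent improvement of the best observed relative titre over M9 (=1.0)."""
    best, comp = state.best_observed()
    return 100.0 * (best - 1.0), comp
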