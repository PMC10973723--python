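"""Flow-injection trace processing: baseline, integration, QC, normalisation.

Turns raw 1-minute injection traces into a per-batch table of
outlier-filtered relative abundances: asymmetric-least-squares (AsLS)
baseline correction where a drift statistic calls for it, trapezoid
integration of the baseline-corrected peak, interquartile-range outlier
removal within replicate groups, and normalisation of every area by the
per-batch mean of the M9-reference wells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .design import M9_REFERENCE, PlateLayout
from .synthetic_data import InjectionTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AsLSConfig:
    """Asymmetric least squares baseline parameters.

    ``lam`` controls baseline smoothness (second-difference penalty) and
    ``p`` the asymmetry: points above the baseline get weight p, points
    below get 1 - p, so peaks are largely ignored.
    """

    lam: float = 1e6
    p: float = 0.01
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must be in (0, 1)")


@dataclass(frozen=True)
class OutlierConfig:
    """IQR filter: keep values in [median - k*IQR, median + k*IQR].

    Groups smaller than ``min_n`` pass unfiltered (quartiles on very few
    points are unstable).
    """

    k: float = 1.5
    min_n: int = 4

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass(frozen=True)
class DriftConfig:
    """Decides which traces receive baseline correction.

    The drift statistic compares trailing- and leading-window medians; a
    trace is corrected when their difference exceeds ``threshold`` times
    the trace's peak amplitude.  ``mode`` can force 'always' or 'never'.
    """

    mode: str = "auto"
    window_frac: float = 0.15
    threshold: float = 0.005


def asls_baseline(trace: "InjectionTrace | np.ndarray", cfg: AsLSConfig | None = None) -> np.ndarray:
    """Estimate the baseline of a trace by asymmetric least squares.

    Iteratively solves (W + lam * D'D) z = W y with D the second-difference
    operator and weights w_i = p where y_i > z_i else 1 - p, until the
    weights stabilise (mean absolute change < tol) or ``max_iter``.
    """
    cfg = cfg or AsLSConfig()
    y = trace.intensities if isinstance(trace, InjectionTrace) else np.asarray(trace, float)
    y = np.asarray(y, float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("asls_baseline requires a 1-D signal of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("asls_baseline: intensities must be finite")
    m = y.size
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m), format="csc")
    DTD = cfg.lam * (D.T @ D)
    w = np.ones(m)
    z = y.copy()
    for _ in range(cfg.max_iter):
        W = sp.diags(w, 0, format="csc")
        z = spsolve(W + DTD, w * y)
        w_new = np.where(y > z, cfg.p, 1.0 - cfg.p)
        if np.mean(np.abs(w_new - w)) < cfg.tol:
            w = w_new
            break
        w = w_new
    return np.asarray(z, float)


def needs_baseline_correction(trace: InjectionTrace, cfg: DriftConfig | None = None) -> bool:
    """Drift statistic deciding whether a trace gets AsLS correction."""
    cfg = cfg or DriftConfig()
    if cfg.mode == "always":
        return True
    if cfg.mode == "never":
        return False
    y = trace.intensities
    w = max(3, int(round(cfg.window_frac * y.size)))
    drift = abs(float(np.median(y[-w:])) - float(np.median(y[:w])))
    amplitude = float(np.ptp(y)) + 1e-30
    return drift > cfg.threshold * amplitude


def integrate_area(trace: InjectionTrace, baseline: Optional[np.ndarray] = None) -> float:
    """Trapezoid-rule area (intensity * min) of the baseline-corrected trace.

    Negative residuals are not clipped; clipping would bias low-abundance
    wells upward.
    """
    y = trace.intensities
    if y.size < 2:
        raise ValueError("integrate_area requires at least 2 samples")
    if baseline is not None:
        baseline = np.asarray(baseline, float)
        if baseline.shape != y.shape:
            raise ValueError("baseline length must match the trace")
        y = y - baseline
    return float(np.trapezoid(y, trace.times))


def iqr_filter(values: Sequence[float], cfg: OutlierConfig | None = None) -> np.ndarray:
    """Boolean kept-mask for the median +/- k*IQR rule.

    Quartiles use linear interpolation between order statistics.
    """
    cfg = cfg or OutlierConfig()
    v = np.asarray(values, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("iqr_filter: values must be finite")
    if v.size < cfg.min_n:
        return np.ones(v.size, dtype=bool)
    med = float(np.median(v))
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = float(q3 - q1)
    lo, hi = med - cfg.k * iqr, med + cfg.k * iqr
    return (v >= lo) & (v <= hi)


@dataclass
class AbundanceTable:
    """Integrated areas (wells x metabolites) for one batch, with kept-mask."""

    data: pd.DataFrame
    batch: str = "batch0"
    kept: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = pd.DataFrame(True, index=self.data.index, columns=self.data.columns)
        if not self.kept.index.equals(self.data.index) or not self.kept.columns.equals(self.data.columns):
            raise ValueError("kept mask must be conformable with the table")
        if not np.all(np.isfinite(self.data.to_numpy(float))):
            raise ValueError("areas must be finite")


@dataclass
class RelativeAbundanceTable:
    """Areas divided by the per-batch mean of kept M9-reference areas."""

    data: pd.DataFrame
    batch: str = "batch0"
    kept: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = pd.DataFrame(True, index=self.data.index, columns=self.data.columns)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)

    def kept_values(self, metabolite: str) -> pd.Series:
        col = self.data[metabolite]
        return col[self.kept[metabolite]]

    def condition_stats(self, layout: PlateLayout, metabolite: str) -> pd.DataFrame:
        """Replicate-group summary: mean, SEM, n of kept relative abundances.

        Rows cover every treatment with a composition (combinations and the
        M9 reference); the control (no composition) is excluded.
        """
        t_of = {w.well: w for w in layout.wells}
        rows = []
        for treatment in layout.treatments:
            wells = [w.well for w in layout.wells_of(treatment)]
            comp = t_of[wells[0]].composition
            if comp is None:
                continue
            vals = []
            for well in wells:
                if well in self.data.index and bool(self.kept.loc[well, metabolite]):
                    vals.append(float(self.data.loc[well, metabolite]))
            vals = np.asarray(vals, float)
            n = vals.size
            mean = float(vals.mean()) if n else np.nan
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append(
                {
                    "treatment": treatment,
                    "glucose_pct": comp.glucose_pct,
                    "nh4cl_mM": comp.nh4cl_mM,
                    "mean": mean,
                    "sem": sem,
                    "n": n,
                }
            )
        return pd.DataFrame(rows)


def integrate_traces(
    traces: Sequence[InjectionTrace],
    asls: AsLSConfig | None = None,
    drift: DriftConfig | None = None,
    batch: str = "batch0",
) -> AbundanceTable:
    """Baseline-correct (where needed) and integrate every trace."""
    asls = asls or AsLSConfig()
    drift = drift or DriftConfig()
    records: dict[str, dict[str, float]] = {}
    for tr in traces:
        base = asls_baseline(tr, asls) if needs_baseline_correction(tr, drift) else None
        records.setdefault(tr.well, {})[tr.metabolite] = integrate_area(tr, base)
    if not records:
        return AbundanceTable(data=pd.DataFrame(), batch=batch)
    df = pd.DataFrame.from_dict(records, orient="index").sort_index()
    df = df[sorted(df.columns)]
    return AbundanceTable(data=df, batch=batch)


def apply_outlier_filter(
    table: AbundanceTable,
    layout: PlateLayout,
    cfg: OutlierConfig | None = None,
) -> AbundanceTable:
    """IQR-filter areas within each (treatment, metabolite) replicate group."""
    cfg = cfg or OutlierConfig()
    kept = table.kept.copy()
    removed = 0
    for treatment in layout.treatments:
        wells = [w.well for w in layout.wells_of(treatment) if w.well in table.data.index]
        if not wells:
            continue
        for met in table.data.columns:
            vals = table.data.loc[wells, met].to_numpy(float)
            mask = iqr_filter(vals, cfg)
            kept.loc[wells, met] = mask
            removed += int((~mask).sum())
    if removed:
        logger.info("outlier filter removed %d of %d values", removed, table.data.size)
    return AbundanceTable(data=table.data, batch=table.batch, kept=kept)


def normalise_to_m9(table: AbundanceTable, layout: PlateLayout) -> RelativeAbundanceTable:
    """Divide kept areas by the mean kept M9-reference area, per metabolite.

    A plate is one batch; every metabolite needs at least one surviving
    M9-reference well.
    """
    m9_wells = [w.well for w in layout.wells_of(M9_REFERENCE) if w.well in table.data.index]
    if not m9_wells:
        raise ValueError(f"batch {table.batch!r}: no M9_reference wells present")
    rel = table.data.copy()
    for met in table.data.columns:
        kept_ref = [w for w in m9_wells if bool(table.kept.loc[w, met])]
        if not kept_ref:
            raise ValueError(
                f"batch {table.batch!r}, metabolite {met!r}: no surviving M9_reference wells"
            )
        ref_mean = float(table.data.loc[kept_ref, met].mean())
        if ref_mean == 0.0:
            raise ValueError(
                f"batch {table.batch!r}, metabolite {met!r}: M9_reference mean is zero"
            )
        rel[met] = table.data[met] / ref_mean
    return RelativeAbundanceTable(data=rel, batch=table.batch, kept=table.kept.copy())


def process_plate(
    traces: Sequence[InjectionTrace],
    layout: PlateLayout,
    asls: AsLSConfig | None = None,
    outlier: OutlierConfig | None = None,
    drift: DriftConfig | None = None,
    batch: str | None = None,
) -> RelativeAbundanceTable:
    """Full chain: baseline -> integrate -> IQR filter -> M9 normalisation."""
    batch = batch if batch is not None else layout.batch
    table = integrate_traces(traces, asls=asls, drift=drift, batch=batch)
    if table.data.empty:
        return RelativeAbundanceTable(data=table.data, batch=batch)
    table = apply_outlier_filter(table, layout, outlier)
    return normalise_to_m9(table, layout)
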