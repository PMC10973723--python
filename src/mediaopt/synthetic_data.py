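"""Synthetic study generator: titre landscapes, metabolite panels, plates, growth.

Everything the real study measured is emulated here so the whole pipeline
is testable without any experimental data:

* a smooth 2-D relative-titre landscape over the glucose/NH4Cl space,
  anchored algebraically to 1.0 at the baseline M9 composition, with a
  configurable maximum (default 2.6x at 0.8 % glucose / 50 mM NH4Cl);
* a correlated metabolite panel with four planted subgroups and a chosen
  number of directionally anisotropic members;
* per-well 1-minute flow-injection traces (Gaussian peak over a drifting
  baseline) with heteroskedastic replicate noise and occasional outliers;
* logistic growth curves (OD600 every 10 min for 36 h, initial OD 0.1).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    CONTROL,
    M9_REFERENCE,
    DesignSpace,
    MediaComposition,
    PlateLayout,
)

TITRE_SIGNAL = "surfactin_C"


# ---------------------------------------------------------------------------
# surfaces


@dataclass(frozen=True)
class BaselineComposition:
    """The M9 medium carbon/nitrogen composition (0.4 % glucose, 18.7 mM NH4Cl)."""

    glucose_pct: float = 0.4
    nh4cl_mM: float = 18.7

    def __post_init__(self) -> None:
        if self.glucose_pct <= 0 or self.nh4cl_mM <= 0:
            raise ValueError("baseline composition values must be strictly positive")

    def as_composition(self) -> MediaComposition:
        return MediaComposition(self.glucose_pct, self.nh4cl_mM)


@dataclass(frozen=True)
class GaussianBump:
    location: MediaComposition
    height: float
    widths: tuple[float, float]

    def __post_init__(self) -> None:
        if self.widths[0] <= 0 or self.widths[1] <= 0:
            raise ValueError("bump widths must be positive")

    def __call__(self, g: np.ndarray, n: np.ndarray) -> np.ndarray:
        dg = (np.asarray(g, float) - self.location.glucose_pct) / self.widths[0]
        dn = (np.asarray(n, float) - self.location.nh4cl_mM) / self.widths[1]
        return self.height * np.exp(-0.5 * (dg**2 + dn**2))


@dataclass(frozen=True)
class SurfaceSpec:
    """Specification of the ground-truth relative-titre landscape.

    The landscape is a sum of anisotropic Gaussian bumps plus a constant
    floor, affinely anchored so the value at ``baseline_anchor`` is exactly
    1.0 and the value at ``peak_location`` is ``peak_relative_height``.
    """

    peak_location: MediaComposition = MediaComposition(0.8, 50.0)
    peak_relative_height: float = 2.6
    bump_widths: tuple[float, float] = (0.35, 28.0)
    baseline_anchor: BaselineComposition = BaselineComposition()
    extra_bumps: tuple[GaussianBump, ...] = ()

    def __post_init__(self) -> None:
        if self.peak_relative_height < 1.0:
            raise ValueError("peak_relative_height must be >= 1")
        if self.bump_widths[0] <= 0 or self.bump_widths[1] <= 0:
            raise ValueError("bump_widths must be positive")


class SurfaceFunction:
    """A deterministic smooth scalar field over the composition space.

    Callable as ``f(glucose_pct, nh4cl_mM)`` with broadcasting, or point
    evaluation through :meth:`at`.
    """

    def __init__(self, fn: Callable[[np.ndarray, np.ndarray], np.ndarray], name: str = "surface"):
        self._fn = fn
        self.name = name

    def __call__(self, glucose_pct, nh4cl_mM) -> np.ndarray:
        g = np.asarray(glucose_pct, dtype=float)
        n = np.asarray(nh4cl_mM, dtype=float)
        return np.asarray(self._fn(g, n), dtype=float)

    def at(self, comp: MediaComposition) -> float:
        return float(self(comp.glucose_pct, comp.nh4cl_mM))

    def on_points(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self(X[:, 0], X[:, 1])

    def __repr__(self) -> str:  # pragma: no cover
        return f"SurfaceFunction({self.name!r})"


def make_landscape(
    spec: SurfaceSpec | None = None,
    seed: int = 0,
    space: DesignSpace | None = None,
) -> SurfaceFunction:
    """Build the ground-truth relative-titre landscape.

    Anchoring is algebraic: with raw bump sum ``g``, the surface is
    ``f = a*g + b`` where (a, b) solve f(anchor) = 1 and f(peak) = H.
    When H = 1 the surface is the constant 1.0.  The realised maximum over
    the space is checked to agree with H within 1 %.
    """
    spec = spec or SurfaceSpec()
    space = space or DesignSpace()
    del seed  # bump placement is fully specified; kept for API symmetry
    peak = spec.peak_location
    if not space.contains(peak):
        raise ValueError(
            f"peak_location ({peak.glucose_pct} % glucose, {peak.nh4cl_mM} mM NH4Cl) "
            f"is outside the design space glucose [{space.glucose_lo}, {space.glucose_hi}], "
            f"nh4cl [{space.nh4cl_lo}, {space.nh4cl_hi}]"
        )
    main = GaussianBump(peak, 1.0, spec.bump_widths)
    bumps = (main,) + spec.extra_bumps

    def raw(g, n):
        out = np.zeros(np.broadcast(np.asarray(g), np.asarray(n)).shape)
        for b in bumps:
            out = out + b(g, n)
        return out

    anchor = spec.baseline_anchor.as_composition()
    g_anchor = float(raw(anchor.glucose_pct, anchor.nh4cl_mM))
    g_peak = float(raw(peak.glucose_pct, peak.nh4cl_mM))
    H = spec.peak_relative_height
    if H == 1.0:
        a, b = 0.0, 1.0
    else:
        if abs(g_peak - g_anchor) < 1e-12:
            raise ValueError("baseline anchor coincides with the peak; cannot anchor")
        a = (H - 1.0) / (g_peak - g_anchor)
        b = 1.0 - a * g_anchor

    fn = SurfaceFunction(lambda g, n: a * raw(g, n) + b, name="titre_landscape")
    if H > 1.0:
        _, _, pts = space.grid((201, 201))
        realised = float(fn.on_points(pts).max())
        if abs(realised - H) > 0.01 * H:
            raise ValueError(
                f"realised landscape maximum {realised:.4f} deviates from "
                f"peak_relative_height {H} by more than 1 % (extra bumps interfere)"
            )
    return fn


# ---------------------------------------------------------------------------
# metabolite panel


@dataclass(frozen=True)
class PanelSpec:
    """Planted-structure specification for the metabolite panel.

    ``group_sizes`` plants four correlated subgroups (amino-acid-like
    groups carry negative signs against lipopeptide/organic-acid groups by
    default).  ``n_asymmetric`` members additionally receive a directional
    (dipole) component around ``center`` so they show anisotropic gradient
    profiles; all other members are radially symmetric there.
    """

    group_sizes: tuple[int, ...] = (6, 7, 7, 5)
    within_group_weight: float = 0.9
    between_group_weight: float = 0.3
    sign_pattern: tuple[int, ...] = (-1, -1, 1, 1)
    n_asymmetric: int = 6
    center: MediaComposition = MediaComposition(0.8, 50.0)
    radii: tuple[float, float] = (0.6, 24.0)
    asym_strength: float = 2.0

    def __post_init__(self) -> None:
        if len(self.sign_pattern) != len(self.group_sizes):
            raise ValueError("sign_pattern must have one entry per group")
        if not all(s in (-1, 1) for s in self.sign_pattern):
            raise ValueError("sign_pattern entries must be +1 or -1")
        if not (0.0 <= self.within_group_weight <= 1.0):
            raise ValueError("within_group_weight must be in [0, 1]")
        if not (0.0 <= self.between_group_weight <= 1.0):
            raise ValueError("between_group_weight must be in [0, 1]")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.n_asymmetric > sum(self.group_sizes):
            raise ValueError("n_asymmetric exceeds the panel size")

    @property
    def size(self) -> int:
        return sum(self.group_sizes)


@dataclass
class MetabolitePanel:
    surfaces: list[SurfaceFunction]
    group_labels: np.ndarray
    names: list[str]
    asymmetric_indices: tuple[int, ...]
    asym_angles_deg: tuple[float, ...]

    def as_dict(self) -> dict[str, SurfaceFunction]:
        return dict(zip(self.names, self.surfaces))


def _random_smooth_surface(rng: np.random.Generator, space: DesignSpace, n_bumps: int = 3):
    """A zero-mean, unit-sd (over the space) sum of random Gaussian bumps."""
    span = space.hi - space.lo
    centers = space.lo + rng.random((n_bumps, 2)) * span
    widths = (0.2 + 0.4 * rng.random((n_bumps, 2))) * span
    heights = rng.uniform(-1.0, 1.0, n_bumps)

    def raw(g, n):
        out = np.zeros(np.broadcast(np.asarray(g), np.asarray(n)).shape)
        for c, w, h in zip(centers, widths, heights):
            out = out + h * np.exp(
                -0.5 * (((np.asarray(g, float) - c[0]) / w[0]) ** 2 + ((np.asarray(n, float) - c[1]) / w[1]) ** 2)
            )
        return out

    _, _, pts = space.grid((41, 41))
    vals = raw(pts[:, 0], pts[:, 1])
    mu, sd = float(vals.mean()), float(vals.std()) or 1.0

    def fn(g, n):
        return (raw(g, n) - mu) / sd

    return fn


def _normalised_radial(profile, radius_fn, space: DesignSpace):
    """Centre and scale a radial profile to unit sd over the space."""
    _, _, pts = space.grid((41, 41))
    vals = profile(radius_fn(pts[:, 0], pts[:, 1]))
    mu, sd = float(vals.mean()), float(vals.std()) or 1.0
    return lambda r: (profile(r) - mu) / sd


def _orthogonalise(fn, basis, eval_at, space: DesignSpace):
    """Residualise ``fn`` against ``basis`` functions over the space grid.

    Smooth random surfaces have few effective degrees of freedom, so two
    independent draws carry large spurious sample correlations; projecting
    each group latent out of the shared latent (and earlier group latents)
    makes the planted between-group correlation structure deterministic.
    """
    _, _, pts = space.grid((41, 41))
    f = eval_at(fn, pts)
    f = f - f.mean()
    coefs = []
    for b in basis:
        bv = eval_at(b, pts)
        bv = bv - bv.mean()
        c = float(f @ bv) / float(bv @ bv)
        coefs.append(c)
        f = f - c * bv
    sd = float(f.std()) or 1.0

    def out(*args):
        val = fn(*args)
        for c, b in zip(coefs, basis):
            val = val - c * b(*args)
        return val / sd

    # recentre so the grid mean is ~0 (constant shift, rank-irrelevant)
    return out


def make_metabolite_panel(
    panel: PanelSpec | None = None,
    seed: int = 0,
    space: DesignSpace | None = None,
) -> MetabolitePanel:
    """Generate the correlated metabolite panel with planted structure.

    Each member is built from radial profiles of the elliptically
    normalised distance ``r`` to the titre optimum (so that, inside the
    anisotropy radius, non-asymmetric members have angle-independent
    gradient magnitude) blended with generic smooth surfaces outside it
    that carry the group/shared correlation structure.  Members are
    exponentiated so abundances are strictly positive; Spearman structure
    is unaffected by that monotone map.
    """
    panel = panel or PanelSpec()
    space = space or DesignSpace()
    rng = np.random.default_rng(seed)
    n_groups = len(panel.group_sizes)
    total = panel.size

    cx, cy = panel.center.glucose_pct, panel.center.nh4cl_mM
    rx, ry = panel.radii

    def radius(g, n):
        return np.hypot((np.asarray(g, float) - cx) / rx, (np.asarray(n, float) - cy) / ry)

    def radial_bump(rho, t):
        return lambda r: np.exp(-0.5 * ((r - rho) / t) ** 2)

    # inside the anisotropy radius every non-asymmetric member is a pure
    # function of r (angle-independent gradients), shared across the whole
    # panel; the group-specific correlation structure is carried by
    # generic surfaces outside it
    psi_core = _normalised_radial(lambda r: np.exp(-0.5 * r**2), radius, space)
    eval_xy = lambda f, pts: np.asarray(f(pts[:, 0], pts[:, 1]), float)
    shared_tail = _random_smooth_surface(rng, space)
    group_tails: list = []
    for _ in range(n_groups):
        group_tails.append(
            _orthogonalise(_random_smooth_surface(rng, space), [shared_tail] + group_tails, eval_xy, space)
        )

    gamma = panel.between_group_weight  # shared-latent fraction (fixes sign)
    w = panel.within_group_weight
    sg, cg = np.sqrt(gamma), np.sqrt(1.0 - gamma)

    labels = np.repeat(np.arange(n_groups), panel.group_sizes)
    asym_idx = tuple(sorted(rng.choice(total, size=panel.n_asymmetric, replace=False).tolist()))
    asym_angles = tuple(float(a) for a in rng.uniform(0.0, 360.0, panel.n_asymmetric))
    angle_of = dict(zip(asym_idx, asym_angles))

    surfaces: list[SurfaceFunction] = []
    names: list[str] = []
    for i in range(total):
        g_id = int(labels[i])
        s = float(panel.sign_pattern[g_id])
        eta = _normalised_radial(radial_bump(rng.uniform(0.0, 2.8), rng.uniform(0.4, 0.9)), radius, space)
        ind_tail = _random_smooth_surface(rng, space)
        g_tail = group_tails[g_id]
        psi_deg = angle_of.get(i)
        psi_rad = np.deg2rad(psi_deg) if psi_deg is not None else None
        A = panel.asym_strength

        def member(g, n, *, s=s, eta=eta, g_tail=g_tail, ind_tail=ind_tail, psi_rad=psi_rad, A=A):
            r = radius(g, n)
            inside = w * psi_core(r) + (1.0 - w) * eta(r)
            outside = w * (sg * shared_tail(g, n) + cg * g_tail(g, n)) + (1.0 - w) * ind_tail(g, n)
            window = np.exp(-0.5 * (np.maximum(0.0, r - 1.0) / 0.35) ** 2)
            val = s * (window * inside + (1.0 - window) * outside)
            if psi_rad is not None:
                u = (np.asarray(g, float) - cx) / rx
                v = (np.asarray(n, float) - cy) / ry
                val = val + A * (u * np.cos(psi_rad) + v * np.sin(psi_rad)) * np.exp(-0.5 * (r / 0.75) ** 2)
            return np.exp(0.6 * val)

        surfaces.append(SurfaceFunction(member, name=f"g{g_id + 1}m{i + 1}"))
        names.append(f"g{g_id + 1}m{i + 1}")

    return MetabolitePanel(
        surfaces=surfaces,
        group_labels=labels,
        names=names,
        asymmetric_indices=asym_idx,
        asym_angles_deg=asym_angles,
    )


# ---------------------------------------------------------------------------
# plate simulation (flow-injection traces)


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate noise model for simulated measurements.

    The effective CV grows with the surface value when
    ``heteroskedastic_slope`` > 0:  cv_eff = replicate_cv * (1 + slope * value).
    """

    replicate_cv: float = 0.15
    heteroskedastic_slope: float = 0.2
    outlier_prob: float = 0.01
    outlier_scale: float = 5.0

    def __post_init__(self) -> None:
        if min(self.replicate_cv, self.heteroskedastic_slope, self.outlier_prob, self.outlier_scale) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.replicate_cv >= 1:
            raise ValueError("replicate_cv must be < 1")

    def cv_eff(self, value: float) -> float:
        return self.replicate_cv * (1.0 + self.heteroskedastic_slope * max(value, 0.0))


@dataclass(frozen=True)
class TraceSpec:
    """Shape of a simulated 1-minute flow-injection trace.

    2 Hz sampling over 60 s; the analyte elutes as a Gaussian peak at 0.3
    min whose area encodes the measured abundance (in arbitrary counts x
    min, ``area_scale`` per unit of relative abundance), over a linear
    baseline drift plus white noise.
    """

    sample_rate_hz: float = 2.0
    duration_min: float = 1.0
    peak_center_min: float = 0.3
    peak_sigma_min: float = 0.05
    area_scale: float = 1e5
    drift_frac: float = 0.02
    white_noise_frac: float = 0.002

    def times(self) -> np.ndarray:
        n = int(round(self.sample_rate_hz * 60.0 * self.duration_min)) + 1
        return np.linspace(0.0, self.duration_min, n)


@dataclass
class InjectionTrace:
    """A single (well, metabolite) intensity-vs-time record over [0, 1] min."""

    well: str
    metabolite: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if len(self.times) and (np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be strictly increasing")
        if len(self.times) and (self.times[0] < -1e-12 or self.times[-1] > 1.0 + 1e-9):
            raise ValueError("trace times must lie within [0, 1] min")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


def simulate_plate(
    layout: PlateLayout,
    surfaces: dict[str, SurfaceFunction],
    noise: NoiseSpec | None = None,
    seed: int = 0,
    trace: TraceSpec | None = None,
    baseline: BaselineComposition | None = None,
    control_value: float = 0.0,
) -> list[InjectionTrace]:
    """Simulate flow-injection traces for every (well, metabolite) pair.

    Each trace is a Gaussian peak whose area equals
    ``surface_value * (1 + eps)`` with eps ~ N(0, cv_eff^2), plus linear
    drift and white noise; with probability ``outlier_prob`` the area is
    multiplied by ``outlier_scale``.  Control wells measure
    ``control_value``; M9-reference wells measure the surface at the
    baseline composition.
    """
    noise = noise or NoiseSpec()
    trace = trace or TraceSpec()
    baseline = baseline or BaselineComposition()
    rng = np.random.default_rng(seed)
    t = trace.times()
    peak_shape = np.exp(-0.5 * ((t - trace.peak_center_min) / trace.peak_sigma_min) ** 2)
    peak_shape = peak_shape / (trace.peak_sigma_min * np.sqrt(2 * np.pi))  # unit area

    out: list[InjectionTrace] = []
    for w in layout.wells:
        if w.treatment == CONTROL or w.composition is None:
            comp = None
        elif w.treatment == M9_REFERENCE:
            comp = baseline.as_composition()
        else:
            comp = w.composition
        for name, surf in surfaces.items():
            value = control_value if comp is None else surf.at(comp)
            cv = noise.cv_eff(value)
            eps = rng.normal(0.0, cv) if cv > 0 else 0.0
            area = value * (1.0 + eps) * trace.area_scale
            if noise.outlier_prob > 0 and rng.random() < noise.outlier_prob:
                area *= noise.outlier_scale
            y = area * peak_shape
            if trace.drift_frac > 0:
                amp = rng.uniform(-1.0, 1.0) * trace.drift_frac * trace.area_scale
                y = y + rng.uniform(0.0, 0.2) * trace.area_scale * trace.drift_frac + amp * t
            if trace.white_noise_frac > 0:
                y = y + rng.normal(0.0, trace.white_noise_frac * trace.area_scale, t.shape)
            out.append(InjectionTrace(well=w.well, metabolite=name, times=t.copy(), intensities=y))
    return out


def traces_to_frame(traces: Sequence[InjectionTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "well": tr.well,
                    "metabolite": tr.metabolite,
                    "time_min": tr.times,
                    "intensity": tr.intensities,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["well", "metabolite", "time_min", "intensity"])
    return pd.concat(frames, ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[InjectionTrace]:
    out = []
    for (well, met), grp in df.groupby(["well", "metabolite"], sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            InjectionTrace(
                well=str(well),
                metabolite=str(met),
                times=grp["time_min"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
            )
        )
    return out


def write_traces_csv(traces: Sequence[InjectionTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path) -> list[InjectionTrace]:
    return traces_from_frame(pd.read_csv(path))


def write_truth_grid(
    surfaces: dict[str, SurfaceFunction],
    path,
    space: DesignSpace | None = None,
    shape: tuple[int, int] = (41, 41),
) -> pd.DataFrame:
    """Export ground-truth surface values on a grid (oracle for tests)."""
    space = space or DesignSpace()
    _, _, pts = space.grid(shape)
    df = pd.DataFrame({"glucose_pct": pts[:, 0], "nh4cl_mM": pts[:, 1]})
    for name, surf in surfaces.items():
        df[name] = surf.on_points(pts)
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class GrowthSpec:
    """Logistic growth model OD(t) = od0 + (K - od0)/(1 + exp(-r (t - t_mid))).

    The carrying capacity K varies smoothly with composition; the coupling
    between the growth surface and the titre landscape is explicit (peak
    location/widths) rather than assumed.
    """

    od0: float = 0.1
    k_min: float = 0.25
    k_gain: float = 1.3
    k_peak: MediaComposition = MediaComposition(1.2, 65.0)
    k_widths: tuple[float, float] = (0.7, 45.0)
    rate_per_min: float = 0.012
    t_mid_min: float = 700.0
    noise_sd: float = 0.01
    cadence_min: float = 10.0
    horizon_min: float = 36 * 60.0


@dataclass
class GrowthCurve:
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.od = np.asarray(self.od, float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od must be non-negative")


def carrying_capacity(comp: MediaComposition, spec: GrowthSpec | None = None) -> float:
    spec = spec or GrowthSpec()
    bump = GaussianBump(spec.k_peak, 1.0, spec.k_widths)
    return float(spec.k_min + spec.k_gain * bump(comp.glucose_pct, comp.nh4cl_mM))


def carrying_capacity_surface(spec: GrowthSpec | None = None) -> SurfaceFunction:
    spec = spec or GrowthSpec()
    bump = GaussianBump(spec.k_peak, 1.0, spec.k_widths)
    return SurfaceFunction(lambda g, n: spec.k_min + spec.k_gain * bump(g, n), name="max_OD")


def simulate_growth(
    composition: MediaComposition,
    seed: int = 0,
    spec: GrowthSpec | None = None,
) -> GrowthCurve:
    """Simulate one OD600 time course (10-min cadence over 36 h)."""
    spec = spec or GrowthSpec()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, spec.horizon_min + 0.5 * spec.cadence_min, spec.cadence_min)
    K = carrying_capacity(composition, spec)
    od = spec.od0 + (K - spec.od0) / (1.0 + np.exp(-spec.rate_per_min * (t - spec.t_mid_min)))
    if spec.noise_sd > 0:
        od = od + rng.normal(0.0, spec.noise_sd, t.shape)
    return GrowthCurve(times=t, od=np.maximum(od, 0.0))


def growth_features(curve: GrowthCurve, smooth_window: int = 0) -> tuple[float, float]:
    """(max OD, final OD) of the optionally median-smoothed curve."""
    od = curve.od
    if smooth_window > 1:
        od = pd.Series(od).rolling(smooth_window, center=True, min_periods=1).median().to_numpy()
    return float(np.max(od)), float(od[-1])
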