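"""Post-loop analyses: correlation clustering, PCA, Pareto fronts, anisotropy.

These reproduce the study's downstream characterisation of the loop data:
Spearman correlation structure of the measured signals with hierarchical
clustering, a PCA of the loop samples, sampled (titre, max OD) Pareto
trade-offs, and the directional "metabolic anisotropy" analysis - the mean
gradient of each signal's surface along straight radial paths around the
titre optimum, as a function of direction angle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .design import DesignSpace, MediaComposition
from .surrogate import GPModel
from .synthetic_data import SurfaceFunction

logger = logging.getLogger(__name__)

#: a signal surface: fitted GP model or a plain deterministic surface
SignalModel = Union[GPModel, SurfaceFunction, Callable]


def _eval_points(model: SignalModel, X: np.ndarray) -> np.ndarray:
    """Posterior mean of a GP, or direct evaluation of a surface, at (m, 2) points."""
    X = np.atleast_2d(np.asarray(X, float))
    if isinstance(model, GPModel):
        mean, _ = model.predict(X)
        return mean
    if isinstance(model, SurfaceFunction):
        return model.on_points(X)
    return np.asarray(model(X[:, 0], X[:, 1]), float)


# ---------------------------------------------------------------------------
# correlation structure


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame
    linkage: Optional[np.ndarray] = None
    leaf_order: Optional[list[str]] = None
    labels: Optional[pd.Series] = None


def spearman_matrix(table: pd.DataFrame) -> CorrelationResult:
    """Pairwise Spearman rank correlation (mid-rank ties) between columns.

    Constant columns have undefined correlation; they are emitted as NaN
    with a warning.
    """
    if table.shape[0] < 3:
        raise ValueError("spearman_matrix requires at least 3 samples")
    values = table.to_numpy(float)
    constant = table.columns[np.ptp(values, axis=0) == 0].tolist()
    if constant:
        warnings.warn(
            f"constant columns have undefined Spearman correlation: {constant}",
            UserWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(values, axis=0).statistic
    p = table.shape[1]
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.atleast_2d(rho)
    assert rho.shape == (p, p)
    mat = pd.DataFrame(rho, index=table.columns, columns=table.columns)
    for c in mat.columns:
        mat.loc[c, c] = 1.0
    return CorrelationResult(matrix=mat)


def hierarchical_cluster(corr: "CorrelationResult | pd.DataFrame", k: int) -> CorrelationResult:
    """Average-linkage agglomerative clustering on distance 1 - rho.

    Returns the merge history, the dendrogram leaf order and the flat
    labels from cutting at ``k`` clusters.
    """
    mat = corr.matrix if isinstance(corr, CorrelationResult) else corr
    if mat.isna().any().any():
        pairs = [
            (str(a), str(b))
            for a in mat.index
            for b in mat.columns
            if pd.isna(mat.loc[a, b])
        ]
        raise ValueError(f"correlation matrix has missing entries for pairs: {pairs[:10]}")
    D = 1.0 - mat.to_numpy(float)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return CorrelationResult(
        matrix=mat,
        linkage=Z,
        leaf_order=[str(mat.columns[i]) for i in leaves],
        labels=pd.Series(labels, index=mat.columns, name="cluster"),
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(table: pd.DataFrame, standardise: bool = True) -> PCAResult:
    """Column-centred (optionally unit-variance) PCA via SVD.

    Explained-variance fractions come from the squared singular values.
    Sign convention: within each component the largest-magnitude loading
    is made positive, so results are deterministic.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("pca requires at least 2 samples and 2 signals")
    X = table.to_numpy(float)
    X = X - X.mean(axis=0)
    if standardise:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = table.columns[sd == 0].tolist()
            raise ValueError(f"zero-variance columns cannot be standardised: {zero}")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    # deterministic sign: largest |loading| positive per component
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    comps = [f"PC{j + 1}" for j in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=table.columns, columns=comps),
        explained_variance_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# Pareto trade-offs


@dataclass
class ParetoResult:
    points: pd.DataFrame  # columns: titre, max_od
    front_indices: np.ndarray  # indices of non-dominated points, sorted by titre

    @property
    def front(self) -> pd.DataFrame:
        return self.points.iloc[self.front_indices]


def sample_tradeoff(
    titre_model: SignalModel,
    od_model: SignalModel,
    n: int,
    space: DesignSpace | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Predict (titre, max OD) at n seeded uniform compositions."""
    space = space or DesignSpace()
    rng = np.random.default_rng(seed)
    X = space.from_unit(rng.random((n, 2)))
    return pd.DataFrame(
        {
            "glucose_pct": X[:, 0],
            "nh4cl_mM": X[:, 1],
            "titre": _eval_points(titre_model, X),
            "max_od": _eval_points(od_model, X),
        }
    )


def pareto_front(points: pd.DataFrame) -> ParetoResult:
    """Non-dominated set under joint maximisation of titre and max OD.

    A point is dominated when another point is >= in both objectives and
    strictly greater in at least one.
    """
    T = points["titre"].to_numpy(float)
    O = points["max_od"].to_numpy(float)
    n = len(T)
    if n == 0:
        return ParetoResult(points=points, front_indices=np.array([], dtype=int))
    ge_t = T[None, :] >= T[:, None]
    ge_o = O[None, :] >= O[:, None]
    strict = (T[None, :] > T[:, None]) | (O[None, :] > O[:, None])
    dominated = np.any(ge_t & ge_o & strict, axis=1)
    idx = np.flatnonzero(~dominated)
    return ParetoResult(points=points, front_indices=idx[np.argsort(T[idx])])


# ---------------------------------------------------------------------------
# directional anisotropy


@dataclass(frozen=True)
class AnisotropyConfig:
    """Radial-path gradient profiling around the titre optimum.

    Directions are defined in axis-normalised coordinates: the ellipse
    with semi-axes ``radius_glucose`` and ``radius_nh4cl`` maps to the
    unit circle, so 0 deg is a pure glucose increase and 90 deg a pure
    NH4Cl increase.
    """

    radius_glucose: float = 0.6
    radius_nh4cl: float = 24.0
    n_angles: int = 36
    n_path: int = 100
    center: Optional[MediaComposition] = None  # default: titre-model argmax

    def __post_init__(self) -> None:
        if self.radius_glucose <= 0 or self.radius_nh4cl <= 0:
            raise ValueError("radii must be positive")
        if self.n_path < 2:
            raise ValueError("n_path must be >= 2")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * (360.0 / self.n_angles)


@dataclass
class AnisotropyProfile:
    name: str
    angles_deg: np.ndarray
    gradients: np.ndarray  # signed mean gradient per angle; NaN = missing
    center: MediaComposition

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"signal": self.name, "angle_deg": self.angles_deg, "gradient": self.gradients}
        )


def find_titre_center(
    titre_model: SignalModel,
    space: DesignSpace,
    grid_shape: tuple[int, int] = (201, 201),
) -> MediaComposition:
    """Model-predicted titre maximiser on a dense grid."""
    _, _, pts = space.grid(grid_shape)
    vals = _eval_points(titre_model, pts)
    best = pts[int(np.argmax(vals))]
    return MediaComposition(float(best[0]), float(best[1]))


def anisotropy_profile(
    signal_model: SignalModel,
    titre_model: SignalModel,
    cfg: AnisotropyConfig | None = None,
    space: DesignSpace | None = None,
    name: str = "signal",
) -> AnisotropyProfile:
    """Mean gradient of a signal along radial paths, per direction angle.

    For each angle the path is the straight segment from the centre to the
    ellipse point at that angle, sampled at ``n_path`` equally spaced
    points; the gradient is the mean of successive finite-difference
    slopes with respect to normalised arc length (centre -> endpoint = 1).
    Paths are clipped at the space bounds (logged); fully clipped angles
    are reported as NaN.
    """
    cfg = cfg or AnisotropyConfig()
    space = space or DesignSpace()
    center = cfg.center or find_titre_center(titre_model, space)
    c = np.array([center.glucose_pct, center.nh4cl_mM])
    on_boundary = np.any(np.isclose(c, space.lo)) or np.any(np.isclose(c, space.hi))
    if on_boundary:
        warnings.warn("anisotropy centre lies on the design-space boundary", UserWarning, stacklevel=2)
    s = np.linspace(0.0, 1.0, cfg.n_path)
    grads = np.full(cfg.n_angles, np.nan)
    for i, theta in enumerate(np.deg2rad(cfg.angles_deg)):
        end = c + np.array([cfg.radius_glucose * np.cos(theta), cfg.radius_nh4cl * np.sin(theta)])
        path = c[None, :] + s[:, None] * (end - c)[None, :]
        clipped = space.clip(path)
        if not np.allclose(clipped, path):
            logger.info("anisotropy path at %.0f deg clipped to the design space", np.rad2deg(theta))
        span = np.linalg.norm(clipped[-1] - clipped[0])
        if span < 1e-12:
            continue  # fully clipped: missing
        vals = _eval_points(signal_model, clipped)
        slopes = np.diff(vals) / np.diff(s)
        grads[i] = float(np.mean(slopes))
    return AnisotropyProfile(name=name, angles_deg=cfg.angles_deg, gradients=grads, center=center)


def asymmetry_index(profile: AnisotropyProfile, eps: float = 1e-12) -> float:
    """(max|g| - min|g|) / (mean|g| + eps) over non-missing angles; 0 if all zero."""
    g = np.abs(profile.gradients[np.isfinite(profile.gradients)])
    if g.size == 0 or np.all(g == 0):
        return 0.0
    return float((g.max() - g.min()) / (g.mean() + eps))


@dataclass
class AsymmetricSignal:
    name: str
    index: float
    dominant_angle_deg: float


def filter_asymmetric(
    profiles: Sequence[AnisotropyProfile],
    threshold: float = 0.5,
) -> list[AsymmetricSignal]:
    """Signals whose gradient profile is directionally asymmetric.

    A signal passes when its asymmetry index exceeds ``threshold``; the
    dominant direction is the angle of the largest |gradient|.
    """
    out = []
    for p in profiles:
        idx = asymmetry_index(p)
        if idx > threshold:
            finite = np.isfinite(p.gradients)
            j = int(np.nanargmax(np.abs(np.where(finite, p.gradients, 0.0))))
            out.append(AsymmetricSignal(name=p.name, index=idx, dominant_angle_deg=float(p.angles_deg[j])))
    return out


def profiles_to_frame(profiles: Sequence[AnisotropyProfile]) -> pd.DataFrame:
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
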