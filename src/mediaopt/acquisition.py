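"""Batch candidate proposal by Monte-Carlo q-noisy expected improvement.

qNEI scores a batch of candidate compositions by drawing joint posterior
samples of the latent titre at the observed and candidate points; per
sample the improvement is ``max(0, max over candidates - (max over
observed + xi))`` and the acquisition value is the sample mean.  The
incumbent is therefore itself sampled ("noisy").  Batches are built by
greedy sequential selection over a seeded Sobol candidate pool, with
already-selected (pending) points conditioned on through the shared joint
samples.  The closed-form single-point expected improvement is provided
as an analytic oracle.

Acquisition values are reported on the model's standardized (z-scored)
output scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm, qmc

from .design import DesignSpace, MediaComposition
from .surrogate import GPModel, _chol_with_jitter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcquisitionConfig:
    q: int = 7
    mc_samples: int = 4096
    xi: float = 0.01
    pool_size: int = 2048
    seed: int = 0
    min_separation: float = 0.02  # unit-square distance between batch members
    grid_shape: tuple[int, int] = (101, 101)

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")


@dataclass
class AcquisitionBatch:
    compositions: list[MediaComposition]
    acq_values: np.ndarray
    acq_se: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.array([[c.glucose_pct, c.nh4cl_mM] for c in self.compositions])


def analytic_ei(mean, sd, incumbent: float, xi: float = 0.0):
    """Closed-form expected improvement over ``incumbent + xi``.

    EI = (mu - f* - xi) Phi(z) + sigma phi(z) with
    z = (mu - f* - xi) / sigma; for sigma = 0 it degenerates to
    max(0, mu - f* - xi).
    """
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    if np.any(sd < 0):
        raise ValueError("sd must be non-negative")
    delta = mean - incumbent - xi
    out = np.where(delta > 0, delta, 0.0).astype(float)
    pos = sd > 0
    if np.any(pos):
        z = np.divide(delta, sd, out=np.zeros_like(delta), where=pos)
        ei = delta * norm.cdf(z) + sd * norm.pdf(z)
        out = np.where(pos, ei, out)
    return out if out.ndim else float(out)


def _joint_samples(
    model: GPModel,
    U: np.ndarray,
    mc_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw joint latent samples (n_points, mc_samples) at unit-square points."""
    mean, cov = model.posterior_joint(U)
    try:
        L, jitter = _chol_with_jitter(cov, start=0.0)
    except np.linalg.LinAlgError:
        # degenerate joint covariance: fall back to eigen clipping
        logger.warning("joint covariance degenerate; using clipped eigendecomposition")
        vals, vecs = np.linalg.eigh(cov)
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        jitter = np.nan
    if np.isfinite(jitter) and jitter > 0:
        logger.debug("joint covariance required jitter %.3e", jitter)
    Z = rng.standard_normal((U.shape[0], mc_samples))
    return mean[:, None] + L @ Z


def qnei_with_se(
    model: GPModel,
    candidates,
    cfg: AcquisitionConfig | None = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """qNEI estimate and its Monte-Carlo standard error."""
    cfg = cfg or AcquisitionConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    Uc = model._as_unit(candidates)
    n_obs = model.n
    if n_obs:
        pts = np.vstack([model.dataset.X_unit, Uc])
    else:
        pts = Uc
    F = _joint_samples(model, pts, cfg.mc_samples, rng)
    incumbent = F[:n_obs].max(axis=0) if n_obs else 0.0
    imp = np.maximum(F[n_obs:].max(axis=0) - (incumbent + cfg.xi), 0.0)
    return float(imp.mean()), float(imp.std(ddof=1) / np.sqrt(cfg.mc_samples))


def qnei(
    model: GPModel,
    candidates,
    cfg: AcquisitionConfig | None = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo q-noisy expected improvement of a candidate batch."""
    return qnei_with_se(model, candidates, cfg, rng)[0]


def _candidate_pool(model: GPModel, space: DesignSpace, cfg: AcquisitionConfig, seed) -> np.ndarray:
    """Seeded Sobol pool on the unit square plus the current grid argmax."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two draws
        sob = qmc.Sobol(d=2, scramble=True, seed=seed)
        U = sob.random(cfg.pool_size)
    _, _, grid_pts = space.grid(cfg.grid_shape)
    mean, _ = model.predict(grid_pts)
    best = space.to_unit(grid_pts[int(np.argmax(mean))])
    return np.vstack([U, best])


def propose_batch(
    model: GPModel,
    space: DesignSpace | None = None,
    cfg: AcquisitionConfig | None = None,
) -> AcquisitionBatch:
    """Greedy sequential qNEI batch construction.

    At each of q steps every pool candidate is scored, jointly with the
    already-selected (pending) points, under one shared set of posterior
    samples; the best candidate is appended.  A minimum pairwise
    separation between batch members is enforced on the unit square.
    """
    cfg = cfg or AcquisitionConfig()
    space = space or model.space
    if model.n < 1:
        raise ValueError("propose_batch requires a model fitted to at least one observation")
    ss = np.random.SeedSequence(cfg.seed)
    pool_seed, sample_seed = [np.random.default_rng(s) for s in ss.spawn(2)]
    rng = sample_seed
    pool = _candidate_pool(model, space, cfg, pool_seed)
    n_pool = pool.shape[0]
    X_obs = model.dataset.X_unit

    selected: list[int] = []
    values: list[float] = []
    ses: list[float] = []
    for _ in range(cfg.q):
        pend = pool[selected] if selected else np.empty((0, 2))
        pts = np.vstack([X_obs, pend, pool])
        F = _joint_samples(model, pts, cfg.mc_samples, rng)
        n_obs, n_pend = X_obs.shape[0], pend.shape[0]
        incumbent = F[:n_obs].max(axis=0)
        pend_max = (
            F[n_obs : n_obs + n_pend].max(axis=0)
            if n_pend
            else np.full(cfg.mc_samples, -np.inf)
        )
        Fc = F[n_obs + n_pend :]
        imp = np.maximum(np.maximum(pend_max[None, :], Fc) - (incumbent + cfg.xi)[None, :], 0.0)
        scores = imp.mean(axis=1)
        allowed = np.ones(n_pool, dtype=bool)
        allowed[selected] = False
        if selected:
            d = np.linalg.norm(pool[:, None, :] - pool[selected][None, :, :], axis=2)
            allowed &= np.all(d >= cfg.min_separation, axis=1)
        if not allowed.any():
            raise RuntimeError(
                "candidate pool exhausted under the separation constraint; "
                "reduce q or min_separation, or enlarge the pool"
            )
        idx = int(np.argmax(np.where(allowed, scores, -np.inf)))
        selected.append(idx)
        values.append(float(scores[idx]))
        ses.append(float(imp[idx].std(ddof=1) / np.sqrt(cfg.mc_samples)))

    comps = [MediaComposition(*space.from_unit(pool[i])[0]) for i in selected]
    return AcquisitionBatch(
        compositions=comps,
        acq_values=np.asarray(values),
        acq_se=np.asarray(ses),
    )
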