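"""Heteroskedastic Gaussian-process surrogate of the titre landscape.

A Matern-5/2 GP with per-axis lengthscales models relative titre over the
glucose/NH4Cl space.  Heteroskedasticity enters through fixed per-point
observation-noise variances (the squared standard error of the replicate
mean), added to the kernel diagonal together with a small homoscedastic
jitter.  Inputs are mapped to the unit square and outputs z-scored before
fitting; predictions are returned on the original titre scale and the
predictive sd is that of the latent mean (observation noise excluded).

Hyperparameters maximise the log marginal likelihood by seeded multi-start
bounded optimisation (delegated to scikit-learn); posterior prediction and
joint covariance are computed here by Cholesky factorisation so that joint
sampling for the acquisition function is available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .design import DesignSpace, MediaComposition, compositions_to_array


@dataclass(frozen=True)
class GPConfig:
    """Hyperparameter bounds (on the unit-square / centred scale) and fit options.

    ``*_prior`` entries are (median, sd-of-log) of lognormal hyperpriors:
    fitting maximises the penalised marginal likelihood (MAP-II), which
    keeps lengthscales away from degenerate flat fits on small early-loop
    datasets and makes uncertainty maps comparable across iterations.
    ``use_priors=False`` recovers plain ML-II.
    """

    lengthscale_bounds: tuple[float, float] = (0.05, 5.0)
    signal_var_bounds: tuple[float, float] = (1e-6, 10.0)
    noise_var_bounds: tuple[float, float] = (1e-6, 10.0)
    n_restarts: int = 8
    seed: int = 0
    jitter: float = 1e-10
    use_priors: bool = True
    signal_var_prior: tuple[float, float] = (0.5, 0.15)
    lengthscale_prior: tuple[float, float] = (0.3, 0.2)
    noise_var_prior: tuple[float, float] = (1e-3, 1.5)


@dataclass
class GPDataset:
    """Training data on internal scales, with invertible transforms stored."""

    X_unit: np.ndarray
    y_raw: np.ndarray
    noise_var_raw: np.ndarray
    space: DesignSpace
    y_mean: float
    y_std: float

    @classmethod
    def from_observations(
        cls,
        compositions: "Sequence[MediaComposition] | np.ndarray",
        y: Sequence[float],
        noise_var: Sequence[float] | None = None,
        space: DesignSpace | None = None,
        standardize: bool = True,
    ) -> "GPDataset":
        space = space or DesignSpace()
        if len(compositions) and isinstance(compositions[0], MediaComposition):
            X = compositions_to_array(compositions)  # type: ignore[arg-type]
        else:
            X = np.atleast_2d(np.asarray(compositions, float))
        y = np.asarray(y, float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("compositions and y must have equal length")
        if y.size < 1:
            raise ValueError("GPDataset requires n >= 1 observations")
        nv = np.zeros_like(y) if noise_var is None else np.asarray(noise_var, float).ravel()
        if np.any(nv < 0):
            raise ValueError("noise_var must be non-negative")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.all(np.isfinite(nv))):
            raise ValueError("GPDataset values must be finite")
        if standardize:
            # centre only: relative titres are already dimensionless O(1),
            # and a fixed output scale keeps uncertainty maps comparable
            # between loop iterations
            y_mean, y_std = float(y.mean()), 1.0
        else:
            y_mean, y_std = 0.0, 1.0
        return cls(
            X_unit=space.to_unit(X),
            y_raw=y,
            noise_var_raw=nv,
            space=space,
            y_mean=y_mean,
            y_std=y_std,
        )

    @property
    def n(self) -> int:
        return int(self.y_raw.size)

    @property
    def y_z(self) -> np.ndarray:
        return (self.y_raw - self.y_mean) / self.y_std

    @property
    def noise_var_z(self) -> np.ndarray:
        return self.noise_var_raw / self.y_std**2


def _chol_with_jitter(K: np.ndarray, start: float = 0.0, max_jitter: float = 1e-3):
    """Cholesky factorisation with escalating diagonal jitter."""
    jitter = start
    scale = float(np.mean(np.diag(K))) if K.size else 1.0
    for _ in range(12):
        try:
            L = np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * max(scale, 1.0))
            if jitter > max_jitter * max(scale, 1.0):
                break
    raise np.linalg.LinAlgError(
        "covariance matrix is not positive definite even after jitter escalation"
    )


class GPModel:
    """A fitted (or fixed-hyperparameter) heteroskedastic GP.

    ``signal_var``, ``lengthscales`` and ``noise_var`` live on the internal
    unit-square / z-scored scale.  A model with an empty dataset represents
    the GP prior.
    """

    def __init__(
        self,
        dataset: Optional[GPDataset],
        signal_var: float,
        lengthscales: Sequence[float],
        noise_var: float,
        space: DesignSpace | None = None,
        lml: Optional[float] = None,
        cfg: GPConfig | None = None,
    ):
        self.dataset = dataset
        self.signal_var = float(signal_var)
        self.lengthscales = np.asarray(lengthscales, float)
        self.noise_var = float(noise_var)
        self.space = dataset.space if dataset is not None else (space or DesignSpace())
        self.lml = lml
        self.cfg = cfg or GPConfig()
        if min(self.signal_var, self.noise_var) <= 0 or np.any(self.lengthscales <= 0):
            raise ValueError("kernel hyperparameters must be strictly positive")
        self._matern = Matern(length_scale=self.lengthscales, nu=2.5)
        self._factor = None
        self._gpr = None

    # -- transforms ---------------------------------------------------------

    @property
    def y_mean(self) -> float:
        return self.dataset.y_mean if self.dataset is not None else 0.0

    @property
    def y_std(self) -> float:
        return self.dataset.y_std if self.dataset is not None else 1.0

    @property
    def n(self) -> int:
        return self.dataset.n if self.dataset is not None else 0

    def _as_unit(self, points) -> np.ndarray:
        if isinstance(points, MediaComposition):
            points = [points]
        if len(points) and isinstance(points[0], MediaComposition):
            points = compositions_to_array(points)
        return self.space.to_unit(np.asarray(points, float))

    # -- posterior ----------------------------------------------------------

    def _kf(self, A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
        return self.signal_var * (self._matern(A) if B is None else self._matern(A, B))

    def _train_factor(self):
        if self._factor is None:
            X = self.dataset.X_unit
            K = self._kf(X) + np.diag(self.dataset.noise_var_z) + self.noise_var * np.eye(self.n)
            L, _ = _chol_with_jitter(K, start=self.cfg.jitter)
            alpha = cho_solve((L, True), self.dataset.y_z)
            self._factor = (L, alpha)
        return self._factor

    def posterior_joint(self, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Latent-mean posterior (mean, full covariance) on the z scale.

        ``U`` is (m, 2) on the unit square.  Observation noise is excluded
        from the covariance.
        """
        U = np.atleast_2d(np.asarray(U, float))
        prior_cov = self._kf(U)
        if self.n == 0:
            return np.zeros(U.shape[0]), prior_cov
        L, alpha = self._train_factor()
        Ks = self._kf(self.dataset.X_unit, U)
        mean = Ks.T @ alpha
        V = solve_triangular(L, Ks, lower=True)
        cov = prior_cov - V.T @ V
        return mean, cov

    def predict(self, points, return_cov: bool = False):
        """Posterior mean and sd (or covariance) on the original titre scale."""
        U = self._as_unit(points)
        if return_cov:
            mean_z, cov_z = self.posterior_joint(U)
            return self.y_mean + self.y_std * mean_z, self.y_std**2 * cov_z
        # diagonal-only path: avoids forming the m x m prior covariance
        if self.n == 0:
            mean_z = np.zeros(U.shape[0])
            var_z = np.full(U.shape[0], self.signal_var)
        else:
            L, alpha = self._train_factor()
            Ks = self._kf(self.dataset.X_unit, U)
            mean_z = Ks.T @ alpha
            V = solve_triangular(L, Ks, lower=True)
            var_z = self.signal_var - np.einsum("ij,ij->j", V, V)
        mean = self.y_mean + self.y_std * mean_z
        sd = self.y_std * np.sqrt(np.clip(var_z, 0.0, None))
        return mean, sd

    def prior_sd(self) -> float:
        return float(self.y_std * np.sqrt(self.signal_var))

    # -- marginal likelihood ------------------------------------------------

    def _kernel(self):
        cfg = self.cfg
        return (
            ConstantKernel(self.signal_var, cfg.signal_var_bounds)
            * Matern(self.lengthscales, (cfg.lengthscale_bounds,) * 2, nu=2.5)
            + WhiteKernel(self.noise_var, cfg.noise_var_bounds)
        )

    def _sk_gpr(self) -> GaussianProcessRegressor:
        if self.n == 0:
            raise ValueError("log marginal likelihood requires at least one observation")
        if self._gpr is None:
            gpr = GaussianProcessRegressor(
                kernel=self._kernel(),
                alpha=self.dataset.noise_var_z + self.cfg.jitter,
                optimizer=None,
                normalize_y=False,
            )
            gpr.fit(self.dataset.X_unit, self.dataset.y_z)
            self._gpr = gpr
        return self._gpr

    def log_marginal_likelihood(self, theta: np.ndarray | None = None, eval_gradient: bool = False):
        """LML of the (z-scored) data; ``theta`` are log kernel parameters
        in scikit-learn order (signal_var, lengthscale_1, lengthscale_2,
        noise_var)."""
        gpr = self._sk_gpr()
        if theta is None:
            theta = gpr.kernel_.theta
        return gpr.log_marginal_likelihood(np.asarray(theta, float), eval_gradient=eval_gradient)

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "signal_var": self.signal_var,
            "lengthscales": self.lengthscales.tolist(),
            "noise_var": self.noise_var,
            "lml": self.lml,
            "space": {
                "glucose_lo": self.space.glucose_lo,
                "glucose_hi": self.space.glucose_hi,
                "nh4cl_lo": self.space.nh4cl_lo,
                "nh4cl_hi": self.space.nh4cl_hi,
            },
        }
        if self.dataset is not None:
            d["dataset"] = {
                "X_unit": self.dataset.X_unit.tolist(),
                "y_raw": self.dataset.y_raw.tolist(),
                "noise_var_raw": self.dataset.noise_var_raw.tolist(),
                "y_mean": self.dataset.y_mean,
                "y_std": self.dataset.y_std,
            }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "GPModel":
        d = json.loads(s)
        space = DesignSpace(**d["space"])
        dataset = None
        if "dataset" in d:
            ds = d["dataset"]
            dataset = GPDataset(
                X_unit=np.asarray(ds["X_unit"], float).reshape(-1, 2),
                y_raw=np.asarray(ds["y_raw"], float),
                noise_var_raw=np.asarray(ds["noise_var_raw"], float),
                space=space,
                y_mean=float(ds["y_mean"]),
                y_std=float(ds["y_std"]),
            )
        return cls(
            dataset=dataset,
            signal_var=d["signal_var"],
            lengthscales=d["lengthscales"],
            noise_var=d["noise_var"],
            space=space,
            lml=d.get("lml"),
        )


def _map_optimizer(cfg: GPConfig):
    """L-BFGS-B optimiser of the lognormal-prior-penalised marginal likelihood.

    theta is the log kernel-parameter vector in scikit-learn order
    (signal_var, lengthscale_1, lengthscale_2, noise_var).
    """
    from scipy.optimize import minimize

    priors = [cfg.signal_var_prior, cfg.lengthscale_prior, cfg.lengthscale_prior, cfg.noise_var_prior]
    mu = np.log([p[0] for p in priors])
    sig = np.array([p[1] for p in priors])

    def optimizer(obj_func, initial_theta, bounds):
        def penalised(theta):
            val, grad = obj_func(theta, eval_gradient=True)
            d = (theta - mu) / sig**2
            return val + 0.5 * np.sum((theta - mu) ** 2 / sig**2), grad + d

        res = minimize(penalised, initial_theta, jac=True, method="L-BFGS-B", bounds=bounds)
        return res.x, float(res.fun)

    return optimizer


def fit_gp(dataset: GPDataset, cfg: GPConfig | None = None, optimize: bool = True) -> GPModel:
    """Fit kernel hyperparameters by seeded multi-start bounded optimisation
    of the (optionally prior-penalised) log marginal likelihood."""
    cfg = cfg or GPConfig()
    kernel = (
        ConstantKernel(1.0, cfg.signal_var_bounds)
        * Matern([0.3, 0.3], (cfg.lengthscale_bounds,) * 2, nu=2.5)
        + WhiteKernel(1e-4, cfg.noise_var_bounds)
    )
    do_opt = optimize and dataset.n >= 2
    if not do_opt:
        optimizer = None
    elif cfg.use_priors:
        optimizer = _map_optimizer(cfg)
    else:
        optimizer = "fmin_l_bfgs_b"
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=dataset.noise_var_z + cfg.jitter,
        optimizer=optimizer,
        n_restarts_optimizer=max(cfg.n_restarts - 1, 0) if do_opt else 0,
        random_state=cfg.seed,
        normalize_y=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gpr.fit(dataset.X_unit, dataset.y_z)
    k = gpr.kernel_
    signal_var = float(k.k1.k1.constant_value)
    lengthscales = np.atleast_1d(np.asarray(k.k1.k2.length_scale, float))
    if lengthscales.size == 1:
        lengthscales = np.repeat(lengthscales, 2)
    noise_var = float(k.k2.noise_level)
    lml = float(gpr.log_marginal_likelihood_value_) if do_opt else None
    model = GPModel(
        dataset=dataset,
        signal_var=signal_var,
        lengthscales=lengthscales,
        noise_var=noise_var,
        lml=lml,
        cfg=cfg,
    )
    return model


def predict(model: GPModel, points) -> tuple[np.ndarray, np.ndarray]:
    """Module-level convenience wrapper around :meth:`GPModel.predict`."""
    return model.predict(points)


def log_marginal_likelihood(model: GPModel, theta: np.ndarray | None = None, eval_gradient: bool = False):
    return model.log_marginal_likelihood(theta, eval_gradient=eval_gradient)
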