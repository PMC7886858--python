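"""Standard Gaussian-process regression with an RBF kernel.

The model is a zero-mean GP over a latent function f with unit signal
variance, observed through Gaussian noise: y_i = f(x_i) + eps_i,
eps_i ~ N(0, sigma^2).  For a test point x* the predictive distribution is
the textbook closed form

    mu*      = K(x*, X) (K(X, X) + sigma^2 I)^-1 Y
    sigma*^2 = K(x*, x*) - K(x*, X) (K(X, X) + sigma^2 I)^-1 K(x*, X)^T

with K the radial basis function kernel
K(x, x') = exp(-||x - x'||^2 / (2 l^2)).  The zero-mean assumption is
realized by centering Y with the training mean and adding it back at
prediction time; features are z-scored on the training fold (a single
lengthscale is only meaningful when heterogeneous features share a scale).
sigma*^2 is the latent-function variance (no observation noise added): it is
the quantity fed to the one-sided z-test downstream.

All linear solves go through a Cholesky factorization of K + sigma^2 I with
a fixed 1e-10 diagonal jitter; the kernel matrix is never explicitly
inverted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.spatial.distance import cdist
from scipy.optimize import minimize

#: Diagonal jitter added to K + sigma^2 I before factorization.
JITTER = 1e-10

#: Hyperparameter search box (natural scale).
LENGTHSCALE_BOUNDS = (1e-2, 1e3)
NOISE_BOUNDS = (1e-6, 10.0)


def rbf_kernel(X1: np.ndarray, X2: np.ndarray, lengthscale: float) -> np.ndarray:
    """RBF kernel matrix K[i, j] = exp(-||x1_i - x2_j||^2 / (2 l^2))."""
    if not np.isfinite(lengthscale) or lengthscale <= 0:
        raise ValueError(f"lengthscale must be a positive real, got {lengthscale!r}")
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(f"feature dimensions differ: {X1.shape[1]} vs {X2.shape[1]}")
    d2 = cdist(X1, X2, "sqeuclidean")
    return np.exp(-d2 / (2.0 * lengthscale**2))


@dataclass(frozen=True)
class GPHyperparameters:
    """RBF lengthscale and observation-noise variance."""

    lengthscale: float
    noise_variance: float

    def __post_init__(self):
        for name, v in (("lengthscale", self.lengthscale), ("noise_variance", self.noise_variance)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")


@dataclass(frozen=True)
class PredictiveDistribution:
    """Gaussian predictive distribution N(mean, variance) on the target scale."""

    mean: float
    variance: float

    def __post_init__(self):
        if self.variance < -1e-10:
            raise ValueError(f"negative predictive variance: {self.variance!r}")
        object.__setattr__(self, "variance", max(float(self.variance), 0.0))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class TrainingSet:
    """Labeled samples: features X, transformed-CNV targets Y, patient IDs."""

    X: np.ndarray
    Y: np.ndarray
    patient_ids: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]} entries"
            )
        if self.patient_ids is not None:
            self.patient_ids = np.asarray(self.patient_ids)
            if self.patient_ids.shape[0] != self.X.shape[0]:
                raise ValueError("patient_ids length does not match X")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("non-finite entries in training data")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class GPFitConfig:
    """Fitting options.

    Explicit ``lengthscale``/``noise_variance`` bypass marginal-likelihood
    optimization.  ``standardize`` z-scores features on the training fold
    (fit statistics are reused at prediction time).  ``n_restarts`` bounded
    multi-start optimizations are run from seeded quasi-random points in
    log-space; ties are broken by highest likelihood then smallest
    lengthscale.
    """

    lengthscale: float | None = None
    noise_variance: float | None = None
    standardize: bool = True
    n_restarts: int = 5
    seed: int = 0


class GPModel:
    """A fitted GP: hyperparameters plus cached factorizations."""

    def __init__(
        self,
        train: TrainingSet,
        hyper: GPHyperparameters,
        *,
        standardize: bool = True,
        log_marginal_likelihood: float | None = None,
    ):
        self.train = train
        self.hyper = hyper
        self.standardize = standardize
        if standardize:
            self._mu = train.X.mean(axis=0)
            sd = train.X.std(axis=0, ddof=0)
            self._sd = np.where(sd > 0, sd, 1.0)  # constant features left at 0
        else:
            self._mu = np.zeros(train.X.shape[1])
            self._sd = np.ones(train.X.shape[1])
        self.Xs = (train.X - self._mu) / self._sd
        self.y_mean = float(train.Y.mean())
        self.yc = train.Y - self.y_mean
        K = rbf_kernel(self.Xs, self.Xs, hyper.lengthscale)
        A = K + (hyper.noise_variance + JITTER) * np.eye(len(train))
        self._cho = cho_factor(A, lower=True)
        self.alpha = cho_solve(self._cho, self.yc)
        if log_marginal_likelihood is None:
            n = len(train)
            L = np.asarray(self._cho[0])
            log_marginal_likelihood = float(
                -0.5 * self.yc @ self.alpha
                - np.sum(np.log(np.diag(L)))
                - 0.5 * n * np.log(2 * np.pi)
            )
        self.log_marginal_likelihood = log_marginal_likelihood

    # -- prediction ---------------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.Xs.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match training dimension {self.Xs.shape[1]}"
            )
        return (X - self._mu) / self._sd

    def predict(self, Xstar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized predictive means and latent variances for rows of Xstar."""
        Xs = self._standardize(Xstar)
        ks = rbf_kernel(Xs, self.Xs, self.hyper.lengthscale)
        mu = ks @ self.alpha + self.y_mean
        v = 1.0 - np.einsum("ij,ji->i", ks, cho_solve(self._cho, ks.T))
        return mu, np.clip(v, 0.0, None)

    def predict_one(self, xstar: np.ndarray) -> PredictiveDistribution:
        mu, v = self.predict(np.atleast_2d(xstar))
        return PredictiveDistribution(mean=float(mu[0]), variance=float(v[0]))

    # -- serialization ------------------------------------------------------
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.train.X).tobytes())
        h.update(np.ascontiguousarray(self.train.Y).tobytes())
        return h.hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "lengthscale": self.hyper.lengthscale,
            "noise_variance": self.hyper.noise_variance,
            "standardize": self.standardize,
            "feature_means": self._mu.tolist(),
            "feature_scales": self._sd.tolist(),
            "y_mean": self.y_mean,
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "training_fingerprint": self.fingerprint(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path, train: TrainingSet) -> "GPModel":
        """Rebuild a model from its JSON sidecar plus the original training set."""
        with open(path) as fh:
            d = json.load(fh)
        model = cls(
            train,
            GPHyperparameters(d["lengthscale"], d["noise_variance"]),
            standardize=d["standardize"],
        )
        if model.fingerprint() != d["training_fingerprint"]:
            raise ValueError("training data does not match the serialized fingerprint")
        return model


def _nll_and_grad(theta: np.ndarray, D2: np.ndarray, yc: np.ndarray):
    """Negative log marginal likelihood and its gradient in log-parameters."""
    log_l, log_s2 = theta
    l, s2 = np.exp(log_l), np.exp(log_s2)
    n = yc.shape[0]
    K = np.exp(-D2 / (2.0 * l**2))
    A = K + (s2 + JITTER) * np.eye(n)
    try:
        L = cholesky(A, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(2)
    alpha = cho_solve((L, True), yc)
    nll = 0.5 * yc @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * n * np.log(2 * np.pi)
    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # d logL / dK = W / 2
    dK_dlogl = K * D2 / l**2
    g_logl = -0.5 * np.sum(W * dK_dlogl)
    g_logs2 = -0.5 * np.trace(W) * s2
    return nll, np.array([g_logl, g_logs2])


def fit_gp(train: TrainingSet, config: GPFitConfig | None = None) -> GPModel:
    """Fit a GP to a training set.

    Hyperparameters maximize the log marginal likelihood via multi-start
    L-BFGS-B in log-space unless explicit overrides are given in the config.
    """
    config = config or GPFitConfig()
    if len(train) < 2:
        raise ValueError("at least 2 training samples required")
    if np.allclose(train.X, train.X[0]):
        raise ValueError("degenerate training set: all feature rows identical")

    if config.lengthscale is not None and config.noise_variance is not None:
        hyper = GPHyperparameters(config.lengthscale, config.noise_variance)
        return GPModel(train, hyper, standardize=config.standardize)

    # Standardize once for the optimization (matches what GPModel will do).
    if config.standardize:
        mu = train.X.mean(axis=0)
        sd = train.X.std(axis=0, ddof=0)
        Xs = (train.X - mu) / np.where(sd > 0, sd, 1.0)
    else:
        Xs = train.X
    yc = train.Y - train.Y.mean()
    D2 = cdist(Xs, Xs, "sqeuclidean")

    lb = np.log([LENGTHSCALE_BOUNDS[0], NOISE_BOUNDS[0]])
    ub = np.log([LENGTHSCALE_BOUNDS[1], NOISE_BOUNDS[1]])
    rng = np.random.default_rng(config.seed)
    # First start from a median-distance heuristic, the rest quasi-random.
    med = np.sqrt(np.median(D2[D2 > 0])) if np.any(D2 > 0) else 1.0
    starts = [np.array([np.log(np.clip(med, *LENGTHSCALE_BOUNDS)), np.log(0.1)])]
    for _ in range(max(config.n_restarts - 1, 0)):
        starts.append(lb + rng.random(2) * (ub - lb))

    best = None
    for x0 in starts:
        res = minimize(
            _nll_and_grad,
            x0,
            args=(D2, yc),
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
        )
        cand = (res.fun, np.exp(res.x[0]), np.exp(res.x[1]))
        if best is None or cand[0] < best[0] - 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
        ):
            best = cand
    nll, l_opt, s2_opt = best
    hyper = GPHyperparameters(float(l_opt), float(s2_opt))
    return GPModel(
        train, hyper, standardize=config.standardize, log_marginal_likelihood=float(-nll)
    )


def log_marginal_likelihood(train: TrainingSet, hyper: GPHyperparameters, *, standardize: bool = True) -> float:
    """Log marginal likelihood of a training set at given hyperparameters."""
    return GPModel(train, hyper, standardize=standardize).log_marginal_likelihood
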