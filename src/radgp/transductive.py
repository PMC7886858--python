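"""Transductive GP prediction using unlabeled neighbor samples.

A transductive GP augments the labeled training set {X_L, Y_L} with
unlabeled samples X_U — here, image neighbors of the test sample — whose
pseudo-targets Yhat_U are the standard-GP predictive means.  The predictive
distribution for a test point x* has the closed forms

    K_tran       = K(x*, X_L) + K(x*, X_U) (K(X_U, X_U) + s2 I)^-1 K(X_U, X_L)
    mu_tran      = K_tran (K(X_L, X_L) + s2 I)^-1 Y_L
    sigma2_tran  = K(x*, x*) - b^T J^-1 b

with b = [K(x*, X_L); K(x*, X_U)] and J the symmetric joint covariance

    J = [[K(X_L, X_L) + s2 I,  K(X_L, X_U)       ],
         [K(X_U, X_L),         K(X_U, X_U) + s2 I]].

Two numerical properties are exercised throughout the test suite: the
transductive predictive variance never exceeds the standard one (conditioning
on more observations cannot increase posterior variance), and as the
unlabeled samples move infinitely far from both the labeled and test samples
the transductive predictive distribution converges to the standard one in
Kullback-Leibler divergence.

The unlabeled samples share the labeled model's hyperparameters and feature
standardization (one model is fitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .gp import JITTER, GPModel, PredictiveDistribution, rbf_kernel


@dataclass
class TransductiveContext:
    """Unlabeled feature vectors plus their cached standard-GP pseudo-targets."""

    X_U: np.ndarray
    Y_U_hat: np.ndarray

    def __post_init__(self):
        self.X_U = np.atleast_2d(np.asarray(self.X_U, dtype=float))
        self.Y_U_hat = np.asarray(self.Y_U_hat, dtype=float).ravel()
        if self.X_U.shape[0] != self.Y_U_hat.shape[0]:
            raise ValueError("Y_U_hat must have one entry per row of X_U")

    def __len__(self) -> int:
        return self.X_U.shape[0]


def build_context(model: GPModel, X_U: np.ndarray | None) -> TransductiveContext | None:
    """Predict pseudo-targets for the unlabeled samples with the labeled model.

    Returns None for an empty / absent unlabeled set (the degenerate path in
    which transductive prediction reduces to the standard GP).
    """
    if X_U is None:
        return None
    X_U = np.atleast_2d(np.asarray(X_U, dtype=float))
    if X_U.size == 0:
        return None
    mu, _ = model.predict(X_U)
    return TransductiveContext(X_U=X_U, Y_U_hat=mu)


def predict_transductive(
    model: GPModel, context: TransductiveContext | None, Xstar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Transductive predictive means and variances for rows of Xstar.

    With an empty context this is exactly ``model.predict``.
    """
    if context is None or len(context) == 0:
        return model.predict(Xstar)

    l = model.hyper.lengthscale
    s2 = model.hyper.noise_variance
    XL = model.Xs
    XU = model._standardize(context.X_U)
    Xs = model._standardize(Xstar)
    nL, nU = XL.shape[0], XU.shape[0]

    k_sL = rbf_kernel(Xs, XL, l)
    k_sU = rbf_kernel(Xs, XU, l)
    K_UU = rbf_kernel(XU, XU, l) + (s2 + JITTER) * np.eye(nU)
    K_UL = rbf_kernel(XU, XL, l)

    try:
        cho_UU = cho_factor(K_UU, lower=True)
        K_tran = k_sL + k_sU @ cho_solve(cho_UU, K_UL)
        # model.alpha = (K_LL + s2 I)^-1 (Y_L - y_mean); add the mean back.
        mu = K_tran @ model.alpha + model.y_mean

        J = np.empty((nL + nU, nL + nU))
        J[:nL, :nL] = rbf_kernel(XL, XL, l) + (s2 + JITTER) * np.eye(nL)
        J[:nL, nL:] = K_UL.T
        J[nL:, :nL] = K_UL
        J[nL:, nL:] = K_UU
        cho_J = cho_factor(J, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance block in transductive prediction"
        ) from exc
    b = np.hstack([k_sL, k_sU])  # (n*, nL+nU)
    v = 1.0 - np.einsum("ij,ji->i", b, cho_solve(cho_J, b.T))
    return mu, np.clip(v, 0.0, None)


def predict_transductive_one(
    model: GPModel, context: TransductiveContext | None, xstar: np.ndarray
) -> PredictiveDistribution:
    mu, v = predict_transductive(model, context, np.atleast_2d(xstar))
    return PredictiveDistribution(mean=float(mu[0]), variance=float(v[0]))


def naive_combined_prediction(
    model: GPModel, context: TransductiveContext, Xstar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Prediction from the literal combined dataset {X_L,Y_L} u {X_U, Yhat_U}.

    Exploratory companion to :func:`predict_transductive`: a standard GP is
    refit (same hyperparameters and standardization) on the union of labeled
    samples and unlabeled samples carrying their pseudo-targets.  Whether this
    equals the closed forms algebraically is an open question; tests record
    the discrepancy rather than asserting equality.
    """
    l = model.hyper.lengthscale
    s2 = model.hyper.noise_variance
    XC = np.vstack([model.Xs, model._standardize(context.X_U)])
    yC = np.concatenate([model.yc, context.Y_U_hat - model.y_mean])
    A = rbf_kernel(XC, XC, l) + (s2 + JITTER) * np.eye(XC.shape[0])
    cho = cho_factor(A, lower=True)
    ks = rbf_kernel(model._standardize(Xstar), XC, l)
    mu = ks @ cho_solve(cho, yC) + model.y_mean
    v = 1.0 - np.einsum("ij,ji->i", ks, cho_solve(cho, ks.T))
    return mu, np.clip(v, 0.0, None)


def kl_divergence(p: PredictiveDistribution, q: PredictiveDistribution) -> float:
    """KL(p || q) between two univariate Gaussian predictive distributions."""
    if p.variance <= 0 or q.variance <= 0:
        raise ValueError("KL divergence requires strictly positive variances")
    return float(
        0.5
        * (
            np.log(q.variance / p.variance)
            + (p.variance + (p.mean - q.mean) ** 2) / q.variance
            - 1.0
        )
    )
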