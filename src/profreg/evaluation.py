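"""Model-fit metrics on logistic-type residuals.

Any model that produces a per-subject fitted case probability can be scored
with the same three quantities, so profile-regression fits can be compared
directly against external models (CART, logistic regression, ...) whose
probabilities are supplied as a plain vector:

    RMSE_y = sqrt(mean (y_i - pihat_i)^2)
    MAE_y  = mean |y_i - pihat_i|
    misclassification = mean 1{(pihat_i > 0.5) != y_i}

A fitted probability of exactly 0.5 counts as a predicted control.  For a
profile-regression chain the fitted probability is the posterior mean, over
retained sweeps, of expit(theta_{Z_i} + beta' w_i) with the subject's actual
sweep-by-sweep allocation.  These are in-sample residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .model_core import Dataset
from .sampler import ChainOutput

__all__ = ["FitAssessment", "fitted_probabilities", "fit_metrics"]


@dataclass(frozen=True)
class FitAssessment:
    fitted: np.ndarray
    rmse: float
    mae: float
    misclassification: float


def fitted_probabilities(chain: ChainOutput, data: Dataset) -> np.ndarray:
    """Posterior-mean case probability per subject.

    Uses the chain's stored centring means so ``data`` is passed on the raw
    confounder scale.
    """
    if data.N != chain.N:
        raise ValueError(f"chain has N={chain.N} but data has N={data.N}")
    eta = chain.theta_by_subject()                      # (T, N)
    if data.n_fixed:
        eta = eta + chain.beta @ (data.w - chain.w_mean[None, :]).T
    return expit(eta).mean(axis=0)


def fit_metrics(y, pihat) -> FitAssessment:
    """The three logistic-residual metrics for outcomes ``y`` and fitted
    probabilities ``pihat``."""
    y = np.asarray(y, dtype=float)
    pihat = np.asarray(pihat, dtype=float)
    if y.shape != pihat.shape:
        raise ValueError("y and fitted probabilities must have the same length")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("y must be binary")
    if pihat.min() < 0 or pihat.max() > 1:
        raise ValueError("fitted probabilities must lie in [0, 1]")
    resid = y - pihat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    predicted_case = pihat > 0.5          # ties at 0.5 count as control
    misclass = float(np.mean(predicted_case != (y == 1.0)))
    return FitAssessment(fitted=pihat, rmse=rmse, mae=mae, misclassification=misclass)
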