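"""Independent oracles used by the acceptance tests.

These deliberately avoid the package's sampler machinery: the partition
posterior is enumerated exhaustively (CRP exchangeable partition probability
function x conjugate marginal likelihoods, with the cluster log odds
integrated by fixed-order Gauss-Legendre quadrature), and the prior law of
the cluster count is simulated directly from the Chinese restaurant process.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import digamma, gammaln

from profreg.model_core import student_t_logpdf


def set_partitions(n: int):
    """All set partitions of range(n) (Bell(n) of them)."""
    if n == 1:
        yield [[0]]
        return
    for part in set_partitions(n - 1):
        for i in range(len(part)):
            yield [b + ([n - 1] if j == i else []) for j, b in enumerate(part)]
        yield part + [[n - 1]]


def crp_log_eppf(blocks, alpha: float, N: int) -> float:
    """Log exchangeable partition probability function of a DP."""
    return (
        len(blocks) * math.log(alpha)
        + sum(gammaln(len(b)) for b in blocks)
        + gammaln(alpha)
        - gammaln(alpha + N)
    )


def enumerate_coclustering(
    y: np.ndarray,
    x: np.ndarray,
    alpha: float = 1.0,
    theta_df: float = 7.0,
    theta_loc: float = 0.0,
    theta_scale: float = 2.5,
    n_quad: int = 61,
    quad_limit: float = 12.0,
) -> np.ndarray:
    """Exact pairwise co-clustering probabilities for binary covariates.

    Posterior over all set partitions weighted by the CRP EPPF, the
    Dirichlet(1,1)-multinomial marginal per covariate, and the Bernoulli
    outcome marginal with theta integrated by n_quad-point Gauss-Legendre
    quadrature over [-quad_limit, quad_limit].
    """
    y = np.asarray(y)
    x = np.asarray(x)
    N = len(y)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_quad)
    nodes = gl_x * quad_limit
    logw = np.log(gl_w * quad_limit) + student_t_logpdf(nodes, theta_df, theta_loc, theta_scale)
    log_sig = -np.logaddexp(0.0, -nodes)
    log_sig_neg = -np.logaddexp(0.0, nodes)

    logps, parts = [], []
    for part in set_partitions(N):
        lp = crp_log_eppf(part, alpha, N)
        for b in part:
            n = len(b)
            k = int(y[b].sum())
            lp += np.logaddexp.reduce(logw + k * log_sig + (n - k) * log_sig_neg)
            for j in range(x.shape[1]):
                c1 = int(x[b, j].sum())
                lp += (
                    gammaln(2) - gammaln(2 + n)
                    + gammaln(1 + n - c1) + gammaln(1 + c1)
                )
        logps.append(lp)
        parts.append(part)
    logps = np.asarray(logps)
    p = np.exp(logps - logps.max())
    p /= p.sum()
    C = np.zeros((N, N))
    for w_, part in zip(p, parts):
        for b in part:
            for i in b:
                C[i, b] += w_
    return C


def crp_exact_mean_k(alpha: float, N: int) -> float:
    """E[K] under the CRP: alpha * (digamma(alpha+N) - digamma(alpha))."""
    return float(alpha * (digamma(alpha + N) - digamma(alpha)))


def crp_simulate_k(alpha: float, N: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Draws of the occupied-cluster count: K = sum of Bernoulli(alpha/(alpha+i))."""
    p = alpha / (alpha + np.arange(N))
    return (rng.random((reps, N)) < p[None, :]).sum(axis=1)
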