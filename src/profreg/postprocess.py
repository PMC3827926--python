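"""Representative clustering from MCMC output.

The mixture components of a Dirichlet-process chain are not identified
across sweeps (labels switch, clusters split and merge), so the posterior
clustering is summarised through a relabelling-invariant object: the
dissimilarity matrix ``delta_ik`` = proportion of retained sweeps in which
subjects i and k sit in *different* components.  Partitioning around medoids
(PAM) on that matrix, with the number of clusters chosen by average
silhouette width, yields a single representative hard partition whose
per-cluster characteristics (profile probabilities, log odds of disease,
log odds ratios versus the lowest-risk cluster) are then read off the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .sampler import ChainOutput

__all__ = [
    "DissimilarityMatrix",
    "RepresentativeClustering",
    "dissimilarity",
    "pam",
    "representative_partition",
    "cluster_summaries",
]


# A dissimilarity matrix is a plain (N, N) ndarray; this helper validates it.
def _check_dissimilarity(D: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=tol):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.abs(np.diag(D)).max() > tol:
        raise ValueError("dissimilarity matrix must have zero diagonal")
    if D.min() < -tol or D.max() > 1 + tol:
        raise ValueError("dissimilarities must lie in [0, 1]")
    return D


DissimilarityMatrix = np.ndarray  # alias for annotation purposes


def dissimilarity(chain: ChainOutput) -> np.ndarray:
    """Pairwise proportion of sweeps allocating two subjects to different
    components.  Invariant to per-sweep relabelling by construction."""
    if chain.n_retained == 0:
        raise ValueError("empty chain")
    N = chain.N
    acc = np.zeros((N, N))
    for t in range(chain.n_retained):
        z = chain.Z[t]
        acc += z[:, None] != z[None, :]
    acc /= chain.n_retained
    np.fill_diagonal(acc, 0.0)
    return acc


# ---------------------------------------------------------------------------
# PAM (k-medoids): classic BUILD + SWAP on a precomputed dissimilarity
# ---------------------------------------------------------------------------

def pam(D: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed matrix.

    Deterministic: BUILD greedily seeds the medoids, SWAP applies the best
    single (medoid, candidate) exchange until no exchange lowers the total
    dissimilarity to the nearest medoid.  Returns (labels, medoid indices).
    """
    D = np.asarray(D, dtype=float)
    N = D.shape[0]
    if not 1 <= k <= N:
        raise ValueError("k must be in [1, N]")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest_d = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest_d[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        best = int(np.argmax(gain))
        medoids.append(best)
        nearest_d = np.minimum(nearest_d, D[:, best])

    medoids = np.asarray(medoids)
    # SWAP
    for _ in range(max_iter):
        dm = D[:, medoids]                      # (N, k)
        order = np.argsort(dm, axis=1)
        d1 = dm[np.arange(N), order[:, 0]]
        d2 = dm[np.arange(N), order[:, 1]] if k > 1 else np.full(N, np.inf)
        nearest_idx = order[:, 0]
        current_cost = d1.sum()
        best_cost = current_cost
        best_swap = None
        for r in range(k):
            base = np.where(nearest_idx == r, d2, d1)
            costs = np.minimum(base[:, None], D).sum(axis=0)   # cost for each candidate
            costs[medoids] = np.inf
            h = int(np.argmin(costs))
            if costs[h] < best_cost - 1e-12:
                best_cost = costs[h]
                best_swap = (r, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    labels = np.argmin(D[:, medoids], axis=1)
    labels[medoids] = np.arange(k)  # each medoid belongs to its own cluster
    return labels, medoids


@dataclass
class RepresentativeClustering:
    """A hard partition plus posterior cluster summaries.

    Cluster indices are 0-based and ordered by increasing posterior mean log
    odds, so cluster 0 is the lowest-risk reference; reported tables number
    clusters from 1.
    """

    labels: np.ndarray                     # (N,) hard cluster per subject
    n_clusters: int
    sizes: np.ndarray = None               # (G,)
    phi_bar: np.ndarray = None             # (G, J, Lmax), rows sum to 1
    log_odds_draws: np.ndarray = None      # (T, G) member-averaged theta
    log_or_draws: np.ndarray = None        # (T, G) versus reference cluster
    cardinalities: tuple[int, ...] = ()
    medoids: np.ndarray = None
    silhouette: float = float("nan")
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def log_or_mean(self) -> np.ndarray:
        return self.log_or_draws.mean(axis=0)

    def log_or_ci(self, level: float = 0.95) -> np.ndarray:
        lo = (1 - level) / 2
        return np.quantile(self.log_or_draws, [lo, 1 - lo], axis=0).T  # (G, 2)

    def summary_table(self) -> pd.DataFrame:
        """Profile-probability table: one row per covariate x category, one
        column per cluster (numbered from 1), preceded by size and log OR rows."""
        G = self.n_clusters
        cols = [str(g + 1) for g in range(G)]
        rows = [
            ("", "No. Subjects", self.sizes.astype(float)),
            ("", "Log OR", np.round(self.log_or_mean, 2)),
        ]
        for j, L in enumerate(self.cardinalities):
            for l in range(L):
                rows.append((f"x{j + 1}", str(l), np.round(self.phi_bar[:, j, l], 2)))
        idx = pd.MultiIndex.from_tuples([(a, b) for a, b, _ in rows], names=["covariate", "category"])
        return pd.DataFrame([v for _, _, v in rows], index=idx, columns=cols)


def representative_partition(
    D: np.ndarray, k_range: range | list[int] = range(2, 21)
) -> RepresentativeClustering:
    """PAM over each k in ``k_range``; pick the k with the highest average
    silhouette width (ties toward smaller k).  A degenerate all-zero matrix
    collapses to a single cluster with a warning."""
    D = _check_dissimilarity(D)
    N = D.shape[0]
    if D.max() == 0.0:
        warnings.warn("degenerate dissimilarity matrix (all zeros): single cluster")
        return RepresentativeClustering(labels=np.zeros(N, dtype=int), n_clusters=1,
                                        medoids=np.array([0]), silhouette=float("nan"))
    ks = [k for k in k_range if 2 <= k <= N - 1]
    if not ks:
        raise ValueError("k_range must contain values in [2, N-1]")
    best = None
    sil_by_k = {}
    for k in ks:
        labels, medoids = pam(D, k)
        if np.unique(labels).size < 2:
            continue
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        sil_by_k[k] = sil
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, labels, medoids)
    if best is None:
        raise ValueError("PAM produced no valid clustering for any k in range")
    sil, k, labels, medoids = best
    return RepresentativeClustering(
        labels=labels, n_clusters=k, medoids=medoids,
        silhouette=sil, silhouette_by_k=sil_by_k,
    )


def cluster_summaries(
    chain: ChainOutput, partition: RepresentativeClustering
) -> RepresentativeClustering:
    """Complete a partition with posterior summaries from the chain.

    At each sweep a hard cluster's log-odds draw is the member-average of the
    allocated components' theta (clusters may straddle components); its
    profile is the member-average of the components' phi, then averaged over
    sweeps.  Clusters are reordered by posterior mean log odds and log OR
    draws are taken against the lowest-risk (reference) cluster.
    """
    labels = np.asarray(partition.labels)
    if labels.shape[0] != chain.N:
        raise ValueError("partition and chain disagree on N")
    G = int(labels.max()) + 1
    sizes = np.bincount(labels, minlength=G)
    if (sizes == 0).any():
        raise ValueError("empty cluster in partition")

    member = np.zeros((chain.N, G))
    member[np.arange(chain.N), labels] = 1.0
    member /= sizes[None, :]

    theta_subj = chain.theta_by_subject()          # (T, N)
    draws = theta_subj @ member                    # (T, G)

    J = chain.J
    Lmax = max(chain.cardinalities)
    phi_bar = np.zeros((G, J, Lmax))
    for t in range(chain.n_retained):
        phi_subj = chain.phi[t][chain.Z[t]]        # (N, J, Lmax)
        phi_bar += (member.T @ phi_subj.reshape(chain.N, J * Lmax)).reshape(G, J, Lmax)
    phi_bar /= chain.n_retained

    order = np.argsort(draws.mean(axis=0), kind="stable")
    relabel = np.empty(G, dtype=int)
    relabel[order] = np.arange(G)
    labels = relabel[labels]
    draws = draws[:, order]
    phi_bar = phi_bar[order]
    sizes = sizes[order]
    medoids = partition.medoids[order] if partition.medoids is not None else None

    log_or = draws - draws[:, [0]]
    return RepresentativeClustering(
        labels=labels, n_clusters=G, sizes=sizes, phi_bar=phi_bar,
        log_odds_draws=draws, log_or_draws=log_or,
        cardinalities=chain.cardinalities, medoids=medoids,
        silhouette=partition.silhouette, silhouette_by_k=partition.silhouette_by_k,
    )
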