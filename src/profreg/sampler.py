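"""Truncation-free MCMC for Dirichlet-process profile regression.

The sampler is a slice-augmented Gibbs / Metropolis-within-Gibbs scheme that
never truncates the infinite mixture: a dependent slice variable
``u_i ~ Uniform(0, psi_{Z_i})`` makes the set of components a subject can
move to finite at every sweep, and new sticks are instantiated from the
prior until the residual stick mass falls below ``min_i u_i``.

Per sweep the moves are, in order:

1. slice variables + allocations ``Z`` (profile terms marginalise missing
   covariates, so this jointly with step 2 draws ``(Z, x_mis)``),
2. imputation of missing profile entries from the allocated component,
3. conjugate stick update ``V_c ~ Beta(1 + n_c, alpha + sum_{l>c} n_l)``,
4. conjugate Dirichlet update of the profile probabilities ``phi``,
5. random-walk Metropolis on each occupied cluster's log odds ``theta_c``
   (empty components redraw from the prior),
6. random-walk Metropolis on the fixed-effect coefficients ``beta``,
7. label-swap moves (a mixing aid; the posterior is invariant),
8. pruning of trailing unoccupied components (interior empties are kept —
   their stick fractions carry information about later counts).

Retained sweeps store the occupied components only, with allocations
renumbered accordingly.

Proposal scales adapt toward an acceptance band of [0.2, 0.5] during
burn-in only and are frozen afterwards so detailed balance is preserved for
the retained sweeps.  Fixed effects are centred internally; the centring
means are stored in the chain so fitted probabilities use raw-scale inputs.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model_core import (
    MISSING,
    Dataset,
    MCMCState,
    PriorSpec,
    bernoulli_loglik,
    expected_clusters,
    joint_loglik,
    normal_logpdf,
    stick_weights,
    student_t_logpdf,
)

__all__ = [
    "SamplerControls",
    "ChainOutput",
    "run_chain",
    "update_slice_and_allocations",
    "update_sticks",
    "update_phi",
    "update_theta",
    "update_beta",
    "impute_missing",
    "label_switch_moves",
    "initial_state",
]

CHAIN_FORMAT_VERSION = 1

_V_EPS = 1e-12  # keep stick fractions strictly inside (0, 1)


@dataclass(frozen=True)
class SamplerControls:
    """Run-length and proposal controls for :func:`run_chain`.

    ``n_sweeps`` counts total sweeps including burn-in; the chain retains
    ``floor((n_sweeps - n_burnin) / thin)`` states.
    """

    n_sweeps: int = 12000
    n_burnin: int = 2000
    thin: int = 10
    seed: int = 0
    proposal_sd_theta: float = 0.5
    proposal_sd_beta: float = 0.2
    adapt_window: int = 50
    label_move_rate: int = 3
    max_extensions: int = 10_000

    def __post_init__(self):
        if not (self.n_sweeps > self.n_burnin >= 0):
            raise ValueError("need n_sweeps > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.proposal_sd_theta <= 0 or self.proposal_sd_beta <= 0:
            raise ValueError("proposal scales must be > 0")
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")


@dataclass
class ChainOutput:
    """Retained sweeps of one MCMC run.

    ``Z`` is (T, N); ``psi``, ``theta`` and ``phi`` are per-sweep ragged
    lists over that sweep's occupied components (``phi[t]`` has shape
    (C_t, J, Lmax), padded with zeros past each covariate's cardinality).
    """

    Z: np.ndarray
    psi: list[np.ndarray]
    theta: list[np.ndarray]
    phi: list[np.ndarray]
    beta: np.ndarray
    K: np.ndarray
    loglik: np.ndarray
    cardinalities: tuple[int, ...]
    w_mean: np.ndarray
    acceptance: dict[str, float] = field(default_factory=dict)
    controls: SamplerControls | None = None
    priors: PriorSpec | None = None

    @property
    def n_retained(self) -> int:
        return self.Z.shape[0]

    @property
    def N(self) -> int:
        return self.Z.shape[1]

    @property
    def J(self) -> int:
        return len(self.cardinalities)

    def theta_by_subject(self) -> np.ndarray:
        """(T, N) matrix of each subject's allocated cluster log odds."""
        return np.stack([th[z] for th, z in zip(self.theta, self.Z)])

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> Path:
        """Persist the chain as a directory of versioned text files."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": CHAIN_FORMAT_VERSION,
            "N": int(self.N),
            "J": int(self.J),
            "cardinalities": list(self.cardinalities),
            "w_mean": [float(v) for v in self.w_mean],
            "acceptance": self.acceptance,
            "controls": asdict(self.controls) if self.controls else None,
            "priors": _priors_to_dict(self.priors) if self.priors else None,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        np.savetxt(d / "allocations.csv.gz", self.Z, fmt="%d", delimiter=",")
        header = ["sweep", "K", "loglik"] + [f"beta{k}" for k in range(self.beta.shape[1])]
        trace = np.column_stack(
            [np.arange(self.n_retained), self.K, self.loglik]
            + [self.beta[:, k] for k in range(self.beta.shape[1])]
        )
        np.savetxt(
            d / "trace.csv", trace, fmt="%.17g", delimiter=",",
            header=",".join(header), comments="",
        )
        with gzip.open(d / "components.jsonl.gz", "wt") as fh:
            for t in range(self.n_retained):
                rec = {
                    "psi": self.psi[t].tolist(),
                    "theta": self.theta[t].tolist(),
                    "phi": [
                        [self.phi[t][c, j, :L].tolist() for j, L in enumerate(self.cardinalities)]
                        for c in range(self.phi[t].shape[0])
                    ],
                }
                fh.write(json.dumps(rec) + "\n")
        return d

    @classmethod
    def load(cls, directory) -> "ChainOutput":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        if meta["format_version"] != CHAIN_FORMAT_VERSION:
            raise ValueError(f"unsupported chain format {meta['format_version']}")
        cards = tuple(meta["cardinalities"])
        Lmax = max(cards)
        Z = np.loadtxt(d / "allocations.csv.gz", dtype=np.int64, delimiter=",", ndmin=2)
        trace = np.loadtxt(d / "trace.csv", delimiter=",", skiprows=1, ndmin=2)
        K = trace[:, 1].astype(np.int64)
        loglik = trace[:, 2]
        beta = trace[:, 3:]
        psi, theta, phi = [], [], []
        with gzip.open(d / "components.jsonl.gz", "rt") as fh:
            for line in fh:
                rec = json.loads(line)
                psi.append(np.asarray(rec["psi"]))
                theta.append(np.asarray(rec["theta"]))
                C = len(rec["theta"])
                p = np.zeros((C, len(cards), Lmax))
                for c in range(C):
                    for j, L in enumerate(cards):
                        p[c, j, :L] = rec["phi"][c][j]
                phi.append(p)
        controls = SamplerControls(**meta["controls"]) if meta.get("controls") else None
        priors = _priors_from_dict(meta["priors"]) if meta.get("priors") else None
        return cls(
            Z=Z, psi=psi, theta=theta, phi=phi, beta=beta, K=K, loglik=loglik,
            cardinalities=cards, w_mean=np.asarray(meta["w_mean"], dtype=float),
            acceptance=meta.get("acceptance", {}), controls=controls, priors=priors,
        )


def _priors_to_dict(p: PriorSpec) -> dict:
    return {
        "alpha": p.alpha,
        "dirichlet_a": None if p.dirichlet_a is None else [list(a) for a in p.dirichlet_a],
        "theta_loc": p.theta_loc, "theta_scale": p.theta_scale, "theta_df": p.theta_df,
        "beta_mean": p.beta_mean, "beta_sd": p.beta_sd,
    }


def _priors_from_dict(d: dict) -> PriorSpec:
    da = d.get("dirichlet_a")
    return PriorSpec(
        alpha=d["alpha"],
        dirichlet_a=None if da is None else tuple(tuple(a) for a in da),
        theta_loc=d["theta_loc"], theta_scale=d["theta_scale"], theta_df=d["theta_df"],
        beta_mean=d["beta_mean"], beta_sd=d["beta_sd"],
    )


# ---------------------------------------------------------------------------
# prior draws
# ---------------------------------------------------------------------------

def _padded_dirichlet_a(priors: PriorSpec, cardinalities) -> np.ndarray:
    Lmax = max(cardinalities)
    a = np.zeros((len(cardinalities), Lmax))
    for j, vec in enumerate(priors.dirichlet_for(cardinalities)):
        a[j, : len(vec)] = vec
    return a


def _draw_phi(rng, gamma_shape: np.ndarray) -> np.ndarray:
    """Dirichlet draws by gamma normalisation; zero-shape slots stay zero."""
    g = np.where(gamma_shape > 0, rng.gamma(np.maximum(gamma_shape, 1e-300)), 0.0)
    tot = g.sum(axis=-1, keepdims=True)
    # guard against an (astronomically unlikely) all-zero gamma draw
    bad = tot[..., 0] <= 0
    if np.any(bad):
        g[bad] = gamma_shape[bad]
        tot = g.sum(axis=-1, keepdims=True)
    return g / tot


def _draw_theta_prior(rng, size, priors: PriorSpec) -> np.ndarray:
    return priors.theta_loc + priors.theta_scale * rng.standard_t(priors.theta_df, size=size)


def initial_state(data: Dataset, priors: PriorSpec, rng: np.random.Generator) -> MCMCState:
    """Draw a valid starting state from the model prior.

    Stick fractions come from the Beta(1, alpha) prior, instantiated until
    the residual mass is negligible, and allocations are drawn i.i.d. over
    the resulting weights — so with the likelihood switched off the chain
    starts (up to a 1e-9 truncation of the stick tail) at its stationary
    distribution, including the correct cluster-to-position label law.
    Component parameters come from the prior; missing entries are imputed
    uniformly.
    """
    Vs = []
    log_res = 0.0
    target = math.log(1e-9)
    while log_res > target or len(Vs) < 2:
        v = float(np.clip(rng.beta(1.0, priors.alpha), _V_EPS, 1 - _V_EPS))
        Vs.append(v)
        log_res += math.log1p(-v)
    V = np.asarray(Vs)
    psi = stick_weights(V)
    Z = rng.choice(V.shape[0], size=data.N, p=psi / psi.sum())
    C0 = V.shape[0]
    theta = _draw_theta_prior(rng, C0, priors)
    a_pad = _padded_dirichlet_a(priors, data.cardinalities)
    phi = _draw_phi(rng, np.broadcast_to(a_pad, (C0,) + a_pad.shape).copy())
    beta = np.zeros(data.n_fixed)
    imputed = data.x.copy()
    for j, L in enumerate(data.cardinalities):
        m = imputed[:, j] == MISSING
        if m.any():
            imputed[m, j] = rng.integers(0, L, size=int(m.sum()))
    state = MCMCState(Z, V, theta, phi, beta, imputed, np.full(data.N, 0.5), data.cardinalities)
    state.u = rng.uniform(0.0, state.psi[state.Z])
    state.u = np.maximum(state.u, 1e-300)
    return state


# ---------------------------------------------------------------------------
# individual updates (each mutates and returns the state)
# ---------------------------------------------------------------------------

def _data_loglik_matrix(state: MCMCState, data: Dataset) -> np.ndarray:
    """(N, C) log likelihood of each subject under each component, with
    missing profile entries marginalised out."""
    eta = state.theta[None, :] + (data.w @ state.beta)[:, None]
    ll = bernoulli_loglik(data.y[:, None], eta)
    obs = ~data.missing_mask
    for j, L in enumerate(data.cardinalities):
        logphi = np.log(state.phi[:, j, :L])  # (C, L)
        sel = obs[:, j]
        ll[sel] += logphi[:, data.x[sel, j]].T
    return ll


def update_slice_and_allocations(
    state: MCMCState,
    data: Dataset,
    priors: PriorSpec,
    rng: np.random.Generator,
    max_extensions: int = 10_000,
    prior_only: bool = False,
) -> MCMCState:
    """Refresh slice variables, extend sticks to cover the slice, and
    resample every allocation among components with ``psi_c > u_i``."""
    state.u = np.maximum(rng.uniform(0.0, state.psi[state.Z]), 1e-300)
    u_min = float(state.u.min())

    log_residual = float(np.log1p(-state.V).sum())
    n_new = 0
    a_pad = _padded_dirichlet_a(priors, state.cardinalities)
    while log_residual > math.log(u_min):
        if n_new >= max_extensions:
            raise RuntimeError(
                f"slice not covered after {max_extensions} stick extensions "
                f"(residual mass {math.exp(log_residual):.3e}, min u {u_min:.3e}); "
                "check alpha and for numeric underflow"
            )
        batch = min(16, max_extensions - n_new)
        Vn = np.clip(rng.beta(1.0, priors.alpha, size=batch), _V_EPS, 1 - _V_EPS)
        state.V = np.concatenate([state.V, Vn])
        state.theta = np.concatenate([state.theta, _draw_theta_prior(rng, batch, priors)])
        phin = _draw_phi(rng, np.broadcast_to(a_pad, (batch,) + a_pad.shape).copy())
        state.phi = np.concatenate([state.phi, phin], axis=0)
        log_residual += float(np.log1p(-Vn).sum())
        n_new += batch
    state.psi = stick_weights(state.V)

    C = state.n_components
    if prior_only:
        logw = np.zeros((data.N, C))
    else:
        logw = _data_loglik_matrix(state, data)
    logw = np.where(state.psi[None, :] > state.u[:, None], logw, -np.inf)
    gumb = rng.gumbel(size=(data.N, C))
    state.Z = np.argmax(logw + gumb, axis=1)
    return state


def impute_missing(state: MCMCState, data: Dataset, priors: PriorSpec, rng) -> MCMCState:
    """Resample missing profile entries from the allocated component's phi."""
    miss = data.missing_mask
    for j, L in enumerate(data.cardinalities):
        rows = np.nonzero(miss[:, j])[0]
        if rows.size == 0:
            continue
        probs = state.phi[state.Z[rows], j, :L]
        cum = np.cumsum(probs, axis=1)
        cum /= cum[:, -1:]
        r = rng.random(rows.size)
        state.imputed_x[rows, j] = (cum < r[:, None]).sum(axis=1)
    return state


def stick_posterior_params(counts: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Beta posterior parameters for each stick fraction given allocation
    counts: ``V_c ~ Beta(1 + n_c, alpha + sum_{l>c} n_l)``."""
    counts = np.asarray(counts, dtype=float)
    tail = counts[::-1].cumsum()[::-1] - counts
    return 1.0 + counts, alpha + tail


def update_sticks(state: MCMCState, data: Dataset, priors: PriorSpec, rng) -> MCMCState:
    counts = np.bincount(state.Z, minlength=state.n_components)
    a, b = stick_posterior_params(counts, priors.alpha)
    state.V = np.clip(rng.beta(a, b), _V_EPS, 1 - _V_EPS)
    state.psi = stick_weights(state.V)
    return state


def phi_posterior_params(
    Z: np.ndarray, x: np.ndarray, n_components: int, cardinalities, a_list
) -> list[np.ndarray]:
    """Per-covariate Dirichlet posterior concentrations ``a + counts``."""
    out = []
    for j, L in enumerate(cardinalities):
        counts = np.bincount(Z * L + x[:, j], minlength=n_components * L).reshape(n_components, L)
        out.append(np.asarray(a_list[j])[None, :] + counts)
    return out


def update_phi(
    state: MCMCState, data: Dataset, priors: PriorSpec, rng, prior_only: bool = False
) -> MCMCState:
    C = state.n_components
    a_pad = _padded_dirichlet_a(priors, state.cardinalities)
    shape = np.broadcast_to(a_pad, (C,) + a_pad.shape).copy()
    if not prior_only:
        a_list = priors.dirichlet_for(state.cardinalities)
        posts = phi_posterior_params(state.Z, state.imputed_x, C, state.cardinalities, a_list)
        for j, L in enumerate(state.cardinalities):
            shape[:, j, :L] = posts[j]
    state.phi = _draw_phi(rng, shape)
    return state


def update_theta(
    state: MCMCState,
    data: Dataset,
    priors: PriorSpec,
    rng,
    proposal_sd: float = 0.5,
    prior_only: bool = False,
) -> MCMCState:
    """Random-walk Metropolis on each occupied component's log odds; empty
    components redraw from the prior.  Acceptance counts go to
    ``state.accept_counts``."""
    C = state.n_components
    counts = np.bincount(state.Z, minlength=C)
    occupied = counts > 0
    if prior_only:
        state.theta = _draw_theta_prior(rng, C, priors)
        return state
    prop = state.theta + proposal_sd * rng.standard_normal(C)
    wb = data.w @ state.beta
    ll_cur = bernoulli_loglik(data.y, state.theta[state.Z] + wb)
    ll_prop = bernoulli_loglik(data.y, prop[state.Z] + wb)
    delta = np.bincount(state.Z, weights=ll_prop - ll_cur, minlength=C)
    delta += student_t_logpdf(prop, priors.theta_df, priors.theta_loc, priors.theta_scale)
    delta -= student_t_logpdf(state.theta, priors.theta_df, priors.theta_loc, priors.theta_scale)
    accept = np.log(rng.random(C)) < delta
    new_theta = np.where(accept, prop, state.theta)
    fresh = _draw_theta_prior(rng, C, priors)
    state.theta = np.where(occupied, new_theta, fresh)
    log = getattr(state, "accept_counts", None)
    if log is not None:
        log["theta_accept"] += int((accept & occupied).sum())
        log["theta_prop"] += int(occupied.sum())
    return state


def update_beta(
    state: MCMCState,
    data: Dataset,
    priors: PriorSpec,
    rng,
    proposal_sd: float = 0.2,
    prior_only: bool = False,
) -> MCMCState:
    """Component-wise random-walk Metropolis on the fixed-effect coefficients
    against the full Bernoulli likelihood.  No-op when there are none."""
    P = state.beta.shape[0]
    if P == 0:
        return state
    if prior_only:
        state.beta = priors.beta_mean + priors.beta_sd * rng.standard_normal(P)
        return state
    eta = state.theta[state.Z] + data.w @ state.beta
    log = getattr(state, "accept_counts", None)
    for k in range(P):
        bk = state.beta[k]
        prop = bk + proposal_sd * rng.standard_normal()
        eta_prop = eta + data.w[:, k] * (prop - bk)
        delta = float(
            bernoulli_loglik(data.y, eta_prop).sum() - bernoulli_loglik(data.y, eta).sum()
        )
        delta += float(
            normal_logpdf(prop, priors.beta_mean, priors.beta_sd)
            - normal_logpdf(bk, priors.beta_mean, priors.beta_sd)
        )
        if math.log(rng.random()) < delta:
            state.beta[k] = prop
            eta = eta_prop
            if log is not None:
                log["beta_accept"] += 1
        if log is not None:
            log["beta_prop"] += 1
    return state


def label_switch_moves(state: MCMCState, rng, n_moves: int = 3) -> MCMCState:
    """Metropolis swaps of the contents (theta, phi, members) of two
    represented components, stick positions held fixed.

    Acceptance ratio ``(psi_c / psi_d)^(n_d - n_c)``; applied on the
    slice-marginal posterior, so slice variables must be refreshed before
    further slice-conditional moves (run_chain refreshes u right after).
    """
    C = state.n_components
    if C < 2:
        return state
    log = getattr(state, "accept_counts", None)
    counts = np.bincount(state.Z, minlength=C)
    logpsi = np.log(state.psi)
    for _ in range(n_moves):
        c, d = rng.choice(C, size=2, replace=False)
        log_ratio = (counts[c] - counts[d]) * (logpsi[d] - logpsi[c])
        if math.log(rng.random()) < log_ratio:
            state.theta[[c, d]] = state.theta[[d, c]]
            state.phi[[c, d]] = state.phi[[d, c]]
            zc = state.Z == c
            zd = state.Z == d
            state.Z[zc] = d
            state.Z[zd] = c
            counts[[c, d]] = counts[[d, c]]
            if log is not None:
                log["label_accept"] += 1
        if log is not None:
            log["label_prop"] += 1
    return state


def _prune_trailing(state: MCMCState) -> MCMCState:
    """Drop unoccupied components past the last occupied stick position.

    Interior empty components must be kept: their stick fractions condition
    on the counts of later components, so discarding and regenerating them
    from the prior would distort the partition law.  Trailing empties carry
    no such information (their conditional is the prior Beta(1, alpha)), so
    they can be dropped and regenerated during the next slice extension.
    """
    C_keep = int(state.Z.max()) + 1
    if C_keep == state.n_components:
        return state
    state.V = state.V[:C_keep]
    state.theta = state.theta[:C_keep]
    state.phi = state.phi[:C_keep]
    state.psi = state.psi[:C_keep]
    return state


# ---------------------------------------------------------------------------
# the driver
# ---------------------------------------------------------------------------

def run_chain(
    data: Dataset,
    priors: PriorSpec | None = None,
    controls: SamplerControls | None = None,
    prior_only: bool = False,
) -> ChainOutput:
    """Run the full sampler and return the retained sweeps.

    Deterministic given ``controls.seed``.  With ``prior_only=True`` the
    likelihood is switched off entirely (outcome and profiles treated as
    unobserved), so the partition over sweeps follows the Dirichlet-process
    prior — useful for validating the sampler against the Chinese-restaurant
    process law.
    """
    priors = priors or PriorSpec()
    controls = controls or SamplerControls()
    rng = np.random.default_rng(controls.seed)

    w_mean = data.w.mean(axis=0) if data.n_fixed else np.zeros(0)
    cdata = Dataset(data.y, data.x, data.cardinalities, w=data.w - w_mean[None, :]) \
        if data.n_fixed else data

    state = initial_state(cdata, priors, rng)
    state.accept_counts = {k: 0 for k in
                           ("theta_accept", "theta_prop", "beta_accept", "beta_prop",
                            "label_accept", "label_prop")}

    sd_theta = controls.proposal_sd_theta
    sd_beta = controls.proposal_sd_beta
    window_mark = dict(state.accept_counts)

    retained = []
    n_keep = (controls.n_sweeps - controls.n_burnin) // controls.thin
    Z_out = np.empty((n_keep, cdata.N), dtype=np.int64)
    beta_out = np.empty((n_keep, cdata.n_fixed))
    K_out = np.empty(n_keep, dtype=np.int64)
    ll_out = np.empty(n_keep)
    psi_out: list[np.ndarray] = []
    theta_out: list[np.ndarray] = []
    phi_out: list[np.ndarray] = []

    t_keep = 0
    for sweep in range(1, controls.n_sweeps + 1):
        update_slice_and_allocations(
            state, cdata, priors, rng, controls.max_extensions, prior_only
        )
        if not prior_only:
            impute_missing(state, cdata, priors, rng)
        update_sticks(state, cdata, priors, rng)
        update_phi(state, cdata, priors, rng, prior_only)
        update_theta(state, cdata, priors, rng, sd_theta, prior_only)
        update_beta(state, cdata, priors, rng, sd_beta, prior_only)
        label_switch_moves(state, rng, controls.label_move_rate)
        _prune_trailing(state)
        state.u = np.maximum(rng.uniform(0.0, state.psi[state.Z]), 1e-300)

        # proposal adaptation, burn-in only
        if sweep <= controls.n_burnin and sweep % controls.adapt_window == 0 and not prior_only:
            sd_theta = _adapt(sd_theta, state.accept_counts, window_mark, "theta")
            sd_beta = _adapt(sd_beta, state.accept_counts, window_mark, "beta")
            window_mark = dict(state.accept_counts)

        if sweep > controls.n_burnin and (sweep - controls.n_burnin) % controls.thin == 0:
            ll = joint_loglik(state, cdata, priors) if not prior_only else 0.0
            if not math.isfinite(ll):
                raise RuntimeError(f"non-finite joint log likelihood at sweep {sweep}")
            occ = np.unique(state.Z)
            Z_out[t_keep] = np.searchsorted(occ, state.Z)
            beta_out[t_keep] = state.beta
            K_out[t_keep] = occ.size
            ll_out[t_keep] = ll
            psi_out.append(state.psi[occ].copy())
            theta_out.append(state.theta[occ].copy())
            phi_out.append(state.phi[occ].copy())
            t_keep += 1

    acc = state.accept_counts
    acceptance = {
        "theta": acc["theta_accept"] / max(acc["theta_prop"], 1),
        "beta": acc["beta_accept"] / max(acc["beta_prop"], 1),
        "label": acc["label_accept"] / max(acc["label_prop"], 1),
        "proposal_sd_theta_final": sd_theta,
        "proposal_sd_beta_final": sd_beta,
    }
    return ChainOutput(
        Z=Z_out, psi=psi_out, theta=theta_out, phi=phi_out, beta=beta_out,
        K=K_out, loglik=ll_out, cardinalities=cdata.cardinalities,
        w_mean=w_mean, acceptance=acceptance, controls=controls, priors=priors,
    )


def _adapt(sd: float, counts: dict, mark: dict, name: str) -> float:
    prop = counts[f"{name}_prop"] - mark[f"{name}_prop"]
    if prop == 0:
        return sd
    rate = (counts[f"{name}_accept"] - mark[f"{name}_accept"]) / prop
    if rate < 0.2:
        return sd / 1.1
    if rate > 0.5:
        return sd * 1.1
    return sd
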