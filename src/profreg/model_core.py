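"""Core model definitions for Dirichlet-process profile regression.

Profile regression is a joint Bayesian mixture model for case-control data:
each subject i carries a binary disease outcome ``y_i``, a profile
``x_i = (x_{i1}, ..., x_{iJ})`` of categorical exposure covariates (category
codes, possibly missing) and optional fixed-effect confounders ``w_i``.
Outcome and profile share a single latent allocation ``Z_i`` to a mixture
component, so clusters are informed jointly by exposure patterns and risk:

    p(y_i, x_i | Theta) = sum_c  psi_c  p(y_i | theta_c, beta)  p(x_i | phi_c)

with a stick-breaking Dirichlet-process prior on the weights
``psi_c = V_c * prod_{l<c} (1 - V_l)``, ``V_c ~ Beta(1, alpha)``; a logistic
response sub-model ``logit(pi_i) = theta_{Z_i} + beta' w_i`` (``theta_c`` is
the cluster log odds of disease); and an independent-multinomial profile
sub-model ``x_{ij} | Z_i = c ~ Multinomial(1, phi_{c,j})``.

This module holds the data containers, the prior specification, the sampler
state, and every elementary probability computation; the MCMC machinery lives
in :mod:`profreg.sampler`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

__all__ = [
    "MISSING",
    "SubjectRecord",
    "Dataset",
    "DiscretisationScheme",
    "PriorSpec",
    "ComponentParams",
    "GlobalParams",
    "MCMCState",
    "discretize",
    "stick_weights",
    "response_logit",
    "profile_loglik",
    "joint_loglik",
    "expected_clusters",
    "load_dataset",
    "save_dataset",
    "log_expit",
    "bernoulli_loglik",
    "student_t_logpdf",
    "normal_logpdf",
    "dirichlet_logpdf",
]

#: Sentinel category code for a missing profile entry.  Distinct from every
#: valid (0-based) category.
MISSING: int = -1


# ---------------------------------------------------------------------------
# numerical helpers
# ---------------------------------------------------------------------------

def log_expit(x: np.ndarray | float) -> np.ndarray | float:
    """log(expit(x)), computed stably for large |x|."""
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Elementwise log Bernoulli(y; expit(eta)).

    ``y`` must be 0/1; broadcasting between ``y`` and ``eta`` is allowed.
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    # y*log(p) + (1-y)*log(1-p) = -logaddexp(0, -eta) - (1-y)*eta  ... use the
    # symmetric form to avoid cancellation:
    return y * log_expit(eta) + (1.0 - y) * log_expit(-eta)


def student_t_logpdf(x: np.ndarray | float, df: float, loc: float, scale: float):
    """Log density of the location-scale Student-t distribution."""
    z = (np.asarray(x, dtype=float) - loc) / scale
    c = gammaln((df + 1.0) / 2.0) - gammaln(df / 2.0) - 0.5 * math.log(df * math.pi) - math.log(scale)
    return c - 0.5 * (df + 1.0) * np.log1p(z * z / df)


def normal_logpdf(x: np.ndarray | float, mean: float, sd: float):
    z = (np.asarray(x, dtype=float) - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def dirichlet_logpdf(p: np.ndarray, a: np.ndarray) -> float:
    """Log density of Dirichlet(a) at p (both 1-D, same length)."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a == 1.0, 0.0, (a - 1.0) * np.log(p))
    return float(gammaln(a.sum()) - gammaln(a).sum() + terms.sum())


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """One subject: outcome ``y`` (1=case), categorical profile ``x`` (codes,
    :data:`MISSING` allowed) and fixed-effect covariates ``w``."""

    y: int
    x: tuple[int, ...]
    w: tuple[float, ...] = ()

    def __post_init__(self):
        if self.y not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.y!r}")


class Dataset:
    """A case-control dataset stored columnwise.

    Parameters
    ----------
    y : (N,) array of 0/1 outcomes.
    x : (N, J) integer array of category codes; missing entries are
        :data:`MISSING`.
    cardinalities : length-J sequence, number of categories per covariate.
    w : optional (N, P) array of fixed-effect covariates.
    """

    def __init__(self, y, x, cardinalities: Sequence[int], w=None):
        self.y = np.ascontiguousarray(y, dtype=np.int8)
        self.x = np.ascontiguousarray(x, dtype=np.int64)
        if self.x.ndim != 2 or self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x must be (N, J) aligned with y")
        self.cardinalities = tuple(int(L) for L in cardinalities)
        if len(self.cardinalities) != self.x.shape[1]:
            raise ValueError("cardinalities must have one entry per covariate")
        if any(L < 2 for L in self.cardinalities):
            raise ValueError("each covariate needs at least 2 categories")
        self.w = (
            np.zeros((self.y.shape[0], 0))
            if w is None
            else np.ascontiguousarray(w, dtype=float)
        )
        if self.w.shape[0] != self.y.shape[0]:
            raise ValueError("w must be aligned with y")
        self._validate()

    def _validate(self):
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("y must be binary (missing outcomes are not supported)")
        if self.y.sum() == 0 or self.y.sum() == self.N:
            raise ValueError("need at least one case and one control")
        for j, L in enumerate(self.cardinalities):
            col = self.x[:, j]
            obs = col[col != MISSING]
            if obs.size and (obs.min() < 0 or obs.max() >= L):
                raise ValueError(
                    f"covariate {j}: category codes must lie in [0, {L}); "
                    f"found range [{obs.min()}, {obs.max()}]"
                )
        if not np.isfinite(self.w).all():
            raise ValueError("fixed-effect covariates must be finite")

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.x.shape[1]

    @property
    def n_fixed(self) -> int:
        return self.w.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.x == MISSING

    @property
    def subjects(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(int(self.y[i]), tuple(self.x[i]), tuple(self.w[i]))
            for i in range(self.N)
        ]

    @classmethod
    def from_subjects(cls, subjects: Iterable[SubjectRecord], cardinalities):
        subjects = list(subjects)
        y = [s.y for s in subjects]
        x = [s.x for s in subjects]
        w = [s.w for s in subjects]
        return cls(y, x, cardinalities, w=np.asarray(w, dtype=float))

    def __repr__(self):
        return (
            f"Dataset(N={self.N}, J={self.J}, cardinalities={self.cardinalities}, "
            f"fixed_effects={self.n_fixed}, cases={int(self.y.sum())})"
        )


# ---------------------------------------------------------------------------
# discretisation of raw exposures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateBins:
    """Half-open numeric bins (lo, hi] -> code, plus named special levels."""

    name: str
    bins: tuple[tuple[float, float, int], ...]  # (lo, hi, code)
    specials: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        ordered = sorted(self.bins, key=lambda b: b[0])
        for (lo, hi, _), (lo2, _, _) in zip(ordered, ordered[1:]):
            if hi > lo2:
                raise ValueError(f"{self.name}: overlapping bins")
        for lo, hi, _ in self.bins:
            if not lo < hi:
                raise ValueError(f"{self.name}: empty bin ({lo}, {hi}]")


class DiscretisationScheme:
    """Maps raw exposure values to category codes, one rule per covariate.

    Serialised as JSON: a list of objects with ``name``, ``bins``
    (``[lo, hi, code]`` triples, half-open ``(lo, hi]``, ``null`` for +/-inf)
    and ``specials`` (level name -> code).  A packaged scheme for the four
    smoking covariates (intensity, duration, time since cessation,
    pack-years; 5 categories each, non-smoker = 0) ships as
    ``profreg/data/smoking_categories.json``.
    """

    def __init__(self, covariates: Sequence[CovariateBins]):
        self.covariates = list(covariates)

    def __len__(self):
        return len(self.covariates)

    def discretize(self, raw_value, covariate: int) -> int:
        """Map one raw value for covariate ``covariate`` to its category code.

        Missing input (None, NaN or "NA") propagates to :data:`MISSING`;
        a value outside all bins and not a named special level is an error.
        """
        if covariate < 0 or covariate >= len(self.covariates):
            raise IndexError(f"no discretisation rule for covariate {covariate}")
        rule = self.covariates[covariate]
        if raw_value is None or (isinstance(raw_value, str) and raw_value.strip().upper() in ("", "NA", "NAN")):
            return MISSING
        if isinstance(raw_value, str):
            key = raw_value.strip().lower()
            if key in rule.specials:
                return rule.specials[key]
            try:
                raw_value = float(key)
            except ValueError:
                raise ValueError(
                    f"covariate {rule.name!r}: unknown level {raw_value!r}"
                ) from None
        v = float(raw_value)
        if math.isnan(v):
            return MISSING
        for lo, hi, code in rule.bins:
            if lo < v <= hi:
                return code
        raise ValueError(f"covariate {rule.name!r}: value {v} falls outside every bin")

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_json(cls, path_or_obj) -> "DiscretisationScheme":
        if isinstance(path_or_obj, (str, Path)):
            obj = json.loads(Path(path_or_obj).read_text())
        else:
            obj = path_or_obj
        covs = []
        for entry in obj:
            bins = tuple(
                (
                    -math.inf if lo is None else float(lo),
                    math.inf if hi is None else float(hi),
                    int(code),
                )
                for lo, hi, code in entry.get("bins", [])
            )
            specials = {k.lower(): int(v) for k, v in entry.get("specials", {}).items()}
            covs.append(CovariateBins(entry["name"], bins, specials))
        return cls(covs)

    def to_json(self) -> list[dict]:
        out = []
        for c in self.covariates:
            out.append(
                {
                    "name": c.name,
                    "bins": [
                        [None if math.isinf(lo) else lo, None if math.isinf(hi) else hi, code]
                        for lo, hi, code in c.bins
                    ],
                    "specials": dict(c.specials),
                }
            )
        return out

    @classmethod
    def packaged_smoking_scheme(cls) -> "DiscretisationScheme":
        """The shipped 5-category scheme for the four smoking covariates."""
        path = Path(__file__).parent / "data" / "smoking_categories.json"
        return cls.from_json(path)


def discretize(raw_value, scheme: DiscretisationScheme, covariate: int) -> int:
    """Functional wrapper around :meth:`DiscretisationScheme.discretize`."""
    return scheme.discretize(raw_value, covariate)


# ---------------------------------------------------------------------------
# priors and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the model.

    alpha : DP concentration (fixed; no hyperprior).  Default 1.0; typical
        sensitivity values are 3.6 and 10.
    dirichlet_a : per-covariate Dirichlet concentration vectors for the
        profile probabilities phi_{c,j}; default flat Dirichlet(1, ..., 1)
        (conjugate).
    theta prior : Student-t(df=7, location 0, scale 2.5) on the cluster log
        odds — a weakly-informative heavy-tailed default.
    beta prior : Normal(0, sd=5) on each fixed-effect coefficient.
    """

    alpha: float = 1.0
    dirichlet_a: tuple[tuple[float, ...], ...] | None = None
    theta_loc: float = 0.0
    theta_scale: float = 2.5
    theta_df: float = 7.0
    beta_mean: float = 0.0
    beta_sd: float = 5.0

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not (self.theta_scale > 0 and self.theta_df > 0 and self.beta_sd > 0):
            raise ValueError("prior scales and df must be > 0")
        if self.dirichlet_a is not None:
            for a in self.dirichlet_a:
                if any(not ai > 0 for ai in a):
                    raise ValueError("Dirichlet concentrations must be > 0")

    def dirichlet_for(self, cardinalities: Sequence[int]) -> list[np.ndarray]:
        """Concrete concentration vectors, defaulting to all-ones."""
        if self.dirichlet_a is None:
            return [np.ones(L) for L in cardinalities]
        if len(self.dirichlet_a) != len(cardinalities):
            raise ValueError("dirichlet_a must have one vector per covariate")
        out = []
        for a, L in zip(self.dirichlet_a, cardinalities):
            a = np.asarray(a, dtype=float)
            if a.shape != (L,):
                raise ValueError("dirichlet_a vector length must match cardinality")
            out.append(a)
        return out


@dataclass
class ComponentParams:
    """Parameters of one mixture component: cluster log odds ``theta`` and
    per-covariate category probability vectors ``phi``."""

    theta: float
    phi: list[np.ndarray]

    def validate(self, tol: float = 1e-10):
        for j, p in enumerate(self.phi):
            if (np.asarray(p) < 0).any() or abs(float(np.sum(p)) - 1.0) > tol:
                raise ValueError(f"phi[{j}] is not a probability vector")


@dataclass
class GlobalParams:
    """Global (non-component) parameters: fixed-effect coefficients."""

    beta: np.ndarray

    def validate(self):
        if not np.isfinite(self.beta).all():
            raise ValueError("beta must be finite")


class MCMCState:
    """Sampler state at one sweep.

    Component parameters are stored padded: ``phi`` is (C, J, Lmax) with
    zeros in slots beyond each covariate's cardinality.  ``imputed_x`` holds
    the full profile matrix with current draws filled in at missing entries.
    """

    def __init__(self, Z, V, theta, phi, beta, imputed_x, u, cardinalities):
        self.Z = np.asarray(Z, dtype=np.int64)
        self.V = np.asarray(V, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.phi = np.asarray(phi, dtype=float)
        self.beta = np.asarray(beta, dtype=float)
        self.imputed_x = np.asarray(imputed_x, dtype=np.int64)
        self.u = np.asarray(u, dtype=float)
        self.cardinalities = tuple(cardinalities)
        self.psi = stick_weights(self.V)

    @property
    def n_components(self) -> int:
        return self.V.shape[0]

    @property
    def K(self) -> int:
        """Number of occupied clusters (distinct allocation values)."""
        return int(np.unique(self.Z).size)

    @property
    def components(self) -> list[ComponentParams]:
        return [
            ComponentParams(
                float(self.theta[c]),
                [self.phi[c, j, :L].copy() for j, L in enumerate(self.cardinalities)],
            )
            for c in range(self.n_components)
        ]

    @property
    def globals(self) -> GlobalParams:
        return GlobalParams(self.beta.copy())

    def validate(self, data: "Dataset | None" = None, tol: float = 1e-10):
        """Check the structural invariants of a sampler state."""
        if ((self.V <= 0) | (self.V >= 1)).any():
            raise ValueError("stick fractions must lie in (0,1)")
        psi = stick_weights(self.V)
        if not np.allclose(psi, self.psi, atol=tol):
            raise ValueError("psi inconsistent with V")
        if psi.sum() >= 1.0 + tol:
            raise ValueError("partial stick sums must stay below 1")
        if self.Z.min() < 0 or self.Z.max() >= self.n_components:
            raise ValueError("allocation indexes an unrepresented component")
        for j, L in enumerate(self.cardinalities):
            block = self.phi[:, j, :L]
            if (block < -tol).any() or np.abs(block.sum(axis=1) - 1.0).max() > tol:
                raise ValueError(f"phi[:, {j}] rows must be probability vectors")
        if ((self.u <= 0) | (self.u > self.psi[self.Z])).any():
            raise ValueError("slice variables must satisfy 0 < u_i <= psi_{Z_i}")
        if data is not None:
            miss = data.missing_mask
            if (self.imputed_x[miss] < 0).any():
                raise ValueError("missing entries lack imputed categories")
            for j, L in enumerate(self.cardinalities):
                if self.imputed_x[:, j].max() >= L:
                    raise ValueError("imputed category out of range")


# ---------------------------------------------------------------------------
# probability computations
# ---------------------------------------------------------------------------

def stick_weights(V: np.ndarray) -> np.ndarray:
    """Stick-breaking weights psi_c = V_c * prod_{l<c} (1 - V_l)."""
    V = np.asarray(V, dtype=float)
    if ((V <= 0) | (V >= 1)).any():
        raise ValueError("stick fractions must lie strictly in (0, 1)")
    log_remain = np.concatenate([[0.0], np.cumsum(np.log1p(-V))[:-1]])
    return V * np.exp(log_remain)


def response_logit(theta: float, beta, w) -> float:
    """Case probability pi = expit(theta + beta'w)."""
    beta = np.asarray(beta, dtype=float)
    w = np.asarray(w, dtype=float)
    if beta.shape != w.shape:
        raise ValueError("beta and w must be conformable")
    return float(expit(theta + float(beta @ w)))


def profile_loglik(x, phi, cardinalities: Sequence[int] | None = None) -> float:
    """Log multinomial profile likelihood, missing entries marginalised.

    ``phi`` may be a list of per-covariate probability vectors or a padded
    (J, Lmax) array (then ``cardinalities`` bounds the valid slots).
    Missing covariates contribute 0 because each phi row sums to one.
    """
    x = np.asarray(x, dtype=np.int64)
    if isinstance(phi, np.ndarray) and phi.ndim == 2:
        rows = [phi[j, : (cardinalities[j] if cardinalities else phi.shape[1])] for j in range(len(x))]
    else:
        rows = list(phi)
    total = 0.0
    for j, (xj, row) in enumerate(zip(x, rows)):
        if xj == MISSING:
            continue
        if xj < 0 or xj >= len(row):
            raise ValueError(f"covariate {j}: category {xj} out of range [0, {len(row)})")
        total += math.log(float(row[xj]))
    return total


def joint_loglik(state: MCMCState, data: Dataset, priors: PriorSpec) -> float:
    """Log joint density of data and parameters in allocated form.

    Sums the Bernoulli outcome terms, the observed-profile multinomial terms
    and the log priors on V, phi, theta and beta.  The allocation mass is
    deliberately excluded, which makes the quantity invariant under any
    relabelling of components applied consistently to Z; it serves as the
    chain's stability diagnostic.  Non-finite results signal an invalid
    state.
    """
    eta = state.theta[state.Z] + data.w @ state.beta
    ll = float(bernoulli_loglik(data.y, eta).sum())
    obs = ~data.missing_mask
    for j, L in enumerate(data.cardinalities):
        sel = obs[:, j]
        probs = state.phi[state.Z[sel], j, data.x[sel, j]]
        if (probs <= 0).any():
            return -math.inf
        ll += float(np.log(probs).sum())
    alpha = priors.alpha
    ll += float((math.log(alpha) + (alpha - 1.0) * np.log1p(-state.V)).sum())
    a_list = priors.dirichlet_for(data.cardinalities)
    for c in range(state.n_components):
        for j, a in enumerate(a_list):
            ll += dirichlet_logpdf(state.phi[c, j, : len(a)], a)
    ll += float(student_t_logpdf(state.theta, priors.theta_df, priors.theta_loc, priors.theta_scale).sum())
    ll += float(normal_logpdf(state.beta, priors.beta_mean, priors.beta_sd).sum())
    if not math.isfinite(ll):
        raise ValueError("joint log likelihood is not finite: invalid state")
    return ll


def expected_clusters(alpha: float, N: int) -> float:
    """Asymptotic expected number of occupied DP clusters, alpha*log(1+N/alpha)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha == 0:
        return 0.0
    return float(alpha * math.log1p(N / alpha))


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def load_dataset(csv_path, config: Mapping | str | Path) -> Dataset:
    """Read a CSV into a :class:`Dataset` using a column-role config.

    ``config`` is a mapping (or path to a JSON file) with keys:

    - ``outcome``: column name of the 0/1 outcome,
    - ``profile``: ordered list of categorical covariate columns,
    - ``cardinalities``: mapping column -> number of categories,
    - ``fixed_effects``: optional list of numeric confounder columns,
    - ``missing_token``: optional token for missing profile values
      (default: empty string or ``NA``).
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    profile_cols = list(config["profile"])
    fixed_cols = list(config.get("fixed_effects", []))
    token = config.get("missing_token", "NA")
    df = pd.read_csv(csv_path, dtype={c: str for c in profile_cols}, keep_default_na=False)
    y_raw = pd.to_numeric(df[config["outcome"]], errors="coerce")
    if y_raw.isna().any():
        raise ValueError("missing outcome values are not supported")
    y = y_raw.to_numpy()
    x = np.empty((len(df), len(profile_cols)), dtype=np.int64)
    for j, col in enumerate(profile_cols):
        vals = df[col].str.strip()
        is_missing = (vals == "") | (vals == token)
        codes = np.full(len(df), MISSING, dtype=np.int64)
        if (~is_missing).any():
            codes[~is_missing] = pd.to_numeric(vals[~is_missing]).astype(np.int64)
        x[:, j] = codes
    cards = [int(config["cardinalities"][c]) for c in profile_cols]
    w = df[fixed_cols].apply(pd.to_numeric).to_numpy(dtype=float) if fixed_cols else None
    return Dataset(y, x, cards, w=w)


def save_dataset(dataset: Dataset, csv_path, missing_token: str = "NA") -> dict:
    """Write a dataset as CSV (deterministic formatting); returns the matching
    column-role config dict."""
    cols: dict[str, object] = {"y": dataset.y.astype(int)}
    profile_cols = [f"x{j + 1}" for j in range(dataset.J)]
    for j, name in enumerate(profile_cols):
        col = dataset.x[:, j]
        cols[name] = [missing_token if v == MISSING else str(int(v)) for v in col]
    fixed_cols = [f"w{k + 1}" for k in range(dataset.n_fixed)]
    for k, name in enumerate(fixed_cols):
        cols[name] = [format(v, ".10g") for v in dataset.w[:, k]]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    return {
        "outcome": "y",
        "profile": profile_cols,
        "fixed_effects": fixed_cols,
        "cardinalities": {c: L for c, L in zip(profile_cols, dataset.cardinalities)},
        "missing_token": missing_token,
    }
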