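"""Seeded generators for study-like case-control populations.

The smoking/lung-cancer dataset these generators emulate is not
redistributable, so every other module is exercised on synthetic populations
with a known generative truth: a finite mixture of covariate clusters, each
with its own modal exposure profile and disease log odds, plus fixed-effect
confounders and sparse completely-at-random missingness.  Two additional
benchmark scenarios — a logistic model with interactions and a
contrasting-profiles mixture, both over ten binary covariates — support
comparisons against regression-style competitors.  Scenario coefficients are
package surrogates stored in versioned JSON under ``profreg/data/``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .model_core import MISSING, Dataset

__all__ = [
    "GenerativeTruth",
    "icare_like_truth",
    "generate_population",
    "expected_case_fraction",
    "generate_scenario_logistic",
    "generate_scenario_profiles",
    "logistic_scenario_config",
    "profiles_scenario_config",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class GenerativeTruth:
    """Ground truth of a synthetic population.

    ``phi`` is (K, J, Lmax) padded with zeros past each cardinality.
    ``confounders`` is a sequence of ("bernoulli", p) specs, one per fixed
    effect; ``beta`` its coefficient vector on the log-odds scale.
    """

    weights: tuple[float, ...]
    theta: tuple[float, ...]
    phi: np.ndarray
    cardinalities: tuple[int, ...]
    beta: tuple[float, ...] = ()
    confounders: tuple[tuple, ...] = ()
    missing_rates: tuple[float, ...] = ()

    def __post_init__(self):
        w = np.asarray(self.weights)
        if abs(w.sum() - 1.0) > 1e-9 or (w <= 0).any():
            raise ValueError("mixing weights must be positive and sum to 1")
        if len(self.theta) != len(self.weights):
            raise ValueError("theta must have one entry per cluster")
        phi = np.asarray(self.phi)
        for j, L in enumerate(self.cardinalities):
            rows = phi[:, j, :L]
            if (rows < 0).any() or np.abs(rows.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"phi[:, {j}] rows must be simplex vectors")
            if L < phi.shape[2] and np.abs(phi[:, j, L:]).max() > 0:
                raise ValueError("phi padding must be zero")
        if len(self.beta) != len(self.confounders):
            raise ValueError("beta must have one coefficient per confounder")
        rates = self.missing_rates or (0.0,) * len(self.cardinalities)
        if len(rates) != len(self.cardinalities) or any(not 0 <= r < 1 for r in rates):
            raise ValueError("missing rates must lie in [0, 1), one per covariate")

    @property
    def K_true(self) -> int:
        return len(self.weights)

    @property
    def J(self) -> int:
        return len(self.cardinalities)


def _modal_phi(modal: Sequence[int], cardinalities, modal_prob: float, Lmax=None) -> np.ndarray:
    """One cluster's phi rows: ``modal_prob`` on the modal category, the rest
    spread evenly."""
    Lmax = Lmax or max(cardinalities)
    out = np.zeros((len(cardinalities), Lmax))
    for j, (m, L) in enumerate(zip(modal, cardinalities)):
        out[j, :L] = (1.0 - modal_prob) / (L - 1)
        out[j, m] = modal_prob
    return out


def icare_like_truth(
    log_or: Sequence[float] = (0.0, 1.5, 3.0, 4.5),
    baseline_log_odds: float = -2.25,
    weights: Sequence[float] | None = None,
    modal_prob_reference: float = 0.97,
    modal_prob: float = 0.92,
) -> GenerativeTruth:
    """Default four-cluster truth mirroring a smoking case-control study:
    J=4 covariates with 5 categories each, a never-exposed low-risk cluster
    concentrated on category 0, and three exposure clusters with increasing
    modal categories.  Cluster log odds are ``baseline_log_odds + log_or``:
    the log odds ratios versus the reference cluster span ~0 to ~4.5 and the
    baseline keeps the sampled case fraction near the ~45% typical of a
    case-control design.  One binary occupational confounder (p=0.3,
    beta=0.4) and sparse missingness (0.3%) on the first and last
    covariates."""
    theta = tuple(baseline_log_odds + lo for lo in log_or)
    K = len(theta)
    cards = (5, 5, 5, 5)
    weights = tuple(weights) if weights is not None else (1.0 / K,) * K
    modal_categories = [
        (0, 0, 0, 0),
        (1, 1, 1, 1),
        (2, 3, 3, 2),
        (4, 4, 4, 4),
    ][:K]
    phi = np.stack(
        [
            _modal_phi(m, cards, modal_prob_reference if k == 0 else modal_prob)
            for k, m in enumerate(modal_categories)
        ]
    )
    return GenerativeTruth(
        weights=weights,
        theta=tuple(theta),
        phi=phi,
        cardinalities=cards,
        beta=(0.4,),
        confounders=(("bernoulli", 0.3),),
        missing_rates=(0.003, 0.0, 0.0, 0.003),
    )


def generate_population(
    truth: GenerativeTruth, N: int, seed: int | np.random.Generator = 0
) -> tuple[Dataset, np.ndarray]:
    """Draw N subjects from the truth; returns (dataset, hidden labels).

    Cluster labels ~ weights; profiles from the cluster's multinomials;
    confounders from their stated laws; outcomes Bernoulli with
    logit = theta_cluster + beta'w; missingness injected MCAR afterwards.
    Byte-identical output for identical seeds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K, J = truth.K_true, truth.J
    labels = rng.choice(K, size=N, p=np.asarray(truth.weights))
    x = np.empty((N, J), dtype=np.int64)
    for j, L in enumerate(truth.cardinalities):
        cum = np.cumsum(truth.phi[labels, j, :L], axis=1)
        cum /= cum[:, -1:]
        x[:, j] = (cum < rng.random(N)[:, None]).sum(axis=1)
    P = len(truth.confounders)
    w = np.zeros((N, P))
    for k, spec in enumerate(truth.confounders):
        kind, *params = spec
        if kind == "bernoulli":
            w[:, k] = rng.random(N) < params[0]
        else:
            raise ValueError(f"unknown confounder law {kind!r}")
    eta = np.asarray(truth.theta)[labels] + (w @ np.asarray(truth.beta) if P else 0.0)
    y = (rng.random(N) < expit(eta)).astype(np.int8)
    if y.sum() == 0 or y.sum() == N:  # pathological tiny draw; nudge one subject
        y[0] = 1 - y[0]
    rates = truth.missing_rates or (0.0,) * J
    for j, r in enumerate(rates):
        if r > 0:
            x[rng.random(N) < r, j] = MISSING
    return Dataset(y, x, truth.cardinalities, w=w if P else None), labels


def expected_case_fraction(truth: GenerativeTruth) -> float:
    """Exact population case fraction by summation over clusters and the
    (finite-support) confounder joint distribution."""
    theta = np.asarray(truth.theta)
    weights = np.asarray(truth.weights)
    if not truth.confounders:
        return float(weights @ expit(theta))
    supports, probs = [], []
    for spec in truth.confounders:
        kind, *params = spec
        if kind != "bernoulli":
            raise ValueError("exact case fraction needs finite-support confounders")
        supports.append([0.0, 1.0])
        probs.append([1 - params[0], params[0]])
    total = 0.0
    beta = np.asarray(truth.beta)
    for combo in product(*range_indices(supports)):
        wvec = np.array([supports[k][i] for k, i in enumerate(combo)])
        pw = np.prod([probs[k][i] for k, i in enumerate(combo)])
        total += pw * float(weights @ expit(theta + beta @ wvec))
    return total


def range_indices(supports):
    return [range(len(s)) for s in supports]


# ---------------------------------------------------------------------------
# benchmark scenarios over ten binary covariates
# ---------------------------------------------------------------------------

def logistic_scenario_config() -> dict:
    return json.loads((_DATA_DIR / "scenario_logistic.json").read_text())


def profiles_scenario_config() -> dict:
    return json.loads((_DATA_DIR / "scenario_profiles.json").read_text())


def generate_scenario_logistic(
    N: int, seed: int = 0, config: dict | None = None
) -> tuple[Dataset, dict]:
    """Ten Bernoulli(0.5) covariates; outcome from a logistic model with main
    effects and pairwise interactions.  Returns (dataset, truth) where truth
    carries the coefficients and each subject's true linear predictor."""
    cfg = config or logistic_scenario_config()
    main = np.asarray(cfg["main_effects"], dtype=float)
    J = main.size
    rng = np.random.default_rng(seed)
    x = (rng.random((N, J)) < 0.5).astype(np.int64)
    eta = cfg["intercept"] + x @ main
    for i, j, coef in cfg["interactions"]:
        eta = eta + coef * x[:, int(i)] * x[:, int(j)]
    y = (rng.random(N) < expit(eta)).astype(np.int8)
    if y.sum() == 0 or y.sum() == N:
        y[0] = 1 - y[0]
    data = Dataset(y, x, (2,) * J)
    truth = {"config": cfg, "linear_predictor": eta}
    return data, truth


def generate_scenario_profiles(
    N: int, seed: int = 0, config: dict | None = None
) -> tuple[Dataset, dict]:
    """Contrasting-profiles scenario: subjects drawn from a few covariate
    clusters over ten binary covariates with cluster-specific risks.
    Returns (dataset, truth) with hidden labels under ``truth['labels']``."""
    cfg = config or profiles_scenario_config()
    patterns = np.asarray(cfg["modal_patterns"], dtype=int)
    K, J = patterns.shape
    cards = (2,) * J
    phi = np.stack([
        _modal_phi(p, cards, cfg["modal_probability"]) for p in patterns
    ])
    truth_obj = GenerativeTruth(
        weights=tuple(cfg["weights"]), theta=tuple(cfg["theta"]),
        phi=phi, cardinalities=cards,
    )
    data, labels = generate_population(truth_obj, N, seed)
    return data, {"config": cfg, "truth": truth_obj, "labels": labels}
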