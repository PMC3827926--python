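"""Posterior-predictive risk for pseudo-profiles.

A pseudo-profile is a hypothetical covariate vector, possibly only partially
specified (NA entries are marginalised), pushed through the fitted posterior
*without* touching the fit.  At each retained sweep t the profile is
allocated among that sweep's occupied components,

    p_c  propto  psi_c * prod_{j observed} phi_{c, j, x*_j},

and the cluster-averaged log odds  lambda* = sum_c p_c theta_c  is recorded.
Over sweeps this yields a posterior density of the log odds (or the log odds
ratio against a reference profile, e.g. the all-zeros never-exposed
profile), plus ordinal expected-category values for covariates left as NA.
Fixed effects are excluded throughout: they cancel in odds ratios taken at
common confounder values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model_core import MISSING
from .sampler import ChainOutput

__all__ = [
    "PseudoProfile",
    "PredictiveDraws",
    "allocate_pseudo",
    "predictive_log_odds",
    "predictive_log_or",
    "expected_category",
    "read_pseudo_profiles",
    "summary_frame",
]


@dataclass(frozen=True)
class PseudoProfile:
    """A partially specified covariate vector; NA entries (:data:`MISSING`)
    are marginalised out of the allocation."""

    x: tuple[int, ...]
    label: str = ""

    @classmethod
    def from_values(cls, values, label: str = "") -> "PseudoProfile":
        codes = []
        for v in values:
            if v is None or (isinstance(v, float) and np.isnan(v)) or (
                isinstance(v, str) and v.strip().upper() in ("", "NA", "NAN")
            ):
                codes.append(MISSING)
            else:
                codes.append(int(v))
        return cls(tuple(codes), label)

    def check(self, cardinalities) -> None:
        if len(self.x) != len(cardinalities):
            raise ValueError("pseudo-profile length must equal the number of covariates")
        for j, (xj, L) in enumerate(zip(self.x, cardinalities)):
            if xj != MISSING and not 0 <= xj < L:
                raise ValueError(f"pseudo-profile covariate {j}: category {xj} out of range [0, {L})")


@dataclass
class PredictiveDraws:
    """Per-sweep predictive output for one pseudo-profile."""

    profile: PseudoProfile
    draws: np.ndarray                      # (T,) lambda* or log OR draws
    allocations: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1)) if self.draws.size > 1 else 0.0

    def quantiles(self, q=(0.025, 0.25, 0.5, 0.75, 0.975)) -> np.ndarray:
        return np.quantile(self.draws, q)

    def density(self, n_grid: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Gaussian KDE (Scott's bandwidth rule) on an evenly spaced grid
        spanning the draws plus three bandwidths each side."""
        d = self.draws
        if np.ptp(d) == 0:  # degenerate: all draws equal
            grid = np.linspace(d[0] - 1, d[0] + 1, n_grid)
            dens = np.zeros(n_grid)
            dens[np.argmin(np.abs(grid - d[0]))] = 1.0
            return grid, dens
        kde = gaussian_kde(d, bw_method="scott")
        h = d.std(ddof=1) * kde.factor
        grid = np.linspace(d.min() - 3 * h, d.max() + 3 * h, n_grid)
        return grid, kde(grid)


def allocate_pseudo(profile: PseudoProfile, psi: np.ndarray, phi: np.ndarray,
                    cardinalities) -> np.ndarray:
    """Allocation probabilities of a pseudo-profile over one sweep's occupied
    components: psi-weighted product of observed-category probabilities,
    renormalised.  NA entries contribute a factor of 1."""
    profile.check(cardinalities)
    weights = np.array(psi, dtype=float, copy=True)
    for j, xj in enumerate(profile.x):
        if xj == MISSING:
            continue
        weights *= phi[:, j, xj]
    total = weights.sum()
    if total <= 0:
        raise ValueError("pseudo-profile has zero probability under every component")
    return weights / total


def _allocation_series(profile: PseudoProfile, chain: ChainOutput) -> list[np.ndarray]:
    if chain.n_retained == 0:
        raise ValueError("empty chain")
    return [
        allocate_pseudo(profile, chain.psi[t], chain.phi[t], chain.cardinalities)
        for t in range(chain.n_retained)
    ]


def predictive_log_odds(profile: PseudoProfile, chain: ChainOutput) -> PredictiveDraws:
    """Cluster-averaged log odds draws lambda* = sum_c p_c theta_c per sweep."""
    allocs = _allocation_series(profile, chain)
    draws = np.array([p @ chain.theta[t] for t, p in enumerate(allocs)])
    return PredictiveDraws(profile=profile, draws=draws, allocations=allocs)


def predictive_log_or(
    profile: PseudoProfile, reference: PseudoProfile, chain: ChainOutput
) -> PredictiveDraws:
    """Per-sweep difference of cluster-averaged log odds against a reference
    pseudo-profile (typically the all-zeros never-exposed profile)."""
    target = predictive_log_odds(profile, chain)
    ref = predictive_log_odds(reference, chain)
    return PredictiveDraws(
        profile=profile, draws=target.draws - ref.draws, allocations=target.allocations
    )


def expected_category(
    profile: PseudoProfile, covariate: int, chain: ChainOutput
) -> tuple[float, float]:
    """Ordinal expected category value of one covariate for a pseudo-profile:
    per sweep  E = sum_c p_c sum_l l * phi_{c, j, l};  returns (mean, sd)
    over sweeps."""
    if not 0 <= covariate < chain.J:
        raise ValueError(f"covariate index {covariate} out of range [0, {chain.J})")
    L = chain.cardinalities[covariate]
    codes = np.arange(L, dtype=float)
    allocs = _allocation_series(profile, chain)
    vals = np.array([
        p @ (chain.phi[t][:, covariate, :L] @ codes) for t, p in enumerate(allocs)
    ])
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def read_pseudo_profiles(csv_path, J: int, missing_token: str = "NA") -> list[PseudoProfile]:
    """Read pseudo-profiles from CSV: one row per profile, optional ``label``
    column, J covariate columns with the missing token for NA entries."""
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    cov_cols = [c for c in df.columns if c != "label"]
    if len(cov_cols) != J:
        raise ValueError(f"expected {J} covariate columns, found {len(cov_cols)}")
    out = []
    for i, row in df.iterrows():
        vals = [None if row[c].strip() in ("", missing_token) else row[c] for c in cov_cols]
        label = row["label"] if "label" in df.columns else f"profile{i + 1}"
        out.append(PseudoProfile.from_values(vals, label))
    return out


def summary_frame(results: list[PredictiveDraws]) -> pd.DataFrame:
    """Mean (sd) summary table for a set of predictive draws."""
    return pd.DataFrame(
        {
            "label": [r.profile.label for r in results],
            "mean": [r.mean for r in results],
            "sd": [r.sd for r in results],
            "q2.5": [r.quantiles((0.025,))[0] for r in results],
            "q97.5": [r.quantiles((0.975,))[0] for r in results],
        }
    )
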