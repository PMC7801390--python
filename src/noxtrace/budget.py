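"""Regional aggregation and fossil/non-fossil NOx emission budgets.

Urban and non-urban source fractions are combined into region-wide
contributions with population weights, split into fossil (coal + vehicle)
and non-fossil (biomass burning + microbial) shares, and converted into
emission amounts from inventory fossil-fuel totals:

    A_total      = A_fossil / F_fossil
    A_non-fossil = A_total - A_fossil

Uncertainty is propagated by Monte Carlo with truncated-normal inputs
(fractions confined to (0, 1], amounts to >= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PopulationWeights",
    "ContributionPair",
    "EmissionBudget",
    "FOSSIL_SOURCES",
    "NON_FOSSIL_SOURCES",
    "regionwide_contribution",
    "fossil_nonfossil_split",
    "emission_budget",
    "propagate_uncertainty",
    "aggregate_regions",
]

FOSSIL_SOURCES = ("coal_combustion", "vehicle_exhaust")
NON_FOSSIL_SOURCES = ("biomass_burning", "microbial_N")


@dataclass(frozen=True)
class PopulationWeights:
    """Urban / non-urban population shares of one region."""

    p_urban: float
    p_non_urban: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_urban <= 1 and 0 <= self.p_non_urban <= 1):
            raise ValueError("population fractions must lie in [0, 1]")
        if abs(self.p_urban + self.p_non_urban - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")

    @classmethod
    def from_urban(cls, p_urban: float) -> "PopulationWeights":
        return cls(p_urban, 1.0 - p_urban)


@dataclass(frozen=True)
class ContributionPair:
    """Urban and non-urban contribution of one source (mean +/- SD)."""

    source: str
    f_urban: float
    f_non_urban: float
    f_urban_sd: float = 0.0
    f_non_urban_sd: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.f_urban, self.f_non_urban):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.f_urban_sd < 0 or self.f_non_urban_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class EmissionBudget:
    """Fossil, total, and non-fossil emission amounts (Mt/yr) with SDs."""

    a_fossil: float
    f_fossil: float
    f_non_fossil: float
    a_total: float
    a_non_fossil: float
    a_fossil_sd: float = 0.0
    f_fossil_sd: float = 0.0
    f_non_fossil_sd: float = 0.0
    a_total_sd: float = 0.0
    a_non_fossil_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a_fossil, self.a_total, self.a_non_fossil) < 0:
            raise ValueError("emission amounts must be >= 0")
        if abs(self.f_fossil + self.f_non_fossil - 1.0) > 1e-9:
            raise ValueError("fossil and non-fossil fractions must sum to 1")
        if abs(self.a_fossil + self.a_non_fossil - self.a_total) > 1e-9 * max(
            1.0, self.a_total
        ):
            raise ValueError("amounts must satisfy a_fossil + a_non_fossil = a_total")


def regionwide_contribution(
    pair: ContributionPair,
    weights: PopulationWeights,
    literal_product: bool = False,
) -> float:
    """Region-wide contribution of one source.

    The population-weighted mean ``f_urban * P_urban + f_non_urban *
    P_non_urban``: it preserves closure (source contributions that sum to 1
    in each stratum sum to 1 region-wide).  ``literal_product=True`` instead
    multiplies all four factors — an audit mode only, since the product is
    not a relative contribution and breaks closure (see the methods note).
    """
    if literal_product:
        return (
            pair.f_urban * weights.p_urban * pair.f_non_urban * weights.p_non_urban
        )
    return pair.f_urban * weights.p_urban + pair.f_non_urban * weights.p_non_urban


def fossil_nonfossil_split(
    f_s1: float, f_s2: float, f_s3: float, f_s4: float
) -> tuple[float, float]:
    """Split per-source contributions into (fossil, non-fossil) sums.

    Fossil = coal (S1) + vehicle (S2); non-fossil = biomass burning (S3) +
    microbial N cycle (S4).  A three-source region passes ``f_s2=0``.
    """
    for f in (f_s1, f_s2, f_s3, f_s4):
        if not 0 <= f <= 1:
            raise ValueError("contributions must lie in [0, 1]")
    if f_s1 + f_s2 + f_s3 + f_s4 > 1 + 1e-6:
        raise ValueError("contributions must sum to at most 1")
    return f_s1 + f_s2, f_s3 + f_s4


def emission_budget(a_fossil: float, f_fossil: float) -> EmissionBudget:
    """Deterministic emission budget from inventory fossil amount and share."""
    if a_fossil < 0:
        raise ValueError("a_fossil must be >= 0")
    if not 0 < f_fossil <= 1:
        raise ZeroDivisionError(
            "f_fossil must lie in (0, 1]: an all-non-fossil regime is outside "
            "the budgeting identity"
        )
    a_total = a_fossil / f_fossil
    return EmissionBudget(
        a_fossil=a_fossil,
        f_fossil=f_fossil,
        f_non_fossil=1.0 - f_fossil,
        a_total=a_total,
        a_non_fossil=a_total - a_fossil,
    )


def _truncnorm_draws(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    n: int,
) -> np.ndarray:
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate distribution outside truncation bounds")
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd).rvs(size=n, random_state=rng)


def propagate_uncertainty(
    a_fossil: float,
    a_fossil_sd: float,
    f_fossil: float,
    f_fossil_sd: float,
    n_draws: int = 10_000,
    seed: int = 0,
    f_fossil_draws: np.ndarray | None = None,
    return_draws: bool = False,
):
    """Monte Carlo propagation of inventory and fraction uncertainty.

    Draws the fossil amount from a normal truncated to [0, inf) and the
    fossil fraction from a normal truncated to (0, 1] (or uses supplied
    posterior draws directly), applies the budgeting identity per draw, and
    reports the SDs of the derived quantities.  Central values are the
    deterministic budget, so the closure ``a_fossil + a_non_fossil =
    a_total`` holds exactly for them and for every retained draw.  With
    ``return_draws=True`` the per-draw arrays are returned alongside the
    budget for auditing.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for stable SD estimates")
    if a_fossil_sd < 0 or f_fossil_sd < 0:
        raise ValueError("SDs must be >= 0")
    central = emission_budget(a_fossil, f_fossil)
    rng = np.random.default_rng(seed)
    a_draws = _truncnorm_draws(rng, a_fossil, a_fossil_sd, 0.0, np.inf, n_draws)
    if f_fossil_draws is not None:
        f_draws = np.asarray(f_fossil_draws, dtype=float)
        if f_draws.size != n_draws:
            raise ValueError(
                f"f_fossil_draws has length {f_draws.size}, expected {n_draws}"
            )
        if np.any((f_draws <= 0) | (f_draws > 1)):
            raise ValueError("supplied f_fossil draws must lie in (0, 1]")
    else:
        f_draws = _truncnorm_draws(rng, f_fossil, f_fossil_sd, 1e-6, 1.0, n_draws)
    total_draws = a_draws / f_draws
    non_fossil_draws = total_draws - a_draws
    result = EmissionBudget(
        a_fossil=central.a_fossil,
        f_fossil=central.f_fossil,
        f_non_fossil=central.f_non_fossil,
        a_total=central.a_total,
        a_non_fossil=central.a_non_fossil,
        a_fossil_sd=float(a_draws.std(ddof=1)),
        f_fossil_sd=float(f_draws.std(ddof=1)),
        f_non_fossil_sd=float(f_draws.std(ddof=1)),
        a_total_sd=float(total_draws.std(ddof=1)),
        a_non_fossil_sd=float(non_fossil_draws.std(ddof=1)),
    )
    if return_draws:
        draws = {
            "a_fossil": a_draws,
            "f_fossil": f_draws,
            "a_total": total_draws,
            "a_non_fossil": non_fossil_draws,
        }
        return result, draws
    return result


def aggregate_regions(
    non_fossil_fractions: Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    """Cross-region mean non-fossil contribution.

    Unweighted by default; pass ``weights`` (for example regional emission
    totals) for a weighted mean.  Both conventions are reported by the
    pipeline because the aggregation rule behind a single headline share is
    a reporting choice, not a physical one.
    """
    f = np.asarray(non_fossil_fractions, dtype=float)
    if f.size == 0:
        raise ValueError("at least one region is required")
    if weights is None:
        return float(f.mean())
    w = np.asarray(weights, dtype=float)
    if w.size != f.size or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and sum to > 0")
    return float(f @ w / w.sum())
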