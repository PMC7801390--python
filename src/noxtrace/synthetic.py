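"""Synthetic observation generators.

The compiled precipitation-nitrate isotope data behind the analysis are not
distributed in machine-readable form, so this module emulates their
statistical structure: per-stratum (region x urban/non-urban) normal
distributions of delta15N of wet-deposited nitrate, a site/replicate
hierarchy, forward-simulated end-member mixtures, and ambient-chemistry
records suitable for initial-NOx reconstruction.  Everything is driven by an
explicit integer seed so downstream stages are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratumSpec",
    "IsotopeObservation",
    "MixtureSpec",
    "OBSERVATION_COLUMNS",
    "default_strata",
    "generate_observation_table",
    "generate_mixture_observations",
    "generate_ambient_records",
]

#: canonical column order of an observation table
OBSERVATION_COLUMNS = ("site_id", "region", "site_class", "year", "delta15n_permil")

REGIONS = ("East Asia", "Europe", "North America")
SITE_CLASSES = ("urban", "non-urban")


@dataclass(frozen=True)
class IsotopeObservation:
    """One replicate delta15N measurement of nitrate in precipitation."""

    site_id: str
    region: str
    site_class: str
    year: int
    delta15n: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta15n):
            raise ValueError("delta15N must be finite")


@dataclass(frozen=True)
class StratumSpec:
    """Sampling stratum: one region x site-class cell.

    ``mean_delta``/``sd_delta`` are the stratum mean and SD of delta15N in
    permil.  ``within_site_fraction`` controls how the stratum variance is
    split between replicate scatter within a site and scatter of site means
    (0.5 by default: an even split).
    """

    region: str
    site_class: str
    mean_delta: float
    sd_delta: float
    n_sites: int
    replicates_per_site: int = 5
    year_range: tuple[int, int] = (2010, 2010)
    within_site_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_delta < 0:
            raise ValueError("sd_delta must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.replicates_per_site < 1:
            raise ValueError("replicates_per_site must be >= 1")
        lo, hi = self.year_range
        if hi < lo:
            raise ValueError("year_range must be a non-empty inclusive interval")
        if not 0.0 <= self.within_site_fraction <= 1.0:
            raise ValueError("within_site_fraction must lie in [0, 1]")

    @property
    def years(self) -> range:
        lo, hi = self.year_range
        return range(lo, hi + 1)


# Printed stratum summaries (mean +/- SD permil; number of sites) for
# delta15N of precipitation nitrate at urban and non-urban sites of the
# three study regions during 2000-2017.
_FIG2_STRATA: tuple[tuple[str, str, float, float, int], ...] = (
    ("East Asia", "urban", 1.7, 5.4, 25),
    ("East Asia", "non-urban", 0.3, 3.1, 38),
    ("Europe", "urban", 0.8, 2.6, 8),
    ("Europe", "non-urban", -1.5, 2.6, 15),
    ("North America", "urban", -0.5, 1.9, 10),
    ("North America", "non-urban", -1.9, 2.1, 73),
)


def default_strata(
    replicates_per_site: int = 5,
    year_range: tuple[int, int] = (2000, 2017),
) -> list[StratumSpec]:
    """The six region x site-class strata with their published moments."""
    return [
        StratumSpec(region, site_class, mean, sd, n_sites,
                    replicates_per_site=replicates_per_site,
                    year_range=year_range)
        for region, site_class, mean, sd, n_sites in _FIG2_STRATA
    ]


def generate_observation_table(
    strata: Sequence[StratumSpec], seed: int
) -> pd.DataFrame:
    """Draw a replicate-level observation table from stratum specifications.

    For each stratum, site-level means are drawn from a normal distribution
    carrying the between-site share of the stratum variance, and replicate
    observations are drawn around each site-year mean with the within-site
    share.  Deterministic given ``seed``.
    """
    if len(strata) == 0:
        raise ValueError("strata must be non-empty")
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for spec in strata:
        sd_within = spec.sd_delta * math.sqrt(spec.within_site_fraction)
        sd_between = spec.sd_delta * math.sqrt(1.0 - spec.within_site_fraction)
        tag = f"{spec.region[:2].upper()}-{spec.site_class[:1].upper()}"
        site_means = rng.normal(spec.mean_delta, sd_between, size=spec.n_sites)
        for i, site_mean in enumerate(site_means):
            site_id = f"{tag}{i + 1:03d}"
            for year in spec.years:
                deltas = rng.normal(site_mean, sd_within,
                                    size=spec.replicates_per_site)
                rows.extend(
                    (site_id, spec.region, spec.site_class, year, float(d))
                    for d in deltas
                )
    return pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))


@dataclass(frozen=True)
class MixtureSpec:
    """Forward model of an isotope mixture for parameter-recovery tests.

    Observations are ``delta = sum_k f_k * d_k + offset + eps`` where the
    per-observation source signatures ``d_k`` are normal with the stated
    source means/SDs, the fractionation offset is normal with
    ``offset_mean``/``offset_sd``, and ``eps`` is residual noise.
    """

    true_fractions: tuple[float, ...]
    source_means: tuple[float, ...]
    source_sds: tuple[float, ...]
    offset_mean: float = 0.0
    offset_sd: float = 0.0
    residual_sd: float = 0.0
    n_obs: int = 100

    def __post_init__(self) -> None:
        f = np.asarray(self.true_fractions, dtype=float)
        if f.size not in (3, 4):
            raise ValueError("number of sources must be 3 or 4")
        if len(self.source_means) != f.size or len(self.source_sds) != f.size:
            raise ValueError("source_means/source_sds must match true_fractions")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("true_fractions must lie on the unit simplex")
        if any(s < 0 for s in self.source_sds):
            raise ValueError("source SDs must be >= 0")
        if self.offset_sd < 0 or self.residual_sd < 0:
            raise ValueError("offset_sd and residual_sd must be >= 0")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")


def generate_mixture_observations(spec: MixtureSpec, seed: int) -> np.ndarray:
    """Forward-simulate mixture delta15N values (permil) under ``spec``."""
    rng = np.random.default_rng(seed)
    f = np.asarray(spec.true_fractions, dtype=float)
    mu = np.asarray(spec.source_means, dtype=float)
    sd = np.asarray(spec.source_sds, dtype=float)
    d = rng.normal(mu, sd, size=(spec.n_obs, f.size))
    offset = rng.normal(spec.offset_mean, spec.offset_sd, size=spec.n_obs)
    eps = rng.normal(0.0, spec.residual_sd, size=spec.n_obs)
    return d @ f + offset + eps


#: ambient-record generator defaults; concentrations are in a single
#: arbitrary consistent unit (the reconstruction is ratio-invariant), f_NO2
#: is the global mean fraction of NO2 in NOx, and the isotope means/SDs are
#: representative ambient values.
DEFAULT_CONCENTRATION_PARAMS: Mapping[str, tuple[float, float]] = {
    "c_no2": (10.0, 5.0),
    "c_hno3": (1.0, 0.5),
    "c_pno3": (2.0, 1.0),
    "f_no2": (0.64, 0.10),
}
DEFAULT_ISOTOPE_PARAMS: Mapping[str, tuple[float, float]] = {
    "d15n_nox": (-7.7, 2.9),
    "d15n_hno3": (0.0, 3.0),
    "d15n_pno3": (3.0, 3.0),
}

AMBIENT_COLUMNS = (
    "c_no2", "c_hno3", "c_pno3", "f_no2",
    "d15n_nox", "d15n_hno3", "d15n_pno3",
)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-match a log-normal to the requested natural-scale mean/sd
    if mean <= 0:
        raise ValueError("concentration mean must be > 0")
    if sd == 0:
        return math.log(mean), 0.0
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def generate_ambient_records(
    n: int,
    concentration_params: Mapping[str, tuple[float, float]] | None = None,
    isotope_params: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate co-located ambient chemistry records.

    Concentrations are log-normal (strictly positive), f_NO2 is a normal
    truncated to (0, 1], and isotope values are normal.  Parameters are
    ``(mean, sd)`` pairs on the natural scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    conc = dict(DEFAULT_CONCENTRATION_PARAMS)
    conc.update(concentration_params or {})
    iso = dict(DEFAULT_ISOTOPE_PARAMS)
    iso.update(isotope_params or {})
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in ("c_no2", "c_hno3", "c_pno3"):
        mean, sd = conc[name]
        mu, sigma = _lognormal_params(mean, sd)
        out[name] = rng.lognormal(mu, sigma, size=n) if sigma > 0 else np.full(n, mean)
    f_mean, f_sd = conc["f_no2"]
    if not 0 < f_mean <= 1:
        raise ValueError("f_no2 mean must lie in (0, 1]")
    if f_sd > 0:
        lo = (1e-9 - f_mean) / f_sd
        hi = (1.0 - f_mean) / f_sd
        dist = stats.truncnorm(lo, hi, loc=f_mean, scale=f_sd)
        out["f_no2"] = dist.rvs(size=n, random_state=rng)
    else:
        out["f_no2"] = np.full(n, f_mean)
    for name in ("d15n_nox", "d15n_hno3", "d15n_pno3"):
        mean, sd = iso[name]
        out[name] = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean)
    return pd.DataFrame(out, columns=list(AMBIENT_COLUMNS))
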