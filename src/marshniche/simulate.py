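"""Synthetic quadrat surveys with the statistical structure the analysis assumes.

The generator emulates the sampling design of the field survey -- three UK
regions, three marsh age classes (MR, AR, NAT), at least 30 quadrats per
site along elevation-spanning transects -- and the environmental structure
the analysis targets: managed realignments sit lower in the tidal frame,
and redox potential increases roughly linearly with relative tidal height
(RTH) with an age-dependent slope plus noise.

Species occurrence is drawn from known parametric suitability surfaces: the
latent (probit-scale) suitability is a downward quadratic bell in (RTH,
redox) with additive region offsets and age-class shifts, and presence is
Bernoulli(Phi(latent)).  The surface is deliberately parametric rather than
a Gaussian-process draw so that recovery of optima, breadths and age shifts
can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from marshniche._seeding import stage_rng
from marshniche.survey import (
    AGE_CLASSES,
    REGIONS,
    SPECIES_CODES,
    SurveyDataset,
    SurveyValidationError,
    TidalDatum,
)


@dataclass(frozen=True)
class SpeciesSimProfile:
    """Ground-truth suitability surface for one simulated species.

    The latent suitability at a quadrat is::

        latent = max_latent - ((rth - rth_optimum) / rth_breadth)**2
                            - ((redox - redox_optimum) / redox_breadth)**2
                 + region_offsets[region] + age_shifts[age_class]

    and presence is Bernoulli(Phi(latent)).  ``age_shifts['NAT']`` is 0 by
    convention so shifts are read as contrasts against natural marshes.
    """

    species: str
    rth_optimum: float
    rth_breadth: float
    redox_optimum: float
    redox_breadth: float
    max_latent: float
    region_offsets: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in REGIONS}
    )
    age_shifts: Mapping[str, float] = field(
        default_factory=lambda: {a: 0.0 for a in AGE_CLASSES}
    )

    def __post_init__(self) -> None:
        if self.rth_breadth <= 0 or self.redox_breadth <= 0:
            raise ValueError(f"{self.species}: breadths must be strictly positive")
        missing = set(AGE_CLASSES) - set(self.age_shifts)
        if missing:
            raise ValueError(f"{self.species}: age_shifts missing {sorted(missing)}")

    def latent(self, rth, redox, region, age_class):
        """Latent suitability at given environments (vectorized over rth/redox)."""
        rth = np.asarray(rth, dtype=float)
        redox = np.asarray(redox, dtype=float)
        base = (
            self.max_latent
            - ((rth - self.rth_optimum) / self.rth_breadth) ** 2
            - ((redox - self.redox_optimum) / self.redox_breadth) ** 2
        )
        return base + self.region_offsets.get(region, 0.0) + self.age_shifts[age_class]


@dataclass(frozen=True)
class SiteSpec:
    site_id: str
    region: str
    age_class: str
    n_quadrats: int


@dataclass
class SimulationConfig:
    """Survey design and environmental model for the generator.

    Attributes
    ----------
    sites : list of SiteSpec
        One entry per simulated site; each site needs >= 30 quadrats,
        matching the field design.
    rth_ranges : dict
        ``age_class -> (low, high)`` uniform sampling range of RTH.
    redox_intercept : float
        Redox (mV SHE) at RTH = 0 before noise.
    redox_slopes : dict
        ``age_class -> slope`` in mV per RTH unit.
    redox_noise_sd : float
        Gaussian noise sd on redox, mV.
    species_profiles : list of SpeciesSimProfile
    seed : int
        Master seed; stages split it into named streams.
    """

    sites: list[SiteSpec]
    rth_ranges: dict[str, tuple[float, float]]
    redox_intercept: float
    redox_slopes: dict[str, float]
    redox_noise_sd: float
    species_profiles: list[SpeciesSimProfile]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("empty site plan")
        for s in self.sites:
            if s.n_quadrats < 30:
                raise ValueError(
                    f"site {s.site_id}: {s.n_quadrats} quadrats; the survey design "
                    "requires at least 30 per site"
                )
            if s.region not in REGIONS or s.age_class not in AGE_CLASSES:
                raise ValueError(f"site {s.site_id}: unknown region or age_class")
        if self.redox_noise_sd < 0:
            raise ValueError("redox_noise_sd must be >= 0")
        for a in {s.age_class for s in self.sites}:
            if a not in self.rth_ranges or a not in self.redox_slopes:
                raise ValueError(f"age_class {a}: missing rth_range or redox_slope")

    @property
    def species_codes(self) -> list[str]:
        return [p.species for p in self.species_profiles]


# Default ground-truth species profiles.  Optima run from pioneer species low
# in the tidal frame (broad niches) to upper-marsh species near and above MHWS
# (narrow niches), with redox preferences separating species at similar
# heights.  MR/AR shifts depress the mid-marsh perennials on restored marshes
# and favour the annual pioneers on young realignments.
_PROFILE_TABLE = [
    # species  rth_opt breadth redox_opt breadth max_latent  MR     AR
    ("Spar",   0.15,   0.55,    50.0,    260.0,  1.2,       -0.8,  +0.4),
    ("Sali",   0.00,   0.65,     0.0,    300.0,  1.5,       +0.6,   0.0),
    ("Suae",   0.15,   0.50,   250.0,    280.0,  1.2,       +0.5,   0.0),
    ("Aste",   0.45,   0.45,   150.0,    260.0,  1.0,       +0.4,  +0.1),
    ("Pucc",   0.65,   0.40,   150.0,    240.0,  1.3,       -0.7,  +0.3),
    ("Atri",   0.80,   0.35,   330.0,    220.0,  1.2,       -0.9,  +0.5),
    ("Limo",   0.70,   0.30,   120.0,    220.0,  1.0,       -1.2,  -0.6),
    ("Trig",   0.70,   0.28,   100.0,    220.0,  0.8,       -1.5,  -0.8),
    ("Plan",   0.75,   0.30,   120.0,    220.0,  0.8,       -1.4,  -0.7),
    ("Elyt",   1.05,   0.22,   330.0,    200.0,  1.2,       -0.5,  +0.1),
]

_DEFAULT_REGION_OFFSETS = {"Essex": 0.0, "Norfolk": 0.1, "Humber": -0.1}


def default_species_profiles() -> list[SpeciesSimProfile]:
    return [
        SpeciesSimProfile(
            species=code,
            rth_optimum=ro,
            rth_breadth=rb,
            redox_optimum=xo,
            redox_breadth=xb,
            max_latent=ml,
            region_offsets=dict(_DEFAULT_REGION_OFFSETS),
            age_shifts={"NAT": 0.0, "MR": mr, "AR": ar},
        )
        for code, ro, rb, xo, xb, ml, mr, ar in _PROFILE_TABLE
    ]


def _default_sites() -> list[SiteSpec]:
    # 22 sites: 7 MR, 4 AR, 11 NAT, spread over the three regions, with
    # per-site quadrat counts chosen so class totals match the survey
    # (290 MR, 249 AR, 506 NAT).
    plan = []
    mr_regions = ["Essex", "Essex", "Essex", "Norfolk", "Norfolk", "Humber", "Humber"]
    mr_counts = [42, 42, 42, 41, 41, 41, 41]
    ar_regions = ["Essex", "Essex", "Norfolk", "Humber"]
    ar_counts = [63, 62, 62, 62]
    nat_regions = ["Essex"] * 4 + ["Norfolk"] * 4 + ["Humber"] * 3
    nat_counts = [46] * 11
    for i, (r, n) in enumerate(zip(mr_regions, mr_counts), 1):
        plan.append(SiteSpec(f"MR{i:02d}", r, "MR", n))
    for i, (r, n) in enumerate(zip(ar_regions, ar_counts), 1):
        plan.append(SiteSpec(f"AR{i:02d}", r, "AR", n))
    for i, (r, n) in enumerate(zip(nat_regions, nat_counts), 1):
        plan.append(SiteSpec(f"NAT{i:02d}", r, "NAT", n))
    return plan


def default_config(seed: int = 0) -> SimulationConfig:
    """The generator's standard study conditions.

    22 sites (7 MR, 4 AR, 11 NAT) across Essex, Norfolk and the Humber with
    class totals of 290/249/506 quadrats; RTH sampled Uniform(-0.3, 1.4) on
    NAT and AR transects and Uniform(-0.6, 1.1) on MR (realignments sit
    lower in the tidal frame); redox 238 mV per RTH unit on natural marshes,
    steeper (318) in MRs and flatter (178) in ARs, with 80 mV noise.
    """
    return SimulationConfig(
        sites=_default_sites(),
        rth_ranges={"NAT": (-0.3, 1.4), "AR": (-0.3, 1.4), "MR": (-0.6, 1.1)},
        redox_intercept=-60.0,
        redox_slopes={"NAT": 238.0, "MR": 318.0, "AR": 178.0},
        redox_noise_sd=80.0,
        species_profiles=default_species_profiles(),
        seed=seed,
    )


def generate_environment(config: SimulationConfig, seed: int | None = None) -> SurveyDataset:
    """Generate the environmental skeleton of a survey (presences all zero).

    Per site, RTH is drawn uniformly from the age class's range and sorted
    to mimic a transect running up the shore; elevation is back-computed
    from a site tidal datum; redox is intercept + slope[age] * RTH plus
    Gaussian noise.  Deterministic given the seed.
    """
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "environment")
    rows = []
    datums = {}
    for site in config.sites:
        mhwn = rng.uniform(1.8, 2.4)
        span = rng.uniform(0.8, 1.2)
        datums[site.site_id] = TidalDatum(site.site_id, mhwn, mhwn + span)
        lo, hi = config.rth_ranges[site.age_class]
        rth = np.sort(rng.uniform(lo, hi, size=site.n_quadrats))
        redox = (
            config.redox_intercept
            + config.redox_slopes[site.age_class] * rth
            + rng.normal(0.0, config.redox_noise_sd, size=site.n_quadrats)
        )
        for j in range(site.n_quadrats):
            rows.append(
                {
                    "quadrat_id": f"{site.site_id}-Q{j + 1:03d}",
                    "site_id": site.site_id,
                    "region": site.region,
                    "age_class": site.age_class,
                    "elevation": mhwn + rth[j] * span,
                    "rth": rth[j],
                    "redox": redox[j],
                }
            )
    df = pd.DataFrame(rows)
    for sp in config.species_codes:
        df[sp] = 0
    return SurveyDataset(
        quadrats=df, datums=datums, species_codes=list(config.species_codes)
    )


def generate_occurrence(
    skeleton: SurveyDataset,
    profiles: Sequence[SpeciesSimProfile],
    seed: int = 0,
) -> SurveyDataset:
    """Fill species presences from the latent suitability surfaces.

    Presence is Bernoulli(Phi(latent)) independently per quadrat and
    species; deterministic given the seed.
    """
    unknown = [p.species for p in profiles if p.species not in skeleton.species_codes]
    if unknown:
        raise SurveyValidationError(f"profile(s) for unknown species: {unknown}")
    rng = stage_rng(seed, "occurrence")
    df = skeleton.quadrats.copy()
    rth = df["rth"].to_numpy()
    redox = df["redox"].to_numpy()
    for prof in profiles:
        p = np.empty(len(df))
        for (region, age), idx in df.groupby(["region", "age_class"], sort=True).groups.items():
            loc = df.index.get_indexer(idx)
            p[loc] = norm.cdf(prof.latent(rth[loc], redox[loc], region, age))
        df[prof.species] = (rng.uniform(size=len(df)) < p).astype(int)
    return SurveyDataset(
        quadrats=df, datums=dict(skeleton.datums), species_codes=list(skeleton.species_codes)
    )


def generate_survey(config: SimulationConfig, seed: int | None = None) -> SurveyDataset:
    """Environment plus occurrence in one call (the full synthetic survey)."""
    if seed is None:
        seed = config.seed
    skeleton = generate_environment(config, seed=seed)
    return generate_occurrence(skeleton, config.species_profiles, seed=seed)
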