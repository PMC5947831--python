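"""Shared fixtures: synthetic surveys and hand-built toy datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import marshniche as mn
from marshniche.simulate import SimulationConfig, SiteSpec, SpeciesSimProfile
from marshniche.survey import SurveyDataset, TidalDatum

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_dataset(
    rth,
    redox=None,
    age_class=None,
    region=None,
    presence=None,
    species_codes=("SpA",),
    site_per_class: bool = True,
) -> SurveyDataset:
    """Build a small validated SurveyDataset directly from arrays.

    Each quadrat's elevation equals its RTH (datums are MHWN=0, MHWS=1).
    ``presence`` maps species code -> 0/1 array; omitted species are absent.
    """
    rth = np.asarray(rth, dtype=float)
    n = len(rth)
    redox = np.zeros(n) if redox is None else np.asarray(redox, dtype=float)
    age_class = ["NAT"] * n if age_class is None else list(age_class)
    region = ["Essex"] * n if region is None else list(region)
    presence = presence or {}
    site_of = (lambda a: f"S-{a}") if site_per_class else (lambda a: "S0")
    df = pd.DataFrame(
        {
            "quadrat_id": [f"Q{i}" for i in range(n)],
            "site_id": [site_of(a) for a in age_class],
            "region": region,
            "age_class": age_class,
            "elevation": rth,
            "rth": rth,
            "redox": redox,
        }
    )
    for sp in species_codes:
        df[sp] = np.asarray(presence.get(sp, np.zeros(n, dtype=int)), dtype=int)
    datums = {s: TidalDatum(s, 0.0, 1.0) for s in df["site_id"].unique()}
    return SurveyDataset(quadrats=df, datums=datums, species_codes=list(species_codes))


def small_sim_config(seed: int = 0, quadrats: int = 100, profiles=None) -> SimulationConfig:
    """One site per region x age class: ~`quadrats` per site (>= 30)."""
    sites = [
        SiteSpec(f"{a}-{r[:2]}", r, a, quadrats)
        for a in ("MR", "AR", "NAT")
        for r in ("Essex", "Norfolk", "Humber")
    ]
    base = mn.default_config(seed=seed)
    return SimulationConfig(
        sites=sites,
        rth_ranges=base.rth_ranges,
        redox_intercept=base.redox_intercept,
        redox_slopes=base.redox_slopes,
        redox_noise_sd=base.redox_noise_sd,
        species_profiles=profiles if profiles is not None else base.species_profiles,
        seed=seed,
    )


def flat_profile(
    species="SpA", max_latent=0.0, age_shifts=None, region_offsets=None,
    rth_breadth=1e6, redox_breadth=1e6, rth_optimum=0.5, redox_optimum=100.0,
) -> SpeciesSimProfile:
    """Profile whose latent is (near-)constant in the environment."""
    return SpeciesSimProfile(
        species=species,
        rth_optimum=rth_optimum, rth_breadth=rth_breadth,
        redox_optimum=redox_optimum, redox_breadth=redox_breadth,
        max_latent=max_latent,
        region_offsets=region_offsets or {r: 0.0 for r in ("Essex", "Norfolk", "Humber")},
        age_shifts=age_shifts or {"MR": 0.0, "AR": 0.0, "NAT": 0.0},
    )


@pytest.fixture(scope="session")
def default_survey() -> SurveyDataset:
    """The generator's standard study conditions (22 sites, 1045 quadrats)."""
    return mn.generate_survey(mn.default_config(seed=11))


@pytest.fixture(scope="session")
def small_survey() -> SurveyDataset:
    """Reduced synthetic survey: one site per region x class, 90 quadrats each."""
    return mn.generate_survey(small_sim_config(seed=7, quadrats=90))
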