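"""Quadrat-survey domain model and I/O.

A survey is a flat table of 0.5 m x 0.5 m quadrats, each carrying its site,
region, marsh age class (MR = managed realignment, AR = accidental
realignment, NAT = natural reference marsh), elevation (m ODN), sediment
redox potential (mV vs. the standard hydrogen electrode) and the
presence/absence of the study species.  Elevation is standardized to
relative tidal height (RTH) using per-site tidal datums, so that RTH = 0 at
mean high water neap (MHWN) and 1 at mean high water spring (MHWS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Closed factor sets for the survey design.
REGIONS: tuple[str, ...] = ("Essex", "Norfolk", "Humber")
AGE_CLASSES: tuple[str, ...] = ("MR", "AR", "NAT")

#: Four-letter codes of the 10 study species, ordered from pioneer to
#: upper-marsh: Spartina anglica, Salicornia europaea agg., Suaeda maritima,
#: Aster tripolium, Puccinellia maritima, Atriplex portulacoides, Limonium
#: vulgare, Triglochin maritima, Plantago maritima, Elytrigia atherica.
SPECIES_CODES: tuple[str, ...] = (
    "Spar", "Sali", "Suae", "Aste", "Pucc", "Atri", "Limo", "Trig", "Plan", "Elyt",
)

#: Offset converting an Ag/AgCl-referenced redox reading to the standard
#: hydrogen electrode scale (mV).
SHE_OFFSET_MV: float = 204.0

#: Core (non-species) columns of the survey table, in file order.
CORE_COLUMNS: tuple[str, ...] = (
    "quadrat_id", "site_id", "region", "age_class", "elevation", "rth", "redox",
)


class SurveyValidationError(ValueError):
    """Raised when a survey table or tidal datum violates its contract."""


@dataclass(frozen=True)
class TidalDatum:
    """Per-site tidal levels used to standardize elevation.

    Parameters
    ----------
    site_id : str
        Site identifier.
    mhwn, mhws : float
        Mean high water neap and spring levels in m ODN.  ``mhws`` must be
        strictly greater than ``mhwn`` so the RTH denominator is positive.
    """

    site_id: str
    mhwn: float
    mhws: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mhwn) and np.isfinite(self.mhws)):
            raise SurveyValidationError(
                f"datum for site {self.site_id!r}: non-finite tidal level"
            )
        if not self.mhws > self.mhwn:
            raise SurveyValidationError(
                f"datum for site {self.site_id!r}: MHWS ({self.mhws}) must "
                f"exceed MHWN ({self.mhwn})"
            )


def compute_rth(elevation, datum: TidalDatum):
    """Relative tidal height of an elevation under a site's tidal datum.

    RTH = (elevation - MHWN) / (MHWS - MHWN): 0 at MHWN, 1 at MHWS.  Values
    outside [0, 1] are legal -- species occur both below MHWN and above MHWS
    -- and are never clipped.

    Parameters
    ----------
    elevation : float or array-like
        Elevation(s) in m ODN.
    datum : TidalDatum
        The site's tidal levels (validated at construction).
    """
    elevation = np.asarray(elevation, dtype=float)
    if not np.all(np.isfinite(elevation)):
        raise SurveyValidationError("non-finite elevation")
    out = (elevation - datum.mhwn) / (datum.mhws - datum.mhwn)
    return float(out) if out.ndim == 0 else out


def standardize_redox(raw_reading):
    """Convert an Ag/AgCl-referenced redox reading to the SHE scale (+204 mV)."""
    raw = np.asarray(raw_reading, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise SurveyValidationError("non-finite redox reading")
    out = raw + SHE_OFFSET_MV
    return float(out) if out.ndim == 0 else out


@dataclass
class SurveyDataset:
    """A validated quadrat survey.

    Attributes
    ----------
    quadrats : pandas.DataFrame
        One row per quadrat with columns ``quadrat_id, site_id, region,
        age_class, elevation, rth, redox`` followed by one 0/1 presence
        column per species code.  Row order is the file/generation order.
    datums : dict
        ``site_id -> TidalDatum`` for every site appearing in ``quadrats``.
    species_codes : list of str
        Ordered species codes (the 10 study species unless overridden).
    excluded : pandas.DataFrame
        Rows dropped at load time for missing elevation or redox; kept for
        the load log, never used in model fitting.
    """

    quadrats: pd.DataFrame
    datums: dict[str, TidalDatum]
    species_codes: list[str] = field(default_factory=lambda: list(SPECIES_CODES))
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.quadrats
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise SurveyValidationError(f"missing required columns: {missing}")
        for sp in self.species_codes:
            if sp not in df.columns:
                raise SurveyValidationError(f"missing presence column {sp!r}")
        if df["quadrat_id"].duplicated().any():
            dup = df.loc[df["quadrat_id"].duplicated(), "quadrat_id"].iloc[0]
            raise SurveyValidationError(f"duplicate quadrat_id {dup!r}")
        bad_region = set(df["region"]) - set(REGIONS)
        if bad_region:
            raise SurveyValidationError(f"unknown region label(s): {sorted(bad_region)}")
        bad_age = set(df["age_class"]) - set(AGE_CLASSES)
        if bad_age:
            raise SurveyValidationError(f"unknown age_class label(s): {sorted(bad_age)}")
        sites_without = set(df["site_id"]) - set(self.datums)
        if sites_without:
            raise SurveyValidationError(f"site(s) without tidal datum: {sorted(sites_without)}")
        pres = df[list(self.species_codes)].to_numpy()
        if not np.isin(pres, (0, 1)).all():
            bad = np.argwhere(~np.isin(pres, (0, 1)))[0]
            raise SurveyValidationError(
                f"non-binary presence value in column {self.species_codes[bad[1]]!r}, "
                f"row {df.index[bad[0]]}"
            )
        # RTH must agree with elevation under the site's datum.
        for site, grp in df.groupby("site_id", sort=False):
            expect = compute_rth(grp["elevation"].to_numpy(), self.datums[site])
            if not np.allclose(grp["rth"].to_numpy(), expect, atol=1e-9, rtol=0.0):
                raise SurveyValidationError(
                    f"rth inconsistent with elevation and datum at site {site!r}"
                )

    @property
    def n_quadrats(self) -> int:
        return len(self.quadrats)

    def subset(self, age_class: str | None = None, region: str | None = None) -> "SurveyDataset":
        """Restrict to one age class and/or region, preserving row order."""
        df = self.quadrats
        if age_class is not None:
            if age_class not in AGE_CLASSES:
                raise SurveyValidationError(f"unknown age_class {age_class!r}")
            df = df[df["age_class"] == age_class]
        if region is not None:
            if region not in REGIONS:
                raise SurveyValidationError(f"unknown region {region!r}")
            df = df[df["region"] == region]
        if df.empty:
            raise SurveyValidationError("empty subset")
        keep = {s for s in df["site_id"]}
        return SurveyDataset(
            quadrats=df.reset_index(drop=True),
            datums={s: d for s, d in self.datums.items() if s in keep},
            species_codes=list(self.species_codes),
        )

    def counts(self) -> pd.DataFrame:
        """Quadrat counts per region x age class (validated-dataset summary)."""
        return (
            self.quadrats.groupby(["region", "age_class"], sort=True)
            .size()
            .rename("n_quadrats")
            .reset_index()
        )

    def presence(self, species: str) -> np.ndarray:
        if species not in self.species_codes:
            raise SurveyValidationError(f"unknown species code {species!r}")
        return self.quadrats[species].to_numpy(dtype=int)


def _read_datums(source) -> dict[str, TidalDatum]:
    """Accept a datum CSV path, a DataFrame, an iterable of TidalDatum or a dict."""
    if isinstance(source, Mapping):
        return dict(source)
    if isinstance(source, (str, Path)):
        source = pd.read_csv(source)
    if isinstance(source, pd.DataFrame):
        for col in ("site_id", "mhwn", "mhws"):
            if col not in source.columns:
                raise SurveyValidationError(f"datum table missing column {col!r}")
        return {
            str(r.site_id): TidalDatum(str(r.site_id), float(r.mhwn), float(r.mhws))
            for r in source.itertuples()
        }
    return {d.site_id: d for d in source}


def load_survey_table(
    path,
    datums,
    redox_is_raw: bool = False,
    species_codes: Sequence[str] = SPECIES_CODES,
) -> SurveyDataset:
    """Read a quadrat CSV and return a validated :class:`SurveyDataset`.

    The file is comma-separated UTF-8, one row per quadrat, with species
    presence as 0/1 columns named by species code.  RTH is recomputed from
    elevation and the site datum (an ``rth`` column, if present, is checked
    rather than trusted).  When ``redox_is_raw`` the redox column is on the
    Ag/AgCl scale and is standardized to SHE on load.  Rows lacking
    elevation or redox are excluded from the dataset (they cannot enter a
    model fit) and reported on the load log and in ``dataset.excluded``.
    """
    df = pd.read_csv(path)
    datums = _read_datums(datums)
    required = ["quadrat_id", "site_id", "region", "age_class", "elevation", "redox"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{path}: missing required column(s) {missing}")
    missing_sp = [s for s in species_codes if s not in df.columns]
    if missing_sp:
        raise SurveyValidationError(f"{path}: missing species column(s) {missing_sp}")

    incomplete = df["elevation"].isna() | df["redox"].isna()
    excluded = df[incomplete].copy()
    if len(excluded):
        logger.warning(
            "%s: excluded %d row(s) with missing elevation/redox (quadrat_ids %s)",
            path, len(excluded), list(excluded["quadrat_id"]),
        )
    df = df[~incomplete].copy()

    unknown_sites = set(df["site_id"].astype(str)) - set(datums)
    if unknown_sites:
        raise SurveyValidationError(f"{path}: site(s) without tidal datum: {sorted(unknown_sites)}")

    if redox_is_raw:
        df["redox"] = standardize_redox(df["redox"].to_numpy())
    df["site_id"] = df["site_id"].astype(str)
    df["quadrat_id"] = df["quadrat_id"].astype(str)
    rth = np.empty(len(df))
    for site, grp in df.groupby("site_id", sort=False):
        rth[df.index.get_indexer(grp.index)] = compute_rth(
            grp["elevation"].to_numpy(), datums[site]
        )
    if "rth" in df.columns and df["rth"].notna().all():
        if not np.allclose(df["rth"].to_numpy(dtype=float), rth, atol=1e-6):
            raise SurveyValidationError(f"{path}: rth column inconsistent with elevation and datums")
    df["rth"] = rth

    cols = list(CORE_COLUMNS) + [s for s in species_codes]
    extra = [c for c in df.columns if c not in cols]
    df = df[cols + extra].reset_index(drop=True)
    ds = SurveyDataset(
        quadrats=df,
        datums={s: datums[s] for s in df["site_id"].unique()},
        species_codes=list(species_codes),
        excluded=excluded,
    )
    n = ds.quadrats["age_class"].value_counts()
    logger.info(
        "%s: loaded %d quadrats from %d sites (MR %d, AR %d, NAT %d)",
        path, ds.n_quadrats, len(ds.datums),
        n.get("MR", 0), n.get("AR", 0), n.get("NAT", 0),
    )
    return ds


def write_survey_table(dataset: SurveyDataset, path, datum_path=None) -> None:
    """Write the survey (and optionally the datum table) back to CSV.

    The written file round-trips through :func:`load_survey_table` to an
    identical dataset (redox is stored SHE-standardized).
    """
    cols = list(CORE_COLUMNS) + list(dataset.species_codes)
    dataset.quadrats[cols].to_csv(path, index=False)
    if datum_path is not None:
        pd.DataFrame(
            [(d.site_id, d.mhwn, d.mhws) for d in dataset.datums.values()],
            columns=["site_id", "mhwn", "mhws"],
        ).to_csv(datum_path, index=False)


@dataclass(frozen=True)
class SpeciesOccupancySummary:
    """Median and range of RTH and redox over a species' occupied quadrats."""

    species: str
    n_occupied: int
    median_rth: float = float("nan")
    rth_range: float = float("nan")
    median_redox: float = float("nan")
    redox_range: float = float("nan")

    @property
    def occupied(self) -> bool:
        return self.n_occupied > 0


def occupancy_summaries(
    dataset: SurveyDataset, age_class_filter: str | None = None
) -> list[SpeciesOccupancySummary]:
    """Per-species medians and ranges of RTH and redox over occupied quadrats.

    A species absent from every considered quadrat yields a flagged summary
    (``n_occupied == 0`` and NaN statistics) rather than an error.
    """
    ds = dataset if age_class_filter is None else dataset.subset(age_class=age_class_filter)
    df = ds.quadrats
    out = []
    for sp in ds.species_codes:
        occ = df[df[sp] == 1]
        if occ.empty:
            out.append(SpeciesOccupancySummary(species=sp, n_occupied=0))
            continue
        rth = occ["rth"].to_numpy()
        redox = occ["redox"].to_numpy()
        out.append(
            SpeciesOccupancySummary(
                species=sp,
                n_occupied=len(occ),
                median_rth=float(np.median(rth)),
                rth_range=float(rth.max() - rth.min()),
                median_redox=float(np.median(redox)),
                redox_range=float(redox.max() - redox.min()),
            )
        )
    return out


def range_median_correlation(
    summaries: Iterable[SpeciesOccupancySummary], variable: str = "rth"
):
    """Pearson correlation of per-species niche range against niche median.

    On natural marshes, species occupying low tidal positions tend to occupy
    a broader band of conditions, so the correlation is expected negative.
    Returns ``(r, df, p)`` with ``df = n_species - 2`` and a two-sided p from
    the t transform.  Species with no occupied quadrats are dropped.
    """
    if variable not in ("rth", "redox"):
        raise ValueError("variable must be 'rth' or 'redox'")
    med_attr = f"median_{variable}"
    rng_attr = f"{variable}_range"
    pts = [(getattr(s, med_attr), getattr(s, rng_attr)) for s in summaries if s.occupied]
    if len(pts) < 3:
        raise ValueError("need at least 3 species with occupied quadrats")
    med = np.array([p[0] for p in pts])
    rng = np.array([p[1] for p in pts])
    if np.ptp(med) == 0 or np.ptp(rng) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(med, rng)
    return float(res.statistic), len(pts) - 2, float(res.pvalue)
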