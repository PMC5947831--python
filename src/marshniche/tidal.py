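"""Species position in the tidal frame: observed vs. model-expected.

Compares where species actually occur (mean/median RTH of occupied
quadrats per marsh age class) with where the natural-marsh niche models
expect them if they occupied the most suitable quadrats, and tests
age-class differences with Kruskal-Wallis and pairwise
Mann-Whitney-Wilcoxon tests under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from marshniche.gp import GaussianProcessProbitClassifier
from marshniche.survey import AGE_CLASSES, SurveyDataset

logger = logging.getLogger(__name__)

#: Largest number of group-label arrangements enumerated for an exact
#: tie-aware Mann-Whitney p-value; beyond this (or with no ties) scipy's
#: implementations are used.
_ENUMERATION_LIMIT = 200_000

#: Sample size above which the normal approximation (with tie and
#: continuity corrections) replaces exact computation.
_EXACT_LIMIT = 50


def _occupied_rth(dataset: SurveyDataset, species: str) -> dict[str, np.ndarray]:
    df = dataset.quadrats
    occ = df[df[species] == 1]
    return {
        a: occ.loc[occ["age_class"] == a, "rth"].to_numpy()
        for a in AGE_CLASSES
        if (occ["age_class"] == a).any()
    }


def kruskal_wallis_rth(dataset: SurveyDataset, species: str):
    """Kruskal-Wallis test of occupied-quadrat RTH across marsh age classes.

    Returns ``(H, df, p)`` with the standard tie correction and a
    chi-squared p-value on (groups - 1) degrees of freedom.
    """
    groups = _occupied_rth(dataset, species)
    if len(groups) < 2:
        raise ValueError(f"{species}: present in fewer than 2 age classes")
    h, p = stats.kruskal(*groups.values())
    return float(h), len(groups) - 1, float(p)


def _mww_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with ties counting one half."""
    return float(
        np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :])
    )


def exact_mww_p(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group assignments.

    Every way of splitting the pooled values into groups of the observed
    sizes is enumerated; the p-value is the proportion of arrangements
    whose U statistic is at least as far from its null mean as the observed
    one.  Handles ties exactly (mid-count U).  Intended for small groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    centre = n1 * (n - n1) / 2.0
    obs_dev = abs(_mww_u(x, y) - centre)
    count = 0
    total = comb(n, n1)
    idx = np.arange(n)
    for chosen in itertools.combinations(idx, n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(chosen)] = True
        u = _mww_u(pooled[sel], pooled[~sel])
        if abs(u - centre) >= obs_dev - 1e-12:
            count += 1
    return count / total


def mww_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns ``(U, p)``.

    Small groups (both sizes <= 50) are tested exactly -- by scipy's exact
    null distribution when there are no ties, or by full enumeration when
    ties are present and the arrangement count is tractable; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    u = _mww_u(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= _EXACT_LIMIT
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return u, float(res.pvalue)
    if small and comb(len(pooled), len(x)) <= _ENUMERATION_LIMIT:
        return u, exact_mww_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compact_letter_display(
    levels: list[str], nonsignificant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Letters such that two levels share a letter iff not significantly different.

    Maximal cliques of the non-significance graph each receive one letter
    (a greedy clique cover; isolated levels get their own letter).
    """
    g = nx.Graph()
    g.add_nodes_from(levels)
    g.add_edges_from(nonsignificant_pairs)
    cliques = sorted(
        (sorted(c, key=levels.index) for c in nx.find_cliques(g)),
        key=lambda c: [levels.index(v) for v in c],
    )
    letters = {lv: "" for lv in levels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for lv in clique:
            letters[lv] += ch
    return letters


@dataclass
class PairwiseTestTable:
    """Pairwise MWW tests of tidal position between age classes for one species."""

    species: str
    pairs: list[tuple[str, str]]
    u_statistics: list[float]
    raw_p: list[float]
    adjusted_p: list[float]
    letters: dict[str, str]
    alpha: float = 0.05


def pairwise_mww_fdr(
    dataset: SurveyDataset, species: str, alpha: float = 0.05
) -> PairwiseTestTable:
    """All pairwise age-class comparisons of occupied-quadrat RTH.

    Raw two-sided MWW p-values are Benjamini-Hochberg adjusted across the
    (at most 3) pairs, and compact-letter groups are derived from the
    adjusted significance graph at ``alpha``.  Empty pairs are omitted and
    logged.
    """
    groups = _occupied_rth(dataset, species)
    present = [a for a in AGE_CLASSES if a in groups]
    if len(present) < 2:
        raise ValueError(f"{species}: fewer than 2 non-empty age classes")
    for a in AGE_CLASSES:
        if a not in groups:
            logger.info("%s: age class %s has no occupied quadrats; pair(s) omitted", species, a)
    pairs, us, raws = [], [], []
    for a, b in itertools.combinations(present, 2):
        u, p = mww_test(groups[a], groups[b])
        pairs.append((a, b))
        us.append(u)
        raws.append(p)
    adj = benjamini_hochberg(raws)
    nonsig = {pr for pr, p in zip(pairs, adj) if p >= alpha}
    letters = compact_letter_display(present, nonsig)
    return PairwiseTestTable(
        species=species, pairs=pairs, u_statistics=us,
        raw_p=list(map(float, raws)), adjusted_p=list(map(float, adj)),
        letters=letters, alpha=alpha,
    )


@dataclass
class ObservedPosition:
    """Order statistics of occupied-quadrat RTH for one species x age class."""

    mean: float
    median: float
    iqr: tuple[float, float]
    n_occupied: int

    @property
    def defined(self) -> bool:
        return self.n_occupied > 0


def observed_position(dataset: SurveyDataset, species: str, age_class: str) -> ObservedPosition:
    """Mean, median and IQR of RTH over quadrats the species occupies.

    Quantiles use linear interpolation of order statistics (numpy default,
    type-7).  With no occupied quadrats the summary is flagged undefined.
    """
    df = dataset.quadrats
    rth = df.loc[(df["age_class"] == age_class) & (df[species] == 1), "rth"].to_numpy()
    if rth.size == 0:
        return ObservedPosition(float("nan"), float("nan"), (float("nan"), float("nan")), 0)
    q25, q75 = np.percentile(rth, [25, 75])
    return ObservedPosition(
        mean=float(rth.mean()), median=float(np.median(rth)),
        iqr=(float(q25), float(q75)), n_occupied=int(rth.size),
    )


@dataclass
class ExpectedPosition:
    """Model-expected mean RTH if the species occupied the best quadrats."""

    mean: float
    ci: tuple[float, float]
    defined: bool = True


def expected_position(
    natural_fit: GaussianProcessProbitClassifier,
    dataset: SurveyDataset,
    species: str,
    n_occupied: int,
    n_draws: int = 1000,
    seed: int = 0,
) -> ExpectedPosition:
    """Expected mean RTH under the natural-marsh niche model.

    ``dataset`` must be restricted to one age class.  For each posterior
    draw, the class's quadrats are ranked by drawn occurrence probability
    and the top ``n_occupied`` (ties broken by quadrat order, a stable
    documented rule) have their RTH averaged.  The across-draw mean and
    2.5/97.5 percentile interval are returned.  ``n_occupied == 0`` yields
    a flagged, undefined summary.
    """
    classes = dataset.quadrats["age_class"].unique()
    if len(classes) != 1:
        raise ValueError("dataset must be restricted to a single age class")
    n_quadrats = dataset.n_quadrats
    if n_occupied > n_quadrats:
        raise ValueError(f"n_occupied ({n_occupied}) exceeds class size ({n_quadrats})")
    if n_occupied == 0:
        logger.info("%s: no occupied quadrats in %s; expected position undefined",
                    species, classes[0])
        return ExpectedPosition(float("nan"), (float("nan"), float("nan")), defined=False)
    X = dataset.quadrats[
        list(natural_fit.continuous_covariates_) + list(natural_fit.categorical_covariates_)
    ]
    rth = dataset.quadrats["rth"].to_numpy()
    draws = natural_fit.sample_posterior_probabilities(X, n_draws=n_draws, seed=seed).draws
    # stable argsort on the negated draws: ties keep quadrat (row) order
    top = np.argsort(-draws, axis=1, kind="stable")[:, :n_occupied]
    per_draw_mean = rth[top].mean(axis=1)
    lo, hi = np.percentile(per_draw_mean, [2.5, 97.5])
    return ExpectedPosition(float(per_draw_mean.mean()), (float(lo), float(hi)))


@dataclass
class TidalPositionSummary:
    """Observed and model-expected tidal position for one species x age class."""

    species: str
    age_class: str
    observed: ObservedPosition
    expected: ExpectedPosition


def tidal_position_summary(
    dataset: SurveyDataset,
    natural_fit: GaussianProcessProbitClassifier,
    species: str,
    age_class: str,
    n_draws: int = 1000,
    seed: int = 0,
) -> TidalPositionSummary:
    """Observed vs. expected position of one species in one age class."""
    obs = observed_position(dataset, species, age_class)
    sub = dataset.subset(age_class=age_class)
    exp = expected_position(
        natural_fit, sub, species, n_occupied=obs.n_occupied, n_draws=n_draws, seed=seed
    )
    return TidalPositionSummary(
        species=species, age_class=age_class, observed=obs, expected=exp
    )
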