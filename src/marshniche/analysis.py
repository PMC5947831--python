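"""Model-based analysis stages built on the GP occurrence models.

Covers cross-validated discrimination (AUC over repeated random 75/25
splits), transfer of natural-marsh models to restored marshes with full
posterior uncertainty, marsh-age effects evaluated at the latent optimum,
hierarchical partitioning of predictor importance, and gridded niche
surfaces clipped by available environmental conditions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from scipy.stats import gaussian_kde, rankdata

from marshniche._seeding import stage_rng
from marshniche.gp import (
    DegenerateResponseError,
    GaussianProcessProbitClassifier,
    KernelSpec,
)
from marshniche.survey import SurveyDataset

logger = logging.getLogger(__name__)

#: Canonical covariate sets: natural-marsh niche models use environment and
#: region; the age model adds the marsh age class.
NICHE_CONTINUOUS = ("rth", "redox")
NICHE_CATEGORICAL = ("region",)
AGE_CATEGORICAL = ("region", "age_class")


def fit_species_model(
    dataset: SurveyDataset,
    species: str,
    include_age: bool = False,
    kernel: KernelSpec | None = None,
    optimize: bool = False,
    prior_mean_prob: float | None = None,
) -> GaussianProcessProbitClassifier:
    """Fit the occurrence model for one species on a (sub)survey.

    Covariates are redox, RTH and region, plus marsh age class when
    ``include_age``.
    """
    cat = list(AGE_CATEGORICAL if include_age else NICHE_CATEGORICAL)
    est = GaussianProcessProbitClassifier(
        continuous_covariates=list(NICHE_CONTINUOUS),
        categorical_covariates=cat,
        kernel=kernel,
        optimize=optimize,
        prior_mean_prob=prior_mean_prob,
    )
    X = dataset.quadrats[list(NICHE_CONTINUOUS) + cat]
    est.fit(X, dataset.presence(species))
    return est


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve of scores against binary labels.

    Computed as the Mann-Whitney concordance probability via midranks, so
    tied scores count exactly one half.  Both classes must be present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: labels contain a single class")
    n_pos = int((labels == 1).sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # average ranks: ties contribute exactly 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CrossValidationResult:
    """Repeated random-split discrimination performance for one species."""

    species: str
    auc_per_run: np.ndarray
    mean_auc: float
    prevalence: float
    n_redrawn: int = 0
    flagged: bool = False
    note: str = ""


def cross_validate(
    dataset: SurveyDataset,
    species: str,
    n_runs: int = 1000,
    train_fraction: float = 0.75,
    seed: int = 0,
    kernel: KernelSpec | None = None,
    optimize: bool = False,
    max_redraws_per_run: int = 200,
) -> CrossValidationResult:
    """Repeated random 75/25 split cross-validation of the niche model.

    Each run draws a simple random (unstratified) split, refits the model
    on the training part (redox, RTH, region) and scores the held-out part
    with AUC.  A run whose training or test part lacks both classes is
    redrawn and the redraw count logged.  A species too rare for any valid
    split yields a flagged result rather than an abort.
    """
    y = dataset.presence(species)
    n = len(y)
    n_train = int(round(train_fraction * n))
    n_test = n - n_train
    # A valid split needs both classes on both sides.
    n_pos = int(y.sum())
    if n_pos < 2 or (n - n_pos) < 2 or n_train < 2 or n_test < 2:
        logger.warning("%s: too rare for any valid split (%d/%d presences)", species, n_pos, n)
        return CrossValidationResult(
            species, np.array([]), float("nan"), n_pos / n,
            flagged=True, note="too rare for any valid split",
        )
    rng = stage_rng(seed, f"crossval:{species}")
    aucs = np.empty(n_runs)
    n_redrawn = 0
    X = dataset.quadrats[list(NICHE_CONTINUOUS) + list(NICHE_CATEGORICAL)]
    for run in range(n_runs):
        for _ in range(max_redraws_per_run):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if 0 < y[tr].sum() < n_train and 0 < y[te].sum() < n_test:
                break
            n_redrawn += 1
        else:
            return CrossValidationResult(
                species, np.array([]), float("nan"), n_pos / n,
                n_redrawn=n_redrawn, flagged=True,
                note="no valid split found",
            )
        est = GaussianProcessProbitClassifier(
            continuous_covariates=list(NICHE_CONTINUOUS),
            categorical_covariates=list(NICHE_CATEGORICAL),
            kernel=kernel,
            optimize=optimize,
        )
        est.fit(X.iloc[tr], y[tr])
        aucs[run] = compute_auc(est.predict_probability(X.iloc[te]), y[te])
    if n_redrawn:
        logger.info("%s: redrew %d invalid split(s) over %d runs", species, n_redrawn, n_runs)
    return CrossValidationResult(
        species, aucs, float(aucs.mean()), n_pos / n, n_redrawn=n_redrawn
    )


@dataclass
class TransferPrediction:
    """Posterior mean occurrence probability of one species in one age class.

    ``per_draw_mean`` holds, for each posterior draw, the mean predicted
    occurrence probability over the class's quadrats; the summary is its
    median with an equal-tailed 95% interval.
    """

    species: str
    age_class: str
    per_draw_mean: np.ndarray
    median: float
    ci_low: float
    ci_high: float


def predict_transfer(
    natural_fit: GaussianProcessProbitClassifier,
    dataset: SurveyDataset,
    species: str,
    n_draws: int = 1000,
    seed: int = 0,
) -> TransferPrediction:
    """Transfer a natural-marsh model to the quadrats of one age class.

    ``dataset`` must be restricted to a single age class.  Per posterior
    draw, the drawn occurrence probabilities are averaged over the class's
    quadrats; the median and 2.5/97.5 percentiles across draws summarize
    the expected occupancy under available environmental conditions alone.
    """
    classes = dataset.quadrats["age_class"].unique()
    if len(classes) != 1:
        raise ValueError(f"dataset must contain exactly one age class, got {list(classes)}")
    if "age_class" in natural_fit.categorical_covariates_:
        raise ValueError("transfer model must be trained without the age-class covariate")
    X = dataset.quadrats[
        list(natural_fit.continuous_covariates_) + list(natural_fit.categorical_covariates_)
    ]
    draws = natural_fit.sample_posterior_probabilities(X, n_draws=n_draws, seed=seed)
    per_draw = draws.draws.mean(axis=1)
    lo, med, hi = np.percentile(per_draw, [2.5, 50.0, 97.5])
    return TransferPrediction(
        species=species, age_class=str(classes[0]), per_draw_mean=per_draw,
        median=float(med), ci_low=float(lo), ci_high=float(hi),
    )


@dataclass
class AgeClassEffect:
    """Occurrence probability in one age class at the latent optimum.

    The other covariates (redox, RTH, region) are set to the observed
    combination that maximizes the latent predictive mean for that age
    class; ``mode`` is a kernel-density argmax over the posterior draws and
    the interval is the equal-tailed 95% band.
    """

    species: str
    age_class: str
    draws: np.ndarray
    mode: float
    ci_low: float
    ci_high: float
    optimum_covariates: dict = field(default_factory=dict)


def _kde_mode(draws: np.ndarray) -> float:
    """Argmax of a boundary-reflected Gaussian KDE of draws on (0, 1)."""
    if np.ptp(draws) < 1e-12:
        return float(draws[0])
    kde = gaussian_kde(draws)
    grid = np.linspace(0.0, 1.0, 512)
    dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
    return float(grid[np.argmax(dens)])


def age_effect_at_optimum(
    age_fit: GaussianProcessProbitClassifier,
    dataset: SurveyDataset,
    species: str,
    n_draws: int = 1000,
    seed: int = 0,
) -> list[AgeClassEffect]:
    """Marsh-age effect on occurrence at the most favourable conditions.

    The most favourable environment is the observed quadrat covariate
    vector (redox, RTH, region -- the search never leaves the sampled
    environmental space) that maximizes the latent predictive mean over all
    age-class substitutions; every age class is then evaluated at that one
    fixed environment, so the classes are compared under identical
    conditions.  Posterior draws of the occurrence probability there give
    the posterior mode and 95% credible interval.
    """
    if "age_class" not in age_fit.categorical_covariates_:
        raise ValueError("age_effect_at_optimum requires a model fitted with age_class")
    cols = list(age_fit.continuous_covariates_) + list(age_fit.categorical_covariates_)
    base = dataset.quadrats[cols].copy()
    best, best_mu = 0, -np.inf
    for age in ("MR", "AR", "NAT"):
        X = base.copy()
        X["age_class"] = age
        mu, _ = age_fit.latent_predictive(X)
        if mu.max() > best_mu:
            best_mu, best = float(mu.max()), int(np.argmax(mu))
    out = []
    for age in ("MR", "AR", "NAT"):
        x_star = base.iloc[[best]].copy()
        x_star["age_class"] = age
        draws = age_fit.sample_posterior_probabilities(
            x_star, n_draws=n_draws, seed=stage_rng(seed, f"age_effect:{species}:{age}")
        ).draws[:, 0]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        out.append(
            AgeClassEffect(
                species=species, age_class=age, draws=draws,
                mode=_kde_mode(draws), ci_low=float(lo), ci_high=float(hi),
                optimum_covariates=x_star.iloc[0].to_dict(),
            )
        )
    return out


@dataclass
class PartitionResult:
    """Independent goodness-of-fit contribution of each predictor."""

    species: str
    contributions: dict[str, float]
    total_gof: float


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def hierarchical_partition(
    dataset: SurveyDataset,
    species: str,
    predictors: tuple[str, ...] = ("rth", "redox", "region", "age_class"),
    kernel: KernelSpec | None = None,
    optimize: bool = False,
) -> PartitionResult:
    """Chevan-Sutherland hierarchical partitioning of predictor importance.

    The GP occurrence model is fitted for every non-empty predictor subset;
    goodness of fit is the in-sample log-likelihood gain over the
    prevalence-only null (a deviance-based measure, exactly additive in the
    averaging identity).  Each predictor's independent contribution is the
    average, over hierarchy levels, of its mean marginal gain when added to
    subsets not containing it; contributions sum to the full-model gain.
    A subset whose fit fails is imputed the null fit and logged.
    """
    if len(predictors) < 1:
        raise ValueError("need at least one predictor to partition")
    df = dataset.quadrats
    y = dataset.presence(species)
    ll_null = _bernoulli_ll(y, np.full(len(y), y.mean()))
    k = len(predictors)

    gof: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, k + 1):
        for subset in itertools.combinations(predictors, r):
            cont = [p for p in subset if pd.api.types.is_numeric_dtype(df[p])]
            cat = [p for p in subset if p not in cont]
            est = GaussianProcessProbitClassifier(
                continuous_covariates=cont,
                categorical_covariates=cat,
                kernel=kernel if set(subset) == set(predictors) else None,
                optimize=optimize,
            )
            key = frozenset(subset)
            try:
                est.fit(df[list(subset)], y)
                gof[key] = _bernoulli_ll(y, est.predict_probability(df[list(subset)])) - ll_null
            except (np.linalg.LinAlgError, DegenerateResponseError) as exc:
                logger.warning("subset %s fit failed (%s); imputing null GOF", subset, exc)
                gof[key] = 0.0

    contributions = {}
    others = {p: [q for q in predictors if q != p] for p in predictors}
    for p in predictors:
        level_means = []
        for h in range(k):  # size of the subset p is added to
            gains = [
                gof[frozenset(s) | {p}] - gof[frozenset(s)]
                for s in itertools.combinations(others[p], h)
            ]
            level_means.append(np.mean(gains))
        contributions[p] = float(np.mean(level_means))
    total = gof[frozenset(predictors)]
    return PartitionResult(species=species, contributions=contributions, total_gof=total)


@dataclass
class NicheSurface:
    """Occurrence probabilities over an (RTH, redox) grid with availability mask.

    ``probability`` and ``available`` have shape ``(len(redox_grid),
    len(rth_grid))``; unavailable cells (outside the convex hull of the
    observed environment) are the clipped region of the niche plot.
    """

    rth_grid: np.ndarray
    redox_grid: np.ndarray
    probability: np.ndarray
    available: np.ndarray
    region: str

    def argmax_available(self) -> tuple[float, float]:
        """(rth, redox) of the highest-probability available cell."""
        p = np.where(self.available, self.probability, -np.inf)
        i, j = np.unravel_index(np.argmax(p), p.shape)
        return float(self.rth_grid[j]), float(self.redox_grid[i])


def _availability_mask(points: np.ndarray, grid_pts: np.ndarray) -> np.ndarray:
    """True for grid points inside the convex hull of observed points.

    A degenerate (collinear) point cloud has an empty-interior hull: only
    grid points on the segment (to 1e-9) count as available.
    """
    try:
        tri = Delaunay(points)
        inside = tri.find_simplex(grid_pts) >= 0
    except QhullError:
        # Collinear observations: available = on the segment between extremes.
        d = points - points.mean(axis=0)
        # principal direction of the degenerate cloud
        _, _, vt = np.linalg.svd(d, full_matrices=False)
        u = vt[0]
        t = d @ u
        g = grid_pts - points.mean(axis=0)
        along = g @ u
        perp = g - np.outer(along, u)
        inside = (
            (np.linalg.norm(perp, axis=1) <= 1e-9)
            & (along >= t.min() - 1e-9)
            & (along <= t.max() + 1e-9)
        )
    # Observed points themselves are always available.
    if not inside.all():
        from scipy.spatial.distance import cdist as _cdist

        near = _cdist(grid_pts, points).min(axis=1) <= 1e-9
        inside = inside | near
    return inside


def niche_surface(
    natural_fit: GaussianProcessProbitClassifier,
    rth_grid,
    redox_grid,
    region: str,
    clip: bool = True,
) -> NicheSurface:
    """Predicted occurrence probability over an (RTH, redox) grid.

    When ``clip`` is set, grid cells outside the convex hull of the
    observed (RTH, redox) training points are masked as unavailable, so the
    surface shows the niche only where such conditions actually occur.
    """
    rth_grid = np.asarray(rth_grid, dtype=float)
    redox_grid = np.asarray(redox_grid, dtype=float)
    if rth_grid.size == 0 or redox_grid.size == 0:
        raise ValueError("empty grid")
    RR, XX = np.meshgrid(rth_grid, redox_grid)
    X = pd.DataFrame({"rth": RR.ravel(), "redox": XX.ravel()})
    for c in natural_fit.categorical_covariates_:
        X[c] = region if c == "region" else natural_fit.categories_[c][0]
    prob = natural_fit.predict_probability(
        X[list(natural_fit.continuous_covariates_) + list(natural_fit.categorical_covariates_)]
    ).reshape(RR.shape)
    if clip:
        # training points back on the raw covariate scale
        raw = natural_fit.Xc_train_ * natural_fit.X_sd_ + natural_fit.X_mean_
        cols = list(natural_fit.continuous_covariates_)
        pts = raw[:, [cols.index("rth"), cols.index("redox")]]
        mask = _availability_mask(pts, np.column_stack([RR.ravel(), XX.ravel()]))
        available = mask.reshape(RR.shape)
    else:
        available = np.ones_like(prob, dtype=bool)
    return NicheSurface(
        rth_grid=rth_grid, redox_grid=redox_grid,
        probability=prob, available=available, region=region,
    )
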