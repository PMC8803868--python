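"""Supervised models on graph features: t-SNE, random forest, and the GLM.

Three evaluation protocols, each with a paired shuffled baseline:

* 2-D t-SNE embedding of per-map feature vectors with per-condition median
  centroids — exploratory visualisation only;
* random-forest classification of the locomotor condition (150 trees, max
  depth 30, 100 stratified 80:20 train/test trials), with chance estimated
  by permuting the training labels on the same splits;
* prediction of an individual behavioral feature from graph features by a
  Gaussian identity-link GLM with a ±1 group-interaction term
  (Y = β0 + Σβ_j G_j + Σγ_j T G_j + ε), 100 random 75:25 trials, reporting
  held-out Pearson r and MSE against a shuffled-target baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedShuffleSplit, ShuffleSplit


@dataclass
class ClassifierConfig:
    """Random-forest protocol settings."""

    n_trees: int = 150
    max_depth: int = 30
    n_trials: int = 100
    test_fraction: float = 0.2
    seed: int = 0
    shuffle_within_training: bool = True   # False → permute labels globally
    run_shuffled: bool = True              # False skips the baseline arm

    def __post_init__(self) -> None:
        if min(self.n_trees, self.max_depth, self.n_trials) <= 0:
            raise ValueError("classifier settings must be positive")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test fraction must be in (0, 1)")


@dataclass
class GLMSpec:
    """Cross-validation settings for the behavioral GLM."""

    n_trials: int = 100
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or not 0 < self.test_fraction < 1:
            raise ValueError("invalid GLM cross-validation settings")


@dataclass
class EvalResult:
    """Per-trial scores for actual and shuffled fits, plus aggregates."""

    actual: np.ndarray               # per-trial accuracy, or (n_trials, 2) [r, mse]
    shuffled: np.ndarray
    confusion: np.ndarray | None = None    # row-normalised test-set confusion
    classes: list | None = None
    coefficients: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        a, s = np.atleast_2d(self.actual.T).T, np.atleast_2d(self.shuffled.T).T
        return {
            "actual_mean": a.mean(axis=0).tolist(),
            "actual_sd": a.std(axis=0).tolist(),
            "shuffled_mean": s.mean(axis=0).tolist(),
            "shuffled_sd": s.std(axis=0).tolist(),
        }


def _standardize(train: np.ndarray, test: np.ndarray):
    """Per-feature standardisation fit on the training split only.

    Missing entries (NaN) are imputed with the training-split median before
    scaling.
    """
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr = np.where(np.isnan(train), med, train)
    te = np.where(np.isnan(test), med, test)
    mu, sd = tr.mean(axis=0), tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (tr - mu) / sd, (te - mu) / sd


def _impute_scale(train: np.ndarray, test: np.ndarray):
    """Impute + scale (no centering) on the training split.

    Centering a feature that also enters a T·G interaction would add a bare
    group-offset term outside the interaction model class, so the GLM design
    is only rescaled; the intercept absorbs the β-part location.
    """
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr = np.where(np.isnan(train), med, train)
    te = np.where(np.isnan(test), med, test)
    sd = tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tr / sd, te / sd


def tsne_embed(
    features: np.ndarray,
    labels=None,
    seed: int = 0,
    perplexity: float = 10.0,
):
    """2-D t-SNE embedding with per-group median centroids.

    Returns ``(coords, centroids)`` where centroids maps each label to the
    median embedded coordinates with interquartile dispersion.
    """
    x = np.asarray(features, dtype=float)
    med = np.nanmedian(x, axis=0)
    x = np.where(np.isnan(x), np.where(np.isfinite(med), med, 0.0), x)
    if x.shape[0] < 3 * perplexity:
        raise ValueError("too few samples for the requested perplexity")
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(x)
    centroids = {}
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            pts = coords[labels == lab]
            centroids[lab] = {
                "median": np.median(pts, axis=0),
                "iqr": np.subtract(*np.percentile(pts, [75, 25], axis=0)),
            }
    return coords, centroids


def classify_conditions(
    features: np.ndarray, labels, config: ClassifierConfig | None = None
) -> EvalResult:
    """Random-forest condition classification with a shuffled-label baseline.

    Each of the ``n_trials`` trials draws a stratified 80:20 split, fits the
    forest, and scores the held-out samples; the shuffled arm permutes the
    training labels on the identical split.  The confusion matrix aggregates
    held-out predictions over all trials, rows normalised to 1.
    """
    config = config or ClassifierConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members for stratification")
    rng = np.random.default_rng(config.seed)
    splitter = StratifiedShuffleSplit(
        n_splits=config.n_trials, test_size=config.test_fraction,
        random_state=config.seed,
    )
    acc = np.empty(config.n_trials)
    acc_sh = np.empty(config.n_trials)
    k = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k))
    for t, (tr, te) in enumerate(splitter.split(x, y)):
        xtr, xte = _standardize(x[tr], x[te])
        ytr, yte = y[tr], y[te]
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, max_depth=config.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(xtr, ytr)
        pred = forest.predict(xte)
        acc[t] = np.mean(pred == yte)
        for p, a in zip(pred, yte):
            confusion[cls_index[a], cls_index[p]] += 1
        if not config.run_shuffled:
            acc_sh[t] = np.nan
            continue
        if config.shuffle_within_training:
            ysh = ytr[rng.permutation(len(ytr))]
        else:
            perm = rng.permutation(len(y))
            ysh = y[perm][tr]
        forest_sh = RandomForestClassifier(
            n_estimators=config.n_trees, max_depth=config.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(xtr, ysh)
        acc_sh[t] = np.mean(forest_sh.predict(xte) == yte)
    row_sums = confusion.sum(axis=1, keepdims=True)
    confusion = np.divide(
        confusion, row_sums, out=np.zeros_like(confusion), where=row_sums > 0
    )
    return EvalResult(
        actual=acc, shuffled=acc_sh, confusion=confusion, classes=list(classes)
    )


def _glm_design(g: np.ndarray, t: np.ndarray) -> np.ndarray:
    """[1 | G | T·G] design matrix of the interaction GLM."""
    return np.column_stack([np.ones(len(t)), g, t[:, None] * g])


def fit_glm(features: np.ndarray, targets: np.ndarray, group_codes: np.ndarray):
    """Fit the Gaussian identity-link interaction GLM on the full data.

    Returns the statsmodels results object; coefficients are ordered
    [β0, β_1..β_p, γ_1..γ_p].
    """
    g = np.asarray(features, dtype=float)
    t = np.asarray(group_codes, dtype=float)
    y = np.asarray(targets, dtype=float)
    design = _glm_design(g, t)
    return sm.GLM(y, design, family=sm.families.Gaussian()).fit()


def glm_predict(
    features: np.ndarray,
    targets: np.ndarray,
    group_codes: np.ndarray,
    spec: GLMSpec | None = None,
) -> EvalResult:
    """Cross-validated GLM prediction of behavior with shuffled baseline.

    100 random 75:25 splits by default; each trial fits the interaction GLM
    on the training split and scores the held-out targets by Pearson r and
    MSE.  The shuffled arm permutes training targets on the same split.
    ``actual``/``shuffled`` have columns [r, mse]; full-data coefficients
    are attached.
    """
    spec = spec or GLMSpec()
    g = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    t = np.asarray(group_codes, dtype=float)
    if not np.all(np.isin(t, (-1.0, 1.0))):
        raise ValueError("group codes must be ±1")
    if len(y) != g.shape[0]:
        raise ValueError("one target per map is required")
    rng = np.random.default_rng(spec.seed)
    splitter = ShuffleSplit(
        n_splits=spec.n_trials, test_size=spec.test_fraction, random_state=spec.seed
    )
    res = np.empty((spec.n_trials, 2))
    res_sh = np.empty((spec.n_trials, 2))
    warn = False
    for k, (tr, te) in enumerate(splitter.split(g)):
        gtr, gte = _impute_scale(g[tr], g[te])
        dtr = _glm_design(gtr, t[tr])
        dte = _glm_design(gte, t[te])
        if np.linalg.matrix_rank(dtr) < dtr.shape[1]:
            warn = True
        fit = sm.GLM(y[tr], dtr, family=sm.families.Gaussian()).fit()
        pred = fit.predict(dte)
        res[k] = _score(y[te], pred)
        ysh = y[tr][rng.permutation(len(tr))]
        fit_sh = sm.GLM(ysh, dtr, family=sm.families.Gaussian()).fit()
        res_sh[k] = _score(y[te], fit_sh.predict(dte))
    full = fit_glm(g, y, t)
    return EvalResult(
        actual=res,
        shuffled=res_sh,
        coefficients=np.asarray(full.params),
        extras={"rank_deficient": warn},
    )


def _score(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    mse = float(np.mean((actual - predicted) ** 2))
    if np.std(actual) == 0 or np.std(predicted) == 0:
        return (0.0, mse)
    r = float(stats.pearsonr(actual, predicted)[0])
    return (r, mse)


def permutation_ci(
    values: np.ndarray, n_boot: int = 1000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean via index permutation/resampling."""
    rng = np.random.default_rng(seed)
    vals = np.asarray(values, dtype=float)
    boots = np.array([
        vals[rng.integers(0, len(vals), len(vals))].mean() for _ in range(n_boot)
    ])
    return (
        float(np.percentile(boots, 100 * alpha / 2)),
        float(np.percentile(boots, 100 * (1 - alpha / 2))),
    )
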