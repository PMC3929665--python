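"""Iterative presence/pseudo-absence ensemble classifier.

The development-probability model treats known infrastructure locations
as a fixed positive class and, at each iteration, draws a fresh equal-
size set of pseudo-absences with weights from the complement of the
presence kernel-density surface. A Random Forest is fitted to each
presence/background set and its class-1 probabilities are predicted
back to the presence points. Iterations are pooled by averaging
per-point probabilities; iteration stops when a two-sample
Kolmogorov-Smirnov test no longer distinguishes successive pooled
distributions (p >= alpha, default 0.001). Because the forest is a
weak-learner ensemble, pooling iterations this way is equivalent to one
large forest over all background replicates, so the pooled surface is
stable against the arbitrariness of any single background draw.

Variable selection follows the model-improvement-ratio (MIR)
convention: each covariate's permutation importance is scaled by the
maximum importance, candidate subsets are formed by thresholding the
ratio, and the subset minimizing out-of-bag error is retained.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .geostats import background_sample
from .grids import GridRaster, PresenceSet, sample_stack

__all__ = [
    "IterationModel",
    "EnsembleState",
    "ConvergenceConfig",
    "fit_iteration",
    "combine",
    "ks_converged",
    "run_until_convergence",
    "predict_raster",
    "model_selection_mir",
    "auc_roc",
    "sensitivity_weighted_kappa",
    "probability_exceedance",
]


@dataclasses.dataclass
class IterationModel:
    """One presence-vs-background forest and its training snapshot."""

    classifier: RandomForestClassifier
    background_seed: int
    covariate_names: list[str]
    training_probabilities: np.ndarray  # class-1 probability at each presence
    X_train: np.ndarray
    y_train: np.ndarray

    def __post_init__(self) -> None:
        n_presence = int(self.y_train.sum())
        if len(self.training_probabilities) != n_presence:
            raise ValueError("training_probabilities length must equal presence count")


@dataclasses.dataclass
class EnsembleState:
    """Pooled iterations plus the convergence audit trail."""

    iterations: list[IterationModel] = dataclasses.field(default_factory=list)
    pooled_probabilities: np.ndarray | None = None
    convergence_history: list[tuple[int, float, float]] = dataclasses.field(default_factory=list)
    converged: bool = False

    @property
    def covariate_names(self) -> list[str] | None:
        return self.iterations[0].covariate_names if self.iterations else None

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


@dataclasses.dataclass(frozen=True)
class ConvergenceConfig:
    """KS stopping rule: converged when successive pooled distributions
    are not significantly different at ``alpha``."""

    alpha: float = 0.001
    max_iterations: int = 100
    min_iterations: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_iterations < 2:
            raise ValueError("KS comparison needs at least 2 iterations")


def _training_matrix(
    presences: PresenceSet,
    background: PresenceSet,
    covariates: dict[str, GridRaster],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    Xp = sample_stack(covariates, presences.xy)
    Xb = sample_stack(covariates, background.xy)
    X = pd.concat([Xp, Xb], ignore_index=True)
    keep = [c for c in X.columns if X[c].to_numpy().std() > 0]
    dropped = sorted(set(X.columns) - set(keep))
    if dropped:
        warnings.warn(f"zero-variance covariates dropped: {dropped}")
    y = np.concatenate([np.ones(len(presences)), np.zeros(len(background))])
    return X[keep].to_numpy(), y, list(keep)


def fit_iteration(
    presences: PresenceSet,
    covariates: dict[str, GridRaster],
    kde: GridRaster,
    seed: int,
    n_trees: int = 500,
    exclusion_mask: np.ndarray | None = None,
) -> IterationModel:
    """Fit one forest to presences vs. a fresh background draw.

    The background set has exactly as many points as there are
    presences, drawn via the inverse-KDE weights, so every iteration's
    training set is balanced by construction.
    """
    if len(presences) < 20:
        raise ValueError("need at least 20 presence points")
    for name, r in covariates.items():
        kde.require_aligned(r, name)
    background = background_sample(kde, len(presences), seed, exclusion_mask=exclusion_mask)
    X, y, names = _training_matrix(presences, background, covariates)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X, y)
    train_prob = clf.predict_proba(X[: len(presences)])[:, 1]
    return IterationModel(
        classifier=clf,
        background_seed=seed,
        covariate_names=names,
        training_probabilities=train_prob,
        X_train=X,
        y_train=y,
    )


def combine(state: EnsembleState, new: IterationModel) -> EnsembleState:
    """Fold a new iteration into the pool.

    The pooled per-presence probability is the arithmetic mean over
    iterations — with equal tree counts this equals pooling all trees
    into one forest, and it is order-invariant. The covariate list must
    stay fixed across iterations.
    """
    if state.iterations and state.covariate_names != new.covariate_names:
        raise ValueError("covariate list changed between iterations")
    state.iterations.append(new)
    probs = np.stack([it.training_probabilities for it in state.iterations])
    state.pooled_probabilities = probs.mean(axis=0)
    return state


def ks_converged(
    prev_pooled: np.ndarray, new_pooled: np.ndarray, config: ConvergenceConfig
) -> tuple[bool, float, float]:
    """Two-sample KS test between successive pooled distributions.

    Converged when the distributions are NOT significantly different,
    i.e. p >= alpha.
    """
    prev_pooled = np.asarray(prev_pooled, float)
    new_pooled = np.asarray(new_pooled, float)
    if len(prev_pooled) != len(new_pooled) or len(new_pooled) < 20:
        raise ValueError("pooled vectors must be equal length >= 20")
    res = stats.ks_2samp(prev_pooled, new_pooled, method="asymp")
    d, p = float(res.statistic), float(res.pvalue)
    if d == 0.0:
        p = 1.0
    return p >= config.alpha, d, p


def run_until_convergence(
    presences: PresenceSet,
    covariates: dict[str, GridRaster],
    kde: GridRaster,
    config: ConvergenceConfig | None = None,
    seed: int = 0,
    n_trees: int = 500,
    exclusion_mask: np.ndarray | None = None,
) -> EnsembleState:
    """Iterate fit/combine until the pooled distribution stabilizes.

    Per-iteration background seeds are ``seed + iteration index`` so a
    run is reproducible from the single master seed. If the KS rule is
    not met by ``max_iterations`` the state is returned with
    ``converged=False``.
    """
    config = config or ConvergenceConfig()
    state = EnsembleState()
    for i in range(config.max_iterations):
        model = fit_iteration(
            presences, covariates, kde, seed=seed + i, n_trees=n_trees,
            exclusion_mask=exclusion_mask,
        )
        prev = (
            None if state.pooled_probabilities is None else state.pooled_probabilities.copy()
        )
        state = combine(state, model)
        if prev is None:
            state.convergence_history.append((1, np.nan, np.nan))
            continue
        ok, d, p = ks_converged(prev, state.pooled_probabilities, config)
        state.convergence_history.append((i + 1, d, p))
        if ok and state.n_iterations >= config.min_iterations:
            state.converged = True
            break
    return state


def predict_raster(
    state: EnsembleState, covariates: dict[str, GridRaster], force: bool = False
) -> GridRaster:
    """Mean class-1 probability surface over all pooled iterations."""
    if not state.converged and not force:
        raise RuntimeError("ensemble has not converged; pass force=True to predict anyway")
    names = state.covariate_names
    missing = set(names or []) - set(covariates)
    if missing:
        raise ValueError(f"missing covariate rasters: {sorted(missing)}")
    template = covariates[names[0]]
    stack = np.column_stack([covariates[n].data.ravel() for n in names])
    valid = ~np.isnan(stack).any(axis=1)
    acc = np.zeros(valid.sum())
    for it in state.iterations:
        acc += it.classifier.predict_proba(stack[valid])[:, 1]
    out = np.full(stack.shape[0], np.nan)
    out[valid] = acc / state.n_iterations
    return template.like(out.reshape(template.shape))


def model_selection_mir(
    presences: PresenceSet,
    covariates: dict[str, GridRaster],
    kde: GridRaster,
    thresholds: np.ndarray | list[float] | None = None,
    seed: int = 0,
    n_trees: int = 500,
) -> list[str]:
    """Model-improvement-ratio covariate selection.

    A pilot forest supplies permutation importances; MIR_j is
    importance_j / max importance. Each threshold keeps covariates
    with MIR >= t; the retained set is refitted with out-of-bag scoring
    and the subset with the lowest OOB error wins (ties go to the
    smaller subset).
    """
    if len(covariates) < 2:
        raise ValueError("need at least 2 candidate covariates")
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 1.0, 0.1), 2)
    pilot = fit_iteration(presences, covariates, kde, seed=seed, n_trees=n_trees)
    imp = permutation_importance(
        pilot.classifier, pilot.X_train, pilot.y_train, n_repeats=5, random_state=seed
    ).importances_mean
    imp = np.maximum(imp, 0.0)
    if imp.max() <= 0:
        raise ValueError("no covariate has positive importance")
    mir = imp / imp.max()
    names = np.array(pilot.covariate_names)

    best: tuple[float, int, list[str]] | None = None
    for t in np.asarray(thresholds, float):
        retained = [n for n, m in zip(names, mir) if m >= t]
        if not retained:
            continue
        cols = [pilot.covariate_names.index(n) for n in retained]
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, oob_score=True
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny forests may miss OOB for some rows
            clf.fit(pilot.X_train[:, cols], pilot.y_train)
        err = 1.0 - clf.oob_score_
        key = (err, len(retained), retained)
        if best is None or key[:2] < best[:2]:
            best = key
    assert best is not None
    return best[2]


# ---------------------------------------------------------------------
# Validation metrics
# ---------------------------------------------------------------------

def auc_roc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outranks random negative),
    ties counted half (Mann-Whitney form)."""
    probabilities = np.asarray(probabilities, float)
    labels = np.asarray(labels)
    pos, neg = probabilities[labels == 1], probabilities[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(probabilities)
    r1 = ranks[labels == 1].sum()
    return float((r1 - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _kappa(tp: int, tn: int, fp: int, fn: int) -> float:
    n = tp + tn + fp + fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def sensitivity_weighted_kappa(
    probabilities: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Cohen's kappa at the threshold maximizing kappa x sensitivity.

    Scans the observed probabilities as cut candidates; at each cut
    computes the 2x2 confusion (predicted positive when p >= cut),
    Cohen's kappa and sensitivity, and returns (kappa, cut) at the
    maximum of their product. Weighting chance-corrected agreement by
    sensitivity favors cuts that do not sacrifice detection of the
    positive class.
    """
    probabilities = np.asarray(probabilities, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    best = (-np.inf, 0.0, 0.0)  # score, kappa, threshold
    for cut in np.unique(probabilities):
        pred = probabilities >= cut
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        if tp + fn == 0:
            continue
        sens = tp / (tp + fn)
        k = _kappa(tp, tn, fp, fn)
        score = k * sens
        if score > best[0]:
            best = (score, k, float(cut))
    return best[1], best[2]


def probability_exceedance(probabilities: np.ndarray, cutoff: float) -> float:
    """Fraction of values strictly above ``cutoff``."""
    probabilities = np.asarray(probabilities, float)
    if len(probabilities) == 0:
        raise ValueError("empty probability vector")
    return float(np.mean(probabilities > cutoff))
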