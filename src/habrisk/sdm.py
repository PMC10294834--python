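"""Random-forest species distribution model: fitting, tuning, evaluation,
importance, response curves, and habitat-map prediction.

The model is a bagged ensemble of unpruned classification trees on
presence (1) / pseudo-absence (0) points. Presence probability is the
fraction of trees voting presence. Evaluation follows the standard SDM
protocol: a stratified 70/30 train/test split, AUC-ROC (Mann-Whitney
formulation), the true skill statistic TSS = sensitivity + specificity - 1
at the threshold maximizing sensitivity + specificity on the training
scores, and stratified k-fold cross-validated AUC on the training data.
Variable importance is the mean decrease in Gini impurity (MDG), the
unnormalized per-tree sum of impurity decreases averaged over trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .geodata import Grid, PointSet, PredictorStack

__all__ = [
    "LabeledDataset",
    "SDMReport",
    "ResponseCurve",
    "RandomForestSDM",
    "make_dataset",
    "split_train_test",
    "tune_mtry",
    "roc_auc",
    "select_threshold",
    "tss",
    "cross_validate",
    "gini_importance",
    "median_importance",
    "response_curve",
    "predict_surface",
    "binarize",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Point-level covariate matrix with labels, split tags and CV folds."""

    species: str
    X: pd.DataFrame
    y: np.ndarray
    split: np.ndarray | None = None   # "train" / "test" per point
    folds: np.ndarray | None = None   # 1..k on training points, 0 elsewhere

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int).reshape(-1)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")

    @property
    def names(self) -> list[str]:
        return list(self.X.columns)

    def train(self) -> tuple[pd.DataFrame, np.ndarray]:
        m = self.split == "train"
        return self.X[m], self.y[m]

    def test(self) -> tuple[pd.DataFrame, np.ndarray]:
        m = self.split == "test"
        return self.X[m], self.y[m]


def make_dataset(
    stack: PredictorStack, presences: PointSet, pseudo_absences: PointSet
) -> LabeledDataset:
    """Assemble the model dataset by sampling the stack at every point."""
    pts = presences.concat(
        PointSet(presences.species, pseudo_absences.coords, pseudo_absences.labels)
    )
    X = stack.extract(pts.x, pts.y)
    ok = np.isfinite(X.to_numpy()).all(axis=1)
    for n in stack.names:
        ok &= X[n].to_numpy() != stack.layers[n].spec.nodata
    return LabeledDataset(presences.species, X[ok].reset_index(drop=True), pts.labels[ok])


@dataclass
class ResponseCurve:
    """Partial-dependence curve of predicted presence probability."""

    variable: str
    grid: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if len(self.grid) > 1 and not (np.diff(self.grid) > 0).all():
            raise ValueError("response grid must be strictly increasing")
        if ((self.probability < 0) | (self.probability > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SDMReport:
    """Fitted-model metrics for one species.

    The TSS fields are recomputed from sensitivity and specificity at
    construction so the identity tss = sens + spec - 1 holds exactly.
    """

    species: str
    n_trees: int
    mtry: int
    seed: int | None
    auc_train: float
    auc_test: float
    threshold: float
    sens_train: float
    spec_train: float
    sens_test: float
    spec_test: float
    cv_aucs: list[float] = field(default_factory=list)
    cv_auc_mean: float = float("nan")
    cv_auc_sd: float = float("nan")
    importance: dict[str, float] = field(default_factory=dict)
    tss_train: float = field(init=False)
    tss_test: float = field(init=False)

    def __post_init__(self) -> None:
        self.tss_train = tss(self.sens_train, self.spec_train)
        self.tss_test = tss(self.sens_test, self.spec_test)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Evaluation primitives
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC as the Mann-Whitney probability of correct ranking.

    Probability that a random presence outscores a random absence, ties
    counted 1/2. 1 is ideal discrimination, 0.5 is random.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both presences and absences")
    ranks = rankdata(scores)  # mid-ranks handle ties
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _sens_spec_at(scores_pos: np.ndarray, scores_neg: np.ndarray,
                  thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sp = np.sort(scores_pos)
    sn = np.sort(scores_neg)
    tp = len(sp) - np.searchsorted(sp, thresholds, side="left")
    tn = np.searchsorted(sn, thresholds, side="left")
    return tp / len(sp), tn / len(sn)


def select_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the midpoints between consecutive sorted unique scores
    plus the endpoints {0, 1}; presence is predicted when score >=
    threshold. Ties in sens + spec resolve to the smallest threshold.
    Returns (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("threshold selection needs both classes")
    uniq = np.unique(scores)
    candidates = np.unique(np.concatenate([[0.0, 1.0], (uniq[:-1] + uniq[1:]) / 2]))
    sens, spec = _sens_spec_at(pos, neg, candidates)
    total = sens + spec
    best = int(np.argmax(total))  # argmax returns the first (smallest) maximizer
    return float(candidates[best]), float(sens[best]), float(spec[best])


def tss(sens: float, spec: float) -> float:
    """True skill statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sens + spec - 1


# ---------------------------------------------------------------------------
# Forest fitting
# ---------------------------------------------------------------------------

def split_train_test(
    y: np.ndarray, train_frac: float = 0.7, seed: int | None = None
) -> np.ndarray:
    """Stratified random train/test assignment; returns "train"/"test" tags.

    Per class, round(train_frac * n) points go to training (round half
    up), so proportions are within one point of the target per class.
    """
    y = np.asarray(y, dtype=int)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split = np.empty(len(y), dtype=object)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 points; cannot split")
        rng.shuffle(idx)
        n_train = int(np.floor(train_frac * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both splits non-empty
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"
    return split


def _vote_fraction(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Presence probability as the fraction of trees voting class 1."""
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
    votes = np.zeros(len(X))
    for est in forest.estimators_:
        leaf_class = np.argmax(est.tree_.value[:, 0, :], axis=1)
        votes += forest.classes_[leaf_class[est.apply(X)]]
    return votes / len(forest.estimators_)


def _oob_vote_fraction(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Out-of-bag vote fraction for the forest's own training rows.

    Each row is scored only by the trees whose bootstrap resample omitted
    it, so training-side metrics are honest rather than memorized. Rows
    that every tree happened to include (vanishingly rare beyond a few
    dozen trees) fall back to the all-tree vote.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
    n = len(X)
    votes = np.zeros(n)
    counts = np.zeros(n)
    for est, samp in zip(forest.estimators_, forest.estimators_samples_):
        in_bag = np.zeros(n, dtype=bool)
        in_bag[samp] = True
        leaf_class = np.argmax(est.tree_.value[:, 0, :], axis=1)
        pred = forest.classes_[leaf_class[est.apply(X)]]
        oob = ~in_bag
        votes[oob] += pred[oob]
        counts[oob] += 1
    never_oob = counts == 0
    if never_oob.any():
        votes[never_oob] = _vote_fraction(forest, X[never_oob]) * 1.0
        counts[never_oob] = 1.0
    return votes / counts


def _mtry_candidates(p: int) -> list[int]:
    """Doubling/halving ladder of split-variable counts around floor(sqrt(p))."""
    m0 = max(1, int(np.floor(np.sqrt(p))))
    cands = {m0}
    m = m0
    while m > 1:
        m = max(1, m // 2)
        cands.add(m)
    m = m0
    while m < p:
        m = min(p, m * 2)
        cands.add(m)
    return sorted(cands)


def tune_mtry(
    X, y, n_trees: int = 50, seed: int | None = None
) -> int:
    """Pick the split-variable count (mtry) minimizing out-of-bag error.

    Candidates form a doubling/halving ladder around floor(sqrt(p)); ties
    go to the smaller mtry. OOB error is estimated on a forest of
    ``n_trees`` trees per candidate.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p == 1:
        return 1
    best_m, best_err = None, np.inf
    for m in _mtry_candidates(p):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small forests warn about OOB coverage
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features=m, oob_score=True,
                bootstrap=True, random_state=seed, n_jobs=1,
            ).fit(X, np.asarray(y, dtype=int))
        err = 1.0 - rf.oob_score_
        if err < best_err:  # strict: ties keep the smaller candidate
            best_m, best_err = m, err
    return int(best_m)


def cross_validate(
    X, y, k: int = 10, seed: int | None = None,
    n_trees: int = 1000, tune: bool = True, mtry: int | None = None,
) -> tuple[list[float], float, float]:
    """Stratified k-fold cross-validated AUC on the training data.

    Each fold refits the forest on the other k-1 folds (re-tuning mtry
    unless a fixed ``mtry`` is supplied) and scores the held-out fold.
    Returns (per-fold AUCs, mean, sample SD).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError(
            f"k={k} exceeds the smaller class size ({counts.min()}); "
            "every fold must contain both classes"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        fold_seed = None if seed is None else (seed + 1009 * (i + 1)) % (2**31 - 1)
        m = mtry if mtry is not None else (
            tune_mtry(X[tr], y[tr], seed=fold_seed) if tune
            else max(1, int(np.sqrt(X.shape[1])))
        )
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features=m, bootstrap=True,
            random_state=fold_seed, n_jobs=1,
        ).fit(X[tr], y[tr])
        aucs.append(roc_auc(_vote_fraction(rf, X[te]), y[te]))
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    return aucs, mean, sd


def gini_importance(
    forest: RandomForestClassifier, feature_names: list[str]
) -> pd.Series:
    """Mean decrease Gini: per variable, the mean over trees of the total
    (sample-weighted, unnormalized) Gini impurity decrease at its splits."""
    totals = np.zeros(len(feature_names))
    for est in forest.estimators_:
        t = est.tree_
        internal = t.children_left != -1
        w = t.weighted_n_node_samples
        dec = (
            w * t.impurity
            - w[t.children_left] * t.impurity[t.children_left]
            - w[t.children_right] * t.impurity[t.children_right]
        )
        np.add.at(totals, t.feature[internal], dec[internal])
    mdg = totals / len(forest.estimators_)
    return pd.Series(np.maximum(mdg, 0.0), index=list(feature_names), name="mdg")


def median_importance(per_species: dict[str, pd.Series], top: int = 3) -> pd.DataFrame:
    """Median MDG across species; variables ranked descending, top-k flagged."""
    if not per_species:
        raise ValueError("need at least one importance table")
    names = None
    for sp, tab in per_species.items():
        cur = set(tab.index)
        if names is None:
            names = cur
        elif cur != names:
            raise ValueError(f"importance table for {sp!r} has a mismatched variable set")
    df = pd.DataFrame(per_species)
    df["median"] = df.median(axis=1)
    df = df.sort_values("median", ascending=False)
    df["rank"] = np.arange(1, len(df) + 1)
    df["top"] = df["rank"] <= top
    return df


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class RandomForestSDM(ClassifierMixin, BaseEstimator):
    """Random-forest species distribution model with the SDM evaluation
    protocol built in.

    ``fit(X, y)`` performs the stratified 70/30 split, tunes the number of
    split variables by out-of-bag error (unless ``mtry`` is fixed), fits an
    ensemble of unpruned trees on bootstrap resamples of the training
    split, selects the presence threshold maximizing sensitivity +
    specificity on the out-of-bag training scores, and evaluates AUC/TSS
    on both splits plus k-fold cross-validated AUC on the training data.
    Training-side metrics use out-of-bag votes (the R randomForest
    convention); test-side metrics use all-tree votes on the held-out
    split.

    Parameters
    ----------
    n_trees : int, default=1000
        Trees in the ensemble.
    mtry : int or None, default=None
        Variables tried at each split; None tunes by OOB error.
    train_frac : float, default=0.7
        Fraction of each class assigned to the training split.
    cv_folds : int, default=10
        Folds for cross-validated AUC; 0 skips cross-validation.
    cv_retune : bool, default=True
        Re-tune mtry inside every CV fold (avoids tuning leakage).
    species : str, default="species"
        Name recorded in the report.
    random_state : int or None
        Seed for the split, tuning, forest, and CV.

    Attributes
    ----------
    model_ : fitted sklearn RandomForestClassifier
    mtry_ : int
    threshold_ : float
    auc_train_, auc_test_ : float
    sens_, spec_ : float  (training split, at threshold_)
    tss_train_, tss_test_ : float
    cv_aucs_, cv_auc_mean_, cv_auc_sd_
    importance_ : pd.Series of mean decrease Gini per variable
    report_ : SDMReport
    split_ : ndarray of "train"/"test" tags aligned with the fit data
    """

    def __init__(
        self,
        n_trees: int = 1000,
        mtry: int | None = None,
        train_frac: float = 0.7,
        cv_folds: int = 10,
        cv_retune: bool = True,
        species: str = "species",
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.train_frac = train_frac
        self.cv_folds = cv_folds
        self.cv_retune = cv_retune
        self.species = species
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def _frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y):
        X = self._frame(X)
        y = np.asarray(y, dtype=int).reshape(-1)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if set(classes) - {0, 1} or len(classes) < 2:
            raise ValueError("y must contain both classes, coded 0/1")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)

        seed = self.random_state
        self.split_ = split_train_test(y, self.train_frac, seed)
        tr = self.split_ == "train"
        te = ~tr
        Xtr, ytr = X[tr].to_numpy(float), y[tr]
        Xte, yte = X[te].to_numpy(float), y[te]

        self.mtry_ = (
            int(self.mtry) if self.mtry is not None
            else tune_mtry(Xtr, ytr, seed=seed)
        )
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_features=self.mtry_,
            bootstrap=True, random_state=seed, n_jobs=1,
        ).fit(Xtr, ytr)

        # training-side scores are out-of-bag votes (the R randomForest
        # convention): in-bag votes are memorized and would push the
        # max-sens+spec threshold to the top of the score range
        s_tr = _oob_vote_fraction(self.model_, Xtr)
        s_te = _vote_fraction(self.model_, Xte)
        self.auc_train_ = roc_auc(s_tr, ytr)
        self.auc_test_ = roc_auc(s_te, yte)
        self.threshold_, self.sens_, self.spec_ = select_threshold(s_tr, ytr)
        sens_te, spec_te = _sens_spec_at(
            np.sort(s_te[yte == 1]), np.sort(s_te[yte == 0]),
            np.array([self.threshold_]),
        )
        self.tss_train_ = tss(self.sens_, self.spec_)
        self.tss_test_ = tss(float(sens_te[0]), float(spec_te[0]))

        if self.cv_folds:
            self.cv_aucs_, self.cv_auc_mean_, self.cv_auc_sd_ = cross_validate(
                Xtr, ytr, k=self.cv_folds, seed=seed, n_trees=self.n_trees,
                tune=self.cv_retune and self.mtry is None,
                mtry=None if (self.cv_retune and self.mtry is None) else self.mtry_,
            )
        else:
            self.cv_aucs_, self.cv_auc_mean_, self.cv_auc_sd_ = [], float("nan"), float("nan")

        self.importance_ = gini_importance(self.model_, list(X.columns))
        self.report_ = SDMReport(
            species=self.species,
            n_trees=self.n_trees,
            mtry=self.mtry_,
            seed=seed,
            auc_train=self.auc_train_,
            auc_test=self.auc_test_,
            threshold=self.threshold_,
            sens_train=self.sens_,
            spec_train=self.spec_,
            sens_test=float(sens_te[0]),
            spec_test=float(spec_te[0]),
            cv_aucs=[float(a) for a in self.cv_aucs_],
            cv_auc_mean=self.cv_auc_mean_,
            cv_auc_sd=self.cv_auc_sd_,
            importance=dict(self.importance_),
        )
        return self

    def suitability(self, X) -> np.ndarray:
        """Predicted presence probability (tree-vote fraction)."""
        check_is_fitted(self, "model_")
        X = self._frame(X)
        return _vote_fraction(self.model_, X.to_numpy(float))

    def predict_proba(self, X) -> np.ndarray:
        p = self.suitability(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.suitability(X) >= self.threshold_).astype(int)


# ---------------------------------------------------------------------------
# Curves and surfaces
# ---------------------------------------------------------------------------

def response_curve(
    model: RandomForestSDM, X, variable: str, n_grid: int = 50,
    max_rows: int = 1000,
) -> ResponseCurve:
    """Partial dependence of presence probability on one variable.

    For each grid value spanning the variable's observed range, that
    variable is set to the value for every dataset row and the predicted
    probabilities are averaged. Datasets larger than ``max_rows`` are
    subsampled deterministically (evenly spaced rows) before averaging;
    all grid values are scored in one batched forest pass.
    """
    X = model._frame(X)
    if variable not in X.columns:
        raise KeyError(f"variable {variable!r} not in dataset")
    vals = X[variable].to_numpy(float)
    lo, hi = float(np.min(vals)), float(np.max(vals))
    grid = np.array([lo]) if lo == hi else np.linspace(lo, hi, n_grid)
    if len(X) > max_rows:
        X = X.iloc[np.linspace(0, len(X) - 1, max_rows).astype(int)]
    base = X.to_numpy(float)
    col = list(X.columns).index(variable)
    tiled = np.repeat(base[None, :, :], len(grid), axis=0)
    tiled[:, :, col] = grid[:, None]
    flat = tiled.reshape(-1, base.shape[1])
    probs = _vote_fraction(model.model_, flat).reshape(len(grid), len(X)).mean(axis=1)
    return ResponseCurve(variable, grid, probs)


def predict_surface(model: RandomForestSDM, stack: PredictorStack) -> Grid:
    """Predicted presence-probability raster; nodata propagates."""
    check_is_fitted(model, "model_")
    needed = [str(n) for n in model.feature_names_in_]
    missing = [n for n in needed if n not in stack]
    if missing:
        raise KeyError(f"stack is missing model variable(s): {missing}")
    sub = stack.subset(needed)
    mat, idx = sub.to_matrix()
    out = np.full(sub.spec.shape, sub.spec.nodata).ravel()
    if len(idx):
        out[idx] = _vote_fraction(model.model_, mat)
    return Grid(sub.spec, out.reshape(sub.spec.shape))


def binarize(surface: Grid, threshold: float) -> Grid:
    """Binary habitat map: 1 where probability >= threshold; nodata kept."""
    nd = surface.mask_nodata()
    out = np.where(surface.values >= threshold, 1.0, 0.0)
    out = np.where(nd, surface.spec.nodata, out)
    return Grid(surface.spec, out)
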