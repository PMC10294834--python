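"""Multicollinearity screening of candidate predictors.

Before fitting a species distribution model, predictor pairs whose
absolute Pearson, Spearman, or Kendall correlation exceeds a threshold
(default 0.75) are reduced to a single member: the one whose univariate
binomial regression on the presence/absence labels explains more
deviance survives. Deviance explained is measured with a smooth (spline)
term when the smoother converges, otherwise with a plain linear logit.

The screen is exposed both as plain functions and as the sklearn-style
``CollinearityScreener`` transformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "ScreeningReport",
    "pairwise_correlations",
    "univariate_deviance",
    "screen_collinear",
    "CollinearityScreener",
]

MAX_DEVIANCE_PCT = 100.0


@dataclass
class ScreeningReport:
    """Outcome of the collinearity screen.

    correlation_triplets maps each unordered variable pair (a sorted
    2-tuple) to (pearson, spearman, kendall). dropped records, in drop
    order, which variable was removed and which collinear partner forced
    the decision.
    """

    correlation_triplets: dict[tuple[str, str], tuple[float, float, float]]
    deviance_explained: dict[str, float]
    retained: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)
    threshold: float = 0.75

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "var_a": a,
                "var_b": b,
                "pearson": p,
                "spearman": s,
                "kendall": k,
                "max_abs": max(abs(p), abs(s), abs(k)),
            }
            for (a, b), (p, s, k) in self.correlation_triplets.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "retained": self.retained,
            "dropped": [
                {"variable": v, "because_of": w} for v, w in self.dropped
            ],
            "deviance_explained": self.deviance_explained,
            "correlations": [
                {"pair": list(pair), "pearson": p, "spearman": s, "kendall": k}
                for pair, (p, s, k) in self.correlation_triplets.items()
            ],
        }


def _constant(x: np.ndarray) -> bool:
    return np.ptp(x) == 0


def pairwise_correlations(
    X: pd.DataFrame,
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Pearson, Spearman and Kendall coefficients for every variable pair.

    A constant variable cannot correlate with anything; its pairs are
    recorded as (0, 0, 0) with a warning.
    """
    names = list(X.columns)
    if len(X) < 3:
        raise ValueError("need at least 3 points to estimate correlations")
    out: dict[tuple[str, str], tuple[float, float, float]] = {}
    const = {n for n in names if _constant(X[n].to_numpy())}
    for n in const:
        warnings.warn(f"variable {n!r} is constant; correlations undefined, set to 0")
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            key = (a, b)
            if a in const or b in const:
                out[key] = (0.0, 0.0, 0.0)
                continue
            xa = X[a].to_numpy(float)
            xb = X[b].to_numpy(float)
            p = stats.pearsonr(xa, xb).statistic
            s = stats.spearmanr(xa, xb).statistic
            k = stats.kendalltau(xa, xb).statistic
            out[key] = (float(p), float(s), float(k))
    return out


def univariate_deviance(
    x: np.ndarray, labels: np.ndarray, smooth: bool = True
) -> float:
    """Percent deviance explained by a univariate binomial regression.

    Tries a penalized spline (GAM) first when ``smooth`` is True; falls
    back to a linear logit if the smoother cannot be fit. Returns
    100 * (null_deviance - residual_deviance) / null_deviance, capped to
    [0, 100]; perfect separation caps at 100 with a warning.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(labels, dtype=float).reshape(-1)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if _constant(x):
        return 0.0

    res = None
    if smooth and len(np.unique(x)) >= 10:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bs = BSplines(x[:, None], df=[6], degree=[3])
                gam = GLMGam(y, np.ones((len(y), 1)), smoother=bs,
                             family=sm.families.Binomial())
                res = gam.fit()
            if not np.isfinite(res.deviance):
                res = None
        except Exception:
            res = None
    if res is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial())
            res = glm.fit(maxiter=100)
    null_dev = res.null_deviance
    if null_dev <= 0:
        return 0.0
    pct = 100.0 * (null_dev - res.deviance) / null_dev
    # residual deviance ~0 means (quasi-)complete separation: the MLE is
    # unbounded and the exact percentage is an artifact of early stopping
    if pct >= 99.99:
        warnings.warn("near-perfect separation; deviance explained capped at 100")
        return MAX_DEVIANCE_PCT
    return float(max(pct, 0.0))


def screen_collinear(
    X: pd.DataFrame,
    labels: np.ndarray,
    threshold: float = 0.75,
    smooth: bool = True,
) -> ScreeningReport:
    """Iteratively drop the weaker member of each over-correlated pair.

    While any retained pair exceeds the threshold on |Pearson|, |Spearman|
    or |Kendall|, the worst-offending pair (largest max-|r|) is resolved by
    dropping its member with the lower percent deviance explained; ties in
    deviance drop the alphabetically later name. Deterministic for a given
    dataset, independent of column order when deviances are distinct.
    """
    if X.shape[1] < 2:
        raise ValueError("screening needs at least 2 variables")
    y = np.asarray(labels)
    triplets = pairwise_correlations(X)
    deviance = {
        name: (0.0 if _constant(X[name].to_numpy())
               else univariate_deviance(X[name].to_numpy(), y, smooth=smooth))
        for name in X.columns
    }

    retained = sorted(X.columns)
    dropped: list[tuple[str, str]] = []
    while True:
        worst_pair = None
        worst_r = threshold
        for a, b in ((a, b) for i, a in enumerate(retained) for b in retained[i + 1:]):
            trip = triplets[(a, b) if (a, b) in triplets else (b, a)]
            r = max(abs(v) for v in trip)
            if r > worst_r:
                worst_r = r
                worst_pair = (a, b)
        if worst_pair is None:
            break
        a, b = worst_pair
        da, db = deviance[a], deviance[b]
        if da > db:
            loser, keeper = b, a
        elif db > da:
            loser, keeper = a, b
        else:  # tie: drop the alphabetically later name
            loser, keeper = max(a, b), min(a, b)
        retained.remove(loser)
        dropped.append((loser, keeper))

    # preserve the input column order for the retained list
    retained = [c for c in X.columns if c in set(retained)]
    return ScreeningReport(
        correlation_triplets=triplets,
        deviance_explained=deviance,
        retained=retained,
        dropped=dropped,
        threshold=threshold,
    )


class CollinearityScreener(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping the collinearity screen.

    Parameters
    ----------
    threshold : float, default=0.75
        Maximum tolerated absolute correlation (any of Pearson, Spearman,
        Kendall) between two retained predictors.
    smooth : bool, default=True
        Whether to attempt a spline (GAM) fit for deviance explained
        before falling back to a linear logit.

    Attributes
    ----------
    report_ : ScreeningReport
    retained_ : list of str
    dropped_ : list of (variable, because_of) tuples
    n_features_in_ : int
    feature_names_in_ : ndarray of str
    """

    def __init__(self, threshold: float = 0.75, smooth: bool = True):
        self.threshold = threshold
        self.smooth = smooth

    def fit(self, X, y):
        X = self._as_frame(X)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.report_ = screen_collinear(
            X, np.asarray(y), threshold=self.threshold, smooth=self.smooth
        )
        self.retained_ = self.report_.retained
        self.dropped_ = self.report_.dropped
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        X = self._as_frame(X)
        return X[self.retained_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "retained_")
        kept = set(self.retained_)
        return np.array([n in kept for n in self.feature_names_in_])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "retained_")
        return np.asarray(self.retained_, dtype=object)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
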