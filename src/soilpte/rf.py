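"""PMF-informed random-forest prediction of element concentrations.

Preprocessing follows the conventions of environmental RF modelling:
targets winsorized at the 5th/95th percentiles, continuous predictors
z-scored, categoricals one-hot encoded with a dropped reference level, and
source contributions (columns of the PMF G matrix) appended as predictors.
The ensemble is bootstrap-aggregated regression trees with a random
predictor subset per split (mtry = ceil(p/3), minimum leaf size 5); the
ensemble prediction is the arithmetic mean of the tree predictions, and
out-of-bag (OOB) records drive the error curve and permutation importance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor

from .core import COVARIATE_COLUMNS, ELEMENTS, SoilDataset


class RFError(ValueError):
    pass


# ---------------------------------------------------------------------------
# preprocessing


def winsorize(values, lower_pct: float = 5.0, upper_pct: float = 95.0) -> np.ndarray:
    """Clip a vector to its [lower_pct, upper_pct] percentiles (linear
    interpolation between order statistics).  Idempotent."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise RFError("cannot winsorize an empty vector")
    lo, hi = np.percentile(v, [lower_pct, upper_pct], method="linear")
    return np.clip(v, lo, hi)


@dataclass
class Standardizer:
    """z-score transform with stored mean and sd (n-1 denominator), reusable
    on new data."""

    mean: float = 0.0
    sd: float = 1.0

    def fit(self, values) -> "Standardizer":
        v = np.asarray(values, float)
        self.mean = float(v.mean())
        self.sd = float(v.std(ddof=1))
        if self.sd == 0:
            raise RFError("zero variance; cannot standardize")
        return self

    def transform(self, values) -> np.ndarray:
        return (np.asarray(values, float) - self.mean) / self.sd


def zscore(values) -> np.ndarray:
    return Standardizer().fit(values).transform(values)


@dataclass
class OneHotEncoder:
    """Indicator encoding with a dropped reference level.

    ``fit`` records the observed levels; ``transform`` fails loudly on a
    level never seen in training.
    """

    reference: str
    levels: list[str] = field(default_factory=list)

    def fit(self, categories) -> "OneHotEncoder":
        observed = list(dict.fromkeys(categories))
        if self.reference not in observed:
            raise RFError(f"reference level {self.reference!r} not observed")
        self.levels = [l for l in observed if l != self.reference]
        return self

    def transform(self, categories) -> pd.DataFrame:
        cats = list(categories)
        known = set(self.levels) | {self.reference}
        unseen = sorted(set(cats) - known)
        if unseen:
            raise RFError(f"unseen level(s) at transform time: {unseen}")
        data = {l: [1.0 if c == l else 0.0 for c in cats] for l in self.levels}
        return pd.DataFrame(data)


def one_hot(categories, reference_level: str) -> pd.DataFrame:
    return OneHotEncoder(reference_level).fit(categories).transform(categories)


def split_data(n: int, train_frac: float = 0.7, seed: int | None = None):
    """Random hold-out split; train size = round(train_frac * n)."""
    if n < 2:
        raise RFError("need at least two samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def build_feature_matrix(
    ds: SoilDataset,
    G: np.ndarray | None = None,
    landuse_reference: str = "CM",
    impute_missing: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the predictor table: z-scored continuous covariates and
    coordinates, one-hot land use / texture / depth class, and (optionally)
    the PMF contribution columns F1..Fk.

    Returns (features, preprocessing state).  Constant encoded columns are
    dropped so no degenerate predictors reach the trees.
    """
    df = ds.df
    blocks: list[pd.DataFrame] = []
    state: dict = {"standardizers": {}, "encoders": {}}
    for col in list(COVARIATE_COLUMNS) + ["x", "y"]:
        vals = df[col].to_numpy(float)
        if np.isnan(vals).any():
            if not impute_missing:
                raise RFError(f"missing values in covariate {col!r}")
            vals = np.where(np.isnan(vals), np.nanmean(vals), vals)
        try:
            st = Standardizer().fit(vals)
        except RFError:
            continue  # constant covariate carries no signal
        state["standardizers"][col] = st
        blocks.append(pd.DataFrame({col: st.transform(vals)}))
    for col, ref in (("land_use", landuse_reference),
                     ("texture", None), ("depth_class", None)):
        cats = df[col].astype(str).tolist()
        reference = ref if ref is not None else cats[0]
        enc = OneHotEncoder(reference).fit(cats)
        state["encoders"][col] = enc
        out = enc.transform(cats)
        out.columns = [f"{col}={l}" for l in out.columns]
        out = out.loc[:, out.nunique() > 1]  # drop constant indicators
        if out.shape[1]:
            blocks.append(out)
    if G is not None:
        G = np.asarray(G, float)
        if G.shape[0] != len(df):
            raise RFError("G matrix row count must match the dataset")
        blocks.append(pd.DataFrame(
            G, columns=[f"F{f + 1}" for f in range(G.shape[1])]))
    X = pd.concat(blocks, axis=1)
    if (X.nunique() <= 1).any():
        bad = list(X.columns[X.nunique() <= 1])
        raise RFError(f"constant feature column(s) after encoding: {bad}")
    return X, state


# ---------------------------------------------------------------------------
# model


@dataclass
class RFModel:
    """A bagged-tree regressor plus the training records needed for OOB
    diagnostics."""

    bagger: BaggingRegressor
    feature_names: list[str]
    X_train: np.ndarray
    y_train: np.ndarray
    seed: int | None

    @property
    def n_trees(self) -> int:
        return len(self.bagger.estimators_)

    def predict(self, X) -> np.ndarray:
        return self.bagger.predict(self._as_array(X))

    def per_tree_predictions(self, X) -> np.ndarray:
        """(n_trees, n) matrix of individual tree predictions; the ensemble
        output is exactly their arithmetic mean."""
        Xa = self._as_array(X)
        return np.stack([t.predict(Xa) for t in self.bagger.estimators_])

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names].to_numpy(float)
        return np.asarray(X, float)

    def oob_mask(self) -> np.ndarray:
        """(n_trees, n_train) boolean: True where a sample is out-of-bag."""
        n = len(self.y_train)
        mask = np.ones((self.n_trees, n), dtype=bool)
        for t, idx in enumerate(self.bagger.estimators_samples_):
            mask[t, idx] = False
        return mask


def train_rf(features, target, n_trees: int = 300, seed: int | None = None,
             mtry: int | None = None, min_leaf: int = 5) -> RFModel:
    """Fit the bagged ensemble.

    ``mtry`` defaults to ceil(p/3), the regression-bagging convention.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(float)
    else:
        X = np.asarray(features, float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(target, float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise RFError("NaN in features or target")
    p = X.shape[1]
    if mtry is None:
        mtry = math.ceil(p / 3)
    tree = DecisionTreeRegressor(max_features=min(mtry, p),
                                 min_samples_leaf=min_leaf)
    bagger = BaggingRegressor(
        estimator=tree, n_estimators=n_trees, bootstrap=True,
        random_state=seed, n_jobs=1,
    )
    bagger.fit(X, y)
    return RFModel(bagger, names, X, y, seed)


def evaluate(model: RFModel, features, target, train_target_mean: float) -> dict:
    """Hold-out metrics.

    R^2 is computed against the test-set mean, Q^2 (predictive squared
    correlation) against the training-set mean, RMSE in target units.
    """
    y = np.asarray(target, float)
    if y.size == 0:
        raise RFError("empty test set")
    yhat = model.predict(features)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_test = float(np.sum((y - y.mean()) ** 2))
    if ss_test == 0:
        raise RFError("zero-variance test target; R^2 undefined")
    ss_train = float(np.sum((y - train_target_mean) ** 2))
    return {
        "R2": 1.0 - ss_res / ss_test,
        "Q2": 1.0 - ss_res / ss_train,
        "RMSE": math.sqrt(ss_res / y.size),
    }


def _oob_predictions(model: RFModel, per_tree: np.ndarray) -> np.ndarray:
    """Aggregate OOB prediction per training sample (NaN when never OOB)."""
    mask = model.oob_mask()
    num = np.where(mask, per_tree, 0.0).sum(axis=0)
    den = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def oob_error_curve(model: RFModel) -> np.ndarray:
    """Cumulative OOB mean-squared error after t trees, t = 1..n_trees."""
    per_tree = model.per_tree_predictions(model.X_train)
    mask = model.oob_mask()
    num = np.cumsum(np.where(mask, per_tree, 0.0), axis=0)
    den = np.cumsum(mask, axis=0)
    curve = np.empty(model.n_trees)
    for t in range(model.n_trees):
        have = den[t] > 0
        if not have.any():
            curve[t] = np.nan
            continue
        pred = num[t, have] / den[t, have]
        curve[t] = float(np.mean((model.y_train[have] - pred) ** 2))
    return curve


def permutation_importance(model: RFModel, features=None, target=None,
                           n_repeats: int = 5, seed: int | None = None) -> pd.Series:
    """Mean increase in squared error after permuting each predictor.

    With no held-out data supplied the OOB records of the training set are
    used (the TreeBagger convention); otherwise the given set is scored
    directly.
    """
    rng = np.random.default_rng(seed)
    if features is None:
        X = model.X_train.copy()
        y = model.y_train
        oob = True
    else:
        X = model._as_array(features).copy()
        y = np.asarray(target, float)
        oob = False
    if X.shape[0] < 2:
        raise RFError("need at least two rows for permutation importance")

    def score(Xs) -> float:
        if oob:
            per_tree = np.stack([t.predict(Xs) for t in model.bagger.estimators_])
            pred = _oob_predictions(model, per_tree)
            have = ~np.isnan(pred)
            return float(np.mean((y[have] - pred[have]) ** 2))
        return float(np.mean((y - model.bagger.predict(Xs)) ** 2))

    base = score(X)
    rows = {}
    for j, name in enumerate(model.feature_names):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            deltas.append(score(Xp) - base)
        rows[name] = float(np.mean(deltas))
    return pd.Series(rows, name="importance")


def partial_dependence(model: RFModel, features, column: str, grid=None,
                       n_grid: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Marginal effect curve: PD(v) = mean over rows of the prediction with
    ``column`` set to v.  The default grid spans the observed range."""
    X = model._as_array(features)
    if column not in model.feature_names:
        raise RFError(f"unknown feature {column!r}")
    j = model.feature_names.index(column)
    if grid is None:
        grid = np.linspace(X[:, j].min(), X[:, j].max(), n_grid)
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise RFError("empty grid")
    pd_vals = np.empty(grid.size)
    for i, v in enumerate(grid):
        Xg = X.copy()
        Xg[:, j] = v
        pd_vals[i] = float(np.mean(model.bagger.predict(Xg)))
    return grid, pd_vals
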