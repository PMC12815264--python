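"""Random-forest modelling of per-sample HGT prevalence from the environment.

The workflow mirrors the in-depth environmental analysis: drop redundant
variables (|Spearman rho| >= 0.95 to an already-retained one), cluster the
rest by |1 - rho| average-linkage distance, fit a regression forest
(mtry = floor(sqrt(p)) by default), and test each variable's permutation
importance against a shuffle-null distribution built by refitting the forest
on response-permuted data. Interpretation tools: ICE curves (whose mean is
the partial-dependence curve) and the Friedman-Popescu H-statistic for
pairwise interactions.

The forest is a bagging ensemble of regression trees with per-split feature
subsampling — the classic random-forest construction — built on
``BaggingRegressor`` so each tree's bootstrap indices are available for
out-of-bag (OOB) error and OOB permutation importance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Variable preprocessing
# ---------------------------------------------------------------------------


def dedupe_env(
    env: pd.DataFrame, rho_threshold: float = 0.95
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy redundancy filter on environmental variables.

    Variables are processed in column order; one is dropped when its
    |Spearman rho| with an already-retained variable reaches the threshold.
    Returns the retained list and (dropped, representative, rho) records.
    """
    if env.shape[1] < 2:
        raise ValueError("need at least two variables")
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for col in env.columns:
        rep = None
        for kept in retained:
            rho = float(stats.spearmanr(env[col], env[kept]).statistic)
            if abs(rho) >= rho_threshold:
                rep = (kept, rho)
                break
        if rep is None:
            retained.append(col)
        else:
            dropped.append((col, rep[0], rep[1]))
    return retained, dropped


@dataclass
class EnvDendrogram:
    """Average-linkage clustering of variables on |1 - Spearman rho| distance."""

    linkage_matrix: np.ndarray
    labels: list[str]
    distance: pd.DataFrame


def env_distance_cluster(env: pd.DataFrame) -> EnvDendrogram:
    """UPGMA dendrogram over variables with distance |1 - Spearman rho|.

    Note the printed distance maps perfect anticorrelation to 2, not 0.
    Constant variables have undefined correlations and are rejected.
    """
    if env.shape[1] < 3:
        raise ValueError("need at least three variables to cluster")
    for col in env.columns:
        if env[col].nunique() <= 1:
            raise ValueError(f"variable {col!r} is constant; correlation undefined")
    rho = env.corr(method="spearman")
    dist = (1.0 - rho).abs()
    np.fill_diagonal(dist.values, 0.0)
    Z = linkage(squareform(dist.to_numpy(), checks=False), method="average")
    return EnvDendrogram(linkage_matrix=Z, labels=list(env.columns), distance=dist)


# ---------------------------------------------------------------------------
# Forest model / results
# ---------------------------------------------------------------------------


class EnvForest:
    """Regression forest for HGT prevalence ~ environmental variables.

    Parameters
    ----------
    env, response
        Predictor table (samples x variables) and the per-sample HGT
        prevalence (fraction of present genomes with >= 1 transfer).
    n_trees
        Ensemble size. The reference configuration is 10 000 trees; smaller
        forests are appropriate for null replicates and desk-scale runs.
    mtry
        Features considered per split; default floor(sqrt(p)) (3 for the
        12-variable table).
    """

    def __init__(
        self,
        env: pd.DataFrame,
        response: pd.Series,
        n_trees: int = 10_000,
        mtry: int | None = None,
        seed: int = 0,
    ) -> None:
        if env.shape[1] == 0:
            raise ValueError("no predictor variables")
        if env.shape[0] < 30:
            raise ValueError("need at least 30 samples")
        if env.isna().any().any() or response.isna().any():
            raise ValueError("missing values must be handled before fitting")
        self.env = env.copy()
        self.response = response.reindex(env.index).astype(float)
        self.n_trees = int(n_trees)
        self.mtry = int(mtry) if mtry is not None else max(1, math.isqrt(env.shape[1]))
        self.seed = int(seed)

    def fit(self) -> "EnvForestResults":
        model = BaggingRegressor(
            estimator=DecisionTreeRegressor(max_features=self.mtry),
            n_estimators=self.n_trees,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        model.fit(self.env.to_numpy(), self.response.to_numpy())
        return EnvForestResults(self, model)


class EnvForestResults:
    """Fitted forest with OOB R^2, OOB permutation importance and PD tools."""

    def __init__(self, spec: EnvForest, model: BaggingRegressor) -> None:
        self.spec = spec
        self.model = model
        self._X = spec.env.to_numpy()
        self._y = spec.response.to_numpy()
        self._oob_masks = self._build_oob_masks()
        self.oob_r2 = self._compute_oob_r2()
        self.importance = self._permutation_importance()

    # -- OOB bookkeeping ---------------------------------------------------

    def _build_oob_masks(self) -> list[np.ndarray]:
        n = self._X.shape[0]
        masks = []
        for samples in self.model.estimators_samples_:
            mask = np.ones(n, dtype=bool)
            mask[samples] = False
            masks.append(mask)
        return masks

    def _compute_oob_r2(self) -> float:
        n = self._X.shape[0]
        sums = np.zeros(n)
        counts = np.zeros(n)
        for tree, mask in zip(self.model.estimators_, self._oob_masks):
            if not mask.any():
                continue
            sums[mask] += tree.predict(self._X[mask])
            counts[mask] += 1
        seen = counts > 0
        if not seen.any():
            return float("nan")
        pred = sums[seen] / counts[seen]
        resid = self._y[seen] - pred
        total = self._y[seen] - self._y[seen].mean()
        return float(1.0 - (resid @ resid) / (total @ total))

    def _permutation_importance(self) -> pd.Series:
        """ranger-style importance: mean OOB MSE increase after permuting.

        Per tree, the baseline and all single-variable permutations are
        evaluated in one stacked predict call.
        """
        rng = np.random.default_rng(self.spec.seed + 1)
        p = self._X.shape[1]
        deltas = np.zeros(p)
        tree_counts = np.zeros(p)
        for tree, mask in zip(self.model.estimators_, self._oob_masks):
            n_oob = int(mask.sum())
            if n_oob < 2:
                continue
            X_oob = self._X[mask]
            y_oob = self._y[mask]
            perm = rng.permutation(n_oob)
            stacked = np.tile(X_oob, (p + 1, 1))
            for j in range(p):
                block = slice((j + 1) * n_oob, (j + 2) * n_oob)
                stacked[block, j] = X_oob[perm, j]
            preds = tree.predict(stacked).reshape(p + 1, n_oob)
            mses = np.mean((preds - y_oob[None, :]) ** 2, axis=1)
            deltas += mses[1:] - mses[0]
            tree_counts += 1
        with np.errstate(invalid="ignore"):
            imp = np.where(tree_counts > 0, deltas / np.maximum(tree_counts, 1), np.nan)
        return pd.Series(imp, index=self.spec.env.columns, name="importance")

    # -- prediction / interpretation --------------------------------------

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.spec.env.columns].to_numpy()
        return self.model.predict(X)

    def ice_curves(self, variable: str, grid: np.ndarray | None = None) -> pd.DataFrame:
        """Per-sample prediction curves as ``variable`` sweeps the grid.

        The mean over samples of the ICE matrix is exactly the partial
        dependence curve. Grid values outside the training range are allowed
        but represent extrapolation.
        """
        j = list(self.spec.env.columns).index(variable)
        col = self._X[:, j]
        if grid is None:
            grid = np.linspace(col.min(), col.max(), 20)
        grid = np.asarray(grid, dtype=float)
        if grid.min() < col.min() or grid.max() > col.max():
            warnings.warn(f"grid extends beyond the training range of {variable!r}")
        n = self._X.shape[0]
        out = np.empty((n, grid.size))
        for gi, val in enumerate(grid):
            X_mod = self._X.copy()
            X_mod[:, j] = val
            out[:, gi] = self.model.predict(X_mod)
        return pd.DataFrame(out, index=self.spec.env.index, columns=grid)

    def partial_dependence(self, variable: str, grid: np.ndarray | None = None) -> pd.Series:
        ice = self.ice_curves(variable, grid)
        return ice.mean(axis=0)

    def _pd_at_points(self, cols: tuple[int, ...]) -> np.ndarray:
        """Partial dependence of the given columns evaluated at each sample's
        own values of those columns (averaging over all other columns).

        All n x n substitutions are evaluated in one stacked predict call.
        """
        n = self._X.shape[0]
        stacked = np.tile(self._X, (n, 1))
        for i in range(n):
            block = slice(i * n, (i + 1) * n)
            for j in cols:
                stacked[block, j] = self._X[i, j]
        return self.model.predict(stacked).reshape(n, n).mean(axis=1)

    def h_statistic(self, var_j: str, var_k: str) -> float:
        """Friedman-Popescu H^2 for one variable pair.

        H^2 = sum_i [PDjk(x_i) - PDj(x_i) - PDk(x_i)]^2 / sum_i PDjk(x_i)^2
        with every partial-dependence function mean-centered over the
        sample. The share of the pair's joint effect due to interaction;
        symmetric in its arguments; undefined (NaN) when the joint PD is
        identically zero after centering.
        """
        names = list(self.spec.env.columns)
        j, k = names.index(var_j), names.index(var_k)
        pd_j = self._pd_at_points((j,))
        pd_k = self._pd_at_points((k,))
        pd_jk = self._pd_at_points((j, k))
        pd_j = pd_j - pd_j.mean()
        pd_k = pd_k - pd_k.mean()
        pd_jk = pd_jk - pd_jk.mean()
        denom = float(np.sum(pd_jk**2))
        if denom == 0.0:
            return float("nan")
        return float(np.sum((pd_jk - pd_j - pd_k) ** 2) / denom)


def fit_rf(
    env: pd.DataFrame,
    response: pd.Series,
    n_trees: int = 10_000,
    mtry: int | None = None,
    seed: int = 0,
) -> tuple[EnvForestResults, float, pd.Series]:
    """Functional wrapper: returns (results, OOB R^2, permutation importance)."""
    res = EnvForest(env, response, n_trees=n_trees, mtry=mtry, seed=seed).fit()
    return res, res.oob_r2, res.importance


# ---------------------------------------------------------------------------
# Shuffle-null importance significance
# ---------------------------------------------------------------------------


def importance_null_test(
    env: pd.DataFrame,
    response: pd.Series,
    n_replicates: int = 1000,
    n_trees: int = 1000,
    null_n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    plus_one: bool = True,
) -> pd.DataFrame:
    """Permutation-null significance of forest variable importance.

    The observed forest is fitted once; each null replicate permutes the
    response, refits a (typically smaller) forest and records each
    variable's importance. p is the proportion of null importances at or
    above the observed one — with the (+1)/(n+1) convention by default so p
    is never zero — BH-corrected across variables. The Spearman sign of each
    variable with the response is attached as directional context only.
    """
    if n_replicates < 100:
        warnings.warn("fewer than 100 null replicates gives coarse p-value resolution")
    rng = np.random.default_rng(seed)
    obs = EnvForest(env, response, n_trees=n_trees, mtry=mtry, seed=seed).fit()
    null_imp = np.empty((n_replicates, env.shape[1]))
    y = response.to_numpy().copy()
    for r in range(n_replicates):
        y_shuf = y[rng.permutation(y.size)]
        rep = EnvForest(
            env,
            pd.Series(y_shuf, index=env.index),
            n_trees=null_n_trees,
            mtry=mtry,
            seed=int(rng.integers(0, 2**31 - 1)),
        ).fit()
        null_imp[r] = rep.importance.to_numpy()
    observed = obs.importance.to_numpy()
    exceed = (null_imp >= observed[None, :]).sum(axis=0)
    if plus_one:
        p = (exceed + 1) / (n_replicates + 1)
    else:
        p = exceed / n_replicates
    q = multipletests(p, method="fdr_bh")[1]
    direction = [
        float(np.sign(stats.spearmanr(env[c], response).statistic)) for c in env.columns
    ]
    return pd.DataFrame(
        {
            "variable": list(env.columns),
            "observed_importance": observed,
            "null_q50": np.quantile(null_imp, 0.5, axis=0),
            "null_q95": np.quantile(null_imp, 0.95, axis=0),
            "p": p,
            "q": q,
            "significant": q < alpha,
            "direction": direction,
        }
    ).set_index("variable")
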