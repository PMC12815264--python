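"""Genome-pair logistic regression of HGT on ecology and phylogeny.

The focal model predicts whether a genome pair (cross-genus or above, both
genomes passing the prevalence filter) is connected by at least one HGT
event, from: binary co-occurrence, patristic distance, per-variable absolute
differences in median environmental values, and a categorical size-fraction
class. Continuous predictors are transformed with ordered quantile
normalization (orderNorm) so one unit corresponds to one standard deviation.

:class:`PairLogit` / :class:`PairLogitResults` expose the fit in the
model/results idiom; :func:`fit_logistic` is the functional wrapper. The
module also provides VIF diagnostics, AIC model comparison, coefficient ->
odds conversion, and a collider-bias simulation showing how conditioning on
HGT induces a spurious distance difference between co-occurrence strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from hgtcooc.cooccurrence import FractionClass
from hgtcooc.detect import HGTEvent, assign_divergence_level

FRACTION_REFERENCE = "mixed_or_unclassified"


# ---------------------------------------------------------------------------
# orderNorm
# ---------------------------------------------------------------------------


def ordernorm(x) -> np.ndarray:
    """Ordered quantile normalization: ranks mapped to normal quantiles.

    Average ranks for ties, mapped through Phi^-1((rank - 0.5) / n). The
    transform is monotone and rank-invariant; a constant vector is rejected.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("ordernorm expects a 1-d vector")
    if arr.size < 3 or not np.isfinite(arr).all():
        raise ValueError("ordernorm requires >= 3 finite values")
    if np.all(arr == arr[0]):
        raise ValueError("ordernorm undefined for a constant vector")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.5) / arr.size)


# ---------------------------------------------------------------------------
# Pair feature table
# ---------------------------------------------------------------------------


def genome_env_medians(present: pd.DataFrame, env: pd.DataFrame) -> pd.DataFrame:
    """Per-genome median of each environmental variable over occupied samples."""
    env = env.reindex(present.index)
    rows = {}
    for g in present.columns:
        occupied = present.index[present[g]]
        rows[g] = env.loc[occupied].median() if len(occupied) else env.iloc[0] * np.nan
    return pd.DataFrame.from_dict(rows, orient="index")


def build_pair_table(
    events: list[HGTEvent],
    cooc: pd.DataFrame,
    patristic: pd.DataFrame,
    env_medians: pd.DataFrame,
    fraction_classes: list[FractionClass],
    taxonomy: dict[str, dict[str, str]],
    retained_genomes: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the genome-pair feature table for the focal regression.

    One row per unordered cross-genus pair of retained genomes: the binary
    HGT response, the binary co-occurrence flag, patristic distance,
    |median_a - median_b| per environmental variable, the pair's
    size-fraction class, and orderNorm-transformed copies (suffix ``_t``) of
    the continuous columns.
    """
    genomes = sorted(retained_genomes if retained_genomes is not None else cooc_genomes(cooc))
    for g in genomes:
        if g not in patristic.index:
            raise KeyError(f"genome {g} missing from patristic matrix")
        if g not in env_medians.index:
            raise KeyError(f"genome {g} missing from environmental medians")
        if g not in taxonomy:
            raise KeyError(f"genome {g} missing from taxonomy")

    event_pairs = {tuple(sorted((e.genome_a, e.genome_b))) for e in events}
    sig = {
        tuple(sorted((r.genome_a, r.genome_b))): bool(r.significant)
        for r in cooc.itertuples()
    }
    frac = {f.genome_id: f.fraction_class for f in fraction_classes}
    env_vars = list(env_medians.columns)

    rows = []
    for a, b in combinations(genomes, 2):
        if assign_divergence_level(taxonomy[a], taxonomy[b]) == "within_genus":
            continue
        row = {
            "genome_a": a,
            "genome_b": b,
            "hgt": (a, b) in event_pairs,
            "cooccur": sig.get((a, b), False),
            "phylo_dist": float(patristic.loc[a, b]),
            "fraction_class": _pair_fraction_class(frac.get(a), frac.get(b)),
        }
        for v in env_vars:
            row[f"{v}_diff"] = abs(float(env_medians.loc[a, v] - env_medians.loc[b, v]))
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no cross-genus genome pair available")
    for colname in ["phylo_dist", *(f"{v}_diff" for v in env_vars)]:
        vals = table[colname].to_numpy()
        table[f"{colname}_t"] = (
            ordernorm(vals) if not np.all(vals == vals[0]) else 0.0
        )
    return table


def cooc_genomes(cooc: pd.DataFrame) -> list[str]:
    return sorted(set(cooc["genome_a"]) | set(cooc["genome_b"]))


def _pair_fraction_class(cls_a: str | None, cls_b: str | None) -> str:
    if cls_a == cls_b and cls_a in ("free_living", "combined_fl_pa"):
        return cls_a
    return FRACTION_REFERENCE


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Coefficient table and fit statistics of one logistic regression."""

    coefficients: pd.DataFrame  # estimate, se, ci_low, ci_high, z, p per term
    intercept: float
    log_likelihood: float
    aic: float
    n_rows: int
    predictors: list[str]
    separation_flag: bool = False

    def coef(self, name: str) -> float:
        return float(self.coefficients.loc[name, "estimate"])


class PairLogit:
    """Logistic regression of the pair-level HGT response.

    Parameters
    ----------
    table
        Pair feature table (see :func:`build_pair_table`) or any DataFrame
        with a boolean response column and predictor columns.
    predictors
        Columns to include. Categorical (object/category dtype) columns are
        dummy-coded against :data:`FRACTION_REFERENCE` when present,
        otherwise against the first category.
    response
        Boolean response column name.
    """

    def __init__(
        self, table: pd.DataFrame, predictors: list[str], response: str = "hgt"
    ) -> None:
        self.table = table.reset_index(drop=True)
        self.predictors = list(predictors)
        self.response = response
        y = table[response].astype(float)
        if y.nunique() < 2:
            raise ValueError("response must contain both classes")
        X = _design_matrix(self.table, self.predictors)
        if len(table) <= X.shape[1] + 1:
            raise ValueError("more parameters than rows")
        self._y = y.to_numpy()
        self._X = sm.add_constant(X)

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, predictors: list[str], response: str = "hgt"
    ) -> "PairLogit":
        return cls(table, predictors, response)

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "PairLogitResults":
        model = sm.GLM(self._y, self._X, family=sm.families.Binomial())
        separation = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(tol=tol, maxiter=maxiter)
            for w in caught:
                if "separation" in str(w.message).lower():
                    separation = True
        if not res.converged and not separation:
            raise RuntimeError("logistic regression did not converge")
        if np.abs(res.params.iloc[1:] if hasattr(res.params, "iloc") else res.params[1:]).max() > 15:
            separation = True
        return PairLogitResults(self, res, separation)


class PairLogitResults:
    """Results wrapper: coefficient table, AIC, odds conversions, summary."""

    def __init__(self, model: PairLogit, res, separation: bool) -> None:
        self.model = model
        self._res = res
        params = np.asarray(res.params)
        se = np.asarray(res.bse)
        names = list(model._X.columns)
        tab = pd.DataFrame(
            {
                "estimate": params,
                "se": se,
                "ci_low": params - 1.96 * se,
                "ci_high": params + 1.96 * se,
                "z": params / se,
                "p": 2 * stats.norm.sf(np.abs(params / se)),
            },
            index=names,
        )
        self.fit_result = ModelFit(
            coefficients=tab.drop(index="const"),
            intercept=float(tab.loc["const", "estimate"]),
            log_likelihood=float(res.llf),
            aic=float(res.aic),
            n_rows=int(model._X.shape[0]),
            predictors=model.predictors,
            separation_flag=separation,
        )
        if separation:
            warnings.warn("possible complete separation; coefficients unreliable")

    @property
    def coefficients(self) -> pd.DataFrame:
        return self.fit_result.coefficients

    @property
    def aic(self) -> float:
        return self.fit_result.aic

    @property
    def llf(self) -> float:
        return self.fit_result.log_likelihood

    def odds(self, term: str) -> "OddsEffect":
        return odds_from_coefficient(self.fit_result.coef(term))

    def summary(self) -> str:
        f = self.fit_result
        lines = [
            "Pair-level logistic regression (HGT ~ ecology + phylogeny)",
            f"  n = {f.n_rows}, logLik = {f.log_likelihood:.2f}, AIC = {f.aic:.2f}",
            f"  intercept = {f.intercept:.3f}"
            + ("   [separation warning]" if f.separation_flag else ""),
            "",
            f"  {'term':<28}{'coef':>9}{'se':>8}{'ci95':>20}{'p':>10}",
        ]
        for name, r in f.coefficients.iterrows():
            ci = f"[{r.ci_low: .2f}, {r.ci_high: .2f}]"
            lines.append(
                f"  {name:<28}{r.estimate:>9.3f}{r.se:>8.3f}{ci:>20}{r.p:>10.3g}"
            )
        return "\n".join(lines)


def _design_matrix(table: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    parts = []
    for col in predictors:
        s = table[col]
        if s.dtype == bool:
            parts.append(s.astype(float).rename(col))
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            cats = sorted(s.unique())
            ref = FRACTION_REFERENCE if FRACTION_REFERENCE in cats else cats[0]
            for cat in cats:
                if cat == ref:
                    continue
                parts.append((s == cat).astype(float).rename(f"{col}[{cat}]"))
        else:
            parts.append(s.astype(float).rename(col))
    return pd.concat(parts, axis=1)


def fit_logistic(
    table: pd.DataFrame, predictors: list[str], response: str = "hgt"
) -> ModelFit:
    """Functional wrapper over :class:`PairLogit`."""
    return PairLogit(table, predictors, response).fit().fit_result


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def vif(table: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factor per predictor term.

    Continuous and boolean predictors get the classic VIF_j = 1/(1 - R^2_j);
    categorical terms are dummy-coded and get the generalized VIF
    det(R_11) * det(R_22) / det(R) over the correlation matrix. Exact
    collinearity is reported as infinity.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = _design_matrix(table, predictors)
    cols_of: dict[str, list[str]] = {}
    for term in predictors:
        cols_of[term] = [c for c in X.columns if c == term or c.startswith(f"{term}[")]
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    det_R = np.linalg.det(R)
    out = {}
    idx = {c: i for i, c in enumerate(X.columns)}
    for term, cols in cols_of.items():
        i1 = [idx[c] for c in cols]
        i2 = [i for i in range(len(X.columns)) if i not in i1]
        if det_R <= 1e-12:
            out[term] = np.inf
            continue
        d1 = np.linalg.det(R[np.ix_(i1, i1)])
        d2 = np.linalg.det(R[np.ix_(i2, i2)]) if i2 else 1.0
        out[term] = float(d1 * d2 / det_R)
    return pd.Series(out, name="vif")


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits by AIC (all on identical rows) with deltas vs the best."""
    ns = {f.n_rows for f in fits}
    if len(ns) != 1:
        raise ValueError("models fitted on differing row counts cannot be compared")
    df = pd.DataFrame(
        {
            "predictors": ["+".join(f.predictors) for f in fits],
            "k": [len(f.coefficients) + 1 for f in fits],
            "log_likelihood": [f.log_likelihood for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values("aic", kind="mergesort")
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df.reset_index(drop=True)


@dataclass
class OddsEffect:
    """exp(beta) with the reciprocal reported for negative coefficients."""

    beta: float
    fold: float
    fold_decrease: float | None = None


def odds_from_coefficient(beta: float) -> OddsEffect:
    """Convert a log-odds coefficient to a fold change in odds.

    A coefficient of 2.26 is a 9.58-fold increase in the odds; a negative
    coefficient additionally reports the fold *decrease* 1/exp(beta)
    (e.g. -1.66 -> 5.26-fold decrease).
    """
    if not np.isfinite(beta):
        raise ValueError("coefficient must be finite")
    fold = float(np.exp(beta))
    return OddsEffect(
        beta=float(beta),
        fold=fold,
        fold_decrease=float(1.0 / fold) if beta < 0 else None,
    )


def duplicate_pair_table(table: pd.DataFrame) -> pd.DataFrame:
    """Duplicate the pair table for a per-genome random-effect design.

    Each pair appears twice, once attributed to each member genome
    (``genome_id`` column), so a mixed model can control for genomes that
    dominate many comparisons. Because rows are duplicated, variability
    estimates from such a model are not trustworthy; no mixed model is
    fitted here — this constructor only prepares the design table.
    """
    first = table.copy()
    first["genome_id"] = first["genome_a"]
    second = table.copy()
    second["genome_id"] = second["genome_b"]
    return pd.concat([first, second], ignore_index=True)


# ---------------------------------------------------------------------------
# Simulations
# ---------------------------------------------------------------------------


def simulate_pair_table(
    n_pairs: int,
    effect_cooccur: float = 2.26,
    effect_phylo: float = -1.66,
    intercept: float = -3.0,
    p_cooccur: float = 0.3,
    seed: int = 0,
    n_env: int = 2,
    env_effect: float = 0.2,
) -> pd.DataFrame:
    """Generative pair table: independent predictors, logistic HGT response.

    Phylogenetic distance and co-occurrence are drawn independently (so any
    conditional association between them is a collider artifact); the HGT
    probability follows the logistic model with the given effects, matching
    the magnitudes of the focal fit (positive co-occurrence, negative
    distance).
    """
    rng = np.random.default_rng(seed)
    cooccur = rng.random(n_pairs) < p_cooccur
    phylo = rng.normal(size=n_pairs)  # already on the transformed (z) scale
    logit = intercept + effect_cooccur * cooccur + effect_phylo * phylo
    cols = {"cooccur": cooccur, "phylo_dist_t": phylo}
    for i in range(n_env):
        e = rng.normal(size=n_pairs)
        logit = logit + env_effect * e
        cols[f"env{i}_diff_t"] = e
    p = 1.0 / (1.0 + np.exp(-logit))
    cols["hgt"] = rng.random(n_pairs) < p
    return pd.DataFrame(cols)


def collider_simulation(
    n_pairs: int = 100_000,
    effect_cooccur: float = 2.26,
    effect_phylo: float = -1.66,
    seed: int = 7,
    intercept: float = -3.0,
    p_cooccur: float = 0.3,
) -> pd.DataFrame:
    """Show the collider pattern: conditioning on HGT links its causes.

    With distance and co-occurrence independent by construction, among
    HGT-connected pairs the non-co-occurring stratum must be closer on
    average (it needed low distance to achieve HGT). Returns mean distance
    per (hgt-conditioning, cooccurrence) stratum.
    """
    table = simulate_pair_table(
        n_pairs,
        effect_cooccur=effect_cooccur,
        effect_phylo=effect_phylo,
        intercept=intercept,
        p_cooccur=p_cooccur,
        seed=seed,
        n_env=0,
    )
    rows = []
    for condition, sub in (
        ("all_pairs", table),
        ("hgt_only", table[table["hgt"]]),
    ):
        for cooc_val, name in ((True, "cooccurring"), (False, "non_cooccurring")):
            sel = sub[sub["cooccur"] == cooc_val]
            rows.append(
                {
                    "condition": condition,
                    "stratum": name,
                    "n": len(sel),
                    "mean_phylo_dist": float(sel["phylo_dist_t"].mean()),
                }
            )
    return pd.DataFrame(rows)
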