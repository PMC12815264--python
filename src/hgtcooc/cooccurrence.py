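"""Genome presence calling, co-occurrence statistics and prevalence metrics.

Presence is called from breadth of coverage (>= 30% of a genome covered by at
least one read); RPKM values of absent genomes are zeroed. Genomes present in
fewer than 10 samples are excluded, as are samples with no present genome.
Co-occurrence is quantified three ways: an upper-tail hypergeometric test
with a Benjamini-Hochberg correction over all tested pairs (the focal,
binary definition of "significantly co-occurring": q < 0.05 and
observed/expected ratio > 1), a simple overlap fraction
|S1 n S2| / min(|S1|, |S2|), and compositional proportionality (rho_p on
centered log-ratios) of RPKM profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PresenceMatrix:
    """Presence calls plus the post-zeroing abundance matrix."""

    breadth: pd.DataFrame
    rpkm: pd.DataFrame  # zeroed where absent
    present: pd.DataFrame  # boolean
    presence_threshold: float


def call_presence(
    breadth: pd.DataFrame, rpkm: pd.DataFrame, presence_threshold: float = 0.30
) -> PresenceMatrix:
    """Call genomes present where breadth >= threshold; zero RPKM elsewhere."""
    if breadth.shape != rpkm.shape or not breadth.columns.equals(rpkm.columns):
        raise ValueError("breadth and rpkm matrices must share shape and labels")
    if ((breadth < 0) | (breadth > 1)).any().any():
        raise ValueError("breadth values must lie in [0, 1]")
    if (rpkm < 0).any().any():
        raise ValueError("rpkm values must be non-negative")
    present = breadth >= presence_threshold
    return PresenceMatrix(
        breadth=breadth.copy(),
        rpkm=rpkm.where(present, 0.0),
        present=present,
        presence_threshold=presence_threshold,
    )


def filter_prevalence(
    present: pd.DataFrame, min_samples: int = 10
) -> tuple[list[str], list[str]]:
    """Genomes present in >= ``min_samples`` samples, and empty samples to drop."""
    counts = present.sum(axis=0)
    retained = sorted(counts.index[counts >= min_samples])
    empty_samples = sorted(present.index[~present.any(axis=1)])
    return retained, empty_samples


def drop_empty_samples(present: pd.DataFrame) -> pd.DataFrame:
    return present.loc[present.any(axis=1)]


def hypergeom_cooccurrence(
    present: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    midp: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric co-occurrence tests for genome pairs.

    For a pair with per-genome prevalences k_a, k_b over N samples and
    observed joint count ``obs``, p = P[X >= obs] with
    X ~ Hypergeometric(N, k_a, k_b) (the observed table included). The
    co-occurrence ratio is obs / (k_a * k_b / N). BH correction is applied
    jointly over all tested pairs; a pair is significant when q < ``alpha``
    and ratio > 1.

    ``midp=True`` reports the mid-p variant P[X > obs] + P[X = obs]/2
    instead: the exact convention is conservative on discrete support, so
    its null p-values are super-uniform, whereas mid-p is near-uniform —
    useful for calibration diagnostics.
    """
    N = present.shape[0]
    if N == 0:
        raise ValueError("presence matrix has no samples")
    if pairs is None:
        pairs = list(combinations(sorted(present.columns), 2))
    mat = present.to_numpy(dtype=bool)
    col = {g: i for i, g in enumerate(present.columns)}
    rows = []
    for a, b in pairs:
        va, vb = mat[:, col[a]], mat[:, col[b]]
        k_a, k_b = int(va.sum()), int(vb.sum())
        obs = int((va & vb).sum())
        expected = k_a * k_b / N
        ratio = obs / expected if expected > 0 else 0.0
        if midp:
            p = float(
                stats.hypergeom.sf(obs, N, k_a, k_b)
                + 0.5 * stats.hypergeom.pmf(obs, N, k_a, k_b)
            )
        else:
            p = float(stats.hypergeom.sf(obs - 1, N, k_a, k_b))
        rows.append(
            {
                "genome_a": a,
                "genome_b": b,
                "n_samples": N,
                "k_a": k_a,
                "k_b": k_b,
                "obs": obs,
                "expected": expected,
                "ratio": ratio,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = (df["q"] < alpha) & (df["ratio"] > 1)
    return df


def simple_overlap(present: pd.DataFrame, pair: tuple[str, str]) -> float:
    """|S_a n S_b| / min(|S_a|, |S_b|) over the samples containing each genome."""
    a, b = pair
    va = present[a].to_numpy(dtype=bool)
    vb = present[b].to_numpy(dtype=bool)
    k_a, k_b = int(va.sum()), int(vb.sum())
    if k_a == 0 or k_b == 0:
        raise ValueError(f"simple overlap undefined: {a if k_a == 0 else b} never present")
    return int((va & vb).sum()) / min(k_a, k_b)


def proportionality_rho(rpkm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Proportionality rho_p between genome abundance profiles.

    Per sample, ``pseudocount`` is added, values are closed to proportions
    and centered-log-ratio transformed; then
    rho_p(i, j) = 1 - var(clr_i - clr_j) / (var(clr_i) + var(clr_j)).
    Genomes with zero clr variance get missing values against all partners.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (rpkm < 0).any().any():
        raise ValueError("rpkm values must be non-negative")
    x = rpkm.to_numpy(dtype=float) + pseudocount
    props = x / x.sum(axis=1, keepdims=True)
    log_p = np.log(props)
    clr = log_p - log_p.mean(axis=1, keepdims=True)
    var = clr.var(axis=0, ddof=1)
    n = clr.shape[1]
    centered = clr - clr.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / (clr.shape[0] - 1)
    denom = var[:, None] + var[None, :]
    var_diff = var[:, None] + var[None, :] - 2 * cov
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 1.0 - var_diff / denom
    zero_var = var == 0
    rho[zero_var, :] = np.nan
    rho[:, zero_var] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho[zero_var, zero_var] = np.nan if zero_var.any() else 1.0
    return pd.DataFrame(rho, index=rpkm.columns, columns=rpkm.columns)


@dataclass
class FractionClass:
    genome_id: str
    fraction_class: str  # free_living / combined_fl_pa / unclassified
    support: float  # fraction of occupied samples in the winning group
    median_rpkm: dict[str, float]


_FRACTION_GROUPS = ("free_living", "combined_fl_pa")


def classify_size_fraction(
    present: pd.DataFrame,
    rpkm: pd.DataFrame,
    sample_fractions: pd.Series,
    support_threshold: float = 0.75,
) -> list[FractionClass]:
    """Associate genomes with a size-fraction group.

    A genome is classified to a group when strictly more than
    ``support_threshold`` of the samples containing it belong to that group
    AND its median RPKM (over occupied samples) is highest in that group.
    Samples outside both groups still count in the support denominator.
    """
    out: list[FractionClass] = []
    frac = sample_fractions.reindex(present.index)
    for g in present.columns:
        occupied = present.index[present[g]]
        if len(occupied) == 0:
            out.append(FractionClass(g, "unclassified", 0.0, {}))
            continue
        labels = frac.loc[occupied]
        medians = {
            grp: float(rpkm.loc[occupied[labels == grp], g].median())
            if (labels == grp).any()
            else float("nan")
            for grp in _FRACTION_GROUPS
        }
        supports = {grp: float((labels == grp).mean()) for grp in _FRACTION_GROUPS}
        winner = max(_FRACTION_GROUPS, key=lambda grp: supports[grp])
        other = next(grp for grp in _FRACTION_GROUPS if grp != winner)
        ok = supports[winner] > support_threshold and (
            np.isnan(medians[other]) or medians[winner] > medians[other]
        )
        out.append(
            FractionClass(
                genome_id=g,
                fraction_class=winner if ok else "unclassified",
                support=supports[winner],
                median_rpkm=medians,
            )
        )
    return out


def feature_prevalence(present: pd.DataFrame, flags: dict[str, bool]) -> pd.Series:
    """Per-sample fraction of present genomes carrying a feature.

    Samples with zero present genomes get a missing value.
    """
    missing = set(present.columns) - set(flags)
    if missing:
        raise ValueError(f"feature flags missing for genomes: {sorted(missing)[:5]}")
    flag_vec = np.array([bool(flags[g]) for g in present.columns])
    mat = present.to_numpy(dtype=bool)
    totals = mat.sum(axis=1)
    hits = (mat & flag_vec[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, hits / np.maximum(totals, 1), np.nan)
    return pd.Series(frac, index=present.index, name="prevalence")


def paired_fraction_test(
    prevalence_small: pd.Series, prevalence_large: pd.Series
) -> tuple[float, float]:
    """Fold change and paired Wilcoxon p for matched small/large fraction samples.

    Fold change is mean(large) / mean(small); the test is a two-sided
    signed-rank test on the paired differences (p = 1 when all differences
    are zero).
    """
    if len(prevalence_small) != len(prevalence_large):
        raise ValueError("paired series must have equal length")
    if len(prevalence_small) < 6:
        raise ValueError("paired test requires at least 6 samples")
    small = prevalence_small.to_numpy(dtype=float)
    large = prevalence_large.reindex(prevalence_small.index).to_numpy(dtype=float)
    fold = float(large.mean() / small.mean())
    diffs = large - small
    if np.all(diffs == 0):
        return fold, 1.0
    stat = stats.wilcoxon(large, small, alternative="two-sided")
    return fold, float(stat.pvalue)


def paired_feature_tests(
    features: dict[str, tuple[pd.Series, pd.Series]]
) -> pd.DataFrame:
    """Paired small-vs-large tests for several features with BH correction."""
    rows = []
    for name, (small, large) in sorted(features.items()):
        fold, p = paired_fraction_test(small, large)
        rows.append({"feature": name, "fold_change": fold, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
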