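"""Functional enrichment of horizontally transferred genes.

Cluster-level COG-category enrichment uses majority-rule category assignment
(ties and unannotated clusters excluded, as are the eukaryote-specific
categories A, B, Y, Z) and two-sided Fisher exact tests of "cluster in
category" x "cluster in >= 1 HGT relationship", BH-corrected within each
stratum (identity bin x divergence level, plus an unstratified sweep).
Mobile-genetic-element enrichment is tested at the gene level because the
MGE annotations are contig- or gene-level, not cluster-level.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hgtcooc.detect import GeneCluster, HGTEvent
from hgtcooc.records import GeneRecord

EXCLUDED_CATEGORIES = frozenset("ABYZ")  # eukaryote-specific


def assign_cluster_cog(
    clusters: list[GeneCluster], annotations: dict[str, str]
) -> dict[str, str | None]:
    """Majority-rule COG category per cluster.

    Each member gene may carry several single-letter categories; every
    letter votes. The most frequent category wins; ties and clusters with no
    annotated member are unassigned, and the excluded categories never vote.
    """
    out: dict[str, str | None] = {}
    for cluster in clusters:
        votes: Counter[str] = Counter()
        for gid in cluster.member_gene_ids:
            for letter in annotations.get(gid, ""):
                if letter not in EXCLUDED_CATEGORIES:
                    votes[letter] += 1
        if not votes:
            out[cluster.cluster_id] = None
            continue
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out[cluster.cluster_id] = None  # tie
        else:
            out[cluster.cluster_id] = ranked[0][0]
        cluster.majority_cog = out[cluster.cluster_id]
    return out


@dataclass
class EnrichmentResult:
    stratum: str
    category: str
    a: int  # in-category, HGT
    b: int  # in-category, non-HGT
    c: int  # other-category, HGT
    d: int  # other-category, non-HGT
    odds_ratio: float
    p: float
    q: float = float("nan")
    direction: str = ""


def hgt_clusters_by_stratum(events: list[HGTEvent]) -> dict[str, set[str]]:
    """Clusters with >= 1 HGT relationship, per (identity bin, level) stratum."""
    strata: dict[str, set[str]] = defaultdict(set)
    for e in events:
        if e.cluster_id is None:
            continue
        strata["all"].add(e.cluster_id)
        strata[f"{e.identity_bin}:{e.divergence_level}"].add(e.cluster_id)
    return dict(strata)


def cog_enrichment(
    cluster_cogs: dict[str, str | None],
    hgt_clusters: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher exact COG enrichment per stratum over the COG-assigned universe.

    For each stratum and category, the 2x2 compares clusters of that
    category in >= 1 HGT relationship against all other COG-assigned
    clusters; BH correction is applied within the stratum across categories.
    """
    universe = {cid: cat for cid, cat in cluster_cogs.items() if cat is not None}
    if not universe:
        raise ValueError("no COG-assigned clusters in the universe")
    categories = sorted(set(universe.values()))
    if len(categories) < 2:
        raise ValueError("need at least two categories for enrichment")
    rows: list[EnrichmentResult] = []
    for stratum in sorted(hgt_clusters):
        flagged = {cid for cid in hgt_clusters[stratum] if cid in universe}
        stratum_rows = []
        for cat in categories:
            in_cat = {cid for cid, c in universe.items() if c == cat}
            a = len(in_cat & flagged)
            b = len(in_cat) - a
            c = len(flagged) - a
            d = len(universe) - a - b - c
            odds = (a * d) / (b * c) if b * c > 0 else float("inf")
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            stratum_rows.append(
                EnrichmentResult(
                    stratum=stratum,
                    category=cat,
                    a=a,
                    b=b,
                    c=c,
                    d=d,
                    odds_ratio=odds,
                    p=p,
                    direction="enriched" if odds > 1 else ("depleted" if odds < 1 else "none"),
                )
            )
        qs = multipletests([r.p for r in stratum_rows], method="fdr_bh")[1]
        for r, q in zip(stratum_rows, qs):
            r.q = float(q)
        rows.extend(stratum_rows)
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "category": r.category,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "q": r.q,
                "direction": r.direction,
                "significant": r.q < alpha,
            }
            for r in rows
        ]
    )


def mge_fold_enrichment(
    genes: list[GeneRecord],
    hgt_gene_ids: set[str],
    flag_name: str,
) -> tuple[float, float, bool]:
    """Gene-level fold enrichment of an MGE flag among HGT genes.

    Returns (odds ratio, two-sided Fisher p, corrected_flag). A zero margin
    triggers the Haldane-Anscombe 0.5 correction on the odds ratio (flagged);
    the p-value is always from the uncorrected exact test. An odds ratio
    below 1 corresponds to a 1/OR fold depletion (the provirus pattern).
    """
    a = b = c = d = 0
    for g in genes:
        flag = bool(getattr(g.mge_flags, flag_name))
        hgt = g.gene_id in hgt_gene_ids
        if flag and hgt:
            a += 1
        elif flag:
            b += 1
        elif hgt:
            c += 1
        else:
            d += 1
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    corrected = 0 in (a, b, c, d)
    if corrected:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), p, corrected
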