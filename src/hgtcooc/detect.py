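"""HGT calling from gene sequences.

Two complementary detectors:

* the focal *cluster-RBH* path: greedy full-length clustering of all genes at
  >= 95% identity and >= 95% mutual coverage (CD-HIT-style), then reciprocal
  best hits between genomes that differ at the genus level or above;
* the sensitive *region* path: exact k-mer seeds extended ungapped with an
  X-drop rule, reporting segments >= 500 bp at >= 95% identity, intersected
  with gene annotations.

Both paths exclude within-genus comparisons (high identity there is expected
from vertical descent) and drop events on contigs shorter than 5 kb after
calling. Events are binned by identity (>= 99% "recent" vs 95-99% "older")
and by the lowest taxonomic level at which the two genomes differ.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from hgtcooc.records import DIVERGENCE_LEVELS, RANKS, GeneRecord, GenomeRecord

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i


def _enc(seq: str) -> np.ndarray:
    arr = _ENCODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence alphabet must be ACGT")
    return arr


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction identity between two nucleotide sequences.

    Equal lengths: 1 - Hamming/length (the aligned-cluster convention).
    Unequal lengths: 1 - editDistance/max(length), a global-alignment
    fallback; with mutual coverage >= 0.95 the two conventions differ by a
    bounded amount.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if len(seq_a) == len(seq_b):
        return 1.0 - int(np.count_nonzero(_enc(seq_a) != _enc(seq_b))) / len(seq_a)
    d = edlib.align(seq_a, seq_b, task="distance")["editDistance"]
    return 1.0 - d / max(len(seq_a), len(seq_b))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class GeneCluster:
    cluster_id: str
    member_gene_ids: list[str]
    representative_gene_id: str
    majority_cog: str | None = None

    def __len__(self) -> int:
        return len(self.member_gene_ids)


_PREFILTER_K = 16  # lossless for identity >= 0.95: mismatch spacing pigeonhole


def _kmer_set(arr: np.ndarray, k: int) -> np.ndarray:
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    base = arr.astype(np.int64)
    code = np.zeros(arr.size - k + 1, dtype=np.int64)
    for i in range(k):
        code = code * 4 + base[i : arr.size - k + 1 + i]
    return np.unique(code)


def cluster_genes(
    genes: list[GeneRecord], id_threshold: float = 0.95, coverage: float = 0.95
) -> list[GeneCluster]:
    """Greedy incremental clustering against cluster representatives.

    Genes are processed in descending length (ties by gene_id); each joins
    the first existing cluster whose representative it matches at
    ``id_threshold`` identity with a length ratio of at least ``coverage``
    (global alignment covers both sequences end to end, so the length-ratio
    check is the operative coverage condition); otherwise it founds a new
    cluster. A shared-k-mer prefilter restricts the representatives examined;
    at the default thresholds any qualifying pair necessarily shares a
    16-mer, so the partition is identical to the all-pairs greedy scan.
    """
    if not genes:
        raise ValueError("at least one gene required")
    order = sorted(genes, key=lambda g: (-len(g.seq), g.gene_id))
    clusters: list[GeneCluster] = []
    reps: list[tuple[np.ndarray, str]] = []
    index: dict[int, list[int]] = defaultdict(list)

    for gene in order:
        arr = _enc(gene.seq)
        kmers = _kmer_set(arr, _PREFILTER_K)
        candidates: set[int] = set()
        for code in kmers:
            candidates.update(index.get(int(code), ()))
        joined = False
        for ci in sorted(candidates):
            rep, rep_seq = reps[ci]
            lo, hi = min(arr.size, rep.size), max(arr.size, rep.size)
            if lo / hi < coverage:
                continue
            if arr.size == rep.size:
                ident = 1.0 - int(np.count_nonzero(arr != rep)) / arr.size
            else:
                ident = pairwise_identity(gene.seq, rep_seq)
            if ident >= id_threshold:
                clusters[ci].member_gene_ids.append(gene.gene_id)
                joined = True
                break
        if not joined:
            ci = len(clusters)
            clusters.append(
                GeneCluster(
                    cluster_id=f"C{ci:05d}",
                    member_gene_ids=[gene.gene_id],
                    representative_gene_id=gene.gene_id,
                )
            )
            reps.append((arr, gene.seq))
            for code in kmers:
                index[int(code)].append(ci)
    return clusters


# ---------------------------------------------------------------------------
# Divergence level
# ---------------------------------------------------------------------------


def assign_divergence_level(tax_a: dict[str, str], tax_b: dict[str, str]) -> str:
    """Lowest taxonomic level at which two genomes differ.

    Returns one of genus..domain, or ``"within_genus"`` for pairs sharing a
    genus (including same-species pairs), which are excluded from event
    calling.
    """
    for tax, name in ((tax_a, "first"), (tax_b, "second")):
        missing = [r for r in RANKS if not tax.get(r)]
        if missing:
            raise ValueError(f"{name} taxonomy missing rank label(s): {missing}")
    for rank in RANKS:  # domain -> species
        if tax_a[rank] != tax_b[rank]:
            return "within_genus" if rank == "species" else rank
    return "within_genus"


def identity_bin(identity: float) -> str:
    return "ge99" if identity >= 0.99 else "95to99"


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HGTEvent:
    """One putative transfer between two genomes (canonically ordered)."""

    genome_a: str
    genome_b: str
    gene_a: str | None
    gene_b: str | None
    identity: float
    identity_bin: str
    divergence_level: str
    method: str  # "cluster_rbh" or "region"
    cluster_id: str | None = None
    region: tuple[str, int, int] | None = None  # (contig, start, end) for region path

    def pair(self) -> tuple[str, str]:
        return (self.genome_a, self.genome_b)


def events_to_frame(events: list[HGTEvent]) -> pd.DataFrame:
    rows = [
        {
            "genome_a": e.genome_a,
            "genome_b": e.genome_b,
            "gene_a": e.gene_a or "",
            "gene_b": e.gene_b or "",
            "identity": e.identity,
            "identity_bin": e.identity_bin,
            "divergence_level": e.divergence_level,
            "method": e.method,
            "cluster_id": e.cluster_id or "",
            "region_contig": e.region[0] if e.region else "",
            "region_start": e.region[1] if e.region else -1,
            "region_end": e.region[2] if e.region else -1,
        }
        for e in events
    ]
    cols = [
        "genome_a",
        "genome_b",
        "gene_a",
        "gene_b",
        "identity",
        "identity_bin",
        "divergence_level",
        "method",
        "cluster_id",
        "region_contig",
        "region_start",
        "region_end",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(cols[:4], kind="mergesort").reset_index(drop=True)


def call_rbh_hgt(
    clusters: list[GeneCluster],
    genes: dict[str, GeneRecord],
    taxonomy: dict[str, dict[str, str]],
    contig_lengths: dict[str, int],
    min_contig: int = 5000,
    min_identity: float = 0.95,
) -> list[HGTEvent]:
    """Reciprocal-best-hit HGT events from multi-genome clusters.

    Within each cluster, for every genome pair differing at the genus level
    or above, a gene pair is an event iff each gene is the other's
    highest-identity match among the partner genome's cluster members
    (ties broken by gene_id), with identity >= ``min_identity``. At most one
    event is kept per (cluster, genome pair); events with either gene on a
    contig shorter than ``min_contig`` are removed afterwards, per the
    stated order of operations.
    """
    events: list[HGTEvent] = []
    for cluster in clusters:
        if len(cluster) < 2:
            continue
        by_genome: dict[str, list[GeneRecord]] = defaultdict(list)
        for gid in cluster.member_gene_ids:
            gene = genes[gid]
            if gene.genome_id not in taxonomy:
                raise KeyError(f"genome {gene.genome_id} missing from taxonomy")
            by_genome[gene.genome_id].append(gene)
        genome_ids = sorted(by_genome)
        for i, ga in enumerate(genome_ids):
            for gb in genome_ids[i + 1 :]:
                level = assign_divergence_level(taxonomy[ga], taxonomy[gb])
                if level == "within_genus":
                    continue
                event = _best_reciprocal_pair(
                    by_genome[ga], by_genome[gb], min_identity
                )
                if event is None:
                    continue
                gene_a, gene_b, ident = event
                events.append(
                    HGTEvent(
                        genome_a=ga,
                        genome_b=gb,
                        gene_a=gene_a.gene_id,
                        gene_b=gene_b.gene_id,
                        identity=ident,
                        identity_bin=identity_bin(ident),
                        divergence_level=level,
                        method="cluster_rbh",
                        cluster_id=cluster.cluster_id,
                    )
                )
    return [
        e
        for e in events
        if contig_lengths[genes[e.gene_a].contig_id] >= min_contig
        and contig_lengths[genes[e.gene_b].contig_id] >= min_contig
    ]


def _best_reciprocal_pair(
    genes_a: list[GeneRecord], genes_b: list[GeneRecord], min_identity: float
) -> tuple[GeneRecord, GeneRecord, float] | None:
    ident = {
        (ga.gene_id, gb.gene_id): pairwise_identity(ga.seq, gb.seq)
        for ga in genes_a
        for gb in genes_b
    }

    def best(gene_id: str, partners: list[GeneRecord], flip: bool) -> str:
        def key(p: GeneRecord) -> tuple[float, str]:
            pair = (p.gene_id, gene_id) if flip else (gene_id, p.gene_id)
            return (-ident[pair], p.gene_id)

        return min(partners, key=key).gene_id

    reciprocal: list[tuple[float, str, str]] = []
    for ga in genes_a:
        b_best = best(ga.gene_id, genes_b, flip=False)
        if best(b_best, genes_a, flip=True) == ga.gene_id:
            score = ident[(ga.gene_id, b_best)]
            if score >= min_identity:
                reciprocal.append((score, ga.gene_id, b_best))
    if not reciprocal:
        return None
    score, aid, bid = max(reciprocal, key=lambda t: (t[0], t[1], t[2]))
    ga = next(g for g in genes_a if g.gene_id == aid)
    gb = next(g for g in genes_b if g.gene_id == bid)
    return ga, gb, score


# ---------------------------------------------------------------------------
# Region path: seed-and-extend identity segments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentMatch:
    """An ungapped high-identity segment between two contigs."""

    genome_a: str
    contig_a: str
    start_a: int
    end_a: int
    genome_b: str
    contig_b: str
    start_b: int
    end_b: int
    length: int
    identity: float
    score: int  # matches - mismatches


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    if arr.size < k:
        return np.empty(0, dtype=np.uint64)
    base = arr.astype(np.uint64)
    code = np.zeros(arr.size - k + 1, dtype=np.uint64)
    for i in range(k):
        code = (code << np.uint64(2)) | base[i : arr.size - k + 1 + i]
    return code


def _contig_index(contig, k: int):
    """Encoded sequence and (sorted) k-mer codes, memoized on the contig."""
    cache = getattr(contig, "_kmer_cache", None)
    if cache is not None and cache[0] == k:
        return cache[1]
    arr = _enc(contig.seq)
    codes = _kmer_codes(arr, k)
    order = np.argsort(codes, kind="stable")
    value = (arr, codes, order, codes[order])
    contig._kmer_cache = (k, value)
    return value


def _extend_one_way(
    a: np.ndarray,
    b: np.ndarray,
    i0: int,
    j0: int,
    step: int,
    base_matches: int,
    base_len: int,
    min_id: float,
    xdrop: int,
) -> int:
    """Extend from one end of a seeded run in one direction.

    The extension advances while the running identity of run + extension
    stays at or above ``min_id``, with an X-drop stop (extension
    match-mismatch score falling ``xdrop`` below its maximum) as a secondary
    rule; the result is trimmed back to the furthest matching position.
    Returns the number of bases gained.
    """
    matches, length = base_matches, base_len
    score = best = 0
    best_at = 0
    gained = 0
    i, j = i0, j0
    while 0 <= i < a.size and 0 <= j < b.size:
        hit = a[i] == b[j]
        length += 1
        gained += 1
        if hit:
            matches += 1
            score += 1
        else:
            score -= 1
        if matches / length < min_id:
            break
        if hit and score > best:
            best, best_at = score, gained
        if best - score > xdrop:
            break
        i += step
        j += step
    return best_at


def find_identity_segments(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    min_len: int = 500,
    min_id: float = 0.95,
    k: int = 31,
    xdrop: int = 20,
) -> list[SegmentMatch]:
    """Ungapped high-identity segments between two genomes' contigs.

    Exact shared k-mers seed diagonal chains which are extended in both
    directions while the extension's running identity stays at or above
    ``min_id``, with an X-drop stop (running match-mismatch score falling
    ``xdrop`` below its maximum) as a secondary rule. Overlapping extensions
    on the same diagonal are merged and segment identity is recomputed over
    the union; only segments of at least ``min_len`` bp and ``min_id``
    identity are reported. Deterministic for fixed inputs.
    """
    out: list[SegmentMatch] = []
    for ca in sorted(genome_a.contigs, key=lambda c: c.contig_id):
        arr_a, codes_a, order_a, sorted_a = _contig_index(ca, k)
        if codes_a.size == 0:
            continue
        for cb in sorted(genome_b.contigs, key=lambda c: c.contig_id):
            arr_b, codes_b, _ob, _sb = _contig_index(cb, k)
            if codes_b.size == 0:
                continue
            idx = np.searchsorted(sorted_a, codes_b)
            idx_clip = np.minimum(idx, sorted_a.size - 1)
            hit_mask = sorted_a[idx_clip] == codes_b
            if not hit_mask.any():
                continue
            # positions of each shared code in a
            diag_seeds: dict[int, list[int]] = defaultdict(list)
            hit_codes = codes_b[hit_mask]
            hit_pos_b = np.nonzero(hit_mask)[0]
            lo = np.searchsorted(sorted_a, hit_codes, side="left")
            hi = np.searchsorted(sorted_a, hit_codes, side="right")
            for code_lo, code_hi, pb in zip(lo, hi, hit_pos_b):
                for pa in order_a[code_lo:code_hi]:
                    diag_seeds[int(pa) - int(pb)].append(int(pa))
            for diag in sorted(diag_seeds):
                intervals: list[tuple[int, int]] = []
                for run_s, run_e in _chain_runs(sorted(set(diag_seeds[diag])), k):
                    sa, ea = run_s, run_e + k
                    base_len = ea - sa
                    base_matches = int(
                        np.count_nonzero(arr_a[sa:ea] == arr_b[sa - diag : ea - diag])
                    )
                    left = _extend_one_way(
                        arr_a, arr_b, sa - 1, sa - 1 - diag, -1,
                        base_matches, base_len, min_id, xdrop,
                    )
                    right = _extend_one_way(
                        arr_a, arr_b, ea, ea - diag, 1,
                        base_matches, base_len, min_id, xdrop,
                    )
                    intervals.append((sa - left, ea + right))
                for seg_s, seg_e in _merge_intervals(intervals):
                    matches = int(
                        np.count_nonzero(
                            arr_a[seg_s:seg_e] == arr_b[seg_s - diag : seg_e - diag]
                        )
                    )
                    length = seg_e - seg_s
                    ident = matches / length
                    if length >= min_len and ident >= min_id:
                        out.append(
                            SegmentMatch(
                                genome_a=genome_a.genome_id,
                                contig_a=ca.contig_id,
                                start_a=seg_s,
                                end_a=seg_e,
                                genome_b=genome_b.genome_id,
                                contig_b=cb.contig_id,
                                start_b=seg_s - diag,
                                end_b=seg_e - diag,
                                length=length,
                                identity=ident,
                                score=2 * matches - length,
                            )
                        )
    return sorted(out, key=lambda s: (s.contig_a, s.contig_b, s.start_a, s.start_b))


def _chain_runs(positions: list[int], k: int, max_gap: int = 300) -> list[tuple[int, int]]:
    """Chain seed start positions on one diagonal into runs."""
    runs: list[tuple[int, int]] = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev > max_gap:
            runs.append((start, prev))
            start = p
        prev = p
    runs.append((start, prev))
    return runs


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def call_region_hgt(
    segments: list[SegmentMatch],
    genomes: dict[str, GenomeRecord],
    taxonomy: dict[str, dict[str, str]],
    min_contig: int = 5000,
) -> list[HGTEvent]:
    """Region-method events: genes intersecting retained identity segments.

    For each genome pair, overlapping segments are resolved to the highest
    score (ties: longer, then lexicographic coordinates) before gene
    intersection; each gene overlapping a retained segment by >= 1 bp yields
    one event. Within-genus pairs are excluded and the ``min_contig`` filter
    applies as in the cluster path.
    """
    known_contigs = {c.contig_id for g in genomes.values() for c in g.contigs}
    for s in segments:
        for cid in (s.contig_a, s.contig_b):
            if cid not in known_contigs:
                raise KeyError(f"segment references unknown contig {cid}")

    by_pair: dict[tuple[str, str], list[SegmentMatch]] = defaultdict(list)
    for s in segments:
        by_pair[tuple(sorted((s.genome_a, s.genome_b)))].append(s)

    events: list[HGTEvent] = []
    for (ga, gb), segs in sorted(by_pair.items()):
        level = assign_divergence_level(taxonomy[ga], taxonomy[gb])
        if level == "within_genus":
            continue
        kept: list[SegmentMatch] = []
        for s in sorted(
            segs,
            key=lambda s: (-s.score, -s.length, s.contig_a, s.start_a, s.contig_b, s.start_b),
        ):
            if any(_segments_overlap(s, e) for e in kept):
                continue
            kept.append(s)
        for s in kept:
            for genome_id, contig_id, start, end, side in (
                (s.genome_a, s.contig_a, s.start_a, s.end_a, "a"),
                (s.genome_b, s.contig_b, s.start_b, s.end_b, "b"),
            ):
                contig = genomes[genome_id].contig(contig_id)
                if contig.length < min_contig:
                    continue
                for gene in contig.genes:
                    if gene.start < end and start < gene.end:
                        first = genome_id == ga
                        events.append(
                            HGTEvent(
                                genome_a=ga,
                                genome_b=gb,
                                gene_a=gene.gene_id if first else None,
                                gene_b=None if first else gene.gene_id,
                                identity=s.identity,
                                identity_bin=identity_bin(s.identity),
                                divergence_level=level,
                                method="region",
                                region=(contig_id, max(start, gene.start), min(end, gene.end)),
                            )
                        )
    return events


def _segments_overlap(s: SegmentMatch, e: SegmentMatch) -> bool:
    if s.contig_a == e.contig_a and s.start_a < e.end_a and e.start_a < s.end_a:
        return True
    if s.contig_b == e.contig_b and s.start_b < e.end_b and e.start_b < s.end_b:
        return True
    return False


# ---------------------------------------------------------------------------
# Per-level event rates
# ---------------------------------------------------------------------------


def events_per_level(
    events: list[HGTEvent], taxonomy: dict[str, dict[str, str]]
) -> pd.DataFrame:
    """Events and genome-pair counts per divergence level, with the rate
    normalized by the number of genome comparisons at that level."""
    ids = sorted(taxonomy)
    pair_counts = {level: 0 for level in DIVERGENCE_LEVELS}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            level = assign_divergence_level(taxonomy[a], taxonomy[b])
            if level != "within_genus":
                pair_counts[level] += 1
    event_counts = {level: 0 for level in DIVERGENCE_LEVELS}
    for e in events:
        event_counts[e.divergence_level] += 1
    rows = []
    for level in DIVERGENCE_LEVELS:
        n_pairs = pair_counts[level]
        rate = event_counts[level] / n_pairs if n_pairs else np.nan
        rows.append(
            {
                "level": level,
                "n_events": event_counts[level],
                "n_genome_pairs": n_pairs,
                "rate": rate,
            }
        )
    return pd.DataFrame(rows).set_index("level")
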