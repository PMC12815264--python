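"""Synthetic ocean-genome datasets with planted ground truth.

Everything the downstream analysis consumes is generated here: a
taxonomy-consistent ultrametric phylogeny, vertically diverged gene families,
planted HGT events at controlled identities and taxonomic gaps, a
presence/abundance matrix with niche-driven co-occurrence, and environmental
covariates with a planted link to HGT prevalence. The generator's defaults
define the study conditions for every acceptance property; ground truth for
each planted signal is recorded in :class:`~hgtcooc.records.PlantedTruth`.

Sequence evolution uses per-site independent substitution with probability
``1 - exp(-rate * branch_length)`` per branch, the replacement base uniform
over the three alternatives (a Jukes-Cantor-like process without indels), so
identity reduces to ``1 - Hamming/length``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hgtcooc.records import (
    RANKS,
    ContigRecord,
    GeneRecord,
    GenomeRecord,
    MGEFlags,
    PlantedEvent,
    PlantedTruth,
    TaxonomySpec,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: COG categories the generator draws from, with rough marine-pangenome
#: weights. X (mobilome) and V (defense) are common among transferred genes.
COG_CATEGORIES = "JKLDVTMNUOCGEFHIPQRSX"
_COG_WEIGHTS = np.array(
    [5, 6, 6, 2, 7, 4, 5, 2, 3, 4, 5, 6, 7, 3, 4, 4, 5, 3, 6, 8, 6], dtype=float
)
_RARE_EUK_CATEGORIES = "ABYZ"


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class PhyloNode:
    label: str
    rank: str  # "root", one of RANKS, or "genome"
    height: float
    children: list["PhyloNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """Ultrametric genome phylogeny with taxonomy-defined node heights."""

    root: PhyloNode

    @property
    def newick(self) -> str:
        return _to_newick(self.root) + ";"

    def leaf_ids(self) -> list[str]:
        out: list[str] = []

        def walk(n: PhyloNode) -> None:
            if n.is_leaf():
                out.append(n.label)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out


def _to_newick(node: PhyloNode, parent_height: float | None = None) -> str:
    # Collapse unary internal nodes by accumulating branch lengths so the
    # emitted newick has no degree-2 vertices.
    while len(node.children) == 1 and not node.children[0].is_leaf():
        node = PhyloNode(
            node.children[0].label,
            node.children[0].rank,
            node.children[0].height,
            node.children[0].children,
        )
    if len(node.children) == 1:
        node = node.children[0]
    if node.is_leaf():
        body = node.label
    else:
        parts = [_to_newick(c, node.height) for c in node.children]
        body = "(" + ",".join(parts) + ")"
    if parent_height is None:
        return body
    return f"{body}:{parent_height - node.height:.6f}"


def _rank_heights(spec: TaxonomySpec) -> dict[str, float]:
    """Height of the internal node representing a taxon at each rank.

    Two genomes whose lowest differing rank is r coalesce in the node of the
    rank immediately above r, so that node's height is divergence[r]/2.
    """
    h = {"root": spec.divergence["domain"] / 2}
    for upper, lower in zip(RANKS, RANKS[1:]):
        h[upper] = spec.divergence[lower] / 2
    h["species"] = spec.within_species_divergence / 2
    return h


def lowest_differing_rank(tax_a: dict[str, str], tax_b: dict[str, str]) -> str | None:
    """Highest rank (domain -> species) at which two taxonomies differ."""
    for rank in RANKS:
        if tax_a[rank] != tax_b[rank]:
            return rank
    return None


def patristic_distance(
    spec: TaxonomySpec, tax_a: dict[str, str], tax_b: dict[str, str]
) -> float:
    rank = lowest_differing_rank(tax_a, tax_b)
    if rank is None:
        return 0.0
    if rank == "species":
        # different species, same genus
        return spec.divergence["species"]
    return spec.divergence[rank]


def generate_taxonomy_and_tree(
    spec: TaxonomySpec,
    n_genomes: int,
    seed: int,
    genomes_per_species: int = 1,
) -> tuple[list[GenomeRecord], Phylogeny, pd.DataFrame]:
    """Sample ``n_genomes`` leaves from the taxonomy and build their phylogeny.

    Returns genome skeletons (taxonomy and quality metrics, no contigs yet),
    the ultrametric phylogeny, and the symmetric patristic distance matrix.
    Taxonomy labels are consistent with tree topology by construction: two
    genomes differing at rank r are exactly ``divergence[r]`` apart.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    capacity = spec.n_species * genomes_per_species
    if n_genomes > capacity:
        raise ValueError(
            f"spec can produce at most {capacity} genomes, {n_genomes} requested"
        )
    rng = np.random.default_rng(seed)

    # Enumerate all species paths through the taxonomy.
    paths: list[tuple[int, ...]] = [()]
    for rank in RANKS:
        paths = [p + (i,) for p in paths for i in range(spec.branching[rank])]
    slots = [(p, i) for p in paths for i in range(genomes_per_species)]
    chosen = sorted(rng.choice(len(slots), size=n_genomes, replace=False))

    skeletons: list[GenomeRecord] = []
    for gi, slot_idx in enumerate(chosen):
        path, _ = slots[slot_idx]
        taxonomy = {
            rank: f"{rank[0]}{'_'.join(str(x) for x in path[: ri + 1])}"
            for ri, rank in enumerate(RANKS)
        }
        skeletons.append(
            GenomeRecord(
                genome_id=f"G{gi:03d}",
                taxonomy=taxonomy,
                completeness=float(np.round(rng.uniform(76, 100), 2)),
                contamination=float(np.round(rng.uniform(0, 4.9), 2)),
            )
        )

    tree = _build_tree(spec, skeletons)
    ids = [g.genome_id for g in skeletons]
    mat = np.zeros((n_genomes, n_genomes))
    for i, a in enumerate(skeletons):
        for j in range(i + 1, n_genomes):
            d = patristic_distance(spec, a.taxonomy, skeletons[j].taxonomy)
            if d == 0.0:
                d = spec.within_species_divergence
            mat[i, j] = mat[j, i] = d
    patristic = pd.DataFrame(mat, index=ids, columns=ids)
    return skeletons, tree, patristic


def _build_tree(spec: TaxonomySpec, skeletons: list[GenomeRecord]) -> Phylogeny:
    heights = _rank_heights(spec)
    root = PhyloNode("root", "root", heights["root"])

    def child(parent: PhyloNode, label: str, rank: str) -> PhyloNode:
        for c in parent.children:
            if c.label == label:
                return c
        node = PhyloNode(label, rank, heights[rank] if rank in heights else 0.0)
        parent.children.append(node)
        return node

    for g in sorted(skeletons, key=lambda s: s.genome_id):
        node = root
        for rank in RANKS:
            node = child(node, g.taxonomy[rank], rank)
        leaf = PhyloNode(g.genome_id, "genome", 0.0)
        node.children.append(leaf)
    return Phylogeny(root)


def path_edge_lengths(spec: TaxonomySpec, level: str) -> list[float]:
    """Branch lengths along the path between two genomes differing at ``level``."""
    heights = _rank_heights(spec)
    order = ["root", *RANKS]  # node ranks from root down to species
    if level == "within_species":
        top = "species"
    else:
        idx = RANKS.index(level)
        top = order[idx]  # the shared node is one rank above the differing rank
    edges: list[float] = []
    started = False
    prev = None
    for rank in order:
        if rank == top:
            started = True
            prev = heights[rank]
            continue
        if started:
            h = heights[rank]
            edges.append(prev - h)
            prev = h
    edges.append(prev)  # species node down to leaf
    return edges + edges  # both sides of the symmetric path


def expected_ortholog_identity(edge_lengths: list[float], rate: float = 1.0) -> float:
    """Exact expected identity of orthologs under the substitution model.

    Each branch applies a JC-like kernel whose non-unit eigenvalue is
    ``(4*exp(-rate*t) - 1)/3``; composing branches multiplies eigenvalues, so
    P(same base) = 1/4 + 3/4 * prod_i (4*exp(-rate*t_i) - 1)/3.
    """
    lam = 1.0
    for t in edge_lengths:
        lam *= (4.0 * math.exp(-rate * t) - 1.0) / 3.0
    return 0.25 + 0.75 * lam


# ---------------------------------------------------------------------------
# Gene evolution
# ---------------------------------------------------------------------------


def _mutate(seq: np.ndarray, blen: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    p = 1.0 - math.exp(-rate * blen)
    mask = rng.random(seq.size) < p
    n = int(mask.sum())
    if n == 0:
        return seq.copy()
    out = seq.copy()
    out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def encode_seq(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence alphabet must be ACGT")
    return arr


def evolve_genes(
    skeletons: list[GenomeRecord],
    tree: Phylogeny,
    genes_per_genome: int = 100,
    gene_length: int = 900,
    rate: float = 1.0,
    seed: int = 0,
    max_contigs: int = 5,
) -> list[GenomeRecord]:
    """Evolve orthologous gene families down the phylogeny and lay out contigs.

    Every genome receives one gene per family, tiled consecutively on 1 to
    ``max_contigs`` contigs (uniform), all on the + strand. The per-rank
    divergences of the default :class:`TaxonomySpec` are calibrated so that
    vertical ortholog identity stays below the 0.95 detection threshold for
    every genome pair, including within-genus ones; any cluster of two or
    more genes downstream is therefore a planted transfer.
    """
    if gene_length < 100:
        raise ValueError("gene_length must be >= 100")
    rng = np.random.default_rng(seed)
    by_id = {g.genome_id: g for g in skeletons}

    leaf_seqs: dict[str, list[np.ndarray]] = {g.genome_id: [] for g in skeletons}
    for _fam in range(genes_per_genome):
        root_seq = rng.integers(0, 4, size=gene_length, dtype=np.uint8)

        def walk(node: PhyloNode, seq: np.ndarray, parent_h: float) -> None:
            evolved = _mutate(seq, parent_h - node.height, rate, rng)
            if node.is_leaf():
                leaf_seqs[node.label].append(evolved)
                return
            for c in sorted(node.children, key=lambda n: n.label):
                walk(c, evolved, node.height)

        for c in sorted(tree.root.children, key=lambda n: n.label):
            walk(c, root_seq, tree.root.height)
        if not tree.root.children:  # single-genome edge case
            pass

    genomes: list[GenomeRecord] = []
    for gid in sorted(by_id):
        skel = by_id[gid]
        seqs = leaf_seqs[gid]
        n_contigs = int(rng.integers(1, max_contigs + 1))
        n_contigs = min(n_contigs, genes_per_genome)
        cuts = sorted(
            rng.choice(np.arange(1, genes_per_genome), size=n_contigs - 1, replace=False)
        )
        bounds = [0, *cuts, genes_per_genome]
        # Gene order is an independent permutation per genome, so orthologs
        # sit at genome-specific positions and a transferred gene is flanked
        # by unrelated sequence in the recipient (as in rearranged genomes).
        layout = rng.permutation(genes_per_genome)
        contigs: list[ContigRecord] = []
        for ci in range(n_contigs):
            lo, hi = bounds[ci], bounds[ci + 1]
            contig_id = f"{gid}_c{ci}"
            genes = []
            for pos, slot in enumerate(range(lo, hi)):
                fam = int(layout[slot])
                genes.append(
                    GeneRecord(
                        gene_id=f"{gid}_g{fam:04d}",
                        genome_id=gid,
                        contig_id=contig_id,
                        start=pos * gene_length,
                        end=(pos + 1) * gene_length,
                        strand="+",
                        seq=_decode(seqs[fam]),
                    )
                )
            contigs.append(
                ContigRecord(contig_id=contig_id, length=(hi - lo) * gene_length, genes=genes)
            )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                taxonomy=skel.taxonomy,
                completeness=skel.completeness,
                contamination=skel.contamination,
                contigs=contigs,
            )
        )
    return genomes


def gene_family(gene_id: str) -> int:
    """Ortholog family index encoded in the generator's gene ids."""
    return int(gene_id.rsplit("_g", 1)[1])


# ---------------------------------------------------------------------------
# Functional annotation
# ---------------------------------------------------------------------------


def annotate_genes(
    genomes: list[GenomeRecord],
    seed: int = 0,
    promge_background: float = 0.03,
    contig_flag_background: float = 0.02,
    rare_euk_fraction: float = 0.01,
) -> dict[int, str]:
    """Assign per-family COG categories and background MGE flags.

    Orthologous families share a category (occasionally two, mimicking
    multi-category eggNOG assignments); a small fraction receives a
    eukaryote-specific category (A/B/Y/Z) to exercise the downstream
    exclusion rule. Returns the family -> category map.
    """
    rng = np.random.default_rng(seed)
    families = sorted({gene_family(g.gene_id) for g in genomes[0].genes()})
    probs = _COG_WEIGHTS / _COG_WEIGHTS.sum()
    fam_cog: dict[int, str] = {}
    for fam in families:
        if rng.random() < rare_euk_fraction:
            fam_cog[fam] = str(rng.choice(list(_RARE_EUK_CATEGORIES)))
        else:
            cat = str(rng.choice(list(COG_CATEGORIES), p=probs))
            if rng.random() < 0.10:
                other = str(rng.choice(list(COG_CATEGORIES), p=probs))
                if other != cat:
                    cat = cat + other
            fam_cog[fam] = cat
    for genome in genomes:
        for contig in genome.contigs:
            plasmid = rng.random() < contig_flag_background
            virus = (not plasmid) and rng.random() < contig_flag_background
            provirus = rng.random() < contig_flag_background
            for gene in contig.genes:
                gene.cog_category = fam_cog[gene_family(gene.gene_id)]
                gene.mge_flags = MGEFlags(
                    promge_hit=bool(rng.random() < promge_background),
                    plasmid_contig=plasmid,
                    virus_contig=virus,
                    provirus_contig=provirus,
                )
    return fam_cog


# ---------------------------------------------------------------------------
# Planting HGT
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return int(np.count_nonzero(encode_seq(a) != encode_seq(b)))


def _mutate_to_target(seq: str, target: float, rng: np.random.Generator) -> str:
    arr = encode_seq(seq)
    mask = rng.random(arr.size) < (1.0 - target)
    n = int(mask.sum())
    out = arr.copy()
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return _decode(out)


def plant_hgt_events(
    genomes: list[GenomeRecord],
    n_recent: int,
    n_older: int,
    seed: int = 0,
    pair_weights: dict[tuple[str, str], float] | None = None,
    recent_identity: tuple[float, float] = (0.99, 1.0),
    older_identity: tuple[float, float] = (0.955, 0.985),
    n_short_contig: int = 0,
    n_short_region: int = 0,
    short_region_length: int = 400,
    family_weights: dict[int, float] | None = None,
    min_contig: int = 5000,
    promge_rate: float = 0.40,
    plasmid_rate: float = 0.25,
) -> PlantedTruth:
    """Plant transfers by orthologous replacement between cross-genus pairs.

    The donor's gene copy overwrites the recipient's gene of a (globally
    unique per event) family and is then mutated per-site to the target
    identity; the realized identity is recorded in the truth. "Recent"
    events target >= 99% identity, "older" ones 95-99%. Negative controls
    place an event on a short contig (< ``min_contig``) or copy only a
    ``short_region_length`` window (below the region detector's minimum).
    Transferred genes receive elevated mobile-element annotation rates.
    """
    from hgtcooc.detect import assign_divergence_level

    rng = np.random.default_rng(seed)
    by_id = {g.genome_id: g for g in genomes}
    ids = sorted(by_id)

    pairs: list[tuple[str, str]] = []
    levels: dict[tuple[str, str], str] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            level = assign_divergence_level(by_id[a].taxonomy, by_id[b].taxonomy)
            if level != "within_genus":
                pairs.append((a, b))
                levels[(a, b)] = level
    if not pairs:
        raise ValueError("no cross-genus genome pair available for planting")

    w = np.array([(pair_weights or {}).get(p, 1.0) for p in pairs], dtype=float)
    if w.sum() <= 0:
        raise ValueError("pair weights must have positive total mass")
    w = w / w.sum()

    gene_contig_len = {
        g.gene_id: c.length for gm in genomes for c in gm.contigs for g in c.genes
    }
    contig_of = {g.gene_id: c for gm in genomes for c in gm.contigs for g in c.genes}

    families = sorted({gene_family(g.gene_id) for g in genomes[0].genes()})
    fam_w = np.array([(family_weights or {}).get(f, 1.0) for f in families], dtype=float)
    fam_w = fam_w / fam_w.sum()

    kinds = (
        ["recent"] * n_recent
        + ["older"] * n_older
        + ["short_contig"] * n_short_contig
        + ["short_region"] * n_short_region
    )
    # A family may host several independent transfers, provided every genome
    # involved with that family is used once and all of them are pairwise
    # cross-genus: vertical divergence then keeps the per-event gene clusters
    # disjoint, so no spurious high-identity pair arises between events.
    fam_genomes: dict[int, set[str]] = {}
    replaced: set[str] = set()
    events: list[PlantedEvent] = []
    for kind in kinds:
        placed = False
        for _attempt in range(500):
            pi = int(rng.choice(len(pairs), p=w))
            a, b = pairs[pi]
            donor, recipient = (a, b) if rng.random() < 0.5 else (b, a)
            fam = int(rng.choice(families, p=fam_w))
            if kind == "short_contig":
                short = _find_short_contig_gene(by_id[recipient], min_contig, replaced)
                if short is None:
                    continue
                recipient_gene = short
                fam = gene_family(short.gene_id)
            if not _family_compatible(fam_genomes.get(fam, set()), donor, recipient, by_id):
                continue
            donor_gene = by_id[donor].gene(f"{donor}_g{fam:04d}")
            if donor_gene.gene_id in replaced:
                continue
            if kind == "short_region":
                # the short copied window lands inside an unrelated host gene
                host_fam = int(rng.choice(families))
                if host_fam == fam:
                    continue
                recipient_gene = by_id[recipient].gene(f"{recipient}_g{host_fam:04d}")
            elif kind != "short_contig":
                recipient_gene = by_id[recipient].gene(f"{recipient}_g{fam:04d}")
            if recipient_gene.gene_id in replaced:
                continue
            if gene_contig_len[donor_gene.gene_id] < min_contig:
                continue
            if kind != "short_contig" and gene_contig_len[recipient_gene.gene_id] < min_contig:
                continue
            placed = True
            break
        if not placed:
            if kind == "short_contig":
                # Force a short contig onto a recipient so the filter control
                # always exists in the fixture.
                pi = int(rng.choice(len(pairs), p=w))
                a, b = pairs[pi]
                donor, recipient = (a, b) if rng.random() < 0.5 else (b, a)
                fam = _split_short_contig(by_id[recipient], min_contig)
                donor_gene = by_id[donor].gene(f"{donor}_g{fam:04d}")
                recipient_gene = by_id[recipient].gene(f"{recipient}_g{fam:04d}")
                gene_contig_len = {
                    g.gene_id: c.length
                    for gm in genomes
                    for c in gm.contigs
                    for g in c.genes
                }
                contig_of = {
                    g.gene_id: c for gm in genomes for c in gm.contigs for g in c.genes
                }
            else:
                raise ValueError("could not place planted event on eligible pair")

        if kind == "recent":
            target = float(rng.uniform(*recent_identity))
        elif kind == "older":
            target = float(rng.uniform(*older_identity))
        else:
            target = float(rng.uniform(*recent_identity))

        if kind == "short_region":
            L = len(donor_gene.seq)
            off = int(rng.integers(0, L - short_region_length + 1))
            new_seq = (
                recipient_gene.seq[:off]
                + donor_gene.seq[off : off + short_region_length]
                + recipient_gene.seq[off + short_region_length :]
            )
            region_len = short_region_length
        else:
            new_seq = _mutate_to_target(donor_gene.seq, target, rng)
            region_len = 0
        recipient_gene.seq = new_seq
        replaced.add(recipient_gene.gene_id)
        fam_genomes.setdefault(fam, set()).update((donor, recipient))
        realized = 1.0 - _hamming(donor_gene.seq, new_seq) / len(new_seq)

        # Transferred genes carry mobile-element signatures more often.
        for gene in (donor_gene, recipient_gene):
            flags = gene.mge_flags.as_dict()
            flags["promge_hit"] = flags["promge_hit"] or bool(rng.random() < promge_rate)
            if rng.random() < plasmid_rate:
                flags["plasmid_contig"] = True
            gene.mge_flags = MGEFlags(**flags)

        level = levels[tuple(sorted((donor, recipient)))]
        detectable = (
            kind in ("recent", "older")
            and realized >= 0.95
            and gene_contig_len[donor_gene.gene_id] >= min_contig
            and contig_of[recipient_gene.gene_id].length >= min_contig
        )
        events.append(
            PlantedEvent(
                donor_genome=donor,
                recipient_genome=recipient,
                family=fam,
                donor_gene=donor_gene.gene_id,
                recipient_gene=recipient_gene.gene_id,
                target_identity=target,
                realized_identity=realized,
                divergence_level=level,
                kind="recent" if kind == "recent" else ("older" if kind == "older" else kind),
                control="" if kind in ("recent", "older") else kind,
                region_length=region_len,
                detectable=detectable,
            )
        )
    return PlantedTruth(hgt_events=events)


def _family_compatible(
    used: set[str], donor: str, recipient: str, by_id: dict[str, GenomeRecord]
) -> bool:
    """Donor/recipient may reuse a family only against cross-genus strangers."""
    from hgtcooc.detect import assign_divergence_level

    if donor in used or recipient in used:
        return False
    for g in used:
        for cand in (donor, recipient):
            level = assign_divergence_level(by_id[g].taxonomy, by_id[cand].taxonomy)
            if level == "within_genus":
                return False
    return True


def _find_short_contig_gene(
    genome: GenomeRecord, min_contig: int, replaced: set[str]
) -> GeneRecord | None:
    for c in sorted(genome.contigs, key=lambda c: c.contig_id):
        if c.length < min_contig:
            for g in sorted(c.genes, key=lambda g: g.gene_id):
                if g.gene_id not in replaced:
                    return g
    return None


def _split_short_contig(genome: GenomeRecord, min_contig: int) -> int:
    """Split trailing genes of the last contig into a new short contig.

    Returns the family index of a gene now sitting on a sub-threshold contig.
    """
    contig = max(genome.contigs, key=lambda c: len(c.genes))
    gene_len = len(contig.genes[0].seq)
    k = max(1, min_contig // gene_len - 1)  # k * gene_len < min_contig
    if k * gene_len >= min_contig:
        k = max(1, (min_contig - 1) // gene_len)
    moved = contig.genes[-k:]
    contig.genes = contig.genes[:-k]
    contig.length = len(contig.genes) * gene_len
    new_id = f"{genome.genome_id}_c{len(genome.contigs)}"
    for pos, g in enumerate(moved):
        g.contig_id = new_id
        g.start = pos * gene_len
        g.end = (pos + 1) * gene_len
    genome.contigs.append(ContigRecord(contig_id=new_id, length=k * gene_len, genes=moved))
    return gene_family(moved[0].gene_id)


# ---------------------------------------------------------------------------
# Samples, environment, abundance
# ---------------------------------------------------------------------------


@dataclass
class SampleData:
    """Per-sample outputs of the generator."""

    breadth: pd.DataFrame  # samples x genomes, in [0, 1]
    rpkm: pd.DataFrame  # samples x genomes, >= 0
    env: pd.DataFrame  # samples x environmental variables
    fractions: pd.Series  # sample -> {free_living, combined_fl_pa, other}


ENV_VARIABLES = (
    "latitude",
    "longitude",
    "depth",
    "temperature",
    "potential_density",
    "salinity",
    "nitrate",
    "oxygen",
    "chlorophyll_a",
    "par",
    "fcdom",
    "bbp470",
)


def _simulate_env(n_samples: int, rng: np.random.Generator) -> pd.DataFrame:
    """Oceanographic covariates with realistic depth-driven correlation."""
    z = rng.normal(size=n_samples)  # latent depth gradient
    env = pd.DataFrame(
        {
            "latitude": rng.uniform(-70, 70, n_samples),
            "longitude": rng.uniform(-180, 180, n_samples),
            "depth": np.exp(4.5 + 1.1 * z + rng.normal(0, 0.25, n_samples)),
            "temperature": 18 - 5.5 * z + rng.normal(0, 2.0, n_samples),
            "potential_density": 1026 + 0.9 * z + rng.normal(0, 0.6, n_samples),
            "salinity": 35 + rng.normal(0, 0.6, n_samples),
            "nitrate": np.log1p(np.exp(1.5 + 1.8 * z + rng.normal(0, 1.0, n_samples))),
            "oxygen": 250 - 40 * z + rng.normal(0, 25, n_samples),
            "chlorophyll_a": np.exp(-1.0 - 0.9 * z + rng.normal(0, 0.7, n_samples)),
            "par": 100 / (1 + np.exp(1.4 * z - 0.8 + rng.normal(0, 0.8, n_samples))),
            "fcdom": 1.5 + 0.35 * z + rng.normal(0, 0.4, n_samples),
            "bbp470": np.exp(-6.2 - 0.5 * z + rng.normal(0, 0.5, n_samples)),
        },
        index=[f"S{i:04d}" for i in range(n_samples)],
    )
    return env[list(ENV_VARIABLES)]


def assign_niche_groups(
    genome_ids: list[str], n_groups: int, group_size: int, seed: int = 0
) -> list[list[str]]:
    """Partition a random subset of genomes into disjoint shared-niche groups."""
    rng = np.random.default_rng(seed)
    need = n_groups * group_size
    if need > len(genome_ids):
        raise ValueError("not enough genomes for the requested niche groups")
    picked = rng.choice(sorted(genome_ids), size=need, replace=False)
    return [sorted(picked[i * group_size : (i + 1) * group_size]) for i in range(n_groups)]


def generate_samples(
    genomes: list[GenomeRecord],
    n_samples: int = 200,
    seed: int = 0,
    niche_groups: list[list[str]] | None = None,
    fraction_enriched: dict[str, str] | None = None,
    hgt_carriers: set[str] | None = None,
    env_effect: dict[str, float] | None = None,
    base_occupancy: float = 0.35,
    niche_slope: tuple[float, float] = (1.2, 2.0),
) -> tuple[SampleData, list[tuple[str, str]], dict[str, float]]:
    """Simulate breadth/RPKM matrices, environment and size-fraction labels.

    Genomes in the same niche group share a logistic occupancy response to
    two environmental variables and therefore co-occur above chance; other
    genomes get independent mild responses. ``fraction_enriched`` genomes
    occur predominantly (and most abundantly) in samples of their size
    fraction. ``hgt_carriers`` get an occupancy shift along ``env_effect``
    (variable -> slope on the z-scored variable), planting the link between
    environment and per-sample HGT prevalence.

    Returns the sample data, the planted co-occurring pairs, and the planted
    environmental effect (for the truth table).
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20 for downstream analyses")
    rng = np.random.default_rng(seed)
    env = _simulate_env(n_samples, rng)
    zenv = (env - env.mean()) / env.std(ddof=0)
    samples = list(env.index)
    ids = sorted(g.genome_id for g in genomes)

    fractions = pd.Series(
        rng.choice(
            ["free_living", "combined_fl_pa", "other"], size=n_samples, p=[0.55, 0.35, 0.10]
        ),
        index=samples,
        name="size_fraction",
    )

    niche_groups = niche_groups or []
    group_of: dict[str, int] = {}
    for gi, grp in enumerate(niche_groups):
        for g in grp:
            group_of[g] = gi
    group_params: dict[int, tuple[str, str, float, float]] = {}
    var_names = [v for v in ENV_VARIABLES if v not in ("latitude", "longitude")]
    for gi in range(len(niche_groups)):
        v1, v2 = rng.choice(var_names, size=2, replace=False)
        s1 = float(rng.choice([-1, 1]) * rng.uniform(*niche_slope))
        s2 = float(rng.choice([-1, 1]) * rng.uniform(*niche_slope))
        group_params[gi] = (str(v1), str(v2), s1, s2)

    fraction_enriched = fraction_enriched or {}
    hgt_carriers = hgt_carriers or set()
    env_effect = env_effect if env_effect is not None else {}
    base_logit = math.log(base_occupancy / (1 - base_occupancy))

    present = pd.DataFrame(False, index=samples, columns=ids)
    mu = pd.Series(rng.normal(1.0, 0.4, len(ids)), index=ids)
    rpkm_boost = pd.DataFrame(0.0, index=samples, columns=ids)

    for g in ids:
        if g in fraction_enriched:
            target = fraction_enriched[g]
            in_target = (fractions == target).to_numpy()
            p = np.where(in_target, 0.55, 0.03)
            rpkm_boost[g] = np.where(in_target, 0.9, 0.0)
        else:
            if g in group_of:
                v1, v2, s1, s2 = group_params[group_of[g]]
            else:
                v1, v2 = rng.choice(var_names, size=2, replace=False)
                s1 = float(rng.choice([-1, 1]) * rng.uniform(0.15, 0.5))
                s2 = float(rng.choice([-1, 1]) * rng.uniform(0.15, 0.5))
            logit = base_logit + s1 * zenv[v1].to_numpy() + s2 * zenv[v2].to_numpy()
            if g in hgt_carriers:
                for var, slope in env_effect.items():
                    logit = logit + slope * zenv[var].to_numpy()
            p = 1.0 / (1.0 + np.exp(-logit))
        present[g] = rng.random(n_samples) < p

    # Breadth: well above the 30% presence threshold when present, usually
    # zero (occasionally low but sub-threshold) when absent.
    pres = present.to_numpy()
    breadth = np.where(
        pres,
        rng.uniform(0.45, 1.0, pres.shape),
        np.where(rng.random(pres.shape) < 0.15, rng.uniform(0.0, 0.295, pres.shape), 0.0),
    )
    log_rpkm = rng.normal(mu.to_numpy()[None, :] + rpkm_boost.to_numpy(), 0.6)
    rpkm = np.where(
        pres,
        np.exp(log_rpkm),
        np.where(rng.random(pres.shape) < 0.3, rng.uniform(0.0, 0.3, pres.shape), 0.0),
    )

    cooccurring: list[tuple[str, str]] = []
    for grp in niche_groups:
        for i, a in enumerate(grp):
            for b in grp[i + 1 :]:
                cooccurring.append(tuple(sorted((a, b))))

    data = SampleData(
        breadth=pd.DataFrame(breadth, index=samples, columns=ids),
        rpkm=pd.DataFrame(rpkm, index=samples, columns=ids),
        env=env,
        fractions=fractions,
    )
    return data, sorted(cooccurring), dict(env_effect)


def simulate_independent_presence(
    n_samples: int, n_genomes: int, occupancy: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Null presence matrix: every genome occupies samples independently."""
    rng = np.random.default_rng(seed)
    mat = rng.random((n_samples, n_genomes)) < occupancy
    return pd.DataFrame(
        mat,
        index=[f"S{i:04d}" for i in range(n_samples)],
        columns=[f"G{j:03d}" for j in range(n_genomes)],
    )


def simulate_env_response(
    n_samples: int = 150,
    n_noise: int = 11,
    driver_r2: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, str]:
    """Environmental table with one planted driver of HGT prevalence.

    The response is a prevalence-like fraction driven by the first variable
    with the requested (pre-clipping) variance contribution; the remaining
    ``n_noise`` variables are independent noise. Mirrors the scale of the
    in-depth environmental analysis (order 150 samples, 12 variables).
    """
    rng = np.random.default_rng(seed)
    cols = ["driver"] + [f"noise{i:02d}" for i in range(n_noise)]
    X = pd.DataFrame(
        rng.normal(size=(n_samples, n_noise + 1)),
        columns=cols,
        index=[f"S{i:04d}" for i in range(n_samples)],
    )
    signal = math.sqrt(driver_r2) * X["driver"] + math.sqrt(1 - driver_r2) * rng.normal(
        size=n_samples
    )
    y = np.clip(0.30 + 0.10 * signal, 0.0, 1.0)
    return X, pd.Series(y, index=X.index, name="hgt_prevalence"), "driver"


def simulate_paired_prevalence(
    n_samples: int = 43, fold: float = 2.09, seed: int = 0
) -> tuple[pd.Series, pd.Series]:
    """Matched small/large size-fraction HGT prevalence with a planted fold change.

    Emulates the paired design: the same biological samples sequenced after
    small-particle and large-particle filtration, with large-fraction
    prevalence higher by ``fold`` on average.
    """
    rng = np.random.default_rng(seed)
    idx = [f"S{i:04d}" for i in range(n_samples)]
    small = np.clip(rng.normal(0.15, 0.04, n_samples), 0.02, 0.6)
    large = np.clip(small * fold * np.exp(rng.normal(0, 0.12, n_samples)), 0.02, 1.0)
    return pd.Series(small, index=idx, name="small"), pd.Series(large, index=idx, name="large")


# ---------------------------------------------------------------------------
# One-call default dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    genomes: list[GenomeRecord]
    tree: Phylogeny
    patristic: pd.DataFrame
    samples: SampleData
    truth: PlantedTruth
    fam_cog: dict[int, str]
    fraction_enriched: dict[str, str]

    @property
    def taxonomy(self) -> pd.DataFrame:
        rows = {g.genome_id: [g.taxonomy[r] for r in RANKS] for g in self.genomes}
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)).sort_index()


def simulate_dataset(
    seed: int = 0,
    n_genomes: int = 50,
    genes_per_genome: int = 100,
    gene_length: int = 900,
    n_recent: int = 28,
    n_older: int = 12,
    n_samples: int = 200,
    n_short_contig: int = 1,
    n_short_region: int = 1,
    n_niche_groups: int = 10,
    niche_group_size: int = 3,
    n_free_living: int = 8,
    n_combined: int = 5,
    cooccur_weight: float = 20.0,
    combined_pair_weight: float = 4.0,
    distance_decay: float = 0.35,
    hgt_cog_bias: str = "V",
    hgt_cog_bias_weight: float = 25.0,
    env_effect: dict[str, float] | None = None,
    spec: TaxonomySpec | None = None,
) -> SimulatedDataset:
    """Build the default end-to-end fixture with planted truth.

    Planted transfers are biased toward co-occurring (shared-niche) pairs by
    ``cooccur_weight`` and toward phylogenetically close pairs by
    ``exp(-distance / distance_decay)``, planting the positive co-occurrence
    and negative phylogenetic-distance effects the association model should
    recover. Events preferentially hit ``hgt_cog_bias``-category families,
    planting the functional enrichment signal. Genomes touched by HGT get an
    occupancy shift along ``env_effect`` (default: up with nitrate, down with
    PAR), planting the environmental association of HGT prevalence.
    """
    spec = spec or TaxonomySpec()
    if env_effect is None:
        env_effect = {"nitrate": 0.6, "par": -0.6}
    skeletons, tree, patristic = generate_taxonomy_and_tree(spec, n_genomes, seed=seed)
    genomes = evolve_genes(
        skeletons,
        tree,
        genes_per_genome=genes_per_genome,
        gene_length=gene_length,
        seed=seed + 1,
    )
    fam_cog = annotate_genes(genomes, seed=seed + 2)

    ids = sorted(g.genome_id for g in genomes)
    groups = assign_niche_groups(ids, n_niche_groups, niche_group_size, seed=seed + 3)
    in_group = {tuple(sorted((a, b))) for grp in groups for a in grp for b in grp if a < b}

    rng = np.random.default_rng(seed + 5)
    pool = sorted(set(ids) - {g for grp in groups for g in grp})
    if n_free_living + n_combined > len(pool):
        raise ValueError("not enough genomes outside niche groups for fraction classes")
    picked = list(rng.choice(pool, size=n_free_living + n_combined, replace=False))
    fraction_enriched = {g: "free_living" for g in picked[:n_free_living]}
    fraction_enriched.update({g: "combined_fl_pa" for g in picked[n_free_living:]})
    combined_set = {g for g, c in fraction_enriched.items() if c == "combined_fl_pa"}

    # Draft sample draw (no HGT-environment shift) to learn which pairs
    # actually co-occur under the niche model; planting is biased toward
    # them, so "co-occurring pairs exchange genes more" is true of the
    # realized presence matrix, not just of the niche-group labels. The
    # final draw below reuses the same seed, so non-carrier genomes keep
    # identical presence patterns.
    from hgtcooc.cooccurrence import (
        call_presence,
        drop_empty_samples,
        filter_prevalence,
        hypergeom_cooccurrence,
    )

    draft, _, _ = generate_samples(
        genomes,
        n_samples=n_samples,
        seed=seed + 6,
        niche_groups=groups,
        fraction_enriched=fraction_enriched,
    )
    draft_presence = call_presence(draft.breadth, draft.rpkm)
    draft_retained, _empty = filter_prevalence(draft_presence.present)
    draft_cooc = hypergeom_cooccurrence(
        drop_empty_samples(draft_presence.present[draft_retained])
    )
    sig_pairs = {
        tuple(sorted((r.genome_a, r.genome_b)))
        for r in draft_cooc[draft_cooc["significant"]].itertuples()
    }

    pair_weights: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            wt = math.exp(-patristic.loc[a, b] / distance_decay)
            if (a, b) in sig_pairs or (a, b) in in_group:
                wt *= cooccur_weight
            if a in combined_set and b in combined_set:
                wt *= combined_pair_weight
            pair_weights[(a, b)] = wt

    family_weights = {
        fam: (hgt_cog_bias_weight if hgt_cog_bias in cat else 1.0)
        for fam, cat in fam_cog.items()
    }
    truth = plant_hgt_events(
        genomes,
        n_recent=n_recent,
        n_older=n_older,
        seed=seed + 4,
        pair_weights=pair_weights,
        n_short_contig=n_short_contig,
        n_short_region=n_short_region,
        family_weights=family_weights,
    )

    samples, cooccurring, eff = generate_samples(
        genomes,
        n_samples=n_samples,
        seed=seed + 6,
        niche_groups=groups,
        fraction_enriched=fraction_enriched,
        hgt_carriers=truth.carriers(),
        env_effect=env_effect,
    )
    truth.cooccurring_pairs = cooccurring
    truth.env_effect = eff
    return SimulatedDataset(
        genomes=genomes,
        tree=tree,
        patristic=patristic,
        samples=samples,
        truth=truth,
        fam_cog=fam_cog,
        fraction_enriched=fraction_enriched,
    )
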