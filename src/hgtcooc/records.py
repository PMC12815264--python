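"""Core domain records shared across the pipeline.

Coordinates are 0-based half-open internally; GFF3 serialization converts to
1-based inclusive. Taxonomy follows the GTDB-style seven-rank hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Divergence levels at which HGT events can be called (within-genus pairs
#: are excluded from event calling because high identity between them is
#: expected from vertical descent alone).
DIVERGENCE_LEVELS: tuple[str, ...] = (
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "domain",
)


@dataclass(frozen=True)
class TaxonomySpec:
    """Shape of the simulated taxonomy and the divergence attached to each rank.

    Parameters
    ----------
    branching
        Children per node at each rank (e.g. ``{"genus": 3}`` means each
        family contains three genera). Counts must be >= 1.
    divergence
        Expected substitutions/site separating two lineages whose lowest
        shared rank is the parent of the given rank: two genomes in
        different genera of the same family are ``divergence["genus"]``
        apart. Must increase strictly from species to domain.
    within_species_divergence
        Patristic distance between two genomes of the same species.
    """

    branching: dict[str, int] = field(
        default_factory=lambda: {
            "domain": 2,
            "phylum": 2,
            "class": 2,
            "order": 2,
            "family": 2,
            "genus": 3,
            "species": 2,
        }
    )
    divergence: dict[str, float] = field(
        default_factory=lambda: {
            "species": 0.10,
            "genus": 0.18,
            "family": 0.30,
            "order": 0.45,
            "class": 0.60,
            "phylum": 0.78,
            "domain": 1.00,
        }
    )
    within_species_divergence: float = 0.02

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.branching]
        if missing:
            raise ValueError(f"branching missing ranks: {missing}")
        if any(c < 1 for c in self.branching.values()):
            raise ValueError("branching counts must be >= 1")
        divs = [self.divergence[r] for r in reversed(RANKS)]  # species -> domain
        if any(b <= a for a, b in zip(divs, divs[1:])):
            raise ValueError(
                "divergence must increase strictly from species-level to "
                "domain-level splits"
            )
        if not 0 < self.within_species_divergence < self.divergence["species"]:
            raise ValueError(
                "within_species_divergence must lie in (0, divergence['species'])"
            )

    @property
    def n_species(self) -> int:
        n = 1
        for r in RANKS:
            n *= self.branching[r]
        return n


@dataclass(frozen=True)
class MGEFlags:
    """Mobile-genetic-element annotations attached to a gene.

    ``promge_hit`` is a gene-level transposase/recombinase HMM match;
    the remaining flags describe the classification of the contig the gene
    sits on (plasmid, lytic virus, or provirus-containing).
    """

    promge_hit: bool = False
    plasmid_contig: bool = False
    virus_contig: bool = False
    provirus_contig: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


MGE_FLAG_NAMES: tuple[str, ...] = tuple(f.name for f in fields(MGEFlags))


@dataclass
class GeneRecord:
    """A protein-coding gene: location on its contig plus nucleotide sequence."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    seq: str = ""
    cog_category: str = ""  # zero or more single-letter COG categories
    mge_flags: MGEFlags = field(default_factory=MGEFlags)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.seq and len(self.seq) != self.end - self.start:
            raise ValueError(f"{self.gene_id}: sequence length != end - start")
        if self.seq and set(self.seq) - set("ACGT"):
            raise ValueError(f"{self.gene_id}: sequence alphabet must be ACGT")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ContigRecord:
    contig_id: str
    length: int
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: length must be positive")
        for g in self.genes:
            if g.start < 0 or g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id} outside contig {self.contig_id} bounds"
                )

    @property
    def seq(self) -> str:
        """Contig sequence as the concatenation of its (tiled) gene sequences."""
        return "".join(g.seq for g in sorted(self.genes, key=lambda g: g.start))


@dataclass
class GenomeRecord:
    """A genome: taxonomy, quality metrics and contigs carrying genes."""

    genome_id: str
    taxonomy: dict[str, str]
    completeness: float = 100.0
    contamination: float = 0.0
    contigs: list[ContigRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.taxonomy]
        if missing:
            raise ValueError(f"{self.genome_id}: taxonomy missing ranks {missing}")
        if not 0 < self.completeness <= 100:
            raise ValueError(f"{self.genome_id}: completeness must be in (0, 100]")
        if not 0 <= self.contamination < 100:
            raise ValueError(f"{self.genome_id}: contamination must be in [0, 100)")

    def genes(self) -> list[GeneRecord]:
        return [g for c in self.contigs for g in c.genes]

    def gene(self, gene_id: str) -> GeneRecord:
        for c in self.contigs:
            for g in c.genes:
                if g.gene_id == gene_id:
                    return g
        raise KeyError(gene_id)

    def contig(self, contig_id: str) -> ContigRecord:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass
class PlantedEvent:
    """One planted transfer: who gave what to whom, and at which identity."""

    donor_genome: str
    recipient_genome: str
    family: int
    donor_gene: str
    recipient_gene: str
    target_identity: float
    realized_identity: float
    divergence_level: str
    kind: str  # "recent" (>= 0.99) or "older" (0.95-0.99)
    control: str = ""  # "", "short_contig", "short_region"
    region_length: int = 0  # > 0 only for short_region controls
    detectable: bool = True

    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.donor_genome, self.recipient_genome)))


@dataclass
class PlantedTruth:
    """Ground truth of every planted signal in a simulated dataset."""

    hgt_events: list[PlantedEvent] = field(default_factory=list)
    cooccurring_pairs: list[tuple[str, str]] = field(default_factory=list)
    env_effect: dict[str, float] = field(default_factory=dict)

    def detectable_events(self) -> list[PlantedEvent]:
        return [e for e in self.hgt_events if e.detectable]

    def event_pairs(self, detectable_only: bool = True) -> set[tuple[str, str]]:
        events = self.detectable_events() if detectable_only else self.hgt_events
        return {e.pair() for e in events}

    def carriers(self) -> set[str]:
        """Genomes involved in at least one planted (detectable) event."""
        out: set[str] = set()
        for e in self.detectable_events():
            out.add(e.donor_genome)
            out.add(e.recipient_genome)
        return out
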