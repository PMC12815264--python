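"""On-disk fixture format: FASTA + GFF3 per genome, TSV tables, newick tree.

Layout written by :func:`write_fixture` under one directory::

    genomes/<genome_id>.fasta   gene sequences, headers genome|contig|gene
    genomes/<genome_id>.gff     gene features, 1-based inclusive, ID=<gene_id>
    tree.nwk                    phylogeny with branch lengths
    taxonomy.tsv                genome_id + the seven rank columns
    breadth.tsv / rpkm.tsv      samples x genomes
    env.tsv                     samples x environmental variables
    fractions.tsv               sample -> size-fraction label
    annotations.tsv             gene_id, cog_category, four MGE flags
    truth_events.tsv            planted HGT events
    truth_pairs.tsv             planted co-occurring pairs
    truth_env_effect.tsv        planted environment -> HGT prevalence link

Re-reading reproduces the in-memory objects bit-exactly (float columns are
serialized with round-tripping repr).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from hgtcooc.records import (
    RANKS,
    ContigRecord,
    GeneRecord,
    GenomeRecord,
    MGEFlags,
    PlantedEvent,
    PlantedTruth,
)
from hgtcooc.simulate import SampleData, SimulatedDataset


@dataclass
class FixtureData:
    """A fixture as read back from disk."""

    genomes: list[GenomeRecord]
    newick: str
    patristic: pd.DataFrame
    samples: SampleData
    truth: PlantedTruth
    annotations: pd.DataFrame

    @property
    def taxonomy(self) -> pd.DataFrame:
        rows = {g.genome_id: [g.taxonomy[r] for r in RANKS] for g in self.genomes}
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)).sort_index()


def patristic_from_newick(newick: str) -> pd.DataFrame:
    """Patristic distance matrix computed by path sums over a newick tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            d = pdm.patristic_distance(ti, taxa[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    # %.17g round-trips doubles exactly
    df.to_csv(
        path,
        sep="\t",
        index=index_label is not None,
        index_label=index_label,
        float_format="%.17g",
    )


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path) -> Path:
    """Serialize a simulated dataset; returns the directory written."""
    out = Path(out_dir)
    gdir = out / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)

    for genome in dataset.genomes:
        records = []
        gff_lines = ["##gff-version 3"]
        for contig in genome.contigs:
            gff_lines.append(f"##sequence-region {contig.contig_id} 1 {contig.length}")
        for contig in genome.contigs:
            for gene in sorted(contig.genes, key=lambda g: g.start):
                records.append(
                    SeqRecord(
                        Seq(gene.seq),
                        id=f"{genome.genome_id}|{contig.contig_id}|{gene.gene_id}",
                        description="",
                    )
                )
                gff_lines.append(
                    "\t".join(
                        [
                            contig.contig_id,
                            "hgtcooc",
                            "gene",
                            str(gene.start + 1),
                            str(gene.end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={gene.gene_id}",
                        ]
                    )
                )
        SeqIO.write(records, gdir / f"{genome.genome_id}.fasta", "fasta")
        (gdir / f"{genome.genome_id}.gff").write_text("\n".join(gff_lines) + "\n")

    (out / "tree.nwk").write_text(dataset.tree.newick + "\n")
    tax = dataset.taxonomy.copy()
    tax.insert(0, "completeness", [g.completeness for g in sorted(dataset.genomes, key=lambda x: x.genome_id)])
    tax.insert(1, "contamination", [g.contamination for g in sorted(dataset.genomes, key=lambda x: x.genome_id)])
    tax = tax[[*RANKS, "completeness", "contamination"]]
    _write_tsv(tax, out / "taxonomy.tsv", index_label="genome_id")
    _write_tsv(dataset.samples.breadth, out / "breadth.tsv", index_label="sample_id")
    _write_tsv(dataset.samples.rpkm, out / "rpkm.tsv", index_label="sample_id")
    _write_tsv(dataset.samples.env, out / "env.tsv", index_label="sample_id")
    _write_tsv(
        dataset.samples.fractions.to_frame(), out / "fractions.tsv", index_label="sample_id"
    )

    ann_rows = []
    for genome in dataset.genomes:
        for gene in genome.genes():
            ann_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "cog_category": gene.cog_category,
                    **gene.mge_flags.as_dict(),
                }
            )
    _write_tsv(pd.DataFrame(ann_rows).sort_values("gene_id").reset_index(drop=True),
               out / "annotations.tsv")

    _write_tsv(truth_events_frame(dataset.truth), out / "truth_events.tsv")
    _write_tsv(
        pd.DataFrame(dataset.truth.cooccurring_pairs, columns=["genome_a", "genome_b"]),
        out / "truth_pairs.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            sorted(dataset.truth.env_effect.items()), columns=["variable", "slope"]
        ),
        out / "truth_env_effect.tsv",
    )
    return out


def truth_events_frame(truth: PlantedTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor_genome": e.donor_genome,
                "recipient_genome": e.recipient_genome,
                "family": e.family,
                "donor_gene": e.donor_gene,
                "recipient_gene": e.recipient_gene,
                "target_identity": e.target_identity,
                "realized_identity": e.realized_identity,
                "divergence_level": e.divergence_level,
                "kind": e.kind,
                "control": e.control,
                "region_length": e.region_length,
                "detectable": e.detectable,
            }
            for e in truth.hgt_events
        ]
    )


def read_fixture(in_dir: str | Path) -> FixtureData:
    """Read a fixture directory back into in-memory objects."""
    src = Path(in_dir)
    tax = pd.read_csv(src / "taxonomy.tsv", sep="\t", index_col="genome_id")
    ann = pd.read_csv(src / "annotations.tsv", sep="\t")
    ann_by_gene = ann.set_index("gene_id")

    genomes: list[GenomeRecord] = []
    for genome_id in tax.index:
        fasta = src / "genomes" / f"{genome_id}.fasta"
        gff = src / "genomes" / f"{genome_id}.gff"
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(fasta), "fasta"):
            _, _, gene_id = rec.id.split("|")
            seqs[gene_id] = str(rec.seq)
        contig_lengths: dict[str, int] = {}
        genes_by_contig: dict[str, list[GeneRecord]] = {}
        for line in gff.read_text().splitlines():
            if line.startswith("##sequence-region"):
                _, cid, _one, length = line.split()
                contig_lengths[cid] = int(length)
                genes_by_contig.setdefault(cid, [])
                continue
            if line.startswith("#") or not line.strip():
                continue
            cid, _src, _type, start, end, _score, strand, _phase, attrs = line.split("\t")
            gene_id = dict(kv.split("=") for kv in attrs.split(";"))["ID"]
            row = ann_by_gene.loc[gene_id]
            genes_by_contig[cid].append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=cid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    seq=seqs[gene_id],
                    cog_category="" if pd.isna(row["cog_category"]) else str(row["cog_category"]),
                    mge_flags=MGEFlags(
                        promge_hit=bool(row["promge_hit"]),
                        plasmid_contig=bool(row["plasmid_contig"]),
                        virus_contig=bool(row["virus_contig"]),
                        provirus_contig=bool(row["provirus_contig"]),
                    ),
                )
            )
        contigs = [
            ContigRecord(contig_id=cid, length=contig_lengths[cid], genes=genes)
            for cid, genes in sorted(genes_by_contig.items())
        ]
        genomes.append(
            GenomeRecord(
                genome_id=genome_id,
                taxonomy={r: str(tax.loc[genome_id, r]) for r in RANKS},
                completeness=float(tax.loc[genome_id, "completeness"]),
                contamination=float(tax.loc[genome_id, "contamination"]),
                contigs=contigs,
            )
        )

    newick = (src / "tree.nwk").read_text().strip()
    breadth = pd.read_csv(src / "breadth.tsv", sep="\t", index_col="sample_id", float_precision="round_trip").rename_axis(None)
    rpkm = pd.read_csv(src / "rpkm.tsv", sep="\t", index_col="sample_id", float_precision="round_trip").rename_axis(None)
    env = pd.read_csv(src / "env.tsv", sep="\t", index_col="sample_id", float_precision="round_trip").rename_axis(None)
    fractions = pd.read_csv(src / "fractions.tsv", sep="\t", index_col="sample_id")[
        "size_fraction"
    ].rename_axis(None)

    truth_df = pd.read_csv(src / "truth_events.tsv", sep="\t", float_precision="round_trip")
    events = [
        PlantedEvent(
            donor_genome=r.donor_genome,
            recipient_genome=r.recipient_genome,
            family=int(r.family),
            donor_gene=r.donor_gene,
            recipient_gene=r.recipient_gene,
            target_identity=float(r.target_identity),
            realized_identity=float(r.realized_identity),
            divergence_level=r.divergence_level,
            kind=r.kind,
            control="" if pd.isna(r.control) else str(r.control),
            region_length=int(r.region_length),
            detectable=bool(r.detectable),
        )
        for r in truth_df.itertuples()
    ]
    pairs_df = pd.read_csv(src / "truth_pairs.tsv", sep="\t")
    eff_df = pd.read_csv(src / "truth_env_effect.tsv", sep="\t")
    truth = PlantedTruth(
        hgt_events=events,
        cooccurring_pairs=[(r.genome_a, r.genome_b) for r in pairs_df.itertuples()],
        env_effect={r.variable: float(r.slope) for r in eff_df.itertuples()},
    )
    return FixtureData(
        genomes=genomes,
        newick=newick,
        patristic=patristic_from_newick(newick),
        samples=SampleData(breadth=breadth, rpkm=rpkm, env=env, fractions=fractions),
        truth=truth,
        annotations=ann,
    )
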