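"""HGT detection: identity, clustering, RBH calling and identity segments."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtcooc import detect
from hgtcooc.detect import (
    HGTEvent,
    SegmentMatch,
    assign_divergence_level,
    call_rbh_hgt,
    call_region_hgt,
    cluster_genes,
    events_per_level,
    find_identity_segments,
    identity_bin,
    pairwise_identity,
)
from hgtcooc.records import RANKS, ContigRecord, GeneRecord, GenomeRecord

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=80)


def _edit_distance_dp(a: str, b: str) -> int:
    """Quadratic dynamic-programming edit distance (independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def _mk_gene(gene_id: str, seq: str, genome="GX", contig="GX_c0", start=0) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome,
        contig_id=contig,
        start=start,
        end=start + len(seq),
        seq=seq,
    )


def _taxonomy(**overrides) -> dict[str, str]:
    tax = {r: f"{r}0" for r in RANKS}
    tax.update(overrides)
    return tax


class TestPairwiseIdentity:
    def test_equal_length_examples(self):
        s = "A" * 100
        assert pairwise_identity(s, s) == 1.0
        assert pairwise_identity(s, "C" + s[1:]) == pytest.approx(0.99)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_unequal_lengths_match_dp_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            la, lb = rng.integers(40, 61, size=2)
            if la == lb:  # equal lengths use the Hamming convention instead
                lb += 1
            a = "".join(rng.choice(list("ACGT"), la))
            b = "".join(rng.choice(list("ACGT"), lb))
            expected = 1.0 - _edit_distance_dp(a, b) / max(la, lb)
            assert pairwise_identity(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(SEQ, SEQ)
    def test_symmetry(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


class TestClusterGenes:
    def test_identical_pair_merges(self):
        genes = [_mk_gene("g1", "ACGT" * 50), _mk_gene("g2", "ACGT" * 50)]
        out = cluster_genes(genes)
        assert len(out) == 1 and len(out[0]) == 2

    def test_distant_pair_stays_apart(self):
        rng = np.random.default_rng(1)
        base = rng.choice(list("ACGT"), 200)
        other = base.copy()
        idx = rng.choice(200, 20, replace=False)  # 10% divergence
        for i in idx:
            other[i] = "ACGT"[("ACGT".index(other[i]) + 1) % 4]
        out = cluster_genes([_mk_gene("g1", "".join(base)), _mk_gene("g2", "".join(other))])
        assert len(out) == 2

    def test_agrees_with_all_pairs_greedy_oracle(self):
        rng = np.random.default_rng(7)
        genes = []
        for i in range(30):
            L = int(rng.integers(150, 260))
            seq = "".join(rng.choice(list("ACGT"), L))
            genes.append(_mk_gene(f"g{i:02d}", seq))
            if rng.random() < 0.4:  # planted near-duplicate
                arr = list(seq)
                for j in rng.choice(L, max(1, L // 50), replace=False):
                    arr[j] = "ACGT"[("ACGT".index(arr[j]) + 1) % 4]
                genes.append(_mk_gene(f"g{i:02d}dup", "".join(arr)))

        result = cluster_genes(genes)

        # Oracle: identical rules, no k-mer prefilter, checks every rep.
        order = sorted(genes, key=lambda g: (-len(g.seq), g.gene_id))
        oracle: list[list[GeneRecord]] = []
        for gene in order:
            for members in oracle:
                rep = members[0]
                lo, hi = sorted((len(gene.seq), len(rep.seq)))
                if lo / hi >= 0.95 and pairwise_identity(gene.seq, rep.seq) >= 0.95:
                    members.append(gene)
                    break
            else:
                oracle.append([gene])
        expected = sorted(sorted(g.gene_id for g in mem) for mem in oracle)
        got = sorted(sorted(c.member_gene_ids) for c in result)
        assert got == expected


class TestDivergenceLevel:
    @pytest.mark.parametrize(
        "overrides,expected",
        [
            ({"species": "sX"}, "within_genus"),
            ({}, "within_genus"),
            ({"family": "fX", "genus": "gX", "species": "sX"}, "family"),
            ({r: f"{r}X" for r in RANKS}, "domain"),
            ({"genus": "gX", "species": "sX"}, "genus"),
        ],
    )
    def test_lowest_differing_rank(self, overrides, expected):
        assert assign_divergence_level(_taxonomy(), _taxonomy(**overrides)) == expected

    def test_missing_rank_rejected(self):
        broken = _taxonomy()
        broken["order"] = ""
        with pytest.raises(ValueError, match="order"):
            assign_divergence_level(_taxonomy(), broken)

    def test_bin_boundary(self):
        assert identity_bin(0.99) == "ge99"
        assert identity_bin(0.9899) == "95to99"


class TestRBH:
    def test_same_genus_cluster_yields_no_event(self):
        seq = "ACGT" * 250
        genes = {
            "A_g0": _mk_gene("A_g0", seq, genome="A", contig="A_c0"),
            "B_g0": _mk_gene("B_g0", seq, genome="B", contig="B_c0"),
        }
        clusters = cluster_genes(list(genes.values()))
        tax = {"A": _taxonomy(), "B": _taxonomy(species="sX")}
        out = call_rbh_hgt(clusters, genes, tax, {"A_c0": 9000, "B_c0": 9000})
        assert out == []

    def test_planted_cross_family_copy_is_one_event(self):
        seq = "ACGT" * 250
        genes = {
            "A_g0": _mk_gene("A_g0", seq, genome="A", contig="A_c0"),
            "B_g0": _mk_gene("B_g0", seq, genome="B", contig="B_c0"),
        }
        clusters = cluster_genes(list(genes.values()))
        tax = {
            "A": _taxonomy(),
            "B": _taxonomy(family="fX", genus="gX", species="sX"),
        }
        out = call_rbh_hgt(clusters, genes, tax, {"A_c0": 9000, "B_c0": 9000})
        assert len(out) == 1
        assert out[0].divergence_level == "family"
        assert out[0].identity_bin == "ge99"

    def test_short_contig_event_removed_after_calling(self):
        seq = "ACGT" * 250
        genes = {
            "A_g0": _mk_gene("A_g0", seq, genome="A", contig="A_c0"),
            "B_g0": _mk_gene("B_g0", seq, genome="B", contig="B_c0"),
        }
        clusters = cluster_genes(list(genes.values()))
        tax = {"A": _taxonomy(), "B": _taxonomy(family="fX", genus="gX", species="sX")}
        out = call_rbh_hgt(clusters, genes, tax, {"A_c0": 9000, "B_c0": 4000})
        assert out == []

    def test_missing_taxonomy_named(self):
        seq = "ACGT" * 250
        genes = {
            "A_g0": _mk_gene("A_g0", seq, genome="A", contig="A_c0"),
            "B_g0": _mk_gene("B_g0", seq, genome="B", contig="B_c0"),
        }
        clusters = cluster_genes(list(genes.values()))
        with pytest.raises(KeyError, match="B"):
            call_rbh_hgt(clusters, genes, {"A": _taxonomy()}, {"A_c0": 9000, "B_c0": 9000})

    def test_event_set_symmetric_and_deterministic(self, clusters, genes, taxonomy, contig_lengths):
        a = call_rbh_hgt(clusters, genes, taxonomy, contig_lengths)
        b = call_rbh_hgt(clusters, genes, taxonomy, contig_lengths)
        assert detect.events_to_frame(a).equals(detect.events_to_frame(b))
        for e in a:
            assert e.genome_a < e.genome_b  # canonical order

    def test_bin_consistent_with_identity(self, rbh_events):
        for e in rbh_events:
            assert (e.identity_bin == "ge99") == (e.identity >= 0.99)


class TestIdentitySegments:
    def test_identical_contigs_one_full_length_segment(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        ga = GenomeRecord(
            "A", _taxonomy(), contigs=[ContigRecord("A_c0", 2000, [_mk_gene("A_g0", seq, "A", "A_c0")])]
        )
        gb = GenomeRecord(
            "B", _taxonomy(), contigs=[ContigRecord("B_c0", 2000, [_mk_gene("B_g0", seq, "B", "B_c0")])]
        )
        segs = find_identity_segments(ga, gb)
        assert len(segs) == 1
        assert segs[0].length == 2000
        assert segs[0].identity == 1.0
        assert segs[0].score == 2000

    def test_short_perfect_region_not_reported(self):
        rng = np.random.default_rng(6)
        shared = "".join(rng.choice(list("ACGT"), 400))
        bg_a = "".join(rng.choice(list("ACGT"), 1600))
        bg_b = "".join(rng.choice(list("ACGT"), 1600))
        sa = bg_a[:800] + shared + bg_a[800:]
        sb = bg_b[:300] + shared + bg_b[300:]
        ga = GenomeRecord("A", _taxonomy(), contigs=[ContigRecord("A_c0", 2000, [_mk_gene("A_g0", sa, "A", "A_c0")])])
        gb = GenomeRecord("B", _taxonomy(), contigs=[ContigRecord("B_c0", 2000, [_mk_gene("B_g0", sb, "B", "B_c0")])])
        assert find_identity_segments(ga, gb, min_len=500) == []

    def test_planted_region_recovered_with_high_coverage(self, dataset):
        by = {g.genome_id: g for g in dataset.genomes}
        event = dataset.truth.detectable_events()[0]
        segs = find_identity_segments(by[event.donor_genome], by[event.recipient_genome])
        gene = by[event.recipient_genome].gene(event.recipient_gene)
        cov = 0
        for s in segs:
            for cid, start, end in (
                (s.contig_b, s.start_b, s.end_b),
                (s.contig_a, s.start_a, s.end_a),
            ):
                if cid == gene.contig_id:
                    cov = max(cov, min(end, gene.end) - max(start, gene.start))
        assert cov >= 0.9 * len(gene)

    def test_k_larger_than_contig_warns_empty(self):
        ga = GenomeRecord("A", _taxonomy(), contigs=[ContigRecord("A_c0", 20, [_mk_gene("A_g0", "ACGT" * 5, "A", "A_c0")])])
        assert find_identity_segments(ga, ga, k=31) == []


class TestRegionCalling:
    def _two_genomes(self):
        rng = np.random.default_rng(9)
        seq_a = "".join(rng.choice(list("ACGT"), 2000))
        genes_a = [
            _mk_gene("A_g0", seq_a[:1000], "A", "A_c0", start=0),
            _mk_gene("A_g1", seq_a[1000:], "A", "A_c0", start=1000),
        ]
        ga = GenomeRecord("A", _taxonomy(), contigs=[ContigRecord("A_c0", 2000, genes_a)])
        seq_b = "".join(rng.choice(list("ACGT"), 2000))
        gb = GenomeRecord(
            "B",
            _taxonomy(family="fX", genus="gX", species="sX"),
            contigs=[ContigRecord("B_c0", 2000, [_mk_gene("B_g0", seq_b, "B", "B_c0")])],
        )
        return ga, gb

    def _seg(self, sa, ea, sb, eb, score, ident=0.99):
        return SegmentMatch(
            genome_a="A", contig_a="A_c0", start_a=sa, end_a=ea,
            genome_b="B", contig_b="B_c0", start_b=sb, end_b=eb,
            length=ea - sa, identity=ident, score=score,
        )

    def test_segment_spanning_two_genes_yields_two_events(self):
        ga, gb = self._two_genomes()
        genomes = {"A": ga, "B": gb}
        tax = {g: genomes[g].taxonomy for g in genomes}
        seg = self._seg(800, 1400, 100, 700, score=580)
        events = call_region_hgt([seg], genomes, tax, min_contig=1000)
        genes_a = {e.gene_a for e in events if e.gene_a}
        assert genes_a == {"A_g0", "A_g1"}

    def test_overlapping_segments_highest_score_retained(self):
        ga, gb = self._two_genomes()
        genomes = {"A": ga, "B": gb}
        tax = {g: genomes[g].taxonomy for g in genomes}
        strong = self._seg(0, 900, 0, 900, score=900)
        weak = self._seg(500, 1800, 500, 1800, score=500)
        events = call_region_hgt([strong, weak], genomes, tax, min_contig=1000)
        genes_a = {e.gene_a for e in events if e.gene_a}
        assert genes_a == {"A_g0"}  # nothing from the 500-score segment

    def test_same_genus_pair_yields_nothing(self):
        ga, gb = self._two_genomes()
        gb.taxonomy = dict(ga.taxonomy, species="sX")
        genomes = {"A": ga, "B": gb}
        tax = {g: genomes[g].taxonomy for g in genomes}
        seg = self._seg(0, 900, 0, 900, score=900)
        assert call_region_hgt([seg], genomes, tax, min_contig=1000) == []

    def test_unknown_contig_rejected(self):
        ga, gb = self._two_genomes()
        seg = SegmentMatch(
            genome_a="A", contig_a="nope", start_a=0, end_a=600,
            genome_b="B", contig_b="B_c0", start_b=0, end_b=600,
            length=600, identity=0.99, score=590,
        )
        with pytest.raises(KeyError, match="nope"):
            call_region_hgt([seg], {"A": ga, "B": gb}, {"A": ga.taxonomy, "B": gb.taxonomy})


class TestEventsPerLevel:
    def test_rate_arithmetic(self):
        tax = {}
        for i in range(4):  # 4 genomes in distinct families of one order
            tax[f"G{i}"] = _taxonomy(family=f"f{i}", genus=f"g{i}", species=f"s{i}")
        events = [
            HGTEvent("G0", "G1", "a", "b", 1.0, "ge99", "family", "cluster_rbh"),
            HGTEvent("G0", "G2", "a", "b", 1.0, "ge99", "family", "cluster_rbh"),
            HGTEvent("G0", "G3", "a", "b", 1.0, "ge99", "family", "cluster_rbh"),
        ]
        out = events_per_level(events, tax)
        assert out.loc["family", "n_genome_pairs"] == 6
        assert out.loc["family", "rate"] == pytest.approx(0.5)
        assert out.loc["phylum", "n_events"] == 0
        assert np.isnan(out.loc["phylum", "rate"])  # zero pairs at that level

    def test_fixture_rates_follow_planted_bias(self, rbh_events, taxonomy):
        """Transfers are planted with exponential distance decay, so the
        normalized rate is highest at the genus level."""
        out = events_per_level(rbh_events, taxonomy)
        rates = out["rate"].dropna()
        assert rates.idxmax() == "genus"
        assert rates.loc["genus"] > rates.loc["phylum"]
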