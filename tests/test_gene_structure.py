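"""Spliced aligner, structure statistics and tandem-cluster detection."""

import numpy as np
import pytest

from chemogene import (
    GeneModel, GeneRecord, Interval, SequenceRecord, detect_clusters,
    genomic_span, spliced_align, structure_stats,
)
from chemogene.gene_structure import StructureStats, UnmappableError, round_half_away
from chemogene.synthetic_data import GenomeSpec, gen_genome


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSplicedAlign:
    def test_identity_is_single_exon(self, rng):
        seq = _dna(rng, 200)
        aln = spliced_align(SequenceRecord("m", seq), SequenceRecord("g", seq))
        assert len(aln.gene_model.exons) == 1
        assert aln.gene_model.exons[0] == Interval(1, 200)
        assert aln.mismatches == 0 and aln.introns == []

    def test_planted_single_intron(self, rng):
        e1, e2 = _dna(rng, 60), _dna(rng, 60)
        intron = "GT" + _dna(rng, 36) + "AG"  # 40 bp
        genomic = SequenceRecord("g", e1 + intron + e2)
        aln = spliced_align(SequenceRecord("m", e1 + e2), genomic)
        assert [(e.start, e.stop) for e in aln.gene_model.exons] == [(1, 60), (101, 160)]
        (iv, donor, acceptor) = aln.introns[0]
        assert (donor, acceptor) == ("GT", "AG") and len(iv) == 40

    def test_minus_strand_coordinates_on_forward_axis(self, rng):
        spec = GenomeSpec(
            n_genes=6, minus_strand_prob=1.0, intron_counts=(1, 2),
            intron_len_range=(30, 200), exon_len_range=(40, 100), seed=9,
        )
        scaffolds, models, mrnas = gen_genome(spec)
        for s, truth, m in zip(scaffolds, models, mrnas):
            aln = spliced_align(m, s, "-")
            got = [(e.start, e.stop) for e in aln.gene_model.exons]
            assert got == [(e.start, e.stop) for e in truth.exons]
            assert got == sorted(got)  # ascending forward-axis order

    def test_mismatches_reported(self, rng):
        seq = _dna(rng, 150)
        mutated = seq[:70] + ("A" if seq[70] != "A" else "C") + seq[71:]
        aln = spliced_align(SequenceRecord("m", mutated), SequenceRecord("g", seq))
        assert aln.mismatches == 1

    def test_unmappable_raises(self, rng):
        mrna = SequenceRecord("m", "A" * 100)
        genomic = SequenceRecord("g", _dna(rng, 120).replace("AAAA", "CGTG"))
        with pytest.raises(UnmappableError):
            spliced_align(mrna, genomic)

    def test_splice_reconstruction_invariant(self, rng):
        """Concatenated exon sequence equals the mRNA; lengths add up."""
        spec = GenomeSpec(
            n_genes=10, intron_counts=(0, 1, 2, 3), intron_len_range=(30, 500),
            exon_len_range=(40, 150), seed=21,
        )
        scaffolds, models, mrnas = gen_genome(spec)
        for s, truth, m in zip(scaffolds, models, mrnas):
            aln = spliced_align(m, s, truth.strand)
            model = aln.gene_model
            g = s.residues
            pieces = [g[e.start - 1:e.stop] for e in model.exons]
            spliced = "".join(pieces)
            if truth.strand == "-":
                spliced = spliced.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
            assert sum(c1 != c2 for c1, c2 in zip(spliced, m.residues)) == aln.mismatches
            assert len(model.span) == sum(len(e) for e in model.exons) + sum(
                len(i) for i in model.introns
            )


class TestStructureStats:
    def test_published_five_exon_gene(self):
        model = GeneModel(
            "OBP2", "s", "-",
            _exons_from_lengths([100, 150, 182, 150, 150], [1276, 1276, 1276, 1276]),
        )
        s = structure_stats(model)
        assert (s.genomic_bp, s.n_introns, s.total_intron_bp, s.avg_intron_bp) == (
            5836, 4, 5104, 1276,
        )
        assert (s.n_exons, s.total_exon_bp, s.avg_exon_bp) == (5, 732, 146)

    def test_rounding_half_away_from_zero(self):
        model = GeneModel(
            "OBP3", "s", "+",
            _exons_from_lengths([71, 71, 71, 71, 71, 71], [3277, 3277, 3277, 3276, 3277]),
        )
        s = structure_stats(model)
        assert s.total_intron_bp == 16384 and s.avg_intron_bp == 3277  # 3276.8 up

    @pytest.mark.parametrize(
        "value,expected", [(3276.8, 3277), (85.71, 86), (444.83, 445), (244.5, 245), (146.4, 146)]
    )
    def test_round_half_away(self, value, expected):
        assert round_half_away(value) == expected

    def test_single_exon_gene(self):
        s = structure_stats(GeneModel("g", "s", "+", [Interval(11, 310)]))
        assert s == StructureStats(300, 0, 0, 0, 1, 300, 300)

    def test_reproduces_published_table(self, reference_structure):
        """Recomputing averages from printed totals matches every printed row."""
        for gene_id, row in reference_structure.items():
            if row.n_introns:
                assert round_half_away(row.total_intron_bp / row.n_introns) == row.avg_intron_bp
            assert round_half_away(row.total_exon_bp / row.n_exons) == row.avg_exon_bp
            assert row.genomic_bp == row.total_intron_bp + row.total_exon_bp


def _exons_from_lengths(exon_lens, intron_lens):
    exons, pos = [], 1
    for i, l in enumerate(exon_lens):
        exons.append(Interval(pos, pos + l - 1))
        pos += l
        if i < len(intron_lens):
            pos += intron_lens[i]
    return exons


class TestGenomicSpan:
    @pytest.mark.parametrize(
        "start,stop,expected",
        [(340085, 345920, 5836), (593787, 605068, 11282), (5, 5, 1)],
    )
    def test_spans(self, start, stop, expected):
        assert genomic_span(Interval(start, stop)) == expected


def _gene(gid, scaffold, start, stop, family="OBP", strand="+"):
    return GeneRecord(gid, family, scaffold, Interval(start, stop), strand)


def brute_force_clusters(genes, max_gap):
    """Oracle: transitive closure of the pairwise adjacency relation."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(genes)))
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if a.scaffold_id != b.scaffold_id:
                continue
            lo, hi = sorted([a, b], key=lambda x: x.location.start)
            gap = max(hi.location.start - lo.location.stop - 1, 0)
            # adjacency: no third gene between them and gap within limit
            between = [
                c for c in genes
                if c.scaffold_id == a.scaffold_id
                and lo.location.start < c.location.start < hi.location.start
            ]
            if not between and gap <= max_gap:
                g.add_edge(i, j)
    comps = [sorted(c, key=lambda i: genes[i].location.start) for c in nx.connected_components(g)]
    return sorted(
        tuple(genes[i].gene_id for i in c) for c in comps if len(c) >= 2
    )


class TestDetectClusters:
    def test_published_gene_set(self, reference_genes):
        clusters, summary = detect_clusters(reference_genes, max_gap=50_000)
        assert summary == {"CSP": 5, "OBP": 7}
        by_scaffold = {c.scaffold_id: [m.gene_id for m in c.members] for c in clusters}
        assert by_scaffold["21"] == ["MperOBP7", "MperOBP3", "MperOBP8"]
        assert by_scaffold["112"] == ["MperCSP4", "MperCSP1", "MperCSP6"]
        assert by_scaffold["55"] == ["MperCSP9", "MperCSP2"]
        assert by_scaffold["10"] == ["MperCSP5", "MperCSP8"]
        assert len(clusters) == 4

    def test_intergenic_gaps(self, reference_genes):
        clusters, _ = detect_clusters(reference_genes)
        c21 = next(c for c in clusters if c.scaffold_id == "21")
        assert c21.gaps == [798710 - 798189 - 1, 816539 - 815519 - 1]

    def test_all_distinct_scaffolds_no_clusters(self):
        genes = [_gene(f"g{i}", f"s{i}", 100, 500) for i in range(5)]
        clusters, _ = detect_clusters(genes)
        assert clusters == []

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 13))
            genes = []
            for i in range(n):
                start = int(rng.integers(1, 20_000))
                genes.append(
                    _gene(f"g{i}", f"s{rng.integers(1, 4)}", start, start + int(rng.integers(100, 2000)))
                )
            max_gap = int(rng.integers(100, 5000))
            clusters, _ = detect_clusters(genes, max_gap=max_gap)
            got = sorted(tuple(m.gene_id for m in c.members) for c in clusters)
            assert got == brute_force_clusters(genes, max_gap)

    def test_overlapping_genes_gap_zero(self):
        genes = [_gene("a", "s", 100, 500), _gene("b", "s", 400, 900)]
        clusters, _ = detect_clusters(genes, max_gap=10)
        assert clusters[0].gaps == [0]
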