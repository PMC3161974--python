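import numpy as np
import pytest

from syntegene.io_formats import (
    AncestralOrder,
    GeneAnnotation,
    Genome,
    Pillar,
    PillarTable,
)
from syntegene.segments import (
    build_ogs_groups,
    build_segments,
    dump_segments_fasta,
    interval_id,
    map_segment,
)


def _clade(n_genes=6, species="s1", gene_len=90, gap=50):
    """One contig with n adjacent single-exon genes + matching pillars."""
    genes, pillars, pos = [], [], 10
    for i in range(n_genes):
        gid = f"{species}_g{i}"
        genes.append(
            GeneAnnotation(gid, species, "c1", "+", [(pos, pos + gene_len)])
        )
        pillars.append(Pillar(f"P{i}", {species: [gid]}))
        pos += gene_len + gap
    genome = Genome(species, {"c1": "A" * (pos + 100)})
    table = PillarTable(pillars, {species: {"post_wgd": False}})
    order = AncestralOrder({"chr1": [p.pillar_id for p in pillars]})
    return genes, genome, table, order


class TestBuildSegments:
    def test_three_genes_two_segments(self):
        genes, genome, *_ = _clade(3)
        segs = build_segments(genes, genome)
        assert [(s.left_gene, s.right_gene) for s in segs] == [
            ("s1_g0", "s1_g1"),
            ("s1_g1", "s1_g2"),
        ]

    def test_overlapping_genes_have_empty_intergenic(self):
        genome = Genome("s1", {"c1": "A" * 400})
        a = GeneAnnotation("a", "s1", "c1", "+", [(0, 100)])
        b = GeneAnnotation("b", "s1", "c1", "+", [(90, 200)])
        (seg,) = build_segments([a, b], genome)
        assert seg.intergenic_len == 0

    def test_single_gene_contig_yields_nothing(self):
        genes, genome, *_ = _clade(1)
        assert build_segments(genes, genome) == []

    def test_switched_off_genes_excluded(self):
        genes, genome, *_ = _clade(3)
        genes[1].status = "switched_off"
        segs = build_segments(genes, genome)
        assert [(s.left_gene, s.right_gene) for s in segs] == [("s1_g0", "s1_g2")]

    def test_orphan_genes_transparent_when_pillars_given(self):
        genes, genome, table, _ = _clade(3)
        orphan = GeneAnnotation("s1_orphan", "s1", "c1", "+", [(115, 130)])
        segs = build_segments(sorted(genes + [orphan], key=lambda g: g.start),
                              genome, pillars=table)
        assert all("orphan" not in (s.left_gene, s.right_gene) for s in segs)
        assert len(segs) == 2

    def test_contig_end_segments_optional(self):
        genes, genome, *_ = _clade(3)
        segs = build_segments(genes, genome, include_ends=True)
        assert len(segs) == 4
        assert segs[0].left_gene is None and segs[-1].right_gene is None


def test_segment_fasta_dump_covers_spans(tmp_path):
    genes, genome, *_ = _clade(4)
    segs = build_segments(genes, genome)
    path = tmp_path / "dogs.fa"
    dump_segments_fasta(segs, genome, path)
    text = path.read_text()
    assert text.count(">") == 3
    for seg in segs:
        assert seg.segment_id in text
        body = text.split(f">{seg.segment_id}\n")[1].split("\n")[0]
        assert len(body) == seg.span[1] - seg.span[0]


class TestMapSegment:
    def test_adjacent_pillars_one_interval(self):
        genes, genome, table, order = _clade(4)
        seg = build_segments(genes, genome)[1]  # g1-g2
        syn = map_segment(seg, table, order)
        assert syn.mapped_intervals == [interval_id("chr1", 1)]
        assert not syn.rearranged

    def test_deletion_span_covers_consecutive_intervals(self):
        genes, genome, table, order = _clade(6)
        # drop g3, g4 from the species: segment g2-g5 spans three intervals
        kept = [g for g in genes if g.gene_id not in ("s1_g3", "s1_g4")]
        seg = [s for s in build_segments(kept, genome)
               if s.left_gene == "s1_g2"][0]
        syn = map_segment(seg, table, order)
        assert syn.mapped_intervals == [
            interval_id("chr1", 2), interval_id("chr1", 3), interval_id("chr1", 4)
        ]
        assert not syn.rearranged

    def test_flanks_on_different_chromosomes_are_singlehit(self):
        genes, genome, table, _ = _clade(4)
        order = AncestralOrder({"chr1": ["P0", "P1"], "chr2": ["P2", "P3"]})
        seg = [s for s in build_segments(genes, genome)
               if s.left_gene == "s1_g1"][0]  # g1(chr1) - g2(chr2)
        syn = map_segment(seg, table, order)
        assert syn.rearranged
        assert syn.mapped_intervals == [
            interval_id("chr1", 0), interval_id("chr2", 0)
        ]

    def test_interval_cap_marks_rearranged(self):
        genes, genome, table, order = _clade(30)
        kept = [genes[0], genes[-1]]
        (seg,) = build_segments(kept, genome)
        syn = map_segment(seg, table, order, interval_cap=20)
        assert syn.rearranged

    def test_no_mappable_flank(self):
        genes, genome, table, order = _clade(3)
        stray = [
            GeneAnnotation("x1", "s1", "c1", "+", [(10, 100)]),
            GeneAnnotation("x2", "s1", "c1", "+", [(150, 240)]),
        ]
        (seg,) = build_segments(stray, genome)
        syn = map_segment(seg, table, order)
        assert syn.rearranged and syn.mapped_intervals == []


class TestOgsGroups:
    def test_identical_gene_content_pairs_all_groups(self):
        syntenies = []
        for sp in ("s1", "s2"):
            genes, genome, table, order = _clade(5, species=sp)
            for seg in build_segments(genes, genome):
                syntenies.append(map_segment(seg, table, order))
        groups = build_ogs_groups(syntenies)
        assert len(groups) == 4
        assert all(len(g.members) == 2 for g in groups.values())

    def test_long_deletion_segment_joins_every_group(self):
        genes, genome, table, order = _clade(4)
        kept = [genes[0], genes[-1]]
        (seg,) = build_segments(kept, genome)
        syntenies = [map_segment(s, table, order) for s in build_segments(genes, genome)]
        syntenies.append(map_segment(seg, table, order))
        groups = build_ogs_groups(syntenies)
        for iv in [interval_id("chr1", i) for i in range(3)]:
            assert seg.segment_id in groups[iv].members

    def test_empty_input(self):
        assert build_ogs_groups([]) == {}


def test_overlap_chain_and_inverse_consistency(rng):
    """Consecutive segments share exactly one gene, and group membership is
    exactly the inverse of mapped_intervals, over random clades."""
    for _ in range(20):
        n = int(rng.integers(3, 30))
        genes, genome, table, order = _clade(n)
        keep = [g for g in genes if rng.random() > 0.2]
        if len(keep) < 2:
            continue
        segs = build_segments(keep, genome)
        assert len(segs) == len(keep) - 1
        for a, b in zip(segs, segs[1:]):
            assert a.right_gene == b.left_gene
        syntenies = {s.segment_id: map_segment(s, table, order) for s in segs}
        groups = build_ogs_groups(list(syntenies.values()))
        for iv, grp in groups.items():
            for sid in grp.members:
                assert iv in syntenies[sid].mapped_intervals
        for sid, syn in syntenies.items():
            for iv in syn.mapped_intervals:
                assert sid in groups[iv].members


def test_deleting_one_gene_merges_two_segments(rng):
    """Removing one interior gene merges its two segments into one whose
    mapped intervals are the union of the originals'."""
    for _ in range(10):
        n = int(rng.integers(4, 20))
        genes, genome, table, order = _clade(n)
        segs = build_segments(genes, genome)
        victim = int(rng.integers(1, n - 1))
        before = {
            s.segment_id: map_segment(s, table, order)
            for s in segs
            if f"s1_g{victim}" in (s.left_gene, s.right_gene)
        }
        assert len(before) == 2
        kept = [g for g in genes if g.gene_id != f"s1_g{victim}"]
        merged = [
            s for s in build_segments(kept, genome)
            if s.left_gene == f"s1_g{victim - 1}"
        ][0]
        syn = map_segment(merged, table, order)
        union = set()
        for s in before.values():
            union |= set(s.mapped_intervals)
        assert set(syn.mapped_intervals) == union
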