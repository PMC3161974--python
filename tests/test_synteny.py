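import numpy as np
import pytest

from syntegene.io_formats import (
    AncestralOrder,
    GeneAnnotation,
    Genome,
    Pillar,
    PillarTable,
)
from syntegene.segments import interval_id
from syntegene.simdata import PlantedEvent, SimConfig, simulate_clade
from syntegene.synteny import CladeContext


def _two_species_clade(n=8, missing_in_b=(), translocate_b=False):
    """Two species sharing n genes in ancestral order. With
    ``translocate_b`` the ancestor (and spA) has two chromosomes while spB
    fuses them into one contig, so spB segments across the junction are
    rearranged relative to the ancestor."""
    half = n // 2
    genomes, annotations = {}, {}
    cells = {f"P{i}": {} for i in range(n)}

    def contig_of(sp, i):
        if translocate_b and sp == "spA":
            return f"{sp}_c1" if i < half else f"{sp}_c2"
        return f"{sp}_c1"

    for sp in ("spA", "spB"):
        genes, pos_by_contig = [], {}
        for i in range(n):
            if sp == "spB" and i in missing_in_b:
                continue
            cid = contig_of(sp, i)
            pos = pos_by_contig.get(cid, 10)
            gid = f"{sp}_g{i}"
            genes.append(GeneAnnotation(gid, sp, cid, "+", [(pos, pos + 90)]))
            cells[f"P{i}"][sp] = [gid]
            pos_by_contig[cid] = pos + 140
        genomes[sp] = Genome(
            sp, {cid: "A" * (p + 100) for cid, p in pos_by_contig.items()}
        )
        annotations[sp] = genes
    table = PillarTable(
        [Pillar(pid, c) for pid, c in cells.items()],
        {"spA": {"post_wgd": False}, "spB": {"post_wgd": False}},
    )
    if translocate_b:
        order = AncestralOrder({
            "chr1": [f"P{i}" for i in range(half)],
            "chr2": [f"P{i}" for i in range(half, n)],
        })
    else:
        order = AncestralOrder({"chr1": [f"P{i}" for i in range(n)]})
    return CladeContext(genomes, annotations, table, order)


class TestSyntenicContext:
    def test_colinear_includes_flank_orthologs_and_middle_gene(self):
        ctx = _two_species_clade(6)
        seg = [s for s in ctx.segments_by_species["spA"]
               if s.left_gene == "spA_g2"][0]
        # delete spB_g3's annotation? no: plain colinear pair g2-g3
        got = ctx.syntenic_context(seg, "spB")
        assert got.candidate_genes == ["spB_g2", "spB_g3"]
        assert not got.truncated_by_rearrangement

    def test_deletion_span_pulls_intermediate_genes(self):
        ctx = _two_species_clade(6, missing_in_b=())
        # spA segment spanning a deletion in spA: drop g3 from spA instead
        ctx2 = _two_species_clade(6)
        anns = [g for g in ctx2.annotations["spA"] if g.gene_id != "spA_g3"]
        ctx3 = CladeContext(
            ctx2.genomes, {"spA": anns, "spB": ctx2.annotations["spB"]},
            ctx2.pillars, ctx2.order,
        )
        seg = [s for s in ctx3.segments_by_species["spA"]
               if s.left_gene == "spA_g2"][0]
        assert seg.right_gene == "spA_g4"
        got = ctx3.syntenic_context(seg, "spB")
        assert got.candidate_genes == ["spB_g2", "spB_g3", "spB_g4"]

    def test_target_lost_every_gene_keeps_empty_context(self):
        ctx = _two_species_clade(6, missing_in_b=(2, 3))
        seg = [s for s in ctx.segments_by_species["spA"]
               if s.left_gene == "spA_g2"][0]
        got = ctx.syntenic_context(seg, "spB")
        assert got.candidate_genes == []
        assert not got.truncated_by_rearrangement

    def test_rearranged_flanks_step_out_and_truncate(self):
        ctx = _two_species_clade(12, translocate_b=True)
        # the spB segment across the fusion junction spans two ancestral
        # chromosomes -> rearranged -> step-out contexts
        seg = [s for s in ctx.segments_by_species["spB"]
               if s.left_gene == "spB_g5"][0]
        assert seg.right_gene == "spB_g6"
        syn = ctx.syntenies[seg.segment_id]
        assert syn.rearranged
        got = ctx.syntenic_context(seg, "spA")
        assert got.truncated_by_rearrangement
        assert "spA_g5" in got.candidate_genes
        assert "spA_g6" in got.candidate_genes

    def test_step_out_respects_cap_and_stays_near_flanks(self):
        ctx = _two_species_clade(50, translocate_b=True)
        seg = [s for s in ctx.segments_by_species["spB"]
               if s.left_gene == "spB_g24"][0]
        got = ctx.syntenic_context(seg, "spA")
        assert got.truncated_by_rearrangement
        # each flank contributes at most its ortholog plus cap genes per
        # genomic direction, and the walk never leaves the flank's contig
        assert len(got.candidate_genes) <= 2 * (2 * ctx.step_out_cap + 1)
        for g in got.candidate_genes:
            contig, rank = ctx.orders["spA"].index[g]
            near = []
            for flank in ("spA_g24", "spA_g25"):
                fc, fr = ctx.orders["spA"].index[flank]
                if fc == contig and abs(rank - fr) <= ctx.step_out_cap:
                    near.append(flank)
            assert near


def test_context_fasta_dump(tmp_path):
    ctx = _two_species_clade(6)
    seg = ctx.segments_by_species["spA"][0]
    path = tmp_path / "ctx.fa"
    ctx.dump_context_fasta(seg, path)
    text = path.read_text()
    for gid in ctx.syntenic_context(seg, "spB").candidate_genes:
        assert f">{gid} " in text


class TestPillarTargets:
    def _brute_force(self, ctx, query_species, query_gene):
        """All segments of pillar-lacking species whose mapped intervals
        cover the query pillar's ancestral position."""
        pid = ctx.pillars.pillar_of(query_species, query_gene)
        chrom, p = ctx.order.position(pid)
        n = len(ctx.order.chromosomes[chrom])
        adjacent = {
            interval_id(chrom, i) for i in (p - 1, p) if 0 <= i <= n - 2
        }
        out = {}
        for sid, syn in ctx.syntenies.items():
            seg = ctx.segments[sid]
            if seg.species_id == query_species:
                continue
            if ctx.pillars.pillar(pid).genes.get(seg.species_id):
                continue
            ivs = set(syn.mapped_intervals)
            if adjacent <= ivs or (syn.rearranged and adjacent & ivs):
                out.setdefault(seg.species_id, set()).add(sid)
        return out

    def test_deleted_ortholog_locus_found(self):
        ctx = _two_species_clade(8, missing_in_b=(4,))
        got = ctx.pillar_targets("spA", "spA_g4")
        assert set(got) == {"spB"}
        (c,) = got["spB"]
        seg = ctx.segments[c.segment_id]
        assert (seg.left_gene, seg.right_gene) == ("spB_g3", "spB_g5")
        # context genes are spA genes around the locus
        assert "spA_g4" in c.candidate_genes

    def test_matches_brute_force_scan_incl_wgd_tracks(self):
        """pillar_targets equals an exhaustive scan of all segments, on a
        simulated clade with a post-WGD species with track-specific losses."""
        cfg = SimConfig(seed=9, n_species=3, genes_per_chromosome=25,
                        post_wgd_species=("spC",))
        b = simulate_clade(cfg)
        ctx = CladeContext(b.genomes, b.annotations, b.pillars, b.order)
        checked = 0
        for sp in ("spA", "spB"):
            for ann in b.annotations[sp][:40]:
                got = ctx.pillar_targets(sp, ann.gene_id)
                expect = self._brute_force(ctx, sp, ann.gene_id)
                assert {k: {c.segment_id for c in v} for k, v in got.items()} == expect
                checked += 1
        assert checked > 10

    def test_symmetry_between_colinear_segments(self):
        """If a spB segment is a target for a spA query, the spA segment
        holding the query maps to a shared interval (colinear case)."""
        ctx = _two_species_clade(8, missing_in_b=(4,))
        got = ctx.pillar_targets("spA", "spA_g4")
        (c,) = got["spB"]
        b_ivs = set(ctx.syntenies[c.segment_id].mapped_intervals)
        a_segs = [
            s for s in ctx.segments_by_species["spA"]
            if "spA_g4" in (s.left_gene, s.right_gene)
        ]
        a_ivs = set()
        for s in a_segs:
            a_ivs |= set(ctx.syntenies[s.segment_id].mapped_intervals)
        assert a_ivs & b_ivs
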