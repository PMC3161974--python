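"""Syntenic candidate databases for each genomic segment.

For every segment's intergenic DNA the search database is deliberately
tiny: only the proteins of genes that are syntenic with the segment. In
colinear regions that is every target-species gene whose pillar lies
between the segment's flanking pillars (inclusive). Where rearrangement
breaks colinearity we "step out" from each mappable flank through the
target genome, retaining genes while their pillar positions remain locally
colinear, up to a hard cap of 10 genes per flank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .io_formats import AncestralOrder, GeneAnnotation, Genome, PillarTable
from .segments import (
    GenomicSegment,
    SegmentSynteny,
    build_ogs_groups,
    build_segments,
    interval_id,
    map_segment,
)


logger = logging.getLogger(__name__)


@dataclass
class SyntenicContext:
    """Genes of one target species eligible to probe one segment."""

    segment_id: str
    target_species: str
    candidate_genes: List[str]
    truncated_by_rearrangement: bool = False


@dataclass
class _GeneOrder:
    """Per-species genomic order of pillar-bearing genes."""

    by_contig: Dict[str, List[str]]
    index: Dict[str, Tuple[str, int]]  # gene_id -> (contig, rank)

    @classmethod
    def build(cls, annotations: Sequence[GeneAnnotation], pillars: PillarTable):
        by_contig: Dict[str, List[str]] = {}
        tmp: Dict[str, List[GeneAnnotation]] = {}
        for a in annotations:
            if a.status == "switched_off":
                continue
            tmp.setdefault(a.contig_id, []).append(a)
        index: Dict[str, Tuple[str, int]] = {}
        for cid in sorted(tmp):
            genes = sorted(tmp[cid], key=lambda g: (g.start, g.gene_id))
            by_contig[cid] = [g.gene_id for g in genes]
            for i, g in enumerate(genes):
                index[g.gene_id] = (cid, i)
        return cls(by_contig=by_contig, index=index)


def _interval_position_range(intervals: Sequence[str]) -> Optional[Tuple[str, int, int]]:
    """Ancestral chromosome + inclusive pillar-position range covered by a
    set of interval ids (None when they span several chromosomes)."""
    chroms = set()
    lo, hi = None, None
    for iv in intervals:
        chrom, idx = iv.rsplit(":", 1)
        chroms.add(chrom)
        i = int(idx)
        lo = i if lo is None else min(lo, i)
        hi = i + 1 if hi is None else max(hi, i + 1)
    if len(chroms) != 1:
        return None
    return (chroms.pop(), lo, hi)


class CladeContext:
    """Everything the scan needs about one clade snapshot: segments,
    synteny mappings, OGS groups, per-species gene order, and proteins.

    Rebuilt at the start of each discovery cycle because accepted genes
    change the segmentation.
    """

    def __init__(
        self,
        genomes: Dict[str, Genome],
        annotations: Dict[str, Sequence[GeneAnnotation]],
        pillars: PillarTable,
        order: AncestralOrder,
        step_out_cap: int = 10,
        gap_tolerance: int = 5,
        interval_cap: int = 20,
        include_ends: bool = False,
    ) -> None:
        self.genomes = genomes
        self.annotations = {sp: list(v) for sp, v in annotations.items()}
        self.pillars = pillars
        self.order = order
        self.step_out_cap = step_out_cap
        self.gap_tolerance = gap_tolerance
        self.species = sorted(genomes)
        self.ann_by_gene: Dict[Tuple[str, str], GeneAnnotation] = {}
        for sp in self.species:
            for a in self.annotations.get(sp, []):
                self.ann_by_gene[(sp, a.gene_id)] = a
        self._protein_cache: Dict[Tuple[str, str], str] = {}
        self.orders = {
            sp: _GeneOrder.build(self.annotations.get(sp, []), pillars)
            for sp in self.species
        }
        self.segments: Dict[str, GenomicSegment] = {}
        self.segments_by_species: Dict[str, List[GenomicSegment]] = {}
        self.syntenies: Dict[str, SegmentSynteny] = {}
        for sp in self.species:
            segs = build_segments(
                self.annotations.get(sp, []), genomes[sp], pillars=pillars,
                include_ends=include_ends,
            )
            self.segments_by_species[sp] = segs
            for s in segs:
                self.segments[s.segment_id] = s
                self.syntenies[s.segment_id] = map_segment(
                    s, pillars, order, interval_cap=interval_cap
                )
        self.groups = build_ogs_groups(list(self.syntenies.values()))

    # -- helpers ----------------------------------------------------------

    def protein(self, species: str, gene_id: str) -> str:
        key = (species, gene_id)
        cached = self._protein_cache.get(key)
        if cached is None:
            a = self.ann_by_gene[key]
            cached = a.protein(self.genomes[species])
            self._protein_cache[key] = cached
        return cached

    def _ancestral_pos(self, species: str, gene_id: str) -> Optional[Tuple[str, int]]:
        pid = self.pillars.pillar_of(species, gene_id)
        return self.order.position(pid) if pid else None

    def _genes_in_position_range(
        self, species: str, chrom: str, lo: int, hi: int
    ) -> List[str]:
        """Target-species genes whose pillar position lies in [lo, hi],
        ordered by ancestral position then gene id."""
        out = []
        for gid in self.orders[species].index:
            pos = self._ancestral_pos(species, gid)
            if pos and pos[0] == chrom and lo <= pos[1] <= hi:
                out.append((pos[1], gid))
        return [g for _, g in sorted(out)]

    def _step_out(self, species: str, flank_gene: str) -> List[str]:
        """Walk the target genome outward from one flank ortholog, keeping
        genes while local colinearity with the ancestor holds."""
        od = self.orders[species]
        loc = od.index.get(flank_gene)
        if loc is None:
            return []
        contig, rank = loc
        genes = od.by_contig[contig]
        start_pos = self._ancestral_pos(species, flank_gene)
        collected = [flank_gene]
        for step in (1, -1):
            prev_pos = start_pos
            n_kept = 0
            r = rank
            while n_kept < self.step_out_cap:
                r += step
                if r < 0 or r >= len(genes):
                    break
                gid = genes[r]
                pos = self._ancestral_pos(species, gid)
                if pos is None:  # orphan: transparent, does not break synteny
                    continue
                if prev_pos is not None and (
                    pos[0] != prev_pos[0]
                    or abs(pos[1] - prev_pos[1]) > self.gap_tolerance
                ):
                    break  # pillar shows synteny with the region is lost
                collected.append(gid)
                prev_pos = pos
                n_kept += 1
        return collected

    # -- public API -------------------------------------------------------

    def syntenic_context(
        self, segment: GenomicSegment, target_species: str
    ) -> SyntenicContext:
        """Candidate genes of ``target_species`` for one segment's
        intergenic DNA."""
        syn = self.syntenies[segment.segment_id]
        if not syn.mapped_intervals:
            return SyntenicContext(segment.segment_id, target_species, [], True)
        if not syn.rearranged:
            rng = _interval_position_range(syn.mapped_intervals)
            assert rng is not None
            chrom, lo, hi = rng
            genes = self._genes_in_position_range(target_species, chrom, lo, hi)
            return SyntenicContext(segment.segment_id, target_species, genes, False)
        # rearranged: step out from each mappable flank's target ortholog
        collected: List[str] = []
        for flank in (segment.left_gene, segment.right_gene):
            if flank is None:
                continue
            pid = self.pillars.pillar_of(segment.species_id, flank)
            if pid is None or self.order.position(pid) is None:
                continue
            for tgid in self.pillars.pillar(pid).genes.get(target_species, []):
                for g in self._step_out(target_species, tgid):
                    if g not in collected:
                        collected.append(g)
        ordered = sorted(
            collected,
            key=lambda g: (self._ancestral_pos(target_species, g) or ("~", 0), g),
        )
        return SyntenicContext(segment.segment_id, target_species, ordered, True)

    def pillar_targets(
        self, query_species: str, query_gene: str
    ) -> Dict[str, List[SyntenicContext]]:
        """For each species lacking a gene in the query's pillar, the
        segment(s) covering the pillar's ancestral position — the loci
        where an unannotated ortholog could hide — with their contexts
        relative to the query species."""
        pid = self.pillars.pillar_of(query_species, query_gene)
        pos = self.order.position(pid) if pid else None
        if pos is None:
            logger.warning(
                "query gene %s/%s has no placed pillar; no targets",
                query_species, query_gene,
            )
            return {}
        chrom, p = pos
        n = len(self.order.chromosomes[chrom])
        adjacent = []
        if p - 1 >= 0:
            adjacent.append(interval_id(chrom, p - 1))
        if p + 1 <= n - 1:
            adjacent.append(interval_id(chrom, p))
        out: Dict[str, List[SyntenicContext]] = {}
        pillar = self.pillars.pillar(pid)
        for sp in self.species:
            if sp == query_species or pillar.genes.get(sp):
                continue
            found: List[SyntenicContext] = []
            for iv in adjacent:
                for seg_id in sorted(self.groups.get(iv, type("g", (), {"members": set()})()).members):
                    seg = self.segments[seg_id]
                    if seg.species_id != sp:
                        continue
                    syn = self.syntenies[seg_id]
                    covers_all = all(
                        a in syn.mapped_intervals for a in adjacent
                    )
                    if covers_all or syn.rearranged:
                        if all(c.segment_id != seg_id for c in found):
                            ctx = self.syntenic_context(seg, query_species)
                            found.append(ctx)
            if found:
                out[sp] = found
        return out

    def dump_context_fasta(self, segment: GenomicSegment, path) -> None:
        """Write one segment's pooled syntenic proteins as FASTA, for use
        with an external search backend."""
        with open(path, "w") as fh:
            for gid, (sp, pid, prot) in sorted(
                self.pooled_context_proteins(segment).items()
            ):
                fh.write(f">{gid} species={sp} pillar={pid}\n{prot}\n")

    def pooled_context_proteins(
        self, segment: GenomicSegment
    ) -> Dict[str, Tuple[str, str, str]]:
        """Union of syntenic contexts over all other species, as
        gene_id -> (species, pillar_id, protein). This is the small
        database the segment's intergenic DNA is searched against."""
        pooled: Dict[str, Tuple[str, str, str]] = {}
        for sp in self.species:
            if sp == segment.species_id:
                continue
            ctx = self.syntenic_context(segment, sp)
            for gid in ctx.candidate_genes:
                pid = self.pillars.pillar_of(sp, gid)
                if pid is None:
                    continue
                pooled[gid] = (sp, pid, self.protein(sp, gid))
        return pooled
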