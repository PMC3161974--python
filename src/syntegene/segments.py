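"""Two-gene genomic segments and their grouping into orthologous sets.

A genome is cut into overlapping segments, each holding two adjacent
annotated genes and the intergenic DNA between them. Mapping both flanking
genes onto the reference (ancestral) gene order assigns every segment to
one or more ancestral intervals; segments from different species assigned
to the same interval form an Orthologous Genomic Segment (OGS) group — the
unit within which even very weak homology hits are trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .io_formats import AncestralOrder, GeneAnnotation, Genome, PillarTable


@dataclass
class GenomicSegment:
    """Two adjacent genes plus the DNA between them (either flank may be
    missing for contig-end segments)."""

    segment_id: str
    species_id: str
    contig_id: str
    left_gene: Optional[str]
    right_gene: Optional[str]
    span: Tuple[int, int]
    intergenic: Tuple[int, int]  # empty when genes abut or overlap

    @property
    def intergenic_len(self) -> int:
        return max(0, self.intergenic[1] - self.intergenic[0])


@dataclass(frozen=True)
class AncestralInterval:
    interval_id: str
    chromosome: str
    left_pillar: str
    right_pillar: str


@dataclass
class OGSGroup:
    interval_id: str
    members: Set[str] = field(default_factory=set)


@dataclass
class SegmentSynteny:
    segment_id: str
    mapped_intervals: List[str]
    rearranged: bool


def interval_id(chrom: str, index: int) -> str:
    """ID of the interval between ancestral positions index and index+1."""
    return f"{chrom}:{index}"


def intervals_of(order: AncestralOrder, chrom: str) -> List[AncestralInterval]:
    pids = order.chromosomes[chrom]
    return [
        AncestralInterval(interval_id(chrom, i), chrom, pids[i], pids[i + 1])
        for i in range(len(pids) - 1)
    ]


def build_segments(
    genes: Sequence[GeneAnnotation],
    genome: Genome,
    pillars: Optional[PillarTable] = None,
    include_ends: bool = False,
) -> List[GenomicSegment]:
    """Cut one species' genome into overlapping two-gene segments.

    Genes with status ``switched_off`` never anchor a segment. When a
    pillar table is supplied, genes absent from every pillar are
    transparent for adjacency (skipped as anchors, retained inside spans).
    A contig with n eligible genes yields n-1 segments; with
    ``include_ends`` two extra single-flank segments cover the contig tips.
    """
    by_contig: Dict[str, List[GeneAnnotation]] = {}
    for g in genes:
        if g.status == "switched_off":
            continue
        if pillars is not None and pillars.pillar_of(g.species_id, g.gene_id) is None:
            continue
        by_contig.setdefault(g.contig_id, []).append(g)
    segments: List[GenomicSegment] = []
    for contig_id in sorted(by_contig):
        anchors = sorted(by_contig[contig_id], key=lambda g: (g.start, g.gene_id))
        sp = anchors[0].species_id
        if include_ends and anchors:
            first = anchors[0]
            segments.append(
                GenomicSegment(
                    segment_id=f"{sp}|{contig_id}|^|{first.gene_id}",
                    species_id=sp,
                    contig_id=contig_id,
                    left_gene=None,
                    right_gene=first.gene_id,
                    span=(0, first.end),
                    intergenic=(0, first.start),
                )
            )
        for a, b in zip(anchors, anchors[1:]):
            ig = (a.end, b.start) if a.end < b.start else (a.end, a.end)
            segments.append(
                GenomicSegment(
                    segment_id=f"{sp}|{contig_id}|{a.gene_id}|{b.gene_id}",
                    species_id=sp,
                    contig_id=contig_id,
                    left_gene=a.gene_id,
                    right_gene=b.gene_id,
                    span=(a.start, max(a.end, b.end)),
                    intergenic=ig,
                )
            )
        if include_ends and anchors:
            last = anchors[-1]
            clen = len(genome.contigs[contig_id])
            segments.append(
                GenomicSegment(
                    segment_id=f"{sp}|{contig_id}|{last.gene_id}|$",
                    species_id=sp,
                    contig_id=contig_id,
                    left_gene=last.gene_id,
                    right_gene=None,
                    span=(last.start, clen),
                    intergenic=(last.end, clen),
                )
            )
    return segments


def _adjacent_intervals(order: AncestralOrder, chrom: str, pos: int) -> List[str]:
    n = len(order.chromosomes[chrom])
    out = []
    if pos - 1 >= 0:
        out.append(interval_id(chrom, pos - 1))
    if pos + 1 <= n - 1:
        out.append(interval_id(chrom, pos))
    return out


def map_segment(
    segment: GenomicSegment,
    pillars: PillarTable,
    order: AncestralOrder,
    interval_cap: int = 20,
) -> SegmentSynteny:
    """Locate a segment on the ancestral gene order via its flanking genes.

    Both flanks on one ancestral chromosome within the cap: the segment
    covers every interval between them (runs of gene deletion make a single
    segment orthologous to several consecutive intervals). Flanks on
    different chromosomes, a lone mappable flank, or a span beyond the cap:
    the segment is marked rearranged and keeps only the interval(s)
    adjacent to each mappable flank ("singlehit" semantics).
    """
    positions = []
    for gid in (segment.left_gene, segment.right_gene):
        if gid is None:
            positions.append(None)
            continue
        pid = pillars.pillar_of(segment.species_id, gid)
        positions.append(order.position(pid) if pid else None)
    lp, rp = positions
    if lp is None and rp is None:
        return SegmentSynteny(segment.segment_id, [], rearranged=True)
    if lp is not None and rp is not None and lp[0] == rp[0]:
        chrom = lp[0]
        a, b = sorted((lp[1], rp[1]))
        if b - a <= interval_cap:
            if a == b:  # both flanks in one pillar (WGD paralogs / tandem)
                ivs = _adjacent_intervals(order, chrom, a)
            else:
                ivs = [interval_id(chrom, i) for i in range(a, b)]
            return SegmentSynteny(segment.segment_id, ivs, rearranged=False)
    ivs: List[str] = []
    for p in (lp, rp):
        if p is not None:
            for iv in _adjacent_intervals(order, p[0], p[1]):
                if iv not in ivs:
                    ivs.append(iv)
    return SegmentSynteny(segment.segment_id, ivs, rearranged=True)


def dump_segments_fasta(
    segments: Sequence[GenomicSegment], genome: Genome, path
) -> None:
    """Write segments as a nucleotide FASTA (the full database an external
    search tool can index); record IDs encode species/contig/flanks."""
    with open(path, "w") as fh:
        for seg in segments:
            seq = genome.contigs[seg.contig_id][seg.span[0] : seg.span[1]]
            fh.write(f">{seg.segment_id}\n{seq}\n")


def build_ogs_groups(syntenies: Sequence[SegmentSynteny]) -> Dict[str, OGSGroup]:
    """Invert segment->interval mappings into per-interval OGS groups."""
    groups: Dict[str, OGSGroup] = {}
    for syn in syntenies:
        for iv in syn.mapped_intervals:
            groups.setdefault(iv, OGSGroup(interval_id=iv)).members.add(
                syn.segment_id
            )
    return groups
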