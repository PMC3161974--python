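"""Whole-genome discovery cycles.

Each cycle rebuilds the segmentation from the current annotation set
(discoveries change segmentation), searches every unmasked intergenic
region against its syntenic protein database, classifies hit loci, masks
pseudogene loci, and inserts accepted genes into their pillars so they
serve as queries from the next cycle on. Cycling repeats until a cycle
accepts nothing new.

Acceptance policy: the original workflow ended with human inspection of
every candidate; here a reproducible policy stands in for it. Non-flagged
candidates are accepted automatically; flagged candidates (estimated
frameshift positions, small-exon intron members, missing start/stop,
low-similarity alignments, pillar-cell conflicts) go to a review table and
are not inserted unless ``accept_flagged`` is set.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd
import yaml

from .aligner import search_dna_vs_proteins
from .genefinder import (
    CandidateGene,
    FinderParams,
    PillarProfile,
    classify_locus,
)
from .io_formats import (
    AncestralOrder,
    GeneAnnotation,
    Genome,
    PillarTable,
    write_gff,
    write_report,
)
from .synteny import CladeContext

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    finder: FinderParams = field(default_factory=FinderParams)
    step_out_cap: int = 10
    gap_tolerance: int = 5
    interval_cap: int = 20
    include_ends: bool = False
    max_cycles: int = 10
    auto_accept: bool = True
    accept_flagged: bool = False
    min_search_nt: int = 60

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        finder_raw = raw.pop("finder", {})
        search_raw = finder_raw.pop("search", {}) if finder_raw else {}
        finder = FinderParams(**finder_raw)
        if search_raw:
            from .aligner import SearchParams

            finder.search = SearchParams(**search_raw)
        return cls(finder=finder, **raw)


@dataclass
class CladeInputs:
    genomes: Dict[str, Genome]
    annotations: Dict[str, List[GeneAnnotation]]
    pillars: PillarTable
    order: AncestralOrder


@dataclass
class CycleState:
    cycle_index: int = 0
    accepted: List[CandidateGene] = field(default_factory=list)
    review: List[CandidateGene] = field(default_factory=list)
    rejected: List[CandidateGene] = field(default_factory=list)
    masked_regions: List[Tuple[str, str, Tuple[int, int]]] = field(default_factory=list)
    pillar_table: Optional[PillarTable] = None
    stats: List[dict] = field(default_factory=list)
    handled: Set[Tuple[str, str]] = field(default_factory=set)  # (species, pillar)
    converged: bool = False


def _current_annotations(
    inputs: CladeInputs, state: CycleState
) -> Dict[str, List[GeneAnnotation]]:
    out = {sp: list(anns) for sp, anns in inputs.annotations.items()}
    for c in state.accepted:
        out.setdefault(c.species_id, []).append(
            GeneAnnotation(
                gene_id=c.gene_id,
                species_id=c.species_id,
                contig_id=c.contig_id,
                strand=c.strand,
                exons=list(c.model),
                status="discovered",
                correction_site=c.correction_site,
            )
        )
    return out


def _overlaps_masked(
    state: CycleState, species: str, contig: str, rng: Tuple[int, int]
) -> bool:
    return any(
        sp == species and cid == contig and rng[0] < m[1] and m[0] < rng[1]
        for sp, cid, m in state.masked_regions
    )


def _profile_for_pillar(
    pillar_id: str,
    ctx: CladeContext,
) -> PillarProfile:
    proteins: Dict[str, str] = {}
    exon_lens: Dict[str, List[int]] = {}
    for sp, gid in ctx.pillars.pillar(pillar_id).all_genes():
        ann = ctx.ann_by_gene.get((sp, gid))
        if ann is None:
            continue
        proteins[gid] = ctx.protein(sp, gid)
        if len(ann.exons) > 1 and ann.correction_site is None:
            exons = ann.exons if ann.strand == "+" else list(reversed(ann.exons))
            exon_lens[gid] = [e - s for s, e in exons]
    return PillarProfile.from_members(pillar_id, proteins, exon_lens)


def run_cycle(
    state: CycleState, inputs: CladeInputs, params: Optional[PipelineParams] = None
) -> CycleState:
    """One scan over every unmasked intergenic region of every species."""
    params = params or PipelineParams()
    state.cycle_index += 1
    cycle = state.cycle_index
    pillars = state.pillar_table if state.pillar_table is not None else inputs.pillars
    state.pillar_table = pillars
    annotations = _current_annotations(inputs, state)
    ctx = CladeContext(
        inputs.genomes,
        annotations,
        pillars,
        inputs.order,
        step_out_cap=params.step_out_cap,
        gap_tolerance=params.gap_tolerance,
        interval_cap=params.interval_cap,
        include_ends=params.include_ends,
    )
    n_regions = n_hit = 0
    accepted_now: List[CandidateGene] = []
    by_class: Dict[str, int] = {}
    by_reason: Dict[str, int] = {}
    masked_now = 0
    for sp in ctx.species:
        for seg in sorted(
            ctx.segments_by_species[sp], key=lambda s: (s.contig_id, s.span)
        ):
            if seg.intergenic_len < params.min_search_nt:
                continue
            if _overlaps_masked(state, sp, seg.contig_id, seg.intergenic):
                continue
            pooled = ctx.pooled_context_proteins(seg)
            if not pooled:
                continue
            n_regions += 1
            region = ctx.genomes[sp].contigs[seg.contig_id][
                seg.intergenic[0] : seg.intergenic[1]
            ]
            hits = search_dna_vs_proteins(
                region,
                {gid: prot for gid, (_, _, prot) in pooled.items()},
                params.finder.search,
                query_id=seg.segment_id,
                detail=24,
            )
            if not hits:
                continue
            n_hit += 1
            target_pillar = pooled[hits[0].subject_id][1]
            if (sp, target_pillar) in state.handled:
                continue
            profile = _profile_for_pillar(target_pillar, ctx)
            cand = classify_locus(region, hits, profile, params.finder)
            cand.stage1_evalue = hits[0].evalue
            cand.species_id = sp
            cand.pillar_id = target_pillar
            cand.cycle = cycle
            cand.gene_id = f"{sp}_YGOB_{target_pillar}"
            cand.shifted(seg.intergenic[0], seg.contig_id)
            syn = ctx.syntenies[seg.segment_id]
            if syn.rearranged:
                cand.flags.add("rearranged_context")
            if cand.klass == "rejected":
                by_reason[cand.reject_reason or "unknown"] = (
                    by_reason.get(cand.reject_reason or "unknown", 0) + 1
                )
                # keep the locus eligible: a later cycle's new queries may
                # rescue it; remember only its latest classification
                state.rejected = [
                    c
                    for c in state.rejected
                    if (c.species_id, c.pillar_id) != (sp, target_pillar)
                ]
                state.rejected.append(cand)
                continue
            if cand.klass == "pseudogene":
                state.masked_regions.append((sp, seg.contig_id, cand.model[0]))
                state.rejected.append(cand)
                state.handled.add((sp, target_pillar))
                by_class["pseudogene"] = by_class.get("pseudogene", 0) + 1
                masked_now += 1
                logger.info("%s: pseudogene locus masked at %s", sp, cand.model[0])
                continue
            blocking = set(cand.flags) - {"rearranged_context"}
            if params.auto_accept and (not blocking or params.accept_flagged):
                if not pillars.insert_gene(target_pillar, sp, cand.gene_id):
                    cand.flags.add("conflict")
                    state.review.append(cand)
                else:
                    accepted_now.append(cand)
                    state.accepted.append(cand)
                    by_class[cand.klass] = by_class.get(cand.klass, 0) + 1
            else:
                state.review.append(cand)
            state.handled.add((sp, target_pillar))
    state.stats.append(
        {
            "cycle": cycle,
            "regions_searched": n_regions,
            "regions_hit": n_hit,
            "accepted": len(accepted_now),
            "accepted_by_class": dict(sorted(by_class.items())),
            "rejected_by_reason": dict(sorted(by_reason.items())),
            "pseudogenes_masked": masked_now,
        }
    )
    state.converged = not accepted_now
    return state


def run_to_convergence(
    inputs: CladeInputs, params: Optional[PipelineParams] = None
) -> CycleState:
    """Cycle until a scan accepts zero new genes (or max_cycles)."""
    params = params or PipelineParams()
    state = CycleState(pillar_table=inputs.pillars)
    for _ in range(params.max_cycles):
        run_cycle(state, inputs, params)
        if state.converged:
            return state
    logger.warning(
        "no convergence within %d cycles; emitting partial results",
        params.max_cycles,
    )
    return state


def report(state: CycleState, outdir: str) -> Dict[str, pd.DataFrame]:
    """Write summary TSV, per-candidate detail TSV, review TSV, and a GFF3
    of accepted gene models."""
    os.makedirs(outdir, exist_ok=True)
    species = sorted(
        {c.species_id for c in state.accepted}
        | {c.species_id for c in state.review}
        | {m[0] for m in state.masked_regions}
    )
    rows = []
    for sp in species:
        acc = [c for c in state.accepted if c.species_id == sp]
        rows.append(
            {
                "species_id": sp,
                "genes_added": len(acc),
                "intron_containing_added": sum(
                    1 for c in acc if c.klass == "intron_model"
                ),
                "frameshift_corrected": sum(
                    1 for c in acc if c.klass == "frameshift_corrected"
                ),
                "pseudogenes": sum(
                    1 for m in state.masked_regions if m[0] == sp
                ),
                "added_lt_100_codons": sum(1 for c in acc if len(c.protein) < 100),
                "added_lt_200_codons": sum(1 for c in acc if len(c.protein) < 200),
                "flagged_for_review": sum(
                    1 for c in state.review if c.species_id == sp
                ),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "species_id", "genes_added", "intron_containing_added",
            "frameshift_corrected", "pseudogenes", "added_lt_100_codons",
            "added_lt_200_codons", "flagged_for_review",
        ],
    )
    summary.to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False)
    write_report(
        state.accepted + state.review + state.rejected,
        os.path.join(outdir, "details.tsv"),
    )
    write_report(state.review, os.path.join(outdir, "review.tsv"))
    anns = [
        GeneAnnotation(
            gene_id=c.gene_id,
            species_id=c.species_id,
            contig_id=c.contig_id,
            strand=c.strand,
            exons=list(c.model),
            status="discovered",
            correction_site=c.correction_site,
        )
        for c in state.accepted
    ]
    write_gff(anns, os.path.join(outdir, "accepted.gff3"))
    cycles = pd.DataFrame(state.stats)
    cycles.to_csv(os.path.join(outdir, "cycles.tsv"), sep="\t", index=False)
    return {"summary": summary, "cycles": cycles}
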