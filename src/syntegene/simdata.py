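"""Synthetic clades with ground truth.

Generates a small group of related genomes the way the scan expects to
see them: a shared ancestral gene order, per-species sequence divergence
under purifying selection (codon-level substitution with transition bias
and nonsynonymous acceptance probability omega < 1), per-species gene
deletions, optional whole-genome duplication, and planted events — hidden
(unannotated) genes, single-frameshift corruptions, multi-disruption
pseudogenes, GT-AG intron genes, and local gene-order rearrangements.
Intergenic DNA is drawn from a 3rd-order Markov chain trained on the
complement strand of the simulated coding sequences, so spurious ORFs of
realistic length occur and exercise the rejection rules.

Every planted gene keeps an annotated ortholog in at least one other
species: the scan can only find genes for which some species provides a
query.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .genefinder import CandidateGene
from .io_formats import (
    AncestralOrder,
    GeneAnnotation,
    Genome,
    Pillar,
    PillarTable,
    write_ancestral_order,
    write_genome,
    write_gff,
    write_pillars,
)

SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if str(Seq(a + b + c).translate()) != "*"
]
STOPS = ("TAA", "TAG", "TGA")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class SimConfigError(ValueError):
    pass


@dataclass
class PlantedEvent:
    kind: str  # hide_annotation | insert_frameshift | make_pseudogene | add_intron | rearrange
    species: str
    chromosome: int = 0          # ancestral chromosome index
    position: Optional[int] = None  # pillar index; None = auto-assign
    aa_identity: Optional[float] = None  # hidden copy's identity to ancestor
    n_codons: Optional[int] = None
    k_disruptions: int = 2
    exon_codons: Tuple[int, ...] = ()
    splice_sites: Tuple[str, str] = ("GT", "AG")
    block: int = 4               # genes inverted by a rearrange event
    mutate_from: Optional[str] = None  # derive this copy from another
                                       # species' copy instead of the ancestor
                                       # (local non-star phylogeny)
    keep_codons: Optional[Tuple[int, int]] = None  # retain only this codon
                                       # slice (domain loss); start/stop
                                       # codons are restored as needed


@dataclass
class SimConfig:
    seed: int = 0
    n_species: int = 3
    n_chromosomes: int = 1
    genes_per_chromosome: int = 50
    gene_len_codons: Tuple[int, int] = (80, 200)
    identity_to_ancestor: Tuple[float, float] = (0.78, 0.92)
    gene_identity_jitter: float = 0.04
    omega: float = 0.2           # purifying selection: P(accept nonsyn)
    transition_prob: float = 0.66
    deletion_prob: float = 0.04
    intergenic_len: Tuple[int, int] = (120, 300)
    intron_len: Tuple[int, int] = (45, 90)
    post_wgd_species: Tuple[str, ...] = ()
    events: List[PlantedEvent] = field(default_factory=list)

    def species_ids(self) -> List[str]:
        return [f"sp{chr(65 + i)}" for i in range(self.n_species)]


@dataclass
class TruthRecord:
    kind: str
    klass: str                  # expected classification
    species: str
    pillar_id: str
    contig_id: str
    strand: str
    start: int                  # CDS span incl stop codon, forward strand
    end: int
    protein: str
    exons: List[Tuple[int, int]] = field(default_factory=list)
    correction_site: Optional[int] = None


@dataclass
class GroundTruth:
    records: List[TruthRecord] = field(default_factory=list)

    def by_locus(self) -> Dict[Tuple[str, str], TruthRecord]:
        return {(r.species, r.pillar_id): r for r in self.records}


@dataclass
class SimBundle:
    config: SimConfig
    genomes: Dict[str, Genome]
    annotations: Dict[str, List[GeneAnnotation]]
    pillars: PillarTable
    order: AncestralOrder
    truth: GroundTruth

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        for sp, g in self.genomes.items():
            write_genome(g, os.path.join(outdir, f"{sp}.fa"))
            write_gff(self.annotations[sp], os.path.join(outdir, f"{sp}.gff3"))
        write_pillars(self.pillars, os.path.join(outdir, "pillars.tsv"))
        write_ancestral_order(self.order, os.path.join(outdir, "ancestral.txt"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump([asdict(r) for r in self.truth.records], fh, indent=1)
        with open(os.path.join(outdir, "species_meta.json"), "w") as fh:
            json.dump(self.pillars.species_meta, fh, indent=1)


# ---------------------------------------------------------------------------
# sequence-level helpers


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + STOPS[rng.integers(3)]


_AA_OF: Dict[str, str] = {}


def _aa_of(codon: str) -> str:
    if not _AA_OF:
        for a in "TCAG":
            for b in "TCAG":
                for c in "TCAG":
                    cd = a + b + c
                    _AA_OF[cd] = str(Seq(cd).translate())
    return _AA_OF[codon]


def mutate_cds(
    cds: str,
    target_identity: float,
    rng: np.random.Generator,
    omega: float = 0.2,
    transition_prob: float = 0.66,
) -> str:
    """Codon-level divergence under purifying selection until the protein
    identity to the input drops to the target. Start and stop codons are
    preserved; mutations creating stops are rejected; nonsynonymous
    changes are accepted with probability omega (Ka/Ks < 1 results)."""
    n_codons = len(cds) // 3
    _aa_of("ATG")  # ensure table
    orig_aa = [_AA_OF[cds[3 * i : 3 * i + 3]] for i in range(n_codons)]
    seq = list(cds)
    diffs = 0
    needed = int(round((1.0 - target_identity) * (n_codons - 1)))
    attempts = 0
    max_attempts = 500 * n_codons
    chunk = 256
    pos_buf = rand_buf = tv_buf = None
    bi = chunk
    while diffs < needed and attempts < max_attempts:
        if bi >= chunk:
            pos_buf = rng.integers(3, len(seq) - 3, size=chunk)
            tv_buf = rng.random(size=chunk)
            rand_buf = rng.random(size=chunk)
            bi = 0
        pos = int(pos_buf[bi])
        base = seq[pos]
        if tv_buf[bi] < transition_prob:
            new = _TRANSITION[base]
        else:
            choices = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
            new = choices[int(rand_buf[bi] * 2) % 2]
        accept_roll = rand_buf[bi]
        bi += 1
        attempts += 1
        ci = pos // 3
        codon = seq[3 * ci] + seq[3 * ci + 1] + seq[3 * ci + 2]
        nc = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if nc in STOPS:
            continue
        old_aa = _AA_OF[codon]
        new_aa = _AA_OF[nc]
        if new_aa != old_aa and accept_roll >= omega:
            continue
        was_diff = old_aa != orig_aa[ci]
        seq[pos] = new
        is_diff = new_aa != orig_aa[ci]
        diffs += int(is_diff) - int(was_diff)
    return "".join(seq)


class MarkovIntergenic:
    """3rd-order Markov chain over A/C/G/T fitted to training DNA."""

    def __init__(self, training: str, rng: np.random.Generator) -> None:
        self.rng = rng
        self.k = 3
        counts: Dict[str, np.ndarray] = {}
        idx = {b: i for i, b in enumerate("ACGT")}
        for i in range(len(training) - self.k):
            ctx = training[i : i + self.k]
            nxt = training[i + self.k]
            if nxt not in idx:
                continue
            counts.setdefault(ctx, np.ones(4))[idx[nxt]] += 1
        self.probs = {c: v / v.sum() for c, v in counts.items()}
        self.uniform = np.full(4, 0.25)

    def sample(self, length: int) -> str:
        bases = "ACGT"
        out = [bases[int(self.rng.integers(4))] for _ in range(self.k)]
        for _ in range(length - self.k):
            p = self.probs.get("".join(out[-self.k :]), self.uniform)
            out.append(bases[int(self.rng.choice(4, p=p))])
        return "".join(out[:length])


def _slice_codons(cds: str, a: int, b: int) -> str:
    """Keep codons [a, b) of a CDS, restoring ATG start and a stop codon
    (models domain loss after gene fission/truncation)."""
    codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]  # drop stop
    kept = codons[a:b]
    if not kept:
        raise SimConfigError("keep_codons slice is empty")
    if kept[0] != "ATG":
        kept = ["ATG"] + kept
    return "".join(kept) + "TAA"


def _insert_disruptions(
    cds: str, kinds: Sequence[str], positions: Sequence[int]
) -> str:
    """Apply indel/stop disruptions (positions are codon indices, applied
    right-to-left so earlier coordinates stay valid)."""
    seq = cds
    for kind, ci in sorted(zip(kinds, positions), key=lambda t: -t[1]):
        p = 3 * ci
        if kind == "ins":
            seq = seq[:p] + "A" + seq[p:]
        elif kind == "del":
            seq = seq[:p] + seq[p + 1 :]
        elif kind == "stop":
            seq = seq[:p] + "TAA" + seq[p + 3 :]
    return seq


# ---------------------------------------------------------------------------
# clade assembly


def _assign_event_positions(config: SimConfig, rng: np.random.Generator) -> None:
    taken: Dict[int, set] = {}
    explicit: Dict[int, set] = {}
    for ev in config.events:
        if ev.position is not None:
            cells = taken.setdefault(ev.chromosome, set())
            exact = explicit.setdefault(ev.chromosome, set())
            span = {ev.position - 1, ev.position, ev.position + 1}
            # several species may share one planted locus; distinct loci
            # must not be adjacent
            if (
                ev.kind != "rearrange"
                and span & cells
                and ev.position not in exact
            ):
                raise SimConfigError(
                    f"planted events collide near position {ev.position}"
                )
            cells |= span
            exact.add(ev.position)
    for ev in config.events:
        if ev.position is not None:
            continue
        cells = taken.setdefault(ev.chromosome, set())
        n = config.genes_per_chromosome
        for _ in range(200):
            pos = int(rng.integers(2, n - 2 - (ev.block if ev.kind == "rearrange" else 0)))
            span = set(range(pos - 1, pos + 2 + (ev.block if ev.kind == "rearrange" else 0)))
            if not span & cells:
                ev.position = pos
                cells |= span
                break
        else:
            raise SimConfigError("could not place planted event without collision")


def simulate_clade(config: SimConfig) -> SimBundle:
    """Generate genomes, annotations, pillar table, ancestral order and
    ground truth for one synthetic clade."""
    config = copy.deepcopy(config)  # event placement must not leak back
    rng = np.random.default_rng(config.seed)
    species = config.species_ids()
    for ev in config.events:
        if ev.species not in species:
            raise SimConfigError(f"event species {ev.species} not in clade")
        if ev.species in config.post_wgd_species:
            raise SimConfigError("planted events on post-WGD species unsupported")
    _assign_event_positions(config, rng)
    events_at: Dict[Tuple[int, int], List[PlantedEvent]] = {}
    for ev in config.events:
        if ev.kind == "rearrange":
            continue
        key = (ev.chromosome, ev.position)
        cell = events_at.setdefault(key, [])
        if any(e.species == ev.species for e in cell):
            raise SimConfigError(f"two events on one locus {key} for {ev.species}")
        cell.append(ev)
    for ev in config.events:
        if ev.mutate_from is not None and ev.mutate_from >= ev.species:
            raise SimConfigError(
                "mutate_from must name an earlier species in sort order"
            )

    # --- ancestral genome -------------------------------------------------
    lo, hi = config.gene_len_codons
    ancestral: Dict[str, dict] = {}
    chrom_pillars: Dict[str, List[str]] = {}
    for c in range(config.n_chromosomes):
        chrom = f"anc_{c + 1}"
        chrom_pillars[chrom] = []
        for i in range(config.genes_per_chromosome):
            pid = f"Anc_{c + 1}.{i + 1}"
            chrom_pillars[chrom].append(pid)
            evs = events_at.get((c, i), [])
            intron_evs = [e for e in evs if e.kind == "add_intron"]
            if intron_evs:
                exon_codons = tuple(intron_evs[0].exon_codons) or (80, 45)
                n_codons = sum(exon_codons)
            else:
                exon_codons = ()
                sized = [e for e in evs if e.n_codons]
                n_codons = (
                    sized[0].n_codons if sized else int(rng.integers(lo, hi + 1))
                )
            ancestral[pid] = {
                "cds": _random_cds(rng, n_codons),
                "exon_codons": exon_codons,
                "strand": "+" if rng.random() < 0.5 else "-",
                "events": evs,
            }

    markov = MarkovIntergenic(
        str(Seq("".join(a["cds"] for a in ancestral.values())).reverse_complement()),
        rng,
    )

    # --- per-species identity levels --------------------------------------
    id_lo, id_hi = config.identity_to_ancestor
    sp_identity = {sp: float(rng.uniform(id_lo, id_hi)) for sp in species}

    # protected pillars: planted loci and their neighbours stay present
    protected: Dict[str, set] = {sp: set() for sp in species}
    for (c, i) in events_at:
        chrom = f"anc_{c + 1}"
        for sp in species:
            for j in (i - 1, i, i + 1):
                if 0 <= j < config.genes_per_chromosome:
                    protected[sp].add(chrom_pillars[chrom][j])

    genomes: Dict[str, Genome] = {}
    annotations: Dict[str, List[GeneAnnotation]] = {}
    copies: Dict[Tuple[str, str], str] = {}  # (pillar, species) -> clean CDS
    pillar_cells: Dict[str, Dict[str, List[str]]] = {
        pid: {} for pids in chrom_pillars.values() for pid in pids
    }
    truth = GroundTruth()

    for sp in species:
        tracks = ("A", "B") if sp in config.post_wgd_species else ("",)
        contigs: Dict[str, str] = {}
        anns: List[GeneAnnotation] = []
        for c, (chrom, pids) in enumerate(sorted(chrom_pillars.items())):
            order_pids = list(pids)
            for ev in config.events:
                if ev.kind == "rearrange" and ev.species == sp and ev.chromosome == c:
                    i, b = ev.position, ev.block
                    order_pids[i : i + b] = reversed(order_pids[i : i + b])
            for track in tracks:
                contig = f"{sp}_c{c + 1}{track}"
                retained = []
                for pid in order_pids:
                    if sp in config.post_wgd_species:
                        # track-specific loss: each copy kept with p=0.55
                        if rng.random() > 0.55:
                            continue
                    elif (
                        pid not in protected[sp]
                        and rng.random() < config.deletion_prob
                    ):
                        continue
                    retained.append(pid)
                seq_parts: List[str] = []
                pos = 0
                ig = markov.sample(int(rng.integers(*config.intergenic_len)))
                seq_parts.append(ig)
                pos += len(ig)
                for pid in retained:
                    anc = ancestral[pid]
                    ev = next(
                        (e for e in anc["events"] if e.species == sp), None
                    )
                    target = min(
                        0.999,
                        max(
                            0.25,
                            sp_identity[sp]
                            + float(rng.normal(0, config.gene_identity_jitter)),
                        ),
                    )
                    hidden_here = ev is not None and ev.kind != "modify_copy"
                    if ev is not None and ev.aa_identity is not None:
                        target = ev.aa_identity
                    base_cds = anc["cds"]
                    if ev is not None and ev.mutate_from is not None:
                        base_cds = copies[(pid, ev.mutate_from)]
                    cds = mutate_cds(
                        base_cds, target, rng, config.omega, config.transition_prob
                    )
                    if ev is not None and ev.keep_codons is not None:
                        cds = _slice_codons(cds, *ev.keep_codons)
                    copies[(pid, sp)] = cds
                    gene_id = f"{sp}_{pid}" + (f"_{track}" if track else "")
                    strand = anc["strand"]
                    gene_seq, exon_local, extra = _build_gene_dna(
                        cds, anc, ev, sp, rng, config
                    )
                    if strand == "-":
                        L = len(gene_seq)
                        gene_seq = str(Seq(gene_seq).reverse_complement())
                        exon_local = sorted((L - e, L - s) for s, e in exon_local)
                        if extra.get("correction_site") is not None:
                            extra["correction_site"] = L - extra["correction_site"]
                    exons = [(pos + s, pos + e) for s, e in exon_local]
                    if hidden_here:
                        truth.records.append(
                            TruthRecord(
                                kind=ev.kind,
                                klass=extra["klass"],
                                species=sp,
                                pillar_id=pid,
                                contig_id=contig,
                                strand=strand,
                                start=pos,
                                end=pos + len(gene_seq),
                                protein=extra["protein"],
                                exons=exons,
                                correction_site=(
                                    pos + extra["correction_site"]
                                    if extra.get("correction_site") is not None
                                    else None
                                ),
                            )
                        )
                    else:
                        anns.append(
                            GeneAnnotation(
                                gene_id=gene_id,
                                species_id=sp,
                                contig_id=contig,
                                strand=strand,
                                exons=exons,
                            )
                        )
                        pillar_cells[pid].setdefault(sp, []).append(gene_id)
                    seq_parts.append(gene_seq)
                    pos += len(gene_seq)
                    ig = markov.sample(int(rng.integers(*config.intergenic_len)))
                    seq_parts.append(ig)
                    pos += len(ig)
                contigs[contig] = "".join(seq_parts)
        genomes[sp] = Genome(species_id=sp, contigs=contigs)
        annotations[sp] = sorted(anns, key=lambda a: (a.contig_id, a.start))

    species_meta = {
        sp: {"post_wgd": sp in config.post_wgd_species} for sp in species
    }
    table = PillarTable(
        pillars=[
            Pillar(pillar_id=pid, genes=dict(cells))
            for pid, cells in pillar_cells.items()
        ],
        species_meta=species_meta,
    )
    order = AncestralOrder(chromosomes=chrom_pillars)
    # searchability invariant: a hidden gene is only discoverable through
    # an annotated ortholog somewhere else in the clade
    for rec in truth.records:
        if not any(table.pillar(rec.pillar_id).genes.values()):
            raise SimConfigError(
                f"hidden gene at {rec.pillar_id} has no annotated ortholog "
                "in any species"
            )
    return SimBundle(
        config=config,
        genomes=genomes,
        annotations=annotations,
        pillars=table,
        order=order,
        truth=truth,
    )


def _build_gene_dna(
    cds: str,
    anc: dict,
    ev: Optional[PlantedEvent],
    sp: str,
    rng: np.random.Generator,
    config: SimConfig,
) -> Tuple[str, List[Tuple[int, int]], dict]:
    """DNA of one gene copy on its coding strand, local exon coordinates,
    and truth metadata for planted events."""
    protein = str(Seq(cds).translate())[:-1]
    extra: dict = {"protein": protein, "klass": "single_exon"}
    exon_codons = anc["exon_codons"]
    if exon_codons:
        donor, acceptor = ("GT", "AG")
        if ev is not None:
            donor, acceptor = ev.splice_sites
        ilen = int(rng.integers(*config.intron_len))
        intron = donor + "".join(
            "ACGT"[int(rng.integers(4))] for _ in range(ilen - 4)
        ) + acceptor
        cut = 3 * exon_codons[0]
        seq = cds[:cut] + intron + cds[cut:]
        exons = [(0, cut), (cut + len(intron), len(seq))]
        extra["klass"] = "intron_model"
        return seq, exons, extra
    if ev is None or ev.kind in ("hide_annotation", "modify_copy"):
        return cds, [(0, len(cds))], extra
    if ev.kind == "insert_frameshift":
        n_codons = len(cds) // 3
        ci = int(rng.integers(max(2, n_codons // 3), max(3, 2 * n_codons // 3)))
        seq = _insert_disruptions(cds, ["ins"], [ci])
        extra["klass"] = "frameshift_corrected"
        extra["correction_site"] = 3 * ci
        return seq, [(0, len(seq))], extra
    if ev.kind == "make_pseudogene":
        n_codons = len(cds) // 3
        k = max(2, ev.k_disruptions)
        span = max(12, (n_codons - 30) // k)
        positions = [15 + j * span for j in range(k)]
        kinds = ["ins" if j % 2 == 0 else "stop" for j in range(k)]
        seq = _insert_disruptions(cds, kinds, positions)
        extra["klass"] = "pseudogene"
        return seq, [(0, len(seq))], extra
    raise SimConfigError(f"unknown event kind {ev.kind}")


# ---------------------------------------------------------------------------
# scoring


def protein_identity(a: str, b: str) -> float:
    """Global-alignment identity of two proteins, as a fraction of the
    longer sequence."""
    if not a or not b:
        return 0.0
    from Bio import Align
    from Bio.Align import substitution_matrices

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    aln = next(iter(al.align(a.replace("*", "X"), b.replace("*", "X"))))
    ba, bb = aln.aligned
    ident = sum(
        1
        for (s1, e1), (s2, _) in zip(ba, bb)
        for i in range(e1 - s1)
        if a[s1 + i] == b[s2 + i]
    )
    return ident / max(len(a), len(b))


def score_against_truth(
    candidates: Sequence[CandidateGene], truth: GroundTruth
) -> dict:
    """Recall, coordinate-exact precision and per-class confusion of a
    finished run against the simulator's planted events."""
    tl = truth.by_locus()
    by_locus: Dict[Tuple[str, str], CandidateGene] = {}
    for c in candidates:
        key = (c.species_id, c.pillar_id)
        prev = by_locus.get(key)
        if prev is None or c.best_evalue < prev.best_evalue:
            by_locus[key] = c
    confusion: Dict[Tuple[str, str], int] = {}
    exact = {}
    identities = {}
    for key, rec in tl.items():
        cand = by_locus.get(key)
        pred = cand.klass if cand is not None else "missed"
        confusion[(rec.klass, pred)] = confusion.get((rec.klass, pred), 0) + 1
        if cand is not None and pred == rec.klass:
            span = (min(s for s, _ in cand.model), max(e for _, e in cand.model))
            if rec.klass == "intron_model":
                exact[key] = list(map(tuple, cand.model)) == [
                    tuple(e) for e in rec.exons
                ]
            else:
                exact[key] = span == (rec.start, rec.end)
            if cand.protein:
                identities[key] = protein_identity(cand.protein, rec.protein)
    out = {"confusion": confusion, "exact": exact, "identities": identities}
    for klass in ("single_exon", "frameshift_corrected", "intron_model", "pseudogene"):
        planted = [k for k, r in tl.items() if r.klass == klass]
        if not planted:
            continue
        found = [k for k in planted if confusion.get((klass, klass), 0) and
                 by_locus.get(k) is not None and by_locus[k].klass == klass]
        out[f"recall_{klass}"] = len(found) / len(planted)
        if klass in ("single_exon", "intron_model"):
            n_exact = sum(1 for k in found if exact.get(k))
            out[f"coord_exact_{klass}"] = (
                n_exact / len(found) if found else 0.0
            )
    # precision: accepted single-exon calls that are coordinate-exact truths
    # (flagged candidates sit in the review pile, not the accepted set)
    se_calls = [
        (k, c)
        for k, c in by_locus.items()
        if c.klass == "single_exon" and not (set(c.flags) - {"rearranged_context"})
    ]
    if se_calls:
        good = sum(
            1 for k, c in se_calls
            if k in tl and tl[k].klass == "single_exon" and exact.get(k)
        )
        out["precision_single_exon_exact"] = good / len(se_calls)
    return out
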