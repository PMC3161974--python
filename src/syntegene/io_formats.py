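"""Readers and writers for the external formats the toolkit consumes.

All coordinates inside the package are 0-based half-open on the forward
strand of a contig; GFF3's 1-based closed convention is converted exactly
at this boundary and nowhere else.

Formats handled here:

* genome FASTA (one file per species),
* gene annotations as GFF3 CDS features grouped by parent,
* the homology "pillar" table as TSV (one column per species, ``;``-joined
  gene IDs inside a cell for post-WGD paralog pairs, empty cell = absent),
* the ancestral (reference) gene order as plain text, one pillar ID per
  line with ``#chromosome`` headers,
* result reports (TSV) and discovered-gene GFF3.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

#: annotation lifecycle states: original annotation, found by this tool,
#: or disabled (believed spurious) and excluded from segmentation.
GENE_STATUSES = ("annotated", "discovered", "switched_off")


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


@dataclass
class Genome:
    """One species' assembly: ordered contigs of uppercase A/C/G/T/N."""

    species_id: str
    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"{self.species_id}: contig {cid} is empty")
            bad = set(seq) - VALID_BASES
            if bad:
                off = min(seq.index(b) for b in bad)
                raise FormatError(
                    f"{self.species_id}: contig {cid} contains invalid symbol "
                    f"{seq[off]!r} at offset {off}"
                )


@dataclass
class GeneAnnotation:
    """A protein-coding gene model: ordered CDS exons on one strand.

    ``exons`` are (start, end) 0-based half-open, sorted, non-overlapping.
    Multi-exon models encode introns. ``correction_site`` is set for
    frameshift-corrected discoveries only.
    """

    gene_id: str
    species_id: str
    contig_id: str
    strand: str
    exons: List[Tuple[int, int]]
    status: str = "annotated"
    correction_site: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.status not in GENE_STATUSES:
            raise FormatError(f"{self.gene_id}: bad status {self.status!r}")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        self.exons = ex

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds(self, genome: Genome) -> str:
        """Spliced CDS on the coding strand."""
        seq = "".join(genome.contigs[self.contig_id][s:e] for s, e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def protein(self, genome: Genome) -> str:
        """Conceptual translation, trailing stop stripped."""
        cds = self.cds(genome)
        cds = cds[: len(cds) - len(cds) % 3]
        prot = str(Seq(cds).translate())
        return prot[:-1] if prot.endswith("*") else prot


@dataclass
class Pillar:
    """One cross-species homology column: orthologs plus WGD paralog pairs."""

    pillar_id: str
    genes: Dict[str, List[str]]  # species_id -> gene ids (<=1, or <=2 post-WGD)

    def all_genes(self) -> List[Tuple[str, str]]:
        return [(sp, g) for sp, gs in sorted(self.genes.items()) for g in gs]


@dataclass
class PillarTable:
    pillars: List[Pillar]
    species_meta: Dict[str, dict]  # species_id -> {"post_wgd": bool}

    def __post_init__(self) -> None:
        self._by_id: Dict[str, Pillar] = {}
        self._gene_to_pillar: Dict[Tuple[str, str], str] = {}
        for p in self.pillars:
            if p.pillar_id in self._by_id:
                raise FormatError(f"duplicate pillar id {p.pillar_id}")
            self._by_id[p.pillar_id] = p
            for sp, genes in p.genes.items():
                cap = 2 if self.species_meta.get(sp, {}).get("post_wgd") else 1
                if len(genes) > cap:
                    raise FormatError(
                        f"pillar {p.pillar_id}: {len(genes)} genes for {sp} "
                        f"exceeds cardinality {cap}"
                    )
                for g in genes:
                    key = (sp, g)
                    if key in self._gene_to_pillar:
                        raise FormatError(
                            f"gene {g} ({sp}) appears in pillars "
                            f"{self._gene_to_pillar[key]} and {p.pillar_id}"
                        )
                    self._gene_to_pillar[key] = p.pillar_id

    def pillar(self, pillar_id: str) -> Pillar:
        return self._by_id[pillar_id]

    def __contains__(self, pillar_id: str) -> bool:
        return pillar_id in self._by_id

    def pillar_of(self, species_id: str, gene_id: str) -> Optional[str]:
        return self._gene_to_pillar.get((species_id, gene_id))

    def insert_gene(self, pillar_id: str, species_id: str, gene_id: str) -> bool:
        """Add a discovered gene to a pillar cell; False when the cell is full."""
        p = self._by_id[pillar_id]
        cap = 2 if self.species_meta.get(species_id, {}).get("post_wgd") else 1
        cell = p.genes.setdefault(species_id, [])
        if len(cell) >= cap:
            return False
        cell.append(gene_id)
        self._gene_to_pillar[(species_id, gene_id)] = pillar_id
        return True


@dataclass
class AncestralOrder:
    """Reference gene order: ordered pillar IDs per ancestral chromosome."""

    chromosomes: Dict[str, List[str]]

    def __post_init__(self) -> None:
        self._pos: Dict[str, Tuple[str, int]] = {}
        for chrom, pids in self.chromosomes.items():
            for i, pid in enumerate(pids):
                if pid in self._pos:
                    raise FormatError(f"pillar {pid} repeated in ancestral order")
                self._pos[pid] = (chrom, i)

    def position(self, pillar_id: str) -> Optional[Tuple[str, int]]:
        return self._pos.get(pillar_id)


# ---------------------------------------------------------------------------
# readers


def read_genome(path: str | os.PathLike, species_id: Optional[str] = None) -> Genome:
    """Load a FASTA assembly; lowercase is upcased, non-ACGTN rejected."""
    species = species_id or os.path.splitext(os.path.basename(path))[0]
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"{path}: duplicate contig ID {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: contig {rec.id} is empty")
        contigs[rec.id] = seq
    if not contigs:
        raise FormatError(f"{path}: no FASTA records")
    return Genome(species_id=species, contigs=contigs)


def read_annotations(
    path: str | os.PathLike, genome: Genome
) -> List[GeneAnnotation]:
    """Load CDS features from GFF3, grouped by parent, as gene models.

    GFF3 1-based closed coordinates become 0-based half-open here. A CDS
    feature belongs to the gene named by its ``Parent`` attribute (or its
    own ``ID`` when parentless).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    grouped: Dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent", feat.attributes.get("ID"))
        if not parent:
            raise FormatError(f"{path}: CDS feature with no Parent/ID")
        gid = parent[0]
        if feat.seqid not in genome.contigs:
            raise FormatError(f"{path}: gene {gid} on unknown contig {feat.seqid}")
        if feat.end > len(genome.contigs[feat.seqid]):
            raise FormatError(
                f"{path}: gene {gid} CDS end {feat.end} beyond contig "
                f"{feat.seqid} length {len(genome.contigs[feat.seqid])}"
            )
        g = grouped.setdefault(
            gid,
            {"contig": feat.seqid, "strand": feat.strand, "exons": [],
             "status": feat.attributes.get("status", ["annotated"])[0]},
        )
        if feat.strand != g["strand"]:
            raise FormatError(f"{path}: gene {gid} mixes strands")
        if feat.seqid != g["contig"]:
            raise FormatError(f"{path}: gene {gid} spans contigs")
        g["exons"].append((feat.start - 1, feat.end))
    anns = [
        GeneAnnotation(
            gene_id=gid,
            species_id=genome.species_id,
            contig_id=g["contig"],
            strand=g["strand"],
            exons=sorted(g["exons"]),
            status=g["status"],
        )
        for gid, g in grouped.items()
    ]
    anns.sort(key=lambda a: (a.contig_id, a.start, a.gene_id))
    seen = set()
    for a in anns:
        if a.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene id {a.gene_id}")
        seen.add(a.gene_id)
    return anns


def read_pillars(
    path: str | os.PathLike, species_meta: Mapping[str, dict]
) -> PillarTable:
    """Read the pillar TSV: header names species, cells are ';'-joined IDs."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "pillar_id":
            raise FormatError(f"{path}: first column must be 'pillar_id'")
        species = header[1:]
        pillars = []
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            pid = cells[0]
            genes = {
                sp: [g for g in cell.split(";") if g]
                for sp, cell in zip(species, cells[1:])
            }
            pillars.append(
                Pillar(pillar_id=pid, genes={s: g for s, g in genes.items() if g})
            )
    return PillarTable(pillars=pillars, species_meta=dict(species_meta))


def read_ancestral_order(
    path: str | os.PathLike, pillars: PillarTable
) -> AncestralOrder:
    chroms: Dict[str, List[str]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                current = line[1:].strip()
                chroms[current] = []
                continue
            if current is None:
                raise FormatError(f"{path}: pillar id before any #chromosome header")
            if line not in pillars:
                raise FormatError(f"{path}: unknown pillar id {line}")
            chroms[current].append(line)
    return AncestralOrder(chromosomes=chroms)


# ---------------------------------------------------------------------------
# writers


def write_genome(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid in genome.contigs:
            fh.write(f">{cid}\n")
            seq = genome.contigs[cid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff(
    annotations: Sequence[GeneAnnotation], path: str | os.PathLike
) -> None:
    """Write gene models as GFF3 CDS features (round-trips read_annotations)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in sorted(annotations, key=lambda x: (x.contig_id, x.start, x.gene_id)):
            phase = 0
            exons = a.exons if a.strand == "+" else list(reversed(a.exons))
            phased = []
            for s, e in exons:
                phased.append((s, e, phase))
                phase = (3 - ((e - s) - phase) % 3) % 3
            for s, e, ph in sorted(phased):
                attrs = f"ID=cds-{a.gene_id};Parent={a.gene_id};status={a.status}"
                fh.write(
                    f"{a.contig_id}\tsyntegene\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{a.strand}\t{ph}\t{attrs}\n"
                )


def write_pillars(table: PillarTable, path: str | os.PathLike) -> None:
    species = sorted(table.species_meta)
    with open(path, "w") as fh:
        fh.write("pillar_id\t" + "\t".join(species) + "\n")
        for p in table.pillars:
            cells = [";".join(p.genes.get(sp, [])) for sp in species]
            fh.write(p.pillar_id + "\t" + "\t".join(cells) + "\n")


def write_ancestral_order(order: AncestralOrder, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, pids in order.chromosomes.items():
            fh.write(f"#{chrom}\n")
            for pid in pids:
                fh.write(pid + "\n")


REPORT_COLUMNS = [
    "species_id", "pillar_id", "gene_id", "klass", "contig_id", "strand",
    "exons", "protein_len", "best_evalue", "hsp_over_median",
    "similarity_pct", "flags", "reject_reason", "cycle",
]


def write_report(candidates: Iterable, path: str | os.PathLike) -> None:
    """One TSV row per candidate gene with class, coordinates and evidence."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "species_id": c.species_id,
                "pillar_id": c.pillar_id,
                "gene_id": c.gene_id,
                "klass": c.klass,
                "contig_id": c.contig_id,
                "strand": c.strand,
                "exons": ";".join(f"{s}-{e}" for s, e in c.model),
                "protein_len": len(c.protein) if c.protein else 0,
                "best_evalue": c.best_evalue,
                "hsp_over_median": c.hsp_over_median,
                "similarity_pct": c.similarity_pct,
                "flags": ",".join(sorted(c.flags)),
                "reject_reason": c.reject_reason or "",
                "cycle": c.cycle,
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
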