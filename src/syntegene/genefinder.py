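"""From a retained intergenic hit to a validated gene model.

The decision cascade for a locus whose intergenic DNA hit a syntenic
pillar is: intact single-exon ORF -> single-frameshift (or single internal
stop) correction -> GT-AG intron model -> pseudogene -> rejection, with
every outcome carrying its evidence trail. Two or more reading-frame
disruptions (frameshifts plus internal stops) define a pseudogene; exactly
one is presumed a sequencing error and corrected, with the locus flagged
for manual review because the correction position is an estimate.

A counting-method Ka/Ks estimator (proportions of synonymous and
nonsynonymous differences with Jukes-Cantor correction) provides the
purifying-selection sanity check on accepted genes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .aligner import (
    Hsp,
    SearchParams,
    frame_to_nt,
    search_dna_vs_proteins,
    search_protein_vs_proteins,
    translate,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class FinderParams:
    search: SearchParams = field(default_factory=SearchParams)
    min_orf_nt: int = 60          # ORF floor, start to stop
    length_ratio_min: float = 0.5  # best HSP length over pillar median
    fs_max_gap_nt: int = 30       # frameshift is a point event; larger gaps
                                  # fall through to the intron path
    exon_len_tol_aa: int = 10     # candidate exon length vs member exon
    small_exon_codons: int = 20   # below this, exons are flagged not modeled
    extension_aa: int = 40        # terminal extension to reach start/stop
    review_identity_min: float = 30.0
    pseudogene_max_evalue: float = 1e-5  # a pseudogene call asserts positive
                                  # homology, so it needs a confident hit


@dataclass
class OrfCall:
    """One maximal stop-to-stop open reading frame."""

    contig_id: str
    strand: str
    range: Tuple[int, int]  # forward-strand nt, includes trailing stop codon
    frame: int              # signed, ±1..3
    aa_start: int           # offset of first residue in the frame translation
    protein: str            # no internal stops
    has_start: bool
    has_stop: bool


@dataclass
class PillarProfile:
    """Summary of the annotated members of one pillar used for validation."""

    pillar_id: str
    member_proteins: Dict[str, str]
    median_len: float
    has_intron_member: bool
    exon_peptides: Dict[str, List[str]] = field(default_factory=dict)

    @classmethod
    def from_members(
        cls,
        pillar_id: str,
        proteins: Dict[str, str],
        exon_nt_lengths: Optional[Dict[str, List[int]]] = None,
    ) -> "PillarProfile":
        if not proteins:
            raise ValueError(f"pillar {pillar_id}: profile needs >= 1 member")
        exon_peptides: Dict[str, List[str]] = {}
        for gid, lens in (exon_nt_lengths or {}).items():
            if len(lens) < 2:
                continue
            prot = proteins[gid]
            peps, cum = [], 0
            for ln in lens:
                a, b = cum // 3, (cum + ln) // 3
                peps.append(prot[a : min(b, len(prot))])
                cum += ln
            exon_peptides[gid] = peps
        return cls(
            pillar_id=pillar_id,
            member_proteins=dict(proteins),
            median_len=float(median(len(p) for p in proteins.values())),
            has_intron_member=bool(exon_peptides),
            exon_peptides=exon_peptides,
        )


@dataclass
class CandidateGene:
    species_id: str = ""
    pillar_id: str = ""
    gene_id: str = ""
    contig_id: str = ""
    model: List[Tuple[int, int]] = field(default_factory=list)
    strand: str = "+"
    protein: str = ""
    klass: str = "rejected"
    flags: Set[str] = field(default_factory=set)
    evidence: List[Hsp] = field(default_factory=list)
    hsp_over_median: float = 0.0
    similarity_pct: float = 0.0
    best_evalue: float = math.inf
    reject_reason: Optional[str] = None
    correction_site: Optional[int] = None
    cycle: int = 0
    stage1_evalue: float = math.inf  # best E of the translated intergenic scan

    def shifted(self, offset: int, contig_id: str) -> "CandidateGene":
        """Translate region-relative coordinates to contig coordinates."""
        self.model = [(s + offset, e + offset) for s, e in self.model]
        if self.correction_site is not None:
            self.correction_site += offset
        self.contig_id = contig_id
        return self


def _revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _work_seq(dna: str, strand: str) -> str:
    return dna if strand == "+" else _revcomp(dna)


def _work_to_forward(rng: Tuple[int, int], strand: str, L: int) -> Tuple[int, int]:
    if strand == "+":
        return rng
    return (L - rng[1], L - rng[0])


# ---------------------------------------------------------------------------
# ORF extraction


def get_orfs(dna: str, min_nt: int = 60, contig_id: str = "region") -> List[OrfCall]:
    """All maximal stop-to-stop ORFs of length >= min_nt, both strands."""
    if not dna:
        raise ValueError("dna must be non-empty")
    L = len(dna)
    calls: List[OrfCall] = []
    for frame in (1, 2, 3, -1, -2, -3):
        prot = translate(dna, frame)
        if not prot:
            continue
        off = abs(frame) - 1
        a = 0
        for b, ch in enumerate(prot + "*"):
            if ch != "*" and b < len(prot):
                continue
            has_stop = b < len(prot)
            if b > a:
                ws = off + 3 * a
                we = off + 3 * b + (3 if has_stop else 0)
                if we - ws >= min_nt:
                    stretch = prot[a:b]
                    fwd = (ws, we) if frame > 0 else (L - we, L - ws)
                    calls.append(
                        OrfCall(
                            contig_id=contig_id,
                            strand="+" if frame > 0 else "-",
                            range=fwd,
                            frame=frame,
                            aa_start=a,
                            protein=stretch,
                            has_start="M" in stretch,
                            has_stop=has_stop,
                        )
                    )
            a = b + 1
    calls.sort(key=lambda c: (c.range, c.strand, c.frame))
    return calls


# ---------------------------------------------------------------------------
# single-exon validation


def validate_single_exon(
    orf: OrfCall, profile: PillarProfile, params: Optional[FinderParams] = None
) -> CandidateGene:
    """Accept an ORF as an intact single-exon gene when the reciprocal
    protein search hits the expected pillar and the best HSP is long
    enough relative to the pillar's median gene length."""
    params = params or FinderParams()
    cand = CandidateGene(pillar_id=profile.pillar_id, strand=orf.strand,
                         contig_id=orf.contig_id)
    hits = search_protein_vs_proteins(
        orf.protein, profile.member_proteins, params.search, detail=1
    )
    if not hits:
        cand.reject_reason = "non_reciprocal"
        return cand
    best = hits[0]
    ratio = best.aligned_length / profile.median_len
    cand.evidence = hits
    cand.best_evalue = best.evalue
    cand.hsp_over_median = ratio
    cand.similarity_pct = best.identity_pct
    if ratio < params.length_ratio_min:
        cand.reject_reason = "hsp_too_short"
        return cand
    # anchor the model at the in-frame ATG where the subject's start is
    # expected to sit (alignment start minus unaligned subject prefix)
    m_positions = [i for i, c in enumerate(orf.protein) if c == "M"]
    expected_m = max(0, best.query_aa_range[0] - best.subject_range[0])
    if m_positions:
        m = min(m_positions, key=lambda p: (abs(p - expected_m), -p))
        if m > best.query_aa_range[0]:
            cand.flags.add("no_upstream_start")
    else:
        m = 0
        cand.flags.add("no_start_codon")
    if not orf.has_stop:
        cand.flags.add("no_stop_codon")
    # trim 3m nt off the 5' end of the stretch, in forward coordinates
    if orf.frame > 0:
        fwd = (orf.range[0] + 3 * m, orf.range[1])
    else:
        fwd = (orf.range[0], orf.range[1] - 3 * m)
    cand.model = [fwd]
    cand.protein = orf.protein[m:]
    cand.klass = "single_exon"
    if best.identity_pct < params.review_identity_min:
        cand.flags.add("needs_review")
    return cand


# ---------------------------------------------------------------------------
# frameshift / internal-stop correction and pseudogene classification


def _chain_hsps(hsps: List[Hsp]) -> List[Hsp]:
    """Greedy colinear chain: increasing subject and query coordinates.

    Generous overlap tolerance: local alignments on either side of a
    frameshift often extend past the true breakpoint in both frames.
    """
    hsps = sorted(hsps, key=lambda h: (h.subject_range[0], h.query_range[0]))
    chain: List[Hsp] = []
    for h in hsps:
        if not chain:
            chain.append(h)
            continue
        last = chain[-1]
        if (h.subject_range[0] >= last.subject_range[1] - 40
                and h.subject_range[1] > last.subject_range[1]
                and h.query_range[0] >= last.query_range[1] - 120
                and h.query_range[1] > last.query_range[1]):
            chain.append(h)
    return chain


def _stops_in_chain(work: str, chain: List[Hsp]) -> int:
    """Internal stops across chained HSPs, not double-counting regions
    where adjacent alignments overran the breakpoint into each other's
    subject territory."""
    total = 0
    for idx, h in enumerate(chain):
        a, b = h.query_aa_range
        if idx > 0:
            ov = chain[idx - 1].subject_range[1] - h.subject_range[0]
            if ov > 0:
                a += ov
        if idx < len(chain) - 1:
            ov = h.subject_range[1] - chain[idx + 1].subject_range[0]
            if ov > 0:
                b -= ov
        if b > a:
            total += translate(work, h.frame)[a:b].count("*")
    return total


def _extend_upstream_to_atg(
    work: str, off: int, nt_start: int, expected: Optional[int] = None
) -> Tuple[int, bool]:
    """In-frame ATG for the model start: collect every ATG between the
    bounding upstream stop and nt_start and pick the one nearest to the
    expected position (alignment start minus unaligned subject prefix);
    default expectation is nt_start itself."""
    pos = off + 3 * ((nt_start - off) // 3)
    atgs = []
    if work[pos : pos + 3] == "ATG":
        atgs.append(pos)
    p = pos
    while p - 3 >= off:
        p -= 3
        codon = work[p : p + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            atgs.append(p)
    if not atgs:
        return pos, False
    target = pos if expected is None else expected
    return min(atgs, key=lambda a: (abs(a - target), a)), True


def _extend_downstream_to_stop(work: str, off: int, nt_end: int) -> Tuple[int, bool]:
    """Walk downstream codon-by-codon to just past the next stop codon."""
    p = off + 3 * ((nt_end - off + 2) // 3)
    while p + 3 <= len(work):
        codon = work[p : p + 3]
        if codon in STOP_CODONS:
            return p + 3, True
        p += 3
    return p, False


def _validated(
    prot: str, profile: PillarProfile, params: FinderParams
) -> Optional[Tuple[List[Hsp], float]]:
    hits = search_protein_vs_proteins(
        prot, profile.member_proteins, params.search, detail=1
    )
    if not hits:
        return None
    ratio = hits[0].aligned_length / profile.median_len
    if ratio < params.length_ratio_min:
        return None
    return hits, ratio


def _to_work_hsp(h: Hsp, L: int) -> Hsp:
    """Re-express a translated-search HSP in work-strand terms: positive
    frame and query coordinates on the strand that codes the protein."""
    import copy

    w = copy.copy(h)
    off = abs(h.frame) - 1
    a, b = h.query_aa_range
    w.query_range = (off + 3 * a, off + 3 * b)
    w.frame = abs(h.frame)
    return w


def _informative_hsps(hsps: List[Hsp], min_novel: int = 10) -> List[Hsp]:
    """Keep HSPs that are either confident (E < 0.01) or cover at least
    ``min_novel`` subject residues no stronger HSP covers. Marginal HSPs
    that merely overlap genuine fragments are alignment noise and would
    inflate the disruption count; marginal HSPs with novel coverage are
    the short outer fragments of genuinely disrupted genes."""
    kept: List[Hsp] = []
    covered: List[Tuple[int, int]] = []
    for h in sorted(hsps, key=lambda h: (-h.raw_score, h.subject_range)):
        s, e = h.subject_range
        novel = e - s
        for cs, ce in covered:
            lo, hi = max(s, cs), min(e, ce)
            if hi > lo:
                novel -= hi - lo
        if h.evalue < 1e-2 or novel >= min_novel:
            kept.append(h)
            covered.append((s, e))
    return kept


def _subject_coverage(chain: List[Hsp]) -> int:
    ivs = sorted(h.subject_range for h in chain)
    total, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _best_member_score(
    prot: str, profile: PillarProfile, params: FinderParams
) -> Optional[float]:
    """Raw Smith–Waterman score of a candidate protein against its best
    pillar member (cheap scoring pass, no E-value bookkeeping)."""
    from .aligner import _pairwise_aligner, _sanitize

    al = _pairwise_aligner(
        params.search.matrix, params.search.gap_open, params.search.gap_extend
    )
    alphabet = str(al.substitution_matrix.alphabet)
    best = None
    q = _sanitize(prot, alphabet)
    for sseq in profile.member_proteins.values():
        if not sseq:
            continue
        sc = al.score(_sanitize(sseq, alphabet), q)
        if best is None or sc > best:
            best = sc
    return best


def try_frameshift_correction(
    region_dna: str,
    profile: PillarProfile,
    params: Optional[FinderParams] = None,
    scan: Optional[Sequence[Hsp]] = None,
) -> CandidateGene:
    """Correct a single compensable disruption (frameshift or internal
    stop codon); two or more disruptions classify the locus a pseudogene.

    A pseudogene verdict additionally requires the chained HSPs to cover a
    substantial fraction of the pillar's median gene length — weak spot
    hits to random intergenic DNA stay plain rejections.
    """
    params = params or FinderParams()
    rejected = CandidateGene(pillar_id=profile.pillar_id, reject_reason="no_model")
    if scan is None:
        scan = search_dna_vs_proteins(
            region_dna, profile.member_proteins, params.search
        )
    scan = [h for h in scan if h.subject_id in profile.member_proteins]
    if not scan:
        rejected.reject_reason = "non_reciprocal"
        return rejected
    member_order: List[str] = []
    for h in sorted(scan, key=lambda h: (h.evalue, h.subject_id)):
        if h.subject_id not in member_order:
            member_order.append(h.subject_id)
    L = len(region_dna)
    pseudo: Optional[CandidateGene] = None
    repairs: List[CandidateGene] = []
    for gid in member_order[:3]:
        # the caller's scan may carry truncated detail; re-search this
        # member alone so every HSP has full coordinates
        mhits = search_dna_vs_proteins(
            region_dna, {gid: profile.member_proteins[gid]}, params.search
        )
        for strand in ("+", "-"):
            work = _work_seq(region_dna, strand)
            hsps = _informative_hsps(
                [
                    _to_work_hsp(h, L)
                    for h in mhits
                    if (h.frame > 0) == (strand == "+")
                ]
            )
            if not hsps:
                continue
            chain = _chain_hsps(hsps)
            frames = [h.frame for h in chain]
            n_shifts = sum(1 for a, b in zip(frames, frames[1:]) if a != b)
            if n_shifts == 1:
                # stops inside the breakpoint window belong to the
                # disruption itself; the correction removes them
                k = next(
                    i for i in range(len(chain) - 1)
                    if chain[i].frame != chain[i + 1].frame
                )
                # local alignments trim divergent residues, so the true
                # breakpoint may lie a few codons outside both hits
                lo = min(chain[k].query_range[1], chain[k + 1].query_range[0]) - 12
                hi = max(chain[k].query_range[1], chain[k + 1].query_range[0]) + 12
                n_stops = 0
                for idx, h in enumerate(chain):
                    prot_f = translate(work, h.frame)
                    a, b = h.query_aa_range
                    off = h.frame - 1
                    if idx <= k:
                        b = min(b, max(a, (lo - off) // 3))
                    else:
                        a = max(a, min(b, (hi - off + 2) // 3))
                    n_stops += prot_f[a:b].count("*")
            else:
                n_stops = _stops_in_chain(work, chain)
            disruptions = n_shifts + n_stops
            if disruptions == 0:
                continue
            evid = sorted(chain, key=lambda h: h.evalue)
            if _subject_coverage(chain) / profile.median_len < params.length_ratio_min:
                continue  # too little homology for repair or a pseudogene call
            if disruptions >= 2:
                if evid[0].evalue >= params.pseudogene_max_evalue:
                    continue  # weak similarity: reject, don't mask
                lo = min(h.query_range[0] for h in chain)
                hi = max(h.query_range[1] for h in chain)
                c = CandidateGene(
                    pillar_id=profile.pillar_id,
                    klass="pseudogene",
                    strand=strand,
                    model=[_work_to_forward((lo, hi), strand, L)],
                    evidence=evid,
                    best_evalue=evid[0].evalue,
                    similarity_pct=evid[0].identity_pct,
                    reject_reason="pseudogene",
                )
                if pseudo is None or c.best_evalue < pseudo.best_evalue:
                    pseudo = c
                continue
            cand = _correct_one_disruption(
                work, strand, chain, n_shifts, profile, params, L
            )
            if cand is not None:
                cand.evidence = cand.evidence + evid
                repairs.append(cand)
    if repairs:
        # several member/strand combinations may propose corrections;
        # keep the one whose corrected protein validates best
        return max(repairs, key=lambda c: c.evidence[0].raw_score)
    if pseudo is not None:
        return pseudo
    return rejected


def _correct_one_disruption(
    work: str,
    strand: str,
    chain: List[Hsp],
    n_shifts: int,
    profile: PillarProfile,
    params: FinderParams,
    L: int,
) -> Optional[CandidateGene]:
    if n_shifts == 1 and len(chain) >= 2:
        # locate the frame transition
        k = next(
            i for i in range(len(chain) - 1)
            if chain[i].frame != chain[i + 1].frame
        )
        h1, h2 = chain[k], chain[k + 1]
        # work-strand nt coordinates of the two supporting HSPs
        w1 = frame_to_nt(h1.query_aa_range, h1.frame, L)
        w2 = frame_to_nt(h2.query_aa_range, h2.frame, L)
        gap = w2[0] - w1[1]
        if gap > params.fs_max_gap_nt:
            return None
        o1, o2 = h1.frame - 1, h2.frame - 1
        expected_start = w1[0] - 3 * h1.subject_range[0]
        a1, has_atg = _extend_upstream_to_atg(work, o1, w1[0], expected_start)
        w_last = frame_to_nt(chain[-1].query_aa_range, chain[-1].frame, L)
        b2, has_stop = _extend_downstream_to_stop(work, o2, max(w2[1], w_last[1]))
        # the correction position inside the inter-HSP gap (or the HSP
        # overlap, when both alignments extended past the breakpoint) is an
        # estimate: try every codon boundary in the window and keep the one
        # whose corrected protein validates best
        lo_x = min(w1[1], w2[0]) - 12
        hi_x = max(w1[1], w2[0]) + 12
        best: Optional[Tuple[float, int, int, str]] = None
        for x0 in range(max(a1 + 3, lo_x), min(hi_x, b2 - 3) + 1):
            x = o1 + 3 * ((x0 - o1) // 3)
            if x <= a1 or x >= b2:
                continue
            y = x + ((o2 - x) % 3)
            if y >= b2:
                continue
            p1 = translate(work[a1:x], 1)
            p2 = translate(work[y:b2], 1)
            if p2.endswith("*"):
                p2 = p2[:-1]
            if "*" in p1 or "*" in p2:
                continue  # this split leaves an extra disruption
            prot = p1 + p2
            sc = _best_member_score(prot, profile, params)
            if sc is not None and (best is None or sc > best[0]):
                best = (sc, x, y, prot)
        if best is None:
            return None
        _, x, y, prot = best
        ok = _validated(prot, profile, params)
        if ok is None:
            return None
        hits, ratio = ok
        cand = CandidateGene(
            pillar_id=profile.pillar_id,
            klass="frameshift_corrected",
            strand=strand,
            model=[
                _work_to_forward((a1, x), strand, L),
                _work_to_forward((y, b2), strand, L),
            ],
            protein=prot,
            flags={"manual_check_frameshift"},
            evidence=hits,
            hsp_over_median=ratio,
            similarity_pct=hits[0].identity_pct,
            best_evalue=hits[0].evalue,
            correction_site=_work_to_forward((x, x), strand, L)[0],
        )
        cand.model.sort()
        if not has_atg:
            cand.flags.add("no_start_codon")
        if not has_stop:
            cand.flags.add("no_stop_codon")
        return cand
    if n_shifts == 0 and len(chain) >= 1:
        # single internal stop read-through: all chain hits share one frame
        h = chain[0]
        off = h.frame - 1
        aa_lo = h.query_aa_range[0]
        aa_hi = chain[-1].query_aa_range[1]
        w = (off + 3 * aa_lo, off + 3 * aa_hi)
        a1, has_atg = _extend_upstream_to_atg(work, off, w[0])
        # the internal stop sits inside the hit span; extend past it
        prot_frame = translate(work, h.frame)
        stop_aa = next(
            (i for i in range(aa_lo, aa_hi) if prot_frame[i] == "*"), None
        )
        if stop_aa is None:
            return None
        stop_nt = off + 3 * stop_aa
        b2, has_stop = _extend_downstream_to_stop(work, off, w[1])
        seq = work[a1:b2]
        prot = translate(seq, 1)
        if prot.endswith("*"):
            prot = prot[:-1]
        if prot.count("*") != 1:
            return None
        prot = prot.replace("*", "X")
        ok = _validated(prot, profile, params)
        if ok is None:
            return None
        hits, ratio = ok
        cand = CandidateGene(
            pillar_id=profile.pillar_id,
            klass="frameshift_corrected",
            strand=strand,
            model=[_work_to_forward((a1, b2), strand, L)],
            protein=prot,
            flags={"manual_check_frameshift", "null_allele_possible"},
            evidence=hits,
            hsp_over_median=ratio,
            similarity_pct=hits[0].identity_pct,
            best_evalue=hits[0].evalue,
            correction_site=_work_to_forward((stop_nt, stop_nt), strand, L)[0],
        )
        if not has_atg:
            cand.flags.add("no_start_codon")
        if not has_stop:
            cand.flags.add("no_stop_codon")
        return cand
    return None


# ---------------------------------------------------------------------------
# intron models


def _gapless_best_score(a: str, b: str, max_shift: int) -> float:
    """Best ungapped (offset-only) BLOSUM62 comparison of two proteins
    over relative offsets up to ±max_shift."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    alpha = set(str(m.alphabet))
    a = "".join(c if c in alpha else "X" for c in a)
    b = "".join(c if c in alpha else "X" for c in b)
    best = 0.0
    for off in range(-max_shift, max_shift + 1):
        # align a[i] with b[i + off]; score only the positive-sum suffix/
        # prefix-trimmed local stretch (simple running Kadane pass)
        run = 0.0
        high = 0.0
        for i in range(len(a)):
            j = i + off
            if j < 0 or j >= len(b):
                continue
            run = max(0.0, run + m[a[i]][b[j]])
            high = max(high, run)
        best = max(best, high)
    return best


def try_intron_model(
    region_dna: str,
    profile: PillarProfile,
    params: Optional[FinderParams] = None,
) -> CandidateGene:
    """Build a GT-AG spliced model whose exons match an intron-containing
    pillar member in order and length (±10 aa); no frameshifts allowed.
    Members with an exon under 20 codons are flagged for manual work, with
    only the larger exon(s) localized."""
    params = params or FinderParams()
    rejected = CandidateGene(
        pillar_id=profile.pillar_id, reject_reason="no_intron_member"
    )
    if not profile.has_intron_member:
        return rejected
    rejected.reject_reason = "no_gene_model"
    best: Optional[CandidateGene] = None
    for gid in sorted(profile.exon_peptides):
        peps = profile.exon_peptides[gid]
        small = [i for i, p in enumerate(peps) if len(p) < params.small_exon_codons]
        cand = _intron_model_for_member(
            region_dna, gid, peps, small, profile, params, rejected
        )
        if cand is not None and cand.klass == "intron_model":
            if "manual_check_small_exon" not in cand.flags:
                if best is None or cand.best_evalue < best.best_evalue:
                    best = cand
            elif best is None:
                best = cand
    return best if best is not None else rejected


def _intron_model_for_member(
    region_dna: str,
    gid: str,
    peps: List[str],
    small_idx: List[int],
    profile: PillarProfile,
    params: FinderParams,
    rejected: CandidateGene,
) -> Optional[CandidateGene]:
    L = len(region_dna)
    # locate each (large) exon peptide independently in six frames
    per_exon_hits: Dict[int, List[Hsp]] = {}
    for i, pep in enumerate(peps):
        if i in small_idx:
            continue
        hits = search_dna_vs_proteins(
            region_dna, {f"{gid}.exon{i}": pep}, params.search
        )
        if hits:
            per_exon_hits[i] = hits
    if not per_exon_hits:
        return None
    # choose the strand supported by the best hits
    strand_votes: Dict[str, float] = {}
    for hits in per_exon_hits.values():
        h = hits[0]
        s = "+" if h.frame > 0 else "-"
        strand_votes[s] = strand_votes.get(s, 0) + h.raw_score
    strand = max(sorted(strand_votes), key=lambda s: strand_votes[s])
    work = _work_seq(region_dna, strand)
    located: Dict[int, Tuple[int, int, int]] = {}  # exon -> (ws, we, frame)
    for i, hits in per_exon_hits.items():
        cands = [h for h in hits if (h.frame > 0) == (strand == "+")]
        if not cands:
            continue
        h = cands[0]
        if strand == "+":
            ws, we = h.query_range
        else:
            # forward-strand range maps to work coords by reflection
            fs, fe = h.query_range
            ws, we = L - fe, L - fs
        located[i] = (ws, we, h.subject_range[0], h.subject_range[1])
    if small_idx:
        if not located:
            return None
        model = [
            _work_to_forward((ws, we), strand, L)
            for ws, we, _, _ in located.values()
        ]
        model.sort()
        ev = [per_exon_hits[i][0] for i in sorted(per_exon_hits)]
        return CandidateGene(
            pillar_id=profile.pillar_id,
            klass="intron_model",
            strand=strand,
            model=model,
            flags={"manual_check_small_exon"},
            evidence=ev,
            best_evalue=min(h.evalue for h in ev),
            similarity_pct=max(h.identity_pct for h in ev),
        )
    if len(located) != len(peps):
        rejected.reject_reason = "no_gene_model"
        return None
    order = sorted(located, key=lambda i: located[i][0])
    if order != list(range(len(peps))):
        rejected.reject_reason = "no_gene_model"
        return None
    # exon length tolerance (±10 aa) against this member
    for i in range(len(peps)):
        ws, we, _, _ = located[i]
        if abs((we - ws) // 3 - len(peps[i])) > params.exon_len_tol_aa:
            rejected.reject_reason = "exon_length_mismatch"
            return None
    ext = 3 * params.extension_aa
    first_ws, first_we, first_sub0, _ = located[0]
    off0 = first_ws % 3
    a1, has_atg = _extend_upstream_to_atg(
        work, off0, first_ws, expected=first_ws - 3 * first_sub0
    )
    if first_ws - a1 > ext or not has_atg:
        rejected.reject_reason = "no_gene_model"
        return None
    last_ws, last_we, _, _ = located[len(peps) - 1]
    # enumerate GT donor / AG acceptor pairs in small windows around the
    # exon-hit boundaries at every junction; junction phases must agree
    # with the member's exon structure
    win = 12
    member_phases = []
    cum = 0
    for pep in peps[:-1]:
        cum += 3 * len(pep)
        member_phases.append(cum % 3)
    valid_chains: List[List[Tuple[int, int]]] = [[]]
    for j in range(len(peps) - 1):
        # local alignments trim divergent terminal residues: centre the
        # splice-site windows on where the member says the exon edge is
        ge = located[j][1] + 3 * (len(peps[j]) - located[j][3])
        gs = located[j + 1][0] - 3 * located[j + 1][2]
        donors = [
            d
            for d in range(max(a1 + 3, ge - win), min(len(work) - 1, ge + win))
            if work[d : d + 2] == "GT"
        ]
        acceptors = [
            a
            for a in range(max(2, gs - win), min(len(work), gs + win) + 1)
            if work[a - 2 : a] == "AG"
        ]
        valid_chains = [
            chain + [(d, a)]
            for chain in valid_chains
            for d, a in itertools.product(donors, acceptors)
            if a > d + 4
        ]
        if not valid_chains:
            rejected.reject_reason = "no_splice_sites"
            return None
    best_model: Optional[CandidateGene] = None
    for chain in valid_chains:
        exon_bounds: List[Tuple[int, int]] = []
        start = a1
        ok = True
        for j, (d, a) in enumerate(chain):
            if d <= start:
                ok = False
                break
            exon_bounds.append((start, d))
            cum_len = sum(e - s for s, e in exon_bounds)
            if cum_len % 3 != member_phases[j]:
                ok = False  # junction phase must match the member's
                break
            start = a
        if not ok:
            continue
        # extend the final exon through an in-frame stop codon; translation
        # may continue mid-codon across the last junction
        cum = sum(e - s for s, e in exon_bounds)
        phase = cum % 3
        off_last = (start + (3 - phase) % 3) % 3
        b2, has_stop = _extend_downstream_to_stop(
            work, off_last, max(start + 3, last_we)
        )
        if not has_stop or b2 - last_we > ext:
            continue
        exon_bounds.append((start, b2))
        spliced = "".join(work[s:e] for s, e in exon_bounds)
        if len(spliced) % 3:
            continue
        prot = translate(spliced, 1)
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot or not prot.startswith("M"):
            continue
        # per-exon length check on the final bounds (terminal exons get the
        # start/stop extension allowance on top of the ±10 aa tolerance)
        lens_ok = True
        for k, (s, e) in enumerate(exon_bounds):
            cand_aa = (e - s) // 3
            ref = len(peps[k]) + (1 if k == len(peps) - 1 else 0)
            tol = params.exon_len_tol_aa + (
                params.extension_aa if k in (0, len(peps) - 1) else 0
            )
            if abs(cand_aa - ref) > tol:
                lens_ok = False
                break
        if not lens_ok:
            continue
        ok2 = _validated(prot, profile, params)
        if ok2 is None:
            continue
        hits, ratio = ok2
        # a convincing spliced model stays in register with its member
        # end to end: a misplaced splice point shifts everything past the
        # junction by the junk it introduced, so the best offset-only
        # (gapless) comparison collapses relative to the gapped score
        h0 = hits[0]
        q_span = h0.query_range[1] - h0.query_range[0]
        if q_span < 0.8 * len(prot):
            continue
        best_member = profile.member_proteins[h0.subject_id]
        shift = params.extension_aa + params.exon_len_tol_aa
        if _gapless_best_score(prot, best_member, shift) < 0.9 * h0.raw_score:
            continue
        cand = CandidateGene(
            pillar_id=profile.pillar_id,
            klass="intron_model",
            strand=strand,
            model=sorted(_work_to_forward((s, e), strand, L) for s, e in exon_bounds),
            protein=prot,
            evidence=hits,
            hsp_over_median=ratio,
            similarity_pct=hits[0].identity_pct,
            best_evalue=hits[0].evalue,
        )
        if hits[0].identity_pct < params.review_identity_min:
            cand.flags.add("needs_review")
        if best_model is None or cand.evidence[0].raw_score > best_model.evidence[0].raw_score:
            best_model = cand
    if best_model is None:
        rejected.reject_reason = "no_splice_sites"
    return best_model


# ---------------------------------------------------------------------------
# locus cascade


def classify_locus(
    region_dna: str,
    hits: Sequence[Hsp],
    profile: PillarProfile,
    params: Optional[FinderParams] = None,
) -> CandidateGene:
    """Full decision cascade for one intergenic locus that passed the
    synteny-filtered translated search."""
    params = params or FinderParams()
    hits = sorted(hits, key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    best_reject: Optional[CandidateGene] = None
    orfs = get_orfs(region_dna, params.min_orf_nt)
    hit_ranges = [(h.query_range, h.frame > 0) for h in hits]
    accepted: Optional[CandidateGene] = None
    min_prot = params.length_ratio_min * profile.median_len - 10
    for orf in orfs:
        if len(orf.protein) < min_prot:
            continue  # cannot pass the HSP-length rule even if it hits
        overlaps = any(
            orf.range[0] < qr[1] and qr[0] < orf.range[1]
            and ((orf.strand == "+") == fwd)
            for qr, fwd in hit_ranges
        )
        if not overlaps:
            continue
        cand = validate_single_exon(orf, profile, params)
        if cand.klass == "single_exon":
            if accepted is None or cand.best_evalue < accepted.best_evalue:
                accepted = cand
        elif best_reject is None or (
            cand.best_evalue < best_reject.best_evalue
        ):
            best_reject = cand
    # even a full-length-looking ORF must beat the repair paths: a gapped
    # alignment reading straight through an in-frame intron, or across a
    # frameshift, can cover the pillar median yet be the wrong model
    fs = try_frameshift_correction(region_dna, profile, params, scan=hits)
    im: Optional[CandidateGene] = None
    if profile.has_intron_member:
        im = try_intron_model(region_dna, profile, params)
        if best_reject is None and im.klass == "rejected" and im.reject_reason not in (
            None, "no_intron_member",
        ):
            best_reject = im
    contenders = [
        c
        for c in (accepted, fs, im)
        if c is not None
        and c.klass in ("single_exon", "frameshift_corrected", "intron_model")
    ]
    if contenders:
        order = {"single_exon": 0, "frameshift_corrected": 1, "intron_model": 2}
        best = max(
            contenders,
            key=lambda c: (
                c.evidence[0].raw_score if c.evidence else 0,
                -order[c.klass],
            ),
        )
        # parsimony: an intact ORF stands unless the frameshift repair is
        # clearly better — higher score AND substantially more of the
        # pillar median explained. A genuine correction reunites two
        # fragments and gains coverage; a spurious one just restitches
        # residues the intact frame already explains.
        if (
            best.klass == "frameshift_corrected"
            and accepted is not None
            and accepted.evidence
            and (
                best.evidence[0].raw_score
                < 1.1 * accepted.evidence[0].raw_score
                or best.hsp_over_median - accepted.hsp_over_median < 0.15
            )
        ):
            return accepted
        return best
    if fs.klass == "pseudogene":
        return fs
    if best_reject is not None:
        return best_reject
    fs.pillar_id = profile.pillar_id
    return fs


# ---------------------------------------------------------------------------
# Ka/Ks counting estimator (proportions of syn/nonsyn differences with
# Jukes-Cantor correction)

_CODON_TABLE: Dict[str, str] = {}


def _codon_table() -> Dict[str, str]:
    if not _CODON_TABLE:
        bases = "TCAG"
        for c in ("".join(t) for t in itertools.product(bases, repeat=3)):
            _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE


def _syn_fraction(codon: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; mutations to
    stop codons count as nonsynonymous."""
    table = _codon_table()
    aa = table[codon]
    syn = 0.0
    for pos in range(3):
        for alt in "TCAG":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if table[mut] == aa and table[mut] != "*":
                syn += 1 / 3
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str) -> Tuple[float, float]:
    """Average synonymous/nonsynonymous difference counts over all minimal
    mutational paths between two codons, skipping paths through stops."""
    table = _codon_table()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for perm in itertools.permutations(diff):
        cur = c1
        s = n = 0.0
        blocked = False
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[nxt] == "*" and nxt != c2:
                blocked = True
                break
            if table[nxt] == table[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if not blocked:
            paths.append((s, n))
    if not paths:  # every path crosses a stop; fall back to including them
        for perm in itertools.permutations(diff):
            cur = c1
            s = n = 0.0
            for pos in perm:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if table[nxt] == table[cur]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            paths.append((s, n))
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def _jc_correct(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4 * p / 3)


def kaks(candidate_cds: str, ortholog_cds: str) -> Tuple[float, float, float]:
    """Counting-method Ka, Ks and their ratio for two aligned, gap-free CDS
    of equal codon count. Ks=0 with Ka>0 yields +inf; Ka=Ks=0 yields NaN."""
    if len(candidate_cds) != len(ortholog_cds) or len(candidate_cds) % 3:
        raise ValueError("CDS must be equal-length codon multiples")
    n_codons = len(candidate_cds) // 3
    if n_codons < 30:
        warnings.warn(f"Ka/Ks on only {n_codons} codons: low confidence")
    table = _codon_table()
    S = N = Sd = Nd = 0.0
    for i in range(n_codons):
        c1 = candidate_cds[3 * i : 3 * i + 3]
        c2 = ortholog_cds[3 * i : 3 * i + 3]
        if "N" in c1 or "N" in c2:
            continue
        if table[c1] == "*" or table[c2] == "*":
            continue
        s1, n1 = _syn_fraction(c1)
        s2, n2 = _syn_fraction(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    if ks == 0.0:
        ratio = math.nan if ka == 0.0 else math.inf
    else:
        ratio = ka / ks
    return ka, ks, ratio


def codon_align(cds1: str, cds2: str) -> Tuple[str, str]:
    """Protein-guided codon alignment of two CDS; gapped codons removed."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    p1 = translate(cds1[: len(cds1) - len(cds1) % 3], 1)
    p2 = translate(cds2[: len(cds2) - len(cds2) % 3], 1)
    p1 = p1[:-1] if p1.endswith("*") else p1
    p2 = p2[:-1] if p2.endswith("*") else p2
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    aln = next(iter(al.align(p1.replace("*", "X"), p2.replace("*", "X"))))
    b1, b2 = aln.aligned
    out1, out2 = [], []
    for (s1, e1), (s2, e2) in zip(b1, b2):
        out1.append(cds1[3 * s1 : 3 * e1])
        out2.append(cds2[3 * s2 : 3 * e2])
    return "".join(out1), "".join(out2)
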