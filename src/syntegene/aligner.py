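"""Homology search engine.

Translated (six-frame, BLASTX-style) and protein-vs-protein (BLASTP-style)
local alignment with Karlin–Altschul E-values. Because the syntenic
candidate databases are tiny by construction, the built-in backend runs
exact Smith–Waterman with affine gaps (no word-seeding heuristics) for
every frame/target pair; an optional adapter drives the NCBI BLAST+
binaries behind the same contract.

Statistical parameters (lambda, K, H) are fixed published constants per
(matrix, gap penalty) combination, bundled below; no on-the-fly
estimation, so E-values are deterministic.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple, Union

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

#: (matrix, gap_open, gap_extend) -> (lambda, K, H).  gap_open=0 means
#: ungapped.  Values are the standard gapped/ungapped constants reported
#: for these scoring systems.
KARLIN_ALTSCHUL_TABLE: Dict[Tuple[str, int, int], Tuple[float, float, float]] = {
    ("BLOSUM62", 11, 1): (0.267, 0.041, 0.14),
    ("BLOSUM62", 10, 1): (0.243, 0.024, 0.10),
    ("BLOSUM62", 0, 0): (0.3176, 0.134, 0.4012),
    ("BLOSUM45", 14, 2): (0.195, 0.010, 0.10),
}


@dataclass
class SearchParams:
    """Search configuration mirroring the liberal scan settings: E < 10,
    100 results listed, low-complexity filtering off."""

    evalue_cutoff: float = 10.0
    max_results: int = 100
    low_complexity_filter: bool = False
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        key = (self.matrix, self.gap_open, self.gap_extend)
        if key not in KARLIN_ALTSCHUL_TABLE:
            raise ValueError(f"no Karlin-Altschul constants for {key}")
        self.karlin_lambda, self.karlin_k, self.karlin_h = KARLIN_ALTSCHUL_TABLE[key]


@dataclass
class Hsp:
    """One local alignment (high-scoring segment pair)."""

    query_id: str
    subject_id: str
    query_range: Tuple[int, int]  # nt on forward strand for translated search
    subject_range: Tuple[int, int]  # aa on subject
    frame: int  # -3..-1, +1..+3, or 0 for protein-protein
    raw_score: float
    bitscore: float
    evalue: float
    aligned_length: int  # alignment columns, gaps included
    identity_pct: float = 0.0
    query_aa_range: Tuple[int, int] = (0, 0)  # aa within the frame translation


_CODE = None


def translate(dna: str, frame: int) -> str:
    """Translate one reading frame (+1..+3 forward, -1..-3 on the reverse
    complement); stops rendered '*', ambiguous codons 'X', trailing partial
    codon dropped."""
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be in ±1..3, got {frame}")
    seq = dna.upper()
    if frame < 0:
        seq = str(Seq(seq).reverse_complement())
    off = abs(frame) - 1
    sub = seq[off : off + 3 * ((len(seq) - off) // 3)]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def _length_adjustment(k: float, h: float, m: int, n: int, db_seqs: int) -> float:
    """Edge-effect length adjustment: damped fixed-point iteration of
    ell = ln(K*(m-ell)*(n-N*ell))/H with effective lengths floored at 1/K
    (short sequences never shrink below the expected HSP footprint)."""
    floor = 1.0 / k
    ell = 0.0
    for _ in range(30):
        new = math.log(k * max(m - ell, floor) * max(n - db_seqs * ell, floor)) / h
        ell = 0.5 * (ell + max(new, 0.0))
    return ell


def evalue(
    raw_score: float,
    query_len: int,
    db_len: int,
    params: SearchParams,
    db_seqs: int = 1,
) -> float:
    """Karlin–Altschul expectation E = K * m' * n' * exp(-lambda*S) with
    the standard edge-effect length correction."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be > 0")
    lam, k, h = params.karlin_lambda, params.karlin_k, params.karlin_h
    ell = _length_adjustment(k, h, query_len, db_len, db_seqs)
    m_eff = max(query_len - ell, 1.0 / k)
    n_eff = max(db_len - db_seqs * ell, 1.0 / k)
    return k * m_eff * n_eff * math.exp(-lam * raw_score)


def bitscore(raw_score: float, params: SearchParams) -> float:
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2)


@lru_cache(maxsize=8)
def _pairwise_aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST charges open+extend for a length-1 gap
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def _as_target_list(targets: Union[Dict[str, str], Sequence[Tuple[str, str]]]):
    if isinstance(targets, dict):
        return sorted(targets.items())
    return sorted(targets)


def _local_alignment(aligner, subject: str, query: str, min_score: float = 0.0):
    """Best local alignment; returns (score, sub_range, q_range, columns,
    identity_pct) or None when the best score is <= max(0, min_score).

    The score is computed first (cheap) so the full traceback is only done
    for hits that can pass the caller's E-value cutoff."""
    score = aligner.score(subject, query)
    if score <= 0 or score < min_score:
        return None
    aln = next(iter(aligner.align(subject, query)))
    sb, qb = aln.aligned
    sub_range = (int(sb[0][0]), int(sb[-1][1]))
    q_range = (int(qb[0][0]), int(qb[-1][1]))
    matched = 0
    ident = 0
    for (ss, se), (qs, qe) in zip(sb, qb):
        for i in range(se - ss):
            matched += 1
            if subject[ss + i] == query[qs + i]:
                ident += 1
    columns = int(aln.length)
    pct = 100.0 * ident / columns if columns else 0.0
    return float(aln.score), sub_range, q_range, columns, pct


def _finalize(hits: List[Hsp], params: SearchParams) -> List[Hsp]:
    hits = [h for h in hits if h.evalue < params.evalue_cutoff]
    hits.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return hits[: params.max_results]


def search_protein_vs_proteins(
    query: str,
    targets: Union[Dict[str, str], Sequence[Tuple[str, str]]],
    params: Optional[SearchParams] = None,
    query_id: str = "query",
    detail: Optional[int] = None,
) -> List[Hsp]:
    """Exact local search of one protein against a small protein set.

    ``detail`` limits the expensive alignment traceback to the top-ranked
    hits; the rest carry score/E-value only (zeroed coordinate fields).
    """
    params = params or SearchParams()
    tlist = _as_target_list(targets)
    if not tlist or not query:
        return []
    aligner = _pairwise_aligner(params.matrix, params.gap_open, params.gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    q = _sanitize(query, alphabet)
    db_len = sum(len(s) for _, s in tlist)
    scored: List[Tuple[float, float, str, str]] = []
    for sid, sseq in tlist:
        if not sseq:
            continue
        s = _sanitize(sseq, alphabet)
        sc = float(aligner.score(s, q))
        if sc <= 0:
            continue
        e = evalue(sc, len(q), db_len, params, db_seqs=len(tlist))
        if e < params.evalue_cutoff:
            scored.append((e, sc, sid, s))
    scored.sort(key=lambda t: (t[0], -t[1], t[2]))
    scored = scored[: params.max_results]
    hits: List[Hsp] = []
    for rank, (e, sc, sid, s) in enumerate(scored):
        if detail is None or rank < detail:
            res = _local_alignment(aligner, s, q)
            _, sub_range, q_range, columns, ident = res
        else:
            sub_range = q_range = (0, 0)
            columns, ident = 0, 0.0
        hits.append(
            Hsp(
                query_id=query_id,
                subject_id=sid,
                query_range=q_range,
                subject_range=sub_range,
                frame=0,
                raw_score=sc,
                bitscore=bitscore(sc, params),
                evalue=e,
                aligned_length=columns,
                identity_pct=ident,
                query_aa_range=q_range,
            )
        )
    return hits


def frame_to_nt(aa_range: Tuple[int, int], frame: int, dna_len: int) -> Tuple[int, int]:
    """Map an amino-acid range in one frame's translation to forward-strand
    nucleotide coordinates (0-based half-open)."""
    off = abs(frame) - 1
    s = off + 3 * aa_range[0]
    e = off + 3 * aa_range[1]
    if frame > 0:
        return (s, e)
    return (dna_len - e, dna_len - s)


def search_dna_vs_proteins(
    dna: str,
    targets: Union[Dict[str, str], Sequence[Tuple[str, str]]],
    params: Optional[SearchParams] = None,
    query_id: str = "query",
    detail: Optional[int] = None,
) -> List[Hsp]:
    """Six-frame translated search of DNA against a small protein set
    (BLASTX-style); all frames scored by exact Smith–Waterman.

    ``detail`` as in :func:`search_protein_vs_proteins`.
    """
    params = params or SearchParams()
    tlist = _as_target_list(targets)
    if not dna:
        raise ValueError("dna must be non-empty")
    if not tlist:
        return []
    aligner = _pairwise_aligner(params.matrix, params.gap_open, params.gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    db_len = sum(len(s) for _, s in tlist)
    scored: List[Tuple[float, float, str, int, str, str]] = []
    for frame in (1, 2, 3, -1, -2, -3):
        prot = translate(dna, frame)
        if not prot:
            continue
        q = _sanitize(prot, alphabet)
        for sid, sseq in tlist:
            if not sseq:
                continue
            s = _sanitize(sseq, alphabet)
            sc = float(aligner.score(s, q))
            if sc <= 0:
                continue
            e = evalue(sc, len(q), db_len, params, db_seqs=len(tlist))
            if e < params.evalue_cutoff:
                scored.append((e, sc, sid, frame, q, s))
    scored.sort(key=lambda t: (t[0], -t[1], t[2]))
    scored = scored[: params.max_results]
    hits: List[Hsp] = []
    for rank, (e, sc, sid, frame, q, s) in enumerate(scored):
        if detail is None or rank < detail:
            res = _local_alignment(aligner, s, q)
            _, sub_range, q_range, columns, ident = res
        else:
            sub_range = q_range = (0, 0)
            columns, ident = 0, 0.0
        hits.append(
            Hsp(
                query_id=query_id,
                subject_id=sid,
                query_range=frame_to_nt(q_range, frame, len(dna)),
                subject_range=sub_range,
                frame=frame,
                raw_score=sc,
                bitscore=bitscore(sc, params),
                evalue=e,
                aligned_length=columns,
                identity_pct=ident,
                query_aa_range=q_range,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# optional external backend (NCBI BLAST+) behind the same contract


def external_backend_available() -> bool:
    return all(shutil.which(t) for t in ("blastp", "blastx", "makeblastdb"))


def _write_fasta(records: Sequence[Tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def search_external(
    query: str,
    targets: Union[Dict[str, str], Sequence[Tuple[str, str]]],
    params: Optional[SearchParams] = None,
    mode: str = "blastp",
    query_id: str = "query",
) -> List[Hsp]:
    """Run blastp/blastx with E=10, 100 results, SEG off; parse tabular
    output into Hsp records (one best HSP kept per subject)."""
    params = params or SearchParams()
    tlist = _as_target_list(targets)
    if not tlist:
        return []
    with tempfile.TemporaryDirectory() as tmp:
        qpath, dbpath = f"{tmp}/q.fa", f"{tmp}/db.fa"
        _write_fasta([(query_id, query)], qpath)
        _write_fasta(tlist, dbpath)
        subprocess.run(
            ["makeblastdb", "-in", dbpath, "-dbtype", "prot"],
            check=True, capture_output=True,
        )
        cmd = [
            mode, "-query", qpath, "-db", dbpath,
            "-evalue", str(params.evalue_cutoff),
            "-max_target_seqs", str(params.max_results),
            "-seg", "no" if not params.low_complexity_filter else "yes",
            "-outfmt",
            "6 qseqid sseqid pident length qstart qend sstart send evalue bitscore score qframe",
        ]
        out = subprocess.run(cmd, check=True, capture_output=True, text=True).stdout
    hits: List[Hsp] = []
    best_per_subject: Dict[str, Hsp] = {}
    for line in out.splitlines():
        f = line.split("\t")
        (qid, sid, pident, length, qstart, qend, sstart, send,
         ev, bits, score, qframe) = f
        h = Hsp(
            query_id=qid,
            subject_id=sid,
            query_range=(int(qstart) - 1, int(qend)),
            subject_range=(int(sstart) - 1, int(send)),
            frame=int(qframe) if mode == "blastx" else 0,
            raw_score=float(score),
            bitscore=float(bits),
            evalue=float(ev),
            aligned_length=int(length),
            identity_pct=float(pident),
        )
        prev = best_per_subject.get(sid)
        if prev is None or h.evalue < prev.evalue:
            best_per_subject[sid] = h
    hits = list(best_per_subject.values())
    return _finalize(hits, params)
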