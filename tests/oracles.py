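"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: a plain-Python Gotoh
local aligner, a from-scratch Karlin–Altschul expectation formula, a
brute-force six-frame ORF scanner, and a pathway-counting Ka/Ks
estimator. They are slow and simple on purpose.
"""

from __future__ import annotations

import math
from itertools import permutations
from typing import Dict, List, Tuple

from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_B62.alphabet)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    FORWARD_TABLE[stop] = "*"


def aa(codon: str) -> str:
    return FORWARD_TABLE.get(codon, "X")


def revcomp(dna: str) -> str:
    return dna.translate(COMPLEMENT)[::-1]


def smith_waterman_score(
    a: str, b: str, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Exhaustive local alignment score, affine gaps (a length-g gap costs
    gap_open + g*gap_extend, the BLAST convention)."""
    a = "".join(c if c in _ALPHA else "X" for c in a)
    b = "".join(c if c in _ALPHA else "X" for c in b)
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming b
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming a
    best = 0.0
    for i in range(1, n + 1):
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        ai = a[i - 1]
        row = _B62[ai]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] - first, Ei[j - 1] - gap_extend)
            Fi[j] = max(Hp[j] - first, Fp[j] - gap_extend)
            Hi[j] = max(0.0, Hp[j - 1] + row[b[j - 1]], Ei[j], Fi[j])
            if Hi[j] > best:
                best = Hi[j]
    return best


def karlin_altschul_evalue(
    score: float,
    m: int,
    n: int,
    lam: float,
    k: float,
    h: float,
    db_seqs: int = 1,
) -> float:
    """E = K*m'*n'*exp(-lambda*S); the length adjustment is the damped
    fixed point of ell = ln(K*(m-ell)*(n-N*ell))/H, effective lengths
    floored at 1/K (30 damped iterations)."""
    ell = 0.0
    it = 0
    while it < 30:
        m_eff = m - ell if m - ell > 1.0 / k else 1.0 / k
        n_eff = n - db_seqs * ell if n - db_seqs * ell > 1.0 / k else 1.0 / k
        proposal = math.log(k * m_eff * n_eff) / h
        if proposal < 0.0:
            proposal = 0.0
        ell = (ell + proposal) / 2.0
        it += 1
    m_eff = m - ell if m - ell > 1.0 / k else 1.0 / k
    n_eff = n - db_seqs * ell if n - db_seqs * ell > 1.0 / k else 1.0 / k
    return k * m_eff * n_eff * math.exp(-lam * score)


def brute_force_orfs(dna: str, min_nt: int = 60) -> set:
    """Every maximal stop-to-stop ORF >= min_nt on both strands, as
    (strand, start, end) forward-strand tuples (end includes the stop)."""
    out = set()
    L = len(dna)
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        for off in range(3):
            starts = []
            run_start = off
            pos = off
            while pos + 3 <= len(seq):
                codon = seq[pos : pos + 3]
                if aa(codon) == "*":
                    if pos > run_start and (pos + 3 - run_start) >= min_nt:
                        out.add(_fwd(strand, run_start, pos + 3, L))
                    run_start = pos + 3
                pos += 3
            if pos > run_start and (pos - run_start) >= min_nt:
                out.add(_fwd(strand, run_start, pos, L))
    return out


def _fwd(strand: str, s: int, e: int, L: int) -> Tuple[str, int, int]:
    if strand == "+":
        return (strand, s, e)
    return (strand, L - e, L - s)


# --- Ka/Ks (Nei–Gojobori style counting) -----------------------------------


def _site_counts(codon: str) -> Tuple[float, float]:
    syn = 0.0
    ref = aa(codon)
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if aa(alt) == ref and aa(alt) != "*":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _diff_counts(c1: str, c2: str) -> Tuple[float, float]:
    sites = [i for i in range(3) if c1[i] != c2[i]]
    if not sites:
        return 0.0, 0.0
    results: List[Tuple[float, float]] = []
    blocked: List[Tuple[float, float]] = []
    for order in permutations(sites):
        cur, s, n, hit_stop = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if aa(nxt) == "*" and nxt != c2:
                hit_stop = True
            if aa(nxt) == aa(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        (blocked if hit_stop else results).append((s, n))
    use = results if results else blocked
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


def ng86_kaks(cds1: str, cds2: str) -> Tuple[float, float]:
    """(Ka, Ks) by site counting with Jukes-Cantor correction."""
    assert len(cds1) == len(cds2) and len(cds1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
        if "N" in c1 or "N" in c2 or aa(c1) == "*" or aa(c2) == "*":
            continue
        s1, n1 = _site_counts(c1)
        s2, n2 = _site_counts(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _diff_counts(c1, c2)
        Sd += sd
        Nd += nd

    def jc(p: float) -> float:
        if p <= 0:
            return 0.0
        if p >= 0.75:
            return math.inf
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ks = jc(Sd / S) if S else 0.0
    ka = jc(Nd / N) if N else 0.0
    return ka, ks
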