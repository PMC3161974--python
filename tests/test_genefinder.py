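import math

import numpy as np
import pytest

from oracles import brute_force_orfs, ng86_kaks, revcomp
from syntegene.aligner import search_dna_vs_proteins
from syntegene.genefinder import (
    CandidateGene,
    FinderParams,
    PillarProfile,
    classify_locus,
    codon_align,
    get_orfs,
    kaks,
    try_frameshift_correction,
    try_intron_model,
    validate_single_exon,
)
from syntegene.simdata import SimConfig, mutate_cds, _random_cds

AA = list("ARNDCQEGHILKMFPSTWYV")


def _family(rng, n_codons=100, n_members=3, identity=0.8):
    """Ancestral CDS plus diverged member CDSs/proteins for one pillar."""
    from Bio.Seq import Seq

    anc = _random_cds(rng, n_codons)
    members = {}
    for i in range(n_members):
        cds = mutate_cds(anc, identity, rng)
        members[f"m{i}"] = str(Seq(cds).translate())[:-1]
    return anc, members


def _pad(rng, dna, left=90, right=90):
    flank = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    lpad = flank(left)
    return lpad + dna + flank(right), len(lpad)


class TestGetOrfs:
    def test_clean_orf_reported_once_per_strand_context(self, rng):
        cds = _random_cds(rng, 40)  # ATG...stop, 120 nt
        dna, off = _pad(rng, cds)
        calls = [
            o for o in get_orfs(dna, 60)
            if o.strand == "+" and o.range[0] <= off < o.range[1]
        ]
        # exactly one forward call contains the planted ORF and ends at its stop
        containing = [o for o in calls if o.range[1] == off + len(cds)]
        assert len(containing) == 1
        assert containing[0].has_start and containing[0].has_stop

    def test_tandem_stops_leave_no_orf_in_that_frame(self):
        stops = "TAATGATAG" * 10  # every frame-1 codon is a stop
        assert not [o for o in get_orfs(stops, 60) if o.frame == 1]

    def test_matches_brute_force_scanner_on_random_dna(self, rng):
        dna = "".join(rng.choice(list("ACGT"), size=2000))
        mine = {(o.strand, o.range[0], o.range[1]) for o in get_orfs(dna, 60)}
        assert mine == brute_force_orfs(dna, 60)

    def test_min_length_respected(self, rng):
        dna = "".join(rng.choice(list("ACGT"), size=1500))
        for o in get_orfs(dna, 90):
            assert o.range[1] - o.range[0] >= 90


class TestValidateSingleExon:
    def test_full_length_ortholog_accepted(self, rng):
        anc, members = _family(rng, 80, identity=0.85)
        hidden = mutate_cds(anc, 0.6, rng)
        dna, off = _pad(rng, hidden)
        profile = PillarProfile.from_members("P", members)
        orfs = [o for o in get_orfs(dna, 60)
                if o.range[0] <= off and o.range[1] >= off + len(hidden)]
        assert orfs
        cand = validate_single_exon(orfs[0], profile)
        assert cand.klass == "single_exon"
        assert cand.hsp_over_median == pytest.approx(1.0, abs=0.2)
        assert cand.model == [(off, off + len(hidden))]

    def test_short_hsp_rejected(self, rng):
        anc, members = _family(rng, 120, identity=0.85)
        # plant only the last quarter of the gene
        frag = "ATG" + mutate_cds(anc, 0.9, rng)[-90:]
        dna, off = _pad(rng, frag)
        profile = PillarProfile.from_members("P", members)
        orfs = [o for o in get_orfs(dna, 60)
                if o.range[0] <= off and o.range[1] >= off + len(frag)]
        cand = validate_single_exon(orfs[0], profile)
        assert cand.klass == "rejected"
        assert cand.reject_reason == "hsp_too_short"

    def test_unrelated_orf_not_reciprocal(self, rng):
        _, members = _family(rng, 100, identity=0.85)
        stray = _random_cds(rng, 70)
        dna, off = _pad(rng, stray)
        profile = PillarProfile.from_members("P", members)
        orfs = [o for o in get_orfs(dna, 60)
                if o.range[0] <= off and o.range[1] >= off + len(stray)]
        cand = validate_single_exon(orfs[0], profile)
        assert cand.klass == "rejected"
        assert cand.reject_reason in ("non_reciprocal", "hsp_too_short")


class TestFrameshiftCorrection:
    def _planted(self, rng, n=100, identity=0.75, where=0.5):
        anc, members = _family(rng, n, identity=0.85)
        hidden = mutate_cds(anc, identity, rng)
        ci = int(n * where)
        corrupted = hidden[: 3 * ci] + "A" + hidden[3 * ci :]
        dna, off = _pad(rng, corrupted)
        return members, dna, off, hidden, ci

    def test_single_insertion_recovered_with_flag(self, rng):
        from oracles import FORWARD_TABLE

        members, dna, off, hidden, ci = self._planted(rng)
        profile = PillarProfile.from_members("P", members)
        cand = try_frameshift_correction(dna, profile)
        assert cand.klass == "frameshift_corrected"
        assert "manual_check_frameshift" in cand.flags
        assert cand.correction_site is not None
        # recovered protein nearly identical to the uncorrupted one
        truth = "".join(
            FORWARD_TABLE[hidden[i : i + 3]] for i in range(0, len(hidden) - 3, 3)
        )
        from syntegene.simdata import protein_identity

        assert protein_identity(cand.protein, truth) >= 0.95

    def test_two_separated_disruptions_are_pseudogene(self, rng):
        anc, members = _family(rng, 100, identity=0.85)
        hidden = mutate_cds(anc, 0.75, rng)
        corrupted = hidden[:90] + "A" + hidden[90:210] + "A" + hidden[210:]
        dna, off = _pad(rng, corrupted)
        profile = PillarProfile.from_members("P", members)
        cand = try_frameshift_correction(dna, profile)
        assert cand.klass == "pseudogene"

    def test_single_internal_stop_flagged_null_allele(self, rng):
        anc, members = _family(rng, 100, identity=0.85)
        hidden = mutate_cds(anc, 0.8, rng)
        corrupted = hidden[:150] + "TAA" + hidden[153:]
        dna, off = _pad(rng, corrupted)
        profile = PillarProfile.from_members("P", members)
        cand = try_frameshift_correction(dna, profile)
        assert cand.klass == "frameshift_corrected"
        assert "null_allele_possible" in cand.flags

    def test_weak_scraps_are_not_pseudogenes(self, rng):
        """Spot hits to random DNA never produce a pseudogene call."""
        _, members = _family(rng, 150, identity=0.85)
        profile = PillarProfile.from_members("P", members)
        dna = "".join(rng.choice(list("ACGT"), size=500))
        cand = try_frameshift_correction(dna, profile)
        assert cand.klass == "rejected"


def _intron_family(rng, exons=(80, 45), identity=0.8, donor="GT", acceptor="AG"):
    """Pillar with intron-containing members plus a hidden spliced copy."""
    from Bio.Seq import Seq

    n = sum(exons)
    anc = _random_cds(rng, n)
    members, exlens = {}, {}
    for i in range(2):
        cds = mutate_cds(anc, identity, rng)
        members[f"m{i}"] = str(Seq(cds).translate())[:-1]
        exlens[f"m{i}"] = [3 * exons[0], 3 * (n - exons[0])]
    hidden = mutate_cds(anc, 0.7, rng)
    ilen = 60
    intron = donor + "".join(rng.choice(list("ACGT"), size=ilen - 4)) + acceptor
    cut = 3 * exons[0]
    gene = hidden[:cut] + intron + hidden[cut:]
    exon_ranges = [(0, cut), (cut + ilen, len(gene))]
    return members, exlens, gene, exon_ranges


class TestIntronModel:
    def test_two_exon_gene_recovered_with_exact_boundaries(self, rng):
        members, exlens, gene, exon_ranges = _intron_family(rng)
        dna, off = _pad(rng, gene)
        profile = PillarProfile.from_members("P", members, exlens)
        cand = try_intron_model(dna, profile)
        assert cand.klass == "intron_model"
        assert cand.model == [(s + off, e + off) for s, e in exon_ranges]
        assert "*" not in cand.protein

    def test_non_gt_ag_sites_rejected(self, rng):
        members, exlens, gene, _ = _intron_family(rng, donor="GC")
        dna, off = _pad(rng, gene)
        profile = PillarProfile.from_members("P", members, exlens)
        cand = try_intron_model(dna, profile)
        assert cand.klass == "rejected"
        assert cand.reject_reason in ("no_splice_sites", "no_gene_model")

    def test_exon_length_outside_tolerance_rejected(self, rng):
        members, exlens, gene, _ = _intron_family(rng)
        # pretend the member's exons are 15 aa different from reality
        exlens = {k: [v[0] - 45, v[1] + 45] for k, v in exlens.items()}
        dna, off = _pad(rng, gene)
        profile = PillarProfile.from_members("P", members, exlens)
        cand = try_intron_model(dna, profile)
        assert cand.klass == "rejected"

    def test_small_exon_member_flagged_not_modeled(self, rng):
        members, exlens, gene, _ = _intron_family(rng, exons=(12, 90))
        dna, off = _pad(rng, gene)
        profile = PillarProfile.from_members("P", members, exlens)
        cand = try_intron_model(dna, profile)
        assert cand.klass == "intron_model"
        assert "manual_check_small_exon" in cand.flags
        assert len(cand.model) == 1  # only the large exon localized

    def test_no_intron_members_means_no_model(self, rng):
        _, members = _family(rng, 90)
        profile = PillarProfile.from_members("P", members)
        cand = try_intron_model("ATG" + "A" * 300, profile)
        assert cand.klass == "rejected"
        assert cand.reject_reason == "no_intron_member"


class TestClassifyLocus:
    def _search(self, dna, profile):
        return search_dna_vs_proteins(dna, profile.member_proteins)

    def test_intact_orf_wins_cascade(self, rng):
        anc, members = _family(rng, 90, identity=0.85)
        hidden = mutate_cds(anc, 0.7, rng)
        dna, off = _pad(rng, hidden)
        profile = PillarProfile.from_members("P", members)
        cand = classify_locus(dna, self._search(dna, profile), profile)
        assert cand.klass == "single_exon"
        assert cand.model == [(off, off + len(hidden))]

    def test_multi_disruption_region_is_pseudogene(self, rng):
        anc, members = _family(rng, 100, identity=0.85)
        hidden = mutate_cds(anc, 0.8, rng)
        bad = hidden[:60] + "TAA" + hidden[63:150] + "TAG" + hidden[153:240] + "TAA" + hidden[243:]
        dna, off = _pad(rng, bad)
        profile = PillarProfile.from_members("P", members)
        cand = classify_locus(dna, self._search(dna, profile), profile)
        assert cand.klass == "pseudogene"

    def test_output_invariant_to_hit_ordering(self, rng):
        anc, members = _family(rng, 80, identity=0.85)
        hidden = mutate_cds(anc, 0.65, rng)
        dna, off = _pad(rng, hidden)
        profile = PillarProfile.from_members("P", members)
        hits = self._search(dna, profile)
        a = classify_locus(dna, hits, profile)
        b = classify_locus(dna, list(reversed(hits)), profile)
        assert (a.klass, a.model, a.protein) == (b.klass, b.model, b.protein)

    def test_accepted_models_never_contain_internal_stops(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            anc, members = _family(r, 90, identity=0.85)
            hidden = mutate_cds(anc, 0.6, r)
            ci = 45
            corrupted = hidden[: 3 * ci] + "C" + hidden[3 * ci :]
            dna, off = _pad(r, corrupted)
            profile = PillarProfile.from_members("P", members)
            cand = classify_locus(dna, self._search(dna, profile), profile)
            if cand.klass in ("single_exon", "frameshift_corrected", "intron_model"):
                assert "*" not in cand.protein
            if cand.klass == "frameshift_corrected":
                assert cand.correction_site is not None
            if cand.klass == "intron_model":
                assert cand.correction_site is None


class TestKaKs:
    def test_identical_pair_is_undefined_sentinel(self):
        cds = "ATGGCTAGAGAT" * 10
        ka, ks, ratio = kaks(cds, cds)
        assert ka == 0 and ks == 0 and math.isnan(ratio)

    def test_fourfold_synonymous_only_gives_zero_ratio(self):
        # GGT->GGC etc: third-position changes in 4-fold degenerate codons
        a = ("GGT" + "CCT" + "ACT" + "GTT") * 10
        b = ("GGC" + "CCG" + "ACA" + "GTC") * 10
        ka, ks, ratio = kaks(a, b)
        assert ka == 0.0
        assert ks > 0
        assert ratio == 0.0

    def test_matches_counting_oracle_on_simulated_pairs(self, rng):
        from syntegene.simdata import _random_cds, mutate_cds

        for seed in range(6):
            r = np.random.default_rng(seed)
            anc = _random_cds(r, 80)
            der = mutate_cds(anc, 0.75, r)
            a, b = anc[:-3], der[:-3]  # strip stops
            ka, ks, _ = kaks(a, b)
            oka, oks = ng86_kaks(a, b)
            assert ka == pytest.approx(oka, abs=1e-6)
            assert ks == pytest.approx(oks, abs=1e-6)

    def test_purifying_selection_gives_ratio_below_one(self, rng):
        from syntegene.simdata import _random_cds, mutate_cds

        below = 0
        for seed in range(8):
            r = np.random.default_rng(seed)
            anc = _random_cds(r, 150)
            der = mutate_cds(anc, 0.75, r, omega=0.2)
            ka, ks, ratio = kaks(anc[:-3], der[:-3])
            if not math.isnan(ratio):
                below += ratio < 1
        assert below == 8

    def test_codon_align_strips_gaps(self, rng):
        a = "ATGGCTAGAGATCCTTTG"
        b = "ATGGCTGATCCTTTG"  # AGA codon deleted
        ca, cb = codon_align(a, b)
        assert len(ca) == len(cb)
        assert len(ca) % 3 == 0
        assert len(ca) <= len(b) + 3

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            kaks("ATGGCT", "ATG")
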