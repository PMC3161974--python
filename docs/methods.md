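# Methods

## The problem and the approach

Short, rapidly diverging, and intron-containing protein-coding genes are
routinely missed by genome annotation pipelines because they cannot
produce a statistically convincing BLAST hit on their own: a 25-residue
ribosomal protein aligned to its own ortholog rarely scores better than
E ≈ 1e-6, and many genuine orthologs in a diverse clade of yeasts do not
hit one another at all below E = 10. `syntegene` recovers such genes by
adding one piece of outside information to the search: conserved local
gene order. If a weak translated hit lands in the genomic region where
the ortholog is *expected* to be — between the neighbours of its
orthologs in related species — the hit is trustworthy even at E-values
that would be noise in a whole-proteome search.

The pipeline operates on a clade of annotated genomes tied together by
two structures that are taken as input, not inferred:

* a **pillar table** — one column of orthologs per ancestral gene, with
  up to one gene per species, or two for species descended from a
  whole-genome duplication (WGD);
* a **reference (ancestral) gene order** — ordered pillar IDs per
  ancestral chromosome.

## Segments and orthologous groups

Each genome is cut into overlapping **segments**: two adjacent annotated
genes plus the intergenic DNA between them. A contig with *n* eligible
genes yields *n−1* segments; a gene with `switched_off` status, or one
absent from every pillar, is transparent (it never anchors a segment).
Mapping both flanking genes to the ancestral order assigns the segment
to one or more ancestral intervals — a run of gene deletions makes one
segment orthologous to several consecutive intervals. Segments from
different species assigned to the same interval form an **orthologous
genomic segment (OGS) group**. When the two flanks map to different
ancestral chromosomes, when only one flank maps, or when the implied
span exceeds `interval_cap` (default 20 intervals), the segment is
marked *rearranged* and keeps only the interval(s) adjacent to each
mappable flank.

Contig-end (single-flank) segments can be emitted behind
`include_ends=True`; the default pipeline leaves them off so the
*n−1* algebra holds and terminal fragments do not enter the scan.

## The syntenic search database

For each segment, the database searched by its intergenic DNA contains
only syntenically expected proteins. In colinear regions that is every
target-species gene whose pillar position lies between the flanking
pillars, inclusive. Where the mapping is rearranged, the pipeline
*steps out* from each mappable flank's target-species ortholog through
the target genome, retaining genes while their pillar positions remain
locally colinear (same ancestral chromosome, within `gap_tolerance = 5`
positions of the previous retained gene), never crossing a contig
boundary, up to `step_out_cap = 10` genes per direction. The threshold
for "synteny lost" is a package parameter: the underlying concept has no
canonical number, and both knobs are exposed in the configuration.

## Search engine

The candidate databases are tiny (a handful of proteins), so the
built-in engine affords exact local alignment: every frame/target pair
is scored by full Smith–Waterman with affine gaps (BLOSUM62, gap open
11, extend 1; BLAST's convention that a length-g gap costs open + g).
The DP core is Biopython's `PairwiseAligner`; an optional adapter runs
NCBI BLAST+ behind the same interface, and a test asserts set-level
agreement between the two backends for solid alignments. Low-complexity
filtering is off by default. Stop codons in translated frames score as
strong mismatches and do not terminate alignments: disrupted reading
frames are the gene-builder's business.

E-values follow Karlin–Altschul, E = K·m′·n′·e^(−λS), with fixed
published (λ, K, H) per scoring system (0.267, 0.041, 0.14 for gapped
BLOSUM62 11/1) and the standard edge-effect length adjustment: the
damped fixed point of ℓ = ln(K·(m−ℓ)·(n−Nℓ))/H with effective lengths
floored at 1/K (30 damped iterations; deterministic). Searches retain
everything below E = 10 — deliberately liberal — sorted by E-value, raw
score, then subject ID, capped at 100 results. A `detail` argument
limits the expensive alignment traceback to the top-ranked hits when a
caller only needs the best alignment's coordinates.

## From hit to gene model

A segment whose intergenic DNA hits its syntenic database enters a
classification cascade. The target pillar is the best-hit subject's
pillar; its annotated members form the validation profile (proteins,
median length, exon structures).

1. **Single exon.** Maximal stop-to-stop ORFs (≥ 60 nt, both strands)
   overlapping the hit region are translated and searched against the
   pillar members. Acceptance needs a reciprocal hit at E < 10 and a
   best-HSP length of at least `length_ratio_min = 0.5` of the pillar's
   median protein length (the median rule has no published constant; 0.5
   is the package default, configurable). The model runs from the
   in-frame ATG nearest the position implied by the alignment (alignment
   start minus unaligned subject prefix) through the stop codon. ORFs
   with no ATG are flagged, not silently extended.
2. **Single-disruption repair.** HSPs of each member are chained
   colinearly (generous overlap tolerance, because local alignments
   overrun a breakpoint in both frames). One frame transition, or one
   internal stop codon, with no other disruption, is presumed a
   sequencing error: the correction point is scanned across the
   inter-HSP window and the position whose corrected protein validates
   best is kept. The exact position is an estimate, so the candidate
   always carries `manual_check_frameshift`; the internal-stop variant
   also carries `null_allele_possible`, since a strain-specific null
   allele is indistinguishable from a sequencing error.
3. **Intron model.** Attempted when the pillar has an intron-containing
   member. Each member exon peptide is located independently in six
   frames; candidate exons must appear in the member's order with
   lengths within ±10 aa. Introns must begin GT and end AG; donor/
   acceptor pairs are enumerated in ±12-nt windows around the exon-hit
   boundaries, junction phases must match the member's exon structure,
   and no frameshifts are permitted. Terminal exons may be extended by
   up to 40 aa to reach a start/stop; splice windows are centred on the
   member-anchored boundary expectation (hit end corrected for unaligned
   subject residues). A convincing model must validate over ≥ 80% of its
   length and stay in register with its member end to end: the best
   offset-only (gapless) comparison must reach 90% of the gapped score.
   A misplaced splice point shifts everything past the junction out of
   register and fails this check. Members with an exon under 20 codons defeat
   alignment-based localization; such loci are emitted with only the
   larger exon(s) placed and `manual_check_small_exon` set.
4. **Pseudogene.** Two or more disruptions (frame transitions plus
   internal stops, counted without double-counting overlap regions)
   classify the locus as a pseudogene — provided the chained HSPs cover
   ≥ `length_ratio_min` of the median *and* the best hit is confident
   (E < 1e-5). A pseudogene call asserts positive homology; weak
   scrappy hits remain plain rejections. Pseudogene loci are masked and
   excluded from all later cycles.
5. **Rejection.** Everything else is recorded with its reason
   (`non_reciprocal`, `hsp_too_short`, `no_splice_sites`,
   `exon_length_mismatch`, `no_gene_model`, `no_model`). Alignment
   quality is never an automatic rejection: candidates whose best
   identity falls below 30% are flagged `needs_review` instead, standing
   in for the original workflow's human alignment inspection.

The repair paths are always evaluated alongside an accepted ORF, and
the contender whose validated protein scores highest wins — a partial
ORF must not outrank a frameshift correction or intron model that
explains more of the subject, and an ORF whose gapped alignment reads
straight through an in-frame intron or a frameshift must not win just
because its alignment is long. A parsimony guard protects intact genes
in the other direction: a frameshift repair displaces a single-exon
model only when it both scores at least 1.1× higher and explains at
least 0.15 more of the pillar median — a genuine correction reunites
two fragments and gains coverage, while a spurious restitching mostly
re-explains residues the intact frame already covered. HSPs feeding the
disruption count are filtered for informativeness (confident at
E < 0.01, or contributing ≥ 10 subject residues not covered by any
stronger HSP): marginal alignments overlapping genuine fragments are
noise, but the short outer fragments of truly disrupted genes must be
kept.

## Cycling

Each cycle rebuilds segments and OGS groups from the current annotation
set, scans every unmasked intergenic region of length ≥ 60 nt, and
inserts accepted genes into their pillars under the name
`<species>_YGOB_<pillar>`; from the next cycle on they serve as queries,
which is what lets a gene found in one species reveal its orthologs in
others. Flagged candidates go to a review table and are not inserted
unless `accept_flagged` is set; a candidate whose pillar cell is already
full (respecting WGD cardinality) is flagged `conflict` and not
inserted. Rejected loci stay eligible in later cycles — a new query may
rescue them — while accepted, flagged, and masked loci are finalized.
The run converges when a cycle accepts nothing (at most `max_cycles`,
default 10). Iteration order is fully sorted, so runs are deterministic.

## Selection check

For each accepted gene, Ka/Ks against a pillar ortholog is estimated by
the counting method: per-codon synonymous/nonsynonymous site fractions
(changes to stop codons count as nonsynonymous), difference counts
averaged over minimal mutational pathways (paths through stop codons
excluded unless all are blocked), and a Jukes–Cantor correction on both
proportions. Ks = 0 with Ka > 0 reports +inf; an identical pair reports
NaN. Pairs shorter than 30 codons warn. Codon alignment is
protein-guided with gapped codons removed. Ka/Ks < 1 on every accepted
gene is the expected signature of purifying selection and is asserted
in the acceptance suite.

## The synthetic clade generator

All tests run on generated clades, so the generator defines the study
conditions:

* **Phylogeny.** A star topology: each species' copy of each gene is
  mutated from the ancestral CDS until its protein identity to the
  ancestor reaches a per-species target drawn from
  `identity_to_ancestor` (default 0.78–0.92, giving roughly 0.6–0.85
  pairwise — a deeply diverged but alignable clade). Mutations are
  codon-aware: transitions favoured (2:1), stops never created,
  nonsynonymous changes accepted with probability ω = 0.2, so accepted
  genes sit under purifying selection by construction and the Ka/Ks
  check has a true signal. Planted events can instead derive one
  species' copy from another's (`mutate_from`), or retain only a codon
  slice (`keep_codons`, modelling domain loss after gene fission) —
  the chained-discovery fixtures use both.
* **Genome layout.** Genes in ancestral order with random per-gene
  strands conserved across species; intergenic spacers of 120–300 nt
  drawn from a 3rd-order Markov chain trained on the complement strand
  of the simulated coding sequences, so spurious ORFs of realistic
  length occur and exercise the rejection rules. Per-species gene
  deletion probability 0.04 (planted loci and their neighbours are
  protected). Optional post-WGD species carry two tracks per ancestral
  chromosome with independent 0.55 retention per copy.
* **Planted events.** Hidden genes (present in DNA, absent from GFF3),
  single 1-nt frameshift insertions, k-disruption pseudogenes
  (alternating indels and premature stops), GT-AG two-exon intron genes
  (intron 45–90 nt, phase 0; the splice dinucleotides are editable to
  build negative controls), annotation-preserving copy modifications,
  and gene-order rearrangements. Every hidden gene keeps an annotated
  ortholog in at least one other species — the method, by design,
  cannot find genes annotated nowhere.
* **Reproducibility.** One `numpy` generator seeded from `seed` drives
  everything; identical configurations produce byte-identical output
  files.

What the generator does **not** emulate: insertions/deletions within
coding sequence (divergence is substitution-only, which is why the
intron validator can demand indel-free support), non-phase-0 introns,
transposable elements and their degenerate fragments, base-composition
heterogeneity along chromosomes, and non-star gene trees beyond the
explicit `mutate_from` events. Passing tests therefore demonstrate the
machinery of synteny-constrained discovery — not performance on
indel-rich or repeat-rich real genomes, where the review flags and the
liberal/strict threshold interplay would matter more.

## Problem sizes in the test suite

The acceptance suite uses 100 random genomes of 20–200 genes for the
segment algebra; 500 random DNA/protein pairs against a from-scratch
Gotoh oracle for the aligner; twenty 3-species × 200-gene clades with
five hidden genes each (25–150 codons, roughly 30–80% pairwise
identity, two plants per clade drawn from the short/highly-diverged
corner where E-values reach the 1e-3–10 twilight zone) for recovery;
and small dedicated fixtures for repair rules, cycling and Ka/Ks. The
acceptance script scales the same protocol to six 120-gene clades with
mixed event types.

## Known limitations

* Two-flank mapping cannot see *internal* rearrangements of a segment
  that stay on one ancestral chromosome; such inversions simply appear
  colinear.
* A randomly occurring GT…AG pair can occasionally support a consistent,
  indel-free spliced model at a locus whose true sites are non-canonical;
  the phase and indel checks make this rare but cannot exclude it.
* The frameshift correction position is chosen to maximize the corrected
  protein's score; in low-identity regions the true sequencing-error
  position may differ by a few codons (hence the mandatory review flag).
* Pillar assignment of a discovery follows the best-hit subject; at
  loci hit by paralogs from a neighbouring pillar the assignment can be
  wrong in ways only the review table would reveal.
* In the deep twilight zone (roughly 30% identity over ~50 codons) the
  evidence for "intact gene" versus "single frameshift" can genuinely
  favour the wrong reading: a stitched two-frame interpretation may
  out-score and out-cover the intact frame, routing a real gene to the
  review pile as a flagged frameshift candidate. Similarly, a
  two-disruption pseudogene whose short outer fragment yields no
  alignment at all looks like a single-disruption locus and is offered
  as a review-flagged correction instead of being masked. Both failure
  modes stay out of the auto-accepted set.
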