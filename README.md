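# syntegene

Synteny-aware discovery of unannotated protein-coding genes in clades of
related genomes.

Annotation pipelines systematically miss genes that are short, highly
diverged, or intron-containing, because such genes cannot produce a
convincing BLAST hit on their own: a 25-codon protein rarely beats
E ≈ 1e-6 against its own ortholog, and at typical significance cutoffs
it is indistinguishable from noise. `syntegene` rescues these genes by
constraining the search with conserved gene order. Genomes are cut into
overlapping **segments** — two adjacent annotated genes plus the
intergenic DNA between them — and grouped into **orthologous genomic
segment (OGS) groups** by mapping the flanking genes onto a reference
(ancestral) gene order. Each segment's supposedly intergenic DNA is then
searched (six-frame translated Smith–Waterman) against only the proteins
that are *syntenically expected* there. Because the database is so
constrained, hits can be trusted out to the very liberal cutoff E < 10:

> E = K·m′·n′·e^(−λS),  retained whenever E < 10

with Karlin–Altschul constants (λ = 0.267, K = 0.041 for gapped
BLOSUM62, gap 11/1) and the standard edge-effect length correction.
Retained loci are built into validated gene models — intact ORFs
(≥ 60 nt, reciprocal hit, best HSP ≥ half the pillar's median protein
length), single-frameshift or single-internal-stop corrections (flagged
for review; two or more disruptions define a pseudogene, which is masked
from later cycles), and GT-AG intron models whose exons match an
intron-containing ortholog in order and length (±10 aa). Accepted genes
join their homology pillar and serve as queries in the next cycle, so a
gene discovered in one species can reveal its orthologs in others; the
scan repeats until a cycle finds nothing new. A counting-method Ka/Ks
estimator checks that accepted genes evolve under purifying selection
(Ka/Ks < 1).

A bundled simulator generates complete synthetic clades — genomes, GFF3
annotations, pillar table, ancestral order — with planted ground truth
(hidden genes, frameshifts, pseudogenes, intron genes, rearrangements,
optional whole-genome duplication), so the entire pipeline is testable
without downloading anything.

## Worked example

```bash
# simulate a 3-species clade with one hidden gene in species spB
cat > sim.yaml <<'YAML'
n_species: 3
genes_per_chromosome: 20
events:
  - {kind: hide_annotation, species: spB, aa_identity: 0.55}
YAML
syntegene simulate --seed 3 --config sim.yaml --out clade

# run discovery cycles to convergence
syntegene run --db clade --out run1
```

which prints:

```
1 genes accepted, 0 for review, 0 pseudogene loci masked in 2 cycles
```

and `syntegene report run1` shows the per-species summary:

```
species_id  genes_added  intron_containing_added  frameshift_corrected  pseudogenes  added_lt_100_codons  added_lt_200_codons  flagged_for_review
       spB            1                        0                     0            0                    0                    1                   0
```

The one accepted gene is the planted one: `run1/accepted.gff3` places
`spB_YGOB_Anc_1.15` at exactly the hidden locus (GFF3 coordinates
9244–9567 on `spB_c1`, matching the 0-based span 9243–9567 recorded in
`clade/truth.json`), recovered although spB's annotation never
mentioned it — its orthologs' syntenic context said a gene should be
there, and a weak translated hit confirmed it.
`run1/details.tsv` lists every other locus that was hit and why it was
rejected (mostly `hsp_too_short`: spurious weak hits whose alignments
are far shorter than the pillar median — the rejection rules at work).

The same machinery is available as a library:

```python
from syntegene import SimConfig, PlantedEvent, simulate_clade
from syntegene import CladeInputs, run_to_convergence

bundle = simulate_clade(SimConfig(seed=3, events=[...]))
state = run_to_convergence(CladeInputs(bundle.genomes, bundle.annotations,
                                       bundle.pillars, bundle.order))
```

## Layout

| module | role |
| --- | --- |
| `syntegene.io_formats` | FASTA / GFF3 / pillar TSV / ancestral-order readers and writers, strict validation, 0-based half-open coordinates internally |
| `syntegene.segments` | two-gene segments, ancestral-interval mapping, OGS groups |
| `syntegene.synteny` | per-segment syntenic candidate databases, step-out in rearranged regions, clade-wide index |
| `syntegene.aligner` | exact translated & protein local search, Karlin–Altschul statistics, optional BLAST+ backend |
| `syntegene.genefinder` | ORF calling, validation, frameshift correction, intron models, pseudogene classification, Ka/Ks |
| `syntegene.pipeline` | cycle orchestration, masking, pillar insertion, reports |
| `syntegene.simdata` | synthetic clade generator with ground truth and scoring |
| `syntegene.cli` | `syntegene simulate / run / report` |

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.
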