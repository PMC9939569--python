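# Methods

## Problem setting

De novo assemblers report every transcript isoform and many
near-identical contigs; downstream orthology tools want one protein per
gene. `zooclock` implements the reduction from assembly to
representative proteome, the bait-based orthology procedure for
identifying circadian clock components, and the statistics that validate
both. All filters carry exact, stated thresholds so that a run is fully
determined by its configuration and seed.

## Read quality filtering

A read fails when it contains an ambiguous base ('N') or its
arithmetic-mean PHRED score (integer per-base scores, PHRED+33 only) is
strictly below `min_mean_q` (default 20); a pair is discarded when
either mate fails, since unpaired reads are useless for paired-end
assembly. The boundary is deliberately strict-below: a mean of exactly
20 passes. Adapter trimming and error correction are assumed done
upstream; the filter sees already-trimmed reads. Reported retention and
loss percentages are rounded half-away-from-zero to one decimal, and
loss is computed as 100 − retained so the two always sum to 100.0.

## ORF prediction and completeness

All six frames of a transcript are scanned. Within a frame, codon runs
are delimited by stop codons, codons containing N (untranslatable), and
the sequence edges. Candidates are (a) the run from the frame's leading
edge (eligible only when no stop codon precedes it) and (b) the run
from the first ATG of each delimited span. The best ORF is the one with
the longest protein; ties prefer the plus strand, then the lower frame,
then the smaller forward-strand start. Completeness is `cmp` (ATG and
stop), `5p` (stop only), `3p` (ATG only), `int` (neither). Coordinates
are 0-based half-open on the forward strand, with the stop codon
included in the span; minus-strand ORFs store forward-strand coordinates
of the reverse-complemented span. ORFs below `min_aa` (default 100
residues) are discarded. Scoring is purely by length — no coding-
potential model — which keeps the predictor fully testable against an
exhaustive six-frame enumeration; the known cost is that a longer
partial frame can outscore a shorter complete one, a behavior real
ORF predictors also exhibit.

## Near-identical sequence clustering

Greedy incremental clustering in descending length order (ties broken
lexicographically by id): a sequence joins the first existing
representative it matches, else founds a new cluster, and the founding
(longest) member is the representative. Matching requires global
identity ≥ `min_identity` and coverage ≥ `min_target_cov` (both default
0.98). Identity is defined as 1 − d/max(|a|, |b|), where d is the
unit-cost global (Needleman–Wunsch) edit distance: on gap-free
alignments this equals the fraction of identical columns, and unlike
matched-columns/alignment-length it does not depend on which co-optimal
traceback an aligner happens to return, so an independent
implementation reproduces it exactly. Coverage is the shorter/longer
length ratio — in a global alignment every residue of the shorter
sequence is aligned, so the length ratio is the informative quantity.
A length-ratio prefilter (identity can never exceed shorter/longer
under this normalization) skips provably hopeless alignments without
changing results; distances come from edlib with an early-exit bound
k = ⌊L·(1 − t)⌋.

## Isoform selection and final extraction

Trinity ids `TRINITY_DN<d>_c<d>_g<d>_i<d>[.p<d>]` group isoforms by
their `DN_c_g` gene key. Per gene, the longest predicted protein wins;
ties go to the smallest isoform index, then lexicographic id. Final
transcriptomes are extracted from the initial assembly in assembly
order, one transcript per kept protein.

## Assembly statistics

N50 is the length at which the cumulative sum over descending-sorted
lengths first reaches half the total bases (boundary cases resolve to
the larger length). Complete-ORF percentage is the share of predicted
ORFs tagged `cmp`. Phase summaries report arithmetic means — N50 and
transcript counts rounded to integers, percentages to two decimals.
BUSCO completeness is parsed from external summaries, never computed;
completeness = (single-copy + duplicated)/total.

## Annotation merging

Homology hits above the E-value cutoff (default 1e−5) are dropped; per
query the minimum-E-value hit survives, ties broken by higher bitscore
then lexicographic target. No coverage cutoff is applied at this stage
so short sequences can still be annotated. Any non-empty row from the
orthology-style annotation source counts as an annotation; rates
(source-specific and either-source) are percentages of the sequence
universe at one decimal.

## Bait-based clock identification

Reference clock proteins are tagged by appending a unique marker
(`SOIREF`) to their FASTA ids inside their proteomes; a registry maps
each of the ten components to its tagged id, Pfam domain set and
family/subfamily accession. Every pairwise-ortholog row with exactly
one tagged member yields a raw candidate for the untagged member's
species (one-to-many orthology yields several; duplicates collapse;
rows with two tagged members are skipped with a warning). The vetting
cascade then applies, in order: (S1) candidates lacking either domain
or family annotation are dropped; (S2) candidates sharing no Pfam
accession with their bait are dropped; (S3) candidates outside the
bait's family are dropped; (S4) within each (species, component)
group, if any survivor carries the bait's subfamily, only those are
kept. Failing a stage short-circuits later stages, and every candidate
carries a per-stage audit record. Swiss-Prot confirmation — is the
candidate's best homolog on a user-supplied whitelist of clock
accessions — is logged per candidate but never removes one: vetting
survivors are all retained, because no in-silico criterion reliably
separates multiple surviving candidates of single-copy components. A
candidate orthologous to two baits is kept under both assignments.

Validation compares found vs expected (component, accession) pairs as
plain set arithmetic (TP/FN/FP). Run comparison reports shared and
exclusive candidate counts keyed by (species, sequence id, component),
as percentages of the union at one decimal. Fallback searches against
external assemblies drop hits with query or target coverage below 0.20
(exactly 0.20 survives), keep the single minimum-E-value survivor per
species and component, and emit status codes: `-` already found
upstream, `YES` found here, `NH` no homolog, `ND` no data available.

## Synthetic data generator

The generator emulates the input structure the analysis assumes, not
sequence biology: per species, one true ortholog per clock component is
the bait protein with i.i.d. substitutions at `divergence_per_species`
(default 0.15; substitutions only, initiator Met preserved, no indels —
keeping identity/coverage arithmetic exact for oracle checks).
Component architectures are fixed domain layouts (360–1000 residues,
one to three domains at fixed coordinates) with one distinct
family/subfamily accession per component. Optional planted structure:

- **Paralogs** (rate 0.25): extra copies at double divergence, same
  family, different subfamily, absent from the pair table.
- **Fragments** (rate 0.2): orthologs truncated 5', 3' or both, cuts
  placed outside all domains and never on a Met, at least 150 residues
  retained, so the ORF classifier independently re-derives the planted
  tag and the vetting cascade still sees every domain.
- **Decoys** (3 per species): one bait domain copied into a random
  protein assigned to an unrelated family — they pass the shared-domain
  stage and fail the family stage by construction.
- **Isoforms** (1–3 per gene): the i1 isoform back-translates the full
  protein (fixed codon per amino acid; Leu/Ser codons chosen so their
  reverse complements are stop codons, keeping reverse-strand open
  frames short); later isoforms are prefix truncations.
- **Near-duplicates** (rate 0.25): transcript copies with ~1%
  substitutions, 3 nt shorter than the original so the original
  deterministically founds the cluster.
- **Pair-table noise**: true pairs dropped at `ortholog_fn_rate`, decoy
  pairs injected at `ortholog_fp_rate` (defaults 0).

Untranslated flanks carry stop codons in all three forward frames so no
predicted ORF can run through them. Reads are uniformly sampled
fixed-length windows at Q40, with configurable fractions given an 'N'
or a low mean quality; the generator records which pairs were planted
clean. Everything derives from one integer seed via Python's `random`
and is byte-reproducible.

What the generator does **not** emulate: realistic codon usage or
divergence models, indels, expression levels, sequencing-error
profiles beyond the two defect classes, or assembly artifacts.
Passing tests therefore demonstrate the correctness of the pipeline's
logic on inputs with the assumed structure — not robustness to
misassembly or annotation error in real data.

## Pipeline and determinism

Stages operate on a run directory and record config and input hashes in
a run manifest; re-running an unchanged stage is a no-op unless forced,
and stages check their declared dependencies. Identical configuration
and seed give identical artifacts. Structured log lines report in/out
counts at every filter. Acceptance-scale problem sizes (5 species × 10
components, ~170 transcripts, 500 read pairs per species; property
suites at 1000 N50 draws, 100 clustering seeds on ≤ 20-sequence
instances, 50 random 300-nt ORF scans) were chosen so the whole suite
completes in seconds on one CPU while still exercising every planted
feature class.

## Known limitations

- Length-scored ORFs can differ from coding-potential-scored picks of
  dedicated tools on real data; completeness tags inherit any such
  differences.
- The clustering identity definition, while exact and symmetric, is not
  identical to any specific external clustering tool's notion of
  identity; thresholds tuned for one definition do not transfer
  bit-for-bit.
- The pairwise-orthology inference itself (orthogroup construction,
  tree rooting) is out of scope: ortholog tables are consumed, not
  computed, and the candidate quality ceiling is set by whatever
  produced them.
- Swiss-Prot confirmation depends entirely on the supplied whitelist;
  an empty whitelist yields all-unconfirmed flags, never removals.
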