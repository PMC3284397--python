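# Methods

## Classification model

A read is assigned by maximum likelihood under a naive Bayes model over
fixed-length N-mers. For taxon *g* with count table c_g and total T_g,

    log Pr(s | g) = Σ_w log [ (c_g(w) + α) / (T_g + α·4^N) ]

over every valid window *w* of the read. Assumptions worth stating
explicitly:

- **N-mer independence.** Overlapping windows are treated as independent
  observations. This overcounts evidence but is the standard trade-off in
  composition classifiers; it is what makes the method trainable from
  partial and unaligned sequences.
- **Uniform prior, dropped evidence.** Pr(g) is uniform and Pr(s) is
  treated as equiprobable across taxa. The consequence is a genome-length
  bias: a longer training genome contains more distinct N-mers and
  therefore attracts queries that resemble no taxon in particular. The
  package reproduces this bias by design (it is a property of the model,
  verified by a dedicated test) rather than attempting a length
  correction; query-length score normalisation is an open problem for
  this whole model family and is out of scope here.
- **Per-profile smoothing only.** α is added inside each taxon's own
  profile; no information is shared across taxa. Corpus-wide or
  genus-specific priors (as used by marker-gene classifiers trained on
  dense, homogeneous databases) behave poorly when profiles are built
  from partial and incomplete sequence sets, so they are deliberately
  not offered. α = 0 is supported: unseen N-mers then score −∞ and a
  read matching nothing becomes *unclassified* instead of being forced
  onto some taxon.

Numerical choices: all scores are natural-log; windows containing any
non-ACGT character are skipped whole (no fractional counting), so results
are deterministic; coordinates are 0-based half-open; argmax ties break
on lexicographic taxon id for cross-platform reproducibility. For N ≤ 10
each profile is expanded to a dense 4^N log-probability vector when many
reads are scored; above that a sparse dictionary with a shared
unseen-N-mer default is used. Both paths are checked against an
exact-rational brute-force scorer.

Key parameters: `n` (N-mer length, bases; default 15, the value used by
the deployed NBC ecosystem — tests and the desk-scale benchmark use
n ∈ {2..8} where 4^n enumeration and dense scoring are cheap), `alpha`
(pseudocount, default 1), `strand_policy` (profiles are built from the
deposited strand by default; reads are scored `max_of_strands` by default
since shotgun reads have no preferred orientation).

## Grouping and databases

Training sequences are grouped into one profile per taxon via an explicit
record→taxon mapping TSV: `by_strain` (viral-style, one label per
genome/segment; how multi-segment viruses are pooled is the mapping
file's decision) or `by_species` (fungal-style, many deposited records
pooled per species). FASTA headers are never parsed for taxonomy —
deposited headers ("uncultured fungus", "fungus sp.") are too
inconsistent. The serialized database is versioned JSON holding only
observed N-mers (a dense 4^15 table is infeasible), build metadata and
source-file SHA-256 digests, plus a payload digest verified at load; the
build timestamp is recorded only on request so identical inputs always
serialize byte-identically. `heterogeneity_warning` flags databases whose
per-taxon training sizes span more than a 100× ratio (advisory only):
mixing, say, viral genomes with bacterial chromosomes hands most novel
reads to the longest genomes.

## Read simulator

Reads emulate a 454 pyrosequencer in two stages. A clone length is drawn
from Normal(2000, 200) bp, rounded, truncated to the source record,
placed uniformly on a uniform strand. The clone is then read by a
flowgram model: nucleotides flow in the fixed order TACG for 99 cycles
(396 flows); a flow whose base matches the current template position
reads the *entire* homopolymer run h with signal ~ Normal(h, 0.15·√h),
while a non-matching (negative) flow draws a lognormal background signal
with raw-scale mean 0.23 and sd 0.15; the called run is the rounded
signal. Homopolymer over/under-calls and occasional one-base insertions —
the characteristic 454 error modes — emerge from the rounding. Per-read
error counts are Levenshtein distances (edlib) against the consumed
template prefix.

This is a *simplified stand-in* in the standard flowgram
parameterisation, not a bit-level reproduction of any specific simulator:
the lognormal parameters are interpreted on the raw signal scale (the
conventional reading of "mean 0.23 ± 0.15"; the underlying-parameter
reading would insert a base at nearly every empty flow), and the
positive-flow width scale (default 0.15 signal units per √h) is a free
parameter of this implementation. Under the defaults the mean read
length on random sequence is ≈ 270–276 bp, consistent with the ~252 bp
nominal flow budget plus background insertions. "Approximately 100 reads
per genome" is resolved to exactly 100 for determinism; a single
generator seeded from the config drives the whole read set, so outputs
are byte-reproducible. FASTQ output (constant qualities) exists only for
tool compatibility; qualities are never used.

## Taxonomy and evaluation

Lineages use a fixed eight-rank schema (strain → superkingdom) with a
reserved `UNKNOWN` token for lineage gaps; merged historical rank names
are opaque single labels. Every comparison is three-valued: match,
mismatch, or *indeterminate* when either side is UNKNOWN or a read is
unclassified. Indeterminate reads are reported as their own category and
excluded from accuracy denominators — an unknown is never silently
counted as an error, mirroring how real fungal databases are full of
uncultured/unclassified entries. Rank accuracy is reported per read;
`organism_mean_accuracy` additionally averages per source organism with
equal weights, since "accuracy on average" is ambiguous between the two
conventions. The predominant-match breakdown reports, per source
organism, the modal predicted taxon and its read fraction, with
`confident` requiring the fraction to strictly exceed 0.40. Agreement
between two classifiers defaults to species/genus/phylum over the shared
read set and is symmetric.

## Synthetic scenarios

`fixtures` generates i.i.d. random genomes with configurable GC, a
tree-consistent nested taxonomy (taxa per genus, genera per order, orders
per phylum; one family per genus, one class per order), and *novel*
held-out taxa as point-substitution derivatives (default divergence 0.10
substitutions/site, a typical within-genus nucleotide distance) of
training genomes, sharing the relative's lineage from genus upward.
Scenario defaults follow the benchmark conditions the package targets:
55% of taxa novel, genome lengths 50–150 kb. All outputs are pure
functions of the seed.

What the generator does *not* emulate: real genomes' repeat families,
skewed composition, indels and rearrangements, conserved genes shared
across distant taxa, or realistic viral/fungal evolution. Passing
benchmarks on these fixtures therefore demonstrate the correctness and
internal consistency of the classifier and harness — that in-database
reads are recovered, that novelty degrades leaf-level but not rolled-up
accuracy, that the length bias exists — not field accuracy on real
metagenomes, where inter-taxon similarity is far higher than between
i.i.d. random genomes.

## Problem sizes

The desk-scale benchmark uses 20 genomes of 50–150 kb, N = 8 and 2,000
simulated reads (seconds on one core); unit and property tests use
N ∈ {2..8}, genomes ≤ 100 kb, 200 oracle cases, 1,000 self-consistency
trials and 10,000 clone draws. These sizes were chosen so the whole
suite runs comfortably on a laptop while keeping every statistical check
well-powered (e.g. 3σ bands for sample means, KS at α = 0.001,
binomial p < 0.01 for the length-bias direction).

## Known limitations

- Scoring at the deployed N = 15 uses the sparse path and is orders of
  magnitude slower than the dense desk-scale path; the package is a
  reference implementation, not a production-scale server.
- The flowgram model's positive-flow width and the raw-scale lognormal
  reading are this package's own choices; observed error rates (~4–5%
  of bases) are plausible for the platform but not calibrated against
  real flowgram data.
- No handling of NCBI taxonomy dumps or name synonymy; the taxonomy TSV
  is the single source of lineage truth, and cross-classifier comparison
  requires both prediction sets to share it.
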