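# nbckit

Naive Bayes N-mer classification of metagenomic reads — a
composition-based taxonomic classifier in the NBC family, aimed at reads
that can come from *anywhere* in a genome (whole viral genomes, fungal
ITS/LSU markers or genomic fragments), not just from a universal marker
gene. It ships with the full benchmarking apparatus: a 454-style read
simulator with per-read truth, multi-rank accuracy evaluation with
explicit handling of unknown lineages, a predominant-match breakdown for
novel organisms, and cross-classifier agreement reports.

Intended users: microbiome/metagenomics researchers who need a trainable,
database-agnostic read classifier and a reproducible synthetic benchmark
harness around it.

## The model

Each training taxon *g* (a viral strain or a fungal species, depending on
grouping policy) is summarised by its N-mer frequency profile. A read
*s* is scored by Bayes' rule,

    Pr(g | s) ∝ Pr(s | g) · Pr(g),

with a uniform prior Pr(g) and the evidence Pr(s) dropped (it is common
to every taxon in the argmax). Assuming N-mer independence,

    log Pr(s | g) = Σ_w log [ (c_g(w) + α) / (T_g + α·4^N) ],

where the sum runs over every length-N window *w* of the read, c_g(w) is
the training count of *w* in taxon *g*, and T_g the taxon's total N-mer
count. The pseudocount α (default 1) lives entirely inside each taxon's
profile — there is deliberately no corpus-wide or genus-level smoothing
prior, and α = 0 reproduces the strict no-smoothing behaviour in which a
read containing an N-mer unseen by every taxon becomes *unclassified*.
The read is assigned to the taxon with maximal log-likelihood (the better
strand under the default `max_of_strands` policy), ties broken by
lexicographic taxon id.

Because no length normalisation is applied, longer training genomes win
queries that resemble nothing in the database — an inherent bias of this
model family that the package reproduces, tests for, and warns about when
a database mixes very different training sizes (`heterogeneity_warning`).

## Worked example

```
$ cat spec.json
{"n_taxa": 6, "length_range": [20000, 40000], "fraction_novel": 0.5, "seed": 42}
$ nbc fixtures --spec spec.json --out-dir .
wrote scenario: 3 training + 3 held-out taxa -> .
$ nbc build --fasta training.fasta --map training_map.tsv --taxonomy taxonomy.tsv \
      --n 8 --policy by_strain --out db.json
built database: 3 taxa, n=8 -> db.json
$ nbc simulate --fasta heldout.fasta --map heldout_map.tsv \
      --reads-per-genome 50 --seed 7 --out-prefix novel
simulated 150 reads -> novel.reads.fasta
$ nbc classify --db db.json --reads novel.reads.fasta --out pred.tsv
classified 150/150 reads -> pred.tsv
$ nbc evaluate --pred pred.tsv --truth novel.truth.tsv --taxonomy taxonomy.tsv
        rank  n_evaluable  n_correct  n_indeterminate  accuracy
      strain          150          0                0       0.0
     species          150          0                0       0.0
       genus          150        150                0       1.0
      family          150        150                0       1.0
       order          150        150                0       1.0
       class          150        150                0       1.0
      phylum          150        150                0       1.0
superkingdom          150        150                0       1.0
```

The held-out organisms are *novel*: absent from the training database, so
no read can be right at the strain or species level. Every read is
nevertheless assigned to a same-genus relative, so the roll-up accuracy
jumps to 1.0 from genus upward — the behaviour that makes a leaf-level
classifier useful on organisms it has never seen. `nbc compare` produces
the analogous match/mismatch/indeterminate breakdown between two
classifiers' prediction files.

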