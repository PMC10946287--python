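# Methods

`ribodb` builds curated, taxonomy-unified, region-specific 16S rRNA
reference databases from arbitrary FASTA + taxonomy-table sources, and
benchmarks taxonomic classifier output against in-silico mock communities.
This note records the models and procedures implemented, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Data model

A reference database is a list of entries, each pairing a DNA sequence
(uppercase IUPAC; RNA `U` is folded to `T` at read time) with a seven-rank
lineage in Greengenes notation (`k__Bacteria; p__Firmicutes; …; s__…`).
Absent ranks are empty labels; parsing and formatting are mutually inverse
on this canonical form. On disk, a database is a FASTA file plus a
two-column TSV (`Feature ID\tTaxon`), the interchange dialect of the QIIME2
ecosystem; the reader accepts headerless tables, the writer always emits
the header.

## Curation

Filters run in a fixed order, and synonym unification runs last so that
removals are judged on the original labels:

1. **Kingdom filter** — keep only Bacteria and Archaea (configurable set).
2. **Unknown-label filter** — drop entries whose species label is empty or
   whose lineage contains one of the unknown-species patterns
   (`uncultured`, `unidentified`, `candidate`), matched as case-insensitive
   substrings. The default list is applied verbatim: `Candidatus` does
   *not* contain the substring `candidate` and therefore survives unless
   the user extends the list. The pattern list is configuration, not a
   grammar.
3. **Rank-sparsity filter** — drop entries annotated only at kingdom and
   species (e.g. `k__Bacteria; …; s__bacterium_Te63R`), a hallmark of
   poorly characterised environmental isolates. Implemented
   unconditionally with an opt-out flag, since "rare bacteria from
   non-characterized environments" is not machine-checkable.
4. **Cross-kingdom filter** — drop entries whose species resolves through
   the synonym map to a canonical lineage outside the allowed kingdoms
   (e.g. a plant filed under Bacteria). Species absent from the map cannot
   be judged and are kept.
5. **Unification** — every rank label is replaced by its canonical name
   where the synonym map knows it; unmapped names pass through unchanged
   but are counted in the report, keeping non-canonical names observable.
   Clustered (multi-name) labels unify each component independently and
   are re-assembled with the clustering grammar.

Synonym tables are plain 4-column TSVs (name, canonical, taxid, kingdom);
there are no live taxonomy-service queries. Lookup is case-sensitive with
a case-insensitive fallback. The curation report satisfies the exact
accounting identity `input = output + Σ removals`, checked on every run,
and curation is idempotent for fixed rules and synonyms.

## Merging

The pairwise integration rule: walk the candidate database in input order;
an entry whose full 7-rank taxonomy string is new to the merged set is
added; if the taxonomy already exists, the candidate sequence is compared
against the sequences carrying that exact taxonomy and skipped only when
it is identical to, or a contiguous substring of, one of them. The
substring test is deliberately one-directional — a shorter merged sequence
does not block a longer candidate. Accepted candidates join the merged set
immediately, so later candidates are checked against them as well; this
makes a multi-source merge exactly the left fold of the pairwise rule and
keeps the output free of internal duplicates. Existing entries are never
modified or removed, so merging is order-sensitive by construction (and a
test asserts an engineered case of this).

Taxonomy identity is exact string equality on the unified form — merging
assumes curation/unification ran first and refuses entries with empty
taxonomies. Sequence comparison is forward-strand only. Id collisions
across sources are resolved by prefixing the source label. Substring
search is exact (no heuristic seeding); at the scales this tool targets,
correctness beats speed. The implementation is cross-checked against an
independent brute-force O(n²) oracle on hundreds of random database pairs.

## Region extraction

An amplicon region is defined by a primer pair (reverse primer given
5'→3' on the reverse strand, as published) plus length bounds. The
extractor finds the leftmost forward-primer hit, then the leftmost hit of
the reverse-complemented reverse primer downstream, and returns the
subsequence strictly between them — primers excluded, matching the fact
that amplicon reads are primer-trimmed before denoising. If the forward
strand fails (no hits, or extracted length outside bounds), the
reverse-complemented sequence is searched; otherwise the entry is dropped
and counted. Coordinates are 0-based half-open internally.

Primer letters follow the IUPAC degeneracy code. A window position matches
when the window letter's IUPAC set is a subset of the primer letter's set
(plain membership for concrete bases; any primer matches itself). The
default mismatch tolerance is 0 per primer, which keeps extraction exact
and deterministic; it is configurable per region. The shipped primer pairs
(V4 515F/806R, V1–V3 27F/534R, V3–V4 341F/805R, V3–V5 357F/926R, with
conventional length bounds) are the community-standard choices, not values
with any special provenance; users can override them from YAML.

Dereplication collapses exact (sequence, full-taxonomy) duplicates,
keeping the first-seen id. Identical sequences with *different* taxonomy
are deliberately retained — resolving them is the clustering stage's job.

## Clustering and merged nomenclature

Region databases are clustered at 100% identity with containment: greedy
longest-first (CD-HIT-like), a sequence joining the first representative
that contains it. Representatives are a longest member; ties break by
sequence then id, making the partition deterministic. Member lineages
merge rank by rank:

- kingdom–genus: distinct names, sorted case-insensitively, joined with
  `-` (`g__Lactobacillus-Limosilactobacillus`);
- species: names grouped by genus token (text before the first
  underscore); within a group the alphabetically first full binomial is
  kept and later members contribute only their epithet, joined with `-`;
  groups sorted and joined with `:`
  (`s__Lactobacillus_crispatus:Limosilactobacillus_fermentum-oris`);
  free-text names form their own verbatim group;
- a rank collecting more than 10 distinct names (per rank, counting full
  distinct post-unification names) collapses to the bare placeholder
  `Unknown` behind its prefix.

Alphabetical ordering of merged names is a package choice — the worked
examples in the field are consistent with it, and no other ordering rule
is documented anywhere. Expansion (`expand_label`) is the exact inverse of
the grammar and is property-tested as such; `Unknown` expands to the empty
set. Note the genus grammar cannot round-trip names that themselves contain
`-` or `:`; such names do not occur in prefixed Greengenes-style lineages.

## Mock communities and simulated classifier output

A mock community draws `n_taxa` species without replacement from a
database (default 5 samples per community). Each species contributes one
representative sequence, which keeps per-sequence expected abundances
unambiguous. Per-sample abundance profiles come from one of two models:

- `uniform` (default): independent U(0,1) variates, normalized — an
  even-ish community;
- `lognormal`: exp(N(0, σ=2)) normalized — a heavy-tailed, gut-like
  profile with a few dominant taxa. σ=2 was chosen once as a realistic
  skew for stool-like communities.

Simulated classifier output perturbs the truth table: each sequence keeps
its true taxonomy with probability `1 − error_rate − unassigned_rate`,
receives the lineage of a uniformly drawn database entry with a different
species with probability `error_rate`, and an all-empty lineage with
probability `unassigned_rate`. All randomness flows through one explicit
integer seed.

What the generator emulates — and what it does not: fixture databases have
internally consistent random lineages, engineered duplicate/substring/
curation-trap entries, and (optionally) primer-flanked amplicon structure;
they do **not** emulate sequencing error profiles, chimeras, length
heterogeneity of real 16S genes, phylogenetic sequence similarity, or the
correlated mistakes of a real naive-Bayes classifier (simulated errors are
uniform over the database, real errors concentrate among close relatives).
Passing tests therefore demonstrate the correctness of the bookkeeping,
grammar, matching and metric arithmetic — not field performance of any
particular reference database.

## Evaluation

Both the expected and the assigned tables are taxonomy-unified before any
comparison. At each rank, a multi-class confusion matrix is tallied over
the union of expected and assigned labels: taxon `T_i` scores TP on a
sequence when it matches both the assigned and the expected label, FP when
only the assigned, FN when only the expected, TN when neither; by
construction TP+FP+FN+TN equals the number of sequences for every taxon.
Restricting the taxon frame to the union of observed labels (rather than
the whole database) is a choice; it matches the worked confusion-matrix
framing of the benchmarking literature.

Matching is containment-aware: two labels match when identical or when
their expansions intersect, so a clustered label matches each of its
member names. Empty labels match nothing (an unassigned sequence matches
no taxon). The production tally uses an inverted expansion index
(name → taxa), costing O(sequences × average matches); the defining
double loop over taxa × sequences is kept as an independent oracle in the
test suite.

Per-taxon scores are the standard `accuracy`, `precision`, `recall`, and
`f1` (harmonic mean of precision and recall — the standard definition of
the F1 score). 0/0 ratios return 0 and are flagged, so a fully missed rare
taxon penalizes the aggregate instead of silently vanishing. The tally is
sequence-level — each representative sequence counts once; abundance
enters only afterwards, through the weighted mean
`s̄ = Σ aᵢ sᵢ / Σ aᵢ` with the expected relative abundances as weights
(taxa absent from the expected composition weigh 0).

Compositional agreement is the Bray-Curtis distance
`1 − 2 Σ min(eᵢ, aᵢ) / (Σ eᵢ + Σ aᵢ)` over the union of taxa, delegated to
`scipy.spatial.distance.braycurtis`; unassigned mass is kept as its own
label so it registers as disagreement. `evaluate_dataset` emits one row
per (sample, rank); `summarize_configurations` aggregates mean ± sd per
configuration and rank and flags the best configuration per rank by mean
F1. Significance testing between configurations is summary statistics over
the emitted tables and is left to the user.

## Numerical and testing choices

- Composition tables must sum to 1 within 1e-9 per sample; weighted means
  use elementwise product plus a shared summation so that all-perfect
  scores aggregate to exactly 1.0.
- Determinism everywhere: fixed seeds give byte-identical artifacts; the
  pipeline manifest records seed, version and per-stage accounting, and a
  re-run with the same config is byte-identical.
- Oracle scales: the merge oracle runs 200 random pairs of ≤100 entries,
  the confusion oracle 100 random ~24-sequence tables — sizes at which
  the O(n²) reference implementations are instant while still exercising
  engineered overlaps.
- Parameter recovery: at `error_rate = 0.2` with 2,000 single-sequence
  taxa, species-level weighted recall is compared to 0.8 within three
  binomial standard errors of the *across-seed mean* over 5 seeds. With
  Dirichlet-like abundance weights a single draw has an effective sample
  size of roughly n/2, so the per-seed three-SE band would be a ~2σ test
  that fails by design a few percent of the time; averaging seeds tests
  the same recovery property without the engineered flakiness.

## Known limitations

- Strand handling in merging is forward-only; reverse-complement
  duplicates are not detected (extraction, by contrast, searches both
  strands).
- The merged-label grammar is lossy above 10 names (`Unknown`) and cannot
  represent names containing its own separators.
- Primer search is a naive scan — fine for reference-database
  construction, not meant for read-scale in-silico PCR.
- The curation percentages and database sizes reported for real
  Greengenes/SILVA/RDP integrations depend on those external datasets and
  are out of scope here; the package reproduces the *procedures* and
  validates them on generated data.
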