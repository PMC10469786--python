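# Methods

This note documents the models and procedures implemented in `magtaxa`, the
assumptions behind them, the defaults that matter, and what the synthetic
fixtures do and do not establish about real data.

## Sequence identity

Identity between two sequences is the fraction of matching columns over the
aligned region, excluding terminal (overhang) gap columns; internal gap
columns count as non-matching columns. Coverage is measured on the shorter
sequence. Two routes exist:

* **Hamming route** — for equal-length, ungapped pairs, identity is exactly
  `1 − Hamming/L`. This is the route the synthetic fixtures take (they are
  generated without indels), which keeps their identity oracle trivial.
* **Alignment route** — global pairwise alignment with free end gaps
  (match +2, mismatch −1, gap open −2.5, extend −0.5, terminal gaps 0),
  via `Bio.Align.PairwiseAligner`. Co-optimal alignments can differ in
  identity; the pair is therefore put in a canonical order (shorter, then
  lexicographic) before aligning, making the reported identity symmetric.
  The tests validate the route against exhaustive enumeration of all
  alignments on tiny strings.

The original workflow computed 16S identities on a base-frequency-filtered
curated alignment; that column mask is not reproducible here, so identities
are computed directly from the (optionally pre-aligned) sequences. The rank
thresholds are interpreted on that scale.

## Greedy clustering and screening

`greedy_cluster` mirrors cd-hit-est semantics: records sorted by length
descending, each joining the first cluster whose representative it matches
at ≥ the identity threshold with coverage ≥ 0.9 of the shorter sequence.
The default identity threshold is **97%** (the workflow's stated value;
its quoted flag `-c 0.95` disagrees with its prose — the prose value is the
default here and the parameter is configurable).

`filter_best_hits` keeps one hit per query — highest bitscore, ties broken
by lowest e-value, then input order (the order-dependence of the original
helper script is made explicit) — then requires identity ≥ 97 and query
coverage ≥ 0.7, both inclusive (the upstream filter used `>=`). The
rare/abundant biosphere boundary is 0.1% relative abundance; exactly 0.1%
is classified rare (the rare biosphere is defined as `< 0.1%`, so
"abundant" requires strictly more).

`oligo_coverage` scans every window of each target (and the reverse
complement of the oligo) and counts targets with a window at ≤ k mismatches
(default 0). The oligo must be unambiguous; IUPAC ambiguity codes expand on
the target side only — a target `Y` is compatible with an oligo `C` or `T`.

## Genus delineation

A genus call requires (i) ≥ 2 sequences, (ii) monophyly in both input trees
(the leaf set equals the descendant set of an internal node in each), and
(iii) minimum pairwise identity **strictly above 94.5%** ("identities above
94.5%" read as a strict bound). Qualifying clades are selected top-down from
the root, and a qualifying clade blocks its descendants — the "largest
monophyletic group" reading — so calls are maximal, disjoint, and invariant
to swapping the trees (a shared clade is found from either side). Rank
assignment at order (82.0%) and family (86.5%) uses ≥, these being stated as
thresholds rather than strict bounds; both are configurable. Bootstrap
support values, if present, are ignored. Sequences are partitioned for tree
building as backbone (> 1200 bp), addable ([800, 1200] bp) and excluded
(< 800 bp); parsimony insertion of addable sequences is not implemented, so
delineation operates on whatever leaf set the supplied trees share.

## MAG curation

Depth per contig is the summed aligned length of best-hit reads (identity
≥ 95%, coverage ≥ 0.7) divided by contig length. The mapping filter's
published awk clause contains `$3=95` (an assignment); the implemented rule
is the stated intent, identity ≥ 95. The depth filter removes contigs
**strictly** more than twofold from the mean — a contig at exactly 2.0× is
retained — in a single pass against the simple (unweighted) mean over
contigs; the mean is not recomputed after removals, and a length-weighted
mean is available as an option (the original does not state which was used).
The taxonomy filter replaces "visual inspection" with a deterministic
plurality rule: the consensus is the taxon with the highest total best-hit
count across contigs, a tie is an error requiring an explicit override, and
a contig is removed only when it has protein evidence but zero votes for the
consensus (contigs with no proteins are retained). Depth then taxonomy, once
each — the original describes a single-pass manual curation.

The quality gate is strict (`completeness > 80`, `contamination < 5`).
Genome size is estimated as assembly size / completeness, so the estimate is
never below the assembly size. Genome-size-by-origin uses one-way ANOVA
plus Tukey HSD (`scipy.stats.tukey_hsd`, unbalanced groups allowed), the
Python equivalent of the R `aov` + `HSD.test` recipe.

## Genome-level taxonomy

AAI is the mean percent identity over reciprocal best-hit protein pairs,
with a hit requiring identity ≥ 30% and coverage ≥ 70% of the shorter
protein — common AAI-calculator defaults, stated here as an assumption since
the original tool is not specified; a pair with no reciprocal hits is
reported missing and treated as below every threshold. Species clustering is
single linkage at ≥ 95% (the conventional ANI/AAI species threshold) and
genus clustering is single linkage strictly above a 65% AAI floor; single
linkage follows dereplication-tool practice, the original naming no linkage.
Dereplication gates on quality first, clusters at ≥ 95%, and keeps the
genome maximizing completeness − 5 × contamination (the cited
dereplication tool's default score), ties broken by larger assembly then
lexicographic id. The exhaustive-alignment AAI is intended for the small
proteomes used in tests, not full genomes.

## Functional profiling

Pathway presence: completeness = detected required genes / pathway size;
present iff ≥ 0.8 (inclusive — "at least 80%"). Multi-copy pathways are
scored on distinct required gene identifiers. The packaged pathway table
(`data/pathway_definitions.tsv`) holds compact KEGG-orthology gene lists for
16 pathways (glycolysis, TCA, nitrate/nitrite/nitrous-oxide respiration,
vitamin biosyntheses, hydrogenase, sulfate assimilation, CO dehydrogenase,
urease, trehalose, metal resistance); it is data, meant to be edited or
replaced.

Module enrichment between genome groups: a genome carries a module when its
completeness reaches 0.8; per module a group × presence contingency table is
tested — Fisher's exact test for two groups, chi-square for more (no exact
R×C test is available) — with Benjamini–Hochberg q-values and enrichment at
q < 0.01. The original workflow used its own internal enrichment statistic;
the interface (completion 0.8, q < 0.01) is matched, equivalence of the
statistic is not claimed.

CAZyme consensus accepts a (gene, family) assignment only when both
strategies pass, all bounds strict: alignment identity > 40% with coverage
> 0.5 (alignment length / query protein length) and profile e-value < 1e-15
with coverage > 0.35 (profile coverage of the model); the denominators are
stated explicitly because the original does not define them. PUL markers are
the per-genome count of accepted CAZymes and of susC/susD genes.

Group comparisons: Kruskal–Wallis omnibus plus all-pairs two-sided
Mann–Whitney tests with Bonferroni correction over the number of pairs
(`corrected = min(1, raw × pairs)`). "More than 16 samples" is read
strictly: groups enter only with n ≥ 17. The exact null is used when both
groups have n < 50 with no ties, mirroring R's `wilcox.test` (the recipe the
original ran); significance is `corrected p < α`. With two groups of 20 and
rejection at corrected p < 0.05, the exact attained size of the procedure is
0.0491 — the acceptance test asserts this analytically and checks the
1,000-simulation Monte Carlo estimate against it within binomial error.

## Synthetic data: what it emulates, and what it does not

`simulate_sequences` evolves sequences by uniform random substitution
without indels (an indel-free model keeps identity = 1 − Hamming/L exact).
Within a genus, members mutate disjoint position sets, so within-genus
identities are *exact*; genus ancestors mutate independent random sets sized
by solving the per-site divergence equation `2m − (4/3)m² = d`, so
between-genus identities are exact in expectation with binomial spread. The
true genealogy is returned twice, as stand-ins for independently inferred NJ
and ML trees; `discordant_pairs` plants NJ/ML conflicts by swapping leaves.
Default study conditions for recovery experiments: 16 genera × 4 members,
1,200 nt, within 97% / between 88%.

`simulate_amplicon` draws multinomial read counts per sample (10,000 reads
per sample in the recovery experiments, planted proportions spanning 0.05%
to 34.3%); target reads produce hits passing the screen (identity drawn
≥ 97.5, coverage ≥ 0.7), and a 20% fraction of background reads produce
decoys failing it — half by identity, half by coverage, exercising both
filter clauses. `simulate_assembly` draws clean depths lognormally with
σ = 0.1 (the probability of a clean contig leaving the twofold band is
< 10⁻⁴, keeping false-positive removals out of fixtures), plants depth
contaminants at 4-fold above/below the mean and taxonomy contaminants with
zero consensus-taxon proteins, and verifies the planted truth is recoverable
under the all-contig mean before emitting. Contig lengths are 2–8 kb so the
50-seed curation experiment stays fast. `simulate_annotations` plants
⌊completeness × size⌋ genes per pathway without replacement.

These fixtures establish that the *rules* are implemented exactly and that
recovery behaves as designed under the stated noise models. They do not
model chimeras, indels, alignment uncertainty, tree-inference error beyond
planted discordance, compositional effects, or database incompleteness — so
passing tests bound implementation error, not biological error, and results
on real surveys inherit the usual caveats of 16S copy-number and primer
bias.

## Numerical and design choices

* Boundary semantics are fixed and tested: screening filter ≥; genus
  identity >; order/family ≥; twofold depth rule >; quality gate strict;
  pathway rule ≥ 0.8; CAZyme bounds strict; biosphere boundary 0.1% → rare.
* Best-hit ties: bitscore, then e-value, then input order.
* Cluster indexing and component ordering are deterministic
  (lexicographically smallest member).
* Degenerate inputs raise rather than guess: empty FASTA, duplicate ids,
  zero totals, all-zero depths, consensus ties, single origins, < 2 eligible
  groups.
* A genus-size-by-origin ANOVA on all-equal values is defined as F = 0,
  p = 1 (no effect by definition) instead of propagating a 0/0.
* Problem sizes in the tests and acceptance script (20-seed clade recovery,
  100-seed abundance recovery, 50-seed curation, 1,000-simulation
  calibrations, 52-genome matrices) were chosen to make every planted
  recovery statistically decisive while keeping the whole suite around a
  minute.

## Known limitations

* No tree inference, parsimony insertion, binning or completeness
  estimation: trees and quality values are inputs.
* AAI by exhaustive alignment is quadratic in proteome size.
* Enrichment for > 2 groups falls back to chi-square (asymptotic).
* The packaged pathway definitions are deliberately compact defaults, not a
  curated reconstruction of any database release.
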