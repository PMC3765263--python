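# Methods

This note documents the models, rules and numerical choices behind
`mircycle`, the assumptions they rest on, and what the synthetic studies
used by the test suite do and do not demonstrate.

## Read cleaning

Reads are classified in a fixed precedence order — low quality, 3' adapter
absent, empty insert, 5' adapter in the insert, poly(A), shorter than
18 nt, longer than the cap, clean — so each read lands in exactly one
category and the categories partition the high-quality reads. Choices
that the underlying protocol leaves open, fixed here for a testable
contract:

* **Low quality**: more than 2 `N` bases, or more than 20% of bases below
  Phred 10. Low-quality reads are excluded before the high-quality
  accounting, matching the convention of reporting contaminant categories
  as percentages of high-quality reads.
* **3' adapter detection**: leftmost exact match of the adapter's first
  6 bases; the adapter may run off the read end, but fewer than 6 adapter
  bases at the end counts as "adapter absent". Exact matching keeps
  classification deterministic; a mismatch budget would need an aligner
  and is out of scope.
* **5' adapter contamination**: the 5' adapter's first 6 bases anywhere in
  the trimmed insert (adapter–adapter ligation products).
* **poly(A)**: trimmed insert with ≥ 90% adenine.
* **Length window**: inserts of 18–30 nt are kept (the gel-selection
  window); the 30-nt cap is configurable (`FilterPolicy.max_insert_len`)
  and over-long inserts get their own accounting field so the partition
  invariant holds on arbitrary input.

Tags are unique insert sequences; all downstream stages operate on tags
with counts, ordered lexicographically for reproducible output.

## Mapping and annotation

Tags are matched exactly and full-length against both strands of the
genome (seed-and-verify on 18-mers; equivalent to a naive substring scan,
which the tests assert). Every locus is reported; tags with more than 20
loci are flagged for the hairpin-prediction copy-number cap. Each tag is
assigned one class over the union of all its loci by priority: the
structural ncRNA tier (rRNA, scRNA, snRNA, snoRNA, srpRNA, tRNA, with
GenBank-sourced entries outranking Rfam-sourced ones), then known miRNA
precursors, repeats, exons, introns; exon/intron calls split into
sense/antisense by strand agreement, preferring sense. One base of
overlap suffices. Unmapped or featureless tags are "unan" — the input to
novel-miRNA prediction. The abundance-weighted rRNA fraction is reported
with a PASS/WARN verdict at the strict 40% animal-sample threshold.

## Conserved miRNA quantification

Because the target species lacks a deposited miRNA catalogue, tags are
quantified against a related species' precursor/mature reference. A tag
is credited to a mature miRNA when it lies inside the precursor with at
most 2 mismatches and its 5' end within ±4 nt of the mature 5' end —
the usual isomiR-tolerant counting window; the reference itself states no
tolerances, so these defaults are configurable. Each tag is credited to
at most one miRNA (fewest mismatches, then smallest offset, then
lexicographic id), so credited counts can never exceed library totals.
Stage membership uses presence (count ≥ 1, configurable); the seven Venn
regions partition the detected set.

## Secondary structure

The default folding engine minimises summed pair energies (GC −3.0,
AU −2.0, GU −1.0 kcal/mol) over pseudoknot-free structures with hairpin
loops of at least 3 nt, by interval dynamic programming with a
deterministic tie-break (more pairs, then 5'-most pairing). Loops,
dangling ends and stacking are deliberately costless: the engine is a
self-contained, oracle-verifiable stability score, not a thermodynamic
ensemble, and the −18 kcal/mol hairpin threshold is interpreted on this
scale. A full nearest-neighbour engine (ViennaRNA) can be selected with
`EnergyModel(backend="vienna")`; thresholds then apply on that engine's
scale, and each backend is validated against its own reference — the two
scales are not compared against each other. Duplex energies for target
scoring sum the same pair energies over the aligned positions;
`perfect_complement_energy` is the corresponding per-base Watson–Crick
sum.

## Novel miRNA prediction

Unannotated tag loci on one chromosome/strand are clustered when within
35 nt; the deepest tag (ties: 5'-most) is the putative mature, and two
windows — star arm upstream or downstream, plus 10-nt flanks — are folded
and screened. Criteria (defaults are the conventional hairpin-screening
set): mature length 18–26 nt; genomic copy length 20–24 nt (equal to the
tag length under exact mapping — the two bounds are recorded as separate
verdicts); precursor MFE ≤ −18 kcal/mol; mature and star on opposite
arms separated by ≤ 35 nt; ≥ 14 mature/star base pairs; largest bulge in
either arm ≤ 4 nt; arm asymmetry ≤ 5 nt; ≥ 3 reads sharing the mature
5' end ("cut-site depth" — the Drosha/Dicer homogeneity notion); ≤ 20
genomic loci.

Two structural conventions matter under the loop-cost-free energy model.
First, the star arm is identified as the dominant cluster of mature-arm
partner positions within the admissible star zone (35 nt plus one star
length): with free loops, the global minimum happily adds isolated
opportunistic pairs between a mature edge base and a flank base, or
bulges a single wobble pair out of the stem in favour of a distant
Watson–Crick pair, and a literal "all partners on one side, contiguous"
reading would reject structurally valid hairpins. Duplex metrics (pairs,
bulge, asymmetry) are computed only over mature↔star-cluster pairs.
Second, star-supporting reads are optional; when present, their 5' ends
must agree with the 2-nt 3' overhang geometry within ±2 nt, otherwise
the check is skipped (a soft check, since overhang evidence depends on
star-arm expression that most genuine loci lack).

Acceptance is monotone in every threshold (tested), and rejected
candidates are returned with their per-criterion verdicts rather than
raised as errors.

## Target prediction

Target sites are ungapped antiparallel duplexes: miRNA position *i*
(1-based from the 5' end) faces UTR-window position *L−i*. Gapped
alignment is excluded because every rule is positional over the miRNA and
ill-defined under gaps. Rules: weighted mismatches ≤ 4 with G:U = 0.5;
no run of more than 2 consecutive mismatch positions; no adjacent
mismatch positions within 2–12; no mismatch position at 10–11; weighted
mismatches in 1–12 ≤ 2.5; duplex energy at least 75% of the
perfect-complement energy (ratios of absolute values, since both are
negative). A wobble contributes 0.5 to the weighted counts but is a full
mismatch *position* for adjacency and positional exclusions. Acceptance
is monotone in each threshold, and the scan is verified window-by-window
against an independent brute-force evaluation.

## Differential expression

Expression is TPM: `1e6 · count / library clean total`. Zero TPMs are
revised to 0.01 so the log2 fold change is defined; the rule's conventional
wording is ambiguous between "revise any zero" and "revise only when both
are zero", so the first (more permissive) reading is the default and the
second is available behind `only_when_both_zero=True`. Pairs with both
revised TPMs below 1 are flagged excluded.

The two-library test conditions on the control count x: with
r = N2/N1, `p(y|x) = r^y (x+y)!/(x! y! (1+r)^(x+y+1))` — a negative
binomial tail in y. The implementation evaluates log-pmfs with
log-gamma, sums the finite lower tail with log-sum-exp, and takes the
infinite upper tail as its complement; the two-sided p is `2·min(tails)`
capped at 1 (the tail formulas come without a stated
combination rule; twice-the-smaller-tail is the standard exact-test
choice). The implementation agrees with arbitrary-precision rational
summation to < 1e-9 over the full 0 ≤ x, y ≤ 50 grid at library ratios
½, 1 and 2, and its type-I error on same-mean Poisson pairs is ~0.04 at
the 0.05 level (discreteness makes it conservative). One known property
of this formulation: it is *not* exchangeable — swapping (x, N1) with
(y, N2) can change the p-value, because the test conditions on the
control count. Callers should fix the control/treatment orientation of
each pair, as the pipeline does.

Significance bands (p < 0.01, 0.01 ≤ p < 0.05, NS) and ratio bands
(ratio > 2, ½ < ratio ≤ 2, ratio ≤ ½, on revised TPMs) follow the stated
cut-offs with boundaries exactly as written. Fold-change profiles across
the three stage pairs are clustered agglomeratively (Euclidean distance,
average linkage) and cut to k clusters; k defaults to 5, reading the
"five rounds/patterns" description as five expression patterns. With
fewer profiles than k, each profile is its own cluster.

## Enrichment

For a universe of N annotated genes, n candidates, a term with M genes
and m candidate overlaps, the p-value is the hypergeometric upper tail
`P(X ≥ m) = 1 − Σ_{i<m} C(M,i)C(N−M,n−i)/C(N,n)` (scipy's log-space
survival function; verified against draw enumeration for all N ≤ 12).
Only terms with at least one candidate overlap are tested — a zero-overlap
term can never be enriched, and the Bonferroni factor counts tested terms.
GO-style analyses adjust by Bonferroni, pathway-style by Benjamini–
Hochberg (the FDR method is unnamed in the source convention; BH is the
standard default), both at 0.05. The universe N is mode-specific
(GO-annotated vs pathway-annotated genes). Candidates missing from the
universe are dropped from n with a logged tally.

## Synthetic studies

The generator emulates the structure of a three-stage small-RNA study:
a single-contig genome (120 kb by default) hosting 14 conserved and 6
novel planted hairpins, 4 loci per structural-ncRNA class, 8 repeats and
10 exon/intron pairs, placed without overlap (a capacity error is raised
otherwise); three libraries of 50,000 reads. Per-miRNA counts are
Poisson around configured stage means — the simplest count process
consistent with the exact test's assumptions (`count_noise="exact"`
plants means verbatim). The default roster plants ten all-stage miRNAs,
one anagen-, one catagen- and two telogen-specific miRNAs, and three
4-fold changes at means ≥ 500. Contaminants of every accounting category
are injected at rates matching a realistic library (counts are
`floor(rate · library size)`, so recovery can be asserted exactly);
clean inserts are screened so no spurious adapter seed forms at the
insert/adapter junction. Background reads sample the planted features
with class weights that put the rRNA fraction near 34% (passing the 40%
rule) and insert lengths moded at 22 nt; mature lengths are pinned per
roster slot (heavy expressers at 22 nt) so the modal insert length is
22 nt at any seed. Planted hairpins are perfect stems — mature, an
8–20 nt loop, and the reverse-complement star carrying one centrally
placed G:U wobble. The single wobble makes the star differ from the
exact reverse complement (so the mature tag maps uniquely to its own
arm) while leaving the stem robust: scattered or clustered multiple
wobbles let the free-loop energy model peel stem pairs into flank pairs
and fail valid hairpins. Mature 5' ends are uridine with probability
0.7, emulating the canonical U bias.

What the synthetic studies do **not** emulate: sequencing errors and
quality-score structure (low quality is operationalised as N-containing
reads), isomiR heterogeneity, multi-contig genomes at scale, spliced
transcripts, or realistic miRNA sequence composition. Passing the
planted-truth suite therefore demonstrates the correctness of the
pipeline's logic and arithmetic under its stated assumptions, not its
robustness to real-data noise.

## Problem sizes and determinism

The test suite and the acceptance script run the default study
(3 × 50,000 reads, 120 kb genome, 20 hairpins) — large enough for every
planted signal to be unambiguous, small enough to re-run everywhere in
seconds. All randomness flows from explicit integer seeds through
numpy's `default_rng`; identical configuration and seed reproduce
byte-identical genomes, FASTQ files and pipeline summaries (asserted by
tests). Folding is exact dynamic programming, so all structure-dependent
results are deterministic.
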