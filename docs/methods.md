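# Methods

This note documents the models and procedures implemented in
`clockortho`, the defaults they use and why, what the synthetic-data
generator does and does not emulate, and the numerical choices that make
runs bit-reproducible.

## Sequence search and E-values

The search engine is full Smith–Waterman dynamic programming in protein
space (no heuristic seeding — desk-scale databases make exact DP
affordable): BLOSUM62, affine gaps costing `open + k·extend` for a gap of
length k, with defaults open 11, extend 1.  CDS records are translated
before searching because at deep divergence (monocot/dicot separation and
beyond) homology signal survives in protein space long after nucleotide
identity decays; genomic records are not searchable.  Raw scores are
converted to bit scores and E-values with the Karlin–Altschul form
`E = K·m·n·e^(−λS)` using the published *ungapped* BLOSUM62 constants
(λ = 0.3176, K = 0.134) applied to gapped scores.  This is a stated
approximation: absolute E-values are biased, but only hit *ranking* and
*ratios between hits of the same query* feed the downstream logic, and
both are monotone transforms of the raw score.  The reporting threshold
defaults to E ≤ 1e−5.  All ranking ties break on
(E-value, −bitscore, subject id), which makes every downstream decision
independent of database record order.

## Reciprocal orthology classification

The classifier iterates the cross-species reciprocal-best-hit procedure
to a fixed point.  From a set of seed genes, every query is searched
against every other species' database; its top hit and all hits with a
"similar" E-value are recorded; every reported hit joins the search
frontier (so it is itself searched against all databases exactly once);
and whenever the reciprocal search of a similar hit identifies a
*different* gene of the query's species, that gene and its home-species
family (all home-database hits above the reporting threshold) join the
frontier too.  Termination is guaranteed because (query, target-species)
pairs are never retried.

Calls are then read off the cached graph, one per co-occurring pair:

* **orthologue** — mutual top hits.  When either side had E-value ties
  the call is flagged ambiguous.
* **orthologue, one-to-many (ambiguous)** — two rescue rules for
  lineage-specific duplications: (a) an E-value tie member whose
  reciprocal is the shared partner; (b) the *shared-partner* rule — gene
  b's top hit is a, the gene x that a prefers in b's species itself
  reciprocates to a, and b lies within a second-tier E-value window of x
  (`family_ratio`, default 1e8) on a's hit list.
* **paralogue** — same-species genes that are family co-members (each
  other's home hits, or joint members of an external query's second-tier
  window) and agree on their top hit in at least one other species.
* **unresolved** — everything else.

Two constants deserve comment.  "Similar E-value" is undefined in the
underlying protocol; the default ratio of 10 (one order of magnitude,
with a 2-bit score window when the top E-value underflows to zero) is
this package's choice and is configurable.  The `family_ratio` of 1e8
separates two regimes that are structurally identical in the reciprocity
graph: a post-speciation duplicate (which should be called a
co-orthologue) and a pre-speciation subfamily member surviving where its
true counterpart was lost (which should not).  The value was calibrated
on the simulator: E-value gaps produced by within-species duplicate
divergence at the benchmark's timescale stay within a few orders of
magnitude, while between-subfamily gaps (≥ 0.5 substitutions/site of
extra divergence) exceed fifteen orders.  Cases inside the window are
always flagged ambiguous, so downstream consumers can treat them
conservatively.  Tree-reconciliation-based orthology is deliberately out
of scope; trees are confirmation, not the caller.

Recovery under benchmark conditions (six species, all pairwise
divergences < 0.5 substitutions/site, ≤ 1 expected duplication per
family, 200-codon CDS, 50 replicate families) is precision ≈ 0.995 and
recall ≈ 0.98, as computed by `evaluate_orthology_recovery` and the
acceptance suite.  On a deeper panel (moss-depth outgroup) precision
stays ≈ 0.98 while recall drops toward 0.91 — the residual errors are
hidden paralogy through complementary losses and duplicate copies whose
E-values drift outside every window, both inherent limits of
reciprocal-best-hit calling rather than implementation artifacts.

## Gene-model re-annotation

Gene structures use 1-based closed intervals on the forward genomic
strand with a strand flag (GFF3 convention); all splicing logic is
transcript-oriented after strand normalisation.  Validation enforces the
two sequence-intrinsic criteria: every intron begins GT and ends AG
(reverse-complemented for minus-strand models), and the spliced CDS keeps
an open reading frame — no internal stops, and ATG start / terminal stop
/ length divisible by three when the model claims completeness.
Non-canonical splice classes (GC–AG, AT–AC) are rejected, not warned.

Re-annotation is an exact local spliced-alignment DP of an evidence CDS
against the genomic sequence: match +2, mismatch −3, genomic-only and
CDS-only gaps −6 per nucleotide, and intron jumps — permitted only over
genomic segments that start GT, end AG and span ≥ 20 nt — at a flat −12.
The flat intron cost makes a true intron vastly cheaper than mismatching
or gapping through it, while still discouraging spurious jumps.  Both
strands are tried; the best-scoring evidence wins and runner-up scores
are reported.  If the resulting model fails validation or does not cover
the whole evidence, it is returned flagged `partial` — never silently
invalid.  With the true CDS as evidence and canonical introns, recovery
of the generator's exon coordinates is exact (boundary slippage that
would preserve both GT..AG and the spliced sequence is impossible,
because a shifted intron would have to begin with the donor G and T in
positions that contradict the original boundary).

Structure comparison maps introns between two models through a codon
coordinate pairing (from a protein alignment; identity by default): two
introns correspond when they interrupt homologous codons at the same
phase.  The output separates conserved introns (with length ratios, since
intron length inflation without position change is the common pattern
between these genomes) from genuine gains/losses, plus UTR length
differences.

## Codon alignment

Proteins are aligned progressively: an NJ guide tree on shared 3-mer
distances, then profile–profile global alignment at each internal node
(BLOSUM62; gaps cost `10 + k`; column scores are count-weighted
sum-of-pairs with gap symbols contributing zero).  The two-sequence case
reduces exactly to canonical Gotoh global alignment, which is the oracle
contract in the tests.  Equivalence with any particular legacy aligner's
output is *not* a goal; the contracts are the downstream invariants.
Stop codons are trimmed before alignment and never aligned.
Back-translation replaces each residue by its source codon and each gap
by `---`, so gap runs are always codon multiples and ungapping any row
reproduces its CDS (minus the trimmed stop).  Complete deletion removes
every codon column containing a gap or N/X in any row; the result can be
legitimately empty and is then flagged degenerate.

## Distances, trees, bootstrap

Distances implement the composite-likelihood idea as pooled-parameter
TN93: base frequencies and the two transition/transversion rate ratios
are estimated once, by maximum likelihood (Nelder–Mead over log
parameters) on the *sum* of all pairwise site-pattern count matrices;
each pairwise distance is then a bounded 1-D ML fit of the divergence
time under those shared parameters, in substitutions per site.  Exact
numerical equality with any specific desktop package is not a contract;
the verified limits are: identical rows give 0; Jukes–Cantor simulations
match `−(3/4)ln(1 − 4p/3)` within 2% at ≥ 5 kb; the two-row case matches
the closed-form TN93 estimator; pooled rate ratios are recovered within
10% at 50 kb.  A pair is flagged *saturated* when its fitted distance
hits the bound (10) or its observed mismatch fraction reaches 95% of the
model's stationary expectation; tree building refuses saturated matrices
rather than guessing.

NJ is the classic Saitou–Nei Q-criterion algorithm with two fixed
tie-breaks (lexicographically smallest pair of subtree labels; negative
branch estimates clamped to zero with a warning).  It recovers the
generating topology from every additive matrix (verified 4–8 taxa) and
agrees with an exhaustive minimum-evolution search over all topologies at
6 taxa.

The bootstrap resamples *codon columns* with replacement — the alignment
preserves codon structure, so resampling whole codons respects the unit
of signal; a config switch selects plain nucleotide columns.  Each
replicate re-estimates pooled parameters, distances and an NJ tree;
bipartition frequencies are mapped onto the full-data tree.  Degenerate
(saturated) replicates count as non-supporting and are logged.  Supports
below the display threshold (default 50%) are retained in the object and
suppressed only at rendering time.  Defaults are 2000 replicates and the
50% display threshold; tests and the acceptance script use 100–200
replicates, which is sufficient at the simulated signal strengths.
Rates are uniform across sites (no gamma heterogeneity).

Rooting places the root at the midpoint of the edge separating a
monophyletic outgroup; a non-monophyletic or missing outgroup is an
explicit error, and `root_on_edge` provides the manual override used when
a family has no true outgroup gene (root placed on a designated family
branch).  Pseudogene-flagged records are excluded from tree input, with
counts logged, to avoid poorly supported topologies.

## Synthetic data: what it emulates, what it does not

`simulate_family` grows a gene family along a rooted species tree whose
branch lengths are *observed* CDS substitutions per site for conserved
genes.  The default six-species panel (moss outgroup; barley/wheat grass
clade; Arabidopsis/tomato/potato dicot clade) places the moss-to-crop
pairwise distance near 0.6 substitutions/site — deliberately below
neutral expectation, because clock genes evolve under purifying selection
and published clock-gene trees show moss-depth distances of this order;
at neutral depths a uniform-rate simulator erases protein similarity that
real conserved domains would retain.  Duplications and losses arrive as
Poisson events per unit branch length (defaults 0.3 and 0.05 per
lineage); sequences evolve under TN93 (JC by default) site-by-site, with
start/stop codons held fixed and internal stop codons rejected by
per-codon redraws (a ≤ 1% deficit in realized substitution counts,
within three standard errors of the JC expectation at 10 kb).  The root
CDS defaults to 600 nt (200 codons), at the short end of real clock
proteins, chosen so that search scores, not sequence length, limit
detectability.  Genomic context adds 60–200 nt GT..AG introns at uniform
positions/phases (minimum 9 nt exons) and random flanks.

Known departures from real data, hence limits on what passing tests
show: no among-site rate variation or domain structure (real proteins
keep islands of conservation the simulator does not); no indels within
coding sequence (alignment difficulty is tuned by substitution divergence
only); no codon-usage bias; no whole-genome duplications (duplications
are independent events); no UTRs on simulated genes; intron gain/loss is
not simulated along the tree (structure-comparison fixtures are
constructed directly).  Benchmarks on this generator therefore validate
the *logic* of the chain, not its robustness to alignment-hostile real
sequence.

## Catalogue

The packaged TSV transcribes the published table of clock and
clock-associated genes (family, species, gene name, locus identifier,
orthologue/paralogue relation, partial-sequence flag) plus the genes
named only in the running text (marked `source=text`, including the
barley CAB-family homologue).  The headline "60%" is operationalized
explicitly: a family counts as one-to-one when barley has exactly one
gene in it and that gene is a one-to-one orthologue; six families
qualify (LHY, TOC1, GI, ELF3, LUX, FKF1) out of the ten components
attributed to the monocot/dicot common ancestor (LHY, TOC1, PRR3/7,
PRR9/5, GI, LUX, ELF3, FKF1, ZTL, ELF4-like), and the report always
prints numerator, denominator and the component list rather than a bare
percentage.  Supplementary per-species tables are not transcribed; the
loader accepts user-supplied transcriptions in the same schema.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed (numpy `default_rng`);
fixed seed and inputs give byte-identical outputs, including pipeline
manifests.  The acceptance script and tests use scaled problem sizes
chosen to exercise each property well inside statistical resolution:
50 replicate families for orthology recovery, 100+ genes for
re-annotation round trips, 6 kb pairs for distance closed forms, 50 kb
for pooled parameter recovery, and 2 kb / 200 bootstrap replicates / 20
repeats for the support benchmark.
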