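# Methods

This note documents the models, statistics, and numerical choices behind
intronerkit, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Boundary-anchored intron pair detection

The defining observable of an Introner family is a set of introns that are
near-identical **end to end**: created by insertions of one element, their
similarity must reach the splice boundaries, unlike introns that share
interior repeats (microsatellite expansion, secondary transposon insertion
into preexisting introns) or introns from duplicated gene regions (where
similarity extends through the flanking exons).

*End windows.* Each intron contributes a 5′ window (exonic flank + first
min(100, len) intronic nt) and a 3′ window (last min(100, len) intronic nt
+ exonic flank).  Judging each end separately, rather than requiring one
end-to-end alignment, tolerates secondary indels in the element interior.
Corresponding ends (5′–5′, 3′–3′) are compared for same-orientation pairs
and opposing ends for opposite-orientation pairs, and the alignments must
place the two intron interiors in consistent orientation.

*Seeding and alignment.* Candidate pairs share at least one exact 11-mer
(either strand) between their flanked sequences; seeded pairs are aligned
per end by optimal local alignment under match +1, mismatch −2, gap open
−5, extend −2 (N matches nothing).  An exhaustive mode aligns every pair
and is the oracle for seeding completeness in the test suite: at the ≤ 5 %
per-copy divergence regime the pipeline targets, conserved 11-mers are
effectively guaranteed.  Sensitivity decays for families diverged far
beyond that regime; this is a known limitation shared by any
exact-seed homology search.

*Significance.* E = K·S·exp(−λ·score), with λ solved exactly from
Σ pᵢpⱼ exp(λ·sᵢⱼ) = 1 under uniform base composition (λ ≈ 1.33 for the
default scores) and K = 0.1 fixed once against a shuffled-intron empirical
null; the shipped null-calibration test verifies ≤ 1 chance pair per 10⁵
comparisons at the default threshold E ≤ 10⁻⁵.  The search space S is the
query window length times the summed window lengths of all introns, so the
e-value scales linearly with database size.

*Boundary window.* An aligned region is anchored at a boundary when its
boundary-proximal edge lies within 5 exonic or 10 intronic bases of the
splice site (half-open offset interval [−5, +10) at 5′-type boundaries,
mirrored at 3′-type).  All four boundaries of both introns must be
anchored.  The window is applied to the alignment's boundary-proximal edge
only; the distal edge is unconstrained, which is what lets diverged
interiors and secondary indels through.  One adjustment proved necessary:
chance matches in the random exonic flank occasionally drag the *optimal*
alignment a few positions past the 5-base exonic limit, rejecting a true
pair (~2 % of identical-copy pairs).  Overhangs of ≤ 10 aligned positions
beyond the window are therefore trimmed back to the window edge before the
test; genuine duplication-driven similarity spans the full 15–20-position
flank and still fails.

## Filters, clustering, consensus

*Paralog filter.* Pairs whose host genes encode locally alignable proteins
(BLOSUM62, gap open 11 / extend 1, Karlin–Altschul constants λ = 0.267,
K = 0.041, threshold e ≤ 10⁻²⁰) are removed; same-gene pairs are exempt
(two insertions of one family in one gene are real).  Untranslatable CDS
are handled conservatively: a warning, and the pairs are retained.  In
practice most duplication-driven pairs never reach this filter because the
boundary rule already rejects them; the protein filter catches the residue
where exonic DNA has diverged (fast-evolving gene families) while protein
similarity persists.

*Low-complexity screen.* A family is flagged (reported, not silently
dropped) when a single ≤ 6-mer tandem run covers > 50 % of the consensus or
its 3-mer Shannon entropy is below 2.0 bits.  These thresholds automate
what is otherwise a manual inspection for repeat-driven similarity.

*Clustering.* Families are connected components of the filtered pair graph
(single linkage, breadth-first).  Orientations propagate from an arbitrary
reference with sign flips across opposite-orientation edges; an odd
inversion cycle is logged and the first-assigned orientation kept.
Components need ≥ 4 members — small clusters cannot be distinguished from
chance or from simple duplication history.

*Consensus.* Center-star multiple alignment: the star is the member with
minimal summed pairwise distance (ties by id); members are projected onto
star coordinates ("once a gap, always a gap").  Columns emit a base only
when one symbol (gap counted as a fifth symbol) exceeds 50 %;
gap-majority and tied columns are dropped, so the consensus covers only
well-supported positions.  Center-star is not a general-purpose MSA, but at
the ≥ 90 % identities of detected families it is exact enough, and it is
deterministic.  Exonic flank consensi are built columnwise, aligned at the
splice boundary, with N where no majority exists; they frame the consensus
for TIR calling.

## Transposon signatures

*TSD profile.* For each signed offset k (|k| ≤ 10; positive = into the
intron at the 5′ site and into the downstream exon at the 3′ site), A(k) is
the fraction of members whose 5′-side and 3′-side bases at offset k match
within the same intron, E(k) the same fraction over 1,000 random
cross-member 5′/3′ re-pairings, and R(k) = A/E.  A genuine TSD produces
locus-specific matching: A ≈ 1, E ≈ background, R ≫ 1.  Splice-site
dinucleotides and other family-wide motifs inflate A *and* E, leaving
R ≈ 1 — the degenerate case (e.g. every intron preceded by AG and followed
by ag) in which TSD presence cannot be decided and the call is
*ambiguous*.  Profiling requires ≥ 15 members with adequate flanks; fewer
members leave E too noisy.

*TSD call.* *Present* requires at least one offset with R ≥ 1.5 and an
exact-binomial excess of A over E at α = 0.01; the reported TSD is the
contiguous high-A run (A ≥ 0.75) touching the boundary that contains such
an offset, summed over the two sides (a split TSD contributes a run on
each side).  High-A runs with no locus-specific support at
boundary-adjacent offsets give *ambiguous*; otherwise *absent*.  The R and
α thresholds were chosen on simulations to separate the locus-specific
from the shared-motif regime; they are not sensitive within a factor of
two.

*TIR call.* The longest reverse-complementary arm pair within ±20 nt of
the two element boundaries, allowing 1 mismatch per 10 nt (N never
matches).  A *present* call additionally requires near-terminal, symmetric
geometry: both arm offsets from their boundaries ≤ 6 and offset difference
≤ 2.  Without that gate, a ≥ 6-nt inverted repeat arises by chance in
~30 % of random 40-nt window pairs, which would make the call meaningless;
with it, chance calls drop to ~2 % while planted 8-nt TIRs are always
found.  Exact symmetric arms of 4–5 nt give *ambiguous*.

*Mechanism label.* Splice-site provenance is read from the TSD geometry: a
donor (acceptor) covered by the locus-specific TSD run on its side is
co-opted from the target site, otherwise carried in the element.  TSD/TIR
presence plus provenance map onto the six-mechanism taxonomy (A: carries
both sites, no TSD/TIR; B: TSD+TIR, donor co-opted; C: TSD only, acceptor
co-opted; D: TIR only; E: both sites co-opted from a split TSD; F: mRNA
lengthened); combinations outside the taxonomy return *undetermined*.

*End PWMs.* 22-position column-stochastic matrices from member end
sequences (pseudo-count 0.01), scanned as log-odds against genome-wide
mononucleotide frequencies on both strands; 5′ matches above threshold are
paired with 3′ matches within 10 kb downstream and contained ORFs ≥ 100
codons are reported.  Classification of those ORFs (e.g. as transposases)
requires external protein databases and is out of scope; the scan stops at
coordinates and sequences.

## Recovery and insertion-bias statistics

*Consensus scan.* The consensus is searched against both strands of the
whole genome (11-mer seeds, local-alignment extension, the same e-value
machinery with S = 2 × genome length × consensus length).  Hits are
deduplicated at 50 % reciprocal overlap — an invented but stated threshold
— and hits reciprocally overlapping an annotated member are self hits and
dropped; the remainder are classified genic/intergenic by hit midpoint.

*Genic enrichment.* Observed genic site count versus 1,000 permutations
placing the same number of positions uniformly on the genome
(chromosome-weighted; the null rate is the gene density).  Positional
randomization was chosen over binomial draws to honor chromosome
structure; the permutation p uses the +1 pseudo-count convention
p = (1 + #{null ≥ obs}) / (n + 1), which is valid and super-uniform.  The
permutation is not conditioned on chromosome of origin.

*GC bias.* Observed mean GC of the concatenated 10 bp up- and downstream
of each genic insertion (20 bp, element excluded) versus 10,000
per-site redraws of 20-bp windows from the same host gene with all element
spans masked, so the elements' own composition cannot contaminate the
null.  Conditioning on the host gene is deliberately conservative: any
within-gene GC skew is inherited by the null.  A 100-bp window variant is
exposed via the `flank` argument.  Cross-species aggregation uses the
one-sided exact binomial tail at p₀ = 0.5.

## Splicing and expression

The ingestion boundary is a tab-delimited per-intron table (columns
`intron_id, gene_id, is_introner, proper_splices, missplices, retained,
depth, length`); read alignment and junction extraction live upstream in
any junction caller.  `missplices` counts junctions within 50 nt of either
annotated boundary that are not the annotated pair; `depth` is per-gene
mean exonic coverage (per-intron depth would also be defensible; per-gene
was chosen to decouple depth from the retention signal being tested).

Two binomial GLMs (logit link, IRLS to 10⁻⁸) are fitted per genome and
compared by AIC with and without the Introner indicator:
mis-splicing `(proper, mis) ~ introner + depth + length` and retention
`(retained, spliced) ~ introner + depth + length`.  The indicator is
interpreted only when the full model wins the AIC comparison; a negative
retention coefficient means Introners are retained less, i.e. spliced more
efficiently.  Degenerate tables (all-zero successes or failures) and
suspected separation (SE > 50) return flagged results with no direction.
Host-gene expression context uses (i) a permutation test in which 10,000
random gene sets of matching size are drawn with probability proportional
to gene length, reporting p_low = (1 + #{null mean ≤ observed}) / (n+1) —
small when Introner genes are lowly expressed — and (ii) a rank-sum test
on RPKM after removing transcripts with < 10 reads (exact null for ≤ 8
observations per group, tie-corrected normal approximation otherwise).

## Habitat association

The species table (habitat flag, Introner presence flag) collapses to a
2×2 contingency table.  The two-sided Fisher's exact p sums all tables
with probability ≤ the observed one (the dominant convention; conventions
differ, so it is stated), with the conditional-MLE odds ratio.  Habitat
percentages are rounded half-up to one decimal and the headline ratio is
the quotient of the *rounded* percentages — on the published survey counts
(39/230 aquatic, 35/1367 non-aquatic) this gives 17.0 %, 2.6 % and 6.5,
while the unrounded ratio (≈ 6.62) is reported alongside.

## The synthetic-data generator

The generator is the package's test bed: genomes of non-overlapping
protein-coding genes (both strands, ATG…stop CDS free of internal stops,
canonical GT..AG introns, configurable genic fraction and genic/intergenic
GC), planted families under mechanisms A–F, confounders, and junction
count tables.  Defaults: 2 chromosomes × 1 Mb, 400 genes, 2–6 exons/gene,
60–120-nt background introns, genic fraction 0.4, GC 0.5 genic / 0.4
intergenic — a compact caricature of the small, gene-dense genomes in
which Introner families are typically found.  Element length defaults to
200 nt (inside the 30–654-nt range of reported family median lengths);
per-copy divergence 0–5 % is a testability choice, since within-family
divergence of real elements is not well characterized.

Mechanism geometry is exact, not approximate: B duplicates a host motif
beginning GT so the new intron is TSD+element with a co-opted donor; C
mirrors it at the acceptor; D's element has perfect terminal TIRs with the
splice dinucleotides immediately outside them; E duplicates a split target
motif T = P·S (P ends AG, S starts GT) so the intron S·element·P co-opts
both sites while the mature mRNA is unchanged; F leaves both TSD copies
plus 4 element bp exonic, lengthening the mRNA by tsd + 4 nt (12 with the
8-bp default).  All of A–E preserve the mRNA and hence the reading frame.
Post-insertion divergence mutates element-derived positions only — TSD
copies and splice dinucleotides are host-derived or functionally
constrained and stay intact, as expected for recently expanded copies.
Insertions update all downstream coordinates, gene models, and previously
recorded truth tables, so truth intervals always re-extract the planted
sequence exactly.

Confounders: whole-gene duplications (~1 % nucleotide divergence,
codon-aware so the protein stays ≥ 90 % identical and stop-free), five
introns sharing a 45-nt tandem-repeat interior, and five introns sharing a
50-nt motif placed ≥ 20 nt from each boundary — one planted generator for
each false-positive class the filters claim to remove.

Count simulation: per-gene expression is reads_per_kb × lognormal noise
(σ = 0.3), optionally scaled by `introner_expression_factor` for
Introner-hosting genes; junction totals are Poisson at gene depth;
retention and mis-splicing are binomial thinnings at the configured rates
(defaults 0.01 Introner vs 0.10 background retention, 0.02 mis-splicing).

**What the generator does not emulate** — and therefore what passing tests
do *not* establish about real data: sequencing error and read-level
artifacts (counts are drawn, not aligned), assembly gaps and adapter
contamination, isoform complexity and UTR introns (only CDS introns
exist), nucleosome positioning (occupancy-based insertion bias is out of
scope), rare GC/GA 5′ splice sites (supported in real annotations, off by
default in simulation for determinism), deep within-family divergence, and
real genome-scale repeat landscapes.  Tests demonstrate that the
statistics are calibrated and the detectors recover what was planted under
the stated conditions, not that those conditions span all real genomes.

## Numerical and engineering choices

Internal coordinates are 0-based half-open; GFF3 is written and read
1-based inclusive.  Sequences are uppercase ACGTN; minus-strand features
are handled in transcription orientation at extraction.  One isoform per
gene (longest CDS) prevents double-counting introns.  Every stochastic
routine takes an explicit integer seed and uses a single NumPy generator
stream, making all outputs bit-reproducible.  Equal-scoring alignment ties
resolve to the aligner's first enumerated optimum, which is deterministic.
Permutation p-values never return 0 by construction.  GLMs converge by
IRLS at tolerance 10⁻⁸ and match a direct Newton optimization of the
binomial log-likelihood to 10⁻⁶ in the test suite.
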