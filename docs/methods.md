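# Methods

This note documents the models and procedures implemented in chemomine,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic benchmarks do and do not show.

## Translated homology search

The built-in search is a seed-and-extend local aligner over the six frame
translations of the genome: exact amino-acid 5-mers shared between query
and translated frame seed ungapped extensions in both directions under
BLOSUM62 with an X-drop of 18. Significance uses a Karlin–Altschul
expectation E = K·m·n·e^(−λS) with the ungapped BLOSUM62 defaults
λ = 0.267, K = 0.041, and search space m·n = (Σ query lengths) × (Σ
scaffold lengths). The two E-value cutoffs (10⁻⁵ for discovery, 10⁻²⁰ for
the rescan) function as stringency tiers; the contract of the search is
recall on planted genes and monotonicity of E in score, not score-level
agreement with any external tool. Codons containing IUPAC ambiguity codes
translate to X; stops render `*`. Externally produced 12-column tabular
hits can be imported instead (1-based inclusive subject coordinates,
`sstart > send` encoding the minus strand, converted internally to the
package-wide convention: 0-based half-open forward coordinates plus a
strand flag).

Protein–protein scoring (family assignment, reference identities) uses an
exact local Smith–Waterman (BLOSUM62, gap open −11 / extend −1) rather
than the seeded heuristic: at protein-vs-protein scale the exact answer is
affordable, and it is strictly stronger than a seeded approximation of the
same scoring scheme.

## Single-exon mining

Round 1: search → non-overlapping best-hit regions (per overlap cluster,
the span of the single highest-scoring hit; ties broken by score, then
start, then query id) → 1 kb flank extension, clipped at scaffold bounds
with clip flags, overlapping extensions unioned → ORF scan at the family
minimum (750/810/850 bp, counting the terminal stop codon) → best-match
family assignment. ORFs are ATG-anchored by default (first ATG per
stop-bounded segment, i.e. the longest ORF per segment); stop-to-stop mode
is available, since the anchoring convention of the original tooling in
this space is ambiguous. Round 2 repeats the search at E ≤ 10⁻²⁰ with the
round-1 completes added as queries, drops any hit overlapping a complete
gene by ≥ 1 bp (masking; prevents double-counting), and classifies each
remaining region via the LoF alignment described below.

Family assignment scores the candidate against every reference record —
family queries, outgroups and non-chemoreceptor GPCR decoys — and keeps
the candidate only when the top record (score desc, ref id asc) is a
family query of the mined family and scores at least 80 (floor against
random ORFs in best-hit regions).

## Multi-exon mining

Hits are extended 30 kb per side and unioned into regions. The exon-count
cap per region is the number of merged hit blocks after dropping hits
< 50 bp and merging hits < 100 bp apart (computed per strand, maximum
taken). The spliced predictor chains ungapped protein-to-DNA seeds
(floor 45) on one strand by dynamic programming: chains must increase in
both query and target, query overlaps up to 30 residues are allowed (seed
extension can overshoot an exon boundary by chance matches in the intron),
and each junction costs an intron penalty of 25 plus 1 per 200 bp of
intron, minus a bonus of 15 when the intron is GT..AG; introns longer than
10 kb are disallowed. Junction boundaries are refined by searching a small
window of candidate split points for the GT donor / AG acceptor pair
(closest to the seed-derived boundary wins); when the query coverage has a
real gap the exons are left as-is rather than stretched over intron
sequence. A terminal stop codon immediately following the last exon is
appended to the CDS.

Model selection is an iterative filter: discard models
with more exons than the cap; with threshold L starting at the mean
expected CDS length, keep models with CDS ≥ L, accept the best-scoring
model among overlapping survivors, remove everything overlapping an
accepted model, then halve L (never below the reporting floor; stop when
an iteration at the floor accepts nothing). The halving schedule is a
design choice — the original decrement is unspecified — and is
configurable. Accepted models go through LoF detection; family assignment
runs on the LoF-removed translation (the reference-aligned residues of the
codon alignment, frameshifts and stops excised); V2R/T1R models under
400 bp are discarded before status assignment.

## Loss-of-function alignment

Candidate DNA is aligned to the reference protein by a local dynamic
program over (reference codon, nucleotide) cells. A reference residue may
consume 3 nt (BLOSUM62-scored codon; in-frame stops stay on the path and
are recorded), 1–2 nt or 4–5 nt (frameshift, penalty −15), or 0 nt
(whole-codon deletion, −12); whole extra codons in the DNA cost −12. Rows
are numpy-vectorized; the within-row insertion move is a prefix-max scan
per frame class. Premature stops are reported only ≥ 15 codons
(`stop_margin`, configurable) before the reference C-terminus, so natural
C-terminal variation is not called a LoF. Because cheap frameshift moves
could hop onto chance matches in flanking sequence, an event is only
believed when flanked by ≥ 25 points of alignment score on both sides;
unsupported leading/trailing events are trimmed from the path. Frameshift
positions at codon boundaries are inherently ambiguous by ± 1 codon.

## Status assignment

Decision order: any ambiguity code in the CDS → *ambiguous*; intact CDS
(ATG start, terminal stop, no internal stop, no Ns) of at least the family
minimum → *complete*; any LoF → *pseudogene* (LoF dominates even near a
border); no LoF but the region's flank extension was clipped by a scaffold
end on the side where the reference alignment is incomplete → *edge*;
otherwise → *truncated*. The seven-TM screen (Kyte–Doolittle, window 19,
segment = run of window means ≥ 1.6 of length ≥ 15, runs < 5 residues
apart merged, pass at ≥ 6 segments) is recorded on completes but never
changes status — it is a reported annotation, as the check is applied as a
final step in this kind of survey. Note the window is only evaluated where
it fully fits, so a transmembrane helix at the extreme terminus of a
protein with no flanking loop is not counted.

## Loss-branch inference and the branch-drawing null

A tip is non-functional when its LoF set is non-empty. For every maximal
clade whose tips are all non-functional and share ≥ 1 identical LoF key
(`kind@reference-codon`, exact match by default, tolerance configurable),
one loss is placed on the branch above the clade's MRCA; a non-functional
tip sharing no mutation gets a terminal-branch loss. If the root itself
qualifies the loss predates the tree and is placed on the root's child
branches. Independent losses are loss branches without a loss ancestor;
intact branches per category exclude independent losses and all their
descendants.

The simulation starts each replicate with every branch complete, draws
branches sequentially (uniform, or probability ∝ branch length) among
branches still complete, and marks each drawn branch plus descendants
lost. Replicates that exhaust the tree early are discarded and do not
enter the p-value denominator. The branch universe excludes the root edge.
A drawn branch that is an ancestor of an earlier draw absorbs it:
independent losses per replicate are drawn branches with no drawn
ancestor. P(c) = fraction of replicates whose category-c independent-loss
count reaches the observed count. Weighted sampling without replacement is
sequential draw–remove–renormalize (implemented with exponential keys,
which is equivalent).

The four-way reclassification maps assembly evidence to complete /
high-confidence loss / low-confidence loss / undetermined; "distant" LoF
mutations are ≥ 50 codons apart (configurable). A pseudogene with two
*close* uncorroborated mutations is treated as a low-confidence loss (the
source rules only discuss the single-mutation case; this is the
conservative reading).

## Shared-missing-gene simulation

Each species draws its number of missing genes from the universal set
without replacement, uniformly or with probability ∝ gene length
(exponential-key sequential sampling); the shared count is the size of the
intersection across species. Under the uniform null the expected shared
count is G·∏ᵢ(Nᵢ/G), which the simulation reproduces within Monte-Carlo
error across a parameter grid.

## Fisher's exact test for 2×k tables

scipy covers only 2×2. For k > 2 the test enumerates the full fiber with
fixed margins, scoring each table by its multivariate hypergeometric
probability; the two-sided p-value sums probabilities ≤ the observed
table's (with a 10⁻⁹ relative tolerance for ties). Above 10⁶ candidate
tables a seeded Monte-Carlo estimate over margin-preserving draws is used.
Categories with no branches at all are dropped; fully degenerate tables
return p = 1.

## pGLS with Pagel's λ

V is built from shared root-to-MRCA path lengths (no ultrametricity
requirement; a warning is emitted for non-ultrametric trees). Pagel's
transform multiplies off-diagonals by λ; λ is estimated by maximizing the
restricted likelihood over [10⁻⁶, 1] with bounded Brent (profile ML
offered as an option; boundary values are checked explicitly against the
optimizer's result). Estimation whitens through the Cholesky factor of
V(λ); a jitter of 10⁻¹⁰·mean(diag V) is added when near-zero terminal
branches make V numerically semi-definite. R² = 1 − RSS/TSS in whitened
space, with TSS from the whitened intercept-only GLS fit — declared, not
asserted to equal any other package's definition — and the reported
p-value is the overall F-test. Categorical predictors use treatment coding
with the lexicographically first level as baseline. With λ = 0 on an
ultrametric tree the fit reduces exactly to OLS; an independent
cross-check against R's `nlme::gls` with `ape::corPagel` (ML) agrees to
four decimals on coefficients in the test suite. Trophic levels are
rounded half-up to two decimals before diet binning, which makes the bin
edges (2.19/2.2, 2.79/2.8) well defined for values inside the open gaps.

## Synthetic data: what it emulates, what it does not

Reference proteins are synthetic receptor-like sequences — seven
hydrophobic 23-mers (I/L/V/F) joined by 12-residue polar loops, padded in
the N-terminal ectodomain to the family's length (310 aa OR, 300 aa
TAAR/T2R/V1R, 900 aa V2R/T1R, so every complete plant clears its length
floor) — reverse-translated with uniform synonymous codons. No third-party
sequence data ships with the package. Plants carry ~2% amino-acid
divergence from their family base; references include the base and two 5%
variants plus decoys and an outgroup. Pseudogene recipes substitute TAA at
a requested codon or apply 1-nt indels; truncated/edge plants are
5'-fragments (defaults 450/900 nt, short enough that read-through into
background essentially never completes an ORF above the family floor);
ambiguous plants carry a few Ns. Multi-exon plants insert GT..AG introns
at codon boundaries (a generator simplification: real splice sites
interrupt codons; the miner's junction refinement does not rely on the
codon alignment, but exact planted-CDS recovery is only guaranteed for
codon-aligned junctions). Background is i.i.d. with configurable GC — no
repeats, no segmental duplications, no assembly gaps beyond N insertion —
so passing benchmarks demonstrate the pipeline's logic, not robustness to
repeat-rich real assemblies or to deep reference divergence.

Loss scenarios draw loss branches like the simulation null, except that a
draw that is an ancestor of an earlier draw is redrawn (and the scenario
restarted if the tree exhausts), so exactly `n_losses` maximal lost clades
are planted; each lost tip receives the clade's shared LoF key plus 0–2
private mutations with globally unique positions.

## Problem sizes

The benchmarks use ~1 Mb genomes with 14 plants across three families and
both exon modes (20 seeds in the round-trip test), 40,000-replicate
simulations for enumeration comparisons, 10,000 replicates for the
default null-model runs, 200 replicates of 64-tip trees for slope
coverage, and 100 scenarios for the loss round trip — sizes at which every
check runs in seconds to a couple of minutes on one CPU while keeping
Monte-Carlo error well below the tested tolerances.

## Known limitations

- The built-in search is heuristic; highly diverged family members
  (< ~50% identity to every reference) may be missed where a
  Smith–Waterman scan would find them. The tabular-import path exists for
  exactly this case.
- Frameshift positions are resolved to ± 1 codon at boundaries; LoF keys
  shared across species should be matched with a tolerance window when the
  alignments are noisy (supported, default exact).
- Overlapping genes on opposite strands: round-2 masking is
  strand-agnostic, so a pseudogene overlapping a complete gene on the
  other strand is not reported.
- The 2×k Fisher enumeration is exponential in k; for wide tables the
  seeded Monte-Carlo path is used automatically.
- pGLS assumes a single λ for the whole tree and Gaussian residuals;
  count responses are used as-is (log-transform upstream if needed).
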