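# Methods

This note documents the models and procedures implemented in `lepcompgen`,
the parameter choices behind them, what the synthetic-data generators do and
do not emulate, and the numerical conventions that make results
reproducible.

## 1. k-mer heterozygosity profiling (`kmercov`)

A diploid genome sequenced at depth *c* yields a k-mer multiplicity
histogram with two peaks: k-mers covering a heterozygous site exist on only
one haplotype and accumulate to ≈ *c*/2, while homozygous k-mers accumulate
to ≈ *c*.  Because a read of length *L* contributes *L−k+1* k-mers, the
peaks actually sit at *c*(L−k+1)/L and half of that; consumers should
rescale when comparing against nominal read depth.  The ratio of the two
peak heights grows with the heterozygosity level: the probability a k-mer
window of size k=17 covers at least one heterozygous site is
1−(1−h)¹⁷, so at h = 0.5 %, 1.6 % and 2.3 % roughly 8 %, 24 % and 32 % of
k-mers are haplotype-specific.

K-mers are canonicalized to the lexicographic minimum of the k-mer and its
reverse complement (2-bit encoded, vectorized); k must be odd so no k-mer is
its own reverse complement.  Peak calling: the histogram is smoothed with a
centered moving average (window 3, raw desk-scale counts are noisy),
multiplicities < 3 are discarded (error k-mers in real data), local maxima
are collected, and two guards are applied — a secondary maximum below 5 % of
the main peak height is noise, and maxima closer than 30 % (relative
multiplicity) belong to the same broad peak and are absorbed into the
tallest.  The true het/hom peaks are a factor 2 apart, far outside the
suppression radius.  The diploid coverage interval is [0.75, 1.25] × the
modal window depth: a symmetric bracket that excludes the half-coverage
peak at 0.5×.

## 2. Haplotig merging (`hapmerge`)

Highly heterozygous regions may assemble twice: embedded in a long scaffold
and again as a standalone short scaffold at about half the expected read
depth.  Merge rule (all inequalities strict): the haplotig must align to a
longer scaffold with query coverage > 0.90 **and** uncovered query < 500 bp
**and** identity > 0.95 **and** the target region must itself be
under-covered.  "Significantly less covered" is quantified as target-region
depth < 0.75 × diploid depth — the same bracket boundary as the diploid
coverage interval — and is configurable, since only the direction, not the
number, is dictated by the merge logic.  Candidates are scaffolds with mean
depth in [0.3, 0.75] × diploid depth and length below the assembly N50 (a
self-scaling reading of "short").

The bundled aligner is a semi-global dynamic program (match +1, mismatch
−2, gap −2; end gaps free on the target only), vectorized row-wise; its
identity is matches / alignment columns and its query coverage counts query
bases aligned against target bases.  For long inputs an edit-distance scan
(edlib, infix mode) first locates the target region, and when even the
windowed DP would exceed ~3×10⁷ cells the identity/coverage are taken from
the edit-distance alignment path itself; at the > 95 % identities that
matter for the decision the two agree to well within the thresholds.
Conflict resolution: one merge per haplotig (highest identity, then longer
target, then lexicographic id); a consumed scaffold cannot serve as a
target; circular requests are an error; re-applying merges to merged output
is a no-op.

## 3. SNP-rate distributions (`snpdist`)

Analyses are restricted to regions whose read coverage falls in the diploid
interval, partitioned into exon > intron > repeat > intergenic (precedence
resolves overlaps; everything is intersected with the diploid BED, so class
lengths sum exactly to its length).  SNP rates are computed in 1000-bp
windows anchored every 100 bp — 1000 bp is the conventional scale for
local heterozygosity tracks, and a 100-bp step gives 10× overlap without
flooding memory.  Windows never straddle region-class boundaries
(mixed-class rates would be uninterpretable); intervals shorter than the
window emit nothing.  SNP-free segments are maximal diploid sub-intervals
with zero SNPs; a SNP at position *p* splits [s,e) into [s,p) and [p+1,e).

**Mixture model.**  Window rates (excluding exact zeros, i.e. the SNP-free
windows) are fit by 1- and 2-component Gaussian mixtures with a hand-rolled
1-D EM: deterministic quantile initialization (component *j* at the
(2j−1)/2k quantile, equal weights, pooled SD), tolerance 1e-8 relative
log-likelihood, cap 500 iterations, SD floored at 1e-12.  The
log-likelihood is asserted non-decreasing every iteration.  Selection is by
lower BIC = −2·LL + (3k−1)·ln n — one- vs two-peak histograms are obvious
to the eye, but a program needs a criterion, and BIC is conservative for
nested mixtures.  Degenerate input (all rates equal)
is an error for k=2.

**Coding effects.**  A SNP inside a CDS is classified by locating its codon
through CDS-coordinate arithmetic (minus-strand genes are read
reverse-complemented so codons are always in coding orientation) and
comparing translations under the standard genetic code; the reference base
must match the scaffold, and genes whose CDS length is not divisible by 3
are excluded as non-coding.  Per-protein substitution profiles count
non-synonymous SNPs per amino-acid position, with disorder masks (aa
intervals) splitting counts into ordered and total.

## 4. Enrichment statistics (`subenrich`)

Per-protein test: with background rate p̄ = total substitutions / total
length (computed in the same mode — all positions or ordered-only — as the
per-protein counts, for self-consistency), the p-value is the binomial
upper tail P[X ≥ m], X ~ Bin(N, p̄), evaluated through the regularized
incomplete beta (scipy's survival function) for stability.  Multiplicity is
controlled by Benjamini–Hochberg step-up (q(i) = min over j ≥ i of
n·p(j)/j), flagging q < 0.1 strictly.  GO enrichment repeats the binomial
test at term level: P = term frequency in the universe, m carriers among
the N flagged proteins, BH across terms; terms with P ≥ 0.5 are still
tested — multiplicity handles them, and pre-filters would bias the
families.  Cross-species agreement is scored as the product of the two
species' term p-values (a ranking score, not a calibrated p-value), and
the overlap of two flagged-term sets is tested hypergeometrically.

## 5. Gene-order rearrangement phylogeny (`rearrphylo`)

Families present in every species with ≤ 4 copies in each are retained.  A
family resolves in a species when all its copies share one scaffold and one
strand; a family pair is usable when both families resolve and co-occur on
one scaffold in **every** species.  Its state in a species is the ordered
strand pair in canonical (lexicographic) family order: A=(+,+), B=(−,−),
C=(+,−), D=(−,+).  The letter map is a fixed convention — any bijection
yields the same Hamming distances.  All co-scaffolded pairs are used, not
only adjacent ones; an inversion capturing exactly one gene of a pair flips
its state (A↔D/B↔C for the first gene, A↔C/B↔D for the second), so state
differences count rearrangement events.  Each family joins at most one pair
via deterministic greedy matching in sorted order (any maximal matching is
a valid reduction; greedy over sorted family ids is reproducible).  States are read relative to the
assembled scaffold strand as given; no strand-flip canonicalization is
applied (caveat: a scaffold assembled in opposite orientation in one
species shifts that species' states coherently).

**BioNJ.**  Distances are Hamming counts between the per-species state
strings.  The tree is built by neighbor joining with the variance-weighted
reduction: pair choice by the Q-criterion (r−2)d(i,j) − S_i − S_j with ties
broken by lexicographic taxon-pair order; branch lengths from the two-point
formulas; the reduction d(u,k) = λ(d(i,k)−b_i) + (1−λ)(d(j,k)−b_j) with λ
chosen to minimize the variance of the reduced matrix
(λ = 1/2 + Σ_k(v(j,k)−v(i,k)) / (2(r−2)v(i,j)), clamped to [0,1], variance
matrix initialized to the distances).  On additive matrices this
reconstructs the generating tree exactly; the test suite verifies RF = 0
and path-length agreement to 1e-9 against random 5–8 taxon trees and
cross-checks topology against classical NJ.

**Sequence-side machinery.**  `consistent_columns` keeps a global-MSA
column iff every residue pair it asserts as homologous is also asserted by
a second alignment (MSA or pairwise mode); columns asserting no pairs (≤ 1
non-gap residue) are kept vacuously, with filtering left to an explicit
min-non-gap option, because dropping them silently would change column
counts between aligners.  `sample_column_groups` partitions a fresh uniform
permutation of the columns into contiguous near-equal chunks (sizes differ
by ≤ 1) per repetition — at the reference scale of 570,686 columns into
100 groups this yields 86 groups of 5,707 and 14 of 5,706.  Majority-rule
consensus keeps splits occurring in strictly more than the threshold
fraction (default 0.5, so retained splits are pairwise compatible), with
occurrence fractions as supports.  `topology_report` classifies a 7-taxon
butterfly tree against the field's two competing resolutions
("traditional" keeps skippers outside the other butterflies; "alternate"
swaps Pgl and Lac).

## 6. Family expansion (`famexp`)

Families sharing a modal closest reference-proteome homolog (ties to the
lexicographically smallest entry) are merged as connected components of the
shared-hit graph; merging is idempotent.  A focal species is *expanded* in
a family iff both its copy number and its total protein length strictly
exceed 1.5 × the respective means over the other species — the conjunction
is deliberate, count alone can reflect fragmented gene models.  Ortholog
categories (1:1:1, N:N:N, configured clades, species-specific, patchy,
unclustered) are assigned in that order and partition the families.

## 7. Synthetic data: what it emulates, and what it does not

`simulate_diploid` tiles the genome with geometric-length blocks (mean 5 kb)
that are SNP-free with probability `free_fraction` (identity-by-descent
segments) or carry a per-site SNP probability drawn from a 2-component
Gaussian mixture truncated at 0 by resampling.  Default centers 0.35 % and
2.5 % (equal weights) reproduce the low/high local-heterozygosity regime of
a highly heterozygous skipper genome; SNPs are independent Bernoulli per
site.  `simulate_reads` draws error-free uniform reads alternating
haplotypes — no sequencing errors, indels or coverage biases, so k-mer
histograms lack the error spike near multiplicity 1 (the peak caller's
`min_depth=3` guard exists for real data).  `simulate_split_assembly`
splits blocks whose *realized* SNP rate exceeds 1.5 % into an embedded hap1
copy and a standalone hap2 haplotig, with Poisson read-sampling noise on
100-bp window depths; blocks under 1 kb never split because assemblers do
not emit sub-contig-scale scaffolds.  Haplotig-merge studies use mixture
weights (0.85, 0.15) so unmerged high-het regions are a minority and the
coverage mode sits on the diploid peak, as in a real assembly.

`simulate_gene_orders` evolves a shuffled ancestral order of 1,200 families
on 8 scaffolds (≈ 600 disjoint orientation pairs — a half-scale version of
the ~1,100 pairs a real 7-species Lepidoptera data set yields) along the
7-taxon reference topology: 3–8 inversions per branch drawn uniformly
(every branch gets signal; a Poisson option exists), Poisson translocations
(rate 1) and in-place duplications (rate 0.5, family size capped at 5 to
exercise the ≤ 4-copy filter).  Real rearrangements are not uniform in size
or placement, and real draft-genome fragmentation — the main limit on how
many pairs are determinable across all species — is only mimicked by
scattering families across scaffolds.

`simulate_sub_profiles` gives every protein `mean_len` = 400 aa (optional
lognormal spread), a contiguous disordered segment covering 20 %, and
Bernoulli substitutions at p0 = 0.007/aa — the rate implied by a coding SNP
rate just under 1 % of which about a quarter are non-synonymous, times 3 nt
per codon — with a 5× multiplier for the planted enriched 5 % and a 2×
multiplier inside disorder.  Planted-effect sensitivity studies run
disorder-free in "all" mode to isolate the binomial+BH pipeline's power;
disorder-mask mechanics are tested separately.

Passing tests on these generators demonstrate correctness of the
statistics and recoverability under the stated conditions; they do not
certify performance on real data with sequencing errors, mapping artifacts,
annotation errors or assembly chimeras.

## 8. Problem sizes and reproducibility

All generators take explicit seeds; EM and greedy steps are deterministic,
so every reported number is reproducible bit-for-bit.  The validation
studies (`lepcompgen.experiments`, driven by `scripts/acceptance.py`) use:
50 replicates for topology recovery, 20 random additive matrices for
BioNJ, 5,000 window rates for mixture recovery, 200 null replicates of 400
proteins (plus 5 × 2,000-protein planted-effect replicates) for enrichment
calibration, 10 replicates of 150-kb split assemblies for haplotig merging,
and 10 replicates of 60-kb genomes at 60× for k-mer peaks — sizes chosen so
the full suite stays in the minutes range while keeping Monte-Carlo error
well inside the asserted tolerances.

## 9. Known limitations

* The DP aligner is quadratic; whole-chromosome alignment is out of scope
  (the edlib-seeded path handles desk-scale long targets).
* The EM fitter is 1-D and limited to k ∈ {1, 2}, matching the analysis it
  supports.
* GO annotations are treated as flat sets; no propagation to ancestor
  terms; carrying counts up the GO graph would change term frequencies.
* Hamming distances between orientation strings are uncorrected event
  counts; no saturation correction is applied, so very deep trees would
  compress basal branches.
* `consistent_columns` in pairwise mode is quadratic in the residues per
  column; fine for protein MSAs of ≤ dozens of sequences.
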