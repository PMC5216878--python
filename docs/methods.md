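# Methods

This note documents the models, estimators, numerical choices and known
limitations of `beanscan`.  Everything quantitative stated here is computed
by the test suite or the `analysis/` drivers; nothing is asserted that the
code does not check.

## Data model

A *locus* is a pre-aligned multiple sequence alignment over
{A, C, G, T, N, -}, one row per accession.  Accessions are highly inbred
lines and are treated as haploid sequences throughout.  A locus may carry a
region annotation — non-overlapping exon/intron/5'UTR/3'UTR intervals in
0-based half-open coordinates (GFF-style input is 1-based inclusive) with a
reading-frame offset for the concatenated exon sequence; a trailing partial
codon is dropped from codon-wise analyses.  Loci without annotations are
analyzable only as whole sequences and are excluded from the selection scan.

Missing-data policy: *complete deletion per analyzed subset* — an alignment
column is unusable if any retained row carries `-` or `N`, so indels never
enter any statistic.  Because the mask is recomputed per accession subset,
different populations can use different column sets of the same locus; this
matches the way per-population summaries are usually produced from such
panels.  A pairwise-deletion variant is not offered as a switch on the
estimators; it was considered and rejected because it makes per-site
denominators pair-specific and breaks the additive site-count identities the
reports rely on.

## Diversity estimators

For a population sample of n sequences over L usable sites:

- π: mean pairwise Hamming distance per usable site (Tajima's estimator).
- θ_W: S / (a_n · L) with a_n = Σ_{i<n} 1/i; by default S counts
  segregating sites, optionally η (total mutations, k−1 per site with k
  alleles) since the upstream tool this mirrors offers both.
- Haplotype diversity: Hd = n/(n−1) · (1 − Σ p_k²) (Nei's unbiased form).
- Site classes: a variable site is a *singleton* iff every non-major allele
  occurs exactly once (this extends the biallelic definition to the rare
  tri-allelic case deterministically and symmetrically across populations);
  *parsimony-informative* iff at least two alleles occur at least twice.

Loss of diversity for a wild/domesticated contrast: L = 1 − d̄/w̄ from the
across-locus means (monomorphic loci retained; they add zero to both means)
and L¹ = mean over loci of (1 − d_i/w_i), excluding loci with w_i = 0 (the
count of exclusions is reported).

All estimators are verified against independent brute-force implementations
on hundreds of random small alignments to 1e−12.

## Shared/private partition and coding effects

At each usable column of the pooled two-population alignment, a *baseline*
allele is chosen: an allele present in both populations if any, else the
fixed allele of a monomorphic population.  Every other allele is one
mutation, classified shared (segregating in both), private-wild or
private-domesticated.  Sites variable in neither population (including pure
fixed differences) are excluded, which makes the three categories sum to
the pooled η restricted to sites variable in at least one population — an
identity the tests enforce on random data.  In the vanishingly rare case of
disjoint polymorphic allele sets in the two populations the wild major
allele is the baseline.

A coding site's effect is classified from the observed whole-haplotype
codons: synonymous if every pair of codons differing at the site encodes
the same amino acid, nonsynonymous if every differing pair changes it,
mixed otherwise; mixed sites are tallied with the nonsynonymous counts.
Codons containing masked columns are excluded.

The private-replacement report lists amino-acid variants carried only by
the focal (domesticated) population among the *P. vulgaris* populations,
with carrier counts for every population and the two outgroup species; a
variant is flagged *derived* (consistent with a recent, post-domestication
origin) when the outgroups also carry the background state.

The binomial test for an excess of domesticated-private coding mutations
uses X ~ Binomial(n, p₀) with n the total private-domesticated count and
p₀, under the default *raw-count* null, the coding fraction of the
private-wild mutations.  A *length-standardized* null sets p₀ to the coding
share of the per-bp private-wild rates instead.  The published analysis did
not state which standardization produced its printed P value, and the raw
Table counts do not reproduce it under the literal null; both modes are
provided and neither is asserted against that value.

## dN/dS

The modified Nei–Gojobori method: per codon position, the three possible
changes are weighted R (transition) or 1 (transversion) and the synonymous
site fraction is the weighted share of synonymous changes; R = 1 recovers
the original method and is the default because the upstream analysis did
not state its R.  Changes creating stop codons count as nonsynonymous in
site counting.  Differences between two codons are pathway-counted: all
orderings of the differing positions are enumerated, orderings passing
through a stop codon are excluded when any stop-free ordering exists, and
synonymous/nonsynonymous steps are averaged over the retained orderings.
Per pair, p_S = S_d/S and p_N = N_d/N (site totals averaged over the two
sequences) are Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3); a pair with
p ≥ 3/4 is flagged JC-undefined and excluded from the averages, never
clipped.  dN and dS are the means over all sequence pairs; standard errors
come from bootstrap over codons (default 1000 replicates, seeded).

For speed, the per-codon synonymous fractions and per-codon-pair pathway
counts are precomputed as 64- and 64×64-element tables and all pair/bootstrap
arithmetic is table lookups; the unit tests pin the results to an
independent pathway-enumeration oracle built on Biopython's translation.

## Rank tests

The Wilcoxon signed-rank test drops zero differences and midranks ties; its
tail is exact — the full sign-assignment distribution computed by dynamic
programming over doubled ranks — for up to 25 informative pairs, and a
continuity-corrected normal approximation with tie correction beyond.  The
two-sample rank-sum test enumerates all C(n+m, n) group assignments when
that count is ≤ 2·10⁵ and otherwise uses the tie-corrected normal
approximation.  Two-sided exact p-values are defined by the absolute
deviation of the rank sum from its null mean.  Both tests match full
enumeration exactly on random small inputs, including ties, which is why
they are implemented here rather than delegated (library exact modes
decline tied data).

## Differentiation

Hudson's F_ST = 1 − H_w/H_b, with H_w the unweighted average of the two
within-population mean pairwise differences and H_b the between-population
mean, computed over the pooled usable columns.  Monomorphic pooled data are
reported as undefined ("na"), and negative estimates are reported as
computed.  The permutation test shuffles population labels with fixed group
sizes and uses the add-one estimator p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1),
which cannot return zero; permutations with no between-group differences
are treated as maximally undifferentiated.  With few polymorphic sites the
permutation distribution of F_ST is discrete and the p-values are
conservative (super-uniform); the calibration tests therefore use loci long
enough that ties are rare.

AMOVA decomposes pairwise difference counts (squared Euclidean distances on
the haplotype mismatch indicator) into among- and within-population
components with the standard unequal-size correction n₀;
Φ_ST = σ²_a/(σ²_a + σ²_w).  Variance-component estimates can be negative
and are not truncated.

## Demographic models and the selection scan

Two domestication demographies are parameterized (times in generations —
the crop is annual, so one generation per year; haploid effective sizes):
the Mesoamerican and Andean pools split from a common ancestor at T_ANC,
each wild pool founded a domesticated pool through a bottleneck window
[T_E·D, T_B·D], and the Andean wild pool passed a founder bottleneck —
recent under Model 1 (constant wild sizes), immediately after the split
under Model 2 (exponentially growing wild pools).  Bottleneck intensity I
(percent) is the bottleneck size as a percentage of the pre-bottleneck wild
size.  Migration is per-lineage per-generation; M_WD denotes wild→
domesticated introgression forward in time.  The scan uses the
two-population (MW/MD) reduction; the four-population topology is exercised
by the simulator's own tests.

Defaults (N_MW = N_MWANC = N_ANC = 2.5·10⁵, N_MD = 2·10⁵, T_BMD = 8000,
T_EMD = 6000, I_MD = 0.2%, M_WD = 5·10⁻⁵) were chosen once so that, at the
stated mutation rates (introns 10⁻⁸/site/generation, exons 10-fold lower),
the wild panel's noncoding diversity is of order 5·10⁻³/site, the
domesticated panel loses roughly half of the wild diversity, and the mean
per-locus F_ST is of order 0.2 — the regime the study reports.  The
introgression term matters: without it, a bottleneck strong enough to halve
diversity leaves a substantial fraction of loci with a monomorphic
domesticated sample, which both exaggerates differentiation and fattens the
null's upper tail.

Per polymorphic fragment (exonic = concatenated exons; intronic = introns
plus UTRs) three statistics are computed: Φ_ST from AMOVA, the
branch-length statistic −ln(1 − F_ST) with F_ST clamped to [0, 1−10⁻⁹), and
Δπ = (π_w − π_d)/(π_w + π_d) (zero when the denominator is zero).  Each is
z-scored with mean/SD estimated from the observed fragment panel and the
index is the sum of the three z-scores; a zero SD silences its component.
The same constants are applied to the simulated fragments, which is the
only choice that puts observed and simulated indices on one scale so that
"the fraction of simulated indices larger than the observed value" is
well-defined.

The null distribution is built per fragment class: each simulation draws a
fragment length with replacement from the observed class-specific length
multiset and a mutation rate from the class prior, runs a neutral
coalescent under the model (with parameters redrawn from priors per
simulation when priors are supplied; fixed otherwise, which batches
tree-sequence replicates for speed), and records the component statistics.
Monomorphic simulated fragments are counted and excluded, mirroring the
restriction of the observed panel to polymorphic fragments.  Empirical
p-values are paper-literal (#{null > obs}/n, an add-one variant is off by
default), corrected by Benjamini–Hochberg step-up (verified against
statsmodels), and fragments with q below the FDR level (default 5%) are
flagged; a gene is flagged if any of its fragments is.

The original demographic priors are unpublished; `reconstructed_priors`
ships wide uniform/log-uniform ranges around literature-scale values and is
labeled a reconstruction.  All validation runs use a fixed, known model —
never the reconstruction — so no result in this package depends on it.

## Synthetic data generator

The generator emulates the study design: by default 49 loci of 150–900 bp,
19 wild + 20 domesticated haploid accessions, ~4/49 loci without structural
annotation and ~42/45 annotated loci carrying exons (the study's
proportions), exon columns mutating 10-fold slower than noncoding columns
via a rate map.  Sequences are rendered from msprime tree sequences onto a
random reference whose exons are stop-free; any exon mutation that would
create an internal stop codon in any accession is rewritten to a substitute
base (preserving the mutation) or, if no substitute clears every carrier,
collapsed to the column majority (removing it).  The repair touches only
offending codons, so mutation counts are approximately preserved; the bias
is a slight deficit of nonsense-like variation, which real exons share.
Every generated exon translates cleanly in frame — a tested invariant.

Sweeps are emulated demographically rather than with selection
coefficients: a swept locus is re-simulated with (i) a bottleneck sized so
a domesticated lineage pair survives the domestication window with
probability equal to the configured retention fraction (default 0.05), (ii)
a proportionally reduced modern domesticated size, (iii) no introgression
at the locus (selection removes migrant alleles), and (iv) a divergence
boost — the domesticated lineage merges into the wild pool
`divergence_boost`·N_MWANC generations deeper than the neutral split,
emulating selection on a divergent standing haplotype.  The boost default
(4.0) is sized analytically so the swept haplotype's stem branch carries
several marking mutations at intron rates (2·boost·N·μ·L ≈ 5 for a median
fragment); without such mutations a sweep is invisible at the sequence
level no matter how complete, and per-locus recovery becomes a coin flip on
the mutational draw.  Even so, short fragments can fail to pick up marking
mutations, which is why sweep recovery is asserted as ≥3 of 4 rather than
all 4.

Analytic helpers give E[T₂] under piecewise-constant sizes (used for
calibration tests); they ignore migration and therefore apply to
migration-free configurations only.

What the generator does not emulate: base-composition and codon-usage
realism, indels, intralocus recombination (fragments ≤ 900 bp are treated
as non-recombining; a hook exists to revisit this), sequencing error, and
locus-specific mutation-rate variation beyond the exon/noncoding split.
Passing tests on generated data therefore demonstrate the statistical
machinery under the stated model, not robustness to these real-data
features.

## FST-outlier test

Observed biallelic markers are filtered (missing fraction > 5% or minor
allele frequency ≤ 1% removed — the thresholds of the re-analysis this
mirrors), then per-marker He = 2p̄(1−p̄) and Hudson F_ST from allele
frequencies (with the n/(n−1) small-sample correction on the within terms)
are compared with a simulated neutral cloud.  Cloud loci are single
coalescent trees from a symmetric island model of haploid demes (default
20 demes of size 50, two demes sampled at the observed sizes) with one
mutation dropped uniformly on the branches, resampled if it fixes in the
sample — a biallelic rendering of the infinite-alleles scheme that spreads
the cloud over the full heterozygosity range.  The same F_ST estimator is
used for cloud and data so both live on one scale.

The migration rate is first solved from the exact island-model expectation
F_ST = 1/(1 + 2mdN/(d−1)) — with targets clamped to [0.02, 0.95], since the
simulation cost per locus scales as (1−F)/F and a near-panmictic envelope
is indistinguishable from the floor's — and then calibrated with pilot runs (up to three
iterations of 2000 simulations under a 1/(1+βm) response model) because the
mean of per-SNP F_ST ratios sits below the coalescent-time ratio.  The
envelope splits the cloud into 20 equal-count He bins, takes per-bin
empirical quantiles at (1±ci)/2 and interpolates across bin medians; at
ci = 1.0 the bounds switch to adjacent-bin extremes so the envelope encloses
the entire cloud.  Classification uses a small tolerance so a marker exactly
on the boundary — common, since panels and clouds share a discrete value
set — is neutral.  Forced-mean mode iterates: drop current outliers,
recompute the mean F_ST of the remainder, re-simulate, reclassify (≤5
iterations or convergence).

Known limitation: per-SNP F_ST is bounded by 1, and for target means above
roughly 0.15 the island-model cloud's upper 99.5% quantile reaches that
ceiling in high-He bins, so markers fixed between the samples can never be
flagged.  Under a strong domestication bottleneck even neutral markers
average F_ST ≈ 0.2, and forced-mean iteration then converges to an
envelope that swallows everything.  The demonstration driver therefore
targets the cloud at the median marker F_ST; a hierarchical or
bottleneck-aware null would be the principled fix and is out of scope.

## Published-summary replication

The shipped fixtures transcribe the study's printed per-region diversity
summary, loss-of-diversity table, per-locus F_ST/mutation-pattern table and
coding-effect counts; SHA-256 checksums guard against silent edits.
`replicate_paper_summaries` recomputes the loss statistics from the printed
means, the diversity fold-ratios, the per-region mean F_ST over defined
entries, the significant-locus count, the mutation-pattern totals and the
shared-synonymous percentage, comparing each at the precision the source
printed (two decimals for L and F_ST, one for percentages, integers for
counts).  The printed noncoding overall shared/private-wild cells of the
mutation-pattern table are inconsistent with the sums of that table's own
noncoding columns (the whole-sequence and coding totals, and the noncoding
private-domesticated total, all agree); the replication asserts only the
internally consistent cells.  The "na" (undefined: monomorphic locus) and
"/" (structurally absent region) sentinels are typed distinctly and
excluded from means and sums exactly as the printed footers imply.

## Problem sizes used in validation

The automated validation uses: oracle equivalence on 200–300 random
instances per estimator; 2000 neutral single-population loci for estimator
calibration; 300 permutation tests and a ~500-fragment neutral scan for
p-value uniformity; three fixed-seed sweep-recovery runs of 40 genes with
5000 null simulations per fragment class; and a 50 000-simulation FDIST
cloud against a 500-marker neutral panel.  These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances while keeping
the full suite at a few minutes on one core.
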