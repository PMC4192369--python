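# Methods

This note documents the statistical models behind each pipeline stage,
the synthetic-data generator that stands in for the real substrates, the
numerical conventions, and the limits of what the test suite demonstrates.

## Mouse stage: marker-to-gene interpolation

A single-marker QTL scan delivers one p-value per marker. Gene-level
p-values are obtained by linear interpolation **on the raw p scale**
between the two markers flanking the gene's start position: a gene
halfway between markers with p = 0.02 and 0.04 receives 0.03. The start
position (not the midpoint, and regardless of strand) is the anchor.
Outside the marker range the nearest marker's p is used rather than
extrapolating, since extrapolation can leave (0, 1]. Interpolating on
−log₁₀(p) instead is exposed as an option but is not the default; on the
p scale the interpolated value is always bounded by the flanking values,
which makes the convexity property exact. A chromosome with a single
marker clamps all its genes to that marker with a warning; a gene on a
chromosome with no markers is an error.

Significance selection takes genes with p ≤ α (default 0.05), ordered by
p with lexicographic tie-break. Whether that selection is specific to a
QTL depends entirely on the *scale* of the input p-values: interval
mapping tools report genome-wide (family-wise) adjusted significance, so
p ≤ 0.05 means "exceeds the genome-wide permutation threshold" and only
genes under real linkage peaks qualify. Nominal per-marker p-values, by
contrast, dip under 0.05 at rate α anywhere in the genome. The generator
supports both conventions (below); the full pipeline uses the
genome-wide one, matching the provenance of real scan files.

## Human stage: gene-based association with a simulated LD null

SNPs are assigned to a gene when they fall within ±50 kb of its
boundaries (1-based inclusive; a SNP may serve several overlapping
genes; genes with zero SNPs are reported but not tested). Each SNP
p-value is mapped through the upper-tail χ²(1 df) quantile Q and summed:
T = Σ Q(pᵢ). Under linkage equilibrium T ~ χ²(n df); under LD the null
is simulated by drawing z ~ MVN(0, R) and forming Σ zᵢ², where R is the
SNP–SNP Pearson correlation estimated from a reference dosage panel.

Numerical conventions:

* empirical p uses (r+1)/(n+1), never r/n — bounded away from 0 and
  conservative; ties (T_sim = T_obs) count against rejection;
* p-values of exactly 0 in the input are floored at 1e-300 with a
  warning before the quantile map (Q diverges at 0);
* R is repaired to positive semi-definite by eigenvalue clipping at
  1e-8 with the unit diagonal restored — finite panels give indefinite
  sample correlations after SNP filtering; monomorphic SNPs are removed
  from both R and T with a warning;
* the optional staged schedule (10³ → 10⁴ → 10⁶ draws) escalates only
  while p < 10/stage, spending large simulation counts only on genes
  whose p needs the resolution; the schedule is configurable.

## Cross-species stage

Human and mouse tables are joined through a homology map; duplicate
mappings keep the pair with the smallest human p (logged). Three tests:

* **Genomic-control λ** (median convention): λ = median(Q(p)) / 0.45494,
  the χ²(1) median. λ of the candidate set's human p-values is compared
  with λ of random same-size gene sets drawn without replacement from
  the joined table; the permutation p counts strictly greater random λs
  and divides by the permutation count (a ≥ comparison and the
  (r+1)/(n+1) variant are configurable; the reported p is floored at
  1/(n_perm+1) to stay in (0, 1]).
* **RRHO**: both lists ranked ascending by p; for every pair of rank
  thresholds (multiples of a step, default N/100) the hypergeometric
  upper-tail p of the top-list overlap is computed; the familywise
  correction permutes one list's ranks (the other held fixed — under
  the null of no rank association this is exchangeable) and compares
  maximal −log₁₀ p values.
* **Bonferroni overlap**: threshold α/|candidate set|; hits are the
  candidates whose homologue's human p clears it.

## Coexpression stage

Probe concordance builds the graph on a gene's probes with edges where
Pearson r ≥ 0.5 and the two-sided t-transform p (n−2 df) ≤ 0.05, then
grows a clique greedily from the highest-degree probe (ties by probe
id). The greedy clique is exact whenever the concordant probes are
mutually correlated, the structure the filter is meant to find (real
exon arrays show all pairwise correlations among the "good" probes
passing). Single-probe genes are returned flagged untestable; a gene
with no passing pair returns a singleton.

Top-K correlate lists rank by **signed** r descending (coexpression is a
positive-association concept; an |r| mode exists), ties by probe id,
focal probe excluded, zero-variance probes dropped with a warning.

Overlap significance: the intersection size of m random k-subsets of
[N] is simulated by sequential conditional draws I₁ = k,
I_{j+1} ~ Hypergeom(N, I_j, k) — distribution-identical to sampling the
subsets explicitly but O(m) per replicate, which is what makes one
million permutations at N = 1,236,087 take seconds. The two-set version
additionally reports the exact hypergeometric upper tail. The
protein-coding universe for two-resource comparisons defaults to 19,000
genes; the conclusions are insensitive across 17,787–20,000.

The eQTL scan applies the same Welch marker test to an expression trait,
with a genome-wide threshold from the max-statistic (minimum-p) null
distribution over strain-label permutations (familywise α = 0.05). The
peak is *cis* if significant and within the cis window (default 10 Mb)
of the gene, *trans* if significant elsewhere, *none* otherwise.

## Synthetic data

The generator produces, seed-deterministically, every input the pipeline
reads; truth records make planted signals scorable.

**RI cross.** 37 strains by default (an RI panel of 35 lines plus both
parents), genotypes coded 0/1 — RI strains are fully inbred, so
heterozygotes do not occur. Chromosomes are first-order Markov: each
strain's allele flips between adjacent markers with probability
`recomb_prob`. The phenotype is `qtl_effect · g + noise`, and marker
p-values come from a Welch two-group comparison per marker (monomorphic
markers get p = 1 with a warning) — mimicking a single-marker scan
without re-implementing interval mapping, since the interpolation
consumes p-values, not the scan itself. Default `recomb_prob` = 0.2: a
desk-scale map of 30 markers per chromosome has intervals several-fold
wider than a real dense RI map, so per-interval recombination must be
correspondingly larger; at 0.2 the planted marker is the chromosome-wide
minimum p in ~98% of strong-effect replicates. `marker_stat="genomewide"`
replaces nominal p-values with max-statistic permutation-adjusted ones
(the convention of interval-mapping software); the pipeline's simulate
stage uses it, together with `recomb_prob` = 0.05 to emulate the tight
adjacent-marker linkage of a dense map, so the significant region spans
several genes as a real QTL does.

**GWAS summary statistics.** LD is blockwise-exchangeable: within a
block every haplotype allele copies a block-ancestral allele with
probability √r and is otherwise an independent Bernoulli(maf) draw,
giving pairwise dosage correlation exactly r within blocks and zero
between. Each block sits on one gene (cycling through the gene table),
which guarantees SNP coverage of every gene at desk scale. The phenotype
is a linear effect of the standardized dosage at one SNP inside the
causal gene plus unit noise; per-SNP p-values come from the marginal
regression t-test. The study genotypes double as the LD reference panel.
No MRI covariate structure, population stratification or realistic
human LD is simulated — the block model is the point, being the simplest
structure that separates the MVN null from independence.

**Homology map.** A uniform random subset of human genes of size
round(coverage × n), each paired with a distinct mouse gene; default
coverage 0.883, typical of curated homology resources genome-wide. The
pipeline forces the planted pair into the map so that recovery is not
confounded by mapping dropout; everything else is random.

**Expression matrix.** Probes of module genes load on one shared latent
factor with loading √module_r (pairwise probe correlation = module_r);
the focal gene receives 6 concordant probes plus 11 independent noise
probes by default — 17 in total, the mixed exon/intron probe structure
of a focal gene on a real exon array. Non-module genes' probes are
independent noise. Each probe is standardized across strains. The
pipeline drives the module factor with the genotype at the planted QTL
marker, which gives every module gene (in particular the focal one) a
cis-eQTL at that locus. One observation per strain throughout — no
within-strain replicates are modelled.

What passing tests therefore show: each statistic is correctly computed
and calibrated *under its own model assumptions* (exchangeable LD
blocks, a single shared latent factor, Gaussian noise). They do not show
robustness to real-data features the generator omits: long-range LD,
allele-frequency-dependent power, batch structure in expression data,
many-to-many homology, or polygenic mouse traits.

## Desk-scale study conditions

Calibration and recovery runs use: 37 strains, 5 chromosomes × 30
markers (genes every ~1.2 Mb); 60 human genes with one 10-SNP LD block
each (r = 0.7), 800–2,000 individuals; expression over the cross's 37
strains with an 8-gene module at r = 0.85. Planted effects:
`qtl_effect` = 2 (in noise-SD units) and `causal_beta` = 0.5. Permutation
counts in routine runs are 10³–10⁵; the two published-scale overlap
tests always use 10⁶ (they consume only counts, not data). Under these
conditions the end-to-end Bonferroni recovery of the shared planted
gene is ~85–90%, and the null pipeline's familywise hit rate is
consistent with α.

## Reproducibility

All randomness flows from one global seed. Per-stage generators are
derived by keying a `SeedSequence` with a CRC-32 hash of the stage name,
so any stage re-run in isolation reproduces its draws exactly, and two
runs with the same config and seed produce byte-identical outputs
(modulo wall-clock fields in the run report).

## Known limitations

* The marker scan is a two-group comparison, not Haley–Knott or mixture
  interval mapping; between-marker QTL positions are not modelled.
* The concordance clique is greedy; for probe sets whose pass/fail graph
  is not close to a clique it can return a non-maximum clique (ties and
  near-ties are resolved deterministically).
* The MVN null treats the panel correlation as known; panel sampling
  noise is not propagated.
* RRHO permutes one list only; both-list permutation gives the same
  null but at twice the cost.
* The eQTL scan classifies only the single peak marker; secondary peaks
  are not reported.
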