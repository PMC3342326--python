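# Methods

## Problem and model

A founder mutation — a pathogenic variant inherited by many apparently
unrelated patients from one common ancestor — travels inside an ancestral
chromosome fragment that recombination whittles down over generations.
Carriers therefore share a short haplotype, identical by descent (IBD),
around the mutant locus.  In cancer, a second feature helps: the wild-type
copy of a mutant tumor-suppressor gene is frequently lost somatically
(loss of heterozygosity, LOH), so in a tumor the retained chromosome's
haplotype can be read directly off the SNP-array B-allele-frequency (BAF)
profile without statistical phasing.  The package scans a set of tumor
haplotypes, reconstructed inside recurrent LOH regions, for genomic
positions where IBD sharing is significantly more frequent and/or longer
than chance.

## Pipeline

1. **LOH calling** (`loh_haplotypes`).  Allele-specific copy-number
   segments are consumed as input; a segment is LOH when the minor-allele
   copy number is below 0.5, whatever the copy number of the retained
   chromosome (covers deletion, copy-neutral LOH, and LOH with gain under
   normal-cell contamination).  Recurrent regions are maximal intervals
   where the per-basepair carrier fraction reaches `min_frequency`
   (default 0.2; 1.0 selects regions lost in every sample).

2. **Haplotype inference** (`loh_haplotypes`).  Inside an LOH region,
   BAF > 0.65 calls the B allele, BAF < 0.35 calls A; anything between is
   unreliable, and a marker unreliable in any tumor is dropped panel-wide.
   The thresholds are deliberately wide: under LOH the BAF sits near 0 or
   1, displaced towards 0.5 only by normal-cell contamination, and a
   synthetic profile with Gaussian noise (sigma 0.05) is recovered with
   error below 1e-3 (test suite).  With a matched constitutive sample,
   the lost haplotype follows by genotype comparison: at heterozygous
   sites the lost allele is the one not retained, at homozygous sites it
   is the homozygous allele, and a retained allele absent from the
   constitutive genotype is flagged missing.

3. **Pairwise IBD matching** (`ibd_match`).  A seed-and-extend matcher:
   markers are partitioned into fixed words of `bits` markers; haplotype
   pairs sharing an identical aligned word are extended marker-by-marker
   while alleles agree; maximal runs of at least `min_m` cM are reported.
   Defaults `min_m = 0.4` cM, `err_hom = 0`, `bits = 5`: haplotypes read
   off LOH regions have negligible error, so no mismatch tolerance is
   needed, and short seeds keep segment boundaries accurate.  For
   `err_hom = 0` the output provably equals the exhaustive maximal-run
   scan (`brute_force_ibd`, kept as an independent oracle) whenever
   `min_m` spans at least `2*bits - 1` markers; the implementation screens
   candidates at the word level (any qualifying run must contain K
   consecutive equal words, K derived from the sparsest stretch of the
   genetic map) which makes a 374-haplotype, 10,000-marker scan take
   about a second on one core.  The `err_hom > 0` path (extend until the
   mismatch budget is exceeded, then trim trailing mismatches) is
   best-effort and excluded from the oracle equivalence.

4. **IBD scoring** (`ibd_score`).  A segment sharing haplotype `H` over
   markers `i` scores `S = -2 * sum_i ln f(H_i)` with `f(H_i)` the
   population frequency of the carried allele — the log-probability of
   two independent haplotypes agreeing everywhere on the segment, so S
   grows with segment length and allele rarity.  Frequencies are
   estimated from the reference panel (so tumor and null scores share one
   frequency table) and clamped to `[1e-4, 1 - 1e-4]` to keep monomorphic
   markers finite.  The per-SNP IBD score sums S over all segments
   covering the SNP.  The constant factor and log base are immaterial for
   inference because the null is built from the identical statistic.

5. **Significance** (`ibd_score`).  Linkage disequilibrium inflates
   scores regionally, so raw scores are compared with an empirical null:
   `n_subsets` (default 100) subsets of the reference panel, each the
   size of the tumor panel, are drawn without replacement and pushed
   through the identical matching + scoring pipeline; a Gumbel
   distribution is fitted per SNP by maximum likelihood
   (method-of-moments initialisation, fixed-point ML refinement,
   vectorised across markers; cross-checked against `scipy.stats.gumbel_r.fit`).
   The Gumbel fits the right-skewed, extreme-value-like subset scores
   better than a Gaussian and errs conservative in the tail.  Because
   pairwise matching is local to a pair, subset segments are the
   reference-wide segments restricted to the subset — matching runs once,
   making 50–100 subsets nearly free.  Markers whose subset scores are
   constant (typically all zero) are degenerate: the observed constant is
   kept and the tumor score is compared directly (p = 0 above it, 1
   otherwise).  P-values are the fitted upper tails; q-values are
   Benjamini–Hochberg over all scanned markers.

6. **Benchmark** (`dash_bench`).  A frequency-only alternative in the
   style of cluster-association methods: the chromosome is tiled into
   0.2 cM windows, haplotypes are linked when a pairwise segment fully
   spans a window, connected components of size >= 2 are clusters
   (identical member sets in adjacent windows merge), and each cluster is
   tested for tumor enrichment with a one-sided Fisher's exact test,
   BH-corrected across clusters.  The published clustering algorithm's
   density-refinement internals are intentionally not reproduced — the
   benchmark's defining property is that its test sees only cluster
   frequency, not haplotype length.

7. **Founder age** (`ibd_score.estimate_generations`).  Pairwise IBD
   segments average 1/(2n) Morgans after n generations, so
   n = 1 / (2 * mean length in Morgans); 5.4 cM gives ~9.26, "around nine
   generations".

## Synthetic data

`simulate` provides a founder-mosaic (Li–Stephens-like) panel generator:
per-marker B-allele frequencies are uniform on (0.05, 0.95), founder
haplotypes are Bernoulli draws, and each panel haplotype copies founders
in blocks with Poisson(1 per cM) switch points plus a 0.002 per-marker
allele flip.  This reproduces the two features the empirical null exists
to absorb — an allele-frequency spectrum and block-structured LD with
chance identical-by-state sharing — while staying cheap and fully seeded.

The power study mirrors a split-panel design: one population of 548
mosaics is generated per replicate and divided into a 274-haplotype
reference panel and a 274-haplotype tumor pool from which the 100-tumor
set is drawn.  Sharing founders across the split is essential: with
unrelated generator draws the tumor panel carries its own founder/LD
landscape that the resampled null cannot absorb, and drawing tumors as a
subset of a fixed pool matches the sampling variance of the null's
reference subsets.  `n_founders = 548` (the pool size) was chosen so that
(i) a random pair shares a founder block at only ~0.2% of positions, far
below the sharing among planted carriers, (ii) across ~37,000 reference
pairs every marker is still covered by chance segments, keeping the null
non-degenerate everywhere, and (iii) the two halves of the split are
statistically exchangeable — measured cross-half p-values are calibrated
(tail inflation ~1.0).  Substantially fewer founders (e.g. 20) floods the
scan with background sharing (per-marker null location ~2e4, scale ~2e3)
that reduces 7%-prevalence detection power to ~0.7; substantially more
thins the null towards degeneracy.

Planted signals copy the first tumor haplotype's alleles into the chosen
carriers (always including the source) over segments whose lengths are
Gumbel(location = mean, scale = mean) — the shape that mimics the natural
spread of IBD lengths around a real founder mutation — truncated to
(0.1 cM, chromosome span], placed so the focal position falls at a
uniform fraction of the segment.  Detection means at least one marker
with q <= 0.01 inside the union of planted segments; FDR pools
significant markers outside planted segments across replicates; ROC
curves average per-marker TPR/FPR over a q-threshold grid.

### Study scale

The default study runs 100 tumors against 274 references on 10,000
markers over one 100 cM chromosome (100 markers/cM, ~370K-array density;
near-equal power is expected at higher densities), 25 replicates and 50
null subsets per condition.  One replicate takes ~2 s (scan) plus ~3 s
when the cluster benchmark runs, so a condition completes in one to three
minutes on a single core.

## What the simulations do and do not show

The generator emulates frequency spectra, block LD, chance IBS sharing
and panel-splitting, and the planted-haplotype geometry of a founder
mutation under LOH.  It does not model coalescent demography, marker
ascertainment, genotyping artefacts, BAF noise at the matching stage
(haplotypes enter the matcher error-free; the BAF stage is validated
separately), or real recombination-map heterogeneity (the simulated map
is uniform).  Passing tests therefore show the statistical machinery is
correct and calibrated under a realistic sharing regime, not that power
on a particular cohort will match the simulated numbers.

## Numerical choices and edge cases

- Allele frequencies clamped at 1e-4; Gumbel scale floored at 1e-8
  (degenerate markers only).
- The ML Gumbel fixed point runs to relative tolerance 1e-12 (max 200
  iterations); constant samples are rejected.
- cM lengths use the boundary markers' interpolated positions; no
  half-marker end correction is applied.
- Genetic-map interpolation is piecewise linear on the cumulative-cM
  column; positions outside the map extrapolate with the nearest
  interval's rate.
- Segment output order is (hap1_id, hap2_id, start_idx); window clusters
  sort by window then members.
- Recurrent-LOH carrier sets list every sample whose LOH overlaps the
  region (the region boundary rule is per-basepair counting; the
  frequency cut-off is the only published constraint).
- ROC averaging is per q-threshold (pointwise), not vertical.

## Known limitations

- Per-marker FDR of the scaled-down study runs at ~1e-2, above the
  ~8.6e-3 seen at full genome scale: a single chance long-sharing event
  between two tumor haplotypes covers a ~2.5–3x larger fraction of a
  100 cM / 10,000-marker chromosome than of a full-density genome, so the
  pooled per-marker FDR is geometry-inflated even though p-values are
  calibrated and BH is applied identically.
- The mismatch-tolerant matcher path is a simplification; only the
  mismatch-free configuration is contractually exact.
- The significance model assumes the reference panel matches the tumor
  population's ancestry; a mismatched reference yields anti-conservative
  scans (use reference samples of the same ancestry).
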