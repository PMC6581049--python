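# Methods

## The assay model

The pipeline analyses a nucleosome disassembly experiment in which a
library of native mononucleosomes is incubated with ATP and the histone
chaperone Nap1, with or without an ATP-dependent remodeler. Four gel
bands are sequenced — nucleosomal (NUC) and released naked DNA (DNA)
from the reaction without remodeler, and their counterparts NUCR and
DNAR with remodeler — in two replicates each. For a nucleosome with
occupancy w, intrinsic disassembly probability p and remodeler
disassembly probability r, the expected read mass in the four bands is

    NUC  ∝ w(1 − p)        DNA  ∝ wp
    NUCR ∝ w(1 − p)(1 − r) DNAR ∝ w(p + (1 − p)r)

so each band pair conserves material (NUC + DNA = NUCR + DNAR = w).
The per-window scores estimate the corresponding log-odds:

    IS = log2(DNA/NUC)          → log2(p / (1 − p))
    RS = log2(DNAR/NUCR) − IS   → log2((p + (1 − p)r) / (p(1 − r)))

IS is monotone in p. RS increases with r at fixed p, but also depends
on p (for nearly-certainly-unstable nucleosomes there is nothing left
for the remodeler to reveal); moreover the subtracted IS contributes
its sampling noise with a negative sign, so IS and RS are
anticorrelated on null data. Both behaviours are properties of the
score definitions, not artifacts, and the test suite asserts them.

## Pipeline stages and their order

1. **Tiling and counting.** 167-bp windows every 25 bp; trailing
   partial windows are dropped so width (and hence GC and counts) is
   constant. A fragment increments every window containing its
   midpoint floor((start+end)/2). With this geometry an interior
   midpoint lies in 7 windows when its 25-bp grid phase is below
   167 mod 25 = 17, else 6. Midpoint assignment (rather than
   any-overlap) keeps one "position" per ~167-bp fragment; any-overlap
   would smear each fragment over ~13 windows and flatten the ratios.
2. **Coverage filter on raw counts.** A window is dropped for the IS
   when DNA + NUC < 5 reads in replicate 1 *and* in replicate 2;
   analogously for the RS with DNAR + NUCR. The filter is stated on
   reads, so it precedes any rescaling.
3. **GC correction, per sample.** Windows are split into 20
   equal-occupancy GC bins; counts in bin b are scaled by
   (median of per-bin medians)/(median of bin b), medians over windows
   with positive counts. This removes the monotone count–GC
   confounding introduced by library preparation while touching
   nothing else; a lowess-on-log-counts variant (`gc_method: loess`)
   is provided as a cross-check. With integer counts near ~25 the
   binned medians are quantized, so the residual |Spearman ρ| between
   corrected counts and GC is bounded by a few hundredths rather than
   zero; the acceptance suite requires < 0.05 over ~10,000 windows.
4. **Size factors.** Median-of-ratios across all eight samples,
   restricted to windows positive in every sample, rescaled to
   geometric mean one. This reimplements the count-package estimator
   as a plain, documented computation: the scores are log-ratios, so
   dispersion shrinkage has no role here, and scale invariance
   (multiplying one library by a constant changes nothing) is exact.
5. **Scores.** Per replicate, log2((num + c)/(den + c)) with
   pseudocount c = 0.5, averaged over the two replicates; RS subtracts
   the window's IS and is therefore only defined where both filters
   pass.
6. **Percentiles and regions.** Windows are ranked per score (ties
   broken by genomic coordinate so binning is deterministic) and cut
   at 0/10/25/50/75/90/95/99/100 percent. Same-bin windows that
   overlap or touch end-to-start are merged to maximal regions
   (`merge_bookended: false` restricts merging to strict overlap).
7. **Annotation.** The operational NFR is 250–50 bp upstream of the
   TSS in transcription direction (minus-strand genes: [tss+50,
   tss+250)); the promoter is the 250 bp upstream of the TSS. Scores
   are projected onto the 25-bp step grid (each grid bin averaging the
   windows that cover its start) for TSS metaprofiles, which average
   the track over genes in transcription direction within ±1 kb in
   25-bp offset bins. Mean-centered profiles subtract the genome-wide
   track mean; when two strata of the same track are compared (H2AZ+
   vs H2AZ−) both strata subtract the *full* track's mean so they
   share a zero — per-stratum centering would shift the two profiles
   against each other by the difference of the strata means.
8. **H2AZ stratification.** Elements (windows or grid bins) are
   labeled H2AZ+ when their mean H2AZ density is strictly above the
   70th percentile of element values, H2AZ− strictly below the 30th.
   Strict inequalities mean a constant track classifies nothing.
9. **Tests.** Group comparisons use the Wilcoxon rank-sum
   (Mann–Whitney U) test: exact enumeration for tie-free samples with
   n_a + n_b ≤ 12, otherwise the normal approximation with midranks,
   tie correction and continuity correction (delegated to
   `scipy.stats.mannwhitneyu`). The per-gene remodeling summary used
   for target-gene enrichment is the maximum RS over windows whose
   midpoint lies within ±250 bp of the TSS — the most remodeled
   promoter/TSS window of the gene.

## The simulator

The generator emulates exactly the statistical structure the scoring
assumes, so that every pipeline property can be tested against known
truth without any download.

* **Genome**: i.i.d. bases with P(G or C) following a sinusoidal wave
  (default 0.5 ± 0.15, period 10 kb), giving the GC correction real
  structure to remove.
* **Annotation**: genes laid out left to right with 600-bp intergenic
  gaps, random strands, tRNAs (75 bp) interleaved among mRNAs
  (1200 bp). Nucleosomes are placed non-overlapping at 165–200 bp
  dyad spacing with Gamma(20) occupancy (mean 1, CV ≈ 0.22).
* **Planted parameters**: base p_unstable ~ U(0.08, 0.40) and
  r_remodel ~ U(0.02, 0.80), independent. These ranges were chosen by
  a closed-form design analysis of the expected scores: IS must vary
  enough in p for rank recovery, while RS's residual p-dependence must
  stay small relative to its r-signal; at assay depth 50 both
  rank-correlations exceed 0.8 with margin. Effects are additive on
  the probabilities: +0.35 p for nucleosomes overlapping tRNA bodies,
  +0.20 p for promoter (NFR-proximal) nucleosomes, and +0.30 r for
  H2AZ-flagged TSS-proximal nucleosomes — at the design means a ~1.5
  log2-unit shift of the expected DNAR/NUCR ratio. 60% of
  TSS-proximal nucleosomes (dyad within ±150 bp of an mRNA TSS) are
  flagged H2AZ; the H2AZ track gives their footprints density 5–10
  versus 0.1–2 for other nucleosomes over a 0.05 baseline.
* **Libraries**: band counts are Poisson around depth × occupancy ×
  band weight per replicate (`overdispersion` switches to
  Gamma–Poisson to probe robustness); fragment lengths are truncated
  normal (167 ± 15, clipped to [100, 250] — lengths are homogeneous
  across bands, as in the assay); starts are dyad-centered with
  ±10 bp jitter; finally fragments are thinned with acceptance weight
  exp(gc_beta·(gc − 0.5)), the multiplicative GC bias the pipeline
  must undo. Everything is deterministic per seed, with named
  substreams per stage.

What the simulator does **not** model: MNase sequence preference,
band-specific fragment lengths, alignment error, overlapping or fuzzy
nucleosome positioning, chromosome-end read loss, and any correlation
between instability and remodeling beyond what the score definitions
impose. Passing tests therefore show that the *computations* are
correct and well calibrated under the assay's own assumptions — not
that those assumptions hold for any particular real dataset.

## Problem sizes and defaults

Simulated checks run on 2 × 100 kb genomes (~8,000 windows, ~1,100
nucleosomes, ~170,000 fragments) at depth 50 per nucleosome per band
pair — small enough for a laptop, large enough that the percentile
machinery, the GC fit and the metaprofiles operate in their intended
regime. `PipelineConfig` centralizes every constant: window geometry
(167/25), read filter (5), percentile edges, NFR bounds (250/50),
H2AZ percentiles (30/30), tract minimum (5 bp, homopolymer A-runs or
T-runs; `tract_mixed_at` accepts mixed A/T runs instead), metaprofile
grid (±1000/25), pseudocount (0.5), GC bins (20).

## Known limitations

* The binned-median GC correction leaves a small residual count–GC
  association within bins (bounded, see above); the loess variant is
  smoother but nondeterministic in ranking edge cases and slower.
* RS is not a pure function of r: genes whose promoters carry planted
  instability depress nearby RS, which is visible as a TSS dip in
  effect-free simulations.
* One TSS per gene is taken as input; resolving multiple annotated
  TSSs is out of scope.
* Real aligned data enters as BED intervals; BAM conversion is left to
  upstream tools.
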