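# Methods

## Problem and model

Multiple displacement amplification (MDA) with phi29 polymerase turns
nanograms of genomic DNA into micrograms, but the product is not a perfect
copy: amplification efficiency varies along the genome.  `wgaqc` implements
the evaluation framework used to characterize that variation for two
commercial MDA kits (REPLI-g, GenomiPhi) on three human DNA samples: each
sample is amplified four times per kit and co-hybridized with its unamplified
template on a two-channel CGH array, with four self-self hybridizations of
unamplified DNA defining the technical noise floor (28 arrays in all).

Per probe, the statistic is the log2 ratio of test to reference intensity.
The analysis chain is:

1. **Normalization** — one global multiplicative factor on the test channel,
   equivalent to median-centering the log2 ratios.  This is a deliberate
   stand-in for a generic "linear" dye-bias correction; no spatial or
   intensity-dependent (loess) correction is attempted.
2. **DLRS** — the derivative log ratio spread estimates per-probe noise as
   IQR(within-chromosome consecutive differences) / (1.349·√2).  The
   quantity is standard but the estimator is not canonically fixed; the
   IQR-based form was chosen for robustness to the occasional true
   change-point in the difference sequence, and is calibrated so iid
   Gaussian noise of sd σ yields σ.
3. **CBS** — circular binary segmentation partitions each chromosome into
   constant-mean segments.  The statistic is the standardized
   mean-difference (t-like) comparison of every circular arc against its
   complement; the maximizing arc is kept when a within-segment permutation
   test rejects at level α, and its endpoints recurse.  Defaults: α = 0.01,
   1,000 permutations (200 in the study driver), minimum arc width 2, and an
   "undo" pass that re-merges adjacent segments whose means differ by less
   than 1.0 × the chromosome's robust noise sd.  Arcs are enumerated
   exhaustively up to 5,000 probes per segment (far above any profile used
   here) and randomly sampled above that; ties in the maximizing arc break
   toward the shortest, then leftmost arc so results are reproducible.
   Permutation loops stop early once significance has become impossible,
   which leaves the accept/reject decision unchanged.
4. **CNV calls** — after replacing each probe by its segment mean, a probe
   is "changed" when its direction-agnostic fold change 2^|r| exceeds 2.0;
   segments within 2-fold are unchanged.
5. **Consistency statistics** — the Kolmogorov distance between two arrays
   is the two-sample KS statistic sup|ECDF₁ − ECDF₂| of their ratio
   distributions (right-continuous ECDFs, supremum over pooled sample
   points; no p-value).  The Phi correlation of two binary CNV-location
   vectors is the Pearson correlation computed from the 2×2 agreement
   table.  Within-group matrices summarize the 6 unique pairs of 4
   replicates; between-group matrices all 16 ordered cells; both are
   reported with their median (midpoint of central order statistics for
   even counts).
6. **Regions** — aberrations are maximal runs of ≥ 3 consecutive probes
   beyond 3-fold in a consistent direction, computed on the quality-weighted
   (1/DLRS², equal weights if any DLRS is 0) combination of the four
   replicates.  Consistently under-amplified loci are the base-pair
   intersection of every group's loss regions; they are summarized as a
   genome fraction and by GC content (G+C over unambiguous bases, pooled
   across regions so the mean is length-weighted).
7. **qPCR** — comparative-Ct copy number CN = 2 · E^−ΔΔCt against a
   reference assay and the unamplified calibrator, with efficiency E = 2
   (perfect doubling) by default.  Replicates are combined on the CN scale
   (mean with min/max bars) and flagged when any replicate deviates from the
   calibrator by more than 2-fold.
8. **Fidelity** — bidirectional base calls are compared per position against
   the unamplified reference with a fixed precedence: no-call ('N' on either
   strand) before strand discordance before mutation (both strands
   concordantly differ from the reference).  The classes are exhaustive and
   mutually exclusive.  With zero mutations in N examined bases the rate is
   bounded as 1/N ("fewer than one per N"); the rule-of-three bound 3/N (an
   exact one-sided 95% binomial bound for zero events) is also emitted.

## Conventions

All genomic intervals are 0-based, half-open (BED-native).  The single
exception is the sequencing primer table, whose coordinates follow the
1-based inclusive convention of such panels, so an amplicon spans
`rev_end − fwd_start + 1` bp.  Ratios-vs-cutoff tables are direction-agnostic
(2^|r| > k) because over- and under-amplification are counted together;
a one-sided variant is available.  Threshold tables are computed on raw
per-probe ratios; Phi correlations on CBS-smoothed calls.  Both choices are
configurable.

Phi degeneracy: two identical call vectors — including two all-zero vectors,
i.e. two arrays agreeing that nothing is changed — return 1.0; differing
vectors with a degenerate marginal return 0.0 with a warning.

## Synthetic data: what it emulates, and what it does not

The generator exists so the whole pipeline is exercised end to end without
the original arrays (which were never deposited).  It emulates:

* probe layouts at 1–2 kb spacing, GC computed exactly from the emitted
  sequence (a two-state strong/weak Markov chain with block-varying GC
  target, so GC-rich blocks exist);
* MDA bias as a linear model on the log2 scale: a GC coefficient acting on
  probe GC deviation from the genome mean, an exponential depression
  max·exp(−d/λ) near chromosome ends, injected constant-shift CNV segments,
  and iid Gaussian probe noise.  Self-self arrays use noise sd 0.165 — the
  published DLRS of the real self-self hybridizations.  Kit presets
  (REPLI-g: noise 0.40, GC −1.2, end depression 1.6; GenomiPhi: noise 0.48,
  GC −1.8, end depression 2.0; λ = 8 kb) were chosen once to reproduce the
  published *orderings* — GenomiPhi shows more CNV than REPLI-g, within-group
  distances are far below amplified-vs-unamplified distances, and recovered
  under-amplified regions are GC-richer than the genome — not the absolute
  array-level values;
* qPCR Ct tables with Ct_target = reference level − log_E(CN/2) plus
  Gaussian cycle noise (copy number 0 reports the 40-cycle ceiling);
* pre-aligned bidirectional reads with disjoint injected mutation, no-call
  and discordant position sets.

It does **not** emulate intensity-dependent dye bias, spatial array
artifacts, probe-sequence effects beyond GC, correlated (wavy) baseline
noise, segmental duplications, or real CNV genotypes of the donors.  Passing
tests therefore demonstrate correctness of the statistics and the pipeline's
qualitative behavior under MDA-like bias, not quantitative reproduction of
any particular array.

Reproducibility: one root seed; every replicate/stage derives its stream as
`SeedSequence([root, crc32(labels)])`, so outputs are byte-identical across
runs and platforms for a fixed config and seed.

## Problem sizes

The default study driver uses a 3 × 400 kb genome (~800 probes per array, 28
arrays) and 200 CBS permutations — the package's desk-scale rendition of the
~970,000-probe design, chosen so a full run completes in about a minute.
Injected under-amplified windows are 16 kb (≥ 10 probes), the regime in
which per-group 3-fold detection is reliable; the published common regions
span 86–1,500 probes, so this is the conservative end of the real scale.
The test suite uses further-reduced genomes with the same presets.

## Known limitations

* The CBS variant and parameters behind the original analysis (a commercial
  workbench) are unpublished; only qualitative agreement is possible, and
  the implementation is validated against an exhaustive-arc oracle instead.
* The replicate quality weights of the original software are unstated;
  1/DLRS² is this package's stand-in.
* Whether the published cutoff-table percentages were computed on raw or
  smoothed ratios is unstated; raw is the default here and both are
  supported.
* One published within-group median (CF1/REPLI-g, printed 0.085) is not the
  median of its own printed cells (0.0635 under any midpoint convention);
  the implementation follows the convention that reproduces the other seven
  blocks.
* The aligner utility in the fidelity module handles offset reads, but
  chromatogram parsing, base-quality modeling and heterozygote calling are
  out of scope.
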