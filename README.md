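# wgaqc — uniformity and fidelity assessment of whole-genome-amplified DNA

Whole-genome amplification (WGA) by multiple displacement amplification
(MDA, phi29 polymerase) expands nanogram DNA samples to the microgram
quantities that genotyping assays and reference materials require — but the
amplified product is not a perfect copy.  `wgaqc` implements, as a tested
pipeline, the evaluation framework used to characterize MDA uniformity and
fidelity with two-channel array CGH, qPCR copy-number assays and
bidirectional Sanger sequencing, together with a seed-reproducible synthetic
data generator that emulates MDA bias so every stage runs without real
arrays.

It is aimed at people qualifying WGA DNA for downstream assays and at anyone
needing the building blocks: per-probe log2 ratios r = log2(T/R) with
median-centering normalization; the derivative log ratio spread
DLRS = IQR(Δr)/(1.349·√2) as a per-array noise estimate; circular binary
segmentation (CBS) with permutation significance and segment-mean smoothing;
binary CNV calls at 2^|r| > 2; the two-sample Kolmogorov distance
D = sup|F̂₁ − F̂₂| between ratio distributions; the Phi correlation
φ = (n₁₁n₀₀ − n₁₀n₀₁)/√(n₁·n₀·n·₁n·₀) between CNV-location vectors;
≥3-probe aberration runs beyond 3-fold and their cross-sample intersection
with GC summaries; comparative-Ct copy number CN = 2·2^−ΔΔCt; and
per-position bidirectional base-call concordance with no-call/discordance
exclusion rules.

## Worked example

Run the full study design — 3 samples × 2 kits × 4 replicates plus 4
self-self hybridizations on a desk-scale synthetic genome — and collect the
headline statistics:

```python
from wgaqc.workflow import StudyConfig, run_study

result = run_study(StudyConfig(), seed=1)
med = result["medians"]
print(round(med[("ks_within", "Normal", "REPLI-g")], 3))     # 0.033
print(round(med[("ks_vs_selfself", "Normal", "REPLI-g")], 3))# 0.312
print(round(med[("phi_within", "Normal", "REPLI-g")], 3))    # 0.903
rs = result["region_summary"]
print(rs["n_regions"], round(100 * rs["region_mean_gc"], 1),
      round(100 * rs["genome_mean_gc"], 1))                  # 3 53.8 40.9
```

Reading: replicates of the same amplification agree closely (within-group
Kolmogorov distance ≈ 0.03) while amplification changes the ratio
distribution markedly (amplified vs self-self ≈ 0.3), yet the *locations* of
the changes are reproducible (Phi ≈ 0.9) — uniform bias, consistently
placed.  The loci consistently under-amplified by >3-fold across all six
sample/kit groups are GC-rich (≈54% GC against a ≈41% genome), the
hallmark of MDA's GC-dependent under-amplification.

The same stages are scriptable from the shell — `wgaqc simulate`, `wgaqc
segment`, `wgaqc uniformity`, `wgaqc regions`, `wgaqc qpcr`, `wgaqc
fidelity`, and `wgaqc study --config study.yaml --seed 1 --out bundle/` —
with user data entering at any stage via plain TSV/BED/FASTA files.

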