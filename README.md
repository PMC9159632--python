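# mucoquant

Quantitative analysis of **mucocyst docking and tip-polarized protein
localization** from two-channel fluorescence micrographs, and
**pooled-segregant mapping of causal mutations** (bulk segregant analysis /
mapping-by-sequencing) — implemented as a tested, reusable Python library
with synthetic-data generators that carry full ground truth.

Mucocysts are elongated secretory organelles of the ciliate *Tetrahymena
thermophila* that dock in regular rows beneath the plasma membrane.  Two
recurring questions in this system are (i) whether a protein of interest
decorates the organelle uniformly or concentrates at one **tip**, and
whether organelles **dock** at the cell periphery at all; and (ii) which
mutation causes a docking/secretion defect, identified by sequencing pools
of phenotype-selected F2 segregant clones.

## What it computes

**Image analysis** (channels: `grl` marks the organelle body, `mdl` the
candidate tip protein):

- adaptive-threshold segmentation with morphological cleanup and
  moment-based ellipse fits (centroid, full axis lengths, orientation);
- object-based **colocalization**: the fraction of Mdl features overlapping
  a Grl feature, against a null built by randomly translocating Mdl
  features within the cell mask;
- **tip polarity**: for each overlapping pair, the acute angle θ ∈ [0°, 90°]
  between the organelle's major axis and the centroid-connecting segment,
  and the normalized offset d = ‖c_mdl − c_grl‖ / (L_major/2), so a punctum
  at the tip scores 1.  Nulls re-place the punctum uniformly inside the
  fitted ellipse; observed vs. null samples are compared with the
  two-sample Kolmogorov–Smirnov test
  (D = sup_x |F̂₁(x) − F̂₂(x)|, asymptotic p at √(n₁n₂/(n₁+n₂))·D);
- **docking**: the peripheral fraction of Grl intensity (band = cell mask
  minus its erosion), compared across strains with single-factor ANOVA.

**Genetic mapping**: from a two-sample pooled VCF (`MUT`, `WT`; per-pool
`DP`/`AD`), each site is scored with the allelic contrast
Δ = alt_MUT/depth_MUT − alt_WT/depth_WT, coverage-filtered (default ≥ 100×
in both pools), smoothed per chromosome (200 kb windows), normalized to a
genome-wide maximum of 1, scanned for the peak region (longest run at
≥ 90% of the maximum), and refiltered for candidates in which the mutant
pool — but not the wildtype pool — looks homozygous (alt frequency ≥ 0.9 at
≥ 5× depth), ranked by SnpEff-style impact category.

The `synthetic_data` module generates both input types with known ground
truth: docked or cytoplasmic organelle images with a configurable tip bias
β ∈ [0, 1], and F2 whole-genome-homozygote segregant pools (32 clones/pool,
~90× depth) with one planted causal variant and Haldane-model linkage.

## Worked example

Simulate a tip-biased cell image (β = 0.9) and test tip polarity:

```console
$ mucoquant simulate-image --out cell.tif --truth truth.csv --seed 1
wrote cell.tif (512x512, 25 mucocysts)
$ mucoquant tipstats cell.tif --mdl-sensitivity 0.4 -R 1000 --out-summary summary.csv
 n_pairs  n_angle_excluded  angle_D      angle_p  offset_D     offset_p
      25                 0  0.81264 9.447227e-15   0.94904 5.789187e-20
```

All 25 puncta pair with an organelle; the observed angles pile up near 0°
and the offsets near 0.9, so both KS statistics are far above the
uniform-within-organelle null and the p-values are vanishing — the planted
tip bias is detected.

Simulate a segregant cross and map the planted mutation:

```console
$ mucoquant simulate-cross --out pools.vcf --seed 1
wrote pools.vcf: 5001 sites, causal at chr4:5364873
$ mucoquant bsamap pools.vcf --out-candidates candidates.tsv
peak region chr4:500000-9000000 (852 candidate variants)
top candidate chr4:5364873 T>C impact=HIGH contrast=1.000
```

The linkage track peaks on the causal chromosome; the peak region is broad
(a few megabases — with 32 clones per pool the signal has a flat top
between the nearest recombination breakpoints), and impact-aware ranking
puts the planted variant first.

Every subcommand (`segment`, `coloc`, `tipstats`, `docking`, `bsamap`,
`coexpr`, and the two simulators) is a thin wrapper over library functions
in `mucoquant.*`; see the module docstrings for the API.

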