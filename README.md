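# periscope

Quantitative tools for two recurring questions in nuclear-organization
studies:

1. **Where does a fluorescent signal sit inside the nucleus?** Peripheral
   heterochromatin marks such as H3K9me2 concentrate under the nuclear
   lamina; `periscope` quantifies this by radial profiling — from each
   nucleus centroid, 200 line scans are drawn to the nuclear boundary,
   each divided into 200 points, and the mean intensity I(f) is reported
   as a function of normalized radius f ∈ [0, 1], with center
   (f < 0.25) versus periphery (f ≥ 0.75) mean-fluorescence-intensity
   (MFI) summaries and cohort aggregation (mean ± SD).
2. **Do two chromatin factors occupy the same megabase-scale territory?**
   For two ChIP-seq peak sets (e.g. a methyltransferase and lamin B1),
   peaks are counted in 1-Mb windows; each window's observed/expected
   ratio is computed per chromosome (expected = chromosome total ÷ number
   of windows), windows above 1.5-fold are flagged, and the association
   between the two factors' ratio tracks is tested with a seeded
   permutation correlation (Spearman by default):
   p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + N). Peak-level summaries —
   co-bound counts (two-set Venn), upstream/exon/intron/others
   classification, and TSS composite profiles — round out the genomic
   side.

A synthetic-data generator plants known ground truth for both pipelines
(elliptical nuclei with a parameterized peripheral ring; Poisson peak
counts with planted window enrichment and a tunable coupling ρ between
factors), so every stage is verifiable without raw study data. See
`docs/methods.md` for the model details and verification scales.

## Worked example

Simulate a cohort of 20 nuclei with a planted 4-fold peripheral ring and
profile them:

```sh
periscope simulate-nuclei --n 20 --ring-contrast 4 --seed 1 --outdir sim/
periscope profile --image sim/nuclei.tif --mask sim/nuclei_mask.png --out sim/prof
```

`sim/prof_mfi.tsv` then contains one row per nucleus; the cohort mean
peripheral enrichment recovers the planted contrast (this run:
`peripheral_enrichment` mean 3.90 against a planted 4.0, i.e. within 3%).

Simulate two coupled peak sets on a 500-Mb toy genome and run the window
analysis:

```sh
printf 'chr1\t500000000\n' > genome.chrom.sizes
periscope simulate-peaks --genome genome.chrom.sizes --lambda 10 --mult 8 \
    --frac-enriched 0.2 --coupling 0.8 --seed 1 --out-a a.bed --out-b b.bed
periscope windows --genome genome.chrom.sizes --peaks-a a.bed --peaks-b b.bed \
    --n-perm 10000 --seed 1 --outdir win/
```

which prints:

```
wrote 12125 + 11798 peaks
r = 0.3860, permutation p = 1.00e-04 (500 windows)
```

— the planted co-enrichment (80% of A's 8-fold windows shared with B) is
detected at p = 1/(N+1), the resolution floor of 10,000 permutations and
well below the 0.001 level; `win/` holds the per-window
count/expected/ratio/flag tables, bedGraph ratio tracks and the
correlation record. `periscope overlap`, `periscope annotate` and
`periscope tss-profile` cover the peak-level summaries.

The numbered scripts under `analysis/` run the same pipeline as a
narrative — simulate cohorts at contrasts {1, 2, 4, 8}, profile them,
simulate coupled peak sets, and analyze windows and peak annotations —
writing tables under `results/` (large binaries under `scratch/`).

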