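#!/usr/bin/env python
"""Peak-level summaries: co-bound Venn, genomic classification, TSS composite.

On the simulated peak sets plus a synthetic gene annotation: how many peaks
of each factor are co-bound (>= 1 bp overlap with the other factor's
peaks), where peak midpoints fall relative to genes (upstream / exon /
intron / others), and how peak density distributes around TSSs.
"""

from pathlib import Path

from periscope import io
from periscope.annotation import classify_peaks, tss_composite
from periscope.genome import GenomeModel
from periscope.overlap import cobound
from periscope.simulate import make_annotation
from periscope.windows import PeakSet

SEED = 20260927
results = Path("results")

genome = GenomeModel.read_chrom_sizes(results / "genome.chrom.sizes")
peaks_a = PeakSet.read_bed(results / "peaks_a.bed", name="factor_a")
peaks_b = PeakSet.read_bed(results / "peaks_b.bed", name="factor_b")

res = cobound(peaks_a, peaks_b, min_overlap_bp=1)
io.atomic_write(results / "cobound.tsv", res.write_tsv)
print(f"A: {res.n_a} peaks ({res.cobound_a} co-bound, {res.unique_a} unique); "
      f"B: {res.n_b} peaks ({res.cobound_b} co-bound, {res.unique_b} unique); "
      f"{res.cobound_regions} co-occupied regions")

annotation = make_annotation(genome, n_genes=2_000, seed=SEED)
annotation.write_bed12(results / "genes.bed12")
for peaks in (peaks_a, peaks_b):
    table = classify_peaks(peaks, annotation)
    io.write_tsv(results / f"classification_{peaks.name}.tsv", table)
    fr = table.set_index("category")["fraction"]
    print(f"{peaks.name}: " + ", ".join(f"{c} {100 * fr[c]:.1f}%" for c in fr.index))
    comp = tss_composite(peaks, annotation, flank=5_000, bin=100)
    io.atomic_write(results / f"tss_composite_{peaks.name}.tsv", comp.write_tsv)
    print(f"  TSS composite: {comp.n_tss} TSSs, "
          f"{int(comp.profile['count'].sum())} midpoints within ±5 kb")
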