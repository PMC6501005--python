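#!/usr/bin/env python
"""Profile the synthetic cohorts: center-to-periphery curves and MFI recovery.

Reads the cohort images written by 01_simulate_nuclei.py (regenerating them
if absent), runs the 200-ray x 200-point radial profiler on every nucleus,
aggregates per cohort, and compares recovered peripheral enrichment
(periphery MFI / center MFI) with the planted ring contrast.
"""

from pathlib import Path

import pandas as pd

from periscope import io
from periscope.radial import (
    aggregate_profiles,
    aggregate_to_frame,
    compare_conditions,
    radial_scan,
    records_from_labels,
)
from periscope.simulate import make_nucleus_cohort

CONTRASTS = [1.0, 2.0, 4.0, 8.0]
SEED = 20260927

results = Path("results")
scratch = Path("scratch/nuclei")
results.mkdir(exist_ok=True)

aggregates = []
for i, contrast in enumerate(CONTRASTS):
    tag = f"contrast{contrast:g}"
    img_path = scratch / f"nuclei_{tag}.tif"
    if img_path.exists():
        image = io.read_image(img_path)
        labels = io.read_mask(scratch / f"nuclei_{tag}_mask.png")
    else:
        image, labels, _ = make_nucleus_cohort(
            20, ring_contrast=contrast, noise_sd=10.0, seed=SEED + i
        )
    records = records_from_labels(image, labels)
    profiles = [radial_scan(rec) for rec in records]
    agg = aggregate_profiles(profiles)
    aggregates.append((tag, agg))
    io.write_tsv(results / f"radial_aggregate_{tag}.tsv", aggregate_to_frame(agg))

curves, summaries = compare_conditions(aggregates)
summaries["planted_contrast"] = CONTRASTS
io.write_tsv(results / "radial_mfi_summary.tsv", summaries)
io.write_tsv(results / "radial_curves_long.tsv", curves)

print(summaries[["condition", "n_nuclei", "center_mfi", "periphery_mfi",
                 "peripheral_enrichment", "planted_contrast"]].to_string(index=False))
rec = summaries["peripheral_enrichment"]
print(f"\nrecovered enrichment is strictly increasing with planted contrast: "
      f"{bool(rec.is_monotonic_increasing)}")
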