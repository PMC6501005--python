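"""Self-calibration experiments on synthetic data.

Each function runs one end-to-end check of a pipeline property against
ground truth or an independent brute-force oracle — flat-field identity and
parameter recovery for the radial profiler, count conservation, null
calibration and planted-coupling power for the window analysis — and
returns the measured quantities. They are used by the test suite and by
the reproduction script; none of them fixes thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .genome import GenomeModel
from .overlap import cobound
from .radial import NucleusRecord, aggregate_profiles, mfi_summary, radial_scan, records_from_labels
from .simulate import NucleusSimParams, PeakSimParams, make_nucleus_cohort, make_nucleus_image, make_peak_sets
from .simulate.nuclei import elliptical_radius
from .windows import PeakSet, count_peaks_in_windows, enrichment_ratio, tile_windows, window_correlation


def _record_from_params(params: NucleusSimParams) -> tuple[NucleusRecord, dict]:
    image, mask, truth = make_nucleus_image(params)
    centroid = ndimage.center_of_mass(mask)
    return NucleusRecord(1, image, mask, centroid), truth


# ---------------------------------------------------------------------------
# radial profiler


def flat_field_deviation(constant: float = 150.0) -> float:
    """Worst fractional deviation of the profile from a constant input.

    Profiles constant-intensity nuclei of several mask shapes (circle,
    rotated ellipses, and a non-elliptical two-lobed blob) and returns the
    maximum |profile − constant| / constant over all radius points except
    the 2 outermost.
    """
    records = []
    for semi_axes, rot in [((45.0, 45.0), 0.0), ((60.0, 40.0), 0.0), ((55.0, 35.0), 0.7)]:
        rec, _ = _record_from_params(
            NucleusSimParams(
                semi_axes=semi_axes, rotation=rot, ring_contrast=1.0,
                base_intensity=constant, noise_sd=0.0,
            )
        )
        records.append(rec)
    # two-lobed blob: union of overlapping disks
    rr, cc = np.mgrid[0:160, 0:160]
    blob = ((rr - 80) ** 2 + (cc - 65) ** 2 <= 40**2) | (
        (rr - 80) ** 2 + (cc - 105) ** 2 <= 32**2
    )
    records.append(
        NucleusRecord(9, np.where(blob, constant, 0.0), blob, ndimage.center_of_mass(blob))
    )
    worst = 0.0
    for rec in records:
        prof = radial_scan(rec)
        dev = np.abs(prof.mean_intensity[:-2] - constant) / constant
        worst = max(worst, float(dev.max()))
    return worst


def radial_binning_profile(
    image: np.ndarray, truth: dict, n_points: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force per-pixel radial binning oracle.

    Bins every pixel of the planted ellipse by its ground-truth normalized
    radius (nearest of ``n_points`` grid values) and averages intensity per
    bin — no ray geometry, no interpolation.
    """
    r = elliptical_radius(
        image.shape,
        (truth["center_row"], truth["center_col"]),
        (truth["semi_a"], truth["semi_b"]),
        truth["rotation"],
    )
    mask = r <= 1.0
    idx = np.clip(np.rint(r[mask] * (n_points - 1)).astype(int), 0, n_points - 1)
    counts = np.bincount(idx, minlength=n_points)
    sums = np.bincount(idx, weights=image[mask], minlength=n_points)
    profile = np.full(n_points, np.nan)
    nz = counts > 0
    profile[nz] = sums[nz] / counts[nz]
    return np.linspace(0.0, 1.0, n_points), profile


def profiler_oracle_rms(contrasts=(1.0, 2.0, 4.0, 8.0)) -> float:
    """Worst relative RMS between ray profiles and the binning oracle.

    Noiseless nuclei at generator defaults, one per planted contrast; RMS
    over radius fractions in [0.05, 0.95], relative to the oracle mean.
    """
    worst = 0.0
    for contrast in contrasts:
        rec, truth = _record_from_params(
            NucleusSimParams(ring_contrast=contrast, noise_sd=0.0, semi_axes=(60.0, 45.0))
        )
        prof = radial_scan(rec)
        f, oracle = radial_binning_profile(rec.intensity, truth)
        sel = (f >= 0.05) & (f <= 0.95) & np.isfinite(oracle)
        rms = np.sqrt(np.mean((prof.mean_intensity[sel] - oracle[sel]) ** 2))
        worst = max(worst, float(rms / oracle[sel].mean()))
    return worst


def enrichment_recovery(
    seed: int = 0,
    contrasts=(1.0, 2.0, 4.0, 8.0),
    n_nuclei: int = 20,
    noise_frac: float = 0.1,
    base_intensity: float = 100.0,
) -> pd.DataFrame:
    """Recover planted peripheral ring contrast from synthetic cohorts.

    For each contrast level, profiles a cohort of ``n_nuclei`` noisy nuclei
    (noise SD = ``noise_frac`` × base) and one noiseless nucleus, and
    reports the cohort-mean peripheral enrichment plus the noiseless
    recovery's relative error against the planted contrast.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for contrast in contrasts:
        image, labels, _ = make_nucleus_cohort(
            n_nuclei,
            image_size=(1024, 1024),
            base_intensity=base_intensity,
            ring_contrast=contrast,
            noise_sd=noise_frac * base_intensity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        records = records_from_labels(image, labels)
        agg = aggregate_profiles([radial_scan(r) for r in records])
        cohort_enrichment = mfi_summary(agg).peripheral_enrichment
        rec, _ = _record_from_params(
            NucleusSimParams(
                ring_contrast=contrast, noise_sd=0.0, base_intensity=base_intensity
            )
        )
        clean = mfi_summary(radial_scan(rec)).peripheral_enrichment
        rows.append(
            {
                "planted_contrast": contrast,
                "n_nuclei": len(records),
                "cohort_enrichment": cohort_enrichment,
                "noiseless_enrichment": clean,
                "noiseless_rel_error": abs(clean - contrast) / contrast,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# window analysis


def window_conservation(seed: int = 0, n_fixtures: int = 100) -> dict:
    """Count conservation and per-chromosome ratio normalization.

    Random peak fixtures (including window-boundary-crossing peaks) on a
    two-chromosome genome; returns the worst |Σ window counts − n peaks|
    (must be 0) and the worst |mean chromosome ratio − 1|.
    """
    genome = GenomeModel.from_dict({"chr1": 23_000_000, "chr2": 11_500_000})
    grid = tile_windows(genome)
    rng = np.random.default_rng(seed)
    worst_count_err = 0
    worst_ratio_dev = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(1, 400))
        chroms = np.where(rng.random(n) < 0.67, "chr1", "chr2")
        limits = np.where(chroms == "chr1", 23_000_000, 11_500_000)
        starts = (rng.random(n) * (limits - 1)).astype(np.int64)
        lengths = rng.integers(1, 2_000_000, size=n)  # many cross window edges
        ends = np.minimum(starts + lengths, limits)
        peaks = PeakSet.from_arrays("fixture", chroms, starts, ends)
        track = enrichment_ratio(count_peaks_in_windows(peaks, grid))
        worst_count_err = max(worst_count_err, abs(int(track.counts.sum()) - n))
        df = track.to_frame()
        for _, sub in df.groupby("chrom"):
            m = sub["ratio"].mean()
            if np.isfinite(m):
                worst_ratio_dev = max(worst_ratio_dev, abs(m - 1.0))
    return {"worst_count_error": worst_count_err, "worst_ratio_mean_dev": worst_ratio_dev}


def _brute_force_cobound_counts(a: PeakSet, b: PeakSet, min_overlap: int, span: int) -> tuple[int, int]:
    """Per-bp coverage oracle: overlap of each peak with the other set's union."""

    def count(src: PeakSet, other: PeakSet) -> int:
        n = 0
        cover: dict[str, np.ndarray] = {}
        for chrom, sub in other.df.groupby("chrom", sort=False):
            c = np.zeros(span, bool)
            for s, e in zip(sub["start"], sub["end"]):
                c[s:e] = True
            cover[chrom] = c
        for chrom, sub in src.df.groupby("chrom", sort=False):
            c = cover.get(chrom)
            if c is None:
                continue
            for s, e in zip(sub["start"], sub["end"]):
                if int(c[s:e].sum()) >= min_overlap:
                    n += 1
        return n

    return count(a, b), count(b, a)


def cobound_oracle_check(seed: int = 0, n_fixtures: int = 100, max_peaks: int = 200) -> int:
    """Number of random fixtures where sweep-line and brute force disagree."""
    rng = np.random.default_rng(seed)
    span = 3_000
    mismatches = 0
    for _ in range(n_fixtures):
        def random_set(name):
            n = int(rng.integers(1, max_peaks + 1))
            chroms = rng.choice(["chr1", "chr2"], size=n)
            starts = rng.integers(0, span - 150, size=n)
            lengths = rng.integers(1, 150, size=n)
            return PeakSet.from_arrays(name, chroms, starts, starts + lengths)

        a, b = random_set("a"), random_set("b")
        min_ov = int(rng.integers(1, 30))
        res = cobound(a, b, min_overlap_bp=min_ov)
        exp = _brute_force_cobound_counts(a, b, min_ov, span)
        if (res.cobound_a, res.cobound_b) != exp:
            mismatches += 1
    return mismatches


def null_flag_calibration(
    seed: int = 0, lam: float = 10.0, n_windows: int = 1000, n_replicates: int = 50
) -> dict:
    """Fraction of windows flagged >1.5-fold under the null vs the Poisson tail.

    With all multipliers 1, counts are Poisson(λ); a window is flagged when
    count / λ̂ > 1.5 with λ̂ the chromosome mean. Compares the empirical
    flag rate with the Poisson tail P(X > 1.5 λ̂) evaluated per replicate,
    in units of the Monte-Carlo standard error.
    """
    genome = GenomeModel.from_dict({"chr1": n_windows * 1_000_000})
    rng = np.random.default_rng(seed)
    flags = 0
    predicted = []
    for _ in range(n_replicates):
        params = PeakSimParams(base_rate=lam, enriched_fraction=0.0, coupling=0.0,
                               seed=int(rng.integers(0, 2**31 - 1)))
        peaks, _, _ = make_peak_sets(genome, params)
        track = enrichment_ratio(count_peaks_in_windows(peaks, tile_windows(genome)))
        flags += int(track.flag.sum())
        lam_hat = float(track.expected[0])
        predicted.append(float(stats.poisson.sf(1.5 * lam_hat, lam_hat)))
    n_total = n_windows * n_replicates
    rate = flags / n_total
    pred = float(np.mean(predicted))
    se = np.sqrt(max(pred * (1 - pred), 1e-12) / n_total)
    return {
        "flag_rate": rate,
        "predicted_tail": pred,
        "mc_se": float(se),
        "z": float((rate - pred) / se),
        "n_windows_total": n_total,
    }


def permutation_p_uniformity(
    seed: int = 0,
    lam: float = 10.0,
    n_windows: int = 200,
    n_replicates: int = 200,
    n_permutations: int = 999,
) -> dict:
    """KS test of permutation p-values against U(0,1) for independent tracks."""
    genome = GenomeModel.from_dict({"chr1": n_windows * 1_000_000})
    grid = tile_windows(genome)
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_replicates):
        params = PeakSimParams(base_rate=lam, enriched_fraction=0.0, coupling=0.0,
                               seed=int(rng.integers(0, 2**31 - 1)))
        peaks_a, peaks_b, _ = make_peak_sets(genome, params)
        ta = enrichment_ratio(count_peaks_in_windows(peaks_a, grid))
        tb = enrichment_ratio(count_peaks_in_windows(peaks_b, grid))
        res = window_correlation(ta, tb, n_permutations=n_permutations,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        pvals.append(res.p_value)
    ks = stats.kstest(pvals, "uniform")
    return {"ks_stat": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
            "n_replicates": n_replicates}


def coenrichment_power(
    seed: int = 0,
    n_replicates: int = 100,
    n_windows: int = 500,
    lam: float = 10.0,
    multiplier: float = 8.0,
    enriched_fraction: float = 0.2,
    coupling: float = 0.8,
    n_permutations: int = 1000,
    alpha: float = 0.001,
) -> dict:
    """Power of the permutation test under planted co-enrichment.

    Replicates the study-scale scenario: 20% of windows enriched 8-fold in
    factor A, 80% of those shared with factor B. Returns the fraction of
    replicates reaching p <= alpha and the median correlation.
    """
    genome = GenomeModel.from_dict({"chr1": n_windows * 1_000_000})
    grid = tile_windows(genome)
    rng = np.random.default_rng(seed)
    pvals, rvals, pearson_r = [], [], []
    for _ in range(n_replicates):
        params = PeakSimParams(
            base_rate=lam, enriched_fraction=enriched_fraction,
            enrichment_multiplier=multiplier, coupling=coupling,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        peaks_a, peaks_b, _ = make_peak_sets(genome, params)
        ta = enrichment_ratio(count_peaks_in_windows(peaks_a, grid))
        tb = enrichment_ratio(count_peaks_in_windows(peaks_b, grid))
        res = window_correlation(ta, tb, n_permutations=n_permutations,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        pvals.append(res.p_value)
        rvals.append(res.r)
        pearson_r.append(float(np.corrcoef(ta.ratio, tb.ratio)[0, 1]))
    pvals = np.array(pvals)
    return {
        "power": float(np.mean(pvals <= alpha)),
        "median_spearman_r": float(np.median(rvals)),
        "median_pearson_r": float(np.median(pearson_r)),
        "median_p": float(np.median(pvals)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# determinism


def determinism_check(workdir, seed: int = 0) -> int:
    """Run both CLI pipelines twice with identical seeds; count differing files.

    Each run executes in its own working directory with identical relative
    paths, so every output — data tables, BED files, images, run manifests —
    must be byte-identical between runs.
    """
    import contextlib
    from pathlib import Path

    from click.testing import CliRunner

    from .cli import main as cli_main

    workdir = Path(workdir).resolve()
    runner = CliRunner()
    outputs: list[dict[str, bytes]] = []
    for run in ("run1", "run2"):
        d = workdir / run
        d.mkdir()
        GenomeModel.from_dict({"chr1": 20_000_000, "chr2": 10_000_000}).write_chrom_sizes(
            d / "genome.chrom.sizes"
        )
        with contextlib.chdir(d):
            res = runner.invoke(cli_main, [
                "simulate-nuclei", "--n", "3", "--image-size", "384",
                "--seed", str(seed), "--outdir", "."])
            assert res.exit_code == 0, res.output
            res = runner.invoke(cli_main, [
                "profile", "--image", "nuclei.tif", "--mask", "nuclei_mask.png",
                "--n-lines", "100", "--n-points", "100", "--out", "prof"])
            assert res.exit_code == 0, res.output
            res = runner.invoke(cli_main, [
                "simulate-peaks", "--genome", "genome.chrom.sizes",
                "--seed", str(seed), "--out-a", "a.bed", "--out-b", "b.bed",
                "--out-truth", "truth.tsv"])
            assert res.exit_code == 0, res.output
            res = runner.invoke(cli_main, [
                "windows", "--genome", "genome.chrom.sizes",
                "--peaks-a", "a.bed", "--peaks-b", "b.bed",
                "--n-perm", "199", "--seed", str(seed), "--outdir", "win"])
            assert res.exit_code == 0, res.output
        outputs.append(
            {
                str(p.relative_to(d)): p.read_bytes()
                for p in sorted(d.rglob("*"))
                if p.is_file()
            }
        )
    assert outputs[0].keys() == outputs[1].keys()
    return sum(1 for k in outputs[0] if outputs[0][k] != outputs[1][k])
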