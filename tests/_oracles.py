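"""Independent brute-force oracles the implementation is checked against."""

from __future__ import annotations

import numpy as np

from periscope.simulate.nuclei import elliptical_radius


def radial_binning_profile(
    image: np.ndarray, truth: dict, n_points: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel radial binning profile from the planted ellipse geometry.

    Every mask pixel is assigned to the nearest of n_points normalized-radius
    bins (radius computed from the ground-truth ellipse, not from the
    profiler's ray geometry); the profile is the per-bin mean intensity.
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


def brute_force_cobound(peaks_a, peaks_b, min_overlap_bp: int = 1) -> tuple[int, int]:
    """O(n^2) co-bound counts: overlap of each peak with the other set's union."""

    def count(src, other) -> int:
        n = 0
        for _, p in src.df.iterrows():
            covered = set()
            for _, q in other.df.iterrows():
                if q["chrom"] != p["chrom"]:
                    continue
                lo = max(p["start"], q["start"])
                hi = min(p["end"], q["end"])
                if hi > lo:
                    covered.update(range(int(lo), int(hi)))
            if len(covered) >= min_overlap_bp:
                n += 1
        return n

    return count(peaks_a, peaks_b), count(peaks_b, peaks_a)
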