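"""Radial center-to-periphery nuclear fluorescence profiling.

Quantifies where a fluorescent signal (e.g. the heterochromatin mark
H3K9me2) sits inside each nucleus: from the nucleus centroid, 200 rays are
cast to the nuclear boundary, each ray is sampled at 200 evenly spaced
points of normalized radius, and the per-nucleus profile is the mean over
rays at each radius fraction. Cohort aggregation and center-vs-periphery
mean-fluorescence-intensity (MFI) summaries sit on top.

Conventions
-----------
* Ray k points at angle 2πk/n_lines, with angle 0 along the +column axis
  and angles increasing counter-clockwise (rows up).
* The ray endpoint is the LAST mask pixel along the ray from the centroid,
  so mildly non-convex nuclei are profiled out to their true boundary.
* Intensities are sampled by bilinear interpolation after replicating each
  boundary pixel outward (background filled with the nearest in-mask
  value), so edge samples are not biased toward the zero background;
  samples falling in mask concavities likewise take the nearest boundary
  value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

DEFAULT_N_LINES = 200
DEFAULT_N_POINTS = 200
DEFAULT_CENTER_FRAC = 0.25
DEFAULT_PERIPHERY_FRAC = 0.75


@dataclass
class NucleusRecord:
    """One segmented nucleus: intensity patch, boolean mask, sub-pixel centroid."""

    label: int
    intensity: np.ndarray
    mask: np.ndarray
    centroid: tuple[float, float]  # (row, col) within the patch

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.ndim != 2 or self.intensity.shape != self.mask.shape:
            raise ValueError("intensity and mask must be 2-D arrays of equal shape")


@dataclass
class RadialProfile:
    """Per-nucleus mean intensity as a function of normalized radius."""

    label: int
    n_lines: int
    n_points: int
    radius_fractions: np.ndarray
    mean_intensity: np.ndarray
    per_line_intensity: np.ndarray | None = field(default=None, repr=False)


@dataclass
class ProfileAggregate:
    """Point-wise mean ± SD of per-nucleus profiles across a cohort.

    SD is the population standard deviation (ddof=0).
    """

    n_nuclei: int
    radius_fractions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class MFISummary:
    """Center vs periphery mean fluorescence intensity.

    center_mfi averages the profile over radius fractions < center_frac;
    periphery_mfi over fractions >= periphery_frac. peripheral_enrichment
    is their ratio, NaN (with ``undefined=True``) when center_mfi <= 0.
    """

    center_mfi: float
    periphery_mfi: float
    center_frac: float
    periphery_frac: float
    peripheral_enrichment: float
    undefined: bool


# ---------------------------------------------------------------------------
# segmentation


def segment_nuclei(
    image: np.ndarray,
    min_area: int = 200,
    threshold_method: str | float = "otsu",
    border_policy: str = "exclude",
    centroid_mode: str = "binary",
    pad: int = 2,
) -> list[NucleusRecord]:
    """Threshold, label and extract nuclei from a grayscale image.

    Parameters
    ----------
    threshold_method
        "otsu" or a numeric threshold; pixels strictly above it are
        foreground.
    border_policy
        "exclude" (default) drops components touching the image border;
        "include" keeps them.
    centroid_mode
        "binary" (unweighted mask centroid, default) or "intensity"
        (intensity-weighted within the mask).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if border_policy not in ("exclude", "include"):
        raise ValueError(f"unknown border_policy {border_policy!r}")
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold_method {threshold_method!r}")
        if np.ptp(image) == 0:
            return []
        thr = filters.threshold_otsu(image)
    else:
        thr = float(threshold_method)
    fg = image > thr
    labels = measure.label(fg, connectivity=2)
    return records_from_labels(
        image,
        labels,
        min_area=min_area,
        border_policy=border_policy,
        centroid_mode=centroid_mode,
        pad=pad,
    )


def records_from_labels(
    image: np.ndarray,
    labels: np.ndarray,
    min_area: int = 0,
    border_policy: str = "exclude",
    centroid_mode: str = "binary",
    pad: int = 2,
) -> list[NucleusRecord]:
    """Build NucleusRecords from a labeled mask (e.g. a provided mask image)."""
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    H, W = image.shape
    records: list[NucleusRecord] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        if border_policy == "exclude" and (r0 == 0 or c0 == 0 or r1 == H or c1 == W):
            continue
        pr0, pc0 = max(r0 - pad, 0), max(c0 - pad, 0)
        pr1, pc1 = min(r1 + pad, H), min(c1 + pad, W)
        patch = image[pr0:pr1, pc0:pc1]
        mask = labels[pr0:pr1, pc0:pc1] == region.label
        if centroid_mode == "binary":
            cr, cc = region.centroid
        elif centroid_mode == "intensity":
            w = np.where(labels == region.label, image, 0.0)
            cr, cc = ndimage.center_of_mass(w)
        else:
            raise ValueError(f"unknown centroid_mode {centroid_mode!r}")
        records.append(
            NucleusRecord(
                label=int(region.label),
                intensity=patch,
                mask=mask,
                centroid=(cr - pr0, cc - pc0),
            )
        )
    return records


# ---------------------------------------------------------------------------
# radial scanning


def radial_scan(
    nucleus: NucleusRecord,
    n_lines: int = DEFAULT_N_LINES,
    n_points: int = DEFAULT_N_POINTS,
    boundary_step: float = 0.25,
    keep_lines: bool = True,
) -> RadialProfile:
    """Cast rays from the centroid to the mask boundary and sample intensity.

    For each of ``n_lines`` rays the endpoint is the last mask pixel along
    the ray (marched at ``boundary_step``-pixel resolution); the ray is then
    sampled at radius fractions j/(n_points−1) by bilinear interpolation,
    and the profile is the mean over rays at each fraction.
    """
    mask = nucleus.mask
    if mask.sum() < 4:
        raise ValueError("degenerate nucleus: mask smaller than 4 px")
    cr, cc = nucleus.centroid
    H, W = mask.shape
    ir, ic = int(round(cr)), int(round(cc))
    if not (0 <= ir < H and 0 <= ic < W) or not mask[ir, ic]:
        raise ValueError("degenerate nucleus: centroid outside mask")

    angles = 2.0 * np.pi * np.arange(n_lines) / n_lines
    # angle 0 = +column axis, counter-clockwise with rows pointing down
    dr = -np.sin(angles)
    dc = np.cos(angles)

    corners = np.array([[0.0, 0.0], [0.0, W - 1.0], [H - 1.0, 0.0], [H - 1.0, W - 1.0]])
    tmax = float(np.max(np.hypot(corners[:, 0] - cr, corners[:, 1] - cc))) + 1.0
    ts = np.arange(0.0, tmax, boundary_step)
    rows = cr + np.outer(dr, ts)
    cols = cc + np.outer(dc, ts)
    ri = np.rint(rows).astype(int)
    ci = np.rint(cols).astype(int)
    inb = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
    hit = np.zeros_like(inb)
    hit[inb] = mask[ri[inb], ci[inb]]
    # last mask pixel along each ray
    any_hit = hit.any(axis=1)
    last = hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1)
    radius = np.where(any_hit, ts[last], 0.0)
    if not any_hit.all() or (radius <= 0).any():
        raise ValueError("degenerate nucleus: ray found no boundary")

    fracs = np.linspace(0.0, 1.0, n_points)
    samp_r = cr + radius[:, None] * fracs[None, :] * dr[:, None]
    samp_c = cc + radius[:, None] * fracs[None, :] * dc[:, None]
    # Boundary-aware sampling: replicate each boundary pixel outward (fill
    # background with the nearest in-mask value) so bilinear samples at the
    # nuclear edge are not dragged toward the zero background.
    if mask.all():
        filled = nucleus.intensity
    else:
        _, (ir_idx, ic_idx) = ndimage.distance_transform_edt(~mask, return_indices=True)
        filled = nucleus.intensity[ir_idx, ic_idx]
    values = ndimage.map_coordinates(
        filled,
        [samp_r.ravel(), samp_c.ravel()],
        order=1,
        mode="nearest",
    ).reshape(n_lines, n_points)

    return RadialProfile(
        label=nucleus.label,
        n_lines=int(n_lines),
        n_points=int(n_points),
        radius_fractions=fracs,
        mean_intensity=values.mean(axis=0),
        per_line_intensity=values if keep_lines else None,
    )


# ---------------------------------------------------------------------------
# aggregation and summaries


def aggregate_profiles(profiles: list[RadialProfile]) -> ProfileAggregate:
    """Point-wise mean and population SD over per-nucleus mean profiles."""
    if not profiles:
        raise ValueError("need at least one profile")
    n_points = profiles[0].n_points
    if any(p.n_points != n_points for p in profiles):
        raise ValueError("profiles have mixed n_points")
    stack = np.vstack([p.mean_intensity for p in profiles])
    return ProfileAggregate(
        n_nuclei=len(profiles),
        radius_fractions=profiles[0].radius_fractions,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0),
    )


def mfi_summary(
    profile: RadialProfile | ProfileAggregate,
    center_frac: float = DEFAULT_CENTER_FRAC,
    periphery_frac: float = DEFAULT_PERIPHERY_FRAC,
) -> MFISummary:
    """Center vs periphery MFI from a radial profile.

    Center band: radius fractions in [0, center_frac); periphery band:
    [periphery_frac, 1]. Both bands must contain at least one sample point.
    """
    if not (0 < center_frac < periphery_frac <= 1):
        raise ValueError("need 0 < center_frac < periphery_frac <= 1")
    fracs = profile.radius_fractions
    values = profile.mean_intensity if isinstance(profile, RadialProfile) else profile.mean
    center_sel = fracs < center_frac
    periph_sel = fracs >= periphery_frac
    if not center_sel.any() or not periph_sel.any():
        raise ValueError("center or periphery band contains no sample points")
    center = float(values[center_sel].mean())
    periph = float(values[periph_sel].mean())
    undefined = center <= 0
    return MFISummary(
        center_mfi=center,
        periphery_mfi=periph,
        center_frac=float(center_frac),
        periphery_frac=float(periphery_frac),
        peripheral_enrichment=(np.nan if undefined else periph / center),
        undefined=undefined,
    )


def compare_conditions(
    aggregates: list[tuple[str, ProfileAggregate]],
    center_frac: float = DEFAULT_CENTER_FRAC,
    periphery_frac: float = DEFAULT_PERIPHERY_FRAC,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate center→periphery curves and MFI summaries per condition.

    Returns ``(curves, summaries)``: a long-format table (condition,
    radius_fraction, mean, sd, n_nuclei) and one MFI summary row per
    condition.
    """
    if len(aggregates) < 2:
        raise ValueError("need at least two conditions to compare")
    labels = [lab for lab, _ in aggregates]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate condition labels")
    curve_rows = []
    summary_rows = []
    for lab, agg in aggregates:
        for f, m, s in zip(agg.radius_fractions, agg.mean, agg.sd):
            curve_rows.append((lab, f, m, s, agg.n_nuclei))
        summ = mfi_summary(agg, center_frac, periphery_frac)
        summary_rows.append(
            (
                lab,
                agg.n_nuclei,
                summ.center_mfi,
                summ.periphery_mfi,
                summ.peripheral_enrichment,
                summ.undefined,
            )
        )
    curves = pd.DataFrame(
        curve_rows, columns=["condition", "radius_fraction", "mean", "sd", "n_nuclei"]
    )
    summaries = pd.DataFrame(
        summary_rows,
        columns=[
            "condition",
            "n_nuclei",
            "center_mfi",
            "periphery_mfi",
            "peripheral_enrichment",
            "undefined",
        ],
    )
    return curves, summaries


# ---------------------------------------------------------------------------
# tabular output


def profiles_to_frame(profiles: list[RadialProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for j, (f, v) in enumerate(zip(p.radius_fractions, p.mean_intensity)):
            rows.append((p.label, j, f, v))
    return pd.DataFrame(
        rows, columns=["nucleus", "point_index", "radius_fraction", "mean_intensity"]
    )


def aggregate_to_frame(agg: ProfileAggregate) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "radius_fraction": agg.radius_fractions,
            "mean": agg.mean,
            "sd_population": agg.sd,
            "n_nuclei": agg.n_nuclei,
        }
    )


def save_per_line_matrix(path_prefix: str | Path, profile: RadialProfile) -> None:
    """Write the 200×200 per-line matrix as flat float32 binary + text header."""
    if profile.per_line_intensity is None:
        raise ValueError("profile carries no per-line matrix")
    prefix = Path(path_prefix)
    arr = profile.per_line_intensity.astype("<f4")
    arr.tofile(prefix.with_suffix(".bin"))
    prefix.with_suffix(".hdr").write_text(
        "dtype\tfloat32-little-endian\n"
        f"shape\t{arr.shape[0]}x{arr.shape[1]}\n"
        "order\trow-major (lines x points)\n"
    )
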