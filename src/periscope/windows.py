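"""Genome-window observed/expected peak enrichment.

Implements the two-step window analysis used to compare the genome-wide
distribution of two ChIP-seq factors (e.g. a histone methyltransferase and
lamin B1): peak counts per 1-Mb window, per-chromosome observed/expected
ratios, fold-enrichment flags, and a seeded permutation test of the
correlation between the two window tracks.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel

DEFAULT_WINDOW_BP = 1_000_000


# ---------------------------------------------------------------------------
# peak sets


@dataclass
class PeakSet:
    """A named set of genomic intervals for one factor.

    ``df`` has columns ``chrom``, ``start``, ``end`` (0-based half-open),
    sorted by (chrom, start). Extra BED columns are ignored on input.
    """

    name: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        df = self.df[["chrom", "start", "end"]].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]]
            raise ValueError(f"{len(bad)} intervals with start >= end in {self.name!r}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_arrays(cls, name, chroms, starts, ends) -> "PeakSet":
        return cls(name, pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}))

    @classmethod
    def read_bed(cls, path: str | Path, name: str | None = None) -> "PeakSet":
        """Read BED3+; columns beyond chrom/start/end are dropped."""
        path = Path(path)
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
        return cls(name or path.stem, df)

    def write_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def validate_against(self, genome: GenomeModel) -> None:
        """Raise if any peak lies on an unknown chromosome or outside its bounds."""
        lengths = genome.lengths
        unknown = sorted(set(self.df["chrom"]) - set(lengths))
        if unknown:
            raise ValueError(
                f"peaks of {self.name!r} on chromosomes absent from genome: {unknown}"
            )
        limit = self.df["chrom"].map(lengths).to_numpy()
        out = (self.df["start"].to_numpy() < 0) | (self.df["end"].to_numpy() > limit)
        if out.any():
            raise ValueError(
                f"{int(out.sum())} peaks of {self.name!r} outside chromosome bounds"
            )

    def midpoints(self) -> np.ndarray:
        s = self.df["start"].to_numpy()
        e = self.df["end"].to_numpy()
        return (s + e) // 2


# ---------------------------------------------------------------------------
# window grid


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-width windows tiling every chromosome; last window may be short."""

    genome: GenomeModel
    width: int
    df: pd.DataFrame = field(compare=False, repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.df)

    def n_windows_per_chrom(self) -> dict[str, int]:
        return self.df.groupby("chrom", sort=False).size().to_dict()


def tile_windows(genome: GenomeModel, width: int = DEFAULT_WINDOW_BP) -> WindowGrid:
    """Tile each chromosome of length L with ceil(L / width) windows covering [0, L)."""
    if width <= 0:
        raise ValueError("window width must be positive")
    if len(genome) == 0:
        raise ValueError("empty genome")
    rows = []
    for chrom, length in genome.chromosomes:
        n = -(-length // width)  # ceil
        for i in range(n):
            rows.append((chrom, i * width, min((i + 1) * width, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return WindowGrid(genome=genome, width=int(width), df=df)


# ---------------------------------------------------------------------------
# window track


@dataclass
class WindowTrack:
    """Per-window peak counts and observed/expected ratios for one factor.

    ``expected`` is the per-chromosome mean count per window (total peaks on
    the chromosome divided by the number of windows on that chromosome),
    so the mean ratio on each chromosome with any peaks is exactly 1.
    ``ratio`` is NaN on chromosomes with zero total peaks; ``flag`` is False
    there.
    """

    factor: str
    grid: WindowGrid
    counts: np.ndarray
    expected: np.ndarray | None = None
    ratio: np.ndarray | None = None
    flag: np.ndarray | None = None
    fold: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.grid.n_windows,):
            raise ValueError("counts length must equal number of windows")

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.df.copy()
        out["count"] = self.counts
        if self.expected is not None:
            out["expected"] = self.expected
            out["ratio"] = self.ratio
            out["flag"] = self.flag
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_bedgraph(self, path: str | Path) -> None:
        """bedGraph of observed/expected ratios; undefined windows written as 0."""
        if self.ratio is None:
            raise ValueError("ratios not computed; run enrichment_ratio first")
        out = self.grid.df.copy()
        out["ratio"] = np.nan_to_num(self.ratio, nan=0.0)
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def count_peaks_in_windows(
    peaks: PeakSet, grid: WindowGrid, assignment: str = "midpoint"
) -> WindowTrack:
    """Count peaks per window.

    ``assignment="midpoint"`` (default) assigns each peak to exactly one
    window by its midpoint ``floor((start + end) / 2)``, so window counts sum
    to the number of peaks. ``assignment="overlap"`` counts a peak in every
    window it intersects (non-conserving; boundary-crossing peaks are counted
    more than once).
    """
    peaks.validate_against(grid.genome)
    wdf = grid.df
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    # window row offsets per chromosome, in grid order
    offsets: dict[str, tuple[int, int]] = {}
    for chrom, sub in wdf.groupby("chrom", sort=False):
        offsets[chrom] = (int(sub.index[0]), len(sub))
    width = grid.width
    for chrom, sub in peaks.df.groupby("chrom", sort=False):
        off, n_win = offsets[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if assignment == "midpoint":
            idx = (starts + ends) // 2 // width
            counts[off : off + n_win] += np.bincount(idx, minlength=n_win)
        elif assignment == "overlap":
            first = starts // width
            last = (ends - 1) // width  # end is exclusive
            for a, b in zip(first, last):
                counts[off + a : off + b + 1] += 1
        else:
            raise ValueError(f"unknown assignment {assignment!r}")
    return WindowTrack(factor=peaks.name, grid=grid, counts=counts)


def enrichment_ratio(track: WindowTrack, fold: float = 1.5) -> WindowTrack:
    """Add per-chromosome expected counts, observed/expected ratios and flags.

    expected(chrom) = total peaks on chrom / number of windows on chrom.
    flag = ratio strictly greater than ``fold``. Chromosomes with zero total
    peaks get NaN ratios and False flags.
    """
    wdf = track.grid.df
    chroms = wdf["chrom"].to_numpy()
    counts = track.counts.astype(float)
    expected = np.zeros_like(counts)
    for chrom in track.grid.genome.names:
        sel = chroms == chrom
        if sel.any():
            expected[sel] = counts[sel].sum() / sel.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, counts / expected, np.nan)
    flag = np.where(np.isnan(ratio), False, ratio > fold)
    return WindowTrack(
        factor=track.factor,
        grid=track.grid,
        counts=track.counts,
        expected=expected,
        ratio=ratio,
        flag=flag.astype(bool),
        fold=float(fold),
    )


# ---------------------------------------------------------------------------
# correlation with permutation null


@dataclass
class CorrelationResult:
    """Correlation between two window tracks with a permutation p-value.

    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_permutations).
    """

    method: str
    r: float
    n_windows: int
    n_permutations: int
    p_value: float
    seed: int
    per_chromosome: pd.DataFrame | None = None

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            ("method", self.method),
            ("r", repr(self.r)),
            ("n_windows", self.n_windows),
            ("n_permutations", self.n_permutations),
            ("p_value", repr(self.p_value)),
            ("seed", self.seed),
        ]
        Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in rows))


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def window_correlation(
    track_a: WindowTrack,
    track_b: WindowTrack,
    method: str = "spearman",
    n_permutations: int = 10_000,
    seed: int = 0,
    variable: str = "ratio",
    per_chromosome: bool = False,
) -> CorrelationResult:
    """Correlate two window tracks and test by permutation.

    The statistic is computed over windows where both tracks are defined
    (``variable="ratio"``, the default, skips NaN windows; ``"count"`` uses
    raw counts). The null distribution is built by jointly permuting track
    B's window values with a seeded RNG; the p-value uses the add-one rule
    so it is never exactly zero.
    """
    if track_a.grid.df is not track_b.grid.df and not track_a.grid.df.equals(
        track_b.grid.df
    ):
        raise ValueError("tracks are on different window grids")
    if variable == "ratio":
        if track_a.ratio is None or track_b.ratio is None:
            raise ValueError("ratio tracks required; run enrichment_ratio first")
        xa, xb = np.asarray(track_a.ratio, float), np.asarray(track_b.ratio, float)
    elif variable == "count":
        xa, xb = track_a.counts.astype(float), track_b.counts.astype(float)
    else:
        raise ValueError(f"unknown variable {variable!r}")
    defined = np.isfinite(xa) & np.isfinite(xb)
    x, y = xa[defined], xb[defined]
    n = len(x)
    if n < 10:
        raise ValueError(f"only {n} windows defined in both tracks; need >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate track: zero variance")

    if method == "spearman":
        x_stat = stats.rankdata(x)
        y_stat = stats.rankdata(y)
    elif method == "pearson":
        x_stat, y_stat = x, y
    else:
        raise ValueError(f"unknown method {method!r}")
    # Pearson on the (possibly rank-transformed) values, vectorized over
    # permutations: r = <x_c, y_c> with both standardized.
    xc = (x_stat - x_stat.mean()) / (x_stat.std() * np.sqrt(n))
    yc = (y_stat - y_stat.mean()) / (y_stat.std() * np.sqrt(n))
    r_obs = float(xc @ yc)

    rng = np.random.default_rng(seed)
    n_perm = int(n_permutations)
    # permute y in blocks to bound memory
    exceed = 0
    block = max(1, min(n_perm, int(2e7) // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perm = np.tile(yc, (b, 1))
        perm = rng.permuted(perm, axis=1)
        r_perm = perm @ xc
        exceed += int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        done += b
    p = (1 + exceed) / (1 + n_perm)

    per_chrom_df = None
    if per_chromosome:
        chroms = track_a.grid.df["chrom"].to_numpy()[defined]
        rows = []
        for chrom in track_a.grid.genome.names:
            sel = chroms == chrom
            if sel.sum() >= 3 and np.ptp(x[sel]) > 0 and np.ptp(y[sel]) > 0:
                rows.append((chrom, int(sel.sum()), _corr(x[sel], y[sel], method)))
        per_chrom_df = pd.DataFrame(rows, columns=["chrom", "n_windows", "r"])

    return CorrelationResult(
        method=method,
        r=r_obs,
        n_windows=n,
        n_permutations=n_perm,
        p_value=float(p),
        seed=int(seed),
        per_chromosome=per_chrom_df,
    )
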