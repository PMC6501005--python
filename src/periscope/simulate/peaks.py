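"""Synthetic peak sets with planted window-level co-enrichment.

Emulates the statistical structure the 1-Mb window analysis assumes: per
window w, the peak count of factor A is Poisson(λ·m_A(w)) and of factor B
Poisson(λ·m_B(w)). A fraction of windows is designated enriched (multiplier
m > 1, lamina-associated-domain-like); the coupling ρ controls what share
of A's enriched windows are enriched in B as well (with the same
multiplier), the remainder of B's enriched windows being drawn
independently. Peak starts are uniform within their window and never cross
window boundaries, so planted per-window counts are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genome import GenomeModel
from ..windows import DEFAULT_WINDOW_BP, PeakSet, WindowGrid, tile_windows


@dataclass(frozen=True)
class PeakSimParams:
    """Window-model parameters for a pair of coupled synthetic peak sets.

    base_rate is λ, the expected peak count per window at multiplier 1;
    enriched_fraction the share of windows planted with
    enrichment_multiplier; coupling ρ ∈ [0, 1] the share of A's enriched
    windows that are enriched in B too. peak_length is bp, a scalar or an
    inclusive (lo, hi) range.
    """

    window_width: int = DEFAULT_WINDOW_BP
    base_rate: float = 10.0
    enriched_fraction: float = 0.2
    enrichment_multiplier: float = 8.0
    coupling: float = 0.8
    peak_length: int | tuple[int, int] = 1_000
    seed: int = 0

    def validate(self) -> None:
        if self.base_rate <= 0:
            raise ValueError("base_rate (λ) must be > 0")
        if not (0 <= self.enriched_fraction <= 1):
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if self.enrichment_multiplier < 0:
            raise ValueError("enrichment_multiplier must be >= 0")
        if not (0 <= self.coupling <= 1):
            raise ValueError("coupling must lie in [0, 1]")
        if self.window_width <= 0:
            raise ValueError("window_width must be > 0")


def _planted_multipliers(
    rng: np.random.Generator, n_windows: int, params: PeakSimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Designate enriched windows for A and B with coupling ρ."""
    m_a = np.ones(n_windows)
    m_b = np.ones(n_windows)
    n_enr = int(round(params.enriched_fraction * n_windows))
    if n_enr == 0:
        return m_a, m_b
    enriched_a = rng.choice(n_windows, size=n_enr, replace=False)
    n_shared = int(round(params.coupling * n_enr))
    shared = rng.choice(enriched_a, size=n_shared, replace=False)
    rest_pool = np.setdiff1d(np.arange(n_windows), shared)
    independent_b = rng.choice(rest_pool, size=n_enr - n_shared, replace=False)
    m_a[enriched_a] = params.enrichment_multiplier
    m_b[shared] = params.enrichment_multiplier
    m_b[independent_b] = params.enrichment_multiplier
    return m_a, m_b


def _draw_peaks(
    rng: np.random.Generator,
    grid: WindowGrid,
    counts: np.ndarray,
    peak_length: int | tuple[int, int],
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    wdf = grid.df
    for (chrom, wstart, wend), k in zip(wdf.itertuples(index=False), counts):
        if k == 0:
            continue
        if np.isscalar(peak_length):
            lens = np.full(k, int(peak_length))
        else:
            lo, hi = peak_length
            lens = rng.integers(lo, hi + 1, size=k)
        # keep peaks inside their window where the window can hold them
        hi_start = np.maximum(wend - lens + 1, wstart + 1)
        s = rng.integers(wstart, hi_start)
        e = np.minimum(s + lens, chrom_lengths[chrom])
        chroms.extend([chrom] * k)
        starts.extend(int(x) for x in s)
        ends.extend(int(x) for x in e)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def make_peak_sets(
    genome: GenomeModel,
    params: PeakSimParams,
    multipliers_a: np.ndarray | None = None,
    multipliers_b: np.ndarray | None = None,
    names: tuple[str, str] = ("factor_a", "factor_b"),
) -> tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Simulate two coupled peak sets on a genome.

    Explicit per-window multiplier arrays (aligned to the window grid of
    ``tile_windows(genome, params.window_width)``) override the
    enriched_fraction/coupling designation. Returns (PeakSet A, PeakSet B,
    truth table) where the truth table has one row per window with the
    planted multipliers and realized counts.
    """
    params.validate()
    if len(genome) == 0:
        raise ValueError("empty genome")
    max_len = max(genome.lengths.values())
    if params.window_width > max_len:
        raise ValueError(
            f"window_width {params.window_width} exceeds longest chromosome ({max_len})"
        )
    grid = tile_windows(genome, params.window_width)
    rng = np.random.default_rng(params.seed)
    if multipliers_a is None and multipliers_b is None:
        m_a, m_b = _planted_multipliers(rng, grid.n_windows, params)
    else:
        m_a = np.ones(grid.n_windows) if multipliers_a is None else np.asarray(multipliers_a, float)
        m_b = np.ones(grid.n_windows) if multipliers_b is None else np.asarray(multipliers_b, float)
        if m_a.shape != (grid.n_windows,) or m_b.shape != (grid.n_windows,):
            raise ValueError("multiplier arrays must have one entry per window")
        if (m_a < 0).any() or (m_b < 0).any():
            raise ValueError("multipliers must be >= 0")
    counts_a = rng.poisson(params.base_rate * m_a)
    counts_b = rng.poisson(params.base_rate * m_b)
    lengths = genome.lengths
    peaks_a = PeakSet(names[0], _draw_peaks(rng, grid, counts_a, params.peak_length, lengths))
    peaks_b = PeakSet(names[1], _draw_peaks(rng, grid, counts_b, params.peak_length, lengths))
    truth = grid.df.copy()
    truth["multiplier_a"] = m_a
    truth["multiplier_b"] = m_b
    truth["count_a"] = counts_a
    truth["count_b"] = counts_b
    truth.attrs["coupling"] = params.coupling
    return peaks_a, peaks_b, truth
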