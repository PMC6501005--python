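"""Peak-level co-binding: how many peaks of one factor touch the other's.

The "co-bound" number behind a two-set peak Venn is ambiguous — it can mean
A-peaks overlapped by B, B-peaks overlapped by A, or merged co-occupied
regions; the three differ whenever one factor's peaks are broader. The
result reports all three; the headline ``cobound`` is the A-side count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .windows import PeakSet


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    cobound_a: int  # peaks of A with >= min_overlap_bp overlap with union of B
    cobound_b: int
    cobound_regions: int  # connected components of union(A) ∩ union(B)
    min_overlap_bp: int

    @property
    def unique_a(self) -> int:
        return self.n_a - self.cobound_a

    @property
    def unique_b(self) -> int:
        return self.n_b - self.cobound_b

    @property
    def cobound(self) -> int:
        return self.cobound_a

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            ("n_a", self.n_a),
            ("n_b", self.n_b),
            ("cobound_a", self.cobound_a),
            ("cobound_b", self.cobound_b),
            ("unique_a", self.unique_a),
            ("unique_b", self.unique_b),
            ("cobound_regions", self.cobound_regions),
            ("min_overlap_bp", self.min_overlap_bp),
        ]
        Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in rows))


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of sorted intervals as disjoint (starts, ends)."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    # sweep: a new component starts where start > running max of previous ends
    running_end = np.maximum.accumulate(e)
    new = np.ones(len(s), dtype=bool)
    new[1:] = s[1:] > running_end[:-1]
    comp = np.cumsum(new) - 1
    ms = s[new]
    me = np.zeros(comp[-1] + 1, dtype=e.dtype)
    np.maximum.at(me, comp, e)
    return ms, me


def _covered_before(ms: np.ndarray, me: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Total covered length of the disjoint union below each position x."""
    if len(ms) == 0:
        return np.zeros(len(x), dtype=np.int64)
    lens = me - ms
    cum = np.concatenate([[0], np.cumsum(lens)])
    i = np.searchsorted(ms, x, side="right")  # number of intervals starting before x
    full = cum[np.maximum(i - 1, 0)]
    partial = np.where(
        i > 0, np.clip(x - ms[np.maximum(i - 1, 0)], 0, lens[np.maximum(i - 1, 0)]), 0
    )
    return np.where(i > 0, full + partial, 0)


def _count_covered(a: PeakSet, b: PeakSet, min_overlap: int) -> int:
    """Number of A peaks whose overlap with the union of B is >= min_overlap."""
    total = 0
    b_by_chrom = {c: sub for c, sub in b.df.groupby("chrom", sort=False)}
    for chrom, sub in a.df.groupby("chrom", sort=False):
        bsub = b_by_chrom.get(chrom)
        if bsub is None:
            continue
        ms, me = _merge(bsub["start"].to_numpy(), bsub["end"].to_numpy())
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        ov = _covered_before(ms, me, e) - _covered_before(ms, me, s)
        total += int(np.sum(ov >= min_overlap))
    return total


def _intersection_components(a: PeakSet, b: PeakSet, min_overlap: int) -> int:
    n = 0
    b_by_chrom = {c: sub for c, sub in b.df.groupby("chrom", sort=False)}
    for chrom, sub in a.df.groupby("chrom", sort=False):
        bsub = b_by_chrom.get(chrom)
        if bsub is None:
            continue
        asx, aex = _merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        bsx, bex = _merge(bsub["start"].to_numpy(), bsub["end"].to_numpy())
        # two-pointer sweep over disjoint sorted unions
        i = j = 0
        while i < len(asx) and j < len(bsx):
            lo = max(asx[i], bsx[j])
            hi = min(aex[i], bex[j])
            if hi - lo >= min_overlap:
                n += 1
            if aex[i] <= bex[j]:
                i += 1
            else:
                j += 1
    return n


def cobound(peaks_a: PeakSet, peaks_b: PeakSet, min_overlap_bp: int = 1) -> OverlapResult:
    """Count co-bound peaks of two factors.

    A peak of A is co-bound when its overlap with the union of B's peaks is
    at least ``min_overlap_bp`` (each A peak counted once however many B
    peaks it touches), and symmetrically for B. Uses a merged-interval
    sweep; equivalent to brute-force pairwise overlap counting.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    return OverlapResult(
        n_a=len(peaks_a),
        n_b=len(peaks_b),
        cobound_a=_count_covered(peaks_a, peaks_b, min_overlap_bp),
        cobound_b=_count_covered(peaks_b, peaks_a, min_overlap_bp),
        cobound_regions=_intersection_components(peaks_a, peaks_b, min_overlap_bp),
        min_overlap_bp=int(min_overlap_bp),
    )
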