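"""Gene annotation model and peak-level genomic summaries.

Holds a minimal BED12-backed gene model (strand, TSS, exon blocks, derived
introns, strand-aware upstream windows) and the two peak summaries built on
it: classification of peak midpoints into upstream/exon/intron/others, and
the strand-oriented composite density of peak midpoints around TSSs
(a metagene profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import PeakSet

DEFAULT_UPSTREAM_BP = 2_000

CATEGORIES = ("upstream", "exon", "intron", "others")


@dataclass
class AnnotationModel:
    """Gene models with exon blocks.

    ``genes`` has columns ``chrom, start, end, name, strand, exon_starts,
    exon_sizes`` where exon_starts are 0-based offsets relative to gene
    start (BED12 blockStarts) and exon blocks lie within the gene body.
    The TSS is ``start`` on the + strand and ``end`` on the − strand
    (as a 0-based position, ``end - 1`` is the last covered base; we use
    the half-open boundary ``end`` as the − strand TSS coordinate).
    """

    genes: pd.DataFrame
    upstream_bp: int = DEFAULT_UPSTREAM_BP

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand", "exon_starts", "exon_sizes"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        for _, g in self.genes.iterrows():
            offs, sizes = g["exon_starts"], g["exon_sizes"]
            if len(offs) != len(sizes) or len(offs) == 0:
                raise ValueError("each gene needs >= 1 exon block")
            if offs[0] != 0 or offs[-1] + sizes[-1] != g["end"] - g["start"]:
                raise ValueError("exon blocks must span the gene body ends")

    def __len__(self) -> int:
        return len(self.genes)

    # -- derived interval tables ------------------------------------------

    def tss(self) -> pd.DataFrame:
        """TSS positions (chrom, pos, strand)."""
        g = self.genes
        pos = np.where(g["strand"] == "+", g["start"], g["end"])
        return pd.DataFrame({"chrom": g["chrom"], "pos": pos, "strand": g["strand"]})

    def exons(self) -> pd.DataFrame:
        rows = []
        for _, g in self.genes.iterrows():
            for off, size in zip(g["exon_starts"], g["exon_sizes"]):
                rows.append((g["chrom"], g["start"] + off, g["start"] + off + size))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def introns(self) -> pd.DataFrame:
        """Inter-exon gaps within each gene body."""
        rows = []
        for _, g in self.genes.iterrows():
            offs, sizes = g["exon_starts"], g["exon_sizes"]
            for k in range(len(offs) - 1):
                lo = g["start"] + offs[k] + sizes[k]
                hi = g["start"] + offs[k + 1]
                if hi > lo:
                    rows.append((g["chrom"], lo, hi))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def upstream(self, length: int | None = None) -> pd.DataFrame:
        """Strand-aware windows of ``length`` bp ending at each TSS."""
        length = self.upstream_bp if length is None else int(length)
        g = self.genes
        start = np.where(
            g["strand"] == "+", g["start"] - length, g["end"]
        )
        end = np.where(g["strand"] == "+", g["start"], g["end"] + length)
        df = pd.DataFrame({"chrom": g["chrom"], "start": start, "end": end})
        df["start"] = df["start"].clip(lower=0)
        return df[df["end"] > df["start"]]

    # -- BED12 I/O ---------------------------------------------------------

    @classmethod
    def read_bed12(cls, path: str | Path, upstream_bp: int = DEFAULT_UPSTREAM_BP):
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            rows.append((chrom, start, end, name, strand, offs, sizes))
        genes = pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "name", "strand", "exon_starts", "exon_sizes"],
        )
        return cls(genes, upstream_bp=upstream_bp)

    def write_bed12(self, path: str | Path) -> None:
        lines = []
        for _, g in self.genes.iterrows():
            sizes = ",".join(str(s) for s in g["exon_sizes"]) + ","
            offs = ",".join(str(o) for o in g["exon_starts"]) + ","
            lines.append(
                "\t".join(
                    str(x)
                    for x in (
                        g["chrom"], g["start"], g["end"], g.get("name", "."), 0,
                        g["strand"], g["start"], g["end"], "0,0,0",
                        len(g["exon_sizes"]), sizes, offs,
                    )
                )
            )
        Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# membership testing against interval tables


def _membership(points_by_chrom, intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    """For each chromosome, boolean mask of points falling in any interval."""
    out = {}
    merged = {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        s = np.sort(sub["start"].to_numpy())
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        e = sub["end"].to_numpy()[order]
        # merge to disjoint intervals so searchsorted parity works
        run = np.maximum.accumulate(e)
        new = np.ones(len(s), bool)
        new[1:] = s[1:] > run[:-1]
        ms = s[new]
        comp = np.cumsum(new) - 1
        me = np.zeros(comp[-1] + 1, dtype=e.dtype)
        np.maximum.at(me, comp, e)
        merged[chrom] = (ms, me)
    for chrom, pts in points_by_chrom.items():
        if chrom not in merged:
            out[chrom] = np.zeros(len(pts), bool)
            continue
        ms, me = merged[chrom]
        i = np.searchsorted(ms, pts, side="right")
        inside = np.zeros(len(pts), bool)
        has = i > 0
        inside[has] = pts[has] < me[i[has] - 1]
        out[chrom] = inside
    return out


def classify_peaks(peaks: PeakSet, annotation: AnnotationModel) -> pd.DataFrame:
    """Assign each peak midpoint one category: upstream > exon > intron > others.

    "upstream" is the strand-aware window of ``annotation.upstream_bp``
    ending at the TSS. Returns a table with per-category counts and
    fractions (fractions sum to 1).
    """
    mids_by_chrom = {
        chrom: ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        for chrom, sub in peaks.df.groupby("chrom", sort=False)
    }
    n_total = len(peaks)
    counts = dict.fromkeys(CATEGORIES, 0)
    if n_total == 0:
        raise ValueError("empty peak set")
    if len(annotation) == 0:
        counts["others"] = n_total
    else:
        in_up = _membership(mids_by_chrom, annotation.upstream())
        in_ex = _membership(mids_by_chrom, annotation.exons())
        intr = annotation.introns()
        in_in = (
            _membership(mids_by_chrom, intr)
            if len(intr)
            else {c: np.zeros(len(p), bool) for c, p in mids_by_chrom.items()}
        )
        for chrom, mids in mids_by_chrom.items():
            up = in_up[chrom]
            ex = in_ex[chrom] & ~up
            inn = in_in[chrom] & ~up & ~ex
            oth = ~(up | ex | inn)
            counts["upstream"] += int(up.sum())
            counts["exon"] += int(ex.sum())
            counts["intron"] += int(inn.sum())
            counts["others"] += int(oth.sum())
    out = pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
        }
    )
    out["fraction"] = out["count"] / n_total
    return out


# ---------------------------------------------------------------------------
# TSS composite (metagene) profile


@dataclass
class CompositeProfile:
    """Strand-oriented density of peak midpoints around TSSs.

    ``profile`` has columns ``bin_start, bin_end`` (bp relative to TSS,
    negative = upstream in the gene's orientation), raw ``count`` and
    ``density`` normalized per 1,000 TSSs.
    """

    flank: int
    bin: int
    n_tss: int
    profile: pd.DataFrame = field(repr=False)

    def write_tsv(self, path: str | Path) -> None:
        self.profile.to_csv(path, sep="\t", index=False)


def tss_composite(
    peaks: PeakSet,
    annotation: AnnotationModel,
    flank: int = 5_000,
    bin: int = 100,
) -> CompositeProfile:
    """Composite profile of peak midpoints within ±flank of each TSS.

    Offsets are sign-flipped for − strand genes so that negative offsets
    always mean upstream of the gene. Counts are normalized per 1,000 TSSs.
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    tss = annotation.tss()
    n_tss = len(tss)
    edges = np.arange(-flank, flank + bin, bin)
    total = np.zeros(len(edges) - 1, dtype=np.int64)
    mids_by_chrom = {
        chrom: np.sort((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        for chrom, sub in peaks.df.groupby("chrom", sort=False)
    }
    for _, t in tss.iterrows():
        mids = mids_by_chrom.get(t["chrom"])
        if mids is None:
            continue
        lo = np.searchsorted(mids, t["pos"] - flank, side="left")
        hi = np.searchsorted(mids, t["pos"] + flank, side="right")
        off = mids[lo:hi] - t["pos"]
        if t["strand"] == "-":
            off = -off
        off = off[(off >= -flank) & (off < flank)]
        total += np.histogram(off, bins=edges)[0]
    density = total / n_tss * 1000.0 if n_tss else np.zeros_like(total, float)
    profile = pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": total,
            "density_per_1000_tss": density,
        }
    )
    return CompositeProfile(flank=int(flank), bin=int(bin), n_tss=n_tss, profile=profile)
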