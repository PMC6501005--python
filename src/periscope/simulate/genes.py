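"""Synthetic gene annotations for TSS-composite and classification tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..annotation import DEFAULT_UPSTREAM_BP, AnnotationModel
from ..genome import GenomeModel


def _exon_blocks(
    rng: np.random.Generator, gene_len: int, max_exons: int
) -> tuple[list[int], list[int]]:
    """Split a gene body into alternating exon/intron blocks.

    The first and last blocks are exons (BED12 convention: blocks span the
    record ends). Cut points are drawn uniformly inside the body.
    """
    n_exons = int(rng.integers(1, max_exons + 1))
    n_parts = 2 * n_exons - 1
    if n_parts == 1 or gene_len < 2 * n_parts:
        return [0], [gene_len]
    cuts = np.sort(rng.choice(np.arange(1, gene_len), size=n_parts - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [gene_len]])
    offs, sizes = [], []
    for k in range(0, n_parts, 2):  # even parts are exons
        offs.append(int(bounds[k]))
        sizes.append(int(bounds[k + 1] - bounds[k]))
    return offs, sizes


def make_annotation(
    genome: GenomeModel,
    n_genes: int,
    seed: int = 0,
    gene_length: tuple[int, int] = (5_000, 50_000),
    max_exons: int = 5,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    max_tries_per_gene: int = 200,
) -> AnnotationModel:
    """Place ``n_genes`` non-overlapping gene models across the genome.

    Genes are assigned to chromosomes proportional to length, given a
    random strand and 1..max_exons exons; introns are the inter-exon gaps.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    names = genome.names
    weights = np.array([lengths[c] for c in names], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    rows = []
    for g in range(n_genes):
        for _ in range(max_tries_per_gene):
            chrom = names[int(rng.choice(len(names), p=weights))]
            L = lengths[chrom]
            glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
            if glen >= L:
                continue
            start = int(rng.integers(0, L - glen))
            end = start + glen
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                break
        else:
            raise RuntimeError(f"could not place gene {g + 1} of {n_genes}")
        strand = "+" if rng.random() < 0.5 else "-"
        offs, sizes = _exon_blocks(rng, glen, max_exons)
        rows.append((chrom, start, end, f"gene_{g + 1}", strand, offs, sizes))
    genes = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "strand", "exon_starts", "exon_sizes"],
    )
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return AnnotationModel(genes, upstream_bp=upstream_bp)
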