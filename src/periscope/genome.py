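"""Genome model: an ordered set of chromosomes with lengths.

The window analyses tile each chromosome independently, so the genome is
nothing more than an ordered ``(name, length)`` list plus chrom.sizes I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths in bp.

    Parameters
    ----------
    chromosomes
        Tuple of ``(name, length_bp)`` pairs. Names must be unique and
        lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeModel":
        return cls(tuple((str(k), int(v)) for k, v in sizes.items()))

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    @classmethod
    def read_chrom_sizes(cls, path: str | Path) -> "GenomeModel":
        """Read a two-column ``chrom<TAB>length`` file."""
        pairs: list[tuple[str, int]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed chrom.sizes line: {line!r}")
            pairs.append((fields[0], int(fields[1])))
        if not pairs:
            raise ValueError(f"empty chrom.sizes file: {path}")
        return cls(tuple(pairs))

    def write_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{length}\n" for name, length in self.chromosomes)
        )
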