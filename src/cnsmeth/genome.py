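"""Genome models for binned copy-number analysis.

The default is a desk-scale toy genome (2 autosomes x 50 Mb); hg19
chromosome sizes are bundled for realistic runs. BED conventions: 0-based
half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = ["GenomeModel", "toy_genome", "hg19_genome", "DEFAULT_BIN_SIZE"]

DEFAULT_BIN_SIZE = 1_000_000  # 1,000 kbp, sized for ~0.5X low-pass coverage


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome sizes plus the set treated as autosomes."""

    chrom_sizes: dict[str, int]
    autosomes: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive size {size}")
        if self.autosomes is None:
            auto = frozenset(
                c for c in self.chrom_sizes if c.lstrip("chr").isdigit()
            )
            object.__setattr__(self, "autosomes", auto)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def bins(self, bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
        """Fixed-width tiling per chromosome; the last bin may be short."""
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        rows = []
        for chrom, size in self.chrom_sizes.items():
            for start in range(0, size, bin_size):
                rows.append((chrom, start, min(start + bin_size, size)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return (
            chrom in self.chrom_sizes
            and 0 <= start < end <= self.chrom_sizes[chrom]
        )


def toy_genome(n_chroms: int = 2, chrom_size: int = 50_000_000) -> GenomeModel:
    return GenomeModel({f"chr{i + 1}": chrom_size for i in range(n_chroms)})


def hg19_genome(include_sex_chroms: bool = False) -> GenomeModel:
    text = resources.files("cnsmeth.data").joinpath("hg19.chrom.sizes").read_text()
    sizes: dict[str, int] = {}
    for line in text.strip().splitlines():
        chrom, size = line.split("\t")
        if not include_sex_chroms and chrom in ("chrX", "chrY"):
            continue
        sizes[chrom] = int(size)
    return GenomeModel(sizes)
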