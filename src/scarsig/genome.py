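"""Genome definitions: chromosome lengths and centromere intervals.

Coordinates are 0-based half-open throughout interval data; variant positions
elsewhere in the package are 1-based (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Chromosome", "GenomeDefinition", "toy_genome", "load_genome_tsv"]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValueError(
                f"chromosome {self.name}: centromere interval must lie strictly "
                f"inside (0, {self.length})"
            )

    @property
    def p_arm(self) -> tuple[int, int]:
        return (0, self.centromere_start)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.centromere_end, self.length)


@dataclass(frozen=True)
class GenomeDefinition:
    """Set of chromosomes with centromere geometry.

    Interval coordinates are 0-based half-open (``coordinate_convention``
    records this for file round-trips).
    """

    chromosomes: tuple[Chromosome, ...]
    coordinate_convention: str = "0-based-half-open"
    _by_name: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        object.__setattr__(self, "_by_name", {c.name: c for c in self.chromosomes})

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


def toy_genome() -> GenomeDefinition:
    """Three-chromosome test genome (60/90/120 Mbp, centromeres at 40%).

    Each centromere is a 3 Mbp interval centred at 40% of the chromosome.
    Small enough for fast simulation, large enough to host >15 Mbp scar
    segments on either arm.
    """
    chroms = []
    for name, length in (("chr1", 60_000_000), ("chr2", 90_000_000), ("chr3", 120_000_000)):
        mid = int(0.4 * length)
        chroms.append(Chromosome(name, length, mid - 1_500_000, mid + 1_500_000))
    return GenomeDefinition(tuple(chroms))


def load_genome_tsv(path) -> GenomeDefinition:
    """Load a genome definition from a TSV with columns
    chrom, length, centromere_start, centromere_end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "length", "centromere_start", "centromere_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome TSV missing columns: {sorted(missing)}")
    chroms = tuple(
        Chromosome(r.chrom, int(r.length), int(r.centromere_start), int(r.centromere_end))
        for r in df.itertuples()
    )
    return GenomeDefinition(chroms)
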