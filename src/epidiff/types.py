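"""Domain types shared across the pipeline.

Coordinate convention: every interval held in memory is 0-based,
half-open (``[start, end)``).  1-based conventions (GFF3, cytosine
reports) are converted at the I/O boundary and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-resolved cytosine with bisulfite read counts.

    ``position`` is 1-based, matching the cytosine-report dialect the
    record is parsed from.  ``level`` is only defined when at least one
    read covers the site.
    """

    contig: str
    position: int  # 1-based, as in the report
    strand: str
    meth_count: int
    unmeth_count: int
    context: str
    trinucleotide: str

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError(
                f"negative read count at {self.contig}:{self.position}"
            )
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def level(self) -> Optional[float]:
        cov = self.coverage
        return self.meth_count / cov if cov > 0 else None


@dataclass(frozen=True)
class GenomicInterval:
    """A located feature in 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SyntenyBlock:
    """A colinearly mapped pair of equal-length intervals, one per species.

    The equal-length 1:1 base mapping is a declared simplification: the
    windowed DMR procedure only needs coordinate-paired windows, and the
    synthetic generator emits gap-free blocks.
    """

    id: str
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    orientation: str = "same"

    def __post_init__(self) -> None:
        if len(self.interval_a) != len(self.interval_b):
            raise ValueError(
                f"synteny block {self.id}: intervals differ in length"
            )
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"invalid orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.interval_a)


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"negative FPKM for {self.gene_id}")


@dataclass(frozen=True)
class SiRNARead:
    """A collapsed small-RNA read: ``copies`` identical molecules."""

    contig: str
    start: int
    end: int
    sequence: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("read span does not match sequence length")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass
class SiRNACluster:
    interval: GenomicInterval
    total_reads: int
    distinct_reads: int
    rpm: float
    te_overlap: bool = False
    region_kind: str = "intergenic"
    mcg_level: Optional[float] = None


@dataclass
class MethWindow:
    """A paired 200 bp window on a synteny block with pooled CG counts."""

    block_id: str
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    meth_a: int = 0
    unmeth_a: int = 0
    meth_b: int = 0
    unmeth_b: int = 0
    sites_a: int = 0
    sites_b: int = 0
    p_value: Optional[float] = None
    q_value: Optional[float] = None

    @property
    def level_a(self) -> Optional[float]:
        n = self.meth_a + self.unmeth_a
        return self.meth_a / n if n else None

    @property
    def level_b(self) -> Optional[float]:
        n = self.meth_b + self.unmeth_b
        return self.meth_b / n if n else None

    @property
    def direction(self) -> Optional[str]:
        la, lb = self.level_a, self.level_b
        if la is None or lb is None or la == lb:
            return None
        return "hyper_in_A" if la > lb else "hyper_in_B"


@dataclass
class DMR:
    """A maximal run of merged same-direction significant windows."""

    interval_a: GenomicInterval
    interval_b: GenomicInterval
    direction: str
    n_windows: int
    min_q: float
    category: str = "intergenic"


@dataclass(frozen=True)
class LTRPair:
    """Aligned 5'/3' long terminal repeats of one full-length element."""

    element_id: str
    seq5: str
    seq3: str
    sites: int
    p_transitions: float
    q_transversions: float
    d: Optional[float]  # None when the K2P log-domain is violated
    age_years: Optional[float] = None

    @property
    def age_my(self) -> Optional[float]:
        return None if self.age_years is None else self.age_years / 1e6

    @property
    def estimable(self) -> bool:
        return self.d is not None
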