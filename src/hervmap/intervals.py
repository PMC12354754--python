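"""Core genomic-interval records shared across the pipeline.

All internal coordinates are 0-based half-open (BED-like); GTF I/O converts
to 1-based inclusive at the boundary.  The transcription start site (TSS) of
a stranded feature is its 5' end: ``start`` on the + strand, ``end - 1`` on
the - strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

STRANDS = ("+", "-", ".")

REGION_CLASSES = ("exonic_removed", "intron_sense", "intron_antisense", "intergenic")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand-agnostic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def tss(self) -> int:
        """Strand-aware 5' position (start on +, end-1 on -; start if unstranded)."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass
class GeneModel:
    """A protein-coding gene with its exon structure."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for exon in self.exons:
            if not self.interval.contains(exon):
                raise ValueError(
                    f"exon {exon} outside gene body of {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        return self.interval.tss

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class HervLocus:
    """A single endogenous-retrovirus locus (one RepeatMasker record).

    ``herv_id`` follows the repName_dupN-chrom convention, e.g.
    ``LTR2B_dup15-chr6``.  ``region_class`` is unset until classification.
    """

    herv_id: str
    interval: GenomicInterval
    family: str = "ERV1"
    region_class: str | None = None

    def __post_init__(self) -> None:
        if self.region_class is not None and self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")

    @property
    def tss(self) -> int:
        return self.interval.tss

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def with_region_class(self, region_class: str) -> "HervLocus":
        return replace(self, region_class=region_class)
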