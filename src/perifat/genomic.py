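"""Genomic coordinate primitives.

All coordinates are 1-based and inclusive at both ends, the convention of
GFF3 and of the coordinate ranges printed in sheep QTL and DMR tables
(``length = end - start + 1``).  BED-style 0-based half-open input must be
converted at read time (see :func:`perifat.io.read_qtl_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on one chromosome strand.

    Parameters
    ----------
    chrom : str
        Chromosome name; matched by exact string comparison.
    start, end : int
        1-based inclusive bounds, ``1 <= start <= end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge distance in bp; 0 if overlapping, None if trans."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end < other.start:
            return other.start - self.end
        return self.start - other.end


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (``end - start + 1``)."""
    return len(iv)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals on the same chromosome."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start <= last.end + 1:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(
                    last.chrom, last.start, iv.end, last.strand
                )
        else:
            merged.append(iv)
    return merged


@dataclass
class GeneModel:
    """A gene body with merged exons and a strand-aware TSS."""

    gene_id: str
    body: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)
        for ex in self.exons:
            if ex.chrom != self.body.chrom:
                raise ValueError(
                    f"exon chromosome {ex.chrom} != gene body {self.body.chrom}"
                    f" for {self.gene_id}"
                )
            if ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(
                    f"exon {ex.start}-{ex.end} outside body of {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        """Transcription start site: body start on '+', body end on '-'."""
        return self.body.end if self.body.strand == "-" else self.body.start

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gene body minus merged exons."""
        out: list[GenomicInterval] = []
        cursor = self.body.start
        for ex in self.exons:
            if ex.start > cursor:
                out.append(
                    GenomicInterval(
                        self.body.chrom, cursor, ex.start - 1, self.body.strand
                    )
                )
            cursor = max(cursor, ex.end + 1)
        if cursor <= self.body.end:
            out.append(
                GenomicInterval(
                    self.body.chrom, cursor, self.body.end, self.body.strand
                )
            )
        return out

    def promoter(self, upstream: int = 1000, downstream: int = 1000) -> GenomicInterval:
        """Strand-aware promoter window around the TSS."""
        if self.body.strand == "-":
            start, end = self.tss - downstream, self.tss + upstream
        else:
            start, end = self.tss - upstream, self.tss + downstream
        return GenomicInterval(self.body.chrom, max(1, start), end, self.body.strand)
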