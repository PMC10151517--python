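"""Coordinate arithmetic for enhancer and promoter windows.

All coordinates are 0-based, half-open (BED/bigWig convention). An enhancer
window extends 1000 bp either side of the midpoint of a candidate regulatory
element, giving a fixed 2000 bp region. A promoter window covers 2000 bp
upstream and 500 bp downstream of the transcription start site, where
"upstream" is defined by the gene's strand, giving a fixed 2500 bp region.
Pair distance is the unsigned base-pair separation of the two window
midpoints.

Windows that would cross a chromosome boundary are rejected rather than
clipped: clipping would change the number of signal bins and break the fixed
feature-matrix geometry downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

ENHANCER_FLANK = 1000  # bp either side of the element midpoint
PROMOTER_UPSTREAM = 2000  # bp upstream of the TSS
PROMOTER_DOWNSTREAM = 500  # bp downstream of the TSS

ENHANCER_WINDOW_LENGTH = 2 * ENHANCER_FLANK
PROMOTER_WINDOW_LENGTH = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic region, optionally stranded.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    start : int
        Start offset, 0-based inclusive.
    end : int
        End offset, exclusive. Must satisfy ``start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint; deterministic for odd-length intervals."""
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class TssRecord:
    """One transcription start site: identifier, position and strand."""

    id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS {self.id}: negative position {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"TSS {self.id}: strand must be '+' or '-', got {self.strand!r}"
            )


def make_enhancer_window(ccre: GenomicInterval) -> GenomicInterval:
    """Build the 2000 bp enhancer window centred on the element midpoint.

    The window spans ``[mid - 1000, mid + 1000)`` with ``mid`` the floor
    midpoint of the element. The result is unstranded. A window with a
    negative start is returned as-is; boundary checking is the job of
    :func:`clip_or_reject`, which needs the chromosome size.
    """
    mid = ccre.midpoint
    return GenomicInterval(ccre.chrom, mid - ENHANCER_FLANK, mid + ENHANCER_FLANK, ".")


def make_promoter_window(tss: TssRecord) -> GenomicInterval:
    """Build the 2500 bp promoter window around a TSS, strand-aware.

    On the plus strand the window is ``[pos - 2000, pos + 500)``; on the
    minus strand it is the mirror image ``[pos - 500, pos + 2000)``. The
    strand is copied from the TSS record.
    """
    if tss.strand == "+":
        start = tss.pos - PROMOTER_UPSTREAM
        end = tss.pos + PROMOTER_DOWNSTREAM
    else:
        start = tss.pos - PROMOTER_DOWNSTREAM
        end = tss.pos + PROMOTER_UPSTREAM
    return GenomicInterval(tss.chrom, start, end, tss.strand)


def pair_distance(enh: GenomicInterval, pro: GenomicInterval) -> int:
    """Unsigned bp distance between the midpoints of two same-chromosome windows."""
    if enh.chrom != pro.chrom:
        raise ValueError(
            f"trans-chromosomal pair not supported: {enh.chrom} vs {pro.chrom}"
        )
    return abs(enh.midpoint - pro.midpoint)


def clip_or_reject(w: GenomicInterval, chrom_size: int) -> GenomicInterval | None:
    """Return ``w`` unchanged if it lies within ``[0, chrom_size)``, else ``None``.

    Rejection (returning ``None``) rather than truncation keeps window
    lengths, and hence bin counts, fixed.
    """
    if chrom_size <= 0:
        raise ValueError(f"chromosome size must be positive, got {chrom_size}")
    if w.start < 0 or w.end > chrom_size:
        return None
    return w
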