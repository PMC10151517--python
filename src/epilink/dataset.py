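"""Benchmark-pair I/O: loaders, label filters, ID resolution, splits.

Pair lists give only element identifiers and a binary interaction label;
coordinates come from two side tables (a BED file of candidate regulatory
elements and a TSV of transcription start sites). This module resolves IDs
to fixed-width windows, applies the duplicate/ambiguity filters, and
produces stratified train/test splits that preserve the class ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coords import (
    GenomicInterval,
    TssRecord,
    clip_or_reject,
    make_enhancer_window,
    make_promoter_window,
    pair_distance,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class RawPair:
    """One benchmark row: element IDs plus a 0/1 interaction label."""

    ccre_id: str
    tss_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True, slots=True)
class AnchorPair:
    """A resolved pair: enhancer and promoter windows, distance and label."""

    enhancer: GenomicInterval
    promoter: GenomicInterval
    distance: int
    label: int
    ccre_id: str
    tss_id: str


@dataclass(frozen=True, slots=True)
class SplitSpec:
    """Stratified train/test split parameters (default 80/20)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ResolutionReport:
    """Bookkeeping for pairs dropped while resolving IDs to windows."""

    resolved: int = 0
    unresolved: int = 0  # unknown cCRE or TSS id
    trans: int = 0  # anchors on different chromosomes
    boundary: int = 0  # window crosses a chromosome edge
    ambiguous_removed: int = 0  # filled in by filter_pairs when chained
    details: list = field(default_factory=list)

    @property
    def dropped(self) -> int:
        return self.unresolved + self.trans + self.boundary

    def as_dict(self) -> dict:
        return {
            "resolved": self.resolved,
            "unresolved": self.unresolved,
            "trans": self.trans,
            "boundary": self.boundary,
            "ambiguous_removed": self.ambiguous_removed,
        }


class PairFileError(ValueError):
    """Malformed or inconsistent input file."""


def load_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV into ``{name: length}``."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PairFileError(f"{path}:{lineno}: expected two columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise PairFileError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return sizes


def load_ccre_bed(path) -> dict[str, GenomicInterval]:
    """Read a BED file of candidate regulatory elements keyed by column-4 ID.

    Duplicate IDs with identical coordinates collapse silently; duplicate IDs
    with conflicting coordinates raise :class:`PairFileError` — guessing a
    canonical interval would silently shift windows.
    """
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise PairFileError(
                    f"{path}:{lineno}: BED needs >= 4 columns (id in column 4)"
                )
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise PairFileError(f"{path}:{lineno}: {exc}") from exc
            name = parts[3]
            prev = out.get(name)
            if prev is not None and (prev.chrom, prev.start, prev.end) != (
                iv.chrom,
                iv.start,
                iv.end,
            ):
                raise PairFileError(
                    f"{path}:{lineno}: id {name!r} already seen with different coordinates"
                )
            out[name] = iv
    return out


def load_tss_table(path, one_based: bool = False) -> dict[str, TssRecord]:
    """Read a TSS table: TSV of (id, chrom, position, strand).

    ``one_based=True`` converts positions from a 1-based dialect by
    subtracting 1. Strand must be '+' or '-': the promoter window is
    strand-aware, so an undefined strand is a hard error. Duplicate IDs
    are rejected; the table must be pre-collapsed to one TSS per gene.
    """
    out: dict[str, TssRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise PairFileError(f"{path}:{lineno}: expected (id, chrom, pos, strand)")
            tid, chrom, pos_s, strand = parts[0], parts[1], parts[2], parts[3]
            if strand not in ("+", "-"):
                raise PairFileError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            if tid in out:
                raise PairFileError(f"{path}:{lineno}: duplicate TSS id {tid!r}")
            try:
                pos = int(pos_s) - (1 if one_based else 0)
            except ValueError as exc:
                raise PairFileError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            out[tid] = TssRecord(tid, chrom, pos, strand)
    return out


def load_pairs(path) -> list[RawPair]:
    """Read a pair list: TSV of (ccre_id, tss_id, label), order preserved."""
    out: list[RawPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PairFileError(f"{path}:{lineno}: expected (ccre_id, tss_id, label)")
            if parts[2] not in ("0", "1"):
                raise PairFileError(
                    f"{path}:{lineno}: label must be 0 or 1, got {parts[2]!r}"
                )
            out.append(RawPair(parts[0], parts[1], int(parts[2])))
    return out


def filter_pairs(
    pairs: list[RawPair], report: ResolutionReport | None = None
) -> list[RawPair]:
    """Collapse exact duplicates and drop label-ambiguous keys.

    Two filters, in this order:

    1. exact duplicate (ccre_id, tss_id, label) triples collapse to one;
    2. any (ccre_id, tss_id) key observed with *both* labels is removed
       entirely — a pair cannot both interact and not interact, and there
       is no basis in the input schema for preferring either record.

    Output preserves first-occurrence order, so the filter is idempotent.
    """
    seen_triples: set[tuple[str, str, int]] = set()
    deduped: list[RawPair] = []
    labels_by_key: dict[tuple[str, str], set[int]] = {}
    for p in pairs:
        triple = (p.ccre_id, p.tss_id, p.label)
        if triple in seen_triples:
            continue
        seen_triples.add(triple)
        deduped.append(p)
        labels_by_key.setdefault((p.ccre_id, p.tss_id), set()).add(p.label)

    kept = [p for p in deduped if len(labels_by_key[(p.ccre_id, p.tss_id)]) == 1]
    n_ambiguous = len(deduped) - len(kept)
    if n_ambiguous:
        logger.info("removed %d label-ambiguous pair records", n_ambiguous)
    if report is not None:
        report.ambiguous_removed += n_ambiguous
    return kept


def resolve_pairs(
    raw: list[RawPair],
    ccres: dict[str, GenomicInterval],
    tsss: dict[str, TssRecord],
    chrom_sizes: dict[str, int],
) -> tuple[list[AnchorPair], ResolutionReport]:
    """Resolve ID pairs to anchored window pairs, dropping the unresolvable.

    Drops (counted in the report, never fatal): unknown IDs, anchors on
    different chromosomes, and windows crossing a chromosome boundary.
    """
    report = ResolutionReport()
    out: list[AnchorPair] = []
    for p in raw:
        ccre = ccres.get(p.ccre_id)
        tss = tsss.get(p.tss_id)
        if ccre is None or tss is None:
            report.unresolved += 1
            report.details.append((p.ccre_id, p.tss_id, "unknown id"))
            continue
        if ccre.chrom != tss.chrom:
            report.trans += 1
            report.details.append((p.ccre_id, p.tss_id, "trans-chromosomal"))
            continue
        size = chrom_sizes.get(ccre.chrom)
        if size is None:
            report.unresolved += 1
            report.details.append((p.ccre_id, p.tss_id, "chromosome not in sizes table"))
            continue
        enh = clip_or_reject(make_enhancer_window(ccre), size)
        pro = clip_or_reject(make_promoter_window(tss), size)
        if enh is None or pro is None:
            report.boundary += 1
            report.details.append((p.ccre_id, p.tss_id, "window crosses boundary"))
            continue
        out.append(
            AnchorPair(enh, pro, pair_distance(enh, pro), p.label, p.ccre_id, p.tss_id)
        )
    report.resolved = len(out)
    return out, report


def stratified_split(
    pairs: list[AnchorPair], spec: SplitSpec
) -> tuple[list[AnchorPair], list[AnchorPair]]:
    """Random per-class 80/20 (by default) partition under a stored seed.

    Within each class the train side takes ``floor(fraction * n)`` members;
    the remainder goes to the test side, so the class ratio is preserved to
    within one sample per class. Output order follows the input order.
    """
    labels = {p.label for p in pairs}
    if labels != {0, 1}:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(spec.seed)
    train_idx: set[int] = set()
    for cls in (0, 1):
        idx = np.array([i for i, p in enumerate(pairs) if p.label == cls])
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        n_train = int(np.floor(spec.train_fraction * len(idx)))
        chosen = rng.permutation(idx)[:n_train]
        train_idx.update(int(i) for i in chosen)
    train = [p for i, p in enumerate(pairs) if i in train_idx]
    test = [p for i, p in enumerate(pairs) if i not in train_idx]
    return train, test


def write_split_manifest(path, train: list[AnchorPair], test: list[AnchorPair]) -> None:
    """Write pair-ID membership lists so a split is exactly reconstructible."""
    with open(path, "w") as fh:
        for name, part in (("train", train), ("test", test)):
            for p in part:
                fh.write(f"{name}\t{p.ccre_id}\t{p.tss_id}\t{p.label}\n")
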