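"""Self-contained synthetic fixtures: genome, annotations, pairs, tracks.

Generates all five input kinds the pipeline consumes — a chromosome-sizes
table, a BED of candidate regulatory elements, a TSS table, a labelled pair
list, and one bigWig per signal track — with a planted statistical
structure: interacting (positive) pairs have all three tracks enriched over
both anchor windows, and their anchor separation follows an exponential
distance decay, emulating the empirical signature of real chromatin
interactions. Negative pairs see background signal only (unless they share
an anchor with a positive pair, in which case the anchor keeps its
enrichment — realistic leakage: one enhancer may contact one promoter but
not another).

Per-base signal is ``max(0, background + Gaussian noise)`` plus the
enrichment effect over positive anchors; truncation at zero reflects the
non-negativity of coverage signals. Everything is deterministic under the
config seed, down to byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pyBigWig

from .coords import (
    GenomicInterval,
    TssRecord,
    make_enhancer_window,
    make_promoter_window,
    pair_distance,
)
from .dataset import RawPair
from .features import DEFAULT_TRACK_ORDER

# margin keeping every enhancer/promoter window clear of chromosome edges
_EDGE_MARGIN = 3000
# minimum separation between placed element anchors (elements never overlap)
_MIN_SEP = 700


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    The 1:4 negative:positive ratio mirrors the benchmark design; the
    default enrichment effect of 3 signal units over a noise SD of 1
    (background 1) plants a clearly learnable but noisy contrast.
    ``distance_decay`` is the exponential scale (bp) of positive-pair
    anchor separation; 50 kb is a typical enhancer-promoter contact scale.
    Candidate elements greatly outnumber interacting pairs (300 + 300
    elements vs 100 positives by default) so that, as in real benchmarks,
    most elements are anchors of no true interaction and most negative
    pairs touch at least one unenriched anchor.

    Noise is drawn once per ``noise_block`` bp and held constant within the
    block (default 50 bp, the sequencing-fragment scale): real coverage
    fluctuates at fragment resolution, not independently per base, so bin
    averaging does not wash the noise out. ``noise_block=1`` recovers
    independent per-base noise.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_ccres: int = 300
    n_tsss: int = 300
    n_positive: int = 100
    neg_per_pos: int = 4
    enrichment_effect: float = 3.0
    background_level: float = 1.0
    noise_sd: float = 1.0
    noise_block: int = 50
    distance_decay: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_ccres", "n_tsss", "n_positive", "neg_per_pos"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Annotations:
    chrom_sizes: dict[str, int]
    ccres: dict[str, GenomicInterval]
    tsss: dict[str, TssRecord]


def _place_positions(rng, n: int, lo: int, hi: int, sep: int) -> np.ndarray:
    """n sorted positions in [lo, hi) pairwise >= sep apart (uniform given feasibility)."""
    span = hi - lo - (n - 1) * sep
    if span <= 0:
        raise ValueError(
            f"cannot place {n} elements with {sep} bp separation in {hi - lo} bp; "
            "increase chrom_length or reduce element counts"
        )
    raw = np.sort(rng.integers(0, span, size=n))
    return lo + raw + sep * np.arange(n)


def simulate_annotations(cfg: SyntheticConfig, rng=None) -> Annotations:
    """Place non-overlapping elements and TSSs with edge margins.

    Elements are spread round-robin across chromosomes; every position
    keeps enough margin that no derived window is boundary-rejected.
    Strands are assigned uniformly at random to TSSs.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    ccres: dict[str, GenomicInterval] = {}
    tsss: dict[str, TssRecord] = {}
    per_chrom_c = np.bincount(np.arange(cfg.n_ccres) % cfg.n_chroms, minlength=cfg.n_chroms)
    per_chrom_t = np.bincount(np.arange(cfg.n_tsss) % cfg.n_chroms, minlength=cfg.n_chroms)
    ci = ti = 0
    for k, chrom in enumerate(chrom_sizes):
        n_here = int(per_chrom_c[k] + per_chrom_t[k])
        if n_here == 0:
            continue
        pos = _place_positions(
            rng, n_here, _EDGE_MARGIN, cfg.chrom_length - _EDGE_MARGIN, _MIN_SEP
        )
        # interleave element kinds at the placed slots, deterministically
        kinds = np.array(["C"] * int(per_chrom_c[k]) + ["T"] * int(per_chrom_t[k]))
        rng.shuffle(kinds)
        for p, kind in zip(pos, kinds):
            if kind == "C":
                length = int(rng.integers(150, 351))
                start = int(p) - length // 2
                ccres[f"CCRE{ci:05d}"] = GenomicInterval(chrom, start, start + length)
                ci += 1
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                tsss[f"TSS{ti:05d}"] = TssRecord(f"TSS{ti:05d}", chrom, int(p), strand)
                ti += 1
    return Annotations(chrom_sizes, ccres, tsss)


def simulate_pairs(cfg: SyntheticConfig, ann: Annotations, rng=None) -> list[RawPair]:
    """Draw labelled pairs: positives distance-decayed, negatives uniform.

    Positive pairs are sampled without replacement with probability
    proportional to ``exp(-d / distance_decay)`` over all same-chromosome
    element-TSS combinations; negatives are drawn uniformly from the
    remaining combinations, so positive and negative keys never overlap.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    combos: list[tuple[str, str, int]] = []
    for cid, ccre in ann.ccres.items():
        enh = make_enhancer_window(ccre)
        for tid, tss in ann.tsss.items():
            if tss.chrom != ccre.chrom:
                continue
            d = pair_distance(enh, make_promoter_window(tss))
            combos.append((cid, tid, d))
    n_neg = cfg.n_positive * cfg.neg_per_pos
    if len(combos) < cfg.n_positive + n_neg:
        raise ValueError(
            f"only {len(combos)} same-chromosome combinations available; "
            f"need {cfg.n_positive + n_neg} — add elements or chromosomes"
        )
    dist = np.array([c[2] for c in combos], dtype=float)
    w = np.exp(-dist / cfg.distance_decay)
    w /= w.sum()
    idx_pos = rng.choice(len(combos), size=cfg.n_positive, replace=False, p=w)
    remaining = np.setdiff1d(np.arange(len(combos)), idx_pos)
    idx_neg = rng.choice(remaining, size=n_neg, replace=False)
    pairs = [RawPair(combos[i][0], combos[i][1], 1) for i in sorted(idx_pos)]
    pairs += [RawPair(combos[i][0], combos[i][1], 0) for i in sorted(idx_neg)]
    return pairs


def _positive_anchor_windows(
    ann: Annotations, pairs: list[RawPair]
) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome (start, end) windows of every positive-pair anchor."""
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in ann.chrom_sizes}
    for p in pairs:
        if p.label != 1:
            continue
        enh = make_enhancer_window(ann.ccres[p.ccre_id])
        pro = make_promoter_window(ann.tsss[p.tss_id])
        per_chrom[enh.chrom].append((enh.start, enh.end))
        per_chrom[pro.chrom].append((pro.start, pro.end))
    return per_chrom


def simulate_tracks(
    cfg: SyntheticConfig,
    ann: Annotations,
    pairs: list[RawPair],
    out_dir,
    track_names: tuple[str, ...] = DEFAULT_TRACK_ORDER,
    rng=None,
) -> dict[str, str]:
    """Write one bigWig per track with enrichment planted at positive anchors.

    Anchors shared between several positive pairs accumulate their effect;
    anchors belonging only to negative pairs stay at background.
    Returns ``{track name: file path}``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    anchors = _positive_anchor_windows(ann, pairs)
    paths: dict[str, str] = {}
    header = [(c, int(L)) for c, L in ann.chrom_sizes.items()]
    for name in track_names:
        path = os.path.join(out_dir, f"{name}.bw")
        bw = pyBigWig.open(path, "w")
        bw.addHeader(header)
        for chrom, length in header:
            n_blocks = -(-length // cfg.noise_block)
            noise = np.repeat(
                rng.normal(0.0, cfg.noise_sd, size=n_blocks), cfg.noise_block
            )[:length]
            signal = np.maximum(cfg.background_level + noise, 0.0)
            for start, end in anchors[chrom]:
                signal[start:end] += cfg.enrichment_effect
            bw.addEntries(
                chrom, 0, values=signal.astype(np.float32), span=1, step=1
            )
        bw.close()
        paths[name] = path
    return paths


def write_annotations(ann: Annotations, out_dir) -> dict[str, str]:
    """Write chrom.sizes, element BED and TSS TSV; returns their paths."""
    paths = {
        "chrom_sizes": os.path.join(out_dir, "genome.chrom.sizes"),
        "ccre_bed": os.path.join(out_dir, "ccres.bed"),
        "tss_table": os.path.join(out_dir, "tss.tsv"),
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, length in ann.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    with open(paths["ccre_bed"], "w") as fh:
        for cid, iv in ann.ccres.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cid}\n")
    with open(paths["tss_table"], "w") as fh:
        for tid, t in ann.tsss.items():
            fh.write(f"{tid}\t{t.chrom}\t{t.pos}\t{t.strand}\n")
    return paths


def write_pairs(pairs: list[RawPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.ccre_id}\t{p.tss_id}\t{p.label}\n")


def make_fixture_bundle(cfg: SyntheticConfig, out_dir) -> dict:
    """Generate and write the full input bundle plus a manifest.

    One root RNG seeded from ``cfg.seed`` drives annotation placement, pair
    sampling and track noise in a fixed order, so the same config always
    yields byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    ann = simulate_annotations(cfg, rng)
    pairs = simulate_pairs(cfg, ann, rng)
    paths = write_annotations(ann, out_dir)
    paths["pairs"] = os.path.join(out_dir, "pairs.tsv")
    write_pairs(pairs, paths["pairs"])
    track_paths = simulate_tracks(cfg, ann, pairs, out_dir, rng=rng)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "paths": {**paths, "tracks": track_paths},
        "n_pairs": len(pairs),
        "n_positive": sum(p.label for p in pairs),
    }
    # the on-disk manifest uses paths relative to its own directory, so two
    # bundles from the same seed are byte-identical wherever they live
    rel = {
        k: os.path.basename(v)
        for k, v in manifest["paths"].items()
        if k != "tracks"
    }
    rel["tracks"] = {k: os.path.basename(v) for k, v in track_paths.items()}
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({**manifest, "paths": rel}, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = manifest_path
    return manifest
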