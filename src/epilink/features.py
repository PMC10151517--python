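"""Binned bigWig signal extraction and feature-matrix assembly.

Each enhancer window (2000 bp) is divided into 40 bins and each promoter
window (2500 bp) into 50 bins of 50 bp. For every signal track the per-bin
value is the arithmetic mean of the per-base signal, with bases absent from
the track counted as 0 — the only convention under which "no data" and
"zero coverage" agree. With the default three tracks (ATAC-seq, H3K27ac,
RAD21) a pair is represented by 40x3 = 120 enhancer values, 50x3 = 150
promoter values, and the raw midpoint distance in bp: 271 columns in a
fixed, documented order.

Bins are oriented 5'->3' relative to the element: on a minus-strand window
the bin order is reversed so bin 0 is always the far-upstream end. This is
a config flag (``strand_aware``) defaulting to on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pyBigWig

from .coords import GenomicInterval
from .dataset import AnchorPair

DEFAULT_BIN_WIDTH = 50
ENHANCER_BINS = 40
PROMOTER_BINS = 50
DEFAULT_TRACK_ORDER = ("ATAC", "H3K27ac", "RAD21")


class SignalTrack:
    """A named bigWig signal track opened for reading.

    Parameters
    ----------
    name : str
        Track role, e.g. ``"ATAC"``, ``"H3K27ac"``, ``"RAD21"`` — or any
        user-supplied name in generic N-track mode.
    path : str
        Path to the bigWig file.
    """

    def __init__(self, name: str, path: str):
        self.name = name
        self.path = str(path)
        self._bw = pyBigWig.open(self.path)
        if self._bw is None:
            raise OSError(f"cannot open bigWig {path!r}")

    @property
    def chroms(self) -> dict[str, int]:
        return self._bw.chroms()

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._bw.chroms():
            raise KeyError(f"chromosome {chrom!r} absent from track {self.name!r}")
        return self._bw.values(chrom, start, end, numpy=True)

    def close(self) -> None:
        self._bw.close()

    def __enter__(self) -> "SignalTrack":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def __repr__(self) -> str:
        return f"SignalTrack({self.name!r}, {self.path!r})"


@dataclass(frozen=True)
class BinnedProfile:
    """Per-bin mean signal over one window on one track."""

    values: np.ndarray
    bin_width: int
    n_bins: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n_bins:
            raise ValueError("values length must equal n_bins")


def extract_binned_signal(
    track: SignalTrack,
    w: GenomicInterval,
    bin_width: int = DEFAULT_BIN_WIDTH,
    strand_aware: bool = True,
) -> BinnedProfile:
    """Mean per-base signal in consecutive ``bin_width`` bp bins over ``w``.

    Bin ``i`` covers ``[start + i*bin_width, start + (i+1)*bin_width)``.
    Bases with no data in the track count as 0. If ``strand_aware`` and the
    window is on the minus strand, bin order is reversed so that bin 0 is
    5'-most relative to the element.
    """
    length = len(w)
    if length % bin_width != 0:
        raise ValueError(
            f"window length {length} not divisible by bin width {bin_width}"
        )
    n_bins = length // bin_width
    vals = track.values(w.chrom, w.start, w.end)
    vals = np.nan_to_num(np.asarray(vals, dtype=np.float64), nan=0.0)
    binned = vals.reshape(n_bins, bin_width).mean(axis=1)
    if strand_aware and w.strand == "-":
        binned = binned[::-1]
    return BinnedProfile(np.ascontiguousarray(binned), bin_width, n_bins)


def feature_schema(
    track_names: tuple[str, ...] = DEFAULT_TRACK_ORDER,
    bin_width: int = DEFAULT_BIN_WIDTH,
    enhancer_bins: int = ENHANCER_BINS,
    promoter_bins: int = PROMOTER_BINS,
    strand_aware: bool = True,
) -> dict:
    """The frozen column schema: names, geometry, and a content hash.

    Layout: for each track in order, the enhancer bins; then for each track
    in order, the promoter bins; then the distance column. Any fixed order
    works for tree ensembles, but persistence and cross-cell-line transfer
    require one canonical schema, enforced by hash comparison.
    """
    columns = [
        f"enh_{t}_bin{i:02d}" for t in track_names for i in range(enhancer_bins)
    ]
    columns += [
        f"pro_{t}_bin{i:02d}" for t in track_names for i in range(promoter_bins)
    ]
    columns.append("distance")
    schema = {
        "tracks": list(track_names),
        "bin_width": bin_width,
        "enhancer_bins": enhancer_bins,
        "promoter_bins": promoter_bins,
        "strand_aware": strand_aware,
        "columns": columns,
    }
    payload = json.dumps(schema, sort_keys=True).encode()
    schema["hash"] = hashlib.sha256(payload).hexdigest()[:16]
    return schema


def assemble_feature_vector(
    pair: AnchorPair,
    tracks: list[SignalTrack],
    bin_width: int = DEFAULT_BIN_WIDTH,
    strand_aware: bool = True,
) -> np.ndarray:
    """One feature row: enhancer bins per track, promoter bins per track, distance."""
    if not tracks:
        raise ValueError("at least one signal track is required")
    blocks = [
        extract_binned_signal(t, pair.enhancer, bin_width, strand_aware).values
        for t in tracks
    ]
    blocks += [
        extract_binned_signal(t, pair.promoter, bin_width, strand_aware).values
        for t in tracks
    ]
    blocks.append(np.array([float(pair.distance)]))
    return np.concatenate(blocks)


def build_matrix(
    pairs: list[AnchorPair],
    tracks: list[SignalTrack],
    bin_width: int = DEFAULT_BIN_WIDTH,
    strand_aware: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Stack feature vectors for a pair list; rows follow input order.

    Returns ``(matrix, labels, schema)``. Extraction errors are re-raised
    with the offending pair's IDs attached.
    """
    if not pairs:
        raise ValueError("empty pair list")
    enh_bins = len(pairs[0].enhancer) // bin_width
    pro_bins = len(pairs[0].promoter) // bin_width
    schema = feature_schema(
        tuple(t.name for t in tracks), bin_width, enh_bins, pro_bins, strand_aware
    )
    rows = []
    for p in pairs:
        try:
            rows.append(assemble_feature_vector(p, tracks, bin_width, strand_aware))
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for pair ({p.ccre_id}, {p.tss_id}): {exc}"
            ) from exc
    matrix = np.vstack(rows)
    labels = np.array([p.label for p in pairs], dtype=np.int64)
    if matrix.shape[1] != len(schema["columns"]):
        raise AssertionError("matrix width disagrees with schema")
    return matrix, labels, schema


def save_matrix(path_prefix: str, matrix: np.ndarray, labels: np.ndarray, schema: dict) -> None:
    """Persist matrix as TSV with a schema header plus a schema JSON sidecar."""
    import pandas as pd

    df = pd.DataFrame(matrix, columns=schema["columns"])
    df["label"] = labels
    df.to_csv(f"{path_prefix}.tsv", sep="\t", index=False, float_format="%.10g")
    with open(f"{path_prefix}.schema.json", "w") as fh:
        json.dump(schema, fh, indent=2, sort_keys=True)


def load_matrix(path_prefix: str) -> tuple[np.ndarray, np.ndarray, dict]:
    """Load a matrix written by :func:`save_matrix`."""
    import pandas as pd

    df = pd.read_csv(f"{path_prefix}.tsv", sep="\t")
    with open(f"{path_prefix}.schema.json") as fh:
        schema = json.load(fh)
    labels = df.pop("label").to_numpy(dtype=np.int64)
    if list(df.columns) != schema["columns"]:
        raise ValueError("matrix columns do not match schema")
    return df.to_numpy(dtype=np.float64), labels, schema
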