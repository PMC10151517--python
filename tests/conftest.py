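import numpy as np
import pyBigWig
import pytest

from epilink import pipeline, simulate

# Small but fully-featured study conditions shared across tests: two
# chromosomes, sparse elements, 30 positives at the 1:4 ratio.
SMALL_CFG = simulate.SyntheticConfig(
    n_chroms=2,
    chrom_length=200_000,
    n_ccres=60,
    n_tsss=60,
    n_positive=30,
    neg_per_pos=4,
    seed=7,
)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A complete synthetic input bundle written once per session."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = simulate.make_fixture_bundle(SMALL_CFG, out)
    return manifest


@pytest.fixture(scope="session")
def extracted(bundle):
    """(matrix, labels, schema, pairs, report) for the session bundle."""
    paths = bundle["paths"]
    return pipeline.extract_features(
        paths["pairs"], paths["ccre_bed"], paths["tss_table"],
        paths["chrom_sizes"], paths["tracks"],
    )


def write_bigwig(path, chrom_arrays):
    """Write {chrom: float array with NaN = no data} to a bigWig file.

    Covered runs are written as exact-interval entries, so the NaN pattern
    survives the round trip and the in-memory array is the ground truth.
    """
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(c, len(a)) for c, a in chrom_arrays.items()])
    for chrom, arr in chrom_arrays.items():
        covered = ~np.isnan(arr)
        if not covered.any():
            continue
        # run-length encode the covered stretches
        edges = np.flatnonzero(np.diff(covered.astype(np.int8)))
        starts = [0] if covered[0] else []
        starts += (edges[~covered[edges]] + 1).tolist()
        ends = (edges[covered[edges]] + 1).tolist()
        if covered[-1]:
            ends.append(len(arr))
        for s, e in zip(starts, ends):
            bw.addEntries(
                chrom,
                np.arange(s, e, dtype=np.int64),
                values=arr[s:e].astype(np.float64),
                span=1,
            )
    bw.close()


def random_track(rng, length, gap_fraction=0.3, block=137):
    """A random per-base signal with NaN gaps, in blocks of ~`block` bp.

    Values are quantised to float32 (the bigWig storage precision) so the
    returned array is exactly what a reader will see.
    """
    arr = rng.gamma(2.0, 1.5, size=length)
    n_blocks = length // block + 1
    gaps = rng.random(n_blocks) < gap_fraction
    mask = np.repeat(gaps, block)[:length]
    arr[mask] = np.nan
    return arr.astype(np.float32).astype(np.float64)
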