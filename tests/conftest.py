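import numpy as np
import pytest

from sinreg.annotation_io import GeneModel, GenomeAnnotation
from sinreg.signal_tracks import SignalTrack


@pytest.fixture
def three_gene_annotation() -> GenomeAnnotation:
    ann = GenomeAnnotation()
    ann.add(GeneModel("gA", "chr2L", 5000, 8000, "+"))
    ann.add(GeneModel("gB", "chr2L", 12000, 20000, "-"))
    ann.add(GeneModel("gC", "chr3R", 1000, 4500, "+"))
    return ann


def random_track(rng: np.random.Generator, chrom: str = "chr1",
                 chrom_len: int = 10_000, n_intervals: int = 40) -> tuple:
    """A random non-overlapping track plus its dense per-base expansion."""
    cuts = np.sort(rng.choice(chrom_len, size=2 * n_intervals, replace=False))
    dense = np.zeros(chrom_len)
    intervals = []
    for s, e in cuts.reshape(-1, 2):
        if s == e:
            continue
        v = float(rng.uniform(0.1, 10.0))
        intervals.append((chrom, int(s), int(e), v))
        dense[s:e] = v
    track = SignalTrack.from_intervals(intervals)
    return track, dense
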