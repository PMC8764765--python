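import numpy as np
import pytest

from isowin.windowing import (
    GenomicInterval,
    WindowingConfig,
    derive_gene_model,
    merge_exons,
    build_windows,
)


def make_model(exon_bounds, chrom="chr1", strand="+", flank=1500, chrom_length=None,
               gene_id="gX", n_w=3):
    """Flattened gene model + windows from raw exon bounds."""
    cfg = WindowingConfig(n_w=n_w, flank_length=flank)
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds]
    model = derive_gene_model(gene_id, merge_exons(exons), chrom_length, cfg)
    return model, build_windows(model, cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_gene_bounds(rng, n_exons=None, lo=2000):
    """Random non-degenerate exon bounds for property tests."""
    if n_exons is None:
        n_exons = int(rng.integers(1, 9))
    pos = lo + int(rng.integers(0, 1000))
    bounds = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 400))
        bounds.append((pos, pos + length))
        pos += length + int(rng.integers(50, 2000))
    return bounds
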