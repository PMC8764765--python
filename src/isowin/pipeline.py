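"""End-to-end helpers gluing the simulator, windowing, counting, and
classification stages without intermediate files.

The simulated-data path counts reads directly from the in-memory block
arrays the simulator produces, which is what makes cohort-scale simulation
studies tractable; the file-based path (BED12/BAM -> windows BED -> feature
matrix TSVs) exposed by the CLI produces identical matrices on the same
inputs.
"""

from __future__ import annotations

import logging
import numpy as np

from .classify import ModelSpec, GeneFitResult, fit_gene, UntestableGene
from .counting import CountMatrix, FeatureMatrix, count_blocks, filter_low_coverage_samples, normalize_proportions
from .simulate import SimDataset, gene_sample_reads
from .windowing import (
    GeneModel,
    Window,
    WindowingConfig,
    build_windows,
    derive_gene_model,
    merge_exons,
    GenomicInterval,
)

logger = logging.getLogger(__name__)


def dataset_gene_models(
    dataset: SimDataset, config: WindowingConfig = WindowingConfig()
) -> dict[str, GeneModel]:
    """Flattened gene models from a dataset's public (canonical-only)
    annotation."""
    from .simulate import chrom_length

    clen = chrom_length(dataset)
    models = {}
    for g in dataset.genes:
        exons = [GenomicInterval(g.chrom, s, e, g.strand) for s, e in g.canonical]
        models[g.gene_id] = derive_gene_model(g.gene_id, merge_exons(exons), clen, config)
    return models


def dataset_windows(
    dataset: SimDataset, config: WindowingConfig = WindowingConfig()
) -> tuple[dict[str, GeneModel], dict[str, list[Window]]]:
    models = dataset_gene_models(dataset, config)
    return models, {gid: build_windows(m, config) for gid, m in models.items()}


def count_dataset(
    dataset: SimDataset,
    windows_by_gene: dict[str, list[Window]],
    min_reads: int = 10,
) -> dict[str, FeatureMatrix]:
    """Simulate reads gene by gene and produce the per-gene normalized
    feature matrices (low-coverage samples already filtered)."""
    truth = dataset.truth
    labels = truth.labels()
    matrices: dict[str, FeatureMatrix] = {}
    n_samples = len(truth.sample_ids)
    for gi, gene in enumerate(dataset.genes):
        windows = windows_by_gene[gene.gene_id]
        w_starts = np.array([w.interval.start for w in windows], dtype=np.int64)
        w_ends = np.array([w.interval.end for w in windows], dtype=np.int64)
        counts = np.zeros((n_samples, len(windows)), dtype=np.int64)
        totals = np.zeros(n_samples, dtype=np.int64)
        for si in range(n_samples):
            rid, bs, be = gene_sample_reads(dataset, gi, si)
            c, tot = count_blocks(w_starts, w_ends, bs, be, rid)
            counts[si] = c
            totals[si] = tot
        cm = CountMatrix(gene.gene_id, list(truth.sample_ids), windows, counts, totals)
        cm = filter_low_coverage_samples(cm, min_reads=min_reads)
        if not cm.samples:
            logger.warning("gene %s untestable: all samples below %d reads", gene.gene_id, min_reads)
            continue
        matrices[gene.gene_id] = normalize_proportions(cm, labels)
    return matrices


def fit_all(
    matrices: dict[str, FeatureMatrix],
    spec: ModelSpec,
    seed: int = 0,
    frac: float = 0.8,
) -> list[GeneFitResult]:
    """Fit one model per gene; untestable genes are skipped with a warning."""
    results = []
    for gene_id, fm in matrices.items():
        try:
            results.append(fit_gene(fm, spec, seed=seed, frac=frac))
        except UntestableGene as exc:
            logger.warning("gene %s untestable: %s", gene_id, exc)
    return results
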