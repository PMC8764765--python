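"""Alternative-splicing read simulator.

Generates synthetic multi-exon genes on a synthetic chromosome, assigns each
an alternative-splicing (AS) event from nine event types, and samples spliced
single-end reads for a two-group cohort.  "Affected" samples (group 1)
express both the canonical and the AS-variant isoform of every AS gene;
unaffected samples (group 2) express only the canonical isoform.  Matched
null datasets carry no AS events and random group labels, preserving the
group-size split.

The public annotation written for a dataset contains the canonical
transcript only — the variant isoform is withheld, emulating the detection
of unannotated isoforms from read distributions alone.

Per-gene expression weights are log-normal(0, 0.5), fixed across samples
within a dataset; each sample's read count per gene is Poisson with mean
proportional to its weight, so the total per-sample chromosomal read count
is Poisson(chrom_read_count).  Reads are emitted as already-aligned genomic
blocks (BED12); no sequencing-error or bias model is applied.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Chain = list[tuple[int, int]]  # exon chain: sorted disjoint genomic blocks

SIM_CHROM = "chrSIM"

# grid values mirrored by simulate_dataset_grid
GRID_COHORT_SIZES = (250, 500, 1000)
GRID_READ_COUNTS = (100_000, 400_000, 1_000_000)
GRID_AFFECTED_FRACTIONS = (0.8, 0.7, 0.6)


class EventType(str, Enum):
    exon_skipping = "exon_skipping"
    multi_exon_skipping = "multi_exon_skipping"
    intron_retention = "intron_retention"
    alt_3ss = "alt_3ss"
    alt_5ss = "alt_5ss"
    mutually_exclusive_exons = "mutually_exclusive_exons"
    alt_first_exon = "alt_first_exon"
    alt_last_exon = "alt_last_exon"
    combination = "combination"


@dataclass
class SimConfig:
    """Simulation design parameters.

    ``chrom_read_count`` is the expected total reads per sample across the
    synthetic chromosome; the default scales the 400,000-read setting of a
    513-gene chromosome down to the default 60-gene chromosome, preserving
    per-gene depth (400000 * 60 / 513 ~= 46784).
    """

    n_genes: int = 60
    cohort_size: int = 500
    affected_fraction: float = 0.8
    chrom_read_count: int = 46784
    read_length: int = 75
    variant_ratio: float = 0.5
    seed: int = 0
    null_mode: bool = False
    exon_count_range: tuple[int, int] = (4, 12)
    exon_len_range: tuple[int, int] = (50, 300)
    intron_len_range: tuple[int, int] = (200, 3000)
    gene_spacing: int = 4000
    event_frequencies: Optional[dict[EventType, float]] = None  # None = equal

    def __post_init__(self) -> None:
        if not 0 < self.affected_fraction < 1:
            raise ValueError("affected_fraction must be in (0, 1)")
        if self.exon_count_range[0] < 4:
            raise ValueError("exon_count must be >= 4 so every event type applies")


@dataclass
class SimGene:
    """One simulated gene: its annotated (canonical) exon chain, and — for
    AS genes — the variant chain its affected samples also express."""

    gene_id: str
    chrom: str
    strand: str
    exons: Chain  # structural exons the gene was built from
    canonical: Chain
    variant: Optional[Chain] = None
    event: Optional[EventType] = None
    expression_weight: float = 1.0


@dataclass
class SimTruth:
    """Ground truth of one dataset: per-gene events and per-sample labels."""

    sample_ids: list[str]
    group: dict[str, str]  # sample -> group1/group2
    affected: dict[str, bool]
    events: dict[str, Optional[EventType]]  # gene -> event (None for null)

    def labels(self) -> dict[str, str]:
        return dict(self.group)


@dataclass
class SimDataset:
    config: SimConfig
    genes: list[SimGene]
    truth: SimTruth


# ---------------------------------------------------------------------------
# gene structures


def simulate_gene_structure(
    rng: np.random.Generator,
    exon_count_range: tuple[int, int] = (4, 12),
    exon_len_range: tuple[int, int] = (50, 300),
    intron_len_range: tuple[int, int] = (200, 3000),
    start: int = 0,
) -> Chain:
    """Draw one gene's exon chain beginning at ``start``."""
    for name, (lo, hi) in (
        ("exon_count", exon_count_range),
        ("exon_len", exon_len_range),
        ("intron_len", intron_len_range),
    ):
        if lo <= 0 or hi < lo:
            raise ValueError(f"infeasible {name} range ({lo}, {hi})")
    n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
    exons: Chain = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
    return exons


# ---------------------------------------------------------------------------
# AS events

_SIMPLE_COMBINABLE = (
    EventType.exon_skipping,
    EventType.intron_retention,
    EventType.alt_3ss,
    EventType.alt_5ss,
)


def _apply_simple(chain: Chain, event: EventType, rng: np.random.Generator) -> Chain:
    """Apply one non-terminal event to an exon chain, returning the variant
    chain.  Raises ValueError when the structure cannot support the event."""
    n = len(chain)
    if event is EventType.exon_skipping:
        if n < 3:
            raise ValueError("exon_skipping needs an internal exon")
        i = int(rng.integers(1, n - 1))
        return chain[:i] + chain[i + 1 :]
    if event is EventType.multi_exon_skipping:
        if n < 4:
            raise ValueError("multi_exon_skipping needs >=2 internal exons")
        k = int(rng.integers(2, min(3, n - 2) + 1))
        i = int(rng.integers(1, n - 1 - k + 1))
        return chain[:i] + chain[i + k :]
    if event is EventType.intron_retention:
        if n < 2:
            raise ValueError("intron_retention needs an intron")
        i = int(rng.integers(0, n - 1))
        merged = (chain[i][0], chain[i + 1][1])
        return chain[:i] + [merged] + chain[i + 2 :]
    if event is EventType.alt_3ss:
        # shift an acceptor site (start of a non-first exon)
        if n < 2:
            raise ValueError("alt_3ss needs >=2 exons")
        i = int(rng.integers(1, n))
        offset = int(rng.integers(20, 101))
        s, e = chain[i]
        intron_len = s - chain[i - 1][1]
        if intron_len - offset >= 20:  # extend exon into the intron
            new = (s - offset, e)
        elif (e - s) - offset >= 20:  # truncate the exon instead
            new = (s + offset, e)
        else:
            raise ValueError("alt_3ss: no room for a 20-100 bp shift")
        return chain[:i] + [new] + chain[i + 1 :]
    if event is EventType.alt_5ss:
        # shift a donor site (end of a non-last exon)
        if n < 2:
            raise ValueError("alt_5ss needs >=2 exons")
        i = int(rng.integers(0, n - 1))
        offset = int(rng.integers(20, 101))
        s, e = chain[i]
        intron_len = chain[i + 1][0] - e
        if intron_len - offset >= 20:
            new = (s, e + offset)
        elif (e - s) - offset >= 20:
            new = (s, e - offset)
        else:
            raise ValueError("alt_5ss: no room for a 20-100 bp shift")
        return chain[:i] + [new] + chain[i + 1 :]
    raise ValueError(f"not a simple event: {event}")


def apply_as_event(gene: SimGene, event: EventType, rng: np.random.Generator) -> SimGene:
    """Attach a variant isoform realizing ``event`` to a gene skeleton.

    For mutually exclusive exons the canonical isoform itself is modified to
    carry exon i while the variant carries exon i+1 (never both).  Terminal
    events (alt first/last exon) place the substitute exon in the flanking
    region so that the signal falls inside the windowed gene span.
    """
    chain = list(gene.canonical)
    n = len(chain)
    if event in _SIMPLE_COMBINABLE or event is EventType.multi_exon_skipping:
        variant = _apply_simple(chain, event, rng)
        canonical = chain
    elif event is EventType.mutually_exclusive_exons:
        if n < 4:
            raise ValueError("mutually_exclusive_exons needs >=2 internal exons")
        i = int(rng.integers(1, n - 2))
        canonical = chain[: i + 1] + chain[i + 2 :]  # carries exon i
        variant = chain[:i] + chain[i + 1 :]  # carries exon i+1
    elif event is EventType.alt_first_exon:
        length = int(rng.integers(100, 201))
        gap = int(rng.integers(100, 801))
        new_end = chain[0][0] - gap
        new_start = new_end - length
        if new_start < 0:
            raise ValueError("alt_first_exon: no room upstream")
        canonical = chain
        variant = [(new_start, new_end)] + chain[1:]
    elif event is EventType.alt_last_exon:
        length = int(rng.integers(100, 201))
        gap = int(rng.integers(100, 801))
        new_start = chain[-1][1] + gap
        canonical = chain
        variant = chain[:-1] + [(new_start, new_start + length)]
    elif event is EventType.combination:
        idx = rng.choice(len(_SIMPLE_COMBINABLE), size=2, replace=False)
        ev1, ev2 = _SIMPLE_COMBINABLE[idx[0]], _SIMPLE_COMBINABLE[idx[1]]
        canonical = chain
        variant = _apply_simple(chain, ev1, rng)
        for _ in range(10):
            try:
                variant = _apply_simple(variant, ev2, rng)
                break
            except ValueError:
                continue
        else:
            raise ValueError("combination: second event inapplicable")
    else:
        raise ValueError(f"unknown event {event}")
    if [tuple(b) for b in variant] == [tuple(b) for b in canonical]:
        raise ValueError("variant identical to canonical")
    return replace(gene, canonical=canonical, variant=variant, event=event)


def _event_schedule(n_genes: int, frequencies: Optional[dict[EventType, float]]) -> list[EventType]:
    """Round-robin (stratified) assignment of events to genes."""
    types = list(EventType)
    if frequencies is None:
        return [types[i % len(types)] for i in range(n_genes)]
    if abs(sum(frequencies.values()) - 1.0) > 1e-9:
        raise ValueError("event frequencies must sum to 1")
    # largest-remainder allocation of n_genes among the types
    quota = {t: frequencies.get(t, 0.0) * n_genes for t in types}
    counts = {t: int(math.floor(q)) for t, q in quota.items()}
    short = n_genes - sum(counts.values())
    for t in sorted(types, key=lambda t: quota[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    schedule: list[EventType] = []
    for t in types:
        schedule.extend([t] * counts[t])
    return schedule[:n_genes]


# ---------------------------------------------------------------------------
# cohorts


def assign_groups(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimTruth:
    """Assign group labels.

    Non-null: round(cohort * affected_fraction) samples are AS-affected and
    labelled group1; the rest are group2.  Null mode: nobody is affected and
    labels are assigned at random with the same group-size split.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.cohort_size
    n1 = int(math.floor(n * config.affected_fraction + 0.5))
    sample_ids = [f"s{i:04d}" for i in range(n)]
    perm = rng.permutation(n)
    group1 = set(np.asarray(sample_ids)[perm[:n1]])
    group = {s: ("group1" if s in group1 else "group2") for s in sample_ids}
    affected = {s: (not config.null_mode) and (s in group1) for s in sample_ids}
    return SimTruth(sample_ids, group, affected, events={})


# ---------------------------------------------------------------------------
# dataset assembly


def simulate_genes(config: SimConfig, structure_seed: Optional[int] = None) -> list[SimGene]:
    """Build the gene set (structures + events) for a dataset.

    The structures and event assignments depend only on ``structure_seed``
    (default: config.seed), so a grid of datasets sharing that seed carries
    the same gene influenced by the same AS event throughout.
    """
    seed = config.seed if structure_seed is None else structure_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    schedule = _event_schedule(config.n_genes, config.event_frequencies)
    genes: list[SimGene] = []
    cursor = config.gene_spacing
    for i in range(config.n_genes):
        chain = simulate_gene_structure(
            rng,
            config.exon_count_range,
            config.exon_len_range,
            config.intron_len_range,
            start=cursor,
        )
        gene = SimGene(
            gene_id=f"g{i:04d}",
            chrom=SIM_CHROM,
            strand="+",
            exons=list(chain),
            canonical=list(chain),
        )
        if not config.null_mode:
            for _ in range(100):
                try:
                    gene = apply_as_event(gene, schedule[i], rng)
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError(f"could not apply {schedule[i]} to gene {gene.gene_id}")
        genes.append(gene)
        cursor = chain[-1][1] + config.gene_spacing
    return genes


def simulate_dataset(config: SimConfig, structure_seed: Optional[int] = None) -> SimDataset:
    genes = simulate_genes(config, structure_seed)
    weights_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    weights = weights_rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))
    for g, w in zip(genes, weights):
        g.expression_weight = float(w)
    truth = assign_groups(config)
    truth.events = {g.gene_id: g.event for g in genes}
    return SimDataset(config, genes, truth)


def simulate_dataset_grid(
    base_config: SimConfig,
    cohort_sizes: Sequence[int] = GRID_COHORT_SIZES,
    chrom_read_counts: Sequence[int] = GRID_READ_COUNTS,
    affected_fractions: Sequence[float] = GRID_AFFECTED_FRACTIONS,
    include_null: bool = True,
) -> tuple[list[SimDataset], list[SimDataset]]:
    """The full simulation grid: one AS dataset per (cohort x depth x
    fraction) combination — 27 with the default grids — with the same gene
    carrying the same event throughout, plus a parallel null grid over
    (cohort x depth) with random labels and no AS."""
    as_datasets: list[SimDataset] = []
    null_datasets: list[SimDataset] = []
    i = 0
    for cohort in cohort_sizes:
        for depth in chrom_read_counts:
            for frac in affected_fractions:
                cfg = replace(
                    base_config,
                    cohort_size=cohort,
                    chrom_read_count=depth,
                    affected_fraction=frac,
                    null_mode=False,
                    seed=int(np.random.SeedSequence([base_config.seed, 10, i]).generate_state(1)[0] % 2**31),
                )
                as_datasets.append(simulate_dataset(cfg, structure_seed=base_config.seed))
                i += 1
            if include_null:
                cfg = replace(
                    base_config,
                    cohort_size=cohort,
                    chrom_read_count=depth,
                    null_mode=True,
                    seed=int(np.random.SeedSequence([base_config.seed, 11, i]).generate_state(1)[0] % 2**31),
                )
                null_datasets.append(simulate_dataset(cfg, structure_seed=base_config.seed))
    return as_datasets, null_datasets


# ---------------------------------------------------------------------------
# read sampling


def _chain_arrays(chain: Chain) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    starts = np.array([s for s, _ in chain], dtype=np.int64)
    ends = np.array([e for _, e in chain], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    return starts, ends, cum


def sample_isoform_reads(
    chain: Chain, n: int, read_length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ``n`` single-end reads uniformly from a mature transcript and
    project them to genomic blocks.

    Returns (read_id, block_start, block_end) arrays; read ids are 0..n-1.
    Reads are clipped to the transcript length when it is shorter than the
    read length (with a warning).
    """
    if n == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    g_starts, _g_ends, cum = _chain_arrays(chain)
    tlen = int(cum[-1])
    L = read_length
    if tlen < read_length:
        logger.warning("transcript length %d < read length %d; clipping reads", tlen, read_length)
        L = tlen
    s = rng.integers(0, tlen - L + 1, size=n)
    e = s + L
    fi = np.searchsorted(cum, s, side="right") - 1
    li = np.searchsorted(cum, e - 1, side="right") - 1
    n_blocks = li - fi + 1
    rid = np.repeat(np.arange(n, dtype=np.int64), n_blocks)
    # exon index of each emitted block
    offsets = np.arange(int(n_blocks.sum())) - np.repeat(np.cumsum(n_blocks) - n_blocks, n_blocks)
    ex = np.repeat(fi, n_blocks) + offsets
    s_rep = np.repeat(s, n_blocks)
    e_rep = np.repeat(e, n_blocks)
    b_start = g_starts[ex] + np.maximum(s_rep - cum[ex], 0)
    b_end = g_starts[ex] + np.minimum(e_rep, cum[ex + 1]) - cum[ex]
    return rid, b_start.astype(np.int64), b_end.astype(np.int64)


def _read_rng(config: SimConfig, gene_idx: int, sample_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 3, gene_idx, sample_idx]))


def gene_sample_reads(
    dataset: SimDataset, gene_idx: int, sample_idx: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All reads of one sample for one gene as (read_id, block_start,
    block_end) arrays; deterministic in (config.seed, gene, sample) alone.

    Affected samples draw each read from the canonical or variant isoform
    with probability ``variant_ratio`` for the variant; unaffected samples
    read the canonical isoform only.
    """
    cfg = dataset.config
    gene = dataset.genes[gene_idx]
    sample = dataset.truth.sample_ids[sample_idx]
    rng = _read_rng(cfg, gene_idx, sample_idx)
    total_w = sum(g.expression_weight for g in dataset.genes)
    lam = cfg.chrom_read_count * gene.expression_weight / total_w
    n = int(rng.poisson(lam))
    affected = dataset.truth.affected[sample] and gene.variant is not None
    n_var = int(rng.binomial(n, cfg.variant_ratio)) if affected else 0
    n_can = n - n_var
    rid_c, bs_c, be_c = sample_isoform_reads(gene.canonical, n_can, cfg.read_length, rng)
    if n_var:
        rid_v, bs_v, be_v = sample_isoform_reads(gene.variant, n_var, cfg.read_length, rng)
        rid = np.concatenate([rid_c, rid_v + n_can])
        bs = np.concatenate([bs_c, bs_v])
        be = np.concatenate([be_c, be_v])
        return rid, bs, be
    return rid_c, bs_c, be_c


# ---------------------------------------------------------------------------
# outputs


def chrom_length(dataset: SimDataset) -> int:
    return dataset.genes[-1].canonical[-1][1] + dataset.config.gene_spacing


def write_annotation_gtf(dataset: SimDataset, path: str | Path) -> None:
    """Write the public annotation: the canonical transcript of each gene
    (variant isoforms deliberately withheld)."""
    with open(path, "w") as fh:
        for g in dataset.genes:
            gs, ge = g.canonical[0][0], g.canonical[-1][1]
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tisowin_sim\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            fh.write(
                f"{g.chrom}\tisowin_sim\ttranscript\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.canonical:
                fh.write(
                    f"{g.chrom}\tisowin_sim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_sample_bed12(dataset: SimDataset, sample_idx: int, path: str | Path) -> None:
    """Write one sample's reads as BED12, genes in genomic order.

    Byte-identical across reruns with the same config seed.
    """
    sample = dataset.truth.sample_ids[sample_idx]
    with open(path, "w") as fh:
        for gi, gene in enumerate(dataset.genes):
            rid, bs, be = gene_sample_reads(dataset, gi, sample_idx)
            if len(rid) == 0:
                continue
            order = np.lexsort((bs, rid))
            rid, bs, be = rid[order], bs[order], be[order]
            boundaries = np.concatenate([[0], np.flatnonzero(np.diff(rid)) + 1, [len(rid)]])
            for k in range(len(boundaries) - 1):
                a, b = boundaries[k], boundaries[k + 1]
                starts, ends = bs[a:b], be[a:b]
                chrom_start, chrom_end = int(starts[0]), int(ends[-1])
                sizes = ",".join(str(int(e - s)) for s, e in zip(starts, ends))
                offs = ",".join(str(int(s - chrom_start)) for s in starts)
                name = f"{sample}:{gene.gene_id}:r{int(rid[a])}"
                fh.write(
                    f"{gene.chrom}\t{chrom_start}\t{chrom_end}\t{name}\t0\t{gene.strand}\t"
                    f"{chrom_start}\t{chrom_end}\t0\t{b - a}\t{sizes}\t{offs}\n"
                )


def write_truth_tables(dataset: SimDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = dataset.truth
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in dataset.genes],
            "event": [g.event.value if g.event else "none" for g in dataset.genes],
            "expression_weight": [g.expression_weight for g in dataset.genes],
        }
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": truth.sample_ids,
            "group": [truth.group[s] for s in truth.sample_ids],
            "affected": [int(truth.affected[s]) for s in truth.sample_ids],
        }
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    cfg = dataset.config
    with open(out / "config.json", "w") as fh:
        json.dump(
            {
                "n_genes": cfg.n_genes,
                "cohort_size": cfg.cohort_size,
                "affected_fraction": cfg.affected_fraction,
                "chrom_read_count": cfg.chrom_read_count,
                "read_length": cfg.read_length,
                "variant_ratio": cfg.variant_ratio,
                "seed": cfg.seed,
                "null_mode": cfg.null_mode,
            },
            fh,
            indent=2,
        )
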