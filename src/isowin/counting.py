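"""Window read counting and length-normalized proportion features.

A read contributes +1 to every window that any of its aligned blocks
overlaps by at least one base (at most +1 per window per read, however many
blocks touch it).  The per-gene read total for a sample is the number of
distinct reads overlapping any window of the gene; samples whose total falls
below a minimum (default 10) are excluded for that gene.  The feature value
for window *w* of sample *s* is

    (count[s, w] / gene_total[s]) / window_length[w]

i.e. the proportion of the sample's gene reads falling in the window,
normalized by window length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .windowing import Window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read: its blocks are the aligned segments (splice gaps
    excluded), sorted and disjoint."""

    sample_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "."


@dataclass
class CountMatrix:
    gene_id: str
    samples: list[str]
    windows: list[Window]
    counts: np.ndarray  # samples x windows, int
    gene_totals: np.ndarray  # per sample, int


@dataclass
class FeatureMatrix:
    """Samples x windows of normalized read proportions plus group labels."""

    gene_id: str
    samples: list[str]
    windows: list[Window]
    values: np.ndarray  # samples x windows, float
    labels: np.ndarray  # per sample, str

    @property
    def window_names(self) -> list[str]:
        return [w.name for w in self.windows]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.samples, columns=self.window_names)
        df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# core counting


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenate arange(lo[i], hi[i]) for all i (hi exclusive)."""
    lens = hi - lo
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    starts = np.repeat(lo, lens)
    offsets = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
    return starts + offsets


def count_blocks(
    w_starts: np.ndarray,
    w_ends: np.ndarray,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
    read_ids: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Count distinct reads per window given aligned blocks.

    Windows must be sorted by start and non-overlapping (they may have
    gaps).  Returns (per-window counts, number of distinct reads hitting
    any window).
    """
    n_w = len(w_starts)
    if n_w == 0 or len(b_starts) == 0:
        return np.zeros(n_w, dtype=np.int64), 0
    lo = np.searchsorted(w_ends, b_starts, side="right")
    hi = np.searchsorted(w_starts, b_ends, side="left")
    widx = _expand_ranges(lo, hi)
    lens = hi - lo
    rid = np.repeat(read_ids, lens)
    # dedup (read, window) pairs: a read spanning a splice gap may touch the
    # same window with two blocks
    key = np.unique(rid.astype(np.int64) * n_w + widx)
    counts = np.bincount(key % n_w, minlength=n_w).astype(np.int64)
    gene_total = len(np.unique(key // n_w))
    return counts, gene_total


def _windows_are_tiled(w_starts: np.ndarray, w_ends: np.ndarray) -> bool:
    return bool(
        np.all(np.diff(w_starts) >= 0) and np.all(w_starts[1:] >= w_ends[:-1])
    )


def count_window_overlaps(
    windows: Sequence[Window],
    alignments: Iterable[ReadAlignment],
    samples: Optional[Sequence[str]] = None,
) -> CountMatrix:
    """Count reads overlapping each window of one gene, per sample.

    Reads on other chromosomes are skipped with a warning.  The result is
    invariant to the order of the input alignments.
    """
    windows = list(windows)
    gene_id = windows[0].gene_id if windows else ""
    chrom = windows[0].interval.chrom if windows else None
    w_starts = np.array([w.interval.start for w in windows], dtype=np.int64)
    w_ends = np.array([w.interval.end for w in windows], dtype=np.int64)
    order = np.argsort(w_starts, kind="stable")
    sorted_ok = _windows_are_tiled(w_starts[order], w_ends[order])

    per_sample: dict[str, list[ReadAlignment]] = {}
    n_skipped = 0
    for aln in alignments:
        if chrom is not None and aln.chrom != chrom:
            n_skipped += 1
            continue
        per_sample.setdefault(aln.sample_id, []).append(aln)
    if n_skipped:
        logger.warning(
            "gene %s: skipped %d alignment(s) on other chromosomes", gene_id, n_skipped
        )
    if samples is None:
        samples = sorted(per_sample)
    counts = np.zeros((len(samples), len(windows)), dtype=np.int64)
    totals = np.zeros(len(samples), dtype=np.int64)
    for si, sample in enumerate(samples):
        alns = per_sample.get(sample, [])
        if not alns:
            continue
        b_starts, b_ends, rids = [], [], []
        for ri, aln in enumerate(alns):
            for bs, be in aln.blocks:
                b_starts.append(bs)
                b_ends.append(be)
                rids.append(ri)
        bs = np.asarray(b_starts, dtype=np.int64)
        be = np.asarray(b_ends, dtype=np.int64)
        rid = np.asarray(rids, dtype=np.int64)
        if sorted_ok:
            c_sorted, total = count_blocks(w_starts[order], w_ends[order], bs, be, rid)
            c = np.empty_like(c_sorted)
            c[order] = c_sorted
        else:
            # general path for arbitrary (possibly overlapping) window sets
            c = np.zeros(len(windows), dtype=np.int64)
            hit_any = np.zeros(len(alns), dtype=bool)
            for wi in range(len(windows)):
                mask = (bs < w_ends[wi]) & (be > w_starts[wi])
                hit = np.unique(rid[mask])
                c[wi] = len(hit)
                hit_any[hit] = True
            total = int(hit_any.sum())
        counts[si] = c
        totals[si] = total
    return CountMatrix(gene_id, list(samples), windows, counts, totals)


def filter_low_coverage_samples(cm: CountMatrix, min_reads: int = 10) -> CountMatrix:
    """Drop samples whose total distinct-read count for this gene is below
    ``min_reads``.  A gene losing all samples is untestable (caller decides
    how to report it)."""
    keep = cm.gene_totals >= min_reads
    if not keep.any():
        logger.warning("gene %s: no sample passes the %d-read filter", cm.gene_id, min_reads)
    samples = [s for s, k in zip(cm.samples, keep) if k]
    return CountMatrix(cm.gene_id, samples, cm.windows, cm.counts[keep], cm.gene_totals[keep])


def normalize_proportions(
    cm: CountMatrix, labels: Optional[dict[str, str]] = None
) -> FeatureMatrix:
    """Length-normalized read proportions per window."""
    lengths = np.array([w.length for w in cm.windows], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("zero-length window present; must be dropped upstream")
    totals = cm.gene_totals.astype(float)
    if np.any(totals < 1):
        raise ValueError("sample with zero gene reads; filter before normalizing")
    values = cm.counts / totals[:, None] / lengths[None, :]
    lab = np.array([labels.get(s, "") for s in cm.samples]) if labels else np.array([""] * len(cm.samples))
    return FeatureMatrix(cm.gene_id, list(cm.samples), cm.windows, values, lab)


# ---------------------------------------------------------------------------
# read I/O


def read_bed12(path: str, sample_id: str) -> list[ReadAlignment]:
    """Read one sample's reads from BED12 (one line per read, spliced blocks
    encoded in blockSizes/blockStarts)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            strand = f[5] if len(f) > 5 else "."
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            out.append(ReadAlignment(sample_id, chrom, blocks, strand))
    return out


def read_bam(
    path: str,
    sample_id: str,
    region: Optional[tuple[str, int, int]] = None,
    stranded: Optional[str] = None,
) -> list[ReadAlignment]:
    """Fetch primary alignments from an indexed BAM as spliced blocks.

    Secondary, supplementary, duplicate, and unmapped records are skipped.
    If ``stranded`` is '+' or '-', only reads on that strand are returned.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(path) as bam:
        it = bam.fetch(*region) if region else bam.fetch()
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            strand = "-" if rec.is_reverse else "+"
            if stranded is not None and strand != stranded:
                continue
            blocks = rec.get_blocks()
            if not blocks:
                continue
            # merge book-ended blocks (deletions split get_blocks output)
            merged = [list(blocks[0])]
            for bs, be in blocks[1:]:
                if bs <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], be)
                else:
                    merged.append([bs, be])
            out.append(
                ReadAlignment(sample_id, rec.reference_name, tuple(map(tuple, merged)), strand)
            )
    return out
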