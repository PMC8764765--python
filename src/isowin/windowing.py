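"""Flattened gene models and window tiling.

Each gene is reduced to a single composite model: the union of its annotated
exon intervals merged into disjoint blocks, the introns between them, and
fixed-length flanking regions on either side.  Every region (flank, exon,
intron) is then tiled into ``n_w`` contiguous windows, giving
``(2 * num_exons + 1) * n_w`` windows per gene.  Windows are the unit feature
of the downstream classifiers: differential isoform usage between two groups
shows up as a shift in the proportion of reads falling into particular
windows.

All coordinates are 0-based half-open; GTF input (1-based closed) is
converted at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

REGION_FLANK_UP = "flank_up"
REGION_FLANK_DOWN = "flank_down"
REGION_EXON = "exon"
REGION_INTRON = "intron"


@dataclass(frozen=True)
class GenomicInterval:
    """A non-empty genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start},{self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class WindowingConfig:
    """Windows per region and flanking-region length (bp)."""

    n_w: int = 3
    flank_length: int = 1500

    def __post_init__(self) -> None:
        if self.n_w < 1:
            raise ValueError("n_w must be >= 1")
        if self.flank_length < 0:
            raise ValueError("flank_length must be >= 0")


@dataclass
class GeneModel:
    """A flattened gene: merged exons, derived introns, and flanks.

    ``flank_up``/``flank_down`` are named with respect to the transcriptional
    strand; either may be ``None`` when truncation at a chromosome boundary
    leaves it empty.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    introns: list[GenomicInterval]
    flank_up: Optional[GenomicInterval]
    flank_down: Optional[GenomicInterval]

    @property
    def num_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span covered by flanks + gene body."""
        left = self.flank_up if self.strand != "-" else self.flank_down
        right = self.flank_down if self.strand != "-" else self.flank_up
        start = left.start if left is not None else self.exons[0].start
        end = right.end if right is not None else self.exons[-1].end
        return start, end


@dataclass(frozen=True)
class Window:
    """One window of a gene region.

    ``region_ordinal`` numbers all regions of the gene 1..R in 5'->3'
    transcriptional order (1 = upstream flank, 2 = first exon, ...);
    ``window_index`` numbers the windows within the region, also 5'->3'.
    """

    gene_id: str
    region_type: str
    region_ordinal: int
    window_index: int
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def name(self) -> str:
        return f"{self.gene_id}|{self.region_type}|{self.region_ordinal}|{self.window_index}"


def merge_exons(transcript_exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended exon intervals into disjoint blocks.

    Idempotent and order-invariant; the base-pair union is preserved
    (book-ended intervals are additionally joined, matching the default of
    the interval-merging tools used for gene-model flattening).
    """
    if not transcript_exons:
        raise ValueError("gene has no exons")
    chroms = {e.chrom for e in transcript_exons}
    if len(chroms) > 1:
        raise ValueError(f"exons span multiple chromosomes: {sorted(chroms)}")
    ordered = sorted(transcript_exons, key=lambda e: (e.start, e.end))
    merged: list[GenomicInterval] = []
    cur_start, cur_end = ordered[0].start, ordered[0].end
    chrom, strand = ordered[0].chrom, ordered[0].strand
    for e in ordered[1:]:
        if e.start <= cur_end:  # overlap or book-ended
            cur_end = max(cur_end, e.end)
        else:
            merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
            cur_start, cur_end = e.start, e.end
    merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    return merged


def derive_gene_model(
    gene_id: str,
    merged_exons: Sequence[GenomicInterval],
    chrom_length: Optional[int],
    config: WindowingConfig,
) -> GeneModel:
    """Fill in introns and flanks around a merged exon chain.

    Introns are the gaps between consecutive merged exons.  Flanks extend
    ``config.flank_length`` bp beyond the terminal exons, clipped at the
    chromosome boundaries (position 0 and ``chrom_length``).  Genes flagged
    unstranded are ordered as if on the + strand.
    """
    exons = list(merged_exons)
    chrom = exons[0].chrom
    strand = exons[0].strand
    if strand == ".":
        logger.warning("gene %s is unstranded; treating as + strand", gene_id)
    introns = [
        GenomicInterval(chrom, a.end, b.start, strand)
        for a, b in zip(exons, exons[1:])
    ]
    left_start = max(0, exons[0].start - config.flank_length)
    left = (
        GenomicInterval(chrom, left_start, exons[0].start, strand)
        if left_start < exons[0].start
        else None
    )
    right_end = exons[-1].end + config.flank_length
    if chrom_length is not None:
        right_end = min(right_end, chrom_length)
    right = (
        GenomicInterval(chrom, exons[-1].end, right_end, strand)
        if right_end > exons[-1].end
        else None
    )
    if strand == "-":
        flank_up, flank_down = right, left
    else:
        flank_up, flank_down = left, right
    return GeneModel(gene_id, chrom, strand, exons, introns, flank_up, flank_down)


def _tile_region(start: int, end: int, n_w: int) -> list[tuple[int, int]]:
    """Split [start, end) into n_w contiguous pieces, larger pieces first in
    genomic order; zero-length pieces are returned as (x, x)."""
    length = end - start
    base, rem = divmod(length, n_w)
    bounds = []
    pos = start
    for i in range(n_w):
        size = base + (1 if i < rem else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


def build_windows(model: GeneModel, config: WindowingConfig) -> list[Window]:
    """Tile every region of a flattened gene into ``n_w`` windows.

    Regions are ordered 5'->3' with respect to the gene's strand; within a
    region the remainder of an uneven split goes to the earliest windows in
    *genomic* order.  Zero-length windows (regions shorter than ``n_w`` bp)
    are dropped with a warning, so the total is ``(2E+1) * n_w`` minus any
    dropped windows.
    """
    minus = model.strand == "-"
    # regions in genomic left-to-right order, with transcriptional labels
    genomic_regions: list[tuple[str, Optional[GenomicInterval]]] = []
    genomic_regions.append(
        (REGION_FLANK_DOWN if minus else REGION_FLANK_UP,
         model.flank_down if minus else model.flank_up)
    )
    for i, exon in enumerate(model.exons):
        genomic_regions.append((REGION_EXON, exon))
        if i < len(model.introns):
            genomic_regions.append((REGION_INTRON, model.introns[i]))
    genomic_regions.append(
        (REGION_FLANK_UP if minus else REGION_FLANK_DOWN,
         model.flank_up if minus else model.flank_down)
    )

    n_regions = len(genomic_regions)
    windows: list[Window] = []
    n_dropped = 0
    for g_idx, (rtype, interval) in enumerate(genomic_regions):
        ordinal = n_regions - g_idx if minus else g_idx + 1
        if interval is None:
            # flank fully truncated at a chromosome boundary
            n_dropped += config.n_w
            continue
        for w_idx, (ws, we) in enumerate(_tile_region(interval.start, interval.end, config.n_w)):
            index = config.n_w - w_idx if minus else w_idx + 1
            if we <= ws:
                n_dropped += 1
                continue
            windows.append(
                Window(
                    gene_id=model.gene_id,
                    region_type=rtype,
                    region_ordinal=ordinal,
                    window_index=index,
                    interval=GenomicInterval(model.chrom, ws, we, model.strand),
                )
            )
    if n_dropped:
        logger.warning(
            "gene %s: dropped %d zero-length window(s)", model.gene_id, n_dropped
        )
    windows.sort(key=lambda w: w.interval.start)
    return windows


# ---------------------------------------------------------------------------
# annotation I/O


def read_gene_exons(gtf_path: str) -> dict[str, list[GenomicInterval]]:
    """Collect exon intervals per gene from a GTF/GFF file (converted to
    0-based half-open)."""
    by_gene: dict[str, list[GenomicInterval]] = {}
    for feat in gffutils.DataIterator(gtf_path):
        if feat.featuretype != "exon":
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        by_gene.setdefault(gene_id, []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        )
    return by_gene


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def build_gene_windows(
    gtf_path: str,
    chrom_sizes: Optional[dict[str, int]] = None,
    config: WindowingConfig = WindowingConfig(),
) -> tuple[dict[str, GeneModel], dict[str, list[Window]]]:
    """Flatten every gene in an annotation and tile it into windows."""
    models: dict[str, GeneModel] = {}
    windows: dict[str, list[Window]] = {}
    for gene_id, exons in read_gene_exons(gtf_path).items():
        merged = merge_exons(exons)
        clen = chrom_sizes.get(merged[0].chrom) if chrom_sizes else None
        model = derive_gene_model(gene_id, merged, clen, config)
        models[gene_id] = model
        windows[gene_id] = build_windows(model, config)
    return models, windows


def windows_to_bed(windows: Iterable[Window], path: str) -> None:
    """Write windows as BED6+3 (chrom, start, end, gene_id, 0, strand,
    region_type, region_ordinal, window_index)."""
    with open(path, "w") as fh:
        for w in windows:
            iv = w.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{w.gene_id}\t0\t{iv.strand}"
                f"\t{w.region_type}\t{w.region_ordinal}\t{w.window_index}\n"
            )


def windows_from_bed(path: str) -> dict[str, list[Window]]:
    """Read back a BED6+3 windows file produced by :func:`windows_to_bed`."""
    out: dict[str, list[Window]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, gene_id, _score, strand, rtype, ordinal, index = f[:9]
            out.setdefault(gene_id, []).append(
                Window(
                    gene_id=gene_id,
                    region_type=rtype,
                    region_ordinal=int(ordinal),
                    window_index=int(index),
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                )
            )
    return out
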