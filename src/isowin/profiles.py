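"""Region-level importance profiling.

Window importances differ in scale between genes and models, so each gene's
importances are first converted to within-gene deciles (10 = most important;
ties get average ranks).  Deciles are then aggregated by region position —
flanks, the first and last eight exons counted from each gene end, and their
neighbouring introns — to reveal which parts of a gene drive group
discrimination.  A one-sided Welch t-test compares the deciles of windows
that touch an internal exon/intron boundary (splice-site windows) against
all other windows; gene start/end boundaries are transcription, not splice,
boundaries and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .windowing import (
    GeneModel,
    Window,
    REGION_EXON,
    REGION_FLANK_DOWN,
    REGION_FLANK_UP,
)

logger = logging.getLogger(__name__)


def decile_transform(importance: np.ndarray) -> np.ndarray:
    """Within-gene decile of each window's importance.

    decile = ceil(10 * rank / W) with average ranks for ties; the most
    important window always lands in decile 10.  Invariant to any strictly
    monotone rescaling of the importances.
    """
    imp = np.asarray(importance, dtype=float)
    if imp.size == 0:
        raise ValueError("no windows")
    ranks = stats.rankdata(imp, method="average")
    dec = np.ceil(10.0 * ranks / imp.size).astype(int)
    return np.clip(dec, 1, 10)


@dataclass
class DecileProfile:
    gene_id: str
    window_names: list[str]
    deciles: np.ndarray


def profile_gene(gene_id: str, window_names: Sequence[str], importance: np.ndarray) -> DecileProfile:
    return DecileProfile(gene_id, list(window_names), decile_transform(importance))


# ---------------------------------------------------------------------------
# region aggregation


def _position_keys(window: Window, num_exons: int, max_terminal: int):
    """Position slot(s) for one window.

    Exons (and introns) are indexed from the 5' end (1..max_terminal) or,
    when beyond that, from the 3' end (-1..-max_terminal); each window
    contributes to exactly one slot, so genes with few exons are never
    double counted.  Returns None for positions outside both terminal
    stretches.
    """
    rt, ordinal = window.region_type, window.region_ordinal
    if rt in (REGION_FLANK_UP, REGION_FLANK_DOWN):
        return (rt, 0, window.window_index)
    if rt == REGION_EXON:
        k = ordinal // 2  # exon number from 5': ordinal = 2k
        total = num_exons
    else:  # intron k sits after exon k: ordinal = 2k + 1
        k = (ordinal - 1) // 2
        total = num_exons - 1
    from3 = total - k + 1
    if k <= max_terminal:
        return (rt, k, window.window_index)
    if from3 <= max_terminal:
        return (rt, -from3, window.window_index)
    return None


def aggregate_region_profile(
    profiles: Sequence[DecileProfile],
    windows_by_gene: dict[str, list[Window]],
    num_exons_by_gene: dict[str, int],
    max_terminal_exons: int = 8,
) -> tuple[pd.DataFrame, float]:
    """Mean decile per region position across genes.

    Positions cover the flanks, the first/last ``max_terminal_exons`` exons
    and their neighbouring introns; the overall mean decile across all
    windows of all genes is returned as the reference value.
    """
    acc: dict[tuple, list[float]] = {}
    genes_at: dict[tuple, set] = {}
    all_deciles: list[float] = []
    for prof in profiles:
        windows = {w.name: w for w in windows_by_gene[prof.gene_id]}
        ne = num_exons_by_gene[prof.gene_id]
        for name, dec in zip(prof.window_names, prof.deciles):
            w = windows.get(name)
            if w is None:
                continue
            all_deciles.append(float(dec))
            key = _position_keys(w, ne, max_terminal_exons)
            if key is None:
                continue
            acc.setdefault(key, []).append(float(dec))
            genes_at.setdefault(key, set()).add(prof.gene_id)
    rows = []
    for (rt, pos, widx), vals in sorted(acc.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
        rows.append(
            {
                "region_type": rt,
                "position": pos,  # 1..8 from 5', -1..-8 from 3', 0 for flanks
                "window_index": widx,
                "mean_decile": float(np.mean(vals)),
                "n_genes": len(genes_at[(rt, pos, widx)]),
            }
        )
    overall = float(np.mean(all_deciles)) if all_deciles else float("nan")
    return pd.DataFrame(rows), overall


# ---------------------------------------------------------------------------
# splice-site enrichment


def splice_site_boundaries(model: GeneModel) -> set[int]:
    """Internal exon/intron boundary coordinates of a flattened gene; the
    gene's outermost start/end (transcription boundaries) are excluded."""
    bounds: set[int] = set()
    for intron in model.introns:
        bounds.add(intron.start)
        bounds.add(intron.end)
    return bounds


def is_splice_site_window(window: Window, boundaries: set[int]) -> bool:
    """True when the window's interval contains or abuts an internal
    exon/intron junction."""
    s, e = window.interval.start, window.interval.end
    return any(s <= b <= e for b in boundaries)


@dataclass
class SpliceSiteTest:
    mean_splice: float
    mean_other: float
    t_statistic: float
    p_value: float
    n_splice: int
    n_other: int


def splice_site_test(
    profiles: Sequence[DecileProfile],
    windows_by_gene: dict[str, list[Window]],
    models_by_gene: dict[str, GeneModel],
) -> Optional[SpliceSiteTest]:
    """One-sided Welch t-test: do splice-site windows carry higher deciles
    than the rest?  Deciles are pooled across the supplied genes."""
    splice: list[float] = []
    other: list[float] = []
    for prof in profiles:
        model = models_by_gene[prof.gene_id]
        boundaries = splice_site_boundaries(model)
        windows = {w.name: w for w in windows_by_gene[prof.gene_id]}
        for name, dec in zip(prof.window_names, prof.deciles):
            w = windows.get(name)
            if w is None:
                continue
            (splice if is_splice_site_window(w, boundaries) else other).append(float(dec))
    if len(splice) < 2 or len(other) < 2:
        logger.warning("splice-site test: a group is (nearly) empty")
        return None
    t, p = stats.ttest_ind(splice, other, equal_var=False, alternative="greater")
    return SpliceSiteTest(
        mean_splice=float(np.mean(splice)),
        mean_other=float(np.mean(other)),
        t_statistic=float(t),
        p_value=float(p),
        n_splice=len(splice),
        n_other=len(other),
    )


def length_decile_correlation(
    profiles: Sequence[DecileProfile],
    windows_by_gene: dict[str, list[Window]],
    region_type: str = REGION_EXON,
) -> tuple[float, float]:
    """Pearson correlation between window length and decile within one
    region type, pooled across genes (a reported diagnostic)."""
    lengths: list[float] = []
    deciles: list[float] = []
    for prof in profiles:
        windows = {w.name: w for w in windows_by_gene[prof.gene_id]}
        for name, dec in zip(prof.window_names, prof.deciles):
            w = windows.get(name)
            if w is not None and w.region_type == region_type:
                lengths.append(float(w.length))
                deciles.append(float(dec))
    if len(lengths) < 3:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(lengths, deciles)
    return float(r), float(p)
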