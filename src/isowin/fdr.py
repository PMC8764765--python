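"""Permutation null, enrichment ratios, FDR estimates, and truth-based
evaluation.

To estimate how many significant genes would appear by chance, the training
labels of every gene are shuffled (the test labels are left unchanged) and
the whole tune/fit/score pipeline is re-run; by default this is repeated ten
times.  At a P-value threshold t the estimated FDR is the mean number of
genes significant in the permutation runs divided by the number observed,
capped at 1; the reciprocal ratio is the enrichment of true signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ModelSpec, fit_gene, UntestableGene

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.001, 0.01, 0.05, 0.1, 1.0)


@dataclass
class PermutationRun:
    perm_index: int
    seed: int
    p_values: dict[str, float]  # gene -> P value under permuted training labels


def run_observed(
    matrices: dict, spec: ModelSpec, seed: int = 0, frac: float = 0.8
) -> dict[str, float]:
    """Fit every gene on the true labels; returns gene -> P value.

    Untestable genes (all samples filtered, single-class partitions, no
    informative windows) are reported as NaN.
    """
    out: dict[str, float] = {}
    for gene_id, fm in matrices.items():
        try:
            out[gene_id] = fit_gene(fm, spec, seed=seed, frac=frac).p_value
        except UntestableGene as exc:
            logger.warning("gene %s untestable: %s", gene_id, exc)
            out[gene_id] = float("nan")
    return out


def run_permutations(
    matrices: dict,
    spec: ModelSpec,
    n_perm: int = 10,
    seed: int = 0,
    frac: float = 0.8,
) -> list[PermutationRun]:
    """Repeat the per-gene pipeline ``n_perm`` times with training labels
    shuffled uniformly within the training set.  Splits and model seeds are
    identical to the observed analysis run with the same ``seed``."""
    runs: list[PermutationRun] = []
    for pi in range(1, n_perm + 1):
        pvals: dict[str, float] = {}
        for gi, (gene_id, fm) in enumerate(matrices.items()):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 101, pi, gi]))
            try:
                res = fit_gene(fm, spec, seed=seed, frac=frac, permute_train_rng=rng)
                pvals[gene_id] = res.p_value
            except UntestableGene:
                pvals[gene_id] = float("nan")
        runs.append(PermutationRun(perm_index=pi, seed=seed, p_values=pvals))
    return runs


def estimate_fdr(
    observed: dict[str, float],
    runs: Sequence[PermutationRun],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    model_type: Optional[str] = None,
) -> pd.DataFrame:
    """Per-threshold observed/permuted counts, FDR, and enrichment.

    FDR = min(1, mean permuted count / observed count); NA when nothing is
    observed at the threshold.
    """
    if not runs:
        raise ValueError("at least one permutation run is required")
    obs = np.array([v for v in observed.values() if np.isfinite(v)])
    rows = []
    for t in thresholds:
        n_obs = int(np.sum(obs <= t))
        perm_counts = [
            int(np.sum(np.array([v for v in r.p_values.values() if np.isfinite(v)]) <= t))
            for r in runs
        ]
        mean_perm = float(np.mean(perm_counts))
        if n_obs == 0:
            fdr, enr = float("nan"), float("nan")
        else:
            fdr = min(1.0, mean_perm / n_obs)
            enr = n_obs / mean_perm if mean_perm > 0 else float("inf")
        rows.append(
            {
                "threshold": t,
                "observed": n_obs,
                "mean_permuted": mean_perm,
                "fdr": fdr,
                "enrichment": enr,
                "model_type": model_type if model_type else "",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DetectionEvaluation:
    threshold: float
    sensitivity: float
    specificity: float
    n_as: int
    n_null: int


def evaluate_against_truth(
    as_pvalues: dict[str, float],
    null_pvalues: dict[str, float],
    as_genes: Sequence[str],
    threshold: float = 0.05,
) -> DetectionEvaluation:
    """Sensitivity and specificity of the detection rule p < threshold.

    ``as_genes`` are the genes simulated with an AS event; genes untestable
    or missing from the results count as undetected.  Specificity is
    computed over the genes of the null datasets, where any detection is a
    false positive.
    """
    as_genes = list(as_genes)
    n_detected = sum(
        1
        for g in as_genes
        if np.isfinite(as_pvalues.get(g, float("nan"))) and as_pvalues[g] < threshold
    )
    null_genes = list(null_pvalues)
    n_fp = sum(
        1
        for g in null_genes
        if np.isfinite(null_pvalues[g]) and null_pvalues[g] < threshold
    )
    sens = n_detected / len(as_genes) if as_genes else float("nan")
    spec = 1.0 - n_fp / len(null_genes) if null_genes else float("nan")
    return DetectionEvaluation(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        n_as=len(as_genes),
        n_null=len(null_genes),
    )


def threshold_sweep(
    as_pvalues: dict[str, float],
    null_pvalues: dict[str, float],
    as_genes: Sequence[str],
    thresholds: Sequence[float] = (0.001, 0.01, 0.05, 0.1),
) -> pd.DataFrame:
    rows = []
    for t in thresholds:
        ev = evaluate_against_truth(as_pvalues, null_pvalues, as_genes, threshold=t)
        rows.append(
            {
                "threshold": t,
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
                "n_as": ev.n_as,
                "n_null": ev.n_null,
            }
        )
    return pd.DataFrame(rows)
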