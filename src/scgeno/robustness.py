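"""Gene-downsampling robustness protocol.

Reduced heterozygous SNP coverage is emulated by retaining a random fraction
of genes per chromosome (40/60/80% in the reference protocol), with the same
gene subset applied to every replicate.  A reduced model is trained on the
thinned chains and compared to the full model two ways: parameter agreement
(Pearson r, mean absolute difference, mean squared error over the
concatenated pi/A/B vector of 18 entries) and decoding consistency (the
fraction of shared genes of one representative replicate assigned the same
genotype state by the reduced and full models, per chromosome and averaged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .discretize import ObservedChain
from .hmm import (
    FitResult,
    GenotypeSegmentation,
    HMMParams,
    baum_welch_fit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RobustnessReport",
    "subsample_genes",
    "compare_params",
    "decoding_consistency",
    "run_robustness",
    "write_robustness_reports",
]


@dataclass
class RobustnessReport:
    """Reduced-vs-full model comparison at one gene fraction."""

    fraction: float
    pearson_r: float
    mad: float
    mse: float
    per_chromosome_consistency: dict[str, float] = field(repr=False)
    mean_consistency: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "pearson_r": self.pearson_r,
            "mad": self.mad,
            "mse": self.mse,
            "mean_consistency": self.mean_consistency,
            "per_chromosome_consistency": self.per_chromosome_consistency,
        }


def subsample_genes(
    chains: list[ObservedChain], fraction: float, seed: int
) -> list[ObservedChain]:
    """Keep a shared random gene subset per chromosome across all replicates.

    For each chromosome, ceil(fraction * n_genes) gene positions are drawn
    once (uniformly, order preserved) and the same positions are removed from
    every replicate's chain of that chromosome.  Chains of the same
    chromosome must share their gene order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return chains
    rng = np.random.default_rng(seed)
    keep_by_chrom: dict[str, np.ndarray] = {}
    out = []
    for chain in chains:
        if chain.chromosome not in keep_by_chrom:
            n = len(chain)
            k = int(np.ceil(fraction * n))
            if k == 0:
                raise ValueError(
                    f"fraction {fraction} keeps zero genes on {chain.chromosome}"
                )
            keep_by_chrom[chain.chromosome] = np.sort(
                rng.choice(n, size=k, replace=False)
            )
        keep = keep_by_chrom[chain.chromosome]
        if keep.max() >= len(chain):
            raise ValueError(
                f"chains for chromosome {chain.chromosome} differ in length; "
                "a shared gene subset requires matched chains"
            )
        out.append(
            ObservedChain(
                replicate_id=chain.replicate_id,
                chromosome=chain.chromosome,
                gene_ids=chain.gene_ids[keep],
                states=chain.states[keep],
                starts=None if chain.starts is None else chain.starts[keep],
                r_mean=None if chain.r_mean is None else chain.r_mean[keep],
            )
        )
    return out


def compare_params(a: HMMParams, b: HMMParams) -> tuple[float, float, float]:
    """Pearson r, MAD and MSE over the 18-entry flattened (pi, A, B) vectors."""
    va, vb = a.flatten(), b.flatten()
    if np.allclose(va, vb, rtol=0, atol=0):
        return 1.0, 0.0, 0.0
    pearson = float(stats.pearsonr(va, vb).statistic)
    diff = va - vb
    return pearson, float(np.abs(diff).mean()), float((diff**2).mean())


def decoding_consistency(
    full_seg: GenotypeSegmentation, reduced_seg: GenotypeSegmentation
) -> tuple[dict[str, float], float]:
    """Fraction of shared genes with identical decoded state, per chromosome.

    Chromosomes with no shared gene are omitted with a warning.  The mean is
    an unweighted average across the remaining chromosomes.
    """
    merged = reduced_seg.genes.merge(
        full_seg.genes[["chrom", "gene_id", "decoded_state"]],
        on=["chrom", "gene_id"],
        suffixes=("_reduced", "_full"),
    )
    per_chrom: dict[str, float] = {}
    for chrom in pd.unique(reduced_seg.genes["chrom"]):
        sub = merged[merged["chrom"] == chrom]
        if sub.empty:
            logger.warning("chromosome %s shares no genes; omitted", chrom)
            continue
        per_chrom[str(chrom)] = float(
            (sub["decoded_state_reduced"] == sub["decoded_state_full"]).mean()
        )
    mean = float(np.mean(list(per_chrom.values()))) if per_chrom else float("nan")
    return per_chrom, mean


def run_robustness(
    chains: list[ObservedChain],
    fractions: list[float],
    seed: int,
    init: HMMParams | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    pseudocount: float = 1e-6,
    representative: str | None = None,
    full_fit: FitResult | None = None,
) -> list[RobustnessReport]:
    """Train reduced models at each gene fraction and compare to the full model.

    The full model is fitted on all chains (or passed in via ``full_fit``).
    The representative replicate defaults to the one with the most genes; its
    chains are decoded with both models and scored for consistency on the
    shared (retained) genes.
    """
    from .model import decode_chains  # deferred: avoids a module cycle

    for fraction in fractions:
        if not 0 < fraction <= 1:
            raise ValueError("fractions must lie in (0, 1]")
    if full_fit is None:
        full_fit = baum_welch_fit(
            chains, init=init, tol=tol, max_iter=max_iter,
            pseudocount=pseudocount, seed=seed,
        )
    if representative is None:
        genes_per_rep: dict[str, int] = {}
        for chain in chains:
            genes_per_rep[chain.replicate_id] = (
                genes_per_rep.get(chain.replicate_id, 0) + len(chain)
            )
        representative = max(sorted(genes_per_rep), key=genes_per_rep.get)
    rep_chains = [c for c in chains if c.replicate_id == representative]
    full_seg = decode_chains(rep_chains, full_fit.params)

    reports = []
    for fraction in fractions:
        reduced = subsample_genes(chains, fraction, seed=seed)
        reduced_fit = baum_welch_fit(
            reduced, init=init, tol=tol, max_iter=max_iter,
            pseudocount=pseudocount, seed=seed,
        )
        pearson, mad, mse = compare_params(reduced_fit.params, full_fit.params)
        reduced_rep = [c for c in reduced if c.replicate_id == representative]
        reduced_seg = decode_chains(reduced_rep, reduced_fit.params)
        per_chrom, mean_cons = decoding_consistency(full_seg, reduced_seg)
        reports.append(
            RobustnessReport(
                fraction=fraction,
                pearson_r=pearson,
                mad=mad,
                mse=mse,
                per_chromosome_consistency=per_chrom,
                mean_consistency=mean_cons,
            )
        )
    return reports


def write_robustness_reports(
    reports: list[RobustnessReport], summary_path: str | Path,
    per_chromosome_path: str | Path | None = None,
) -> None:
    """One summary row per fraction; optionally a per-chromosome companion TSV."""
    pd.DataFrame(
        [
            {
                "fraction": r.fraction,
                "pearson_r": r.pearson_r,
                "mad": r.mad,
                "mse": r.mse,
                "mean_consistency": r.mean_consistency,
            }
            for r in reports
        ]
    ).to_csv(summary_path, sep="\t", index=False, float_format="%.6g")
    if per_chromosome_path is not None:
        rows = [
            {"fraction": r.fraction, "chrom": chrom, "consistency": value}
            for r in reports
            for chrom, value in r.per_chromosome_consistency.items()
        ]
        pd.DataFrame(rows).to_csv(
            per_chromosome_path, sep="\t", index=False, float_format="%.6g"
        )
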