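"""Synthetic F1-hybrid allele-specific count data with known genotype maps.

The generator emulates the cross design of an F1-hybrid experiment: each
replicate inherits, per chromosome, a mosaic of homozygous G1/G1 and
heterozygous G1/G2 blocks produced by a two-state Markov chain with a rare
per-gene switch rate (default 0.002, the expected crossover rate per gene).
Counts mimic droplet scRNA-seq sparsity: per gene and cell a total
allele-assigned count is drawn from an overdispersed (negative-binomial)
distribution and zeroed by an independent dropout mask; the G1 share of the
total is binomial with a beta-distributed per-gene-cell allelic probability
centered at the block's true ratio (≈1 for G1/G1, 0.5 for G1/G2).  This is a
minimal sparsity model for testing the inference pipeline, not a full
scRNA-seq simulator: it has no cell types, expression programs, batch
effects, or realistic SNP density variation.

Dropout uniforms are drawn unconditionally, so two simulations differing only
in ``dropout_rate`` share all other draws and their dropout masks are nested
— higher rates strictly remove information from the same realization.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .allelic import AlleleCountPair
from .hmm import HET, HOM, STATE_NAMES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_annotation",
    "simulate_replicate",
    "simulate_experiment",
    "write_fixture",
    "decoding_accuracy",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic F1-hybrid experiment.

    Defaults describe a small but realistic design: a handful of replicate
    embryos, chromosomes of 200 expressed genes, ~100 cells each, sparse
    counts (mean 2 allele-assigned reads per gene and cell, overdispersed)
    and 30% dropout.
    """

    n_replicates: int = 4
    n_chromosomes: int = 5
    genes_per_chromosome: int = 200
    n_cells: int = 120
    switch_rate: float = 0.002
    p_initial_het: float = 0.5
    het_ratio_center: float = 0.5
    het_ratio_concentration: float = 50.0
    hom_ratio_center: float = 0.98
    hom_ratio_concentration: float = 50.0
    mean_counts_per_gene_cell: float = 2.0
    count_overdispersion: float = 0.5
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("switch_rate", "p_initial_het", "het_ratio_center",
                     "hom_ratio_center", "dropout_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("n_replicates", "n_chromosomes", "genes_per_chromosome",
                     "n_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mean_counts_per_gene_cell <= 0:
            raise ValueError("mean_counts_per_gene_cell must be positive")
        if self.count_overdispersion < 0:
            raise ValueError("count_overdispersion must be >= 0")


@dataclass
class GroundTruth:
    """True hidden genotype and allelic probability per replicate/chrom/gene.

    ``table`` columns: replicate, chrom, gene_id, start, hidden_state (name),
    allelic_prob.
    """

    table: pd.DataFrame = field(repr=False)


def make_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene annotation shared by all simulated replicates.

    Genes sit every 10 kb along chromosomes chr1..chrN, 1-based starts.
    """
    rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for g in range(config.genes_per_chromosome):
            rows.append(
                {
                    "gene_id": f"{chrom}_g{g:04d}",
                    "chromosome": chrom,
                    "start": 10_000 * g + 1,
                    "strand": "+" if g % 2 == 0 else "-",
                }
            )
    return pd.DataFrame(rows)


def _simulate_hidden_chain(
    rng: np.random.Generator, n_genes: int, p_init_het: float, switch_rate: float
) -> np.ndarray:
    hidden = np.empty(n_genes, dtype=np.int64)
    hidden[0] = HET if rng.random() < p_init_het else HOM
    switches = rng.random(n_genes - 1) < switch_rate
    for t in range(1, n_genes):
        hidden[t] = hidden[t - 1] ^ int(switches[t - 1])
    return hidden


def simulate_replicate(
    config: SimulationConfig,
    replicate_id: str,
    rng: np.random.Generator | None = None,
) -> tuple[AlleleCountPair, GroundTruth]:
    """Simulate one replicate's G1/G2 count matrices and its genotype map.

    Deterministic given ``config.seed`` and ``replicate_id`` (a dedicated
    stream is derived from both), or given an explicit ``rng``.
    """
    if rng is None:
        # crc32 is stable across processes, unlike hash()
        rep_key = zlib.crc32(replicate_id.encode()) % (2**31)
        rng = np.random.default_rng([config.seed, rep_key])
    annot = make_annotation(config)
    n_genes_total = len(annot)
    g1 = np.zeros((n_genes_total, config.n_cells), dtype=np.int64)
    g2 = np.zeros((n_genes_total, config.n_cells), dtype=np.int64)
    truth_rows = []
    # negative binomial: var = m + od * m^2  ->  n = 1/od, p = n / (n + m)
    m = config.mean_counts_per_gene_cell
    od = config.count_overdispersion
    row = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_genes = config.genes_per_chromosome
        hidden = _simulate_hidden_chain(
            rng, n_genes, config.p_initial_het, config.switch_rate
        )
        centers = np.where(
            hidden == HOM, config.hom_ratio_center, config.het_ratio_center
        )
        conc = np.where(
            hidden == HOM,
            config.hom_ratio_concentration,
            config.het_ratio_concentration,
        )
        shape = (n_genes, config.n_cells)
        if od > 0:
            n_param = 1.0 / od
            totals = rng.negative_binomial(n_param, n_param / (n_param + m), shape)
        else:
            totals = rng.poisson(m, shape)
        dropout_u = rng.random(shape)  # drawn unconditionally: nested masks
        p_cell = rng.beta(
            conc[:, None] * centers[:, None],
            np.maximum(conc[:, None] * (1 - centers[:, None]), 1e-12),
            shape,
        )
        g1_block = rng.binomial(totals, p_cell)
        mask = dropout_u < config.dropout_rate
        totals = np.where(mask, 0, totals)
        g1_block = np.where(mask, 0, g1_block)
        g1[row : row + n_genes] = g1_block
        g2[row : row + n_genes] = totals - g1_block
        for g in range(n_genes):
            truth_rows.append(
                {
                    "replicate": replicate_id,
                    "chrom": chrom,
                    "gene_id": f"{chrom}_g{g:04d}",
                    "start": 10_000 * g + 1,
                    "hidden_state": STATE_NAMES[hidden[g]],
                    "allelic_prob": centers[g],
                }
            )
        row += n_genes
    pair = AlleleCountPair(
        replicate_id=replicate_id,
        g1_counts=sp.csr_matrix(g1),
        g2_counts=sp.csr_matrix(g2),
        gene_ids=annot["gene_id"].to_numpy(dtype=object),
        cell_barcodes=np.array(
            [f"{replicate_id}_cell{i:04d}" for i in range(config.n_cells)],
            dtype=object,
        ),
    )
    return pair, GroundTruth(table=pd.DataFrame(truth_rows))


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[AlleleCountPair], GroundTruth, pd.DataFrame]:
    """Simulate all replicates; returns (pairs, pooled truth, annotation)."""
    pairs, truths = [], []
    for r in range(config.n_replicates):
        pair, truth = simulate_replicate(config, f"rep{r + 1}")
        pairs.append(pair)
        truths.append(truth.table)
    return (
        pairs,
        GroundTruth(table=pd.concat(truths, ignore_index=True)),
        make_annotation(config),
    )


def _write_triplet(matrix: sp.spmatrix, genes, barcodes, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), sp.coo_matrix(matrix))
    with open(out_dir / "features.tsv", "w") as handle:
        for gene in genes:
            handle.write(f"{gene}\t{gene}\tGene Expression\n")
    with open(out_dir / "barcodes.tsv", "w") as handle:
        for bc in barcodes:
            handle.write(f"{bc}\n")


def write_fixture(
    pair: AlleleCountPair,
    truth: GroundTruth,
    out_dir: str | Path,
    annotation: pd.DataFrame | None = None,
) -> Path:
    """Write a replicate as an on-disk fixture mirroring real input layout.

    Layout: ``g1/`` and ``g2/`` 10x-style triplets, ``annotation.tsv``,
    ``truth.tsv`` and ``truth.bed`` (0-based half-open genotype segments).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_triplet(pair.g1_counts, pair.gene_ids, pair.cell_barcodes, out_dir / "g1")
    _write_triplet(pair.g2_counts, pair.gene_ids, pair.cell_barcodes, out_dir / "g2")
    if annotation is not None:
        annotation.to_csv(out_dir / "annotation.tsv", sep="\t", index=False)
    truth.table.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    _write_truth_bed(truth.table, out_dir / "truth.bed")
    return out_dir


def _write_truth_bed(table: pd.DataFrame, path: Path) -> None:
    rows = []
    for (rep, chrom), sub in table.groupby(["replicate", "chrom"], sort=False):
        sub = sub.sort_values("start")
        states = sub["hidden_state"].to_numpy()
        bounds = np.flatnonzero(np.r_[True, states[1:] != states[:-1]])
        ends = np.r_[bounds[1:], len(states)]
        for lo, hi in zip(bounds, ends):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(sub["start"].iloc[lo]) - 1,
                    "end": int(sub["start"].iloc[hi - 1]),
                    "name": states[lo],
                    "score": hi - lo,
                    "strand": ".",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def decoding_accuracy(genes: pd.DataFrame, truth: GroundTruth) -> float:
    """Fraction of decoded genes whose state matches the simulated truth."""
    merged = genes.merge(
        truth.table[["replicate", "chrom", "gene_id", "hidden_state"]],
        on=["replicate", "chrom", "gene_id"],
        validate="1:1",
    )
    if merged.empty:
        raise ValueError("no overlap between decoded genes and ground truth")
    return float((merged["decoded_state"] == merged["hidden_state"]).mean())
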