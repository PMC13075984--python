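"""Allele-specific count matrices and replicate-level allelic bias estimates.

An F1-hybrid experiment yields, per replicate, two feature-barcode matrices of
identical shape: one counting reads assigned (via strain-specific SNPs) to the
G1 genome and one to the G2 genome.  The per-cell allelic bias of a gene is
``r = G1 / (G1 + G2)``; averaging ``r`` over the cells with at least one
allele-assigned read gives the replicate-level per-gene estimate ``r_mean``,
which concentrates near 0.5 inside heterozygous G1/G2 chromosome segments and
near 1.0 inside homozygous G1/G1 segments.  Genes are then ordered along each
chromosome to form the sequential tracks the HMM consumes.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleCountPair",
    "GeneRatioTrack",
    "read_allele_matrices",
    "read_annotation",
    "cell_ratio",
    "gene_mean_ratio",
    "build_ratio_tracks",
    "write_ratio_table",
]


class InputError(ValueError):
    """A required input file is missing or malformed."""


@dataclass
class AlleleCountPair:
    """Matched G1/G2 allele-specific count matrices for one replicate.

    Both matrices are genes x cells CSR with identical gene and barcode
    orderings; counts are non-negative integers.
    """

    replicate_id: str
    g1_counts: sp.csr_matrix
    g2_counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.g1_counts = sp.csr_matrix(self.g1_counts)
        self.g2_counts = sp.csr_matrix(self.g2_counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.g1_counts.shape != self.g2_counts.shape:
            raise ValueError(
                f"G1 shape {self.g1_counts.shape} != G2 shape {self.g2_counts.shape}"
            )
        if self.g1_counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError("matrix shape does not match gene/barcode labels")
        if self.g1_counts.nnz and self.g1_counts.data.min() < 0:
            raise ValueError("negative counts in G1 matrix")
        if self.g2_counts.nnz and self.g2_counts.data.min() < 0:
            raise ValueError("negative counts in G2 matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.g1_counts.shape


@dataclass
class GeneRatioTrack:
    """Genes of one chromosome ordered by genomic start, with mean ratios.

    ``genes`` columns: gene_id, start, r_mean, n_cells.
    """

    replicate_id: str
    chromosome: str
    genes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        r = self.genes["r_mean"].to_numpy(float)
        if len(r) and (not np.all(np.isfinite(r)) or r.min() < 0 or r.max() > 1):
            raise ValueError("r_mean values must be finite and in [0, 1]")
        starts = self.genes["start"].to_numpy()
        if len(starts) > 1 and np.any(np.diff(starts) < 0):
            raise ValueError("genes must be sorted by start coordinate")

    def __len__(self) -> int:
        return len(self.genes)


def _find_file(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = directory / f"{stem}{suffix}"
            if candidate.exists():
                return candidate
    raise InputError(
        f"none of {[s for s in stems]} (optionally .gz) found in {directory}"
    )


def _read_lines_first_column(path: Path) -> np.ndarray:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return np.array(
            [line.rstrip("\n").split("\t")[0] for line in handle if line.strip()],
            dtype=object,
        )


def _read_triplet(directory: str | Path) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"matrix directory not found: {directory}")
    mtx_path = _find_file(directory, ("matrix.mtx",))
    features_path = _find_file(directory, ("features.tsv", "genes.tsv"))
    barcodes_path = _find_file(directory, ("barcodes.tsv",))
    opener = gzip.open if mtx_path.suffix == ".gz" else open
    with opener(mtx_path, "rb") as handle:
        matrix = sp.csr_matrix(scipy.io.mmread(handle))
    genes = _read_lines_first_column(features_path)
    barcodes = _read_lines_first_column(barcodes_path)
    if matrix.shape != (len(genes), len(barcodes)):
        raise InputError(
            f"{mtx_path}: shape {matrix.shape} does not match "
            f"{len(genes)} features x {len(barcodes)} barcodes"
        )
    return matrix, genes, barcodes


def read_allele_matrices(
    g1_dir: str | Path, g2_dir: str | Path, replicate_id: str
) -> AlleleCountPair:
    """Read the 10x-style G1 and G2 triplets and intersect their universes.

    Each directory must contain ``matrix.mtx``, ``features.tsv`` (or
    ``genes.tsv``) and ``barcodes.tsv``, optionally gzipped.  Genes and
    barcodes present in only one matrix are dropped (a count observed for a
    single allele cannot be turned into a ratio); the retained sets keep the
    G1 file's ordering.
    """
    g1_mat, g1_genes, g1_bc = _read_triplet(g1_dir)
    g2_mat, g2_genes, g2_bc = _read_triplet(g2_dir)

    common_genes = np.array(
        [g for g in g1_genes if g in set(g2_genes)], dtype=object
    )
    common_bc = np.array([b for b in g1_bc if b in set(g2_bc)], dtype=object)
    if len(common_genes) == 0:
        raise InputError("G1 and G2 matrices share no genes")
    if len(common_bc) == 0:
        raise InputError("G1 and G2 matrices share no cell barcodes")

    dropped_genes = len(g1_genes) + len(g2_genes) - 2 * len(common_genes)
    dropped_bc = len(g1_bc) + len(g2_bc) - 2 * len(common_bc)
    if dropped_genes or dropped_bc:
        logger.info(
            "replicate %s: dropped %d gene entries and %d barcode entries "
            "outside the G1/G2 intersection",
            replicate_id,
            dropped_genes,
            dropped_bc,
        )

    def _subset(mat, genes, bcs):
        gene_idx = {g: i for i, g in enumerate(genes)}
        bc_idx = {b: i for i, b in enumerate(bcs)}
        rows = [gene_idx[g] for g in common_genes]
        cols = [bc_idx[b] for b in common_bc]
        return sp.csr_matrix(mat[rows][:, cols])

    return AlleleCountPair(
        replicate_id=replicate_id,
        g1_counts=_subset(g1_mat, g1_genes, g1_bc),
        g2_counts=_subset(g2_mat, g2_genes, g2_bc),
        gene_ids=common_genes,
        cell_barcodes=common_bc,
    )


_ANNOT_COLUMNS = ["gene_id", "chromosome", "start", "strand"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation as TSV (gene_id, chromosome, start, strand) or GTF.

    GTF input is restricted to ``gene`` records; ``start`` is the 1-based
    feature start.  Strand is kept but never used for ordering.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    if path.suffix.lower() in {".gtf", ".gff"} or str(path).endswith(
        (".gtf.gz", ".gff.gz")
    ):
        import pyranges

        gr = pyranges.read_gtf(str(path)).df
        gr = gr[gr["Feature"] == "gene"]
        annot = pd.DataFrame(
            {
                "gene_id": gr["gene_id"].astype(str),
                "chromosome": gr["Chromosome"].astype(str),
                "start": gr["Start"].astype(int) + 1,  # pyranges is 0-based
                "strand": gr.get("Strand", pd.Series(["."] * len(gr))).astype(str),
            }
        )
    else:
        first = pd.read_csv(path, sep="\t", nrows=1, header=None)
        has_header = str(first.iloc[0, 0]) == "gene_id"
        annot = pd.read_csv(
            path,
            sep="\t",
            header=0 if has_header else None,
            names=None if has_header else _ANNOT_COLUMNS,
        )
        missing = set(_ANNOT_COLUMNS) - set(annot.columns)
        if missing:
            raise InputError(f"annotation is missing columns {sorted(missing)}")
    annot = annot[_ANNOT_COLUMNS].astype(
        {"gene_id": str, "chromosome": str, "start": int, "strand": str}
    )
    if annot["gene_id"].duplicated().any():
        dupes = annot.loc[annot["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise InputError(f"duplicated gene_id(s) in annotation, e.g. {dupes}")
    if (annot["start"] < 1).any():
        raise InputError("annotation start coordinates must be >= 1 (1-based)")
    return annot.reset_index(drop=True)


def cell_ratio(g1: float, g2: float) -> float:
    """Per-cell allelic bias r = G1/(G1+G2); NaN when the cell has no reads.

    Zero total coverage carries no allelic information (allelic dropout), so
    the ratio is undefined rather than 0 or 0.5.
    """
    if g1 < 0 or g2 < 0:
        raise ValueError(f"counts must be non-negative, got ({g1}, {g2})")
    total = g1 + g2
    if total == 0:
        return float("nan")
    return g1 / total


def gene_mean_ratio(pair: AlleleCountPair, min_cells: int = 1) -> pd.DataFrame:
    """Replicate-level per-gene allelic bias: mean of r over informative cells.

    A cell is informative for a gene when g1 + g2 > 0 there; other cells are
    treated as missing, not zero-filled.  Genes with fewer than ``min_cells``
    informative cells are flagged ``excluded`` with ``r_mean`` = NaN.

    Returns a DataFrame indexed like ``pair.gene_ids`` with columns
    gene_id, r_mean, n_cells, excluded.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    total = (pair.g1_counts + pair.g2_counts).tocsr()
    total.eliminate_zeros()
    n_cells = np.asarray(total.getnnz(axis=1)).ravel()
    # ratio matrix shares G1's sparsity: r = g1 * (1/total) where total > 0
    recip = total.copy()
    recip.data = 1.0 / recip.data
    ratio_sum = np.asarray(pair.g1_counts.multiply(recip).sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        r_mean = np.where(n_cells > 0, ratio_sum / np.maximum(n_cells, 1), np.nan)
    excluded = n_cells < min_cells
    r_mean = np.where(excluded, np.nan, r_mean)
    return pd.DataFrame(
        {
            "gene_id": pair.gene_ids,
            "r_mean": r_mean,
            "n_cells": n_cells.astype(int),
            "excluded": excluded,
        }
    )


def build_ratio_tracks(
    pair: AlleleCountPair, annot: pd.DataFrame, min_cells: int = 1
) -> list[GeneRatioTrack]:
    """Assemble one ordered ratio track per chromosome.

    Keeps annotated, non-excluded genes only, sorted ascending by the
    annotation start coordinate (strand ignored).  Genes of the pair absent
    from the annotation are dropped with a logged warning.
    """
    ratios = gene_mean_ratio(pair, min_cells=min_cells)
    merged = ratios.merge(annot, on="gene_id", how="left")
    unannotated = merged["chromosome"].isna()
    if unannotated.any():
        logger.warning(
            "replicate %s: %d gene(s) absent from the annotation were dropped",
            pair.replicate_id,
            int(unannotated.sum()),
        )
    kept = merged[~unannotated & ~merged["excluded"]]
    if kept.empty:
        raise InputError("no gene of the count matrices overlaps the annotation")
    tracks = []
    for chrom, sub in kept.groupby("chromosome", sort=True):
        sub = sub.sort_values(["start", "gene_id"], kind="mergesort")
        tracks.append(
            GeneRatioTrack(
                replicate_id=pair.replicate_id,
                chromosome=str(chrom),
                genes=sub[["gene_id", "start", "r_mean", "n_cells"]].reset_index(
                    drop=True
                ),
            )
        )
    return tracks


def write_ratio_table(tracks: list[GeneRatioTrack], path: str | Path) -> None:
    """Write per-gene replicate-level ratios as TSV."""
    rows = []
    for track in tracks:
        frame = track.genes.copy()
        frame.insert(0, "chrom", track.chromosome)
        frame.insert(0, "replicate", track.replicate_id)
        rows.append(frame)
    out = pd.concat(rows, ignore_index=True)
    out = out[["replicate", "chrom", "start", "gene_id", "r_mean", "n_cells"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
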