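"""Discretization of replicate-level allelic ratios into six observed states.

The observed alphabet has six symbols: every ratio below 0.5 collapses into
symbol 0 (values there arise almost exclusively from heterozygous segments,
via balanced or G2-biased expression), and the interval [0.5, 1.0] is split
into five 0.1-wide bins, symbols 1..5.  Bins are left-closed/right-open with
the top bin closed at 1.0, so the map is total and deterministic on [0, 1].
Symbols are numbered in ascending-ratio order, which lets the HMM module
orient its hidden states by expected symbol index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allelic import GeneRatioTrack

logger = logging.getLogger(__name__)

N_SYMBOLS = 6

__all__ = ["N_SYMBOLS", "ObservedChain", "ratio_to_state", "build_chains",
           "write_chains", "read_chains"]


@dataclass
class ObservedChain:
    """Per-chromosome, per-replicate sequence of discrete observed states."""

    replicate_id: str
    chromosome: str
    gene_ids: np.ndarray
    states: np.ndarray
    starts: np.ndarray | None = field(default=None)
    r_mean: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.states = np.asarray(self.states, dtype=np.int64)
        if len(self.states) != len(self.gene_ids) or len(self.states) < 1:
            raise ValueError("states and gene_ids must have equal length >= 1")
        if self.states.min() < 0 or self.states.max() >= N_SYMBOLS:
            raise ValueError(f"observed symbols must lie in 0..{N_SYMBOLS - 1}")
        if self.starts is not None:
            self.starts = np.asarray(self.starts, dtype=np.int64)
            if len(self.starts) != len(self.states):
                raise ValueError("starts must match states length")
        if self.r_mean is not None:
            self.r_mean = np.asarray(self.r_mean, dtype=float)
            if len(self.r_mean) != len(self.states):
                raise ValueError("r_mean must match states length")

    def __len__(self) -> int:
        return len(self.states)


def ratio_to_state(r) -> int | np.ndarray:
    """Map a mean allelic ratio in [0, 1] to its observed symbol in {0..5}.

    Symbol 0 covers r < 0.5; symbols 1..5 cover the five 0.1-wide bins
    [0.5, 0.6), ..., [0.9, 1.0].  Accepts scalars or arrays.
    """
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ratio must be finite")
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("ratio must lie in [0, 1]")
    # left-closed bins: [0, .5), [.5, .6), [.6, .7), [.7, .8), [.8, .9), [.9, 1]
    states = np.digitize(arr, [0.5, 0.6, 0.7, 0.8, 0.9]).astype(np.int64)
    return int(states) if np.isscalar(r) or arr.ndim == 0 else states


def build_chains(tracks: list[GeneRatioTrack]) -> list[ObservedChain]:
    """Discretize ratio tracks into observation chains, one per track.

    Chains shorter than two genes carry no transition information; they are
    still emitted (decoding remains defined) but logged as degenerate.
    """
    if not tracks:
        raise ValueError("tracks must be nonempty")
    chains = []
    for track in tracks:
        chain = ObservedChain(
            replicate_id=track.replicate_id,
            chromosome=track.chromosome,
            gene_ids=track.genes["gene_id"].to_numpy(dtype=object),
            states=ratio_to_state(track.genes["r_mean"].to_numpy(float)),
            starts=track.genes["start"].to_numpy(np.int64),
            r_mean=track.genes["r_mean"].to_numpy(float),
        )
        if len(chain) < 2:
            logger.warning(
                "chain %s/%s has length %d: no transition information",
                track.replicate_id,
                track.chromosome,
                len(chain),
            )
        chains.append(chain)
    return chains


def write_chains(chains: list[ObservedChain], path: str | Path) -> None:
    """Export chains as TSV (replicate, chrom, gene_id, order_index, state[, start])."""
    rows = []
    for chain in chains:
        frame = pd.DataFrame(
            {
                "replicate": chain.replicate_id,
                "chrom": chain.chromosome,
                "gene_id": chain.gene_ids,
                "order_index": np.arange(len(chain)),
                "state": chain.states,
            }
        )
        if chain.starts is not None:
            frame["start"] = chain.starts
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_chains(path: str | Path) -> list[ObservedChain]:
    """Import chains written by :func:`write_chains`."""
    table = pd.read_csv(path, sep="\t")
    chains = []
    for (rep, chrom), sub in table.groupby(["replicate", "chrom"], sort=False):
        sub = sub.sort_values("order_index")
        chains.append(
            ObservedChain(
                replicate_id=str(rep),
                chromosome=str(chrom),
                gene_ids=sub["gene_id"].astype(str).to_numpy(dtype=object),
                states=sub["state"].to_numpy(np.int64),
                starts=sub["start"].to_numpy(np.int64) if "start" in sub else None,
            )
        )
    return chains
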