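"""Categorical hidden Markov model for chromosome-scale genotype inference.

Two hidden states describe the true genotype architecture of a paternal
chromosome in an F1-hybrid cross: homozygous G1/G1 (state 0) and heterozygous
G1/G2 (state 1).  Observations are the six discrete allelic-ratio symbols of
one gene each; a chromosome is one chain.  The biological priors enter through
initialization: the chain may start in either state with probability 0.5, and
switching state between adjacent genes has probability 0.002 — mouse
chromosomes carry on the order of 1,000 protein-coding genes and experience
roughly two meiotic crossovers, hence 2/1,000 switches per gene.  All
parameters (pi, A, B) are subsequently re-estimated by Baum-Welch on
chromosome chains pooled across replicates, and chains are decoded by Viterbi.

Numerics use scaled forward/backward recursions (probability space with
per-position renormalization), batched over equal-length chains.  A small
pseudocount regularizes the M-step so rarely observed symbols cannot lock a
row at exactly zero.  After fitting, hidden-state labels are normalized so
that the state with the higher expected emitted symbol index is G1/G1 —
EM is invariant to label permutation, the biology is not.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discretize import N_SYMBOLS, ObservedChain

logger = logging.getLogger(__name__)

N_HIDDEN = 2
HOM, HET = 0, 1  # G1/G1, G1/G2
STATE_NAMES = ("G1G1", "G1G2")

__all__ = [
    "N_HIDDEN",
    "HOM",
    "HET",
    "STATE_NAMES",
    "HMMParams",
    "FitResult",
    "GenotypeSegmentation",
    "init_params",
    "expected_transition_rate",
    "forward_log_likelihood",
    "sample_training_chains",
    "baum_welch_fit",
    "viterbi_decode",
    "posterior_heterozygous",
    "simulate_chains",
    "segments_from_states",
]


class DecodingError(RuntimeError):
    """A chain contains a symbol with zero emission mass in every hidden state."""


class TrainingError(RuntimeError):
    """The training set carries no usable transition information."""


@dataclass
class HMMParams:
    """Initial vector pi (2), transition matrix A (2x2), emission matrix B (2x6)."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        if self.pi.shape != (N_HIDDEN,) or self.A.shape != (N_HIDDEN, N_HIDDEN):
            raise ValueError("pi must be length 2 and A shape (2, 2)")
        if self.B.shape != (N_HIDDEN, N_SYMBOLS):
            raise ValueError(f"B must have shape (2, {N_SYMBOLS})")
        for name, arr in (("pi", self.pi), ("A", self.A), ("B", self.B)):
            if arr.min() < 0:
                raise ValueError(f"{name} has negative entries")
        if abs(self.pi.sum() - 1) > atol:
            raise ValueError("pi must sum to 1")
        if np.abs(self.A.sum(axis=1) - 1).max() > atol:
            raise ValueError("rows of A must sum to 1")
        if np.abs(self.B.sum(axis=1) - 1).max() > atol:
            raise ValueError("rows of B must sum to 1")

    def expected_symbols(self) -> np.ndarray:
        """Expected emitted symbol index per hidden state."""
        return self.B @ np.arange(N_SYMBOLS, dtype=float)

    def relabel(self) -> "HMMParams":
        """Canonical orientation: state 0 (G1/G1) emits the higher symbols.

        High symbols mean allelic ratios near 1, the homozygous signature.
        Returns self if already canonical, otherwise the label-swapped copy.
        """
        exp = self.expected_symbols()
        if exp[HOM] >= exp[HET]:
            return self
        perm = np.array([HET, HOM])
        return HMMParams(
            pi=self.pi[perm], A=self.A[np.ix_(perm, perm)], B=self.B[perm]
        )

    def flatten(self) -> np.ndarray:
        """Concatenated (pi, A, B) parameter vector of length 18."""
        return np.concatenate([self.pi, self.A.ravel(), self.B.ravel()])

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "label_order": list(STATE_NAMES),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "HMMParams":
        return cls(pi=payload["pi"], A=payload["A"], B=payload["B"])


@dataclass
class FitResult:
    """Outcome of a Baum-Welch fit on pooled chromosome chains."""

    params: HMMParams
    log_likelihood_trace: np.ndarray
    n_iterations: int
    converged: bool
    training_chain_ids: list[str]
    seed: int | None = None

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])

    def save(self, path: str | Path) -> None:
        payload = {
            **self.params.to_dict(),
            "training": {
                "seed": self.seed,
                "chains": self.training_chain_ids,
                "n_iterations": self.n_iterations,
                "converged": self.converged,
                "final_log_likelihood": self.log_likelihood,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        payload = json.loads(Path(path).read_text())
        meta = payload.get("training", {})
        return cls(
            params=HMMParams.from_dict(payload),
            log_likelihood_trace=np.array(
                [meta.get("final_log_likelihood", np.nan)]
            ),
            n_iterations=meta.get("n_iterations", 0),
            converged=meta.get("converged", False),
            training_chain_ids=meta.get("chains", []),
            seed=meta.get("seed"),
        )


@dataclass
class GenotypeSegmentation:
    """Decoded per-gene genotype states plus merged chromosome segments.

    ``genes`` columns: replicate, chrom, gene_id, order_index, start,
    observed_state, decoded_state, posterior_het.
    ``segments`` columns: replicate, chrom, first_gene, last_gene, start_bp,
    end_bp, state, n_genes.
    """

    replicate_id: str
    genes: pd.DataFrame = field(repr=False)
    segments: pd.DataFrame = field(repr=False)

    def write_genes_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_bed(self, path: str | Path) -> None:
        """Segments as BED: 0-based half-open spans, gene start to gene start."""
        bed = pd.DataFrame(
            {
                "chrom": self.segments["chrom"],
                "start": self.segments["start_bp"] - 1,
                "end": self.segments["end_bp"],
                "name": self.segments["state"],
                "score": self.segments["n_genes"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


def init_params() -> HMMParams:
    """Biologically informed starting parameters.

    pi = (0.5, 0.5): the first gene of a chromosome is equally likely to sit
    in either genotype.  A keeps a state with probability 0.998 and switches
    with 0.002, the expected per-gene crossover rate.  B (not biologically
    constrained) is initialized asymmetrically to break the label-switching
    symmetry of EM: the homozygous state ramps linearly toward symbol 5
    (ratios near 1), the heterozygous state concentrates on symbols 0-1
    (ratios at or below ~0.6); every entry stays positive.
    """
    pi = np.full(N_HIDDEN, 0.5)
    A = np.array([[0.998, 0.002], [0.002, 0.998]])
    B = np.empty((N_HIDDEN, N_SYMBOLS))
    B[HOM] = np.arange(1, N_SYMBOLS + 1) / np.arange(1, N_SYMBOLS + 1).sum()
    B[HET] = np.array([0.45, 0.45, 0.025, 0.025, 0.025, 0.025])
    return HMMParams(pi=pi, A=A, B=B)


def expected_transition_rate(
    crossovers_per_chromosome: float, genes_per_chromosome: float
) -> float:
    """Expected per-gene genotype switch rate: crossovers / genes.

    With ~1,000 genes and ~2 crossovers per chromosome this gives the 0.002
    used to initialize the transition matrix.
    """
    if genes_per_chromosome <= 0:
        raise ValueError("genes_per_chromosome must be positive")
    if crossovers_per_chromosome < 0:
        raise ValueError("crossovers_per_chromosome must be non-negative")
    return crossovers_per_chromosome / genes_per_chromosome


def _check_emission_support(chain: ObservedChain, params: HMMParams) -> None:
    dead = params.B.sum(axis=0)[chain.states] == 0
    if dead.any():
        gene = chain.gene_ids[int(np.argmax(dead))]
        raise DecodingError(
            f"symbol {int(chain.states[int(np.argmax(dead))])} at gene {gene} "
            f"({chain.replicate_id}/{chain.chromosome}) has zero emission "
            "probability in both hidden states"
        )


def _forward_scaled(
    obs: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward pass over a batch of equal-length chains.

    obs: (n, T) symbol array.  Returns (alpha, c) with alpha (T, n, 2)
    row-normalized and c (T, n) the normalization constants;
    log-likelihood per chain = sum_t log c[t].  c = 0 marks an impossible
    observation.
    """
    n, T = obs.shape
    alpha = np.zeros((T, n, N_HIDDEN))
    c = np.zeros((T, n))
    a = params.pi[None, :] * params.B[:, obs[:, 0]].T
    c[0] = a.sum(axis=1)
    ok = c[0] > 0
    alpha[0, ok] = a[ok] / c[0, ok, None]
    for t in range(1, T):
        a = (alpha[t - 1] @ params.A) * params.B[:, obs[:, t]].T
        c[t] = a.sum(axis=1)
        ok = c[t] > 0
        alpha[t, ok] = a[ok] / c[t, ok, None]
    return alpha, c


def _backward_scaled(
    obs: np.ndarray, params: HMMParams, c: np.ndarray
) -> np.ndarray:
    """Scaled backward pass matching :func:`_forward_scaled`'s constants."""
    n, T = obs.shape
    beta = np.zeros((T, n, N_HIDDEN))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = (beta[t + 1] * params.B[:, obs[:, t + 1]].T) @ params.A.T
        ok = c[t + 1] > 0
        beta[t, ok] = b[ok] / c[t + 1, ok, None]
    return beta


def forward_log_likelihood(chain: ObservedChain, params: HMMParams) -> float:
    """log P(observations | params); -inf when the chain is impossible."""
    obs = chain.states[None, :]
    _, c = _forward_scaled(obs, params)
    if (c == 0).any():
        logger.warning(
            "chain %s/%s has zero probability under the given parameters",
            chain.replicate_id,
            chain.chromosome,
        )
        return float("-inf")
    return float(np.log(c[:, 0]).sum())


def sample_training_chains(
    chains: list[ObservedChain], per_replicate: int, seed: int
) -> list[ObservedChain]:
    """Sample chromosomes per replicate, uniformly without replacement.

    Replicates with fewer than ``per_replicate`` chromosomes contribute all
    of theirs.  Deterministic under a fixed seed; the returned subset keeps
    the input order.
    """
    if per_replicate < 1:
        raise ValueError("per_replicate must be >= 1")
    if not chains:
        raise ValueError("chains must be nonempty")
    rng = np.random.default_rng(seed)
    by_rep: dict[str, list[int]] = {}
    for i, chain in enumerate(chains):
        by_rep.setdefault(chain.replicate_id, []).append(i)
    selected: set[int] = set()
    for rep in sorted(by_rep):
        idx = by_rep[rep]
        k = min(per_replicate, len(idx))
        chosen = rng.choice(idx, size=k, replace=False)
        selected.update(int(i) for i in chosen)
    return [chain for i, chain in enumerate(chains) if i in selected]


def _group_by_length(chains: list[ObservedChain]) -> dict[int, np.ndarray]:
    groups: dict[int, list[np.ndarray]] = {}
    for chain in chains:
        groups.setdefault(len(chain), []).append(chain.states)
    return {length: np.stack(rows) for length, rows in groups.items()}


def baum_welch_fit(
    chains: list[ObservedChain],
    init: HMMParams | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    pseudocount: float = 1e-6,
    seed: int | None = None,
) -> FitResult:
    """Multi-sequence Baum-Welch (EM) over pooled chromosome chains.

    One parameter set is learned for all chains.  Iteration stops when the
    total log-likelihood improves by less than ``tol`` or after ``max_iter``
    rounds; transition and emission updates carry a ``pseudocount`` so no
    entry collapses to exactly zero.  The trace records the log-likelihood of
    the parameters *entering* each iteration, hence is non-decreasing.
    Labels are normalized after fitting (G1/G1 = higher expected symbol).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not chains:
        raise ValueError("chains must be nonempty")
    if all(len(c) < 2 for c in chains):
        raise TrainingError("all chains have length 1: no transition information")
    params = init if init is not None else init_params()
    for chain in chains:
        _check_emission_support(chain, params)

    groups = _group_by_length(chains)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        loglik = 0.0
        pi_num = np.zeros(N_HIDDEN)
        trans_num = np.zeros((N_HIDDEN, N_HIDDEN))
        emis_num = np.zeros((N_HIDDEN, N_SYMBOLS))
        for T, obs in groups.items():
            alpha, c = _forward_scaled(obs, params)
            if (c == 0).any():
                raise DecodingError(
                    "a training chain has zero probability under the current "
                    "parameters; increase the pseudocount"
                )
            beta = _backward_scaled(obs, params, c)
            loglik += float(np.log(c).sum())
            gamma = alpha * beta  # (T, n, 2); rows sum to 1 by scaling
            pi_num += gamma[0].sum(axis=0)
            # xi[t] proportional to alpha[t] A B[:, o_{t+1}] beta[t+1] / c[t+1]
            for t in range(T - 1):
                right = (params.B[:, obs[:, t + 1]].T * beta[t + 1]) / c[
                    t + 1, :, None
                ]
                trans_num += params.A * (alpha[t].T @ right)
            sym = np.eye(N_SYMBOLS)[obs].swapaxes(0, 1)  # (T, n, 6) one-hot
            emis_num += np.einsum("tnh,tns->hs", gamma, sym)
        trace.append(loglik)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        pi_new = pi_num + pseudocount
        params = HMMParams(
            pi=pi_new / pi_new.sum(),
            A=_normalize_rows(trans_num + pseudocount),
            B=_normalize_rows(emis_num + pseudocount),
        )
    fitted = params.relabel()
    return FitResult(
        params=fitted,
        log_likelihood_trace=np.array(trace),
        n_iterations=len(trace),
        converged=converged,
        training_chain_ids=[f"{c.replicate_id}/{c.chromosome}" for c in chains],
        seed=seed,
    )


def _normalize_rows(matrix: np.ndarray) -> np.ndarray:
    return matrix / matrix.sum(axis=1, keepdims=True)


def viterbi_decode(
    chain: ObservedChain, params: HMMParams
) -> tuple[np.ndarray, float]:
    """Most probable hidden path (log-space Viterbi) and its log-probability.

    Ties are broken toward remaining in the previous state — switches are
    rare a priori — and toward G1/G2 when the terminal scores tie.
    """
    _check_emission_support(chain, params)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
        log_B = np.log(params.B)
    T = len(chain)
    delta = log_pi + log_B[:, chain.states[0]]
    backptr = np.zeros((T, N_HIDDEN), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + log_A  # scores[j, i]: from j into i
        best = scores.argmax(axis=0)
        top = scores.max(axis=0)
        for i in range(N_HIDDEN):
            if scores[i, i] == top[i]:  # tie (or win) for staying put
                best[i] = i
        backptr[t] = best
        delta = top + log_B[:, chain.states[t]]
    # terminal tie broken toward the heterozygous state
    last = HET if delta[HET] >= delta[HOM] else HOM
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = backptr[t, path[t]]
    return path, float(delta[last])


def posterior_heterozygous(chain: ObservedChain, params: HMMParams) -> np.ndarray:
    """Forward-backward smoothed P(hidden = G1/G2 | observations) per gene."""
    _check_emission_support(chain, params)
    obs = chain.states[None, :]
    alpha, c = _forward_scaled(obs, params)
    if (c == 0).any():
        raise DecodingError(
            f"chain {chain.replicate_id}/{chain.chromosome} has zero "
            "probability under the given parameters"
        )
    beta = _backward_scaled(obs, params, c)
    gamma = alpha[:, 0, :] * beta[:, 0, :]
    return gamma[:, HET]


def simulate_chains(
    params: HMMParams,
    n_chains: int,
    lengths: int | list[int],
    seed: int,
    replicate_id: str = "sim",
) -> tuple[list[ObservedChain], list[np.ndarray]]:
    """Ancestral sampling from the model: hidden paths from pi/A, symbols from B.

    ``lengths`` may be a single length or one per chain.  Returns the
    observation chains and the hidden ground-truth paths; deterministic under
    a fixed seed.
    """
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_chains
    if len(lengths) != n_chains:
        raise ValueError("lengths must match n_chains")
    if min(lengths) < 1:
        raise ValueError("chain lengths must be >= 1")
    rng = np.random.default_rng(seed)
    cum_A = np.cumsum(params.A, axis=1)
    cum_B = np.cumsum(params.B, axis=1)
    chains, hiddens = [], []
    for k, T in enumerate(lengths):
        hidden = np.empty(T, dtype=np.int64)
        hidden[0] = rng.random() >= params.pi[0]
        u = rng.random(T - 1)
        for t in range(1, T):
            hidden[t] = np.searchsorted(cum_A[hidden[t - 1]], u[t - 1], side="right")
        symbols = (
            rng.random(T)[:, None] >= cum_B[hidden][:, : N_SYMBOLS - 1]
        ).sum(axis=1)
        chains.append(
            ObservedChain(
                replicate_id=replicate_id,
                chromosome=f"sim{k}",
                gene_ids=np.array([f"sim{k}_g{i}" for i in range(T)], dtype=object),
                states=symbols.astype(np.int64),
            )
        )
        hiddens.append(hidden)
    return chains, hiddens


def segments_from_states(
    genes: pd.DataFrame, annot: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Merge per-gene decoded states into maximal constant-state segments.

    ``genes`` must be ordered by (chrom, order_index) and carry columns
    replicate, chrom, gene_id, decoded_state and (directly or via ``annot``)
    start.  Segment spans run from the start of the first gene to the start
    of the last gene of the run; n_genes counts the run length.
    """
    frame = genes.copy()
    if "start" not in frame.columns:
        if annot is None:
            raise ValueError("gene start coordinates require an annotation")
        frame = frame.merge(
            annot[["gene_id", "start"]], on="gene_id", how="left", validate="m:1"
        )
        if frame["start"].isna().any():
            missing = frame.loc[frame["start"].isna(), "gene_id"].iloc[0]
            raise ValueError(f"gene {missing} is absent from the annotation")
    rows = []
    for (rep, chrom), sub in frame.groupby(["replicate", "chrom"], sort=False):
        sub = sub.sort_values("order_index")
        states = sub["decoded_state"].to_numpy()
        boundaries = np.flatnonzero(
            np.r_[True, states[1:] != states[:-1]]
        )
        ends = np.r_[boundaries[1:], len(states)]
        for lo, hi in zip(boundaries, ends):
            run = sub.iloc[lo:hi]
            rows.append(
                {
                    "replicate": rep,
                    "chrom": chrom,
                    "first_gene": run["gene_id"].iloc[0],
                    "last_gene": run["gene_id"].iloc[-1],
                    "start_bp": int(run["start"].iloc[0]),
                    "end_bp": int(run["start"].iloc[-1]),
                    "state": states[lo],
                    "n_genes": hi - lo,
                }
            )
    return pd.DataFrame(rows)
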