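"""High-level modelling interface: `GenotypeHMM` and `GenotypeHMMResults`.

The model object holds the observation chains (built from allele-specific
count matrices or supplied directly) and the training configuration; `fit()`
runs Baum-Welch and returns a results object carrying the estimated
parameters, the log-likelihood trace and convergence diagnostics, with
methods for decoding, posterior confidence, simulation, posterior predictive
checks and a text summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hmm as _hmm
from .allelic import AlleleCountPair, build_ratio_tracks
from .discretize import N_SYMBOLS, ObservedChain, build_chains
from .hmm import (
    STATE_NAMES,
    FitResult,
    GenotypeSegmentation,
    HMMParams,
    baum_welch_fit,
    posterior_heterozygous,
    sample_training_chains,
    segments_from_states,
    simulate_chains,
    viterbi_decode,
)
from .ppc import PPCReport, run_ppc

__all__ = ["GenotypeHMM", "GenotypeHMMResults", "chains_from_counts",
           "decode_chains"]


def chains_from_counts(
    pair: AlleleCountPair, annot: pd.DataFrame, min_cells: int = 1
) -> list[ObservedChain]:
    """Counts -> per-gene mean ratios -> ordered tracks -> observation chains."""
    return build_chains(build_ratio_tracks(pair, annot, min_cells=min_cells))


def decode_chains(
    chains: list[ObservedChain], params: HMMParams
) -> GenotypeSegmentation:
    """Viterbi-decode chains and assemble the per-gene table plus segments.

    All chains must belong to one replicate (one segmentation map).
    """
    replicates = {c.replicate_id for c in chains}
    if len(replicates) != 1:
        raise ValueError(f"expected chains of one replicate, got {replicates}")
    frames = []
    for chain in chains:
        path, _ = viterbi_decode(chain, params)
        post = posterior_heterozygous(chain, params)
        frame = pd.DataFrame(
            {
                "replicate": chain.replicate_id,
                "chrom": chain.chromosome,
                "gene_id": chain.gene_ids,
                "order_index": np.arange(len(chain)),
                "observed_state": chain.states,
                "decoded_state": np.array(STATE_NAMES, dtype=object)[path],
                "posterior_het": post,
            }
        )
        if chain.starts is not None:
            frame.insert(4, "start", chain.starts)
        if chain.r_mean is not None:
            frame.insert(5 if chain.starts is not None else 4, "r_mean", chain.r_mean)
        frames.append(frame)
    genes = pd.concat(frames, ignore_index=True)
    segments = (
        segments_from_states(genes) if "start" in genes.columns else pd.DataFrame()
    )
    return GenotypeSegmentation(
        replicate_id=replicates.pop(), genes=genes, segments=segments
    )


class GenotypeHMM:
    """Categorical genotype HMM over gene-ordered chromosome chains.

    Parameters
    ----------
    chains
        Observation chains (one per replicate and chromosome).
    init
        Starting parameters; defaults to the biological initialization
        (pi 0.5/0.5, switch rate 0.002, asymmetric emissions).
    tol, max_iter, pseudocount
        EM convergence threshold on the total log-likelihood, iteration cap,
        and the regularizing count added to every transition/emission cell.
    """

    def __init__(
        self,
        chains: list[ObservedChain],
        init: HMMParams | None = None,
        tol: float = 1e-4,
        max_iter: int = 500,
        pseudocount: float = 1e-6,
    ) -> None:
        if not chains:
            raise ValueError("chains must be nonempty")
        self.chains = list(chains)
        self.init = init if init is not None else _hmm.init_params()
        self.tol = tol
        self.max_iter = max_iter
        self.pseudocount = pseudocount

    @classmethod
    def from_counts(
        cls,
        pairs: AlleleCountPair | list[AlleleCountPair],
        annot: pd.DataFrame,
        min_cells: int = 1,
        **kwargs,
    ) -> "GenotypeHMM":
        """Build the model from one or more replicates' allele count matrices."""
        if isinstance(pairs, AlleleCountPair):
            pairs = [pairs]
        chains: list[ObservedChain] = []
        for pair in pairs:
            chains.extend(chains_from_counts(pair, annot, min_cells=min_cells))
        return cls(chains, **kwargs)

    def fit(
        self, chains_per_replicate: int | None = None, seed: int = 0
    ) -> "GenotypeHMMResults":
        """Baum-Welch on chromosomes pooled across replicates.

        ``chains_per_replicate`` randomly subsamples that many chromosomes
        from each replicate for training (the paper-style training design);
        decoding afterwards always covers all chains.
        """
        training = self.chains
        if chains_per_replicate is not None:
            training = sample_training_chains(
                self.chains, chains_per_replicate, seed=seed
            )
        result = baum_welch_fit(
            training,
            init=self.init,
            tol=self.tol,
            max_iter=self.max_iter,
            pseudocount=self.pseudocount,
            seed=seed,
        )
        return GenotypeHMMResults(self, result)


class GenotypeHMMResults:
    """Fitted genotype HMM: estimates, diagnostics, decoding and simulation."""

    def __init__(self, model: GenotypeHMM, fit_result: FitResult) -> None:
        self.model = model
        self.fit_result = fit_result

    @property
    def params(self) -> HMMParams:
        return self.fit_result.params

    @property
    def log_likelihood(self) -> float:
        return self.fit_result.log_likelihood

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def decode(
        self, chains: list[ObservedChain] | None = None
    ) -> dict[str, GenotypeSegmentation]:
        """Segmentation maps per replicate (Viterbi + posterior confidence)."""
        chains = self.model.chains if chains is None else chains
        by_rep: dict[str, list[ObservedChain]] = {}
        for chain in chains:
            by_rep.setdefault(chain.replicate_id, []).append(chain)
        return {
            rep: decode_chains(rep_chains, self.params)
            for rep, rep_chains in sorted(by_rep.items())
        }

    def posterior(self, chain: ObservedChain) -> np.ndarray:
        return posterior_heterozygous(chain, self.params)

    def simulate(
        self,
        n_chains: int | None = None,
        lengths: int | list[int] | None = None,
        seed: int = 0,
    ) -> tuple[list[ObservedChain], list[np.ndarray]]:
        """Sample chains from the fitted model; defaults mirror the data."""
        if n_chains is None:
            n_chains = len(self.model.chains)
            lengths = [len(c) for c in self.model.chains]
        if lengths is None:
            raise ValueError("lengths required when n_chains is given")
        return simulate_chains(self.params, n_chains, lengths, seed=seed)

    def ppc(
        self, chains: list[ObservedChain] | None = None, seed: int = 0
    ) -> PPCReport:
        """Posterior predictive check against the training (or given) chains."""
        chains = self.model.chains if chains is None else chains
        return run_ppc(chains, self.params, seed=seed)

    def save(self, path) -> None:
        self.fit_result.save(path)

    def summary(self) -> str:
        """Human-readable estimation summary (statsmodels-style text table)."""
        p = self.params
        lines = [
            "Genotype HMM (2 hidden states, 6 observed symbols)",
            "=" * 58,
            f"chains: {len(self.model.chains):>5}    "
            f"symbols: {sum(len(c) for c in self.model.chains):>8}",
            f"iterations: {self.fit_result.n_iterations:>4}    "
            f"converged: {self.converged}    "
            f"log-likelihood: {self.log_likelihood:.2f}",
            "-" * 58,
            "initial probabilities (pi)",
            f"  {STATE_NAMES[0]:>6}: {p.pi[0]:.4f}    {STATE_NAMES[1]:>6}: {p.pi[1]:.4f}",
            "transition matrix (A)",
        ]
        for i, name in enumerate(STATE_NAMES):
            row = "  ".join(f"{v:.4f}" for v in p.A[i])
            lines.append(f"  {name:>6} -> {row}")
        lines.append("emission matrix (B) over symbols 0..5")
        header = "  ".join(f"s{k:<5}" for k in range(N_SYMBOLS))
        lines.append(f"  {'':>6}    {header}")
        for i, name in enumerate(STATE_NAMES):
            row = "  ".join(f"{v:.4f}" for v in p.B[i])
            lines.append(f"  {name:>6}    {row}")
        lines.append("=" * 58)
        return "\n".join(lines)
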