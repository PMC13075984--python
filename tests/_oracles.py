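"""Independent brute-force oracles used to verify the fast implementations.

Everything here deliberately favors clarity over speed: exhaustive hidden-path
enumeration for likelihoods, Viterbi scores and posteriors (feasible up to
chain length ~12), and flat Python loops for summary statistics and
run-length encoding.  None of it shares code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_path_weights(states, params):
    """(path, probability) for every hidden path of a short chain."""
    L = len(states)
    out = []
    for path in itertools.product(range(2), repeat=L):
        p = params.pi[path[0]] * params.B[path[0], states[0]]
        for t in range(1, L):
            p *= params.A[path[t - 1], path[t]] * params.B[path[t], states[t]]
        out.append((path, p))
    return out


def enumerate_log_likelihood(states, params) -> float:
    total = sum(p for _, p in enumerate_path_weights(states, params))
    return math.log(total) if total > 0 else float("-inf")


def enumerate_viterbi_score(states, params) -> float:
    best = max(p for _, p in enumerate_path_weights(states, params))
    return math.log(best) if best > 0 else float("-inf")


def enumerate_posterior_het(states, params) -> np.ndarray:
    weights = enumerate_path_weights(states, params)
    total = sum(p for _, p in weights)
    L = len(states)
    post = np.zeros(L)
    for path, p in weights:
        for t in range(L):
            if path[t] == 1:
                post[t] += p
    return post / total


def loop_summary_stats(chains):
    """Mean, population SD and adjacent-pair switch rate via flat loops."""
    values = []
    switches = 0
    pairs = 0
    for chain in chains:
        symbols = list(chain.states)
        values.extend(symbols)
        for a, b in zip(symbols, symbols[1:]):
            pairs += 1
            if a != b:
                switches += 1
    mean = sum(values) / len(values)
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))
    rate = switches / pairs if pairs else float("nan")
    return mean, sd, rate


def loop_run_lengths(values):
    """(value, run_length) pairs of a sequence, plain iteration."""
    runs = []
    for v in values:
        if runs and runs[-1][0] == v:
            runs[-1][1] += 1
        else:
            runs.append([v, 1])
    return [(v, n) for v, n in runs]


def loop_gene_mean_ratios(g1_dense, g2_dense):
    """Per-gene mean allelic ratio over informative cells, cell by cell."""
    n_genes, n_cells = g1_dense.shape
    means, counts = [], []
    for g in range(n_genes):
        ratios = []
        for c in range(n_cells):
            total = g1_dense[g, c] + g2_dense[g, c]
            if total > 0:
                ratios.append(g1_dense[g, c] / total)
        counts.append(len(ratios))
        means.append(sum(ratios) / len(ratios) if ratios else float("nan"))
    return np.array(means), np.array(counts)


def random_params(rng):
    """A random valid parameter set (Dirichlet rows, strictly positive)."""
    from scgeno.hmm import HMMParams

    return HMMParams(
        pi=rng.dirichlet(np.ones(2) * 2),
        A=np.stack([rng.dirichlet(np.ones(2) * 2) for _ in range(2)]),
        B=np.stack([rng.dirichlet(np.ones(6)) for _ in range(2)]),
    )
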