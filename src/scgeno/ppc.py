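"""Posterior predictive checks for the fitted genotype HMM.

Model criticism without ground truth: simulate one synthetic chain per real
chain (length-matched) from the fitted parameters and compare summary
statistics of the pooled observed symbols — mean, standard deviation, and the
per-adjacent-pair symbol switch rate — plus two-sample Kolmogorov-Smirnov and
Mann-Whitney U tests on the pooled symbol distributions.  Agreement in the
summaries indicates the model captures the chromosome segmentation structure;
residual distributional differences typically reflect scRNA-seq noise the
six-symbol emission model does not represent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .discretize import ObservedChain
from .hmm import HMMParams, simulate_chains

__all__ = ["PPCReport", "summary_stats", "run_ppc"]


@dataclass
class PPCReport:
    """Paired real-vs-simulated summary statistics and two-sample tests."""

    real_mean: float
    sim_mean: float
    real_sd: float
    sim_sd: float
    real_transition_rate: float
    sim_transition_rate: float
    ks_statistic: float
    ks_pvalue: float
    mwu_statistic: float
    mwu_pvalue: float
    n_real: int
    n_sim: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([asdict(self)]).to_csv(path, sep="\t", index=False)


def summary_stats(chains: list[ObservedChain]) -> tuple[float, float, float]:
    """Pooled symbol mean, population SD, and adjacent-pair transition rate.

    The transition rate is the fraction of within-chain adjacent gene pairs
    whose observed symbols differ; pairs never span chain boundaries.  With
    no adjacent pair at all (all chains of length 1) the rate is NaN.
    """
    if not chains:
        raise ValueError("chains must be nonempty")
    pooled = np.concatenate([c.states for c in chains])
    mean = float(pooled.mean())
    sd = float(pooled.std())  # population formula
    n_pairs = sum(len(c) - 1 for c in chains)
    if n_pairs == 0:
        return mean, sd, float("nan")
    n_switches = sum(
        int((c.states[1:] != c.states[:-1]).sum()) for c in chains if len(c) > 1
    )
    return mean, sd, n_switches / n_pairs


def run_ppc(
    real_chains: list[ObservedChain], params: HMMParams, seed: int
) -> PPCReport:
    """Simulate length-matched chains from ``params`` and compare with the data."""
    if not real_chains:
        raise ValueError("real_chains must be nonempty")
    params.validate()
    sim_chains, _ = simulate_chains(
        params,
        n_chains=len(real_chains),
        lengths=[len(c) for c in real_chains],
        seed=seed,
    )
    real_mean, real_sd, real_rate = summary_stats(real_chains)
    sim_mean, sim_sd, sim_rate = summary_stats(sim_chains)
    real_pool = np.concatenate([c.states for c in real_chains])
    sim_pool = np.concatenate([c.states for c in sim_chains])
    ks = stats.ks_2samp(real_pool, sim_pool, method="asymp")
    mwu = stats.mannwhitneyu(real_pool, sim_pool, method="asymptotic")
    return PPCReport(
        real_mean=real_mean,
        sim_mean=sim_mean,
        real_sd=real_sd,
        sim_sd=sim_sd,
        real_transition_rate=real_rate,
        sim_transition_rate=sim_rate,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        mwu_statistic=float(mwu.statistic),
        mwu_pvalue=float(mwu.pvalue),
        n_real=int(real_pool.size),
        n_sim=int(sim_pool.size),
    )
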