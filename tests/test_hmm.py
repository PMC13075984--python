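"""HMM core: initialization, likelihoods, EM, decoding, simulation, segments."""

import numpy as np
import pandas as pd
import pytest

import scgeno as sg
from scgeno.hmm import (
    HET,
    HOM,
    DecodingError,
    TrainingError,
    sample_training_chains,
)

from ._oracles import (
    enumerate_log_likelihood,
    enumerate_posterior_het,
    enumerate_viterbi_score,
    loop_run_lengths,
    random_params,
)
from .conftest import make_chain


class TestInitialization:
    def test_biological_priors(self):
        params = sg.init_params()
        np.testing.assert_array_equal(params.pi, [0.5, 0.5])
        np.testing.assert_array_equal(
            params.A, [[0.998, 0.002], [0.002, 0.998]]
        )

    def test_emission_rows_are_distributions(self):
        params = sg.init_params()
        np.testing.assert_allclose(params.B.sum(axis=1), 1.0, atol=1e-12)
        assert params.B.min() > 0

    def test_emission_asymmetry_orients_states(self):
        exp = sg.init_params().expected_symbols()
        assert exp[HOM] > exp[HET]

    @pytest.mark.parametrize(
        "crossovers, genes, rate",
        [(2, 1000, 0.002), (0, 1000, 0.0), (3, 1500, 0.002)],
    )
    def test_expected_transition_rate(self, crossovers, genes, rate):
        assert sg.expected_transition_rate(crossovers, genes) == rate

    def test_transition_rate_rejects_nonpositive_genes(self):
        with pytest.raises(ValueError):
            sg.expected_transition_rate(2, 0)


class TestForwardLikelihood:
    def test_length_one_closed_form(self):
        rng = np.random.default_rng(1)
        params = random_params(rng)
        for symbol in range(6):
            chain = make_chain([symbol])
            expected = np.log(params.pi @ params.B[:, symbol])
            assert sg.forward_log_likelihood(chain, params) == pytest.approx(expected)

    def test_matches_exhaustive_enumeration(self):
        """100 random (params, chain) instances, lengths up to 12."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            params = random_params(rng)
            L = int(rng.integers(1, 13))
            chain = make_chain(rng.integers(0, 6, size=L))
            fast = sg.forward_log_likelihood(chain, params)
            slow = enumerate_log_likelihood(chain.states, params)
            assert fast == pytest.approx(slow, rel=1e-9)

    def test_uniform_emissions_ignore_symbols(self):
        params = sg.HMMParams(
            pi=[0.3, 0.7],
            A=[[0.9, 0.1], [0.4, 0.6]],
            B=np.full((2, 6), 1 / 6),
        )
        rng = np.random.default_rng(3)
        lls = {
            sg.forward_log_likelihood(make_chain(rng.integers(0, 6, 8)), params)
            for _ in range(10)
        }
        assert len({round(v, 12) for v in lls}) == 1

    def test_impossible_observation_gives_minus_inf(self):
        params = sg.HMMParams(
            pi=[0.5, 0.5],
            A=[[0.9, 0.1], [0.1, 0.9]],
            B=[[1, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0]],
        )
        assert sg.forward_log_likelihood(make_chain([0, 3]), params) == -np.inf


class TestViterbi:
    def test_score_matches_exhaustive_max(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            params = random_params(rng)
            L = int(rng.integers(1, 13))
            chain = make_chain(rng.integers(0, 6, size=L))
            _, score = sg.viterbi_decode(chain, params)
            assert score == pytest.approx(
                enumerate_viterbi_score(chain.states, params), rel=1e-9
            )

    def test_high_symbols_decode_homozygous(self):
        chain = make_chain([5] * 30)
        path, _ = sg.viterbi_decode(chain, sg.init_params())
        assert (path == HOM).all()

    def test_single_switch_at_symbol_boundary(self, well_separated_params):
        chain = make_chain([5] * 10 + [0] * 10)
        path, _ = sg.viterbi_decode(chain, well_separated_params)
        assert loop_run_lengths(path.tolist()) == [(HOM, 10), (HET, 10)]

    def test_ties_prefer_staying(self):
        """With symmetric parameters every path ties; no switch should appear."""
        params = sg.HMMParams(
            pi=[0.5, 0.5],
            A=[[0.5, 0.5], [0.5, 0.5]],
            B=np.full((2, 6), 1 / 6),
        )
        path, _ = sg.viterbi_decode(make_chain([0, 5, 3, 2]), params)
        assert len(set(path.tolist())) == 1
        assert path[0] == HET  # first-position ties resolve heterozygous

    def test_dead_symbol_raises_naming_gene(self):
        params = sg.HMMParams(
            pi=[0.5, 0.5],
            A=[[0.9, 0.1], [0.1, 0.9]],
            B=[[1, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0]],
        )
        with pytest.raises(DecodingError, match="chr1_g1"):
            sg.viterbi_decode(make_chain([0, 3, 0]), params)


class TestPosterior:
    def test_length_one_closed_form(self):
        rng = np.random.default_rng(5)
        params = random_params(rng)
        chain = make_chain([4])
        weights = params.pi * params.B[:, 4]
        expected = weights[HET] / weights.sum()
        assert sg.posterior_heterozygous(chain, params)[0] == pytest.approx(expected)

    def test_matches_exhaustive_marginals(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            params = random_params(rng)
            chain = make_chain(rng.integers(0, 6, size=10))
            fast = sg.posterior_heterozygous(chain, params)
            slow = enumerate_posterior_het(chain.states, params)
            np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)

    def test_symmetric_setup_gives_half(self):
        params = sg.HMMParams(
            pi=[0.5, 0.5],
            A=[[0.8, 0.2], [0.2, 0.8]],
            B=np.full((2, 6), 1 / 6),
        )
        post = sg.posterior_heterozygous(make_chain([1, 2, 3]), params)
        np.testing.assert_allclose(post, 0.5, atol=1e-12)


class TestBaumWelch:
    def test_loglik_trace_nondecreasing(self, well_separated_params):
        chains, _ = sg.simulate_chains(well_separated_params, 20, 300, seed=8)
        fit = sg.baum_welch_fit(chains)
        assert np.all(np.diff(fit.log_likelihood_trace) >= -1e-8)
        assert fit.n_iterations == len(fit.log_likelihood_trace)

    def test_stochasticity_preserved(self, well_separated_params):
        chains, _ = sg.simulate_chains(well_separated_params, 10, 200, seed=9)
        params = sg.baum_welch_fit(chains).params
        assert params.pi.sum() == pytest.approx(1, abs=1e-9)
        np.testing.assert_allclose(params.A.sum(axis=1), 1, atol=1e-9)
        np.testing.assert_allclose(params.B.sum(axis=1), 1, atol=1e-9)

    def test_parameter_recovery(self, well_separated_params):
        """200 chains x 1000 genes from known params; A and B recovered."""
        chains, _ = sg.simulate_chains(well_separated_params, 200, 1000, seed=10)
        fit = sg.baum_welch_fit(chains, seed=10)
        for i in range(2):
            j = 1 - i
            assert fit.params.A[i, j] == pytest.approx(0.002, rel=0.5)
        tv = 0.5 * np.abs(fit.params.B - well_separated_params.B).sum(axis=1)
        assert tv.max() < 0.05

    def test_recovery_error_shrinks_with_more_chains(self, well_separated_params):
        """Mean parameter error (averaged over seeds) drops as chains grow."""
        errors = []
        for n_chains in (5, 100):
            per_seed = []
            for seed in range(11, 16):
                chains, _ = sg.simulate_chains(
                    well_separated_params, n_chains, 500, seed=seed
                )
                fit = sg.baum_welch_fit(chains, seed=seed)
                per_seed.append(
                    np.abs(
                        fit.params.flatten() - well_separated_params.flatten()
                    ).mean()
                )
            errors.append(np.mean(per_seed))
        assert errors[1] < errors[0]

    def test_single_support_concentrates_emissions(self):
        """A chain emitting only symbols {4, 5}: EM pins emissions there."""
        chain = make_chain([5, 4, 5, 5, 4, 5, 5, 5, 4, 5] * 5)
        fit = sg.baum_welch_fit([chain], tol=1e-10, max_iter=2000)
        assert fit.params.B[:, 4:].sum(axis=1).min() > 0.999

    def test_all_singleton_chains_rejected(self):
        with pytest.raises(TrainingError):
            sg.baum_welch_fit([make_chain([3]), make_chain([1])])

    def test_label_normalization_invariant_to_permutation(self, well_separated_params):
        chains, _ = sg.simulate_chains(well_separated_params, 15, 200, seed=12)
        swapped = sg.HMMParams(
            pi=well_separated_params.pi[::-1].copy(),
            A=well_separated_params.A[::-1, ::-1].copy(),
            B=well_separated_params.B[::-1].copy(),
        )
        fit_a = sg.baum_welch_fit(chains, init=well_separated_params)
        fit_b = sg.baum_welch_fit(chains, init=swapped)
        np.testing.assert_allclose(fit_a.params.B, fit_b.params.B, atol=1e-6)
        path_a, _ = sg.viterbi_decode(chains[0], fit_a.params)
        path_b, _ = sg.viterbi_decode(chains[0], fit_b.params)
        np.testing.assert_array_equal(path_a, path_b)


class TestSampling:
    def _chains(self):
        return [
            make_chain([0, 1], replicate=f"rep{r}", chrom=f"chr{c}")
            for r in range(5)
            for c in range(19)
        ]

    def test_counts_per_replicate(self):
        subset = sample_training_chains(self._chains(), per_replicate=4, seed=0)
        assert len(subset) == 20
        per_rep = pd.Series([c.replicate_id for c in subset]).value_counts()
        assert (per_rep == 4).all()

    def test_clamped_when_fewer_available(self):
        subset = sample_training_chains(self._chains(), per_replicate=50, seed=0)
        assert len(subset) == 95

    def test_deterministic_under_seed(self):
        chains = self._chains()
        ids = lambda sub: [(c.replicate_id, c.chromosome) for c in sub]
        assert ids(sample_training_chains(chains, 3, seed=7)) == ids(
            sample_training_chains(chains, 3, seed=7)
        )


class TestSimulation:
    def test_identity_transitions_freeze_hidden_state(self):
        params = sg.HMMParams(
            pi=[0.5, 0.5], A=np.eye(2), B=sg.init_params().B
        )
        _, hidden = sg.simulate_chains(params, 20, 50, seed=13)
        for h in hidden:
            assert len(set(h.tolist())) == 1

    def test_switch_frequency_matches_generating_rate(self):
        """1e5 adjacencies at rate 0.002: within 3 binomial standard errors."""
        params = sg.init_params()
        _, hidden = sg.simulate_chains(params, 100, 1001, seed=14)
        switches = sum(int((h[1:] != h[:-1]).sum()) for h in hidden)
        n = 100 * 1000
        se = np.sqrt(0.002 * 0.998 / n)
        assert abs(switches / n - 0.002) < 3 * se

    def test_deterministic_under_seed(self):
        params = sg.init_params()
        a, ha = sg.simulate_chains(params, 5, 30, seed=15)
        b, hb = sg.simulate_chains(params, 5, 30, seed=15)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.states, cb.states)
        for x, y in zip(ha, hb):
            np.testing.assert_array_equal(x, y)

    def test_simulate_then_decode_accuracy(self, well_separated_params):
        """Viterbi recovers >= 99% of hidden states under rare switching."""
        chains, hidden = sg.simulate_chains(well_separated_params, 30, 500, seed=16)
        hits = total = 0
        for chain, truth in zip(chains, hidden):
            path, _ = sg.viterbi_decode(chain, well_separated_params)
            hits += int((path == truth).sum())
            total += len(truth)
        assert hits / total >= 0.99


class TestSegments:
    def _genes(self, states, starts=None):
        n = len(states)
        starts = starts if starts is not None else 1000 * np.arange(1, n + 1)
        return pd.DataFrame(
            {
                "replicate": "r1",
                "chrom": "chr1",
                "gene_id": [f"g{i}" for i in range(n)],
                "order_index": np.arange(n),
                "start": starts,
                "decoded_state": states,
            }
        )

    def test_constant_states_merge_to_one_segment(self):
        segments = sg.segments_from_states(self._genes(["G1G2"] * 3))
        assert len(segments) == 1
        assert segments.loc[0, "n_genes"] == 3

    def test_run_length_counts(self):
        segments = sg.segments_from_states(
            self._genes(["G1G2", "G1G2", "G1G1", "G1G1", "G1G2"])
        )
        assert segments["n_genes"].tolist() == [2, 2, 1]
        assert segments["state"].tolist() == ["G1G2", "G1G1", "G1G2"]

    def test_matches_run_length_oracle_and_spans(self):
        rng = np.random.default_rng(17)
        states = np.array(["G1G1", "G1G2"])[rng.integers(0, 2, 1000)]
        segments = sg.segments_from_states(self._genes(states))
        oracle = loop_run_lengths(states.tolist())
        assert list(zip(segments["state"], segments["n_genes"])) == oracle
        assert segments["n_genes"].sum() == 1000
        # consecutive segments alternate and spans nest within the chromosome
        assert (segments["state"].iloc[1:].to_numpy()
                != segments["state"].iloc[:-1].to_numpy()).all()
        assert (segments["start_bp"] <= segments["end_bp"]).all()


class TestSerialization:
    def test_model_json_roundtrip(self, tmp_path, well_separated_params):
        chains, _ = sg.simulate_chains(well_separated_params, 5, 100, seed=18)
        fit = sg.baum_welch_fit(chains, seed=18)
        path = tmp_path / "model.json"
        fit.save(path)
        loaded = sg.FitResult.load(path)
        np.testing.assert_allclose(loaded.params.pi, fit.params.pi)
        np.testing.assert_allclose(loaded.params.A, fit.params.A)
        np.testing.assert_allclose(loaded.params.B, fit.params.B)
        assert loaded.seed == 18
        assert loaded.training_chain_ids == fit.training_chain_ids
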