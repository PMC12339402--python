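"""HMM fitting, decoding and consensus against independent oracles.

The forward log-likelihood and Viterbi oracles enumerate every state path
explicitly (K^T paths), so they share no code with the fitted models'
forward/Viterbi recursions.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from ladkit.core import DomainSet, Genome, GenomicInterval, BinnedSignalTrack
from ladkit.hmm import (
    HMMModel,
    consensus_domains,
    decode,
    fit_hmm,
    information_criteria,
    log_likelihood,
    select_model,
)
from ladkit.simulate import simulate_gaussian_sequences

from conftest import random_disjoint_intervals


def brute_force_log_likelihood(model: HMMModel, x: np.ndarray) -> float:
    """Sum over all K^T state paths of P(path) * P(obs | path)."""
    K, T = model.K, len(x)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.startprob[path[0]] * norm.pdf(x[0], model.means[path[0]],
                                                model.sds[path[0]])
        for t in range(1, T):
            p *= model.transmat[path[t - 1], path[t]] * norm.pdf(
                x[t], model.means[path[t]], model.sds[path[t]])
        total += p
    return np.log(total)


def brute_force_viterbi(model: HMMModel, x: np.ndarray):
    """Argmax over all paths; iteration order breaks exact ties toward the
    lexicographically smallest (lower-state-first) path."""
    best, best_lp = None, -np.inf
    for path in itertools.product(range(model.K), repeat=len(x)):
        lp = np.log(model.startprob[path[0]]) + norm.logpdf(
            x[0], model.means[path[0]], model.sds[path[0]])
        for t in range(1, len(x)):
            lp += np.log(model.transmat[path[t - 1], path[t]]) + norm.logpdf(
                x[t], model.means[path[t]], model.sds[path[t]])
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


def random_model(rng, K=2):
    means = np.sort(rng.normal(0, 3, K))
    sds = rng.uniform(0.5, 2.0, K)
    A = rng.dirichlet(np.ones(K) * 2, size=K)
    pi = rng.dirichlet(np.ones(K))
    return HMMModel(K=K, means=means, sds=sds, transmat=A, startprob=pi)


class TestForwardOracle:
    def test_k1_closed_form(self):
        m = HMMModel(K=1, means=[1.5], sds=[0.7], transmat=[[1.0]],
                     startprob=[1.0])
        x = np.array([0.3, 1.9, 2.2])
        expected = norm.logpdf(x, 1.5, 0.7).sum()
        assert log_likelihood(m, [x]) == pytest.approx(expected, abs=1e-10)

    def test_single_observation_k2_closed_form(self):
        m = HMMModel(K=2, means=[0.0, 2.0], sds=[1.0, 0.5],
                     transmat=[[0.9, 0.1], [0.2, 0.8]], startprob=[0.6, 0.4])
        x = 1.1
        expected = np.log(0.6 * norm.pdf(x, 0, 1) + 0.4 * norm.pdf(x, 2, 0.5))
        assert log_likelihood(m, [np.array([x])]) == pytest.approx(
            expected, abs=1e-10)

    @pytest.mark.parametrize("K,T", [(2, 6), (2, 8), (3, 5)])
    def test_matches_exhaustive_enumeration(self, K, T):
        rng = np.random.default_rng(100 + K * T)
        for _ in range(10):
            m = random_model(rng, K)
            x = rng.normal(0, 2.5, T)
            assert log_likelihood(m, [x]) == pytest.approx(
                brute_force_log_likelihood(m, x), abs=1e-8)

    def test_sums_over_independent_sequences(self):
        rng = np.random.default_rng(7)
        m = random_model(rng)
        xs = [rng.normal(0, 2, 5), rng.normal(0, 2, 4)]
        assert log_likelihood(m, xs) == pytest.approx(
            log_likelihood(m, [xs[0]]) + log_likelihood(m, [xs[1]]), abs=1e-10)

    def test_empty_sequence_set_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            log_likelihood(random_model(rng), [])


class TestViterbiOracle:
    @pytest.mark.parametrize("T", [4, 8, 12])
    def test_matches_exhaustive_argmax(self, T):
        rng = np.random.default_rng(200 + T)
        for _ in range(10):
            m = random_model(rng, 2)
            x = rng.normal(0, 2.5, T)
            expected, _ = brute_force_viterbi(m, x)
            got = m.to_hmmlearn().predict(x.reshape(-1, 1))
            assert np.array_equal(got, expected)


class TestFit:
    def test_k1_recovers_sample_moments(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5.0, 1.3, 4_000)
        m = fit_hmm([x], K=1, seed=0)
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert m.sds[0] == pytest.approx(x.std(), abs=1e-6)

    def test_two_state_parameter_recovery(self):
        # d' = 6, 5,000 bins, stay-probabilities 0.99
        obs, _ = simulate_gaussian_sequences(
            5_000, means=(0.0, 6.0), sds=(1.0, 1.0),
            stay_probs=(0.99, 0.99), seed=21)
        m = fit_hmm(obs, K=2, seed=0)
        assert m.means[0] == pytest.approx(0.0, abs=0.05 * 6)
        assert m.means[1] == pytest.approx(6.0, rel=0.05)
        assert m.transmat[0, 0] == pytest.approx(0.99, abs=0.01)
        assert m.transmat[1, 1] == pytest.approx(0.99, abs=0.01)

    def test_lnl_history_monotone(self):
        obs, _ = simulate_gaussian_sequences(2_000, seed=5)
        m = fit_hmm(obs, K=2, seed=0)
        history = np.array(m.meta["lnl_history"])
        assert len(history) >= 2
        assert np.all(np.diff(history) >= -1e-6 * np.abs(history[-1]))

    def test_states_sorted_ascending_mean(self):
        obs, _ = simulate_gaussian_sequences(2_000, seed=6)
        for K in (2, 3):
            m = fit_hmm(obs, K=K, seed=1)
            assert np.all(np.diff(m.means) >= 0)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_hmm([np.array([1.0, 1.0, 1.0, 1.0])], K=2, seed=0)


class TestModelSelection:
    def test_information_criteria_closed_form(self):
        aic, bic = information_criteria(0.0, 5, 100)
        assert aic == 10
        assert bic == pytest.approx(5 * np.log(100), abs=1e-9)
        assert bic == pytest.approx(23.0259, abs=1e-3)

    @pytest.mark.parametrize("K,p", [(2, 7), (3, 14), (4, 23), (5, 34)])
    def test_parameter_count(self, K, p):
        rng = np.random.default_rng(0)
        m = random_model(rng, K)
        assert m.n_parameters() == p

    def test_bic_selects_two_states_on_two_state_data(self):
        obs, _ = simulate_gaussian_sequences(
            4_000, means=(0.0, 3.0), sds=(1.0, 1.0), seed=31)
        report = select_model(obs, (2, 3), seed=0)
        assert report.best_bic == 2
        df = report.to_frame()
        assert set(df.columns) >= {"K", "aic", "bic", "log_likelihood"}


def make_track(values, genome=None, mask=None, bin_size=10_000):
    genome = genome or Genome({"chr1": len(values) * bin_size})
    return BinnedSignalTrack(genome, bin_size, {"chr1": np.asarray(values)},
                             {"chr1": mask} if mask is not None else None)


class TestDecode:
    def test_all_high_signal_single_domain(self):
        m = HMMModel(K=2, means=[0.0, 10.0], sds=[1.0, 1.0],
                     transmat=[[0.99, 0.01], [0.01, 0.99]],
                     startprob=[0.5, 0.5])
        t = make_track(np.full(20, 10.0))
        d = decode(m, t, mark="H3K9me2")
        assert [(iv.start, iv.end) for iv in d] == [(0, 200_000)]

    def test_invalid_bins_break_domains(self):
        m = HMMModel(K=2, means=[0.0, 10.0], sds=[1.0, 1.0],
                     transmat=[[0.99, 0.01], [0.01, 0.99]],
                     startprob=[0.5, 0.5])
        mask = np.ones(20, dtype=bool)
        mask[10] = False
        t = make_track(np.full(20, 10.0), mask=mask)
        d = decode(m, t)
        assert [(iv.start, iv.end) for iv in d] == [
            (0, 100_000), (110_000, 200_000)]

    def test_all_bins_invalid_empty_domains(self):
        m = HMMModel(K=2, means=[0.0, 10.0], sds=[1.0, 1.0],
                     transmat=[[0.9, 0.1], [0.1, 0.9]], startprob=[0.5, 0.5])
        t = make_track(np.full(5, np.nan), mask=np.zeros(5, dtype=bool))
        assert len(decode(m, t)) == 0

    def test_final_partial_bin_clips_to_chromosome(self):
        g = Genome({"chr1": 45_000})
        m = HMMModel(K=2, means=[0.0, 10.0], sds=[1.0, 1.0],
                     transmat=[[0.9, 0.1], [0.1, 0.9]], startprob=[0.5, 0.5])
        t = BinnedSignalTrack(g, 10_000, {"chr1": np.full(5, 10.0)})
        d = decode(m, t)
        assert [(iv.start, iv.end) for iv in d] == [(0, 45_000)]

    def test_decoding_recovers_true_domains(self):
        obs, paths = simulate_gaussian_sequences(
            5_000, means=(0.0, 6.0), sds=(1.0, 1.0),
            stay_probs=(0.99, 0.99), seed=21)
        m = fit_hmm(obs, K=2, seed=0)
        states = m.to_hmmlearn().predict(obs[0].reshape(-1, 1))
        agree = (states == paths[0]).mean()
        assert agree >= 0.97


class TestConsensus:
    def test_identical_replicates_identity(self, rng, small_genome):
        ivs = random_disjoint_intervals(rng, small_genome)
        reps = [DomainSet(mark="m", sample=f"r{i}", intervals=list(ivs))
                for i in range(3)]
        cons = consensus_domains(reps)
        assert [(iv.chrom, iv.start, iv.end) for iv in cons] == [
            (iv.chrom, iv.start, iv.end) for iv in ivs]

    def test_pairwise_intersection(self):
        a = DomainSet(mark="m", intervals=[GenomicInterval("chr1", 0, 100)])
        b = DomainSet(mark="m", intervals=[GenomicInterval("chr1", 0, 50)])
        cons = consensus_domains([a, b])
        assert [(iv.start, iv.end) for iv in cons] == [(0, 50)]

    def test_matches_per_base_and_oracle(self, rng, small_genome):
        for _ in range(5):
            reps = [
                DomainSet(mark="m",
                          intervals=random_disjoint_intervals(rng, small_genome))
                for _ in range(3)
            ]
            cons = consensus_domains(reps)
            for chrom in small_genome:
                L = small_genome[chrom]
                cover = np.ones(L, dtype=bool)
                for rep in reps:
                    c = np.zeros(L, dtype=bool)
                    for iv in rep.intervals:
                        if iv.chrom == chrom:
                            c[iv.start:iv.end] = True
                    cover &= c
                got = np.zeros(L, dtype=bool)
                for iv in cons:
                    if iv.chrom == chrom:
                        got[iv.start:iv.end] = True
                assert np.array_equal(got, cover)

    def test_associative_commutative_and_contained(self, rng, small_genome):
        reps = [
            DomainSet(mark="m",
                      intervals=random_disjoint_intervals(rng, small_genome))
            for _ in range(3)
        ]
        c1 = consensus_domains(reps)
        c2 = consensus_domains([reps[2], reps[0], reps[1]])
        c3 = consensus_domains([consensus_domains(reps[:2]), reps[2]])
        coords = lambda d: [(iv.chrom, iv.start, iv.end) for iv in d]
        assert coords(c1) == coords(c2) == coords(c3)
        from ladkit.core import intersect_intervals, union_bp
        for rep in reps:
            inter = intersect_intervals(c1.intervals, rep.intervals)
            assert sum(len(iv) for iv in inter) == c1.total_bp()

    def test_mixed_marks_rejected(self):
        a = DomainSet(mark="H3K9me2", intervals=[GenomicInterval("chr1", 0, 10)])
        b = DomainSet(mark="LAP2B", intervals=[GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError, match="mixed"):
            consensus_domains([a, b])


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        m = random_model(rng, 2)
        m.to_json(tmp_path / "m.json")
        back = HMMModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.means, m.means)
        np.testing.assert_allclose(back.transmat, m.transmat)
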