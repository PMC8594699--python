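from __future__ import annotations

import numpy as np
import pytest

from _oracles import brute_force_mixture_ml
from amplimeth.estimate import (
    ErrorModel,
    apply_cutoff,
    estimate_distribution,
)
from amplimeth.patterns import PatternCountTable


def _table(counts, amplicon="a", sample="s"):
    return PatternCountTable(amplicon, sample, counts, n_called=sum(counts.values()))


def _simulate_counts(mixture, n, error_model, seed):
    """Pattern-level multinomial draw with independent per-site flips."""
    rng = np.random.default_rng(seed)
    pats = [p for p, _ in mixture]
    freqs = [f for _, f in mixture]
    e01 = error_model.p_false_methylated
    e10 = error_model.p_false_unmethylated
    idx = rng.choice(len(pats), n, p=freqs)
    bits = np.array([[c == "1" for c in p] for p in pats])[idx]
    u = rng.random(bits.shape)
    obs = np.where(bits, u >= e10, u < e01)
    counts: dict[str, int] = {}
    for row in obs:
        key = "".join("1" if b else "0" for b in row)
        counts[key] = counts.get(key, 0) + 1
    return counts


class TestEstimateDistribution:
    def test_zero_error_rates_reproduce_empirical(self):
        d = estimate_distribution(_table({"110": 60, "001": 30, "111": 10}), ErrorModel(),
                                  support_cut=0.0)
        assert d.freqs == pytest.approx({"110": 0.6, "001": 0.3, "111": 0.1})
        assert d.n_iter <= 2  # EM fixed point at initialization

    def test_single_pattern_point_mass(self):
        d = estimate_distribution(_table({"1010": 50}), ErrorModel.default())
        assert d.freqs == {"1010": 1.0}

    def test_two_pattern_recovery_eliminates_spurious(self):
        em = ErrorModel(f_nonconv=0.01, g_overconv=0.01, m_subst=0.003)
        counts = _simulate_counts([("1010", 0.7), ("0101", 0.3)], 10_000, em, seed=7)
        d = estimate_distribution(_table(counts), em)
        assert set(d.freqs) == {"1010", "0101"}
        assert abs(d.freqs["1010"] - 0.7) <= 0.02
        assert abs(d.freqs["0101"] - 0.3) <= 0.02

    def test_log_likelihood_never_decreases(self):
        em = ErrorModel.default()
        counts = _simulate_counts([("1100", 0.5), ("0011", 0.35), ("1111", 0.15)],
                                  5_000, em, seed=3)
        d = estimate_distribution(_table(counts), em)
        trace = np.asarray(d.ll_trace)
        tol = 1e-8 * (1.0 + np.abs(trace))
        assert np.all(np.diff(trace) >= -tol[1:])

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_distribution(_table({}), ErrorModel())

    def test_extreme_error_rates_rejected(self):
        with pytest.raises(ValueError):
            estimate_distribution(_table({"1": 5}), ErrorModel(f_nonconv=0.6))

    def test_matches_brute_force_optimizer_small(self):
        """EM maximum-likelihood fit agrees with an SLSQP simplex optimizer
        on small supports (<=4 CpGs, <=6 observed patterns)."""
        rng = np.random.default_rng(11)
        for trial in range(6):
            n_cpg = int(rng.integers(2, 5))
            k = int(rng.integers(2, 7))
            pool = rng.permutation(2**n_cpg)[:k]
            patterns = [format(int(p), f"0{n_cpg}b") for p in pool]
            counts = {p: int(rng.integers(5, 400)) for p in patterns}
            em = ErrorModel(f_nonconv=0.02, g_overconv=0.01, m_subst=0.005)
            d = estimate_distribution(_table(counts), em, support_cut=0.0, lrt_penalty=0.0)
            cvec = np.array([counts[p] for p in sorted(counts)])
            oracle = brute_force_mixture_ml(
                sorted(counts), cvec, em.p_false_methylated, em.p_false_unmethylated
            )
            ours = np.array([d.freqs.get(p, 0.0) for p in sorted(counts)])
            np.testing.assert_allclose(ours, oracle, atol=1e-4)

    def test_parameter_recovery_over_replicates(self):
        """k=6 true patterns, n=20,000, default errors, 20 seeds: dominant
        patterns always retained, small mean error, rare false survivors."""
        from amplimeth.simulate import generate_epiallele_mixture

        em = ErrorModel.default()
        false_reps = 0
        errs = []
        for seed in range(20):
            mix = generate_epiallele_mixture(10, 6, concentration=2.0, seed=500 + seed)
            counts = _simulate_counts(list(mix.components), 20_000, em, seed=600 + seed)
            d = estimate_distribution(_table(counts), em)
            true = dict(mix.components)
            for p, f in true.items():
                if f >= 0.05:
                    assert p in d.freqs, f"dominant pattern lost (seed {seed})"
            if any(p not in true for p in d.freqs):
                false_reps += 1
            errs.append(np.mean([abs(d.freqs.get(p, 0.0) - f) for p, f in true.items()]))
        assert np.mean(errs) <= 0.015
        assert false_reps <= 1  # <=5% of 20 replicates

    def test_support_cut_monotone_in_support_size(self):
        em = ErrorModel.default()
        counts = _simulate_counts([("110", 0.6), ("001", 0.4)], 4_000, em, seed=9)
        sizes = [
            len(estimate_distribution(_table(counts), em, support_cut=c, lrt_penalty=0.0).freqs)
            for c in (0.0, 0.001, 0.01, 0.1)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestApplyCutoff:
    DIST = {"A": 0.60, "B": 0.35, "C": 0.04, "D": 0.01}

    def _dist(self):
        # pattern strings of equal length standing in for real patterns
        freqs = {"1100": 0.60, "0011": 0.35, "1111": 0.04, "0000": 0.01}
        return estimate_distribution(
            _table({p: int(f * 1000) for p, f in freqs.items()}),
            ErrorModel(),
            support_cut=0.0,
        )

    def test_cutoff_zero_is_identity(self):
        d = self._dist()
        filtered, retained = apply_cutoff(d, 0.0)
        assert filtered.freqs == d.freqs
        assert retained == set(d.freqs)

    def test_five_percent_threshold_arithmetic(self):
        filtered, retained = apply_cutoff(self._dist(), 0.05)
        assert retained == {"1100", "0011"}
        # frequencies NOT renormalized
        assert filtered.freqs["1100"] == pytest.approx(0.60)

    def test_five_percent_support_subset_of_one_percent(self):
        d = self._dist()
        _, at1 = apply_cutoff(d, 0.01)
        _, at5 = apply_cutoff(d, 0.05)
        assert at5 <= at1

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            apply_cutoff(self._dist(), 1.0)
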