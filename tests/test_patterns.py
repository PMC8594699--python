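from __future__ import annotations

import numpy as np
import pytest

from amplimeth.estimate import ErrorModel
from amplimeth.extract import MergedRead, extract_pairs
from amplimeth.patterns import (
    PatternCall,
    PatternCountTable,
    call_pattern,
    per_cpg_levels,
    read_counts_tsv,
    tabulate_patterns,
    write_counts_tsv,
)
from amplimeth.simulate import EpialleleMixture, simulate_reads


def _as_merged(seq, template):
    return MergedRead("r", seq, len(seq), 0.0, template.name)


def _with_cpg_bases(template, base_by_index):
    """Template-length sequence with chosen bases at CpG columns."""
    seq = list(template.converted_seq)
    for idx, base in base_by_index.items():
        seq[template.cpg_positions[idx]] = base
    return "".join(seq)


class TestCallPattern:
    def test_all_c_gives_all_ones(self, small_template):
        t = small_template
        seq = _with_cpg_bases(t, {i: "C" for i in range(t.n_cpgs)})
        assert call_pattern(_as_merged(seq, t), t).pattern == "1" * t.n_cpgs

    def test_all_t_gives_all_zeros(self, small_template):
        t = small_template
        seq = _with_cpg_bases(t, {i: "T" for i in range(t.n_cpgs)})
        assert call_pattern(_as_merged(seq, t), t).pattern == "0" * t.n_cpgs

    def test_g_at_cpg_column_is_ambiguous(self, small_template):
        t = small_template
        seq = _with_cpg_bases(t, {0: "C", 1: "G", 2: "T", 3: "C"})
        assert call_pattern(_as_merged(seq, t), t).pattern is None

    def test_uncovered_cpg_is_ambiguous(self, small_template):
        t = small_template
        seq = t.converted_seq[: t.cpg_positions[-1]]  # last CpG outside span
        assert call_pattern(_as_merged(seq, t), t).pattern is None

    def test_deletion_at_cpg_is_ambiguous(self, tiny_template):
        # ACGA context pins the gap on the CpG column (shifting it would
        # misalign A against C), so the deleted C leaves a gap -> ambiguous
        t = tiny_template
        p = t.cpg_positions[1]
        assert t.genomic_seq[p - 1] == "A"
        seq = t.converted_seq[:p] + t.converted_seq[p + 1 :]
        assert call_pattern(_as_merged(seq, t), t).pattern is None

    def test_snp_bases_recorded_verbatim(self, small_template):
        t = small_template
        from amplimeth.panel import AmpliconTemplate

        snp_pos = t.cpg_positions[0] - 5
        t2 = AmpliconTemplate(
            t.name, t.genomic_seq, t.cpg_positions, t.primer_fwd, t.primer_rev,
            snp_positions=(snp_pos,),
        )
        seq = list(t2.converted_seq)
        seq[snp_pos] = "G"
        call = call_pattern(_as_merged("".join(seq), t2), t2)
        assert call.snp_bases == "G"
        assert call.pattern is not None
        # joint pattern/SNP counts aggregate without touching pattern identity
        table = tabulate_patterns([call, call], t2.name, "s")
        assert table.snp_calls == {(call.pattern, "G"): 2}
        assert table.counts == {call.pattern: 2}


class TestTabulate:
    def test_counting(self):
        table = tabulate_patterns(["10", "10", "10", "01"], "a", "s")
        assert table.counts == {"10": 3, "01": 1}
        assert table.n_called == 4
        assert table.n_ambiguous == 0

    def test_empty_stream(self):
        table = tabulate_patterns([], "a", "s")
        assert table.counts == {} and table.n_called == 0

    def test_ambiguous_tallied_separately(self):
        calls = [PatternCall("11"), PatternCall(None), PatternCall("11"), None]
        table = tabulate_patterns(calls, "a", "s")
        assert table.n_called == 2 and table.n_ambiguous == 2

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            tabulate_patterns(["10", "010"], "a", "s")

    def test_sorted_output_deterministic(self):
        table = tabulate_patterns(["01", "10", "10", "00", "01"], "a", "s")
        assert table.sorted_items() == [("01", 2), ("10", 2), ("00", 1)]

    def test_zero_error_simulation_matches_truth(self, small_template, tmp_path):
        from amplimeth.simulate import generate_epiallele_mixture, read_truth_tsv

        t = small_template
        mix = generate_epiallele_mixture(t.n_cpgs, 4, seed=12)
        sim = simulate_reads(t, mix, ErrorModel(), 800, read_len=90, seed=13, out_dir=tmp_path)
        passed, _ = extract_pairs(sim.fastq_r1, sim.fastq_r2, [t])
        table = tabulate_patterns(
            (call_pattern(m, t) for m in passed[t.name]), t.name, "s"
        )
        _, truth = read_truth_tsv(sim.truth)
        assert table.counts == {p: c for p, c in truth.items() if c > 0}
        assert table.n_ambiguous == 0

    def test_counts_tsv_roundtrip(self, tmp_path):
        table = tabulate_patterns(["101", "101", "011"], "ampX", "s1")
        path = tmp_path / "counts.tsv"
        write_counts_tsv([table], path)
        [back] = read_counts_tsv(path)
        assert back.counts == table.counts and back.n_called == table.n_called


class TestPerCpgLevels:
    def test_point_mass(self):
        np.testing.assert_allclose(per_cpg_levels({"111": 1.0}), [1, 1, 1])

    def test_half_half(self):
        np.testing.assert_allclose(per_cpg_levels({"10": 0.5, "01": 0.5}), [0.5, 0.5])

    def test_matches_weighted_column_sum_oracle(self):
        rng = np.random.default_rng(21)
        patterns = {format(i, "08b") for i in rng.integers(0, 256, size=20)}
        w = rng.dirichlet(np.ones(len(patterns)))
        dist = dict(zip(sorted(patterns), w))
        levels = per_cpg_levels(dist)
        for j in range(8):  # direct summation oracle
            expected = sum(w * int(p[j]) for p, w in dist.items())
            assert levels[j] == pytest.approx(expected)

    def test_invariant_under_call_stream_permutation(self):
        calls = ["10", "01", "01", "11", "10", "10"]
        t1 = tabulate_patterns(calls, "a", "s")
        t2 = tabulate_patterns(list(reversed(calls)), "a", "s")
        np.testing.assert_allclose(per_cpg_levels(t1), per_cpg_levels(t2))

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            per_cpg_levels({})

    def test_nonconversion_inflates_levels_by_epsilon(self, small_template, tmp_path):
        """All-zeros single-pattern library with non-conversion rate eps:
        each per-CpG level is eps within 3 binomial standard errors."""
        t = small_template
        eps, n = 0.02, 2000
        mix = EpialleleMixture(t.n_cpgs, (("0" * t.n_cpgs, 1.0),))
        sim = simulate_reads(
            t, mix, ErrorModel(f_nonconv=eps), n, read_len=90, seed=17, out_dir=tmp_path
        )
        passed, _ = extract_pairs(sim.fastq_r1, sim.fastq_r2, [t])
        table = tabulate_patterns(
            (call_pattern(m, t) for m in passed[t.name]), t.name, "s"
        )
        levels = per_cpg_levels(table)
        se = np.sqrt(eps * (1 - eps) / table.n_called)
        assert np.all(np.abs(levels - eps) <= 3 * se)
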