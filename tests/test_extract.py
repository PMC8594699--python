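from __future__ import annotations

import numpy as np
import pytest

from amplimeth.estimate import ErrorModel
from amplimeth.extract import (
    MergedRead,
    Rejection,
    _round_half_up,
    extract_pairs,
    match_primer,
    merge_pair,
    quality_filter,
    read_extract_tsv,
    write_extract_tsv,
)
from amplimeth.panel import revcomp
from amplimeth.simulate import EpialleleMixture, generate_epiallele_mixture, simulate_reads


class TestPrimerMatch:
    PRIMER = "GATTACAGATTACAGATTACAGATTACAGATTA"  # 33 nt

    def test_window_positions_4_to_33(self):
        read = "XXX" + self.PRIMER[-30:] + "ACGT" * 20
        assert match_primer(read, self.PRIMER)

    def test_single_mismatch_rejected(self):
        window = self.PRIMER[-30:]
        bad = window[:10] + ("A" if window[10] != "A" else "C") + window[11:]
        read = "XXX" + bad + "ACGT" * 20
        assert not match_primer(read, self.PRIMER)

    def test_short_read_rejected(self):
        assert not match_primer("ACGTACGTACGTACGTACGT", self.PRIMER)

    def test_case_insensitive(self):
        read = "xxx" + self.PRIMER[-30:].lower() + "acgt" * 10
        assert match_primer(read, self.PRIMER)

    def test_short_primer_is_an_error(self):
        with pytest.raises(ValueError):
            match_primer("A" * 50, "A" * 29)


def _mk_pair(template, span1, span2):
    """Build an error-free pair covering the given template spans."""
    conv = template.converted_seq
    r1 = template.primer_fwd + conv[span1[0] : span1[1]]
    r2 = template.primer_rev + revcomp(conv[span2[0] : span2[1]])
    return r1, r2


class TestMergePair:
    def test_proportional_truncation_rounding(self):
        # overlap v=20 split evenly between equal-length reads
        assert _round_half_up(20 * 60 / 120) == 10
        # odd remainder comes off read 1 (round half up)
        assert _round_half_up(21 * 60 / 120) == 11

    def test_overlapping_pair_reconstructs_template(self, small_template):
        t = small_template
        r1, r2 = _mk_pair(t, (0, 80), (40, 120))  # overlap 40 columns
        merged = merge_pair(r1, r2, t)
        assert isinstance(merged, MergedRead)
        assert merged.sequence == t.converted_seq
        assert merged.aligned_len == t.length_bp
        assert merged.gap_fraction == 0.0

    def test_non_overlapping_pair_concatenates(self, small_template):
        t = small_template
        r1, r2 = _mk_pair(t, (0, 50), (70, 120))
        merged = merge_pair(r1, r2, t)
        assert merged.sequence == t.converted_seq[:50] + t.converted_seq[70:]
        assert merged.aligned_len == 100

    def test_discordant_order_rejected(self, small_template):
        t = small_template
        # read 1 from the 3' end, read 2 from the 5' end: spans out of order
        r1 = t.primer_fwd + t.converted_seq[80:120]
        r2 = t.primer_rev + revcomp(t.converted_seq[0:40])
        result = merge_pair(r1, r2, t)
        assert isinstance(result, Rejection)
        assert result.reason == "discordant"

    def test_full_overlap_still_single_full_length(self, small_template):
        t = small_template
        r1, r2 = _mk_pair(t, (0, 120), (0, 120))
        merged = merge_pair(r1, r2, t)
        assert merged.sequence == t.converted_seq


class TestQualityFilter:
    def _merged(self, seq_len, gap_fraction, amplicon):
        return MergedRead("r", "A" * seq_len, seq_len, gap_fraction, amplicon)

    def test_short_against_90pct_threshold(self, panel):
        t405 = next(t for t in panel if t.length_bp == 405)
        assert quality_filter(self._merged(364, 0.0, t405.name), t405) == "short"
        assert quality_filter(self._merged(365, 0.0, t405.name), t405) is None

    def test_gappy_above_5pct(self, panel):
        t405 = next(t for t in panel if t.length_bp == 405)
        assert quality_filter(self._merged(405, 0.06, t405.name), t405) == "gappy"
        assert quality_filter(self._merged(405, 0.05, t405.name), t405) is None

    def test_short_checked_before_gappy(self, panel):
        t405 = next(t for t in panel if t.length_bp == 405)
        assert quality_filter(self._merged(100, 0.5, t405.name), t405) == "short"


class TestExtractPairs:
    def test_zero_error_full_pass_and_conservation(self, small_template, tmp_path):
        t = small_template
        mix = generate_epiallele_mixture(t.n_cpgs, 3, seed=2)
        sim = simulate_reads(t, mix, ErrorModel(), 400, read_len=90, seed=6, out_dir=tmp_path)
        passed, stats = extract_pairs(sim.fastq_r1, sim.fastq_r2, [t])
        assert stats.n_pairs == 400
        assert stats.n_unmatched == 0
        assert len(passed[t.name]) == 400  # zero-error, full coverage: all pass
        assert stats.conservation_holds()

    def test_conservation_with_errors(self, small_template, tmp_path):
        t = small_template
        mix = generate_epiallele_mixture(t.n_cpgs, 3, seed=2)
        em = ErrorModel(f_nonconv=0.01, m_subst=0.01, r_indel=0.01, nonCpG_fail=0.01)
        sim = simulate_reads(t, mix, em, 500, read_len=90, seed=8, out_dir=tmp_path)
        passed, stats = extract_pairs(sim.fastq_r1, sim.fastq_r2, [t])
        assert stats.conservation_holds()
        total = (
            len(passed[t.name])
            + sum(stats.n_short.values())
            + sum(stats.n_gappy.values())
            + sum(stats.n_discordant.values())
        )
        assert stats.n_pairs == stats.n_unmatched + total

    def test_indel_rate_raises_gappy_rate(self, small_template, tmp_path):
        """Stochastic monotonicity of the gap filter in r_indel, paired over
        20 replicates."""
        t = small_template
        mix = generate_epiallele_mixture(t.n_cpgs, 2, seed=3)
        rates = []
        for r_indel in (0.004, 0.05):
            gappy = 0
            extracted = 0
            for rep in range(20):
                em = ErrorModel(r_indel=r_indel)
                sim = simulate_reads(
                    t, mix, em, 60, read_len=90, seed=50 + rep, out_dir=tmp_path,
                    prefix=f"r{r_indel}_{rep}",
                )
                _, stats = extract_pairs(sim.fastq_r1, sim.fastq_r2, [t])
                gappy += sum(stats.n_gappy.values())
                extracted += stats.n_extracted
            rates.append(gappy / extracted)
        assert rates[1] > rates[0]

    def test_extract_tsv_roundtrip(self, small_template, tmp_path):
        t = small_template
        r1, r2 = _mk_pair(t, (0, 80), (40, 120))
        merged = merge_pair(r1, r2, t, read_id="pair1")
        path = tmp_path / "extract.tsv"
        write_extract_tsv([merged], path)
        back = list(read_extract_tsv(path))
        assert back == [merged]
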