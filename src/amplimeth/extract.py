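"""Read-pair extraction and merging against an amplicon template.

This is the first pass of the pipeline: pairs are selected by an exact primer
match (the 30 nt starting at read position 4 must equal the last 30 nt of the
nested primer), each mate is aligned to the in-silico converted template,
overlapping template columns are proportionally truncated, aligner gaps are
removed, and the two mates are concatenated into one template-oriented
sequence. A quality filter then rejects merges shorter than 90% of the
template or containing more than 5% gap columns.
"""

from __future__ import annotations

import functools
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import OP_DEL, OP_DIAG, OP_INS, align_codes, encode
from .panel import AmpliconTemplate, revcomp

__all__ = [
    "MergedRead",
    "Rejection",
    "ExtractStats",
    "match_primer",
    "merge_pair",
    "quality_filter",
    "extract_pairs",
    "write_extract_tsv",
    "read_extract_tsv",
]

PRIMER_WINDOW_START = 3  # window starts at read position 4 (1-based)
PRIMER_WINDOW_LEN = 30
DEFAULT_BAND = 32  # half-width of the alignment band used by the pipeline

MIN_LENGTH_FRACTION = 0.9
MAX_GAP_FRACTION = 0.05


@dataclass(frozen=True)
class MergedRead:
    """One read pair merged into a single template-oriented sequence."""

    read_id: str
    sequence: str
    aligned_len: int  # template columns covered by the merged read
    gap_fraction: float  # gap columns / alignment columns in the merged span
    amplicon: str


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # "discordant", "short" or "gappy"
    amplicon: str


def match_primer(read_seq: str, primer: str) -> bool:
    """True iff read positions 4-33 (1-based) equal the primer's last 30 nt.

    The comparison is exact and case-insensitive; reads shorter than 33 nt
    can never match.
    """
    if len(primer) < PRIMER_WINDOW_LEN:
        raise ValueError("primer must be at least 30 nt")
    end = PRIMER_WINDOW_START + PRIMER_WINDOW_LEN
    if len(read_seq) < end:
        return False
    return read_seq[PRIMER_WINDOW_START:end].upper() == primer[-PRIMER_WINDOW_LEN:].upper()


@functools.lru_cache(maxsize=64)
def _template_codes(converted_seq: str) -> np.ndarray:
    return encode(converted_seq)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _collect(ops, start_j, read_codes_len, read_seq, keep_lo, keep_hi):
    """Walk alignment ops keeping columns whose template position is in
    [keep_lo, keep_hi); returns (bases, n_cols, n_gap_cols, n_template_cols)."""
    bases: list[str] = []
    j = start_j
    i = 0
    n_cols = 0
    n_gaps = 0
    n_tcols = 0
    for op in ops:
        if op == OP_DIAG:
            if keep_lo <= j < keep_hi:
                bases.append(read_seq[i])
                n_cols += 1
                n_tcols += 1
            i += 1
            j += 1
        elif op == OP_INS:
            # insertion sits immediately before template column j
            if keep_lo <= j < keep_hi:
                bases.append(read_seq[i])
                n_cols += 1
                n_gaps += 1
            i += 1
        else:  # OP_DEL
            if keep_lo <= j < keep_hi:
                n_cols += 1
                n_gaps += 1
                n_tcols += 1
            j += 1
    return "".join(bases), n_cols, n_gaps, n_tcols


def merge_pair(
    read1: str,
    read2: str,
    template: AmpliconTemplate,
    read_id: str = "",
    banded: bool = True,
) -> MergedRead | Rejection:
    """Merge a primer-matched pair into one template-oriented sequence.

    ``read2`` is supplied in sequencer orientation and reverse-complemented
    here. The primer tag (len(primer) leading bases) of each mate is stripped
    before alignment, keeping the template primer-free. When the two template
    spans overlap by ``v`` columns, ``round(v*L1/(L1+L2))`` columns are
    truncated from the 3' end of read 1's span (round half up, so an odd
    remainder comes off read 1) and the rest from the 5' end of read 2's span.
    All aligner gaps are then removed and the two parts concatenated.
    """
    conv = template.converted_seq
    tcodes = _template_codes(conv)
    m = len(conv)
    r1 = read1[len(template.primer_fwd) :]
    r2 = read2[len(template.primer_rev) :]
    if not r1 or not r2:
        return Rejection(read_id, "discordant", template.name)
    r2rc = revcomp(r2)
    halfw = DEFAULT_BAND if banded else None
    c1 = encode(r1)
    c2 = encode(r2rc)
    a1 = align_codes(c1, tcodes, diag=0, halfw=halfw)
    a2 = align_codes(c2, tcodes, diag=m - len(r2rc), halfw=halfw)
    if banded:
        # a read whose true register lies outside the primer-anchored band
        # misaligns without touching the band edge; a poor score (< 1 point
        # per base, against 2 for a perfect match) flags it for a full-matrix
        # realignment so the span logic judges the real geometry
        if a1.score < len(r1):
            a1 = align_codes(c1, tcodes)
        if a2.score < len(r2rc):
            a2 = align_codes(c2, tcodes)
    s1, e1 = a1.start_j, a1.end_j
    s2, e2 = a2.start_j, a2.end_j
    if e2 <= s1:
        return Rejection(read_id, "discordant", template.name)
    L1 = e1 - s1
    L2 = e2 - s2
    if L1 == 0 or L2 == 0:
        return Rejection(read_id, "discordant", template.name)
    v = e1 - s2 if e1 > s2 else 0
    if v > 0:
        t1 = _round_half_up(v * L1 / (L1 + L2))
        t2 = v - t1
        if t2 > L2:  # degenerate containment; push the excess back onto read 1
            t1 += t2 - L2
            t2 = L2
        if t1 > L1:
            t2 += t1 - L1
            t1 = L1
    else:
        t1 = t2 = 0
    cut1 = e1 - t1
    cut2 = s2 + t2
    b1, c1, g1, tc1 = _collect(a1.ops, s1, len(r1), r1, s1, cut1)
    b2, c2, g2, tc2 = _collect(a2.ops, s2, len(r2rc), r2rc, cut2, e2)
    n_cols = c1 + c2
    if n_cols == 0:
        return Rejection(read_id, "discordant", template.name)
    return MergedRead(
        read_id=read_id,
        sequence=b1 + b2,
        aligned_len=tc1 + tc2,
        gap_fraction=(g1 + g2) / n_cols,
        amplicon=template.name,
    )


def quality_filter(merged: MergedRead, template: AmpliconTemplate) -> str | None:
    """Return a rejection reason ("short" or "gappy") or None for a pass.

    A merge passes when its gap-free length is at least 90% of the template
    length and at most 5% of its alignment columns are gaps; the length
    criterion is checked first.
    """
    if len(merged.sequence) < MIN_LENGTH_FRACTION * template.length_bp:
        return "short"
    if merged.gap_fraction > MAX_GAP_FRACTION:
        return "gappy"
    return None


@dataclass
class ExtractStats:
    """Per-sample bookkeeping; input = unmatched + extracted, and
    extracted = passed + short + gappy + discordant, exactly."""

    n_pairs: int = 0
    n_unmatched: int = 0
    n_passed: dict = field(default_factory=dict)  # amplicon -> count
    n_short: dict = field(default_factory=dict)
    n_gappy: dict = field(default_factory=dict)
    n_discordant: dict = field(default_factory=dict)

    def _bump(self, d: dict, amplicon: str) -> None:
        d[amplicon] = d.get(amplicon, 0) + 1

    @property
    def n_extracted(self) -> int:
        return self.n_pairs - self.n_unmatched

    def conservation_holds(self) -> bool:
        total = sum(
            sum(d.values()) for d in (self.n_passed, self.n_short, self.n_gappy, self.n_discordant)
        )
        return total == self.n_extracted

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_unmatched": self.n_unmatched,
            "n_extracted": self.n_extracted,
            "n_passed": dict(self.n_passed),
            "n_short": dict(self.n_short),
            "n_gappy": dict(self.n_gappy),
            "n_discordant": dict(self.n_discordant),
        }


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def extract_pairs(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    templates: Sequence[AmpliconTemplate],
    banded: bool = True,
) -> tuple[dict[str, list[MergedRead]], ExtractStats]:
    """Run primer selection, merging and quality filtering over paired FASTQ.

    A pair is assigned to the first amplicon whose forward primer matches
    read 1 and reverse primer matches read 2 (both exact). Returns passed
    merges per amplicon plus the full rejection tally.
    """
    passed: dict[str, list[MergedRead]] = {t.name: [] for t in templates}
    stats = ExtractStats()
    with _open_text(fastq_r1) as fh1, _open_text(fastq_r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (id1, seq1, _q1), (_id2, seq2, _q2) in zip(it1, it2):
            stats.n_pairs += 1
            template = None
            for t in templates:
                if match_primer(seq1, t.primer_fwd) and match_primer(seq2, t.primer_rev):
                    template = t
                    break
            if template is None:
                stats.n_unmatched += 1
                continue
            read_id = id1.split()[0]
            merged = merge_pair(seq1, seq2, template, read_id=read_id, banded=banded)
            if isinstance(merged, Rejection):
                stats._bump(stats.n_discordant, template.name)
                continue
            reason = quality_filter(merged, template)
            if reason == "short":
                stats._bump(stats.n_short, template.name)
            elif reason == "gappy":
                stats._bump(stats.n_gappy, template.name)
            else:
                stats._bump(stats.n_passed, template.name)
                passed[template.name].append(merged)
    return passed, stats


def write_extract_tsv(merged: Iterable[MergedRead], path: str | Path) -> None:
    """Write the per-amplicon "extract file": one merged read pair per row."""
    with open(path, "w") as fh:
        fh.write("read_id\tamplicon\tsequence\taligned_len\tgap_fraction\n")
        for m in merged:
            fh.write(
                f"{m.read_id}\t{m.amplicon}\t{m.sequence}\t{m.aligned_len}\t{m.gap_fraction:.6f}\n"
            )


def read_extract_tsv(path: str | Path) -> Iterator[MergedRead]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {k: i for i, k in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            yield MergedRead(
                read_id=f[idx["read_id"]],
                sequence=f[idx["sequence"]],
                aligned_len=int(f[idx["aligned_len"]]),
                gap_fraction=float(f[idx["gap_fraction"]]),
                amplicon=f[idx["amplicon"]],
            )
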