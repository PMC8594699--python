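"""Per-read methylation pattern calling and tabulation.

Each merged read pair is re-aligned to the converted template (a second pass,
so indels left over from merging cannot shift CpG columns) and scored at every
CpG position: C -> 1 (methylated, protected from conversion), T -> 0
(unmethylated, converted). A read showing any other base, a gap, or not
covering a CpG column at all is classed ambiguous and excluded whole; the
pattern sample space must stay fixed-length for frequency estimation.
Declared SNP columns are recorded verbatim and never affect pattern identity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .align import OP_DEL, OP_DIAG, align_codes, encode
from .extract import DEFAULT_BAND, MergedRead, _template_codes
from .panel import AmpliconTemplate

__all__ = [
    "PatternCall",
    "PatternCountTable",
    "call_pattern",
    "tabulate_patterns",
    "per_cpg_levels",
    "write_counts_tsv",
    "read_counts_tsv",
]


@dataclass(frozen=True)
class PatternCall:
    """Outcome of scoring one merged read; pattern is None when ambiguous."""

    pattern: str | None
    snp_bases: str | None = None


def call_pattern(
    merged: MergedRead,
    template: AmpliconTemplate,
    banded: bool = True,
) -> PatternCall:
    """Re-align a merged read and score its binary CpG pattern.

    Returns the pattern as a 0/1 string over the template's CpG index, plus
    the raw bases at declared SNP positions ('N' where uncovered). Ambiguity
    at any CpG makes the whole read ambiguous (pattern None).
    """
    tcodes = _template_codes(template.converted_seq)
    aln = align_codes(
        encode(merged.sequence),
        tcodes,
        diag=0,
        halfw=DEFAULT_BAND if banded else None,
    )
    want = {}
    for p in template.cpg_positions:
        want[p] = None
    snp_want = {p: "N" for p in template.snp_positions}
    j = aln.start_j
    i = 0
    seq = merged.sequence
    for op in aln.ops:
        if op == OP_DIAG:
            if j in want:
                want[j] = seq[i]
            if j in snp_want:
                snp_want[j] = seq[i]
            i += 1
            j += 1
        elif op == OP_DEL:
            j += 1
        else:
            i += 1
    bits = []
    for p in template.cpg_positions:
        base = want[p]
        if base == "C":
            bits.append("1")
        elif base == "T":
            bits.append("0")
        else:  # gap, other base, or CpG outside the read's span
            return PatternCall(pattern=None)
    snp = "".join(snp_want[p] for p in template.snp_positions) or None
    return PatternCall(pattern="".join(bits), snp_bases=snp)


@dataclass
class PatternCountTable:
    """Unique-pattern counts for one amplicon x sample."""

    amplicon: str
    sample: str
    counts: dict[str, int] = field(default_factory=dict)
    n_called: int = 0
    n_ambiguous: int = 0
    snp_calls: dict[tuple[str, str], int] | None = None

    def sorted_items(self) -> list[tuple[str, int]]:
        """Deterministic output order: count descending, then pattern ascending."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    @property
    def n_cpgs(self) -> int:
        return len(next(iter(self.counts))) if self.counts else 0


def tabulate_patterns(
    calls: Iterable[PatternCall | str | None],
    amplicon: str,
    sample: str,
) -> PatternCountTable:
    """Aggregate a stream of pattern calls into a count table.

    Accepts :class:`PatternCall` objects, plain pattern strings, or None
    (ambiguous). Mixed pattern lengths raise ValueError.
    """
    counts: Counter[str] = Counter()
    snp_counts: Counter[tuple[str, str]] = Counter()
    n_ambiguous = 0
    has_snp = False
    length = None
    for call in calls:
        if isinstance(call, PatternCall):
            pattern, snp = call.pattern, call.snp_bases
        else:
            pattern, snp = call, None
        if pattern is None:
            n_ambiguous += 1
            continue
        if length is None:
            length = len(pattern)
        elif len(pattern) != length:
            raise ValueError(
                f"mixed pattern lengths in {amplicon}/{sample}: {length} vs {len(pattern)}"
            )
        if set(pattern) - {"0", "1"}:
            raise ValueError(f"pattern {pattern!r} contains characters other than 0/1")
        counts[pattern] += 1
        if snp is not None:
            has_snp = True
            snp_counts[(pattern, snp)] += 1
    return PatternCountTable(
        amplicon=amplicon,
        sample=sample,
        counts=dict(counts),
        n_called=sum(counts.values()),
        n_ambiguous=n_ambiguous,
        snp_calls=dict(snp_counts) if has_snp else None,
    )


def _weights(obj) -> tuple[list[str], np.ndarray]:
    """Patterns and normalized weights from a count table or a distribution."""
    if hasattr(obj, "counts"):
        items = list(obj.counts.items())
    elif hasattr(obj, "freqs"):
        items = list(obj.freqs.items())
    elif isinstance(obj, dict):
        items = list(obj.items())
    else:
        raise TypeError(f"cannot extract pattern weights from {type(obj)!r}")
    if not items:
        raise ValueError("empty pattern table/distribution")
    patterns = [p for p, _ in items]
    w = np.asarray([v for _, v in items], dtype=float)
    return patterns, w / w.sum()


def per_cpg_levels(table_or_distribution) -> np.ndarray:
    """Combined methylation level per CpG: the weighted mean of pattern bits.

    Weights are normalized counts (count table) or estimated frequencies
    (distribution). Matches the per-CpG summary drawn under pattern plots.
    """
    patterns, w = _weights(table_or_distribution)
    bits = np.asarray([[int(c) for c in p] for p in patterns], dtype=float)
    return bits.T @ w


def write_counts_tsv(tables: Iterable[PatternCountTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("amplicon\tsample\tpattern\tcount\n")
        for t in tables:
            for pattern, count in t.sorted_items():
                fh.write(f"{t.amplicon}\t{t.sample}\t{pattern}\t{count}\n")


def read_counts_tsv(path: str | Path) -> list[PatternCountTable]:
    tables: dict[tuple[str, str], PatternCountTable] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {k: i for i, k in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            key = (f[idx["amplicon"]], f[idx["sample"]])
            t = tables.setdefault(key, PatternCountTable(amplicon=key[0], sample=key[1]))
            count = int(f[idx["count"]])
            t.counts[f[idx["pattern"]]] = count
            t.n_called += count
    return list(tables.values())
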