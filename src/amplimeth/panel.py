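"""Amplicon templates: CpG discovery, in-silico bisulfite conversion, panel I/O.

An amplicon *panel* is a FASTA of genomic (top-strand) template sequences plus a
TOML configuration that names, for each amplicon, the nested-PCR primer pair and
optionally the CpG/SNP coordinates. CpG coordinates are derived from the sequence
when not supplied. All coordinates are 0-based half-open in memory; config files
and reports use 1-based inclusive positions.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "PanelError",
    "AmpliconTemplate",
    "scan_cpg_sites",
    "convert_template",
    "load_panel",
    "write_panel",
    "revcomp",
]

_VALID_BASES = frozenset("ACGTN")
MIN_PRIMER_LEN = 30


class PanelError(ValueError):
    """A template or panel configuration failed validation."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return str(Seq(seq).reverse_complement())


def scan_cpg_sites(seq: str) -> list[int]:
    """Return 0-based offsets of the C of every CpG dinucleotide in *seq*.

    ``N`` never matches. An empty sequence yields an empty list.
    """
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise PanelError(f"sequence contains invalid characters: {sorted(bad)}")
    out = []
    start = 0
    while True:
        p = seq.find("CG", start)
        if p < 0:
            return out
        out.append(p)
        start = p + 1


def convert_template(genomic_seq: str, cpg_positions: Sequence[int]) -> str:
    """In-silico bisulfite conversion of the top strand.

    Every cytosine outside *cpg_positions* becomes T (full conversion of
    unmethylated non-CpG C); cytosines at CpG positions are kept as C so that
    the converted template carries the C/T ambiguity only at CpG sites, where
    the methylation signal lives.
    """
    genomic_seq = genomic_seq.upper()
    cpg = set(cpg_positions)
    for p in cpg:
        if p < 0 or p >= len(genomic_seq) or genomic_seq[p] != "C":
            raise PanelError(f"cpg_positions: offset {p} does not hold a C")
    out = []
    for i, b in enumerate(genomic_seq):
        if b == "C" and i not in cpg:
            out.append("T")
        else:
            out.append(b)
    return "".join(out)


@dataclass(frozen=True)
class AmpliconTemplate:
    """One amplicon: genomic and converted sequence, CpG/SNP map, nested primers.

    ``primer_fwd``/``primer_rev`` are the nested primer oligos as they appear at
    the start of read 1 / read 2 (bisulfite-converted read space, >=30 nt).
    """

    name: str
    genomic_seq: str
    cpg_positions: tuple[int, ...]
    primer_fwd: str
    primer_rev: str
    snp_positions: tuple[int, ...] = ()
    converted_seq: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        seq = self.genomic_seq.upper()
        object.__setattr__(self, "genomic_seq", seq)
        object.__setattr__(self, "primer_fwd", self.primer_fwd.upper())
        object.__setattr__(self, "primer_rev", self.primer_rev.upper())
        if not seq:
            raise PanelError(f"{self.name}: empty template sequence")
        if set(seq) - set("ACGT"):
            # 'N' rejected: every pattern position must be certain.
            raise PanelError(f"{self.name}: template may contain only A/C/G/T")
        cpg = tuple(self.cpg_positions)
        object.__setattr__(self, "cpg_positions", cpg)
        if list(cpg) != sorted(set(cpg)):
            raise PanelError(f"{self.name}: cpg_positions must be strictly increasing")
        for p in cpg:
            if p < 0 or p + 1 >= len(seq) or seq[p : p + 2] != "CG":
                raise PanelError(f"{self.name}: cpg_positions: offset {p} is not a CpG")
        snp = tuple(self.snp_positions)
        object.__setattr__(self, "snp_positions", snp)
        if list(snp) != sorted(set(snp)):
            raise PanelError(f"{self.name}: snp_positions must be strictly increasing")
        for p in snp:
            if p < 0 or p >= len(seq):
                raise PanelError(f"{self.name}: snp_positions: offset {p} out of range")
        for label, primer in (("primer_fwd", self.primer_fwd), ("primer_rev", self.primer_rev)):
            if len(primer) < MIN_PRIMER_LEN:
                raise PanelError(
                    f"{self.name}: {label} is {len(primer)} nt; at least "
                    f"{MIN_PRIMER_LEN} nt required"
                )
            if set(primer) - set("ACGT"):
                raise PanelError(f"{self.name}: {label} may contain only A/C/G/T")
        conv = convert_template(seq, cpg)
        if self.converted_seq and self.converted_seq != conv:
            raise PanelError(f"{self.name}: converted_seq inconsistent with genomic_seq")
        object.__setattr__(self, "converted_seq", conv)

    @property
    def length_bp(self) -> int:
        return len(self.genomic_seq)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def _parse_positions(name: str, key: str, values, seq: str) -> tuple[int, ...]:
    try:
        pos = tuple(int(v) - 1 for v in values)  # config is 1-based inclusive
    except (TypeError, ValueError) as exc:
        raise PanelError(f"{name}: {key} must be a list of integers") from exc
    if any(p < 0 or p >= len(seq) for p in pos):
        raise PanelError(f"{name}: {key} contains out-of-range coordinates")
    return pos


def load_panel(template_fasta: str | Path, panel_config: str | Path) -> list[AmpliconTemplate]:
    """Load and validate an amplicon panel from FASTA + TOML config.

    The config holds an ``[[amplicon]]`` table per amplicon with keys ``name``,
    ``primer_fwd``, ``primer_rev`` and optional ``cpg_positions``/``snp_positions``
    (1-based). CpG positions default to :func:`scan_cpg_sites` of the record.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(template_fasta), "fasta")}
    with open(panel_config, "rb") as fh:
        cfg = tomllib.load(fh)
    entries = cfg.get("amplicon")
    if not entries:
        raise PanelError("panel config defines no [[amplicon]] tables")
    templates = []
    for entry in entries:
        name = entry.get("name")
        if not name:
            raise PanelError("amplicon entry missing 'name'")
        if name not in records:
            raise PanelError(f"{name}: no matching record in {template_fasta}")
        seq = records[name]
        for key in ("primer_fwd", "primer_rev"):
            if key not in entry:
                raise PanelError(f"{name}: missing '{key}'")
        if "cpg_positions" in entry:
            cpg = _parse_positions(name, "cpg_positions", entry["cpg_positions"], seq)
        else:
            cpg = tuple(scan_cpg_sites(seq))
        snp = ()
        if "snp_positions" in entry:
            snp = _parse_positions(name, "snp_positions", entry["snp_positions"], seq)
        templates.append(
            AmpliconTemplate(
                name=name,
                genomic_seq=seq,
                cpg_positions=cpg,
                primer_fwd=str(entry["primer_fwd"]),
                primer_rev=str(entry["primer_rev"]),
                snp_positions=snp,
            )
        )
    return templates


def write_panel(
    templates: Sequence[AmpliconTemplate],
    template_fasta: str | Path,
    panel_config: str | Path,
) -> None:
    """Write templates to FASTA + TOML so that :func:`load_panel` round-trips."""
    with open(template_fasta, "w") as fa:
        for t in templates:
            fa.write(f">{t.name}\n{t.genomic_seq}\n")
    lines = ["# amplicon panel; coordinates are 1-based inclusive"]
    for t in templates:
        lines.append("")
        lines.append("[[amplicon]]")
        lines.append(f'name = "{t.name}"')
        lines.append(f'primer_fwd = "{t.primer_fwd}"')
        lines.append(f'primer_rev = "{t.primer_rev}"')
        lines.append(f"cpg_positions = {[p + 1 for p in t.cpg_positions]}")
        if t.snp_positions:
            lines.append(f"snp_positions = {[p + 1 for p in t.snp_positions]}")
    Path(panel_config).write_text("\n".join(lines) + "\n")
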