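"""Synthetic epiallele mixtures and paired amplicon bisulfite reads.

The generator emulates the study design the pipeline targets: a small panel of
long amplicons (551/405/401 bp carrying 10/15/10 CpGs), a handful of dominant
epiallele patterns per condition with Dirichlet-skewed frequencies, 2x300
paired reads whose mates carry the nested-PCR primer oligo at their 5' end,
bisulfite non-conversion and over-conversion at the molecule level, and
per-read substitution/indel sequencing error. Truth tables accompany every
simulated library so downstream stages can be checked exactly.

All randomness flows from one integer seed through a single PCG64 stream in a
fixed draw order, so identical arguments give byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gzip

import numpy as np

from .align import decode, encode
from .estimate import ErrorModel
from .panel import AmpliconTemplate, scan_cpg_sites

__all__ = [
    "EpialleleMixture",
    "SimulatedReads",
    "generate_epiallele_mixture",
    "simulate_reads",
    "synthetic_template",
    "table1_panel",
    "read_truth_tsv",
]

DEFAULT_READ_LEN = 300  # 2x300 paired-end chemistry
DEFAULT_PRIMER_LEN = 33  # 3 nt lead-in + the 30 nt match window
_CHUNK = 4096

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class EpialleleMixture:
    """A set of distinct methylation patterns with their true frequencies."""

    n_cpgs: int
    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        pats = [p for p, _ in self.components]
        freqs = [f for _, f in self.components]
        if len(set(pats)) != len(pats):
            raise ValueError("mixture patterns must be pairwise distinct")
        for p in pats:
            if len(p) != self.n_cpgs or set(p) - {"0", "1"}:
                raise ValueError(f"invalid pattern {p!r} for n_cpgs={self.n_cpgs}")
        if any(f <= 0 for f in freqs):
            raise ValueError("mixture frequencies must be positive")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("mixture frequencies must sum to 1")

    @property
    def patterns(self) -> list[str]:
        return [p for p, _ in self.components]

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray([f for _, f in self.components])


@dataclass(frozen=True)
class SimulatedReads:
    fastq_r1: Path
    fastq_r2: Path
    truth: Path


def generate_epiallele_mixture(
    n_cpgs: int,
    k: int,
    concentration: float = 1.0,
    seed: int = 0,
) -> EpialleleMixture:
    """Draw k distinct patterns uniformly and Dirichlet(concentration) weights.

    Frequencies are sorted descending, so component 0 is the dominant
    epiallele. Small concentration values give the skewed distributions seen
    in pooled brain samples, where most reads belong to a dozen patterns.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    if not 1 <= k <= 2**n_cpgs:
        raise ValueError(f"k={k} outside [1, 2^{n_cpgs}]")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    seen: set[int] = set()
    while len(chosen) < k:  # rejection sampling keeps the draw uniform
        c = int(rng.integers(0, 2**n_cpgs))
        if c not in seen:
            seen.add(c)
            chosen.append(c)
    patterns = [format(c, f"0{n_cpgs}b") for c in chosen]
    freqs = np.sort(rng.dirichlet([concentration] * k))[::-1]
    return EpialleleMixture(
        n_cpgs=n_cpgs,
        components=tuple(zip(patterns, (float(f) for f in freqs))),
    )


def _apply_sequencing_errors(reads: np.ndarray, error_model: ErrorModel, rng) -> list[np.ndarray]:
    """Substitutions vectorized, indels per affected read; returns row arrays."""
    m = error_model.m_subst
    r = error_model.r_indel
    n, length = reads.shape
    if m > 0:
        mask = rng.random(reads.shape) < m
        n_sub = int(mask.sum())
        if n_sub:
            shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
            reads[mask] = (reads[mask] + shift) % 4
    out: list[np.ndarray] = []
    if r > 0:
        k_ind = rng.binomial(length, r, size=n)
    else:
        k_ind = np.zeros(n, dtype=int)
    for i in range(n):
        row = reads[i]
        if k_ind[i]:
            lst = list(row)
            for _ in range(k_ind[i]):
                pos = int(rng.integers(0, len(lst) + 1))
                if rng.integers(0, 2) == 0 and lst:
                    del lst[min(pos, len(lst) - 1)]
                else:
                    lst.insert(pos, int(rng.integers(0, 4)))
            row = np.asarray(lst, dtype=np.uint8)
        out.append(row)
    return out


def simulate_reads(
    template: AmpliconTemplate,
    mixture: EpialleleMixture,
    error_model: ErrorModel,
    n_pairs: int,
    read_len: int = DEFAULT_READ_LEN,
    seed: int = 0,
    out_dir: str | Path = ".",
    prefix: str | None = None,
    gzip_out: bool = False,
) -> SimulatedReads:
    """Simulate a paired FASTQ library for one amplicon plus a truth table.

    Per molecule: a pattern is drawn from the mixture; CpG cytosines survive
    conversion with probability 1-g_overconv (methylated) or f_nonconv
    (unmethylated); non-CpG cytosines survive with probability nonCpG_fail;
    read 1 is the primer oligo followed by the molecule's first ``read_len``
    bases, read 2 the reverse primer followed by the reverse complement of the
    last ``read_len`` bases; sequencing substitutions and indels are applied
    per read. Base qualities are constant 'I' (the pipeline applies no
    quality filter).
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if mixture.n_cpgs != template.n_cpgs:
        raise ValueError(
            f"mixture has {mixture.n_cpgs} CpGs but template {template.name} "
            f"has {template.n_cpgs}"
        )
    if read_len > template.length_bp:
        raise ValueError("read_len exceeds template length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or f"sim_{template.name}"
    suffix = ".fastq.gz" if gzip_out else ".fastq"
    p1 = out_dir / f"{prefix}_R1{suffix}"
    p2 = out_dir / f"{prefix}_R2{suffix}"
    ptruth = out_dir / f"{prefix}_truth.tsv"

    rng = np.random.default_rng(seed)
    L = template.length_bp
    conv = encode(template.converted_seq)
    cpg = np.asarray(template.cpg_positions, dtype=int)
    noncpg_c = np.asarray(
        [
            i
            for i, b in enumerate(template.genomic_seq)
            if b == "C" and i not in set(template.cpg_positions)
        ],
        dtype=int,
    )
    bitmat = np.asarray([[c == "1" for c in p] for p in mixture.patterns], dtype=bool)
    freqs = mixture.frequencies
    tag1 = encode(template.primer_fwd)
    tag2 = encode(template.primer_rev)
    f = error_model.f_nonconv
    g = error_model.g_overconv
    nf = error_model.nonCpG_fail
    C, T = 1, 3

    tally = np.zeros(len(freqs), dtype=int)
    opener = gzip.open if gzip_out else open
    with opener(p1, "wt") as fh1, opener(p2, "wt") as fh2:
        for lo in range(0, n_pairs, _CHUNK):
            nn = min(_CHUNK, n_pairs - lo)
            idx = rng.choice(len(freqs), size=nn, p=freqs)
            np.add.at(tally, idx, 1)
            mol = np.tile(conv, (nn, 1))
            if len(cpg):
                u = rng.random((nn, len(cpg)))
                bits = bitmat[idx]
                base_is_c = np.where(bits, u >= g, u < f)
                mol[:, cpg] = np.where(base_is_c, C, T).astype(np.uint8)
            if len(noncpg_c) and nf > 0:
                u2 = rng.random((nn, len(noncpg_c)))
                fail = u2 < nf
                cols = np.broadcast_to(noncpg_c, fail.shape)
                rows = np.broadcast_to(np.arange(nn)[:, None], fail.shape)
                mol[rows[fail], cols[fail]] = C
            ins1 = mol[:, :read_len]
            ins2 = _COMP[mol[:, L - read_len :][:, ::-1]]
            r1 = np.hstack([np.tile(tag1, (nn, 1)), ins1])
            r2 = np.hstack([np.tile(tag2, (nn, 1)), ins2])
            rows1 = _apply_sequencing_errors(r1, error_model, rng)
            rows2 = _apply_sequencing_errors(r2, error_model, rng)
            buf1 = []
            buf2 = []
            for i in range(nn):
                rid = f"{prefix}:{lo + i}"
                s1 = decode(rows1[i])
                s2 = decode(rows2[i])
                buf1.append(f"@{rid}/1\n{s1}\n+\n{'I' * len(s1)}\n")
                buf2.append(f"@{rid}/2\n{s2}\n+\n{'I' * len(s2)}\n")
            fh1.write("".join(buf1))
            fh2.write("".join(buf2))

    with open(ptruth, "w") as fh:
        fh.write("pattern\ttrue_frequency\tmolecules\n")
        for pat, freq, count in zip(mixture.patterns, freqs, tally):
            fh.write(f"{pat}\t{freq:.8f}\t{count}\n")
    return SimulatedReads(fastq_r1=p1, fastq_r2=p2, truth=ptruth)


def read_truth_tsv(path: str | Path) -> tuple[dict[str, float], dict[str, int]]:
    """Return (pattern -> true frequency, pattern -> molecule tally)."""
    freqs: dict[str, float] = {}
    tally: dict[str, int] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            pat, freq, count = line.rstrip("\n").split("\t")
            freqs[pat] = float(freq)
            tally[pat] = int(count)
    return freqs, tally


def _random_bases(rng, n: int) -> str:
    return decode(rng.integers(0, 4, size=n).astype(np.uint8))


def synthetic_template(
    name: str,
    length: int,
    n_cpgs: int,
    seed: int = 0,
    primer_len: int = DEFAULT_PRIMER_LEN,
) -> AmpliconTemplate:
    """Random amplicon with exactly ``n_cpgs`` CpGs and CpG-free primer zones.

    CpGs are placed outside the first/last ``primer_len + 2`` bases (primers
    are designed CpG-free in bisulfite assays) with at least one base between
    consecutive sites. Accidental background CpGs are destroyed by mutating
    their G to A.
    """
    if length < 2 * primer_len + 3 * n_cpgs + 10:
        raise ValueError("template too short for the requested CpG count")
    rng = np.random.default_rng(seed)
    lo = primer_len + 2
    hi = length - primer_len - 3
    positions: list[int] = []
    while len(positions) < n_cpgs:
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) >= 3 for q in positions):
            positions.append(p)
    positions.sort()
    seq = list(_random_bases(rng, length))
    for p in positions:
        seq[p] = "C"
        seq[p + 1] = "G"
    chosen = set(positions)
    while True:
        extra = [p for p in scan_cpg_sites("".join(seq)) if p not in chosen]
        if not extra:
            break
        for p in extra:
            seq[p + 1] = "A"
    genomic = "".join(seq)
    primer_fwd = _random_bases(rng, primer_len)
    primer_rev = _random_bases(rng, primer_len)
    return AmpliconTemplate(
        name=name,
        genomic_seq=genomic,
        cpg_positions=tuple(positions),
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
    )


def table1_panel(seed: int = 0) -> list[AmpliconTemplate]:
    """Three synthetic amplicons matching the study geometry:
    551 bp / 10 CpGs, 405 bp / 15 CpGs and 401 bp / 10 CpGs."""
    geometry: Sequence[tuple[str, int, int]] = (
        ("amp551", 551, 10),
        ("amp405", 405, 15),
        ("amp401", 401, 10),
    )
    return [
        synthetic_template(name, length, n_cpgs, seed=seed + i)
        for i, (name, length, n_cpgs) in enumerate(geometry)
    ]
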