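"""Bisulfite-aware pairwise alignment of reads to a converted amplicon template.

Semi-global (free end gaps on the read) affine-gap alignment with asymmetric
scoring: a read T aligned to a template C counts as a match, because bisulfite
conversion turns unmethylated C into T on the sequenced strand. Scoring is
match +2, mismatch -3, gap open -5, gap extend -2 (a gap of length k costs
5 + 2k). Traceback ties prefer diagonal, then up (read base inserted), then
left (read gap), so alignments are deterministic.

Amplicon reads are primer-anchored, so their register on the template is known
up front; the pipeline therefore runs the same dynamic program inside a
diagonal band and falls back to the full matrix whenever the traceback touches
the band edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "MATCH",
    "MISMATCH",
    "GAP_OPEN",
    "GAP_EXTEND",
    "Alignment",
    "encode",
    "decode",
    "align_codes",
    "align_read",
]

MATCH = 2
MISMATCH = -3
GAP_OPEN = 5  # positive costs; first gap column scores -(GAP_OPEN + GAP_EXTEND)
GAP_EXTEND = 2

_NEG = -(2**30)

# op codes in traceback output
OP_DIAG = 0  # read base aligned to template base
OP_INS = 1  # read base inserted (gap in template row)
OP_DEL = 2  # read gap (template base skipped)

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=N=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


@njit(cache=True)
def _gotoh(read, tmpl, diag, halfw):  # pragma: no cover - exercised via wrapper
    # Band-compressed storage: template column j of read row i lives at
    # band index jj = j - (i + diag) + halfw. Diagonal moves keep jj,
    # left moves (read gap) go to jj-1, up moves (insertion) to jj+1.
    n = read.shape[0]
    m = tmpl.shape[0]
    go = GAP_OPEN
    ge = GAP_EXTEND
    w = halfw
    W = 2 * w + 1

    M = np.full((n + 1, W), _NEG, dtype=np.int32)
    X = np.full((n + 1, W), _NEG, dtype=np.int32)  # gap in read (left)
    Y = np.full((n + 1, W), _NEG, dtype=np.int32)  # gap in template (up)
    pm = np.zeros((n + 1, W), dtype=np.uint8)
    px = np.zeros((n + 1, W), dtype=np.uint8)
    py = np.zeros((n + 1, W), dtype=np.uint8)

    for jj in range(W):
        j = diag + jj - w
        if 0 <= j <= m:
            M[0, jj] = 0  # leading template columns are free for the read

    for i in range(1, n + 1):
        jj0 = -(i + diag) + w  # band index of template column 0
        if 0 <= jj0 < W:
            Y[i, jj0] = -(go + ge * i)  # read overhang before the template
            py[i, jj0] = 1
        r = read[i - 1]
        base = i + diag - w
        for jj in range(W):
            j = base + jj
            if j < 1 or j > m:
                continue
            t = tmpl[j - 1]
            if (r == t or (r == 3 and t == 1)) and r != 4:
                sc = MATCH
            else:
                sc = MISMATCH
            # M from (i-1, j-1) -> same jj; prefer M(0), Y(1), X(2) on ties
            best = M[i - 1, jj]
            ptr = 0
            if Y[i - 1, jj] > best:
                best = Y[i - 1, jj]
                ptr = 1
            if X[i - 1, jj] > best:
                best = X[i - 1, jj]
                ptr = 2
            if best > _NEG // 2:
                M[i, jj] = best + sc
                pm[i, jj] = ptr
            # X from (i, j-1) -> jj-1
            if jj > 0:
                best = M[i, jj - 1] - go - ge
                ptr = 0
                if Y[i, jj - 1] - go - ge > best:
                    best = Y[i, jj - 1] - go - ge
                    ptr = 1
                if X[i, jj - 1] - ge > best:
                    best = X[i, jj - 1] - ge
                    ptr = 2
                if best > _NEG // 2:
                    X[i, jj] = best
                    px[i, jj] = ptr
            # Y from (i-1, j) -> jj+1
            if jj + 1 < W:
                best = M[i - 1, jj + 1] - go - ge
                ptr = 0
                if Y[i - 1, jj + 1] - ge > best:
                    best = Y[i - 1, jj + 1] - ge
                    ptr = 1
                if X[i - 1, jj + 1] - go - ge > best:
                    best = X[i - 1, jj + 1] - go - ge
                    ptr = 2
                if best > _NEG // 2:
                    Y[i, jj] = best
                    py[i, jj] = ptr

    # trailing template columns are free: best score over row n, states M/Y,
    # smallest j (ascending jj) and M before Y on ties
    score = _NEG
    endjj = 0
    state = 0
    for jj in range(W):
        j = n + diag + jj - w
        if j < 0 or j > m:
            continue
        if M[n, jj] > score:
            score = M[n, jj]
            endjj = jj
            state = 0
        if Y[n, jj] > score:
            score = Y[n, jj]
            endjj = jj
            state = 1

    ops = np.empty(n + m + 2, dtype=np.int8)
    k = ops.shape[0]
    i = n
    jj = endjj
    endj = n + diag + endjj - w
    touched = 0
    while i > 0:
        if jj == 0 or jj == W - 1:
            touched = 1
        k -= 1
        if state == 0:
            ops[k] = OP_DIAG
            ptr = pm[i, jj]
            i -= 1
        elif state == 1:
            ops[k] = OP_INS
            ptr = py[i, jj]
            i -= 1
            jj += 1
        else:
            ops[k] = OP_DEL
            ptr = px[i, jj]
            jj -= 1
        # pointer encodes predecessor state: 0=M, 1=Y, 2=X
        if ptr == 0:
            state = 0
        elif ptr == 1:
            state = 1
        else:
            state = 2
    startj = i + diag + jj - w
    return score, ops[k:], startj, endj, touched


@dataclass(frozen=True)
class Alignment:
    """Result of aligning a read to a template.

    ``ops`` is the column-level cigar over the read's aligned span:
    0 = read base on template base, 1 = read base inserted, 2 = read gap.
    ``start_j``/``end_j`` delimit the template span (0-based half-open).
    """

    score: int
    start_j: int
    end_j: int
    ops: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.ops)


def align_codes(
    read: np.ndarray,
    tmpl: np.ndarray,
    diag: int = 0,
    halfw: int | None = None,
) -> Alignment:
    """Align encoded read to encoded template; optionally inside a band.

    ``diag`` is the expected template offset of read position 0; ``halfw`` the
    band half-width. As with any banded dynamic program, the band must contain
    the optimal path's diagonal: amplicon reads are primer-anchored so their
    register is known. A banded traceback that touches the band edge (a band
    too narrow for the read's indels) is recomputed on the full matrix.
    """
    if len(read) == 0 or len(tmpl) == 0:
        raise ValueError("align_codes requires nonempty sequences")
    n, m = len(read), len(tmpl)
    # a band centred on (m-n)//2 with half-width (n+m)//2 + 3 covers the
    # whole matrix: this is the "full" (unbanded) configuration
    full_diag = (m - n) // 2
    full_w = (n + m) // 2 + 3
    if halfw is None:
        score, ops, start_j, end_j, _ = _gotoh(read, tmpl, full_diag, full_w)
    else:
        score, ops, start_j, end_j, touched = _gotoh(read, tmpl, int(diag), int(halfw))
        if touched:
            score, ops, start_j, end_j, _ = _gotoh(read, tmpl, full_diag, full_w)
    return Alignment(score=int(score), start_j=int(start_j), end_j=int(end_j), ops=np.asarray(ops))


def align_read(read_seq: str, converted_template: str) -> tuple[str, str]:
    """Global alignment with free end gaps on the read, as two gapped strings.

    Free end columns are shown as ``-`` in the read row; internal gaps in
    either row come out of the affine dynamic program.
    """
    aln = align_codes(encode(read_seq), encode(converted_template))
    return gapped_strings(aln, read_seq, converted_template)


def gapped_strings(aln: Alignment, read_seq: str, template_seq: str) -> tuple[str, str]:
    """Expand an :class:`Alignment` into (gapped_read, gapped_template)."""
    rrow = ["-" * aln.start_j]
    trow = [template_seq[: aln.start_j]]
    i = 0
    j = aln.start_j
    for op in aln.ops:
        if op == OP_DIAG:
            rrow.append(read_seq[i])
            trow.append(template_seq[j])
            i += 1
            j += 1
        elif op == OP_INS:
            rrow.append(read_seq[i])
            trow.append("-")
            i += 1
        else:
            rrow.append("-")
            trow.append(template_seq[j])
            j += 1
    rrow.append("-" * (len(template_seq) - aln.end_j))
    trow.append(template_seq[aln.end_j :])
    return "".join(rrow), "".join(trow)


def alignment_score(read_seq: str, converted_template: str) -> int:
    """Optimal alignment score under the bisulfite-aware scoring scheme."""
    return align_codes(encode(read_seq), encode(converted_template)).score
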