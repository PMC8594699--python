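"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: the aligner oracle is a
plain recursion with memoisation, the mixture oracle a generic constrained
optimizer, and the set oracle exhaustive membership enumeration.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

MATCH = 2
MISMATCH = -3
GAP_OPEN = 5
GAP_EXTEND = 2


def brute_force_align_score(read: str, tmpl: str) -> int:
    """Optimal bisulfite-aware semi-global score by naive recursion.

    Free end gaps on the read (leading/trailing template columns cost 0);
    affine gaps, gap of length k costs GAP_OPEN + k*GAP_EXTEND; read T on
    template C is a match.
    """
    n, m = len(read), len(tmpl)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == n:
            return 0.0  # trailing template columns are free
        best = float("-inf")
        if j < m:
            r, t = read[i], tmpl[j]
            s = MATCH if (r == t or (r == "T" and t == "C")) else MISMATCH
            best = max(best, s + rec(i + 1, j + 1, "M"))
            cost = GAP_EXTEND if prev == "X" else GAP_OPEN + GAP_EXTEND
            best = max(best, -cost + rec(i, j + 1, "X"))
        cost = GAP_EXTEND if prev == "Y" else GAP_OPEN + GAP_EXTEND
        best = max(best, -cost + rec(i + 1, j, "Y"))
        return best

    return int(max(rec(0, j, "start") for j in range(m + 1)))


def brute_force_mixture_ml(
    patterns: list[str],
    counts: np.ndarray,
    e01: float,
    e10: float,
) -> np.ndarray:
    """Maximum-likelihood mixture weights by SLSQP on the simplex."""
    B = np.asarray([[c == "1" for c in p] for p in patterns], dtype=float)
    n11 = B @ B.T
    n10 = B @ (1 - B).T
    n01 = (1 - B) @ B.T
    n00 = (1 - B) @ (1 - B).T
    P = (
        np.power(1 - e10, n11)
        * np.power(e10, n10)
        * np.power(e01, n01)
        * np.power(1 - e01, n00)
    )

    def negll(theta):
        mix = theta @ P
        return -np.dot(counts, np.log(np.maximum(mix, 1e-300)))

    k = len(patterns)
    best = None
    for start in range(3):  # a few starts to dodge local issues
        rng = np.random.default_rng(start)
        x0 = counts / counts.sum() if start == 0 else rng.dirichlet(np.ones(k))
        res = minimize(
            negll,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda t: t.sum() - 1.0}],
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.clip(best.x, 0.0, None)
    return theta / theta.sum()


def mixture_loglik(patterns: list[str], counts: np.ndarray, theta: np.ndarray,
                   e01: float, e10: float) -> float:
    B = np.asarray([[c == "1" for c in p] for p in patterns], dtype=float)
    P = (
        np.power(1 - e10, B @ B.T)
        * np.power(e10, B @ (1 - B).T)
        * np.power(e01, (1 - B) @ B.T)
        * np.power(1 - e01, (1 - B) @ (1 - B).T)
    )
    return float(np.dot(counts, np.log(theta @ P)))


def exhaustive_venn(sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Region counts by enumerating every element's membership vector."""
    names = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            key = frozenset(combo)
            count = 0
            for el in set().union(*sets.values()):
                if all(el in sets[c] for c in combo) and not any(
                    el in sets[c] for c in names if c not in combo
                ):
                    count += 1
            out[key] = count
    return out


def scan_cg_dinucleotides(seq: str) -> list[int]:
    """Positionwise dinucleotide scan (oracle for CpG discovery)."""
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]
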