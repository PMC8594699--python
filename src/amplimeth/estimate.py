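"""Pattern-frequency estimation under an explicit bisulfite/sequencing error model.

Observed per-read patterns are modelled as draws from a multinomial mixture:
a molecule carries a true pattern t with frequency theta_t, and each CpG site
is read independently with asymmetric flip probabilities

    p(observe 1 | true 0) = f(1-m) + (1-f)m      (non-conversion or miscall)
    p(observe 0 | true 1) = g(1-m) + (1-g)m      (over-conversion or miscall)

where f is the bisulfite non-conversion rate, g the over-conversion rate and
m the per-base substitution rate. Mixture weights over the observed-pattern
support are fitted by EM (maximum likelihood).

Spurious-pattern elimination runs in two stages. First a frequency floor
(default 10/n_reads) removes patterns too rare to report, iterating removal
and renormalization to a fixed point. A floor alone is not enough: mixture
weights live on the simplex boundary, so sampling noise leaves genuinely
spurious patterns (single-site error neighbours of dominant epialleles) with
small positive maximum-likelihood weight, often above any sensible floor.
Every surviving low-frequency pattern is therefore also tested by a profile
likelihood ratio: the mixture is refitted without it, and the pattern is kept
only when twice the log-likelihood drop exceeds a BIC penalty (ln n_reads),
with backward elimination from the weakest pattern upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("amplimeth")

from .patterns import PatternCountTable

__all__ = [
    "ErrorModel",
    "PatternDistribution",
    "estimate_distribution",
    "apply_cutoff",
    "write_distribution_tsv",
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-site error rates of the observation process.

    f_nonconv: probability an unmethylated CpG C escapes conversion (read C).
    g_overconv: probability a methylated CpG C is converted anyway (read T).
    m_subst: per-base sequencing substitution probability.
    r_indel: per-base sequencing indel probability (simulator only; indels are
        absorbed by the alignment/filter stages, not by this estimator).
    nonCpG_fail: probability a non-CpG C escapes conversion (simulator only).
    """

    f_nonconv: float = 0.0
    g_overconv: float = 0.0
    m_subst: float = 0.0
    r_indel: float = 0.0
    nonCpG_fail: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_nonconv", "g_overconv", "m_subst", "r_indel", "nonCpG_fail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def default(cls) -> "ErrorModel":
        """Plausible post-double-conversion MiSeq magnitudes."""
        return cls(
            f_nonconv=0.005,
            g_overconv=0.005,
            m_subst=0.003,
            r_indel=0.0005,
            nonCpG_fail=0.002,
        )

    @property
    def p_false_methylated(self) -> float:
        """p(observe 1 | true 0)."""
        return self.f_nonconv * (1 - self.m_subst) + (1 - self.f_nonconv) * self.m_subst

    @property
    def p_false_unmethylated(self) -> float:
        """p(observe 0 | true 1)."""
        return self.g_overconv * (1 - self.m_subst) + (1 - self.g_overconv) * self.m_subst


@dataclass
class PatternDistribution:
    """Estimated true pattern frequencies for one amplicon x sample."""

    amplicon: str
    sample: str
    freqs: dict[str, float]
    error_model: ErrorModel
    n_reads: int
    support_cut: float
    n_iter: int = 0
    converged: bool = True
    grad_norm: float | None = None  # set when EM stopped at max_iter
    log_likelihood: float = float("nan")
    ll_trace: list[float] = field(default_factory=list, repr=False)
    observed_counts: dict[str, int] = field(default_factory=dict, repr=False)

    def sorted_items(self) -> list[tuple[str, float]]:
        return sorted(self.freqs.items(), key=lambda kv: (-kv[1], kv[0]))


def _pattern_matrix(patterns: Sequence[str]) -> np.ndarray:
    return np.asarray([[c == "1" for c in p] for p in patterns], dtype=float)


def _log_emission(patterns: Sequence[str], error_model: ErrorModel) -> np.ndarray:
    """log P(observed o | true t) for every (t, o) pair over the support."""
    B = _pattern_matrix(patterns)  # S x J
    e01 = error_model.p_false_methylated
    e10 = error_model.p_false_unmethylated
    with np.errstate(divide="ignore"):
        l01 = np.log(e01) if e01 > 0 else -np.inf
        l10 = np.log(e10) if e10 > 0 else -np.inf
        l00 = np.log1p(-e01)
        l11 = np.log1p(-e10)
    n11 = B @ B.T  # sites true 1, observed 1 (rows t, cols o)
    n10 = B @ (1 - B).T
    n01 = (1 - B) @ B.T
    n00 = (1 - B) @ (1 - B).T
    logP = n11 * l11 + n00 * l00
    # 0 * -inf must contribute 0 (no flipped site), not nan
    if np.isneginf(l10):
        logP = np.where(n10 > 0, -np.inf, logP)
    else:
        logP = logP + n10 * l10
    if np.isneginf(l01):
        logP = np.where(n01 > 0, -np.inf, logP)
    else:
        logP = logP + n01 * l01
    return logP


def _em(
    counts: np.ndarray,
    logP: np.ndarray,
    theta0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[float], bool]:
    """Multinomial-mixture EM over a fixed support; returns theta, ll trace."""
    n = counts.sum()
    theta = theta0.copy()
    trace: list[float] = []
    converged = False
    tiny = np.finfo(float).tiny
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            log_theta = np.log(np.maximum(theta, tiny))
        A = logP + log_theta[:, None]  # S x O
        Amax = A.max(axis=0)
        with np.errstate(invalid="ignore"):  # -inf - -inf when a column is
            Z = np.exp(A - Amax)  # unexplainable by a reduced support
            denom = Z.sum(axis=0)
            ll = float(np.dot(counts, np.log(denom) + Amax))
        if not np.isfinite(ll):
            # a reduced support may assign an observed pattern zero probability
            trace.append(ll)
            break
        if trace and ll < trace[-1] - 1e-8 * (1.0 + abs(ll)):
            # EM guarantees monotonicity up to floating-point round-off
            raise AssertionError(f"log-likelihood decreased: {trace[-1]} -> {ll}")
        done = bool(trace) and abs(ll - trace[-1]) <= tol
        trace.append(ll)
        if done:
            converged = True
            break
        resp = Z / denom  # responsibilities per observed pattern
        theta = (resp @ counts) / n
    return theta, trace, converged


def _floor_eliminate(theta: np.ndarray, keep: np.ndarray, support_cut: float) -> np.ndarray:
    """Drop sub-threshold patterns and renormalize, iterating to a fixed point."""
    while True:
        masked = np.where(keep, theta, 0.0)
        total = masked.sum()
        if total <= 0:
            # keep the single best-supported pattern rather than return nothing
            keep[:] = False
            keep[int(np.argmax(theta))] = True
            masked = np.where(keep, theta, 0.0)
            total = masked.sum()
        norm = masked / total
        below = keep & (norm < support_cut)
        if not below.any() or keep.sum() == 1:
            return norm
        keep &= ~below


def estimate_distribution(
    table: PatternCountTable,
    error_model: ErrorModel,
    support_cut: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    lrt_penalty: float | None = None,
) -> PatternDistribution:
    """Maximum-likelihood pattern frequencies with spurious-pattern elimination.

    The candidate support is the set of observed patterns; EM starts from the
    empirical frequencies and runs to a log-likelihood tolerance of ``tol``.
    Elimination then proceeds in two stages: patterns estimated below
    ``support_cut`` (default 10/n_reads) are removed and the remainder
    renormalized to a fixed point; surviving patterns below 5% are then tested
    by a profile likelihood ratio against ``lrt_penalty`` (default ln n_reads,
    the BIC penalty for one extra mixture component; pass 0 to disable),
    removing the weakest non-significant pattern and refitting until all
    retained patterns are supported. With all error rates zero the emission
    matrix is the identity and the estimate equals the empirical frequencies
    (every observed pattern is its own proof of existence).
    """
    if table.n_called <= 0 or not table.counts:
        raise ValueError("cannot estimate a distribution from an empty table")
    if error_model.p_false_methylated >= 0.5 or error_model.p_false_unmethylated >= 0.5:
        raise ValueError("per-site flip probabilities must be < 0.5")
    patterns = [p for p, _ in sorted(table.counts.items())]
    counts = np.asarray([table.counts[p] for p in patterns], dtype=float)
    n = counts.sum()
    if support_cut is None:
        support_cut = 10.0 / n
    if lrt_penalty is None:
        lrt_penalty = float(np.log(n))
    theta0 = counts / n
    logP = _log_emission(patterns, error_model)
    theta, trace, converged = _em(counts, logP, theta0, tol, max_iter)
    grad_norm = None
    if not converged:
        # report how far from stationarity the returned fit is
        with np.errstate(invalid="ignore"):
            mix = np.exp(logP).T @ theta
            grad = np.exp(logP) @ (counts / np.maximum(mix, np.finfo(float).tiny)) - n
        grad_norm = float(np.linalg.norm(grad))
        logger.warning(
            "EM did not converge for %s/%s after %d iterations (|grad|=%.3g); "
            "returning the final iterate",
            table.amplicon, table.sample, len(trace), grad_norm,
        )

    def _fit(mask: np.ndarray, init: np.ndarray) -> tuple[float, np.ndarray]:
        """Refit EM restricted to *mask*; returns (ll, full-length theta)."""
        idx = np.flatnonzero(mask)
        init_sub = init[idx] / init[idx].sum()
        theta_sub, trace_sub, _ = _em(counts, logP[idx, :], init_sub, tol, max_iter)
        full = np.zeros(len(patterns))
        full[idx] = theta_sub
        return trace_sub[-1], full

    keep = np.ones(len(patterns), dtype=bool)
    norm = _floor_eliminate(theta, keep, support_cut)
    if keep.all():
        ll_ref = trace[-1]
    else:
        ll_ref, theta_k = _fit(keep, norm)
        norm = _floor_eliminate(theta_k, keep, support_cut)

    # profile-LRT backward elimination of boundary-noise survivors: the
    # reference fit and each drop-one fit share the reduced support, so the
    # statistic is the genuine profile likelihood ratio for one component
    lrt_ceiling = 0.05  # patterns at >=5% are never spurious at these depths
    while lrt_penalty > 0 and keep.sum() > 1:
        order = sorted(np.flatnonzero(keep), key=lambda i: norm[i])
        removed = False
        for i in order:
            if norm[i] >= lrt_ceiling:
                break
            sub = keep.copy()
            sub[i] = False
            ll_sub, theta_sub = _fit(sub, np.where(sub, norm, 0.0))
            if 2.0 * (ll_ref - ll_sub) < lrt_penalty:
                keep = sub
                norm = _floor_eliminate(theta_sub, keep, support_cut)
                if not np.array_equal(np.flatnonzero(keep), np.flatnonzero(sub)):
                    ll_sub, theta_sub = _fit(keep, norm)
                    norm = _floor_eliminate(theta_sub, keep, support_cut)
                ll_ref = ll_sub
                removed = True
                break
        if not removed:
            break
    freqs = {p: float(norm[i]) for i, p in enumerate(patterns) if keep[i]}
    return PatternDistribution(
        amplicon=table.amplicon,
        sample=table.sample,
        freqs=freqs,
        error_model=error_model,
        n_reads=int(n),
        support_cut=float(support_cut),
        n_iter=len(trace),
        converged=converged,
        grad_norm=grad_norm,
        log_likelihood=trace[-1],
        ll_trace=trace,
        observed_counts=dict(table.counts),
    )


def apply_cutoff(
    dist: PatternDistribution,
    cutoff: float,
) -> tuple[PatternDistribution, set[str]]:
    """Keep patterns with estimated frequency >= cutoff; do NOT renormalize.

    Returns the filtered distribution (original frequencies preserved on the
    retained patterns) and the retained-pattern set. Mirrors the minimum-
    frequency cut-offs (1% and 5%) used when reporting and comparing pattern
    sets across conditions.
    """
    if not 0.0 <= cutoff < 1.0:
        raise ValueError(f"cutoff={cutoff} outside [0, 1)")
    retained = {p: f for p, f in dist.freqs.items() if f >= cutoff}
    filtered = PatternDistribution(
        amplicon=dist.amplicon,
        sample=dist.sample,
        freqs=retained,
        error_model=dist.error_model,
        n_reads=dist.n_reads,
        support_cut=dist.support_cut,
        n_iter=dist.n_iter,
        converged=dist.converged,
        log_likelihood=dist.log_likelihood,
        observed_counts=dist.observed_counts,
    )
    return filtered, set(retained)


def write_distribution_tsv(dists: Iterable[PatternDistribution], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("amplicon\tsample\tpattern\test_frequency\tobserved_count\n")
        for d in dists:
            for pattern, freq in d.sorted_items():
                obs = d.observed_counts.get(pattern, 0)
                fh.write(f"{d.amplicon}\t{d.sample}\t{pattern}\t{freq:.8f}\t{obs}\n")
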