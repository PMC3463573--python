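"""Tajima's D and Fu's Fs with coalescent-simulation significance.

Both statistics summarise departure from the neutral, constant-size
coalescent: an excess of low-frequency variants (recent expansion or a
selective sweep) drives D below zero, and an excess of haplotypes given
the observed pairwise diversity drives Fs strongly negative.

P-values come from neutral constant-size coalescent replicates
conditioned on the observed number of segregating sites (mutations are
dropped uniformly on the simulated genealogy), the convention of the
classical population-genetics packages.  A theta-conditioned null
(mutations Poisson with rate theta_pi/2) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .errors import InputError, OverflowStatisticError, UndefinedStatisticError
from .seq_io import Alignment, collapse_haplotypes, pairwise_differences
from . import coalsim


@dataclass(frozen=True)
class NeutralityResult:
    d: float
    fs: float
    p_d: float
    p_fs: float
    n: int
    s: int
    k: int
    theta_pi: float  # mean pairwise differences per pair (per sequence, not per site)
    reps: int
    seed: int
    tail: str  # convention used for D's p-value


def _summaries(aln: Alignment) -> tuple[int, int, int, float]:
    n = aln.n
    diffs = pairwise_differences(aln)
    iu = np.triu_indices(n, k=1)
    theta_pi = float(diffs[iu].mean())
    # S on retained columns, consistent with the distances above
    from .diversity import segregating_sites

    s = segregating_sites(aln)
    k = collapse_haplotypes(aln).k
    return n, s, k, theta_pi


def tajimas_d_from_summary(n: int, s: int, theta_pi: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs."""
    if n < 2:
        raise InputError("Tajima's D requires n >= 2")
    if s < 1:
        raise UndefinedStatisticError("Tajima's D is undefined when S = 0")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    num = theta_pi - s / a1
    if var <= 0.0:
        # n = 2: the variance constants vanish and theta_pi == S, so D == 0
        if abs(num) < 1e-9:
            return 0.0
        raise UndefinedStatisticError("variance of D is zero but numerator is not")
    return float(num / math.sqrt(var))


def tajimas_d(aln: Alignment) -> float:
    n, s, _, theta_pi = _summaries(aln)
    return tajimas_d_from_summary(n, s, theta_pi)


@lru_cache(maxsize=64)
def log_stirling_first_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k = 0..n."""
    cur = np.array([-np.inf, 0.0])  # n = 1: |s(1,1)| = 1
    for m in range(1, n):
        nxt = np.full(m + 2, -np.inf)
        # |s(m+1, k)| = m * |s(m, k)| + |s(m, k-1)|
        nxt[1:] = np.logaddexp(np.log(m) + np.pad(cur[1:], (0, 1), constant_values=-np.inf),
                               cur)
        cur = nxt
    return cur if n > 1 else np.array([-np.inf, 0.0])


def ewens_log_probs(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise UndefinedStatisticError("Ewens distribution requires theta > 0")
    ls = log_stirling_first_row(n)
    k = np.arange(n + 1)
    log_denom = float(np.sum(np.log(theta + np.arange(n))))
    with np.errstate(divide="ignore"):
        return ls + k * math.log(theta) - log_denom


def fu_fs_from_summary(n: int, k: int, theta_pi: float) -> float:
    """Fu's Fs = logit of Pr(K >= k_obs | theta = theta_pi) under Ewens sampling."""
    if n < 2 or not 1 <= k <= n:
        raise InputError(f"invalid haplotype count k={k} for n={n}")
    if theta_pi <= 0:
        raise UndefinedStatisticError("Fu's Fs is undefined when theta_pi = 0")
    logp = ewens_log_probs(n, theta_pi)
    log_sp = float(logsumexp(logp[k:]))  # Pr(K >= k)
    log_one_minus = float(logsumexp(logp[1:k])) if k > 1 else -np.inf
    if not np.isfinite(log_one_minus):
        raise OverflowStatisticError(
            f"S' = 1 exactly (k = {k}): Fs diverges to +infinity"
        )
    if not np.isfinite(log_sp):
        raise OverflowStatisticError("S' underflowed to 0: Fs diverges to -infinity")
    return log_sp - log_one_minus


def fu_fs(aln: Alignment) -> float:
    n, _, k, theta_pi = _summaries(aln)
    return fu_fs_from_summary(n, k, theta_pi)


def neutrality_significance(
    aln: Alignment,
    reps: int = 10_000,
    seed: int = 0,
    tail: str = "auto",
    conditioning: str = "fixed_S",
) -> NeutralityResult:
    """Observed D and Fs with p-values from neutral coalescent replicates.

    ``tail`` controls D's p-value: "auto" takes the tail on the side of the
    observed value (lower tail if D_obs <= 0), "lower"/"upper" fix the tail.
    Fs's p-value is always Pr(Fs_sim <= Fs_obs), the convention under which
    small values support expansion.
    """
    if reps < 100:
        raise InputError("need at least 100 replicates")
    if tail not in ("auto", "lower", "upper"):
        raise InputError(f"unknown tail convention {tail!r}")
    n, s, k, theta_pi = _summaries(aln)
    d_obs = tajimas_d_from_summary(n, s, theta_pi)
    fs_obs = fu_fs_from_summary(n, k, theta_pi)
    d_sim, fs_sim = simulate_null_d_fs(
        n, s, reps, seed, conditioning=conditioning, theta=theta_pi
    )
    if tail == "auto":
        tail_used = "lower" if d_obs <= 0 else "upper"
    else:
        tail_used = tail
    if tail_used == "lower":
        p_d = float(np.mean(d_sim <= d_obs))
    else:
        p_d = float(np.mean(d_sim >= d_obs))
    p_fs = float(np.mean(fs_sim <= fs_obs))
    return NeutralityResult(
        d=d_obs, fs=fs_obs, p_d=p_d, p_fs=p_fs, n=n, s=s, k=k,
        theta_pi=theta_pi, reps=reps, seed=seed, tail=tail_used,
    )


def simulate_null_d_fs(
    n: int,
    s: int,
    reps: int,
    seed: int | np.random.Generator,
    conditioning: str = "fixed_S",
    theta: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null distributions of (D, Fs) under the constant-size coalescent.

    fixed_S drops exactly ``s`` mutations uniformly on each genealogy;
    theta conditioning draws Poisson(theta/2 * tree length) mutations and
    redraws the (logged) replicates that come out monomorphic.
    """
    rng = coalsim._as_rng(seed)
    d_sim = np.empty(reps)
    fs_sim = np.empty(reps)
    redraws = 0
    for r in range(reps):
        while True:
            if conditioning == "fixed_S":
                pi, k, s_r = coalsim.simulate_pi_k_s(n, s, rng)
            else:
                gen = coalsim.simulate_genealogy(n, coalsim.Demography.constant(theta), rng)
                s_r = rng.poisson(theta / 2.0 * gen.total_length)
                if s_r >= 1:
                    branches = coalsim._place_mutations(gen, theta, rng, "fixed_S", s_r)
                    counts = gen.leaf_counts()[branches]
                    pi = float((counts * (n - counts)).sum() / (n * (n - 1) / 2.0))
                    k = _k_from_placements(gen, branches)
            if conditioning == "fixed_S" or s_r >= 1:
                break
            redraws += 1
        d_sim[r] = tajimas_d_from_summary(n, s_r, pi)
        fs_sim[r] = fu_fs_from_summary(n, k, pi) if pi > 0 else np.inf
    return d_sim, fs_sim


def _k_from_placements(gen: coalsim.Genealogy, branches: np.ndarray) -> int:
    muts: list[tuple[int, ...]] = [() for _ in range(2 * gen.n - 1)]
    for m, v in enumerate(branches):
        muts[v] = muts[v] + (m,)
    sig = {gen.root: frozenset()}
    children = gen.children()
    stack = [gen.root]
    for v in stack:
        for ch in children[v]:
            sig[ch] = sig[v] | frozenset(muts[ch])
            stack.append(ch)
    return len({sig[i] for i in range(gen.n)})
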