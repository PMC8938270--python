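"""Independent brute-force oracles used to validate the dynamic-programming
implementations on small instances. These enumerate state paths / phase
configurations explicitly and never share code with the package's
forward-backward, Viterbi or chained-pairwise routines."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def enumerate_hmm(log_pi: np.ndarray, log_trans: list[np.ndarray], log_emis: np.ndarray):
    """Exhaustive enumeration over all S^n hidden-state paths.

    Returns (total log-likelihood, best-path log score, per-site marginal
    posteriors of shape (n, S)).
    """
    n, n_states = log_emis.shape
    ll = log_pi + log_emis[0]  # one entry per path, last state = index % S
    for i in range(1, n):
        last = np.arange(len(ll)) % n_states
        ll = (ll[:, None] + log_trans[i - 1][last, :] + log_emis[i][None, :]).ravel()
    total = float(logsumexp(ll))
    best = float(ll.max())
    grid = ll.reshape((n_states,) * n)
    marginals = np.stack(
        [
            np.exp(
                logsumexp(grid, axis=tuple(j for j in range(n) if j != i)) - total
            )
            for i in range(n)
        ]
    )
    return total, best, marginals


def _chain_loglik(
    hap1_alleles: np.ndarray,
    calls: np.ndarray,
    other_dists: np.ndarray,
    switch_probs: np.ndarray,
    emission_matrix: np.ndarray,
) -> float:
    """Log-likelihood of one embryo's calls at the target parent's het sites
    given a phase configuration, by explicit enumeration of the 2^n
    transmitted-haplotype paths (uniform start, per-gap switch probability,
    other parent's transmitted allele marginalized per site)."""
    n = len(hap1_alleles)
    chan = np.where(calls < 0, 3, calls)
    # emission of each (site, transmitted hap h) pair
    site_lik = np.empty((n, 2))
    for i in range(n):
        for h in (0, 1):
            allele = hap1_alleles[i] if h == 0 else 1 - hap1_alleles[i]
            site_lik[i, h] = (
                other_dists[i, 0] * emission_matrix[allele + 0, chan[i]]
                + other_dists[i, 1] * emission_matrix[allele + 1, chan[i]]
            )
    total = 0.0
    for bits in range(2 ** n):
        path = [(bits >> i) & 1 for i in range(n)]
        p = 0.5 * site_lik[0, path[0]]
        for i in range(1, n):
            r = switch_probs[i - 1]
            p *= (r if path[i] != path[i - 1] else 1 - r) * site_lik[i, path[i]]
        total += p
    return float(np.log(total))


def global_ml_phase(
    calls_per_embryo: np.ndarray,
    other_dists: np.ndarray,
    switch_probs: np.ndarray,
    emission_matrix: np.ndarray,
) -> np.ndarray:
    """Maximum-likelihood phase configuration over ALL 2^(n-1) configurations
    (first site's hap-1 allele fixed to 0), maximizing the product of embryo
    chain likelihoods. ``calls_per_embryo`` has shape (n_embryos, n_sites)."""
    n = calls_per_embryo.shape[1]
    best, best_cfg = -np.inf, None
    for bits in range(2 ** (n - 1)):
        cfg = np.array([0] + [(bits >> i) & 1 for i in range(n - 1)], dtype=np.int8)
        ll = sum(
            _chain_loglik(cfg, calls, other_dists, switch_probs, emission_matrix)
            for calls in calls_per_embryo
        )
        if ll > best:
            best, best_cfg = ll, cfg
    return best_cfg
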