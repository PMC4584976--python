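"""Independent oracles used to cross-check the analytic likelihood machinery.

Everything here is implemented from the model definition alone, without
calling the package's probability code: genealogies are sampled directly
from the structured coalescent and configuration probabilities estimated as
Monte-Carlo averages of Poisson likelihoods.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import poisson


def mc_branch_lengths(theta_t1_t2: tuple[float, float, float], n: int, seed: int) -> np.ndarray:
    """Sample (n, 3) unrooted branch lengths (l_a, l_b, l_c).

    Backwards in time: b and c may coalesce on [t1, t1+t2] at rate 1; at
    t1+t2 surviving lineages enter the ancestral population (first of three
    pairs at rate 3, uniform pair; final pair rate 1).  The first coalescence
    at time u and the last at w give lengths u, u and 2w - u.
    """
    _, t1, t2 = theta_t1_t2
    rng = np.random.default_rng(seed)
    x = rng.exponential(size=n)
    bc_early = x < t2
    u = np.where(bc_early, t1 + x, t1 + t2 + rng.exponential(size=n) / 3.0)
    w = np.where(bc_early, t1 + t2 + rng.exponential(size=n), u + rng.exponential(size=n))
    pair = np.where(bc_early, 2, rng.integers(0, 3, size=n))  # 0=(a,b) 1=(a,c) 2=(b,c)
    long_branch = 2.0 * w - u
    la = np.where(pair == 2, long_branch, u)
    lb = np.where(pair == 1, long_branch, u)
    lc = np.where(pair == 0, long_branch, u)
    return np.column_stack([la, lb, lc])


def mc_config_probability(
    params: tuple[float, float, float],
    config: tuple[int, int, int],
    n_draws: int,
    seed: int,
    lengths: np.ndarray | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of a config probability.

    Averages the product of Poisson pmfs (mean theta/2 * branch length) over
    simulated genealogies; ``lengths`` lets one batch of genealogy draws be
    reused across configurations at the same parameters.
    """
    theta = params[0]
    if lengths is None:
        lengths = mc_branch_lengths(params, n_draws, seed)
    m = theta / 2.0
    vals = (
        poisson.pmf(config[0], m * lengths[:, 0])
        * poisson.pmf(config[1], m * lengths[:, 1])
        * poisson.pmf(config[2], m * lengths[:, 2])
    )
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))


def mc_expected_delta_lnl(
    p_full_fn,
    p_nested_fn,
    params: tuple[float, float, float],
    n_loci: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo mean (and SE) of per-locus lnL differences.

    Simulates loci from the generating model (genealogy + Poisson mutation
    counts) and averages ln p_full(x) - ln p_nested(x) using the supplied
    probability callables.
    """
    theta = params[0]
    rng = np.random.default_rng(seed)
    lengths = mc_branch_lengths(params, n_loci, seed + 1)
    counts = rng.poisson(theta / 2.0 * lengths)
    uniq, mult = np.unique(counts, axis=0, return_counts=True)
    diffs = np.array(
        [np.log(p_full_fn(tuple(row))) - np.log(p_nested_fn(tuple(row))) for row in uniq]
    )
    per_locus = np.repeat(diffs, mult)
    return float(per_locus.mean()), float(per_locus.std(ddof=1) / np.sqrt(n_loci))
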