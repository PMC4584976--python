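"""Unrooted-triplet coalescent likelihood for three-population divergence.

One haploid (or N-masked consensus) sequence is sampled from each of three
populations.  Under infinite sites every segregating site in the triplet
alignment shows a 2:1 split and therefore isolates exactly one sequence, so
the per-locus data reduce to the counts ``(s_a, s_b, s_c)`` of sites at which
each sequence carries the minority state.  This module computes the exact
probability of such a configuration under a three-population divergence
model, sums log likelihoods across unlinked loci, fits parameters by maximum
likelihood, and compares the full model against its nested simplifications
(two-population, polytomy, panmixia) with likelihood-ratio tests and
profile-likelihood confidence intervals.

Model
-----
Populations are labelled so that ``a`` is the first to diverge.  Backwards in
time, lineages ``b`` and ``c`` may coalesce (pairwise rate 1 in units of
2*Ne* generations) on the interval ``[t1, t1 + t2]``; any lineages surviving
to ``t1 + t2`` enter a single ancestral population where the standard
n-coalescent applies (first of three pairs at total rate 3, uniformly chosen
pair; the final pair at rate 1).  A genealogy whose first coalescence joins
the pair (x, y) at time ``u`` with final coalescence at ``w`` has unrooted
branch lengths ``l_x = l_y = u`` and ``l_z = 2 w - u``; mutation counts on
the three branches are independent Poisson with mean ``(theta / 2) * l``.

The three-lineage ancestral phase integrates in closed form (regularised
incomplete-gamma sums); the intermediate epoch, present only when ``t2 > 0``,
is a one-dimensional integral of a smooth analytic function handled by a
fixed high-order Gauss-Legendre rule.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "TripletConfiguration",
    "DivergenceParams",
    "PopulationModel",
    "MODELS",
    "FitResult",
    "ModelComparison",
    "config_probability",
    "config_probabilities",
    "config_grid",
    "grid_at",
    "log_likelihood",
    "fit_mle",
    "profile_ci",
    "likelihood_ratio_test",
    "compare_models",
    "patterns_from_alignment",
    "read_configs_tsv",
    "write_configs_tsv",
]

_GL_NODES = 96  # Gauss-Legendre order for the intermediate-epoch integral


@functools.lru_cache(maxsize=8)
def _leggauss(order: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(order)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripletConfiguration:
    """Per-locus unrooted site-pattern counts for one sequence per population.

    ``s_a`` counts segregating sites whose minority state is carried by the
    sequence from the first-diverging population, and likewise ``s_b``,
    ``s_c`` for the two recently diverged populations.
    """

    locus_id: str
    s_a: int
    s_b: int
    s_c: int

    def __post_init__(self) -> None:
        for name in ("s_a", "s_b", "s_c"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.s_a, self.s_b, self.s_c)


@dataclass(frozen=True)
class DivergenceParams:
    """Scaled parameters of the three-population divergence model.

    theta
        Per-locus scaled mutation rate 4*Ne*mu, shared by all populations.
    t1
        Split time of the two most recently diverged populations (b, c),
        in units of 2*Ne* generations.
    t2
        Internode distance between that pair's common ancestor and the
        first-diverging population (a), same units.
    """

    theta: float
    t1: float = 0.0
    t2: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be finite and > 0, got {self.theta!r}")
        if not (np.isfinite(self.t1) and self.t1 >= 0):
            raise ValueError(f"t1 must be finite and >= 0, got {self.t1!r}")
        if not (np.isfinite(self.t2) and self.t2 >= 0):
            raise ValueError(f"t2 must be finite and >= 0, got {self.t2!r}")


@dataclass(frozen=True)
class PopulationModel:
    """One of the four nested divergence models.

    The full model frees (theta, t1, t2); the nested simplifications pin
    divergence times to zero: two_population (t1 = 0), polytomy (t2 = 0)
    and panmixia (t1 = t2 = 0).
    """

    name: str
    free_params: tuple[str, ...]
    fixed_zero: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def constrain(self, params: DivergenceParams) -> DivergenceParams:
        """Return a copy of ``params`` with this model's constraints applied."""
        updates = {name: 0.0 for name in self.fixed_zero}
        return replace(params, **updates)

    def is_nested_in(self, other: "PopulationModel") -> bool:
        return set(self.free_params) < set(other.free_params)


MODELS: dict[str, PopulationModel] = {
    "full": PopulationModel("full", ("theta", "t1", "t2"), ()),
    "two_population": PopulationModel("two_population", ("theta", "t2"), ("t1",)),
    "polytomy": PopulationModel("polytomy", ("theta", "t1"), ("t2",)),
    "panmixia": PopulationModel("panmixia", ("theta",), ("t1", "t2")),
}


def _get_model(model: "PopulationModel | str") -> PopulationModel:
    if isinstance(model, PopulationModel):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}") from None


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit of one model to a set of loci."""

    model: PopulationModel
    mle: DivergenceParams
    max_lnl: float
    n_loci: int
    converged: bool
    assignment: tuple[int, int, int] = (0, 1, 2)
    start_lnls: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "theta": self.mle.theta,
            "t1": self.mle.t1,
            "t2": self.mle.t2,
            "max_lnl": self.max_lnl,
            "n_loci": self.n_loci,
            "converged": self.converged,
            "assignment": list(self.assignment),
        }


@dataclass
class ModelComparison:
    """A likelihood-ratio comparison of a nested model against the full model."""

    full: FitResult
    nested: FitResult
    delta_lnl: float
    statistic: float
    df: int
    p_value: float

    @property
    def preferred(self) -> str:
        return self.full.model.name if self.p_value < 0.05 else self.nested.model.name


# ---------------------------------------------------------------------------
# configuration probabilities
# ---------------------------------------------------------------------------

def _validate_params(params: DivergenceParams) -> None:
    for name in ("theta", "t1", "t2"):
        v = getattr(params, name)
        if not np.isfinite(v):
            raise ValueError(f"non-finite parameter {name}={v!r}")


def _log_gammaincc(n_plus_1: np.ndarray, x: float) -> np.ndarray:
    """log of the regularised upper incomplete gamma Q(n+1, x), guarded."""
    q = special.gammaincc(n_plus_1, x)
    with np.errstate(divide="ignore"):
        return np.log(q)


def _ancestral_log_core(np_max: int, sz_max: int, theta: float, t1: float, t2: float) -> np.ndarray:
    """Log contribution of the ancestral (three-lineage) phase.

    Returns ``L2[np_, sz]`` for pair-count sum ``np_ = s_x + s_y`` (the two
    lineages joined by the first coalescence) and third-lineage count ``sz``,
    *excluding* the per-config ``-lgamma(s_x+1) - lgamma(s_y+1)`` terms so a
    single table serves all three pair assignments.

    Derivation: with m = theta/2, c = m + 1/2, A = t1 + t2 and first
    coalescence at u = A + y, y ~ Exp(3) (uniform pair), final at w = u + v,
    v ~ Exp(1), the v-integral gives

        g(s, u) = m^s / (2 c^(s+1)) * exp(-m u) * sum_{k<=s} (c u)^k / k!

    and the y-integral of u^n exp(-3(1+m) y) terms gives regularised upper
    incomplete gammas Q(n+1, 3(1+m) A).
    """
    m = theta / 2.0
    c = m + 0.5
    A = t1 + t2
    B = 3.0 * (1.0 + m) * A
    log_m = math.log(m)
    log_c = math.log(c)
    log_r = math.log(3.0 * (1.0 + m))

    np_ = np.arange(np_max + 1)[:, None]          # (np, 1)
    out = np.full((np_max + 1, sz_max + 1), -np.inf)
    # accumulate over k = 0..sz  (k indexes the incomplete-gamma sum of g)
    for k in range(sz_max + 1):
        n = np_ + k                                # (np, 1)
        term = (
            k * log_c
            - special.gammaln(k + 1)
            + special.gammaln(n + 1.0)
            - (n + 1.0) * log_r
            + _log_gammaincc(n + 1.0, B)
        )                                          # (np, 1)
        # only columns sz >= k receive the k-th term of g's inner sum
        out[:, k:] = np.logaddexp(out[:, k:], np.broadcast_to(term, (np_max + 1, sz_max + 1 - k)))
    S = np_ + np.arange(sz_max + 1)[None, :]
    sz_col = np.arange(sz_max + 1)[None, :]
    out += (
        -t2
        + 3.0 * A
        + math.log(0.5)
        + S * log_m
        - (sz_col + 1.0) * log_c
    )
    return out


def _log_poisson(s: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log Poisson pmf, with the s=0, lam=0 corner equal to 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -lam + s * np.log(lam) - special.gammaln(s + 1.0)
    return np.where((s == 0) & (lam == 0), 0.0, out)


def _log_g(s: np.ndarray, L: np.ndarray, theta: float) -> np.ndarray:
    """log of g(s, L) = E_v[ Poisson(s; m (L + 2 v)) ], v ~ Exp(1)."""
    m = theta / 2.0
    c = m + 0.5
    return (
        s * math.log(m)
        - math.log(2.0)
        - (s + 1.0) * math.log(c)
        + L / 2.0
        + _log_gammaincc(s + 1.0, c * L)
    )


def _intermediate_nodes(t1: float, t2: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quadrature nodes for the epoch where only (b, c) may coalesce.

    Returns (weights incl. exp(-x) density, branch length u(x) for b and c,
    branch length l_a(x) integrated over the final Exp(1) stage handled by
    ``_log_g``).
    """
    x, w = _leggauss(_GL_NODES)
    x = 0.5 * t2 * (x + 1.0)
    w = 0.5 * t2 * w * np.exp(-x)
    u = t1 + x                      # branch length of b and c
    La = t1 + 2.0 * t2 - x          # deterministic part of a's branch
    return w, u, La


def _case1_factors(theta: float, t1: float, t2: float, smax: int):
    """Per-node factor tables for the intermediate epoch (requires t2 > 0).

    Returns (w, F, G): quadrature weights (incl. the Exp(1) waiting density),
    ``F[q, s]`` the Poisson pmf of s mutations on a pair branch of length
    u(x_q), and ``G[q, s]`` the final-stage-integrated pmf on the third
    branch.  The case-1 probability is ``sum_q w_q G[q, s_a] F[q, s_b]
    F[q, s_c]``.
    """
    w, u, La = _intermediate_nodes(t1, t2)
    m = theta / 2.0
    s = np.arange(smax + 1)[None, :]
    F = np.exp(_log_poisson(s, m * u[:, None]))
    G = np.exp(_log_g(s, La[:, None], theta))
    return w, F, G


def config_probabilities(
    s_a: np.ndarray, s_b: np.ndarray, s_c: np.ndarray, params: DivergenceParams
) -> np.ndarray:
    """Vectorised probability of configurations ``(s_a, s_b, s_c)``.

    All three count arrays must broadcast to a common shape.  ``params`` is
    used as given; apply a model's constraints beforehand (see
    :func:`config_probability`).
    """
    _validate_params(params)
    s_a, s_b, s_c = np.broadcast_arrays(
        np.asarray(s_a, dtype=int), np.asarray(s_b, dtype=int), np.asarray(s_c, dtype=int)
    )
    smax = int(max(s_a.max(initial=0), s_b.max(initial=0), s_c.max(initial=0)))
    theta, t1, t2 = params.theta, params.t1, params.t2

    # ancestral-phase table, shared by the three first-pair assignments
    L2 = _ancestral_log_core(2 * smax, smax, theta, t1, t2)
    gl = special.gammaln(np.arange(smax + 1) + 1.0)

    def pick(sp: np.ndarray, sq: np.ndarray, sz: np.ndarray) -> np.ndarray:
        return np.exp(L2[sp + sq, sz] - gl[sp] - gl[sq])

    p = pick(s_b, s_c, s_a) + pick(s_a, s_c, s_b) + pick(s_a, s_b, s_c)

    if t2 > 0:
        # intermediate epoch: (b, c) coalesce at u in [t1, t1 + t2]
        w, F, G = _case1_factors(theta, t1, t2, smax)
        p = p + np.einsum("q,q...,q...,q...->...", w, G[:, s_a], F[:, s_b], F[:, s_c])
    return p


def config_probability(
    config: "TripletConfiguration | tuple[int, int, int]",
    params: DivergenceParams,
    model: "PopulationModel | str" = "full",
) -> float:
    """Exact probability of one unrooted triplet configuration.

    The model's constraints (t1 and/or t2 pinned to zero) are applied to
    ``params`` before evaluation.  Probabilities over all configurations sum
    to one.
    """
    model = _get_model(model)
    params = model.constrain(params)
    if isinstance(config, TripletConfiguration):
        sa, sb, sc = config.as_tuple()
    else:
        sa, sb, sc = config
    if min(sa, sb, sc) < 0:
        raise ValueError("configuration counts must be non-negative")
    p = float(config_probabilities(np.array(sa), np.array(sb), np.array(sc), params))
    if not np.isfinite(p):
        raise FloatingPointError(
            f"non-finite probability for config {(sa, sb, sc)} at {params}"
        )
    return p


def config_grid(params: DivergenceParams, tail: float = 1e-10, k_max: int = 512) -> np.ndarray:
    """Probabilities of all configurations with counts up to a truncation K.

    K is grown until the grid's total mass is within ``tail`` of one, so the
    neglected tail has probability below ``tail``.  Returns an array ``P``
    with ``P[sa, sb, sc]``.
    """
    _validate_params(params)
    k = 24
    while True:
        p = grid_at(params, k)
        if 1.0 - p.sum() <= tail:
            return p
        if k >= k_max:
            raise FloatingPointError(
                f"configuration grid not converged by K={k_max} (mass {p.sum():.12f})"
            )
        k *= 2


def grid_at(params: DivergenceParams, k: int) -> np.ndarray:
    """Probabilities of all configurations with every count at most ``k``."""
    _validate_params(params)
    theta, t1, t2 = params.theta, params.t1, params.t2
    s = np.arange(k + 1)
    L2 = _ancestral_log_core(2 * k, k, theta, t1, t2)
    gl = special.gammaln(s + 1.0)
    np_idx = s[:, None] + s[None, :]
    # W[sp, sq, sz] = exp(L2[sp+sq, sz]) / (sp! sq!), assembled in log
    # space because the two factors individually overflow at large counts
    W = np.exp(L2[np_idx] - gl[:, None, None] - gl[None, :, None])
    p = (
        np.transpose(W, (2, 0, 1))      # third lineage = a
        + np.transpose(W, (0, 2, 1))    # third lineage = b
        + W                             # third lineage = c
    )
    if t2 > 0:
        w, F, G = _case1_factors(theta, t1, t2, k)
        p = p + np.einsum("q,qa,qb,qc->abc", w, G, F, F)
    return p


# ---------------------------------------------------------------------------
# likelihood, fitting, inference
# ---------------------------------------------------------------------------

def _configs_to_arrays(configs) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a config list to unique rows plus multiplicities."""
    arr = np.array(
        [c.as_tuple() if isinstance(c, TripletConfiguration) else tuple(c) for c in configs],
        dtype=int,
    )
    if arr.size == 0:
        raise ValueError("at least one locus is required")
    if arr.min() < 0:
        raise ValueError("configuration counts must be non-negative")
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    return uniq, counts.astype(float)


def log_likelihood(
    configs,
    params: DivergenceParams,
    model: "PopulationModel | str" = "full",
) -> float:
    """Sum of per-locus log configuration probabilities (loci are unlinked)."""
    model = _get_model(model)
    params = model.constrain(params)
    uniq, counts = _configs_to_arrays(configs)
    p = config_probabilities(uniq[:, 0], uniq[:, 1], uniq[:, 2], params)
    with np.errstate(divide="ignore"):
        lnp = np.log(p)
    if np.any(np.isnan(lnp)):
        raise FloatingPointError("NaN probability encountered in likelihood")
    return float(np.dot(counts, lnp))


_DEFAULT_BOUNDS = {"theta": (1e-4, 50.0), "t1": (0.0, 8.0), "t2": (0.0, 8.0)}


def _pack(params: DivergenceParams, free: tuple[str, ...]) -> np.ndarray:
    vals = {"theta": math.log(params.theta), "t1": params.t1, "t2": params.t2}
    return np.array([vals[name] for name in free])


def _unpack(x: np.ndarray, free: tuple[str, ...]) -> DivergenceParams:
    d = {"theta": 1.0, "t1": 0.0, "t2": 0.0}
    for name, v in zip(free, x):
        d[name] = math.exp(v) if name == "theta" else v
    return DivergenceParams(**d)


def _default_starts(configs_mean_s: float, model: PopulationModel, n_starts: int) -> list[DivergenceParams]:
    """Spread of optimisation starts; theta seeded near the Watterson-style
    moment estimate (E[total segregating sites] = 3 theta / 2 under panmixia)."""
    theta0 = max(2.0 * configs_mean_s / 3.0, 1e-3)
    thetas = [theta0, theta0 * 3, max(theta0 / 3, 2e-4), 1.0, 4.0]
    times = [0.05, 0.3, 1.0, 0.01, 2.0]
    starts = []
    for i in range(n_starts):
        starts.append(
            DivergenceParams(
                theta=thetas[i % len(thetas)],
                t1=times[i % len(times)],
                t2=times[(i + 2) % len(times)],
            )
        )
    return starts


def _maximize(
    uniq: np.ndarray,
    counts: np.ndarray,
    model: PopulationModel,
    bounds: dict,
    starts: list[DivergenceParams],
) -> tuple[DivergenceParams, float, list[float], bool]:
    free = model.free_params
    lo_hi = []
    for name in free:
        lo, hi = bounds[name]
        lo_hi.append((math.log(lo), math.log(hi)) if name == "theta" else (lo, hi))

    def nll(x: np.ndarray) -> float:
        params = _unpack(x, free)
        p = config_probabilities(uniq[:, 0], uniq[:, 1], uniq[:, 2], params)
        with np.errstate(divide="ignore"):
            lnp = np.log(np.maximum(p, 1e-320))
        return -float(np.dot(counts, lnp))

    best, best_val, per_start = None, np.inf, []
    for s in starts:
        x0 = np.clip(_pack(model.constrain(s), free), [b[0] for b in lo_hi], [b[1] for b in lo_hi])
        try:
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=lo_hi)
        except FloatingPointError:
            per_start.append(-np.inf)
            continue
        per_start.append(-res.fun)
        if res.fun < best_val:
            best_val, best = res.fun, res.x
    if best is None:
        return model.constrain(DivergenceParams(theta=1.0)), -np.inf, per_start, False
    finite = sorted([v for v in per_start if np.isfinite(v)], reverse=True)
    converged = len(finite) >= 2 and (finite[0] - finite[1] < 1e-6) or len(finite) == 1
    return _unpack(best, free), -best_val, per_start, bool(converged)


def fit_mle(
    configs,
    model: "PopulationModel | str" = "full",
    bounds: dict | None = None,
    starts: "list[DivergenceParams] | None" = None,
    n_starts: int = 5,
    assignment: str = "best",
) -> FitResult:
    """Maximum-likelihood fit of one divergence model to unlinked loci.

    The labelling of the first-diverging population is not observable from
    unrooted data, so with ``assignment="best"`` (default) all three
    rotations of which sample plays role "a" are fitted and the best
    log-likelihood is reported; ``assignment="fixed"`` trusts the input
    labelling.  Multi-start bounded optimisation (theta on a log scale);
    ``converged`` requires the two best starts to agree to 1e-6 lnL units.
    """
    model = _get_model(model)
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    uniq, counts = _configs_to_arrays(configs)
    mean_s = float((uniq.sum(axis=1) * counts).sum() / counts.sum())
    if starts is None:
        starts = _default_starts(mean_s, model, n_starts)

    rotations = [(0, 1, 2)]
    if assignment == "best" and model.name in ("full", "two_population"):
        # panmixia/polytomy are exchangeable in "a": rotations are redundant
        rotations = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    elif assignment not in ("best", "fixed"):
        raise ValueError("assignment must be 'best' or 'fixed'")

    best: FitResult | None = None
    for rot in rotations:
        u = uniq[:, rot]
        mle, lnl, per_start, conv = _maximize(u, counts, model, bounds, starts)
        fr = FitResult(
            model=model,
            mle=model.constrain(mle),
            max_lnl=lnl,
            n_loci=int(counts.sum()),
            converged=conv,
            assignment=rot,
            start_lnls=tuple(per_start),
        )
        if best is None or fr.max_lnl > best.max_lnl:
            best = fr
    assert best is not None
    return best


def profile_ci(
    configs,
    fit: FitResult,
    param_name: str,
    level: float = 0.95,
    bounds: dict | None = None,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one fitted parameter.

    The interval is the set of values at which the profile log-likelihood
    (re-maximised over the remaining free parameters) stays within half the
    chi-square(1) ``level`` quantile of the maximum.  An endpoint that does
    not bracket the drop within the search bounds is reported as the bound
    itself (an open-ended interval); the lower bound for divergence times is
    0 and may be attained.
    """
    if not fit.converged:
        raise ValueError("profile_ci requires a converged fit")
    if param_name not in fit.model.free_params:
        raise ValueError(f"{param_name} is not free in model {fit.model.name}")
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    drop = stats.chi2.ppf(level, df=1) / 2.0
    target = fit.max_lnl - drop

    uniq, counts = _configs_to_arrays(configs)
    uniq = uniq[:, fit.assignment]
    other = tuple(n for n in fit.model.free_params if n != param_name)
    reduced = PopulationModel("profile", other, ())

    mle_start = _pack(fit.mle, other) if other else None
    warm = {"x": mle_start}

    def profile_lnl(value: float) -> float:
        base = replace(fit.mle, **{param_name: value})
        if not other:
            p = config_probabilities(uniq[:, 0], uniq[:, 1], uniq[:, 2], base)
            with np.errstate(divide="ignore"):
                return float(np.dot(counts, np.log(np.maximum(p, 1e-320))))
        lo_hi = []
        for name in other:
            lo, hi = bounds[name]
            lo_hi.append((math.log(lo), math.log(hi)) if name == "theta" else (lo, hi))

        def nll(x: np.ndarray) -> float:
            d = {"theta": base.theta, "t1": base.t1, "t2": base.t2}
            for name, v in zip(other, x):
                d[name] = math.exp(v) if name == "theta" else v
            pr = DivergenceParams(**d)
            p = config_probabilities(uniq[:, 0], uniq[:, 1], uniq[:, 2], pr)
            with np.errstate(divide="ignore"):
                return -float(np.dot(counts, np.log(np.maximum(p, 1e-320))))

        # optimise from the previous solution and from the MLE: the warm
        # start speeds the scan up while the MLE start keeps each profile
        # value independent of evaluation order (root finding revisits
        # points and must see identical values)
        lo_vec = [b[0] for b in lo_hi]
        hi_vec = [b[1] for b in lo_hi]
        best = np.inf
        for x0 in (warm["x"], mle_start):
            res = optimize.minimize(
                nll, np.clip(x0, lo_vec, hi_vec), method="L-BFGS-B", bounds=lo_hi
            )
            if res.fun < best:
                best, warm["x"] = res.fun, res.x
        return -best

    mle_val = getattr(fit.mle, param_name)
    lo_bound, hi_bound = bounds[param_name]

    def endpoint(a: float, b: float, outer: float) -> float:
        """Root of profile_lnl - target on [a, b]; ``outer`` is returned when
        the drop is not bracketed (open-ended interval)."""
        fa, fb = profile_lnl(a) - target, profile_lnl(b) - target
        if fa * fb > 0:
            return outer
        return float(optimize.brentq(lambda v: profile_lnl(v) - target, a, b, xtol=1e-5))

    eps = max(1e-7, 1e-6 * max(mle_val, 1.0))
    lower = lo_bound if mle_val <= lo_bound + eps else endpoint(lo_bound, mle_val, lo_bound)
    upper = hi_bound if mle_val >= hi_bound - eps else endpoint(mle_val, hi_bound, hi_bound)
    return (max(lower, 0.0), upper)


def likelihood_ratio_test(full_fit: FitResult, nested_fit: FitResult) -> ModelComparison:
    """Chi-square LRT of a nested model against the full model.

    The statistic is 2 * (lnL_full - lnL_nested) with degrees of freedom the
    difference in free-parameter counts (1 for polytomy/two-population vs
    full, 2 for panmixia vs full).  Plain chi-square reference distribution,
    with no boundary mixture adjustment.
    """
    if not nested_fit.model.is_nested_in(full_fit.model):
        raise ValueError(
            f"{nested_fit.model.name} is not nested in {full_fit.model.name}"
        )
    delta = full_fit.max_lnl - nested_fit.max_lnl
    delta = max(delta, 0.0)  # guard tiny negative from optimiser tolerance
    df = full_fit.model.n_free - nested_fit.model.n_free
    statistic = 2.0 * delta
    p = float(stats.chi2.sf(statistic, df=df))
    return ModelComparison(full_fit, nested_fit, delta, statistic, df, p)


def compare_models(configs, assignment: str = "best", n_starts: int = 5) -> dict:
    """Fit all four models and LRT each nested model against the full model."""
    fits = {name: fit_mle(configs, name, n_starts=n_starts, assignment=assignment) for name in MODELS}
    comparisons = {
        name: likelihood_ratio_test(fits["full"], fits[name])
        for name in ("two_population", "polytomy", "panmixia")
    }
    return {"fits": fits, "comparisons": comparisons}


# ---------------------------------------------------------------------------
# alignment bridge and TSV I/O
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def patterns_from_alignment(aln, order: "list[str] | None" = None) -> tuple[TripletConfiguration, int]:
    """Reduce a 3-sequence alignment to its unrooted site-pattern counts.

    Each column with exactly two non-missing states (necessarily a 2:1 split
    among three sequences) contributes one site to the minority-state
    sequence.  Columns containing missing data (N or gap) or three distinct
    states violate the infinite-sites reading and are skipped; the number of
    skipped columns is returned alongside the configuration.
    """
    seqs = dict(aln.sequences) if hasattr(aln, "sequences") else dict(aln)
    if order is None:
        order = list(seqs)
    if len(order) != 3:
        raise ValueError(f"exactly 3 sequences required, got {len(order)}")
    rows = [seqs[k].upper() for k in order]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("sequences differ in length")
    counts = [0, 0, 0]
    skipped = 0
    for col in zip(*rows):
        if any(b not in _BASES for b in col):
            skipped += 1
            continue
        states = set(col)
        if len(states) == 1:
            continue
        if len(states) == 3:
            skipped += 1
            continue
        for state in states:
            idx = [i for i, b in enumerate(col) if b == state]
            if len(idx) == 1:
                counts[idx[0]] += 1
    locus_id = getattr(aln, "locus_id", "triplet")
    return TripletConfiguration(locus_id, *counts), skipped


def read_configs_tsv(path) -> list[TripletConfiguration]:
    """Read per-locus configurations from TSV columns locus_id, s_a, s_b, s_c."""
    df = pd.read_csv(path, sep="\t")
    required = {"locus_id", "s_a", "s_b", "s_c"}
    if not required.issubset(df.columns):
        raise ValueError(f"configs TSV must have columns {sorted(required)}")
    return [
        TripletConfiguration(str(r.locus_id), int(r.s_a), int(r.s_b), int(r.s_c))
        for r in df.itertuples()
    ]


def write_configs_tsv(configs, path) -> None:
    df = pd.DataFrame(
        [(c.locus_id, c.s_a, c.s_b, c.s_c) for c in configs],
        columns=["locus_id", "s_a", "s_b", "s_c"],
    )
    df.to_csv(path, sep="\t", index=False)


def fit_report_json(result: dict, cis: dict | None = None) -> str:
    """Serialise the output of :func:`compare_models` (plus optional CIs)."""
    out = {"fits": {k: v.to_dict() for k, v in result["fits"].items()}, "lrt": {}}
    for name, comp in result["comparisons"].items():
        out["lrt"][name] = {
            "delta_lnl": comp.delta_lnl,
            "statistic": comp.statistic,
            "df": comp.df,
            "p_value": comp.p_value,
            "preferred": comp.preferred,
        }
    if cis:
        out["profile_ci"] = cis
    return json.dumps(out, indent=2)
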