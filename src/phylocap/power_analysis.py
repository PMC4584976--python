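"""Expected likelihood-ratio power analysis for nested divergence models.

How many unlinked loci does it take to reject a simplified population model
(panmixia, polytomy, or two-population) in favour of the full
three-population divergence model, when the full model is true?  Because
loci are unlinked, log likelihoods add across loci, so the expected total
support difference after *n* loci is ``n * E[delta lnL]`` where the per-locus
expectation is taken under the generating model.  Rejection at level alpha
requires the total delta lnL to exceed half the chi-square quantile with
degrees of freedom equal to the difference in free-parameter counts, so

    loci required = ceil( threshold / E[delta lnL] ).

The per-locus expectation is evaluated against the nested model at its
*pseudo-true* parameters — the values maximising the expected log-likelihood
under the generating model (the Kullback-Leibler projection of the full
model onto the nested family).  ``E[delta lnL]`` is then exactly the KL
divergence from the full model to the projected nested model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .triplet_model import (
    MODELS,
    DivergenceParams,
    PopulationModel,
    _get_model,
    config_grid,
    grid_at,
)

__all__ = [
    "PowerScenario",
    "PowerResult",
    "rejection_threshold",
    "pseudo_true_params",
    "expected_delta_lnl",
    "loci_required",
    "power_curve",
]

_TAIL = 1e-10


@dataclass(frozen=True)
class PowerScenario:
    """A generating model, a nested alternative, and a significance level."""

    true_params: DivergenceParams
    nested: PopulationModel
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class PowerResult:
    """Loci required to reject one nested model, with its ingredients."""

    scenario: PowerScenario
    pseudo_true: DivergenceParams
    e_delta_lnl: float
    threshold: float
    df: int
    loci_required: int | None
    raw_ratio: float

    def to_dict(self) -> dict:
        return {
            "nested": self.scenario.nested.name,
            "alpha": self.scenario.alpha,
            "theta_star": self.pseudo_true.theta,
            "t1_star": self.pseudo_true.t1,
            "t2_star": self.pseudo_true.t2,
            "e_delta_lnl": self.e_delta_lnl,
            "threshold": self.threshold,
            "df": self.df,
            "loci_required": self.loci_required,
            "raw_ratio": self.raw_ratio,
        }


def rejection_threshold(df: int, alpha: float = 0.05) -> float:
    """Total delta lnL needed for rejection: half the chi-square quantile.

    The LRT statistic is 2 * delta lnL, compared against the (1 - alpha)
    quantile of chi-square(df); equivalently delta lnL must exceed half that
    quantile (1.9207 for df=1, 2.9957 for df=2 at alpha=0.05).
    """
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return float(stats.chi2.ppf(1.0 - alpha, df=df) / 2.0)


def _expected_lnl(p_true: np.ndarray, nested_params: DivergenceParams) -> float:
    """E_true[ln P_nested(config)] over the truncated configuration grid."""
    k = p_true.shape[0] - 1
    p_nested = grid_at(nested_params, k)
    mask = p_true > 0
    with np.errstate(divide="ignore"):
        lnp = np.log(p_nested[mask])
    if np.any(np.isneginf(lnp)):
        return -np.inf
    return float(np.dot(p_true[mask], lnp))


def pseudo_true_params(
    true_params: DivergenceParams,
    nested: "PopulationModel | str",
    tail: float = _TAIL,
    _p_true: np.ndarray | None = None,
) -> DivergenceParams:
    """KL projection of the generating model onto a nested model family.

    Returns the nested-model parameters maximising the expected per-locus
    log-likelihood under ``true_params``; constrained divergence times are
    exactly zero.
    """
    nested = _get_model(nested)
    if nested.name == "full":
        raise ValueError("nested model must differ from the full model")
    p_true = config_grid(true_params, tail=tail) if _p_true is None else _p_true
    free = nested.free_params

    def objective(x: np.ndarray) -> float:
        d = {"theta": 1.0, "t1": 0.0, "t2": 0.0}
        for name, v in zip(free, x):
            d[name] = math.exp(v) if name == "theta" else v
        val = _expected_lnl(p_true, DivergenceParams(**d))
        return -val if np.isfinite(val) else 1e12

    bounds, starts = [], []
    for name in free:
        if name == "theta":
            bounds.append((math.log(1e-4), math.log(50.0)))
        else:
            bounds.append((0.0, 8.0))
    base = [
        {"theta": true_params.theta, "t1": true_params.t1, "t2": true_params.t2},
        {"theta": max(true_params.theta * 1.5, 0.05), "t1": 0.05, "t2": 0.05},
        {"theta": max(true_params.theta / 2, 1e-3), "t1": 0.5, "t2": 0.5},
    ]
    for b in base:
        starts.append([math.log(b[n]) if n == "theta" else b[n] for n in free])

    best_x, best_val = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            objective, np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B", bounds=bounds,
        )
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
    if best_x is None or not np.isfinite(best_val):
        raise RuntimeError(f"pseudo-true optimisation failed for {nested.name}")
    d = {"theta": 1.0, "t1": 0.0, "t2": 0.0}
    for name, v in zip(free, best_x):
        d[name] = math.exp(v) if name == "theta" else v
    return DivergenceParams(**d)


def expected_delta_lnl(
    true_params: DivergenceParams,
    nested: "PopulationModel | str",
    tail: float = _TAIL,
    return_pseudo_true: bool = False,
):
    """Expected per-locus log-likelihood difference, full vs nested model.

    This is the KL divergence from the full model at ``true_params`` to the
    nested model at its pseudo-true parameters; it is non-negative and zero
    exactly when the generating parameters already satisfy the nested
    constraint.  The configuration sum is truncated at tail mass ``tail``.
    """
    nested = _get_model(nested)
    p_true = config_grid(true_params, tail=tail)
    star = pseudo_true_params(true_params, nested, tail=tail, _p_true=p_true)
    mask = p_true > 0
    e_full = float(np.dot(p_true[mask], np.log(p_true[mask])))
    e_nested = _expected_lnl(p_true, star)
    e_delta = max(e_full - e_nested, 0.0)
    if return_pseudo_true:
        return e_delta, star
    return e_delta


def loci_required(
    true_params: DivergenceParams,
    nested: "PopulationModel | str",
    alpha: float = 0.05,
    tail: float = _TAIL,
) -> PowerResult:
    """Smallest number of unlinked loci whose expected support rejects ``nested``.

    Computes n = ceil(threshold / E[delta lnL]); the unrounded ratio is also
    reported.  When the expectation is zero the nested model cannot be
    rejected in expectation and ``loci_required`` is None.
    """
    nested = _get_model(nested)
    scenario = PowerScenario(true_params, nested, alpha)
    e_delta, star = expected_delta_lnl(true_params, nested, tail=tail, return_pseudo_true=True)
    df = MODELS["full"].n_free - nested.n_free
    threshold = rejection_threshold(df, alpha)
    if e_delta <= 0.0:
        return PowerResult(scenario, star, e_delta, threshold, df, None, math.inf)
    ratio = threshold / e_delta
    return PowerResult(scenario, star, e_delta, threshold, df, max(int(math.ceil(ratio)), 1), ratio)


def power_curve(
    true_params: DivergenceParams,
    alpha: float = 0.05,
    max_loci: int = 1000,
    step: int = 1,
    tail: float = _TAIL,
) -> pd.DataFrame:
    """Expected total support difference versus number of loci, per nested model.

    Returns a tidy table with a row per locus count: the expected cumulative
    delta lnL for each nested model (linear in n by construction) and the two
    rejection thresholds (1 and 2 degrees of freedom).
    """
    if max_loci < 1:
        raise ValueError("max_loci must be >= 1")
    n = np.arange(0, max_loci + 1, step)
    cols = {"n_loci": n}
    for name in ("two_population", "polytomy", "panmixia"):
        e = expected_delta_lnl(true_params, name, tail=tail)
        cols[f"delta_lnl_{name}"] = e * n
    cols["threshold_df1"] = np.full(n.shape, rejection_threshold(1, alpha))
    cols["threshold_df2"] = np.full(n.shape, rejection_threshold(2, alpha))
    return pd.DataFrame(cols)
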