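"""Analytic power and multiple-testing arithmetic for the association scan.

Power of the two-sided single-predictor association test is computed from the
noncentral F distribution with 1 and n−2 degrees of freedom and noncentrality
``lambda = n * r2 / (1 - r2)``, where ``r2`` is the fraction of expression
variance explained by the CpG. Covariates are ignored in the power model; the
``df_adjust`` argument lets ±1-df variants be toggled.
"""

from __future__ import annotations

from scipy import stats


def power_of_r2(n: int, alpha: float, r2: float, df_adjust: int = 0) -> float:
    """Probability of detecting an effect explaining ``r2`` of the variance."""
    _validate(n, alpha)
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must be in [0, 1): got {r2}")
    df2 = n - 2 + df_adjust
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    if r2 == 0:
        return float(alpha)
    lam = n * r2 / (1.0 - r2)
    crit = stats.f.isf(alpha, 1, df2)
    return float(stats.ncf.sf(crit, 1, df2, lam))


def min_r2_detectable(n: int, alpha: float, power: float,
                      df_adjust: int = 0, tol: float = 1e-6) -> float:
    """Smallest variance-explained fraction detectable at the given power.

    Solved by bisection on the monotone ``power_of_r2``.
    """
    _validate(n, alpha)
    if not 0 < power < 1:
        raise ValueError(f"target power must be in (0, 1): got {power}")
    hi = 1.0 - 1e-9
    if power_of_r2(n, alpha, hi, df_adjust) < power:
        raise ValueError("target power unreachable at this sample size")
    lo = 0.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if power_of_r2(n, alpha, mid, df_adjust) >= power:
            hi = mid
        else:
            lo = mid
    return hi


def bonferroni_alpha(n_tests: float, fwer: float = 0.05) -> float:
    """Per-test significance level controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < fwer < 1:
        raise ValueError("fwer must be in (0, 1)")
    return fwer / n_tests


def _validate(n: int, alpha: float) -> None:
    if n <= 3:
        raise ValueError(f"n must exceed 3: got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1): got {alpha}")
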