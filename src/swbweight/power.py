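"""Sample-size and sensitivity (minimal detectable effect) calculations.

Both directions of the a-priori power calculation for a paired (one-sample)
comparison of means at standardized effect size d:

    n   = ceil( ((z_{1-alpha/2} + z_{power}) / d)^2 )
    d   = (z_{1-alpha/2} + z_{power}) / sqrt(n)

The normal approximation is the primary implementation; the noncentral-t
solver (statsmodels) is available with ``method="t"`` and is slightly more
conservative (e.g. it asks for 44 rather than 43 persons at d = 0.50,
power = 0.90, alpha = 0.05 two-sided).
"""

from __future__ import annotations

import math

from scipy import stats

__all__ = ["required_sample_size", "minimal_detectable_effect"]


def _check(alpha: float, power: float) -> None:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 0 < power < 1:
        raise ValueError(f"power must be in (0, 1), got {power}")


def _z_sum(alpha: float, power: float) -> float:
    return stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)


def required_sample_size(
    effect_d: float, alpha: float = 0.05, power: float = 0.90, method: str = "normal"
) -> int:
    """Smallest n detecting a paired effect of size d (two-sided alpha)."""
    _check(alpha, power)
    if effect_d <= 0:
        raise ValueError(f"effect_d must be > 0, got {effect_d}")
    if method == "normal":
        return math.ceil((_z_sum(alpha, power) / effect_d) ** 2)
    if method == "t":
        from statsmodels.stats.power import TTestPower

        n = TTestPower().solve_power(effect_size=effect_d, alpha=alpha, power=power,
                                     alternative="two-sided")
        return math.ceil(n - 1e-9)
    raise ValueError("method must be 'normal' or 't'")


def minimal_detectable_effect(
    n: int, alpha: float = 0.05, power: float = 0.90, method: str = "normal"
) -> float:
    """Smallest Cohen's d detectable with n pairs at the given alpha/power."""
    _check(alpha, power)
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if method == "normal":
        return _z_sum(alpha, power) / math.sqrt(n)
    if method == "t":
        from statsmodels.stats.power import TTestPower

        return float(
            TTestPower().solve_power(nobs=n, alpha=alpha, power=power, alternative="two-sided")
        )
    raise ValueError("method must be 'normal' or 't'")
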