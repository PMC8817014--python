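"""Comparison policies: RCT-derived ATE assignment and a moderator variant.

The RCT baseline randomizes 50/50 in the first period, estimates the average
treatment effect of arm A by OLS of the period-1 response on an arm
indicator, and from period 2 on assigns every individual deterministically to
the arm with the larger estimated mean response — following the coefficient
sign even when it is insignificant, since with equal true means either choice
is equally defensible and a rule is still required.

The moderator baseline additionally interacts the arm indicator with one
observed binary covariate (the group label G), so the assignment can differ
by subgroup:  y = (α₁ + α₂·x₁)·I_A + β₀ + ε, with differential effect α₁ for
x₁ = 0 and α₁ + α₂ for x₁ = 1.  It captures observed heterogeneity but, like
any covariate model, not the unobserved kind.
"""

from __future__ import annotations

import dataclasses as dc

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AteEstimate",
    "ModeratorEstimate",
    "estimate_ate_ols",
    "estimate_moderator_ols",
    "baseline_rule",
    "moderator_rule",
    "RctBaselinePolicy",
    "ModeratorPolicy",
]


@dc.dataclass(frozen=True)
class AteEstimate:
    """OLS average-treatment-effect estimate for arm A vs arm B."""

    alpha_hat: float
    se: float
    p_value: float
    n: int

    def to_frame(self, world=None, period: int = 1) -> pd.DataFrame:
        """One-row exportable record."""
        return pd.DataFrame(
            [{
                "world": world, "period": period, "alpha_hat": self.alpha_hat,
                "se": self.se, "p": self.p_value,
                "chosen_arm": baseline_rule(self),
            }]
        )


@dc.dataclass(frozen=True)
class ModeratorEstimate:
    """Main and interaction coefficients of the moderator OLS model."""

    alpha1: float
    alpha2: float


def estimate_ate_ols(y: np.ndarray, assigned_a: np.ndarray) -> AteEstimate:
    """OLS of response on intercept + arm-A indicator.

    With no further covariates this equals the two-sample difference of
    means with the classical pooled-variance standard error; the p-value is
    the two-sided t-test on the arm coefficient.
    """
    y = np.asarray(y, dtype=float)
    ind = np.asarray(assigned_a, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if ind.min() == ind.max():
        raise ValueError("both arms must be represented")
    res = sm.OLS(y, sm.add_constant(ind)).fit()
    return AteEstimate(
        alpha_hat=float(res.params[1]),
        se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n=len(y),
    )


def estimate_moderator_ols(
    y: np.ndarray, assigned_a: np.ndarray, x1: np.ndarray
) -> ModeratorEstimate:
    """OLS with an arm × covariate interaction: y ~ 1 + x1 + I_A + I_A·x1."""
    y = np.asarray(y, dtype=float)
    ind = np.asarray(assigned_a, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    X = np.column_stack([np.ones_like(y), x1, ind, ind * x1])
    res = sm.OLS(y, X).fit()
    return ModeratorEstimate(alpha1=float(res.params[2]),
                             alpha2=float(res.params[3]))


def baseline_rule(est: AteEstimate, threshold: float = 0.05) -> str:
    """Arm implied by the ATE estimate: A iff α̂ ≥ 0.

    Assignment follows the coefficient sign regardless of significance; the
    threshold is recorded for reporting only.
    """
    return "A" if est.alpha_hat >= 0 else "B"


def moderator_rule(est: ModeratorEstimate, x1: int) -> str:
    """Arm implied by the subgroup differential effect α₁ + α₂·x₁."""
    return "A" if est.alpha1 + est.alpha2 * x1 > 0 else "B"


class RctBaselinePolicy:
    """Randomize once, estimate the ATE, then assign deterministically.

    Parameters
    ----------
    threshold
        Significance level recorded with the estimate (does not change the
        assignment, which is coefficient-wise).
    reestimate
        If True, refit the ATE each period on that period's responses
        instead of freezing the period-1 estimate (off by default).
    initial
        ``"random"`` for the 50/50 first-period randomization, or ``"A"``/
        ``"B"`` to force the first period (useful for analytic checks).
    """

    name = "baseline"

    def __init__(self, threshold: float = 0.05, reestimate: bool = False,
                 initial: str = "random") -> None:
        if initial not in ("random", "A", "B"):
            raise ValueError("initial must be 'random', 'A' or 'B'")
        self.threshold = threshold
        self.reestimate = reestimate
        self.initial = initial
        self.estimate: AteEstimate | None = None
        self.chosen_arm: str | None = None
        self._obs = 0
        self._rng: np.random.Generator | None = None

    def reset(self, obs: int, rng: np.random.Generator,
              observed: dict | None = None) -> None:
        self._obs = obs
        self._rng = rng
        self.estimate = None
        self.chosen_arm = None

    def propose(self) -> np.ndarray:
        if self.chosen_arm is not None:
            return np.full(self._obs, self.chosen_arm)
        if self.initial != "random":
            return np.full(self._obs, self.initial)
        return np.where(self._rng.random(self._obs) < 0.5, "A", "B")

    def observe(self, assignments: np.ndarray, delta_y: np.ndarray) -> None:
        if self.estimate is None or self.reestimate:
            ind = np.asarray(assignments) == "A"
            if ind.all() or not ind.any():
                # deterministic follow-up period: nothing new to estimate
                return
            self.estimate = estimate_ate_ols(delta_y, ind)
            self.chosen_arm = baseline_rule(self.estimate, self.threshold)


class ModeratorPolicy:
    """Subgroup-wise deterministic assignment from a moderator OLS fit.

    Uses the observed group label as the moderating covariate; assignment
    after period 1 is A for a subgroup iff its estimated differential effect
    is positive.
    """

    name = "moderator"

    def __init__(self) -> None:
        self.estimate: ModeratorEstimate | None = None
        self._g: np.ndarray | None = None
        self._obs = 0
        self._rng: np.random.Generator | None = None

    def reset(self, obs: int, rng: np.random.Generator,
              observed: dict | None = None) -> None:
        if observed is None or "G" not in observed:
            raise ValueError("ModeratorPolicy needs the observed group label G")
        self._g = np.asarray(observed["G"], dtype=int)
        self._obs = obs
        self._rng = rng
        self.estimate = None

    def propose(self) -> np.ndarray:
        if self.estimate is None:
            return np.where(self._rng.random(self._obs) < 0.5, "A", "B")
        arm_g1 = moderator_rule(self.estimate, 1)
        arm_g0 = moderator_rule(self.estimate, 0)
        return np.where(self._g == 1, arm_g1, arm_g0)

    def observe(self, assignments: np.ndarray, delta_y: np.ndarray) -> None:
        if self.estimate is None:
            ind = np.asarray(assignments) == "A"
            self.estimate = estimate_moderator_ols(delta_y, ind, self._g)
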