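"""Two-step mediation algebra by the product of coefficients.

With stage-1 effect a (exposure -> mediator), stage-2 effect b (mediator ->
outcome) and total effect c (exposure -> outcome), the indirect effect is a*b,
the direct effect is c' = c - a*b, and the proportion mediated is (a*b)/c.
Uncertainty for the product comes from the delta method,
se = sqrt(b^2 se_a^2 + a^2 se_b^2), or from seeded Monte-Carlo sampling of
(a, b).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .estimators import Z95, MrResult


def indirect_effect(
    a: float,
    a_se: float,
    b: float,
    b_se: float,
    ci_method: str = "delta",
    seed: int | None = None,
    n_draws: int = 100_000,
) -> tuple[float, float, tuple[float, float]]:
    """Product-method indirect effect a*b with SE and 95% CI.

    ``delta`` uses the first-order variance b^2 se_a^2 + a^2 se_b^2 and a
    normal interval; ``monte_carlo`` draws (a, b) from independent normals and
    takes empirical 2.5/97.5 percentiles (SE is the draw standard deviation).
    """
    if a_se <= 0 or b_se <= 0:
        raise ConfigurationError("stage standard errors must be positive")
    indirect = a * b
    if ci_method == "delta":
        se = math.sqrt(b**2 * a_se**2 + a**2 * b_se**2)
        return indirect, se, (indirect - Z95 * se, indirect + Z95 * se)
    if ci_method == "monte_carlo":
        if seed is None:
            raise ConfigurationError("monte_carlo CI requires a seed")
        rng = np.random.default_rng(seed)
        prod = (a + a_se * rng.standard_normal(n_draws)) * (b + b_se * rng.standard_normal(n_draws))
        lo, hi = np.percentile(prod, [2.5, 97.5])
        return indirect, float(np.std(prod, ddof=1)), (float(lo), float(hi))
    raise ConfigurationError(f"unknown ci_method: {ci_method!r}")


def decompose(total: float, total_se: float, indirect: float) -> tuple[float, float]:
    """Direct effect c - a*b and proportion mediated (a*b)/c.

    The proportion is NaN (undefined) when the total effect is zero; the
    direct effect is still returned.
    """
    direct = total - indirect
    proportion = indirect / total if total != 0 else float("nan")
    return direct, proportion


@dataclass
class MediationResult:
    """Full product-method decomposition with uncertainty for the indirect path."""

    a: float
    a_se: float
    b: float
    b_se: float
    total: float
    total_se: float
    indirect: float
    indirect_se: float
    indirect_ci_low: float
    indirect_ci_high: float
    direct: float
    proportion_mediated: float
    method: str
    ci_method: str
    seed: int | None = None

    @property
    def inconsistent_sign(self) -> bool:
        """True when indirect and total effects point in opposite directions."""
        return self.indirect * self.total < 0

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "a_se": self.a_se,
            "b": self.b,
            "b_se": self.b_se,
            "total": self.total,
            "total_se": self.total_se,
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "indirect_ci_low": self.indirect_ci_low,
            "indirect_ci_high": self.indirect_ci_high,
            "direct": self.direct,
            "proportion_mediated": self.proportion_mediated,
            "inconsistent_sign": self.inconsistent_sign,
            "method": self.method,
            "ci_method": self.ci_method,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def mediate(
    stage1: MrResult,
    stage2: MrResult,
    total: MrResult,
    ci_method: str = "delta",
    seed: int | None = None,
) -> MediationResult:
    """Assemble a MediationResult from three MR results of the same method.

    ``stage1`` is exposure->mediator (a), ``stage2`` mediator->outcome (b),
    ``total`` exposure->outcome (c).  A method mismatch between the three is a
    configuration error: mixing estimators across stages would silently mix
    their bias profiles.
    """
    methods = {stage1.method, stage2.method, total.method}
    if len(methods) != 1:
        raise ConfigurationError(f"stage estimators differ: {sorted(methods)}")
    indirect, ind_se, (lo, hi) = indirect_effect(
        stage1.beta, stage1.se, stage2.beta, stage2.se, ci_method=ci_method, seed=seed
    )
    direct, proportion = decompose(total.beta, total.se, indirect)
    return MediationResult(
        a=stage1.beta,
        a_se=stage1.se,
        b=stage2.beta,
        b_se=stage2.se,
        total=total.beta,
        total_se=total.se,
        indirect=indirect,
        indirect_se=ind_se,
        indirect_ci_low=lo,
        indirect_ci_high=hi,
        direct=direct,
        proportion_mediated=proportion,
        method=stage1.method,
        ci_method=ci_method,
        seed=seed,
    )
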