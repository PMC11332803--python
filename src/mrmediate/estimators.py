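"""Two-sample MR estimators.

Implements the per-SNP Wald ratio and the five summary-data estimators used as
a battery in mediated MR studies: inverse-variance weighted (IVW, the primary
method), MR-Egger regression, weighted median, and simple/weighted mode.  All
return an :class:`MrResult` with the effect on the log-odds (or trait-unit)
scale, its standard error, a two-sided p-value, and the odds-ratio scale
``exp(beta)`` with a 95% confidence interval.

Conventions
-----------
* IVW is weighted least squares of outcome on exposure betas through the
  origin with weights 1/se_out^2; the default model is multiplicative random
  effects, which inflates the fixed-effect SE by sqrt(max(Q/(J-1), 1)).
* MR-Egger orients every SNP to beta_exp >= 0 before fitting (the estimator is
  not invariant to joint sign changes); slope and intercept p-values use a t
  distribution with J-2 degrees of freedom.
* Median and mode SEs come from a seeded parametric bootstrap that perturbs
  both exposure and outcome betas by their standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateExposureError,
    InsufficientInstrumentsError,
)
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)

#: z quantile for 95% confidence intervals
Z95 = 1.959964

_P_FLOOR = 1e-300


def _normal_p(z) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _P_FLOOR, 1.0))


def _t_p(t, df: int) -> float:
    return float(np.clip(2.0 * stats.t.sf(abs(t), df), _P_FLOOR, 1.0))


@dataclass
class MrResult:
    """One estimator's causal effect with OR-scale confidence interval."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        with np.errstate(over="ignore"):
            self.or_ = float(np.exp(self.beta))
            self.ci_low = float(np.exp(self.beta - Z95 * self.se))
            self.ci_high = float(np.exp(self.beta + Z95 * self.se))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "n_snp": self.n_snp,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }
        d.update({k: v for k, v in self.extras.items() if np.isscalar(v)})
        return d


@dataclass
class RatioSet:
    """Per-SNP Wald ratios with first-order SEs and inverse-variance weights."""

    ratio: np.ndarray
    ratio_se: np.ndarray
    weight: np.ndarray
    rsids: list[str]


def ratio_set(h: HarmonizedSet) -> RatioSet:
    """Per-SNP ratios; SNPs with beta_exp == 0 are dropped (zero weight, undefined ratio)."""
    bx, by, sy = h.beta_exp, h.beta_out, h.se_out
    ok = bx != 0
    if not ok.all():
        logger.info("dropping %d SNP(s) with beta_exp == 0 from ratio set", int((~ok).sum()))
    if not ok.any():
        raise DegenerateExposureError("all exposure betas are zero")
    r = by[ok] / bx[ok]
    r_se = sy[ok] / np.abs(bx[ok])
    return RatioSet(r, r_se, 1.0 / r_se**2, [s for s, k in zip(h.rsids, ok) if k])


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    se_method: str = "first",
) -> MrResult:
    """Single-SNP causal estimate beta_out / beta_exp.

    ``se_method='first'`` gives the first-order delta SE se_out/|beta_exp|;
    ``'second'`` adds the exposure-uncertainty term
    sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4).
    """
    if beta_exp == 0:
        raise DegenerateExposureError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    if se_method == "first":
        se = se_out / abs(beta_exp)
    elif se_method == "second":
        se = float(np.sqrt(se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4))
    else:
        raise ConfigurationError(f"unknown se_method: {se_method!r}")
    return MrResult("wald_ratio", beta, se, _normal_p(beta / se), 1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect IVW slope, SE and Cochran's Q."""
    w = 1.0 / sy**2
    den = float(np.sum(bx**2 * w))
    if den == 0:
        raise DegenerateExposureError("all exposure betas are zero")
    beta = float(np.sum(bx * by * w)) / den
    se_fixed = float(np.sqrt(1.0 / den))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MrResult:
    """Inverse-variance-weighted estimate (weighted LS through the origin).

    With a single SNP the estimate degrades to the Wald ratio.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown IVW model: {model!r}")
    j = len(h)
    if j == 0:
        raise InsufficientInstrumentsError("IVW needs at least one SNP")
    if j == 1:
        logger.info("IVW with a single SNP degrades to the Wald ratio")
        return wald_ratio(h.beta_exp[0], h.se_exp[0], h.beta_out[0], h.se_out[0])
    beta, se_fixed, q = _ivw_core(h.beta_exp, h.beta_out, h.se_out)
    scale = max(q / (j - 1), 1.0) if model == "multiplicative_random" else 1.0
    se = se_fixed * float(np.sqrt(scale))
    return MrResult(
        "ivw",
        beta,
        se,
        _normal_p(beta / se),
        j,
        extras={
            "model": model,
            "q_statistic": q,
            "q_df": j - 1,
            "q_pvalue": float(stats.chi2.sf(q, j - 1)),
        },
    )


def mr_egger(h: HarmonizedSet) -> MrResult:
    """MR-Egger regression: weighted regression with an intercept.

    The intercept estimates the average directional pleiotropic effect; the
    slope is the pleiotropy-adjusted causal effect.  SNPs are pre-oriented to
    beta_exp >= 0.  The slope SE carries the multiplicative random-effects
    floor sqrt(max(RSS/(J-2), 1)); the intercept SE uses the ordinary
    regression scale so its null p-values are exactly t-distributed.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {j}")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx = h.beta_exp * sign
    by = h.beta_out * sign
    sy = h.se_out
    res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    scale = float(res.scale)  # weighted RSS / (J - 2)
    ncov = np.asarray(res.normalized_cov_params)
    intercept, slope = float(res.params[0]), float(res.params[1])
    slope_se = float(np.sqrt(ncov[1, 1] * max(scale, 1.0)))
    intercept_se = float(np.sqrt(ncov[0, 0] * scale))
    slope_p = _t_p(slope / slope_se, j - 2) if slope_se > 0 else _P_FLOOR
    if intercept_se > 0:
        intercept_p = _t_p(intercept / intercept_se, j - 2)
    else:
        intercept_p = 1.0 if intercept == 0 else _P_FLOOR
    return MrResult(
        "mr_egger",
        slope,
        slope_se,
        slope_p,
        j,
        extras={
            "egger_intercept": intercept,
            "egger_intercept_se": intercept_se,
            "egger_intercept_p": intercept_p,
            "residual_scale": scale,
        },
    )


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="stable")
    r_s, w_s = r[order], w[order]
    cum = np.cumsum(w_s)
    p = (cum - 0.5 * w_s) / cum[-1]
    return float(np.interp(0.5, p, r_s))


def _weighted_median_matrix(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for (B, J) ratio and weight matrices."""
    order = np.argsort(r, axis=1, kind="stable")
    r_s = np.take_along_axis(r, order, axis=1)
    w_s = np.take_along_axis(w, order, axis=1)
    cum = np.cumsum(w_s, axis=1)
    p = (cum - 0.5 * w_s) / cum[:, -1:]
    out = np.empty(len(r))
    for i in range(len(r)):
        out[i] = np.interp(0.5, p[i], r_s[i])
    return out


def _bootstrap_perturb(h: HarmonizedSet, n_boot: int, rng: np.random.Generator):
    """Parametric perturbation of exposure/outcome betas; returns (bx*, by*) of shape (B, J)."""
    j = len(h)
    bx = h.beta_exp + h.se_exp * rng.standard_normal((n_boot, j))
    by = h.beta_out + h.se_out * rng.standard_normal((n_boot, j))
    return bx, by


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, *, seed: int) -> MrResult:
    """Weighted-median estimator (consistent when <50% of weight is invalid).

    The point estimate interpolates the inverse-variance-weighted empirical
    quantile function of the per-SNP ratios at probability 0.5; the SE is a
    seeded parametric bootstrap over both panels' betas.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {j}")
    rs = ratio_set(h)
    beta = _weighted_median_point(rs.ratio, rs.weight)
    rng = np.random.default_rng(seed)
    bx, by = _bootstrap_perturb(h, n_boot, rng)
    safe = np.where(bx == 0, np.finfo(float).tiny, bx)
    r_b = by / safe
    w_b = (safe / h.se_out) ** 2
    boots = _weighted_median_matrix(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = float(np.finfo(float).tiny)
    return MrResult("weighted_median", beta, se, _normal_p(beta / se), j, extras={"n_boot": n_boot})


_GRID_SIZE = 256


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    j = len(r)
    sd = float(np.std(r, ddof=1)) if j > 1 else 0.0
    mad = float(np.median(np.abs(r - np.median(r))))
    s = min(sd, 1.4826 * mad)
    if s == 0:
        s = sd  # >50% ties: fall back to the spread that is nonzero
    return phi * 0.9 * s * j ** (-0.2)


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    h = _mode_bandwidth(r, phi)
    if h <= 0:
        # degenerate spread: the (weighted) most frequent exact value
        vals, inv = np.unique(r, return_inverse=True)
        return float(vals[np.argmax(np.bincount(inv, weights=w))])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, _GRID_SIZE)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def _mode_matrix(r: np.ndarray, w: np.ndarray, phi: float, chunk: int = 128) -> np.ndarray:
    """Row-wise kernel-mode estimates for (B, J) matrices."""
    b, j = r.shape
    sd = np.std(r, axis=1, ddof=1)
    med = np.median(r, axis=1)
    mad = np.median(np.abs(r - med[:, None]), axis=1)
    s = np.minimum(sd, 1.4826 * mad)
    s = np.where(s == 0, sd, s)
    h = phi * 0.9 * s * j ** (-0.2)
    h = np.where(h <= 0, np.finfo(float).tiny, h)
    lo = r.min(axis=1) - 3 * h
    hi = r.max(axis=1) + 3 * h
    out = np.empty(b)
    steps = np.linspace(0.0, 1.0, _GRID_SIZE)
    for start in range(0, b, chunk):
        end = min(start + chunk, b)
        grid = lo[start:end, None] + (hi[start:end] - lo[start:end])[:, None] * steps[None, :]
        z = (grid[:, :, None] - r[start:end, None, :]) / h[start:end, None, None]
        dens = np.einsum("bgj,bj->bg", np.exp(-0.5 * z**2), w[start:end])
        out[start:end] = np.take_along_axis(grid, np.argmax(dens, axis=1)[:, None], axis=1)[:, 0]
    return out


def mode_estimator(
    h: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    *,
    seed: int,
) -> MrResult:
    """Simple (unit-weight) or weighted mode of the per-SNP ratio density.

    A normal-kernel density is evaluated over the ratio support with bandwidth
    phi * 0.9 * min(sd, 1.4826*mad) * J^(-1/5); the estimate is its argmax.
    If every ratio is identical that common value is returned.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"mode estimator needs >= 3 SNPs, got {j}")
    rs = ratio_set(h)
    w = rs.weight if weighted else np.ones_like(rs.ratio)
    beta = _mode_point(rs.ratio, w, phi)
    rng = np.random.default_rng(seed)
    bx, by = _bootstrap_perturb(h, n_boot, rng)
    safe = np.where(bx == 0, np.finfo(float).tiny, bx)
    r_b = by / safe
    w_b = (safe / h.se_out) ** 2 if weighted else np.ones_like(r_b)
    boots = _mode_matrix(r_b, w_b, phi)
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = float(np.finfo(float).tiny)
    method = "weighted_mode" if weighted else "simple_mode"
    return MrResult(method, beta, se, _normal_p(beta / se), j, extras={"n_boot": n_boot, "phi": phi})


def classify_direction(res: MrResult, alpha: float = 0.05) -> str:
    """Decision rule: p >= alpha -> no_causal_evidence; else the sign of beta.

    beta > 0 (OR > 1) marks the exposure a risk factor, beta < 0 (OR < 1) a
    protective factor.
    """
    if res.pvalue >= alpha or res.beta == 0:
        return "no_causal_evidence"
    return "risk" if res.beta > 0 else "protective"


ALL_METHODS = ("ivw", "mr_egger", "weighted_median", "simple_mode", "weighted_mode")


def run_all_estimators(
    h: HarmonizedSet,
    *,
    seed: int,
    n_boot: int = 1000,
    ivw_model: str = "multiplicative_random",
    phi: float = 1.0,
) -> dict[str, MrResult]:
    """Run the five-method battery; methods needing >= 3 SNPs are skipped below that."""
    out: dict[str, MrResult] = {"ivw": ivw(h, model=ivw_model)}
    if len(h) >= 3:
        out["mr_egger"] = mr_egger(h)
        out["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
        out["simple_mode"] = mode_estimator(h, weighted=False, phi=phi, n_boot=n_boot, seed=seed + 1)
        out["weighted_mode"] = mode_estimator(h, weighted=True, phi=phi, n_boot=n_boot, seed=seed + 2)
    else:
        logger.info("only %d SNP(s): Egger/median/mode skipped", len(h))
    return out
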