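"""Sensitivity analyses: Cochran's Q, Egger intercept, MR-PRESSO, leave-one-out.

MR-PRESSO here implements the global residual-sum-of-squares test and the
per-SNP outlier test (Bonferroni-adjusted simulation p-values); the distortion
test is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MrResult, _ivw_core, ivw, mr_egger
from .gwas_io import HarmonizedSet


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Heterogeneity of per-SNP ratio estimates around the fixed-effect IVW.

    Q = sum_j (beta_out_j - beta_IVW * beta_exp_j)^2 / se_out_j^2, which equals
    the ratio-scale form sum_j w_j (r_j - beta_IVW)^2 with w_j = beta_exp_j^2 /
    se_out_j^2 and stays defined when a beta_exp is zero.  p is the upper tail
    of chi-square with J-1 degrees of freedom.
    """
    j = len(h)
    if j < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 SNPs, got {j}")
    _, _, q = _ivw_core(h.beta_exp, h.beta_out, h.se_out)
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """Directional-pleiotropy test: the MR-Egger intercept, its SE and p."""
    res = mr_egger(h)
    return (
        res.extras["egger_intercept"],
        res.extras["egger_intercept_se"],
        res.extras["egger_intercept_p"],
    )


@dataclass
class PressoReport:
    """MR-PRESSO global and per-SNP outlier test results."""

    observed_rss: float
    global_p: float
    outlier_p: pd.Series  # Bonferroni-adjusted, indexed by rsid
    outlier_rsids: list[str]
    n_sim: int
    seed: int


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW betas, vectorized over SNPs."""
    num = np.sum(bx * by * w)
    den = np.sum(bx**2 * w)
    return (num - bx * by * w) / (den - bx**2 * w)


def mr_presso(
    h: HarmonizedSet, n_sim: int = 1000, alpha: float = 0.05, *, seed: int
) -> PressoReport:
    """Simulation-based pleiotropy residual sum of squares and outlier test.

    The observed RSS weights each SNP's residual from its leave-one-out IVW
    prediction by 1/se_out^2.  ``n_sim`` datasets are simulated from the
    no-pleiotropy model (outcome betas normal around the leave-one-out
    prediction with their reported SEs) and the full statistic is recomputed on
    each; p-values use the plus-one estimator, so the smallest reportable
    global p is 1/(n_sim + 1).  Per-SNP outlier p-values are Bonferroni
    adjusted by J and flagged below ``alpha``.
    """
    j = len(h)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 SNPs, got {j}")
    bx, by, sy = h.beta_exp, h.beta_out, h.se_out
    w = 1.0 / sy**2
    loo = _loo_betas(bx, by, w)
    obs_stat = w * (by - loo * bx) ** 2
    observed_rss = float(obs_stat.sum())

    rng = np.random.default_rng(seed)
    expected = loo * bx
    y_sim = expected + sy * rng.standard_normal((n_sim, j))
    num_sim = y_sim @ (bx * w)
    den = float(np.sum(bx**2 * w))
    loo_sim = (num_sim[:, None] - bx * w * y_sim) / (den - bx**2 * w)
    stat_sim = w * (y_sim - loo_sim * bx) ** 2
    rss_sim = stat_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= observed_rss)) / (n_sim + 1))
    p_snp = (1 + np.sum(stat_sim >= obs_stat, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_snp * j)
    outlier_p = pd.Series(p_adj, index=h.rsids)
    flagged = [r for r, p in outlier_p.items() if p < alpha]
    return PressoReport(observed_rss, global_p, outlier_p, flagged, n_sim, seed)


def leave_one_out(h: HarmonizedSet, model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated J times, excluding one SNP each; flags sign changes.

    Returns a DataFrame with one row per excluded rsid (beta, se, pvalue, or,
    ci_low, ci_high, sign_differs) where ``sign_differs`` marks rows whose beta
    sign differs from the full-set IVW.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 3 SNPs, got {j}")
    full = ivw(h, model=model)
    rows = []
    mask = np.ones(j, bool)
    for k in range(j):
        mask[k] = False
        res: MrResult = ivw(h.subset(mask), model=model)
        rows.append(
            {
                "rsid_excluded": h.rsids[k],
                "beta": res.beta,
                "se": res.se,
                "pvalue": res.pvalue,
                "or": res.or_,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "sign_differs": bool(np.sign(res.beta) != np.sign(full.beta)),
            }
        )
        mask[k] = True
    return pd.DataFrame(rows)


def diagnostics_table(h: HarmonizedSet, presso: PressoReport | None, q: tuple, egger: tuple | None) -> dict:
    """Flat per-pair diagnostics record for TSV reporting."""
    rec = {
        "q": q[0],
        "q_df": q[1],
        "q_p": q[2],
        "egger_intercept": egger[0] if egger else float("nan"),
        "egger_intercept_p": egger[2] if egger else float("nan"),
        "presso_global_p": presso.global_p if presso else float("nan"),
        "presso_outliers": ";".join(presso.outlier_rsids) if presso else "",
    }
    return rec
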