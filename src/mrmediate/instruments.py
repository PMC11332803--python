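"""Instrument selection: p-value threshold, greedy LD clumping, F-statistic filter.

The conventions mirror standard two-sample MR practice: genome-wide candidates
at p < 1e-5, clumping with a 10,000 kb window and r2 > 0.001, and removal of
weak instruments at F <= 10 (strict inequalities on both thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingFieldError
from .gwas_io import LdMatrix, SnpAssociation, SummaryStatistics

logger = logging.getLogger(__name__)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, annotated with strength.

    ``data`` carries the summary-statistic columns plus ``f_stat`` and
    ``r2_explained`` (variance in the exposure explained by the SNP).
    """

    exposure_id: str
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rsids(self) -> list[str]:
        return self.data["rsid"].tolist()

    def as_summary(self, trait_role: str = "exposure") -> SummaryStatistics:
        cols = [c for c in self.data.columns if c not in ("f_stat", "r2_explained")]
        return SummaryStatistics(self.exposure_id, trait_role, self.data[cols].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        from .gwas_io import FILE_COLUMNS

        inv = {v: k for k, v in FILE_COLUMNS.items()}
        out = self.data.rename(columns=inv)
        out.to_csv(path, sep="\t", index=False)


def select_by_pvalue(panel: SummaryStatistics, threshold: float = 1e-5) -> SummaryStatistics:
    """Keep records with pvalue strictly below ``threshold``, order preserved."""
    kept = panel.subset(panel.data["pvalue"] < threshold)
    if len(kept) == 0:
        logger.warning("%s: no SNP passes p < %g", panel.trait_id, threshold)
    return kept


def ld_clump(
    candidates: SummaryStatistics,
    ld: LdMatrix,
    window_kb: float = 10000,
    r2_threshold: float = 0.001,
) -> SummaryStatistics:
    """Greedy LD clumping.

    Repeatedly take the unclaimed SNP with the smallest p-value as an index and
    discard every unclaimed SNP on the same chromosome within ``window_kb``
    kilobases AND with r2 > ``r2_threshold`` against it.  A discard requires
    both conditions; SNPs absent from the LD matrix are treated as independent.
    Ties on p-value are broken by (chromosome, position) ascending.
    """
    df = candidates.data
    if len(df) <= 1:
        return candidates
    missing = [r for r in df["rsid"] if r not in ld]
    if missing:
        logger.warning(
            "%s: %d candidate SNP(s) absent from the LD matrix; treated as independent",
            candidates.trait_id,
            len(missing),
        )
    order = np.lexsort(
        (df["position"].to_numpy(), df["chromosome"].to_numpy(), df["pvalue"].to_numpy())
    )
    rsid = df["rsid"].to_numpy()
    chrom = df["chromosome"].to_numpy()
    pos = df["position"].to_numpy(float)
    window_bp = window_kb * 1000.0
    claimed = np.zeros(len(df), bool)
    index_rows: list[int] = []
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        index_rows.append(i)
        for j in order:
            if claimed[j] or chrom[j] != chrom[i] or abs(pos[j] - pos[i]) > window_bp:
                continue
            r2 = ld.lookup(rsid[i], rsid[j])
            if r2 is not None and r2 > r2_threshold:
                claimed[j] = True  # discarded: claimed but not an index
    keep = np.zeros(len(df), bool)
    keep[index_rows] = True
    return candidates.subset(keep)


def f_statistic(record: SnpAssociation, method: str = "wald") -> float:
    """Per-SNP instrument-strength F statistic.

    ``wald``: F = (beta/se)^2.  ``r2_based``: r2 = 2·eaf·(1−eaf)·beta^2 and
    F = (n−2)·r2/(1−r2); requires eaf and n.
    """
    if method == "wald":
        return float((record.beta / record.se) ** 2)
    if method == "r2_based":
        if record.eaf is None or record.n is None:
            raise MissingFieldError(f"{record.rsid}: r2_based F needs both eaf and n")
        r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2
        if r2 >= 1:
            return float("inf")
        return float((record.n - 2) * r2 / (1 - r2))
    raise MissingFieldError(f"unknown F-statistic method: {method!r}")


def _f_vector(df: pd.DataFrame, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized F and r2_explained for a panel DataFrame."""
    beta = df["beta"].to_numpy(float)
    se = df["se"].to_numpy(float)
    eaf = df["eaf"].to_numpy(float)
    n = df["n"].to_numpy(float)
    if method == "wald":
        f = (beta / se) ** 2
    elif method == "r2_based":
        if np.isnan(eaf).any() or np.isnan(n).any():
            raise MissingFieldError("r2_based F needs eaf and n for every record")
        r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
        f = np.where(r2 < 1, (n - 2) * r2 / np.maximum(1 - r2, 1e-300), np.inf)
    else:
        raise MissingFieldError(f"unknown F-statistic method: {method!r}")
    # variance explained: direct when eaf available, otherwise back out of F
    r2_exp = np.full(len(df), np.nan)
    have_eaf = ~np.isnan(eaf)
    r2_exp[have_eaf] = 2.0 * eaf[have_eaf] * (1 - eaf[have_eaf]) * beta[have_eaf] ** 2
    backout = np.isnan(r2_exp) & ~np.isnan(n)
    r2_exp[backout] = f[backout] / (f[backout] + n[backout] - 2)
    return f, np.clip(r2_exp, 0.0, 1.0)


def filter_weak(
    candidates: SummaryStatistics, f_min: float = 10.0, method: str = "wald"
) -> InstrumentSet:
    """Keep instruments with F strictly greater than ``f_min``."""
    f, r2_exp = _f_vector(candidates.data, method)
    keep = f > f_min
    n_weak = int((~keep).sum())
    if n_weak:
        logger.info("%s: removed %d weak instrument(s) at F <= %g", candidates.trait_id, n_weak, f_min)
    data = candidates.data[keep].reset_index(drop=True)
    data["f_stat"] = f[keep]
    data["r2_explained"] = r2_exp[keep]
    return InstrumentSet(candidates.trait_id, data)
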