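"""Reading, validation, harmonization and serialization of GWAS summary statistics.

Summary statistics are tab-delimited text with a GWAS-SSF-like header::

    rsid  chromosome  base_pair_location  effect_allele  other_allele
    effect_allele_frequency  beta  standard_error  p_value  n

``effect_allele_frequency`` and ``n`` are optional.  Other dialects are read by
supplying a ``column_map`` from these canonical names to the file's own names.
LD is read either as a square matrix (header row and first column of rsids) or
as a long table with columns ``rsid_a``, ``rsid_b``, ``r2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, HarmonizationError, ValidationError

logger = logging.getLogger(__name__)

#: canonical file column -> internal column
FILE_COLUMNS = {
    "rsid": "rsid",
    "chromosome": "chromosome",
    "base_pair_location": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_allele_frequency": "eaf",
    "beta": "beta",
    "standard_error": "se",
    "p_value": "pvalue",
    "n": "n",
}
MANDATORY = (
    "rsid",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
)
INTERNAL_COLUMNS = list(FILE_COLUMNS.values())

#: strand-ambiguous allele pairs
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SnpAssociation:
    """One SNP's summary-level association with one trait."""

    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None


@dataclass
class SummaryStatistics:
    """A validated per-trait panel of SNP associations.

    ``data`` holds one row per SNP with the internal columns
    ``rsid, chromosome, position, effect_allele, other_allele, eaf, beta, se,
    pvalue, n`` (``eaf``/``n`` may be NaN).  rsids are unique within a panel.
    """

    trait_id: str
    trait_role: str  # exposure | mediator | outcome
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rsids(self) -> list[str]:
        return self.data["rsid"].tolist()

    def records(self) -> list[SnpAssociation]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                SnpAssociation(
                    rsid=row.rsid,
                    chromosome=row.chromosome,
                    position=int(row.position),
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta=float(row.beta),
                    se=float(row.se),
                    pvalue=float(row.pvalue),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    n=None if pd.isna(row.n) else float(row.n),
                )
            )
        return out

    def subset(self, mask) -> "SummaryStatistics":
        return SummaryStatistics(self.trait_id, self.trait_role, _take(self.data, mask))

    def to_tsv(self, path) -> None:
        write_summary_stats(self, path)


def _take(df: pd.DataFrame, mask) -> pd.DataFrame:
    """Row subset by boolean mask or positional indices."""
    arr = np.asarray(mask)
    sub = df[arr] if arr.dtype == bool else df.iloc[arr]
    return sub.reset_index(drop=True)


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Coerce dtypes and drop rows violating the record invariants."""
    df = df.copy()
    for col in ("rsid", "chromosome", "effect_allele", "other_allele"):
        df[col] = df[col].astype(str)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for col in ("beta", "se", "pvalue", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["position"] = pd.to_numeric(df["position"], errors="coerce")

    ok = (
        df["position"].notna()
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & np.isfinite(df["se"])
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & (df["effect_allele"] != df["other_allele"])
        & (df["effect_allele"].str.len() > 0)
        & (df["other_allele"].str.len() > 0)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & (df["n"].isna() | (df["n"] > 0))
    )
    dropped = int((~ok).sum())
    df = df[ok]
    dup = df["rsid"].duplicated()
    if dup.any():
        dropped += int(dup.sum())
        df = df[~dup]
    df = df.reset_index(drop=True)
    df["position"] = df["position"].astype(np.int64)
    return df[INTERNAL_COLUMNS], dropped


def panel_from_frame(df: pd.DataFrame, trait_id: str, trait_role: str = "exposure") -> SummaryStatistics:
    """Build a validated panel from a DataFrame already using internal column names."""
    df = df.copy()
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    clean, dropped = _validate_frame(df)
    if dropped:
        logger.warning("%s: dropped %d invalid row(s)", trait_id, dropped)
    if clean.empty:
        raise EmptyInputError(f"panel '{trait_id}' has zero valid rows")
    return SummaryStatistics(trait_id, trait_role, clean)


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_role: str = "exposure",
) -> SummaryStatistics:
    """Read a GWAS summary-statistics panel from (optionally gzipped) TSV.

    ``column_map`` maps canonical names (keys of :data:`FILE_COLUMNS`) to the
    names actually used in the file, e.g. ``{"beta": "effect"}``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistics file not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=object)
    column_map = dict(column_map or {})
    rename = {}
    for canonical, internal in FILE_COLUMNS.items():
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = internal
        elif canonical in MANDATORY:
            raise ConfigurationError(f"{path}: mandatory column '{source}' missing from header")
    df = raw.rename(columns=rename)
    for internal in INTERNAL_COLUMNS:
        if internal not in df.columns:
            df[internal] = np.nan
    name = trait_id if trait_id is not None else path.name.removesuffix(".gz").removesuffix(".tsv")
    return panel_from_frame(df[INTERNAL_COLUMNS], name, trait_role)


def write_summary_stats(panel: SummaryStatistics, path) -> None:
    """Write a panel as TSV with the canonical GWAS-SSF-like header."""
    inv = {v: k for k, v in FILE_COLUMNS.items()}
    out = panel.data.rename(columns=inv)[list(FILE_COLUMNS)]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a shared effect allele.

    ``data`` columns: rsid, beta_exp, se_exp, beta_out, se_out, eaf_exp,
    flipped (bool: outcome alleles were swapped and beta_out negated).
    """

    exposure_id: str
    outcome_id: str
    data: pd.DataFrame
    palindromic_removed: list[str] = field(default_factory=list)
    incompatible_removed: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def rsids(self) -> list[str]:
        return self.data["rsid"].tolist()

    @property
    def beta_exp(self) -> np.ndarray:
        return self.data["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.data["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.data["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.data["se_out"].to_numpy(float)

    @classmethod
    def from_arrays(
        cls,
        beta_exp: Sequence[float],
        se_exp: Sequence[float],
        beta_out: Sequence[float],
        se_out: Sequence[float],
        rsids: Sequence[str] | None = None,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
    ) -> "HarmonizedSet":
        beta_exp = np.asarray(beta_exp, float)
        if rsids is None:
            rsids = [f"snp{i + 1}" for i in range(len(beta_exp))]
        df = pd.DataFrame(
            {
                "rsid": list(rsids),
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, float),
                "beta_out": np.asarray(beta_out, float),
                "se_out": np.asarray(se_out, float),
                "eaf_exp": np.nan,
                "flipped": False,
            }
        )
        if (df["se_exp"] <= 0).any() or (df["se_out"] <= 0).any():
            raise ValidationError("standard errors must be positive")
        return cls(exposure_id, outcome_id, df)

    def subset(self, mask) -> "HarmonizedSet":
        return HarmonizedSet(self.exposure_id, self.outcome_id, _take(self.data, mask))

    def to_tsv(self, path) -> None:
        self.data[["rsid", "beta_exp", "se_exp", "beta_out", "se_out", "flipped"]].to_csv(
            path, sep="\t", index=False
        )


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return pd.Series(list(zip(ea, oa)), index=ea.index).isin(PALINDROMIC_PAIRS)


def harmonize(
    exposure: SummaryStatistics,
    outcome: SummaryStatistics,
    palindrome_policy: str = "drop",
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect allele.

    Variants whose outcome alleles are swapped relative to the exposure have
    ``beta_out`` negated (and eaf complemented internally); palindromic (A/T,
    C/G) variants are dropped under ``palindrome_policy='drop'`` or kept when
    both panels report allele frequencies on the same side of 0.5 under
    ``'infer_by_eaf'``.  Variants with incompatible allele sets are removed.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ConfigurationError(f"unknown palindrome policy: {palindrome_policy!r}")
    m = exposure.data.merge(outcome.data, on="rsid", suffixes=("_exp", "_out"), how="inner")
    if m.empty:
        raise HarmonizationError(
            f"no shared rsids between '{exposure.trait_id}' and '{outcome.trait_id}'"
        )
    ea_e, oa_e = m["effect_allele_exp"], m["other_allele_exp"]
    ea_o, oa_o = m["effect_allele_out"], m["other_allele_out"]
    match = (ea_e == ea_o) & (oa_e == oa_o)
    swapped = (ea_e == oa_o) & (oa_e == ea_o) & ~match
    palindromic = _is_palindromic(ea_e, oa_e)

    keep = (match | swapped).to_numpy().copy()
    flipped = swapped.to_numpy().copy()
    incompatible = m.loc[~(match | swapped), "rsid"].tolist()

    pal_removed: list[str] = []
    pal_idx = np.flatnonzero(palindromic.to_numpy() & keep)
    if len(pal_idx):
        if palindrome_policy == "drop":
            keep[pal_idx] = False
            pal_removed = m.loc[pal_idx, "rsid"].tolist()
        else:
            eaf_e = m["eaf_exp"].to_numpy(float)[pal_idx]
            eaf_o = m["eaf_out"].to_numpy(float)[pal_idx]
            same_side = (
                np.isfinite(eaf_e)
                & np.isfinite(eaf_o)
                & (eaf_e != 0.5)
                & (eaf_o != 0.5)
                & ((eaf_e < 0.5) == (eaf_o < 0.5))
            )
            keep[pal_idx[~same_side]] = False
            pal_removed = m.loc[pal_idx[~same_side], "rsid"].tolist()
            # same-side frequencies identify the shared allele: no sign flip,
            # whatever the lexical arrangement (a swap is indistinguishable
            # from a strand flip for these variants)
            flipped[pal_idx[same_side]] = False

    kept = m[keep].reset_index(drop=True)
    flip = flipped[keep]
    if kept.empty:
        raise HarmonizationError(
            f"harmonization of '{exposure.trait_id}' vs '{outcome.trait_id}' removed every variant"
        )
    beta_out = kept["beta_out"].to_numpy(float)
    beta_out[flip] = -beta_out[flip]
    out = pd.DataFrame(
        {
            "rsid": kept["rsid"],
            "beta_exp": kept["beta_exp"].to_numpy(float),
            "se_exp": kept["se_exp"].to_numpy(float),
            "beta_out": beta_out,
            "se_out": kept["se_out"].to_numpy(float),
            "eaf_exp": kept["eaf_exp"].to_numpy(float),
            "flipped": flip,
        }
    )
    n_removed = len(incompatible) + len(pal_removed)
    if n_removed:
        logger.info(
            "harmonize(%s, %s): removed %d variant(s) (%d incompatible, %d palindromic), flipped %d",
            exposure.trait_id,
            outcome.trait_id,
            n_removed,
            len(incompatible),
            len(pal_removed),
            int(flip.sum()),
        )
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, out, pal_removed, incompatible)


# ---------------------------------------------------------------------------
# LD matrices
# ---------------------------------------------------------------------------


@dataclass
class LdMatrix:
    """Symmetric matrix of pairwise squared correlations keyed by rsid."""

    rsids: list[str]
    r2: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, float)
        if self.r2.shape != (len(self.rsids), len(self.rsids)):
            raise ValidationError("LD matrix shape does not match rsid count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8, rtol=0):
            raise ValidationError("LD matrix is not symmetric (tolerance 1e-8)")
        if np.any(self.r2 < -1e-8) or np.any(self.r2 > 1 + 1e-8):
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        self.r2 = 0.5 * (self.r2 + self.r2.T)
        np.clip(self.r2, 0.0, 1.0, out=self.r2)
        np.fill_diagonal(self.r2, 1.0)
        self._index = {r: i for i, r in enumerate(self.rsids)}

    @classmethod
    def identity(cls, rsids: Iterable[str]) -> "LdMatrix":
        rsids = list(rsids)
        return cls(rsids, np.eye(len(rsids)))

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def lookup(self, a: str, b: str) -> float | None:
        """r2 between two rsids, or None when either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def read_ld(path) -> LdMatrix:
    """Read an LD matrix from square TSV or long (rsid_a, rsid_b, r2) TSV."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"LD file not found: {path}")
    head = pd.read_csv(path, sep="\t", nrows=0)
    if {"rsid_a", "rsid_b", "r2"}.issubset(head.columns):
        long = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
        rsids = sorted(set(long["rsid_a"]) | set(long["rsid_b"]))
        idx = {r: i for i, r in enumerate(rsids)}
        mat = np.eye(len(rsids))
        for row in long.itertuples(index=False):
            i, j = idx[row.rsid_a], idx[row.rsid_b]
            mat[i, j] = mat[j, i] = float(row.r2)
        return LdMatrix(rsids, mat)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix([str(r) for r in df.index], df.to_numpy(float))


def write_ld(ld: LdMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.rsids, columns=ld.rsids).to_csv(path, sep="\t")
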