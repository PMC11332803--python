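"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator works directly at the summary level: for each SNP a true
marginal effect is combined with sampling noise whose standard error follows
the standard GWAS approximation se = 1/sqrt(2 * maf * (1 - maf) * n).  Three
non-overlapping panels (exposure, mediator, outcome) share a SNP map, so every
pipeline stage can be scored against the generator's ground truth.

Causal structure (per SNP j):

* exposure instruments carry gamma_j ~ N(0, sigma_gamma^2),
* mediator-specific instruments carry delta_j ~ N(0, sigma_delta^2),
* outcome-specific instruments carry eta_j ~ N(0, sigma_eta^2) (used to test
  reverse-direction screening),
* optional horizontal pleiotropy alpha_j acts on the outcome directly.

True marginal effects: x_j = gamma_j + d*eta_j (d = reverse_effect),
m_j = a*x_j + delta_j, o_j = (c_direct + a*b)*gamma_j + b*delta_j + eta_j +
alpha_j, so the decomposition identity c_total = c_direct + a*b holds by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .gwas_io import LdMatrix, SummaryStatistics, panel_from_frame, read_summary_stats, read_ld, write_ld

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]
_P_FLOOR = 1e-300


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind one generated dataset."""

    a_true: float
    b_true: float
    c_direct_true: float
    gamma: np.ndarray
    delta: np.ndarray
    eta: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    rsids: list[str]
    pleiotropy_mode: str
    n_exp: int
    n_med: int
    n_out: int
    seed: int
    reverse_effect: float = 0.0

    @property
    def c_total(self) -> float:
        return self.c_direct_true + self.a_true * self.b_true

    def to_dict(self) -> dict:
        return {
            "a_true": self.a_true,
            "b_true": self.b_true,
            "c_direct_true": self.c_direct_true,
            "c_total": self.c_total,
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "eta": self.eta.tolist(),
            "alpha": self.alpha.tolist(),
            "maf": self.maf.tolist(),
            "rsids": self.rsids,
            "pleiotropy_mode": self.pleiotropy_mode,
            "n_exp": self.n_exp,
            "n_med": self.n_med,
            "n_out": self.n_out,
            "seed": self.seed,
            "reverse_effect": self.reverse_effect,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        d.pop("c_total", None)
        for k in ("gamma", "delta", "eta", "alpha", "maf"):
            d[k] = np.asarray(d[k], float)
        return cls(**d)


@dataclass
class ChainBundle:
    """One generated mediation dataset: three panels, LD, and its truth."""

    exposure: SummaryStatistics
    mediator: SummaryStatistics
    outcome: SummaryStatistics
    ld: LdMatrix
    truth: SyntheticTruth


def _positions(n_snps: int, block_sizes: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome labels and positions: one well-separated locus per block/SNP.

    Loci are 25 Mb apart (beyond the 10,000 kb clump window); SNPs within a
    block sit 10 kb apart so a block is always clumped together.
    """
    chrom = np.empty(n_snps, object)
    pos = np.empty(n_snps, np.int64)
    sizes = list(block_sizes) + [1] * (n_snps - sum(block_sizes))
    i = 0
    for locus, size in enumerate(sizes):
        c = str(locus % 22 + 1)
        base = (locus // 22) * 25_000_000 + 1_000_000
        for k in range(size):
            chrom[i] = c
            pos[i] = base + 10_000 * k
            i += 1
    return chrom, pos


def _ld_from_blocks(rsids: list[str], block_spec) -> LdMatrix:
    mat = np.eye(len(rsids))
    start = 0
    for size, r2 in block_spec:
        if start + size > len(rsids):
            raise ConfigurationError("LD block spec exceeds the number of SNPs")
        if not 0 <= r2 <= 1:
            raise ConfigurationError("within-block r2 must be in [0, 1]")
        mat[start : start + size, start : start + size] = r2
        start += size
    np.fill_diagonal(mat, 1.0)
    return LdMatrix(rsids, mat)


def _panel(
    trait_id: str,
    role: str,
    rsids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    ea: np.ndarray,
    oa: np.ndarray,
    maf: np.ndarray,
    true_beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> SummaryStatistics:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta = true_beta + se * rng.standard_normal(len(rsids))
    p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), _P_FLOOR, 1.0)
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pvalue": p,
            "n": float(n),
        }
    )
    return panel_from_frame(df, trait_id, role)


def generate_chain(
    j_snps: int = 50,
    a: float = 0.3,
    b: float = -0.25,
    c_direct: float = -0.05,
    *,
    j_mediator_snps: int | None = None,
    j_outcome_snps: int = 0,
    n_null: int = 0,
    n_exp: int = 50_000,
    n_med: int = 50_000,
    n_out: int = 50_000,
    sigma_gamma: float = 0.08,
    sigma_delta: float = 0.08,
    sigma_eta: float = 0.08,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_blocks=None,
    pleiotropy_mode: str = "none",
    pleiotropy_magnitude: float = 0.0,
    pleiotropy_fraction: float = 0.0,
    reverse_effect: float = 0.0,
    seed: int,
) -> ChainBundle:
    """Generate exposure, mediator and outcome summary panels plus LD and truth.

    ``j_snps`` exposure instruments are followed by ``j_mediator_snps``
    mediator-specific instruments (default: same count), ``j_outcome_snps``
    outcome-specific instruments and ``n_null`` null SNPs.  ``ld_blocks`` is a
    sequence of ``(size, within_block_r2)`` tuples laid over the first SNPs;
    remaining SNPs are mutually independent.
    """
    if j_snps < 1:
        raise ConfigurationError("j_snps must be >= 1")
    for n in (n_exp, n_med, n_out):
        if n < 100:
            raise ConfigurationError("per-panel sample sizes must be >= 100")
    if j_mediator_snps is None:
        j_mediator_snps = j_snps
    total = j_snps + j_mediator_snps + j_outcome_snps + n_null
    rng = np.random.default_rng(seed)

    rsids = [f"rs{i + 1:06d}" for i in range(total)]
    maf = rng.uniform(*maf_range, total)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], object)
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], object)

    gamma = np.zeros(total)
    delta = np.zeros(total)
    eta = np.zeros(total)
    gamma[:j_snps] = sigma_gamma * rng.standard_normal(j_snps)
    delta[j_snps : j_snps + j_mediator_snps] = sigma_delta * rng.standard_normal(j_mediator_snps)
    eta[j_snps + j_mediator_snps : j_snps + j_mediator_snps + j_outcome_snps] = (
        sigma_eta * rng.standard_normal(j_outcome_snps)
    )

    alpha = _draw_pleiotropy(gamma, pleiotropy_mode, pleiotropy_magnitude, pleiotropy_fraction, rng)

    block_spec = [tuple(bs) for bs in (ld_blocks or [])]
    if sum(int(s) for s, _ in block_spec) > total:
        raise ConfigurationError("LD block spec exceeds the number of SNPs")
    chrom, pos = _positions(total, [int(s) for s, _ in block_spec])
    ld = _ld_from_blocks(rsids, block_spec) if block_spec else LdMatrix.identity(rsids)
    ld.positions = pos.copy()

    x_true = gamma + reverse_effect * eta
    m_true = a * x_true + delta
    o_true = (c_direct + a * b) * gamma + b * delta + eta + alpha

    truth = SyntheticTruth(
        a_true=a,
        b_true=b,
        c_direct_true=c_direct,
        gamma=gamma,
        delta=delta,
        eta=eta,
        alpha=alpha,
        maf=maf,
        rsids=rsids,
        pleiotropy_mode=pleiotropy_mode,
        n_exp=n_exp,
        n_med=n_med,
        n_out=n_out,
        seed=seed,
        reverse_effect=reverse_effect,
    )
    exposure = _panel("exposure", "exposure", rsids, chrom, pos, ea, oa, maf, x_true, n_exp, rng)
    mediator = _panel("mediator", "mediator", rsids, chrom, pos, ea, oa, maf, m_true, n_med, rng)
    outcome = _panel("outcome", "outcome", rsids, chrom, pos, ea, oa, maf, o_true, n_out, rng)
    return ChainBundle(exposure, mediator, outcome, ld, truth)


def _draw_pleiotropy(
    gamma: np.ndarray, mode: str, magnitude: float, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    if mode not in ("none", "balanced", "directional"):
        raise ConfigurationError(f"unknown pleiotropy mode: {mode!r}")
    if not 0 <= fraction <= 1:
        raise ConfigurationError("pleiotropy fraction must be in [0, 1]")
    alpha = np.zeros(len(gamma))
    if mode == "none" or fraction == 0:
        return alpha
    candidates = np.flatnonzero(gamma != 0)
    k = int(round(fraction * len(candidates)))
    if k == 0:
        return alpha
    chosen = rng.choice(candidates, size=k, replace=False)
    if mode == "balanced":
        alpha[chosen] = magnitude * rng.standard_normal(k)
    else:
        # directional pleiotropy is defined relative to the exposure-raising
        # allele: a constant outcome shift per exposure-increasing allele copy
        alpha[chosen] = magnitude * np.sign(gamma[chosen])
    return alpha


def inject_pleiotropy(
    bundle: ChainBundle, mode: str, magnitude: float, fraction: float, seed: int
) -> ChainBundle:
    """Add horizontal-pleiotropy effects to the outcome panel of a bundle.

    A random ``fraction`` of the exposure-instrument SNPs receive alpha_j
    (balanced: N(0, magnitude^2); directional: the constant ``magnitude``)
    added to their outcome betas; p-values are recomputed and the returned
    bundle's truth carries the updated alpha so diagnostics can be scored.
    """
    rng = np.random.default_rng(seed)
    alpha = _draw_pleiotropy(bundle.truth.gamma, mode, magnitude, fraction, rng)
    out = bundle.outcome.data.copy()
    out["beta"] = out["beta"].to_numpy(float) + alpha
    se = out["se"].to_numpy(float)
    out["pvalue"] = np.clip(
        2.0 * stats.norm.sf(np.abs(out["beta"].to_numpy(float) / se)), _P_FLOOR, 1.0
    )
    truth = SyntheticTruth.from_dict(bundle.truth.to_dict())
    truth.alpha = bundle.truth.alpha + alpha
    truth.pleiotropy_mode = mode if fraction > 0 else bundle.truth.pleiotropy_mode
    outcome = SummaryStatistics(bundle.outcome.trait_id, bundle.outcome.trait_role, out)
    return ChainBundle(bundle.exposure, bundle.mediator, outcome, bundle.ld, truth)


FIXTURE_FILES = ("exposure.tsv", "mediator.tsv", "outcome.tsv", "ld.tsv", "truth.json")


def write_fixture(bundle: ChainBundle, directory) -> list[Path]:
    """Write the bundle as plain-text fixture files; re-reading is lossless."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.exposure.to_tsv(directory / "exposure.tsv")
    bundle.mediator.to_tsv(directory / "mediator.tsv")
    bundle.outcome.to_tsv(directory / "outcome.tsv")
    write_ld(bundle.ld, directory / "ld.tsv")
    (directory / "truth.json").write_text(json.dumps(bundle.truth.to_dict(), sort_keys=True, indent=1))
    return [directory / f for f in FIXTURE_FILES]


def read_fixture(directory) -> ChainBundle:
    """Read a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    exposure = read_summary_stats(directory / "exposure.tsv", trait_id="exposure", trait_role="exposure")
    mediator = read_summary_stats(directory / "mediator.tsv", trait_id="mediator", trait_role="mediator")
    outcome = read_summary_stats(directory / "outcome.tsv", trait_id="outcome", trait_role="outcome")
    ld = read_ld(directory / "ld.tsv")
    truth = SyntheticTruth.from_dict(json.loads((directory / "truth.json").read_text()))
    return ChainBundle(exposure, mediator, outcome, ld, truth)
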