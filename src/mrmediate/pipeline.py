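"""End-to-end orchestration: screening, reverse-MR checks, mediation chains.

The flow mirrors the usual mediated two-sample MR design: many candidate
exposures are screened against the outcome with IVW (pass when p <
alpha_screen), survivors are checked in the reverse direction (pass when p >=
alpha_reverse, i.e. no evidence of reverse causation), and an
exposure/mediator/outcome triple is then analysed with the full five-estimator
battery plus diagnostics, feeding the product-method mediation decomposition.

Determinism: a single master seed fans out to per-component seeds by hashing
the component name, so adding a component never shifts another's stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .diagnostics import cochran_q, diagnostics_table, egger_intercept_test, leave_one_out, mr_presso
from .errors import ConfigurationError, EmptyInputError, HarmonizationError, MrmediateError
from .estimators import MrResult, classify_direction, ivw, run_all_estimators
from .gwas_io import HarmonizedSet, LdMatrix, SummaryStatistics, harmonize
from .instruments import InstrumentSet, filter_weak, ld_clump, select_by_pvalue
from .mediation import MediationResult, mediate

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, component: str) -> int:
    """Stable per-component seed below 2^31 derived from the master seed."""
    digest = hashlib.blake2s(f"{master_seed}:{component}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """All pipeline thresholds and stochastic settings in one record."""

    seed: int
    p_instrument: float = 1e-5
    clump_kb: float = 10_000.0
    clump_r2: float = 0.001
    f_min: float = 10.0
    f_method: str = "wald"
    alpha_screen: float = 0.05
    alpha_reverse: float = 0.05
    ivw_model: str = "multiplicative_random"
    palindrome_policy: str = "drop"
    ci_method: str = "delta"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    multiple_testing: str = "none"  # none | bonferroni | fdr_bh
    exclude_exposure_instruments: bool = True  # stage-2 instrument hygiene

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("a master seed (integer) is required")
        for name in ("p_instrument", "alpha_screen", "alpha_reverse", "presso_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must be in [0, 1]")
        if self.clump_kb < 0 or self.f_min < 0:
            raise ConfigurationError("clump_kb and f_min must be non-negative")
        if self.multiple_testing not in ("none", "bonferroni", "fdr_bh"):
            raise ConfigurationError(f"unknown multiple_testing mode: {self.multiple_testing!r}")
        if self.n_boot < 2 or self.presso_n_sim < 1:
            raise ConfigurationError("n_boot must be >= 2 and presso_n_sim >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def select_instruments(
    panel: SummaryStatistics,
    ld: LdMatrix | None,
    cfg: RunConfig,
    exclude_rsids: set[str] | None = None,
) -> InstrumentSet:
    """p-threshold, optional exclusion list, LD clumping, weak-instrument filter."""
    candidates = select_by_pvalue(panel, cfg.p_instrument)
    if exclude_rsids:
        candidates = candidates.subset(~candidates.data["rsid"].isin(exclude_rsids))
    if ld is not None and len(candidates) > 1:
        candidates = ld_clump(candidates, ld, cfg.clump_kb, cfg.clump_r2)
    if len(candidates) == 0:
        return InstrumentSet(panel.trait_id, candidates.data.assign(f_stat=[], r2_explained=[]))
    return filter_weak(candidates, cfg.f_min, cfg.f_method)


@dataclass
class StageResult:
    """One exposure->outcome MR stage: instruments, harmonized data, results."""

    label: str
    exposure_id: str
    outcome_id: str
    instruments: InstrumentSet
    harmonized: HarmonizedSet
    results: dict[str, MrResult]
    diagnostics: dict


def run_mr(
    exposure: SummaryStatistics,
    outcome: SummaryStatistics,
    ld: LdMatrix | None,
    cfg: RunConfig,
    label: str | None = None,
    exclude_rsids: set[str] | None = None,
    full_battery: bool = True,
) -> StageResult:
    """One complete MR stage with the estimator battery and diagnostics."""
    label = label or f"{exposure.trait_id}_to_{outcome.trait_id}"
    inst = select_instruments(exposure, ld, cfg, exclude_rsids)
    if len(inst) == 0:
        raise EmptyInputError(f"{label}: no instruments survive selection")
    h = harmonize(inst.as_summary(), outcome, cfg.palindrome_policy)
    seed = derive_seed(cfg.seed, f"estimators:{label}")
    if full_battery:
        results = run_all_estimators(
            h, seed=seed, n_boot=cfg.n_boot, ivw_model=cfg.ivw_model
        )
    else:
        results = {"ivw": ivw(h, model=cfg.ivw_model)}
    diag: dict = {}
    if len(h) >= 2:
        diag["cochran_q"] = cochran_q(h)
    if full_battery and len(h) >= 3:
        diag["egger_intercept"] = egger_intercept_test(h)
        diag["leave_one_out"] = leave_one_out(h, model=cfg.ivw_model)
    if full_battery and len(h) >= 4:
        diag["presso"] = mr_presso(
            h,
            n_sim=cfg.presso_n_sim,
            alpha=cfg.presso_alpha,
            seed=derive_seed(cfg.seed, f"presso:{label}"),
        )
    return StageResult(label, exposure.trait_id, outcome.trait_id, inst, h, results, diag)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def forward_pass(pvalue: float, alpha: float) -> bool:
    """Forward screening keeps traits with p strictly below alpha."""
    return pvalue < alpha


def reverse_pass(pvalue: float, alpha: float) -> bool:
    """Reverse check passes (no reverse causation) when p >= alpha; the
    boundary p == alpha counts as non-significant and passes."""
    return pvalue >= alpha


@dataclass
class ScreenResult:
    """Outcome of screening one trait in one direction."""

    trait_id: str
    direction: str  # forward | reverse
    result: MrResult | None
    passed: bool
    pvalue_adjusted: float | None = None
    reason: str | None = None

    def to_dict(self) -> dict:
        d = {
            "trait_id": self.trait_id,
            "direction": self.direction,
            "passed": self.passed,
            "pvalue_adjusted": self.pvalue_adjusted,
            "reason": self.reason,
        }
        if self.result is not None:
            d.update(self.result.to_dict())
        return d


def forward_screen(
    exposures: Sequence[SummaryStatistics],
    outcome: SummaryStatistics,
    ld: LdMatrix | None,
    cfg: RunConfig,
) -> list[ScreenResult]:
    """IVW-screen each candidate exposure against the outcome.

    Per-trait failures (no instruments, empty harmonization) are recorded with
    a reason rather than aborting the batch.  With ``cfg.multiple_testing``
    other than ``none`` the IVW p-values are adjusted jointly before the pass
    decision.
    """
    if not exposures:
        raise ConfigurationError("forward_screen needs at least one exposure panel")
    rows: list[ScreenResult] = []
    for exposure in exposures:
        try:
            stage = run_mr(exposure, outcome, ld, cfg, full_battery=False)
            rows.append(ScreenResult(exposure.trait_id, "forward", stage.results["ivw"], False))
        except MrmediateError as exc:
            logger.warning("screen failure for %s: %s", exposure.trait_id, exc)
            rows.append(ScreenResult(exposure.trait_id, "forward", None, False, reason=str(exc)))
    scored = [r for r in rows if r.result is not None]
    if scored:
        pvals = np.array([r.result.pvalue for r in scored])
        if cfg.multiple_testing != "none":
            pvals = multipletests(pvals, method=cfg.multiple_testing)[1]
        for r, p in zip(scored, pvals):
            r.pvalue_adjusted = float(p)
            r.passed = forward_pass(float(p), cfg.alpha_screen)
    return rows


def reverse_check(
    outcome_as_exposure: SummaryStatistics,
    trait_as_outcome: SummaryStatistics,
    ld: LdMatrix | None,
    cfg: RunConfig,
) -> ScreenResult:
    """Reverse-direction IVW; passes when the reverse effect is non-significant."""
    try:
        stage = run_mr(outcome_as_exposure, trait_as_outcome, ld, cfg, full_battery=False)
    except MrmediateError as exc:
        logger.warning("reverse check failure for %s: %s", trait_as_outcome.trait_id, exc)
        return ScreenResult(trait_as_outcome.trait_id, "reverse", None, False, reason=str(exc))
    res = stage.results["ivw"]
    return ScreenResult(
        trait_as_outcome.trait_id, "reverse", res, reverse_pass(res.pvalue, cfg.alpha_reverse)
    )


# ---------------------------------------------------------------------------
# mediation chain
# ---------------------------------------------------------------------------

STAGE_LABELS = ("exposure_to_mediator", "mediator_to_outcome", "exposure_to_outcome")


@dataclass
class ChainReport:
    """Full three-MR mediation run: stage results, mediation, forest table."""

    stages: dict[str, StageResult]
    mediation: MediationResult
    forest: pd.DataFrame
    config: RunConfig
    classifications: dict[str, str] = field(default_factory=dict)

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        for label, st in self.stages.items():
            rec = diagnostics_table(
                st.harmonized,
                st.diagnostics.get("presso"),
                st.diagnostics["cochran_q"],
                st.diagnostics.get("egger_intercept"),
            )
            rec = {"stage": label, "exposure": st.exposure_id, "outcome": st.outcome_id, **rec}
            rows.append(rec)
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        return {
            "mediation": self.mediation.to_dict(),
            "classifications": self.classifications,
            "stages": {
                label: {m: r.to_dict() for m, r in st.results.items()}
                for label, st in self.stages.items()
            },
            "config": asdict(self.config),
        }

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.forest.to_csv(directory / "forest.tsv", sep="\t", index=False)
        self.diagnostics_frame().to_csv(directory / "diagnostics.tsv", sep="\t", index=False)
        (directory / "mediation.json").write_text(
            json.dumps(self.summary_dict(), sort_keys=True, indent=1)
        )
        for label, st in self.stages.items():
            st.harmonized.to_tsv(directory / f"harmonized_{label}.tsv")


def _forest_frame(stages: dict[str, StageResult]) -> pd.DataFrame:
    rows = []
    for label, st in stages.items():
        for method, res in st.results.items():
            rows.append(
                {
                    "stage": label,
                    "exposure": st.exposure_id,
                    "outcome": st.outcome_id,
                    "method": method,
                    "n_snp": res.n_snp,
                    "beta": res.beta,
                    "se": res.se,
                    "pvalue": res.pvalue,
                    "or": res.or_,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
    return pd.DataFrame(rows)


def run_mediation_chain(
    exposure: SummaryStatistics,
    mediator: SummaryStatistics,
    outcome: SummaryStatistics,
    ld: LdMatrix | None,
    cfg: RunConfig,
) -> ChainReport:
    """Three MR analyses (exposure->mediator, mediator->outcome,
    exposure->outcome) with the full battery, then product-method mediation
    from the IVW triple.

    Stage-2 instrument selection excludes SNPs that qualify as exposure
    instruments when ``cfg.exclude_exposure_instruments`` is set: such SNPs
    reach the outcome through the exposure's direct path as well, which would
    bias the mediator->outcome effect.
    """
    if exposure.trait_id == mediator.trait_id:
        raise ConfigurationError("mediator panel is identical to the exposure panel")
    if len(exposure.data) == len(mediator.data) and np.array_equal(
        exposure.data["beta"].to_numpy(), mediator.data["beta"].to_numpy()
    ):
        raise ConfigurationError("mediator panel is identical to the exposure panel")

    exclude: set[str] | None = None
    if cfg.exclude_exposure_instruments:
        exclude = set(select_by_pvalue(exposure, cfg.p_instrument).rsids)

    stages: dict[str, StageResult] = {}
    for label, (exp_panel, out_panel, excl) in {
        "exposure_to_mediator": (exposure, mediator, None),
        "mediator_to_outcome": (mediator, outcome, exclude),
        "exposure_to_outcome": (exposure, outcome, None),
    }.items():
        try:
            stages[label] = run_mr(exp_panel, out_panel, ld, cfg, label=label, exclude_rsids=excl)
        except MrmediateError as exc:
            raise MrmediateError(f"mediation chain aborted at stage '{label}': {exc}") from exc

    med = mediate(
        stages["exposure_to_mediator"].results["ivw"],
        stages["mediator_to_outcome"].results["ivw"],
        stages["exposure_to_outcome"].results["ivw"],
        ci_method=cfg.ci_method,
        seed=derive_seed(cfg.seed, "mediation_ci"),
    )
    classifications = {
        label: classify_direction(st.results["ivw"], cfg.alpha_screen) for label, st in stages.items()
    }
    return ChainReport(stages, med, _forest_frame(stages), cfg, classifications)
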