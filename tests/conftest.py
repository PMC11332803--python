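import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedSet, generate_chain, panel_from_frame


@pytest.fixture
def three_snp_h() -> HarmonizedSet:
    """Exposure/outcome pairs whose IVW slope is 820/1400."""
    return HarmonizedSet.from_arrays(
        beta_exp=[0.1, 0.2, 0.3],
        se_exp=[0.01, 0.01, 0.01],
        beta_out=[0.04, 0.12, 0.18],
        se_out=[0.01, 0.01, 0.01],
    )


@pytest.fixture
def collinear_h() -> HarmonizedSet:
    """Points lying exactly on beta_out = 0.02 + 0.5 * beta_exp."""
    return HarmonizedSet.from_arrays(
        beta_exp=[0.1, 0.2, 0.3],
        se_exp=[0.01, 0.01, 0.01],
        beta_out=[0.07, 0.12, 0.17],
        se_out=[0.01, 0.01, 0.01],
    )


@pytest.fixture
def chain_factory():
    """Callable building synthetic mediation datasets with the default truth."""

    def make(seed: int, **kwargs):
        return generate_chain(seed=seed, **kwargs)

    return make


def make_panel(
    rsids,
    betas,
    ses,
    pvalues=None,
    chrom="1",
    positions=None,
    ea="A",
    oa="G",
    eaf=None,
    n=None,
    trait_id="trait",
    role="exposure",
):
    """Small hand-built panel for targeted unit tests."""
    k = len(rsids)
    if positions is None:
        positions = [1000 * (i + 1) for i in range(k)]
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "chromosome": [chrom] * k if isinstance(chrom, str) else chrom,
            "position": positions,
            "effect_allele": [ea] * k if isinstance(ea, str) else ea,
            "other_allele": [oa] * k if isinstance(oa, str) else oa,
            "eaf": [np.nan] * k if eaf is None else eaf,
            "beta": betas,
            "se": ses,
            "pvalue": [0.5] * k if pvalues is None else pvalues,
            "n": [np.nan] * k if n is None else n,
        }
    )
    return panel_from_frame(df, trait_id, role)
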