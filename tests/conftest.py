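import numpy as np
import pandas as pd
import pytest

from shrinkmr import SummaryTable, HarmonizedSet


def make_table(rows, **meta) -> SummaryTable:
    """Build a SummaryTable from a list of dicts, filling canonical defaults."""
    defaults = {
        "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
        "pvalue": 0.5, "n": 1000,
    }
    if not rows:
        cols = ["variant_id", "beta", "se", *defaults]
        return SummaryTable(pd.DataFrame(columns=cols), **meta)
    return SummaryTable(pd.DataFrame([{**defaults, **r} for r in rows]), **meta)


def make_hset(gamma, gamma_se, Gamma, Gamma_se, n_exp=10_000, n_out=10_000
              ) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays."""
    p = len(gamma)
    return HarmonizedSet(
        pd.DataFrame(
            {
                "variant_id": [f"rs{j + 1:04d}" for j in range(p)],
                "effect_allele": "A",
                "other_allele": "G",
                "eaf_exp": 0.3,
                "beta_exp": np.asarray(gamma, float),
                "se_exp": np.asarray(gamma_se, float),
                "pvalue_exp": 1e-6,
                "n_exp": n_exp,
                "eaf_out": 0.3,
                "beta_out": np.asarray(Gamma, float),
                "se_out": np.asarray(Gamma_se, float),
                "pvalue_out": 0.01,
                "n_out": n_out,
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def simple_exposure():
    return make_table(
        [
            {"variant_id": "rs0001", "beta": 0.10, "se": 0.02, "pvalue": 5.7e-7},
            {"variant_id": "rs0002", "beta": -0.05, "se": 0.01, "pvalue": 5.7e-7},
            {"variant_id": "rs0003", "beta": 0.08, "se": 0.02, "pvalue": 6.3e-5},
        ],
        trait_label="exposure", stratum="female",
    )
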