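import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from drugtarget_mr import GwasTable, HarmonizedSet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_gwas(rows, label="trait", trait_type="quantitative") -> GwasTable:
    """Build a GwasTable from a list of dicts with sensible defaults."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-8,
        "n": 10_000,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, variant_id=f"rs{i+1}", pos=1000 * (i + 1))
        rec.update(row)
        recs.append(rec)
    return GwasTable(label, trait_type, pd.DataFrame(recs))


def make_harmonized(beta_x, se_x, beta_y, se_y, exposure="X", outcome="Y") -> HarmonizedSet:
    k = len(beta_x)
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{i+1}" for i in range(k)],
            "effect_allele": "A",
            "other_allele": "G",
            "beta_x": np.asarray(beta_x, float),
            "se_x": np.asarray(se_x, float),
            "beta_y": np.asarray(beta_y, float),
            "se_y": np.asarray(se_y, float),
        }
    )
    return HarmonizedSet(exposure, outcome, df)


@pytest.fixture
def consistent_set():
    """Five instruments exactly consistent with causal effect 0.5."""
    bx = np.array([1.0, 2.0, 0.5, 1.5, 1.0])
    return make_harmonized(bx, np.full(5, 0.05), 0.5 * bx, np.full(5, 0.1))
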