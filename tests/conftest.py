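import hypothesis
import numpy as np
import pandas as pd
import pytest

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("suite")


def make_sumstats(rows) -> pd.DataFrame:
    """Build a canonical summary-statistic frame from row dicts."""
    defaults = {"chrom": "1", "eaf": 0.3, "info": 0.95}
    out = []
    for i, row in enumerate(rows):
        rec = {"rsid": f"rs{i + 1}", "pos": 1000 * (i + 1),
               "effect_allele": "A", "other_allele": "G",
               **defaults, **row}
        if "p" not in rec and "se" in rec:
            from scipy.stats import norm
            rec["p"] = 2 * norm.sf(abs(rec["beta"] / rec["se"]))
        out.append(rec)
    df = pd.DataFrame(out)
    df.attrs["sign_flipped"] = False
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def tiny_config():
    from pleioscan import SimulationConfig
    return SimulationConfig(seed=11, n_snps=60, n_blocks=10, block_rho=0.8,
                            maf_range=(0.2, 0.4), n_individuals=500,
                            n_genes=30, n_samples_expr=100, n_cohorts=2)
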