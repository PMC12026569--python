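import numpy as np
import pandas as pd
import pytest

from plasmakit.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A quick cohort: enough sites for moment estimates, light fragments."""
    return SimConfig(n_sites=500, fragments_per_site=20, fragments_per_bin=500, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_variants(rows) -> pd.DataFrame:
    """Variant table helper: rows of (chrom, pos, af, depth[, gts])."""
    records = []
    for i, row in enumerate(rows):
        chrom, pos, af, depth = row[:4]
        rec = {
            "chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
            "allele_fraction": af, "depth": depth,
        }
        if len(row) > 4:
            gp, gm, gf = row[4]
            rec.update({"gt_proband": gp, "gt_mother": gm, "gt_father": gf})
        records.append(rec)
    return pd.DataFrame(records)
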