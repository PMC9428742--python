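import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("repro", derandomize=True)
_hsettings.load_profile("repro")

from gdrisk import (SyntheticConfig, from_counts, load_table_counts,
                    simulate_cohort)


@pytest.fixture(scope="session")
def counts():
    return load_table_counts()


@pytest.fixture(scope="session")
def prs_mets_cohort(counts):
    return from_counts(counts, block="prs_mets")


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic cohort + genotypes shared across tests."""
    cfg = SyntheticConfig(n=800, seed=123, n_variants=30)
    return simulate_cohort(cfg)


def iter_table_rows(counts):
    """Yield (label, cases_in, controls_in, printed) for every row of the
    two published stratified tables, with rest-of-cohort complements."""
    total_cases = counts["cohort"]["cases"]
    total_controls = counts["cohort"]["controls"]
    seen = set()
    for block, rec in counts["covariate_blocks"].items():
        yield (block, rec["parent"]["cases"], rec["parent"]["controls"],
               rec["parent"]["printed"])
        for child, crec in rec["children"].items():
            yield (f"{block}&{child}", crec["cases"], crec["controls"], crec["printed"])
    for name, rec in counts["prs_mets"].items():
        yield (name, rec["cases"], rec["controls"], rec["printed"])
        for child, crec in rec["children"].items():
            label = f"{name}&{child}"
            yield (label, crec["cases"], crec["controls"], crec["printed"])
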