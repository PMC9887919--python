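import pandas as pd
import pytest

from hbiso import association as assoc
from hbiso import body_composition as bc
from hbiso import hbi as hbi_mod
from hbiso import simulate as sim


@pytest.fixture(scope="session")
def adapted_config():
    return hbi_mod.load_hbi_config("adapted")


@pytest.fixture(scope="session")
def original_config():
    return hbi_mod.load_hbi_config("original")


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 300-participant synthetic cohort."""
    return sim.generate_cohort(sim.default_params(n=300, seed=42))


@pytest.fixture(scope="session")
def analyzed_cohort(small_cohort, adapted_config):
    """Filtered, scored, classified and quartile-labelled cohort."""
    kept, _ = hbi_mod.filter_energy(small_cohort)
    scored = hbi_mod.score_cohort(kept, adapted_config)
    status = bc.classify_so(scored)
    scored = scored.assign(
        so=status.flags["so"].astype(int),
        hbi_quartile=assoc.assign_quartiles(scored["hbi_total"], assoc.QuartileScheme()),
    )
    return scored


def make_2x2(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Expand a 2x2 table into participant rows.

    a/b = cases/non-cases among exposed, c/d = cases/non-cases among
    unexposed; returns columns y (outcome) and x (exposure).
    """
    rows = (
        [{"y": 1, "x": 1}] * a + [{"y": 0, "x": 1}] * b
        + [{"y": 1, "x": 0}] * c + [{"y": 0, "x": 0}] * d
    )
    return pd.DataFrame(rows)
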