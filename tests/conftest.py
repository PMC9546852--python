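"""Shared fixtures: simulated cohorts and the fitted bootstrap aging null.

Everything is generated programmatically with fixed seeds; the expensive
objects (default cohort with full mutation records, B=1000 bootstrap null)
are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import chemosig as cs


@pytest.fixture(scope="session")
def sbs_ref() -> pd.DataFrame:
    return cs.synthetic_signatures("SBS96")


@pytest.fixture(scope="session")
def dbs_ref() -> pd.DataFrame:
    return cs.synthetic_signatures("DBS78")


@pytest.fixture(scope="session")
def id_ref() -> pd.DataFrame:
    return cs.synthetic_signatures("ID83")


@pytest.fixture(scope="session")
def default_cohort() -> cs.SimulatedCohort:
    """Default study-condition cohort with full mutation records."""
    return cs.simulate_cohort(cs.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_exposures(default_cohort, sbs_ref, dbs_ref, id_ref):
    """Strict-refit exposures per scheme for the default cohort."""
    filt = cs.filter_clonal(default_cohort.records)
    out = {}
    for mt, ref in (("SBS96", sbs_ref), ("DBS78", dbs_ref), ("ID83", id_ref)):
        cm = cs.build_context_matrix(filt, default_cohort.meta, mt)
        out[mt] = cs.StrictSignatureRefitter(ref).fit_transform(cm.counts)
    return out


@pytest.fixture(scope="session")
def untreated_burden() -> pd.DataFrame:
    """Untreated burden table at the default generator settings."""
    coh = cs.simulate_cohort(
        cs.CohortConfig(n_donors_treated=0, n_radio_donors=0, seed=7), with_records=False
    )
    return cs.burden_from_truth(coh.truth, coh.meta)


@pytest.fixture(scope="session")
def aging_null(untreated_burden) -> cs.AgingBurdenNull:
    """B=1000 bootstrap aging null on the untreated SBS burdens."""
    return cs.AgingBurdenNull(B=1000, mut_type="SBS", random_state=5).fit(untreated_burden)


def null_donor_burdens(n_donors: int, seed: int, age_range=(20.0, 80.0)) -> pd.DataFrame:
    """Burden table of donors generated under the aging law only."""
    cfg = cs.CohortConfig(
        n_donors_untreated=0,
        n_donors_treated=n_donors,
        clones_per_donor_treated=3,
        platinum_per_cycle_mean=0.0,
        platinum_per_cycle_sd=0.0,
        fiveFU_activation_prob=0.0,
        n_radio_donors=0,
        age_range=age_range,
        seed=seed,
    )
    coh = cs.simulate_cohort(cfg, with_records=False)
    return cs.burden_from_truth(coh.truth, coh.meta)
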