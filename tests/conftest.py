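import numpy as np
import pytest

from platformsim import default_parameter_table, make_fixture


@pytest.fixture(scope="session")
def table():
    return default_parameter_table()


@pytest.fixture(scope="session")
def table_means(table):
    """Sampled-parameter dict with every draw fixed at its elicited mean."""
    out = {}
    for p in table:
        key = (p.name, p.design_type)
        out[key] = p.mean
    return out


@pytest.fixture()
def tiny_trial():
    """A 2-arm, ~20-patient trial with single-digit event triggers."""
    scens, _ = make_fixture("tiny")
    return scens[0].trials[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def means_for(table, design_type):
    """Mean-valued sampled dict for a design type (shared fallback)."""
    names = (
        "protocol_development", "trial_approvals", "database_development",
        "protocol_development_time", "trial_approvals_time",
        "database_development_time", "site_setup", "recruitment_per_patient",
        "monthly_followup_per_patient", "site_management_per_site_month",
        "database_management_per_month", "interim_analysis_per_group",
        "final_analysis_per_group",
    )
    return {n: table.resolve(n, design_type).mean for n in names}
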