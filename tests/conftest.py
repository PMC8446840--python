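import pytest

import stepmeta as sm


@pytest.fixture(scope="session")
def gastric_strata():
    """Published ascending example: adjuvant radiochemotherapy after D2
    gastrectomy; per-stage pooled (effect, 95% CI) ratio estimates."""
    return sm.datasets.load_example("gastric_adjuvant_crt")


@pytest.fixture(scope="session")
def oligometastases_strata():
    """Published descending example: local treatment for oligometastases."""
    return sm.datasets.load_example("oligometastases_lct")


def make_portfolio():
    """Small deterministic mixed portfolio: 3 unbalanced observational,
    2 balanced observational, 2 adequate randomized trials."""
    mk = sm.make_estimate
    rec = sm.StudyRecord
    D, B = sm.Design, sm.BalanceMethod
    return [
        rec("obs1", D.OBSERVATIONAL, B.NONE, mk(1.10, 0.80, 1.51)),
        rec("obs2", D.OBSERVATIONAL, B.UNKNOWN, mk(1.05, 0.70, 1.58)),
        rec("obs3", D.OBSERVATIONAL, B.NONE, mk(1.20, 0.85, 1.69)),
        rec("bal1", D.OBSERVATIONAL, B.PROPENSITY_MATCHING, mk(1.35, 1.02, 1.79)),
        rec("bal2", D.OBSERVATIONAL, B.MULTIVARIABLE_ADJUSTMENT, mk(1.42, 1.05, 1.92)),
        rec("rct1", D.RANDOMIZED, B.RANDOMIZATION, mk(1.50, 1.10, 2.05)),
        rec("rct2", D.RANDOMIZED, B.RANDOMIZATION, mk(1.47, 1.06, 2.04)),
    ]


@pytest.fixture
def mixed_portfolio():
    return make_portfolio()
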