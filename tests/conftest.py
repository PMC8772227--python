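import numpy as np
import pytest

from ftdcog import (
    CohortConfig,
    compute_z,
    fit_normative_models,
    fit_penalized_logistic,
    generate_cohort,
)
from ftdcog.battery import DEFAULT_BATTERY
from ftdcog.cohort import cohort_to_frame


@pytest.fixture(scope="session")
def default_cohort():
    """Published-size cohort (69/41/28 carriers, 275 controls), fixed seed."""
    cfg = CohortConfig(seed=11)
    participants = generate_cohort(cfg)
    return cfg, participants


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    _, participants = default_cohort
    return cohort_to_frame(participants).set_index("id")


@pytest.fixture(scope="session")
def default_z(default_cohort):
    """Normative models fitted on the controls of the default cohort plus
    the resulting z-score table."""
    _, participants = default_cohort
    controls = [p for p in participants if p.group == "control"]
    models = fit_normative_models(controls)
    z = compute_z(participants, models)
    return models, z


@pytest.fixture(scope="session")
def c9_fit(default_frame, default_z):
    """Penalized logistic fit of C9orf72 carriers vs controls on the default
    cohort (shared across discrimination/selection tests)."""
    _, z = default_z
    mask = default_frame["group"].isin(["C9orf72", "control"])
    labels = (default_frame.loc[mask, "group"] == "C9orf72").astype(int)
    return (
        fit_penalized_logistic(
            z.loc[mask.to_numpy()], labels.to_numpy(), folds=10, seed=11, gene="C9orf72"
        ),
        z.loc[mask.to_numpy()],
        labels,
    )


def flat_severity():
    """Stage-severity map with no CDR gradient (pure marginal profiles)."""
    return {0.5: 1.0, 1.0: 1.0, 2.0: 1.0, 3.0: 1.0}


def single_group_config(seed, n_carriers, n_controls, profile=None, **kw):
    """One carrier group vs controls, no stage gradient unless requested."""
    kwargs = dict(
        seed=seed,
        n_per_group={"C9orf72": n_carriers, "GRN": 0, "MAPT": 0, "control": n_controls},
        stage_severity=flat_severity(),
    )
    if profile is not None:
        kwargs["deficit_profile"] = {"C9orf72": profile}
    kwargs.update(kw)
    return CohortConfig(**kwargs)


def null_profile():
    return {t: (0.0, 1.0) for t in DEFAULT_BATTERY.ids}


def signal_profile(signal_tests, shift=-1.0):
    prof = null_profile()
    for t in signal_tests:
        prof[t] = (shift, 1.0)
    return prof
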