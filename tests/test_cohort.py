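"""Synthetic cohort generator: calibration, determinism, inversion contracts."""

import numpy as np
import pandas as pd
import pytest

from conftest import flat_severity, null_profile, single_group_config

from ftdcog import (
    CohortConfig,
    CohortConfigError,
    VisitHistory,
    generate_cohort,
    generate_followup,
)
from ftdcog.battery import DEFAULT_BATTERY
from ftdcog.cohort import (
    cohort_to_frame,
    default_control_models,
    frame_to_cohort,
    histories_to_frame,
)


def latent_z(participants, battery=DEFAULT_BATTERY):
    """Recover latent z-deficits using the *true* control models (the
    generator's own inverse transform, independent of the scoring module)."""
    models = default_control_models(battery)
    frame = cohort_to_frame(participants, battery)
    sex_male = (frame["sex"] == "M").astype(float).to_numpy()
    out = {}
    for t in battery:
        m = models[t.id]
        pred = m.predict(
            frame["age"].to_numpy(), frame["education"].to_numpy(), sex_male,
            frame["language"].to_numpy(),
        )
        z = (frame[t.id].to_numpy() - pred) / m.scale
        out[t.id] = -z if t.timed else z
    return frame, out


def test_null_profile_gives_zero_mean_deficits():
    cfg = single_group_config(0, 4000, 0, profile=null_profile(), missing_rate=0.0)
    parts = generate_cohort(cfg)
    _, z = latent_z(parts)
    for t, vals in z.items():
        # MC tolerance: 3 * SD/sqrt(n) with unit marginal SD
        assert abs(np.mean(vals)) < 3.0 / np.sqrt(len(vals)), t


def test_default_profile_marginal_means_match_configured_table():
    cfg = single_group_config(1, 5000, 0, missing_rate=0.0, cdr_stage_probs={0.5: 0.45, 1.0: 0.25, 2.0: 0.20, 3.0: 0.10}, stage_severity={0.5: 0.5, 1.0: 1.0, 2.0: 1.6, 3.0: 2.1})
    parts = generate_cohort(cfg)
    _, z = latent_z(parts)
    prof = cfg.deficit_profile["C9orf72"]
    for t, vals in z.items():
        mean, sd = prof[t]
        assert abs(np.mean(vals) - mean) < 3.0 * sd / np.sqrt(len(vals)), t


def test_stage_gradient_orders_mean_deficit_but_preserves_marginal():
    cfg = single_group_config(
        5, 6000, 0, missing_rate=0.0,
        stage_severity={0.5: 0.5, 1.0: 1.0, 2.0: 1.6, 3.0: 2.1},
    )
    parts = generate_cohort(cfg)
    frame, z = latent_z(parts)
    fcsrt = np.asarray(z["fcsrt_free"])
    cdr = frame["cdr_global"].to_numpy()
    m05 = fcsrt[cdr == 0.5].mean()
    m1 = fcsrt[cdr == 1.0].mean()
    assert m05 > m1  # prodromal carriers are milder
    assert abs(fcsrt.mean() - (-1.68)) < 3 * 1.36 / np.sqrt(len(fcsrt))


def test_seed_determinism_byte_identical():
    cfg = CohortConfig(seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(CohortConfig(seed=42))
    assert cohort_to_frame(a).to_csv() == cohort_to_frame(b).to_csv()
    ha = generate_followup(cfg, a)
    hb = generate_followup(CohortConfig(seed=42), b)
    assert histories_to_frame(ha).to_csv() == histories_to_frame(hb).to_csv()
    c = generate_cohort(CohortConfig(seed=43))
    assert cohort_to_frame(a).to_csv() != cohort_to_frame(c).to_csv()


def test_demographic_marginals_match_config():
    cfg = single_group_config(3, 8000, 8000, missing_rate=0.0)
    frame = cohort_to_frame(generate_cohort(cfg))
    for group in ("C9orf72", "control"):
        dp = cfg.demographic_params[group]
        sub = frame[frame["group"] == group]
        n = len(sub)
        assert abs(sub["age"].mean() - dp.age_mean) < 3 * dp.age_sd / np.sqrt(n)
        assert abs((sub["sex"] == "F").mean() - dp.female_fraction) < 3 * 0.5 / np.sqrt(n)
        # education is clipped to [5, 25]; allow a small clipping bias on top of MC error
        assert abs(sub["education"].mean() - dp.education_mean) < 0.1 + 3 * dp.education_sd / np.sqrt(n)


def test_missingness_rate_and_csv_round_trip(tmp_path):
    cfg = single_group_config(4, 1500, 1500, missing_rate=0.15)
    parts = generate_cohort(cfg)
    frame = cohort_to_frame(parts)
    rate = frame[DEFAULT_BATTERY.ids].isna().to_numpy().mean()
    assert abs(rate - 0.15) < 3 * np.sqrt(0.15 * 0.85 / frame[DEFAULT_BATTERY.ids].size)
    path = tmp_path / "cohort.csv"
    frame.to_csv(path, index=False)
    back = frame_to_cohort(pd.read_csv(path))
    assert back[0].raw_scores.keys() == parts[0].raw_scores.keys()
    assert back[3].cdr_global == parts[3].cdr_global


def test_invalid_correlation_matrix_rejected():
    cfg = single_group_config(0, 10, 10, correlation_within=0.0, correlation_between=0.9)
    with pytest.raises(CohortConfigError, match="positive semi-definite"):
        cfg.validate()


@pytest.mark.parametrize(
    "bad",
    [
        dict(missing_rate=1.5),
        dict(dropout_rate=-0.1),
        dict(annual_hazard=(-0.1,)),
        dict(cdr_stage_probs={0.5: 0.7, 1.0: 0.7}),
    ],
)
def test_invalid_config_fields_rejected(bad):
    with pytest.raises(CohortConfigError):
        CohortConfig(**bad).validate()


def test_zero_hazard_never_converts():
    cfg = single_group_config(6, 500, 0, annual_hazard=(0.0,), dropout_rate=0.0)
    parts = generate_cohort(cfg)
    hist = generate_followup(cfg, parts)
    assert hist  # prodromal carriers exist under the default stage mix
    assert all(c < 1.0 for h in hist for _, c in h.visits)


def test_constant_hazard_matches_exponential_closed_form():
    """KM cumulative incidence on a dense visit grid converges to
    1 - exp(-lambda t) for a constant hazard (no dropout)."""
    lam = 0.231
    cfg = single_group_config(
        7, 6000, 0,
        cdr_stage_probs={0.5: 1.0, 1.0: 0.0, 2.0: 0.0, 3.0: 0.0},
        annual_hazard=(lam,),
        dropout_rate=0.0,
        followup_visits=80,
        visit_interval_years=0.05,
    )
    parts = generate_cohort(cfg)
    hist = generate_followup(cfg, parts)
    from ftdcog import build_survival_records, km_estimate

    km = km_estimate(build_survival_records(hist))
    n = km.n_subjects
    for t in (1.0, 2.0, 3.0):
        expected = 1.0 - np.exp(-lam * t)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(km.cumulative_incidence_at(t) - expected) < 3 * se, t


def test_event_assigned_to_first_visit_after_latent_conversion():
    cfg = single_group_config(
        8, 400, 0,
        cdr_stage_probs={0.5: 1.0, 1.0: 0.0, 2.0: 0.0, 3.0: 0.0},
        annual_hazard=(3.0,),  # nearly everyone converts in year 1
        dropout_rate=0.0,
    )
    parts = generate_cohort(cfg)
    hist = generate_followup(cfg, parts)
    event_times = {t for h in hist for t, c in h.visits if c >= 1.0}
    assert event_times <= {1.0, 2.0, 3.0}
    assert 1.0 in event_times
    # once converted the history stops: at most one visit with cdr >= 1
    assert all(sum(c >= 1.0 for _, c in h.visits) <= 1 for h in hist)


def test_followup_empty_eligible_set_warns(caplog):
    cfg = single_group_config(9, 50, 0, cdr_stage_probs={0.5: 0.0, 1.0: 1.0, 2.0: 0.0, 3.0: 0.0})
    parts = generate_cohort(cfg)
    with caplog.at_level("WARNING"):
        hist = generate_followup(cfg, parts)
    assert hist == []
    assert any("no prodromal" in r.message for r in caplog.records)


def test_visit_history_invariants():
    with pytest.raises(ValueError, match="time 0"):
        VisitHistory(id="x", visits=[(0.5, 0.5)])
    with pytest.raises(ValueError, match="strictly increasing"):
        VisitHistory(id="x", visits=[(0.0, 0.5), (1.0, 0.5), (1.0, 1.0)])


def test_timed_tests_emitted_on_higher_is_worse_scale():
    """A carrier group with a large uniform deficit must have *higher* raw
    timed-test scores and *lower* raw untimed scores than controls."""
    prof = {t: (-3.0, 0.5) for t in DEFAULT_BATTERY.ids}
    cfg = single_group_config(10, 2000, 2000, profile=prof, missing_rate=0.0)
    frame = cohort_to_frame(generate_cohort(cfg))
    carriers = frame[frame["group"] == "C9orf72"]
    controls = frame[frame["group"] == "control"]
    assert carriers["tmt_b"].mean() > controls["tmt_b"].mean()
    assert carriers["fcsrt_free"].mean() < controls["fcsrt_free"].mean()
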