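"""Synthetic cohort generator for genetic frontotemporal dementia studies.

Generates cross-sectional cohorts (C9orf72 / GRN / MAPT mutation carriers and
mutation-negative family controls) and longitudinal CDR-staging visit
histories with the statistical structure the downstream analysis assumes:

* Raw test scores are produced by first sampling latent, demographically
  corrected z-deficits with a configurable correlation structure and then
  inverting the normative transform (a linear demographic model fitted on
  controls), so the scoring stage can recover both the model parameters and
  the latent deficits.
* Carrier deficit means and marginal SDs default to the published per-gene
  z-score profiles; a CDR-stage severity gradient is applied and normalized
  so the marginal (all-carrier) means are preserved exactly.
* Conversion from prodromal (CDR global 0.5) to fully symptomatic (>= 1)
  follows a piecewise-constant annual hazard, observed on a discrete visit
  grid with per-visit dropout.  The default hazard is calibrated in closed
  form so the pooled Kaplan-Meier cumulative conversion hits 21% at 2 years
  and 52% at 3 years.

Timed tests are emitted on their natural "higher raw = worse" scale.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import DEFAULT_BATTERY, TestBattery

logger = logging.getLogger(__name__)

CARRIER_GROUPS = ("C9orf72", "GRN", "MAPT")
CONTROL_GROUP = "control"
GROUPS = CARRIER_GROUPS + (CONTROL_GROUP,)

CDR_STAGES = (0.5, 1.0, 2.0, 3.0)

#: Piecewise-constant annual conversion hazard for prodromal carriers over
#: years (0,1], (1,2], (2,3] (the last rate extends beyond year 3).
#: Calibrated once, in closed form, so that with an annual visit grid the
#: cumulative conversion probability is 21% at 2 years and 52% at 3 years:
#: lambda_1 = lambda_2 = -ln(0.79)/2, lambda_3 = ln(0.79) - ln(0.48).
DEFAULT_ANNUAL_HAZARD = (0.11786115, 0.11786115, 0.49824691)


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class DemographicParams:
    """Per-group demographic sampling parameters."""

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    female_fraction: float

    def validate(self, group: str) -> None:
        if self.age_sd <= 0 or self.education_sd <= 0:
            raise CohortConfigError(f"{group}: demographic SDs must be > 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise CohortConfigError(f"{group}: female_fraction must be in [0, 1]")


#: Default demographics: published group means (SD) and sex ratios.
DEFAULT_DEMOGRAPHICS: dict[str, DemographicParams] = {
    "C9orf72": DemographicParams(55.0, 12.0, 13.7, 3.1, 30 / 69),
    "GRN": DemographicParams(53.0, 11.4, 14.0, 3.5, 20 / 41),
    "MAPT": DemographicParams(51.1, 12.6, 14.3, 3.4, 14 / 28),
    CONTROL_GROUP: DemographicParams(45.8, 12.7, 14.6, 3.4, 160 / 275),
}

#: Published cohort sizes per group.
DEFAULT_N_PER_GROUP: dict[str, int] = {
    "C9orf72": 69,
    "GRN": 41,
    "MAPT": 28,
    CONTROL_GROUP: 275,
}


@dataclass(frozen=True)
class ControlScoreModel:
    """True linear demographic model of a control's raw score on one test.

    raw = intercept + slope_age*age + slope_education*education
          + slope_sex*[male] + language_offset[language] + scale * eps

    where eps is the latent standard-normal residual.  For timed tests the
    residual enters with a *negative* sign so that a lower latent z (worse
    performance) yields a higher (slower) raw score.
    """

    intercept: float
    slope_age: float
    slope_education: float
    slope_sex: float
    scale: float
    language_offsets: Mapping[str, float] = field(default_factory=dict)

    def predict(self, age, education, sex_male, language=None):
        pred = (
            self.intercept
            + self.slope_age * np.asarray(age, dtype=float)
            + self.slope_education * np.asarray(education, dtype=float)
            + self.slope_sex * np.asarray(sex_male, dtype=float)
        )
        if self.language_offsets and language is not None:
            offs = np.array([self.language_offsets.get(l, 0.0) for l in np.atleast_1d(language)])
            pred = pred + offs
        return pred


# Plausible raw-score scales per test: (intercept at age 0 / edu 0, residual SD).
# Slopes are derived from the residual SD by a fixed rule (see _control_models).
_RAW_SCALES: dict[str, tuple[float, float]] = {
    "camel_cactus": (30.0, 2.5),
    "boston_naming": (27.0, 2.5),
    "category_fluency": (22.0, 5.5),
    "digit_span_forward": (8.5, 2.0),
    "tmt_a": (35.0, 12.0),
    "digit_symbol": (55.0, 12.0),
    "cwit_colour": (30.0, 7.0),
    "cwit_word": (23.0, 5.0),
    "digit_span_backward": (6.5, 2.0),
    "tmt_b": (80.0, 30.0),
    "cwit_ink": (55.0, 14.0),
    "phonemic_fluency": (38.0, 11.0),
    "benson_copy": (15.5, 1.2),
    "benson_recall": (11.0, 3.0),
    "fcsrt_free": (30.0, 5.5),
    "fcsrt_total": (46.0, 2.5),
    "fcsrt_delayed_free": (12.0, 2.5),
    "fcsrt_delayed_total": (15.5, 1.0),
    "facial_emotion": (30.0, 3.5),
}

#: Relative language intercept offsets (in residual-SD units) applied to
#: language-dependent tests; stimuli difficulty differs across translations.
_LANGUAGE_OFFSET_UNITS: dict[str, float] = {"en": 0.0, "nl": 0.25, "es": -0.25, "fr": 0.10}

DEFAULT_LANGUAGE_PROBS: dict[str, float] = {"en": 0.4, "nl": 0.2, "es": 0.2, "fr": 0.2}


def default_control_models(battery: TestBattery = DEFAULT_BATTERY) -> dict[str, ControlScoreModel]:
    """True control-score models with stated default slopes.

    Performance declines with age and improves with education; a small male
    disadvantage is included on untimed tests.  Slopes scale with each test's
    residual SD so effects are comparable across raw-score scales.
    """
    models: dict[str, ControlScoreModel] = {}
    for t in battery:
        intercept, scale = _RAW_SCALES[t.id]
        if t.timed:
            # higher raw = slower = worse
            slope_age = +0.025 * scale
            slope_edu = -0.05 * scale
            slope_sex = +0.05 * scale
        else:
            slope_age = -0.02 * scale
            slope_edu = +0.06 * scale
            slope_sex = -0.10 * scale
        offsets = (
            {lang: u * scale for lang, u in _LANGUAGE_OFFSET_UNITS.items()}
            if t.language_dependent
            else {}
        )
        models[t.id] = ControlScoreModel(intercept, slope_age, slope_edu, slope_sex, scale, offsets)
    return models


def load_default_deficit_profile() -> dict[str, dict[str, tuple[float, float]]]:
    """Packaged per-gene (mean z-shift, marginal SD) carrier deficit table."""
    profile: dict[str, dict[str, tuple[float, float]]] = {g: {} for g in CARRIER_GROUPS}
    with resources.files("ftdcog.data").joinpath("carrier_deficit_profiles.csv").open() as fh:
        for row in csv.DictReader(fh):
            profile[row["group"]][row["test"]] = (float(row["mean_z"]), float(row["sd_z"]))
    return profile


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults emulate the published cohort."""

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    demographic_params: dict[str, DemographicParams] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    deficit_profile: dict[str, dict[str, tuple[float, float]]] | None = None
    correlation_within: float = 0.5
    correlation_between: float = 0.2
    missing_rate: float = 0.02
    cdr_stage_probs: dict[float, float] = field(
        default_factory=lambda: {0.5: 0.45, 1.0: 0.25, 2.0: 0.20, 3.0: 0.10}
    )
    stage_severity: dict[float, float] = field(
        default_factory=lambda: {0.5: 0.5, 1.0: 1.0, 2.0: 1.6, 3.0: 2.1}
    )
    control_cdr05_fraction: float = 0.1
    annual_hazard: tuple[float, ...] = DEFAULT_ANNUAL_HAZARD
    followup_visits: int = 3
    visit_interval_years: float = 1.0
    dropout_rate: float = 0.10
    language_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LANGUAGE_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deficit_profile is None:
            self.deficit_profile = load_default_deficit_profile()

    def validate(self, battery: TestBattery = DEFAULT_BATTERY) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise CohortConfigError(f"unknown group {g!r}")
            if n < 0:
                raise CohortConfigError(f"{g}: n must be >= 0")
        for g, dp in self.demographic_params.items():
            dp.validate(g)
        for rate, name in [
            (self.missing_rate, "missing_rate"),
            (self.dropout_rate, "dropout_rate"),
            (self.control_cdr05_fraction, "control_cdr05_fraction"),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise CohortConfigError(f"{name} must be in [0, 1]")
        if any(h < 0 for h in self.annual_hazard) or not self.annual_hazard:
            raise CohortConfigError("annual_hazard rates must be >= 0 and non-empty")
        tot = sum(self.cdr_stage_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise CohortConfigError(f"cdr_stage_probs must sum to 1 (got {tot})")
        if any(s not in CDR_STAGES for s in self.cdr_stage_probs):
            raise CohortConfigError("cdr_stage_probs keys must be in {0.5, 1, 2, 3}")
        for g in CARRIER_GROUPS:
            if self.n_per_group.get(g, 0) > 0:
                missing = [t for t in battery.ids if t not in self.deficit_profile.get(g, {})]
                if missing:
                    raise CohortConfigError(f"deficit_profile[{g}] missing tests: {missing}")
                for t, (_, sd) in self.deficit_profile[g].items():
                    if sd <= 0:
                        raise CohortConfigError(f"deficit_profile[{g}][{t}]: SD must be > 0")
        if self.followup_visits < 1 or self.visit_interval_years <= 0:
            raise CohortConfigError("followup_visits >= 1 and visit_interval_years > 0 required")
        # correlation matrix must be positive semi-definite
        corr = correlation_matrix(battery, self.correlation_within, self.correlation_between)
        _cholesky_psd(corr, battery)


@dataclass
class Participant:
    """One person's demographics, genetic status, CDR stage and raw scores."""

    id: str
    group: str
    sex: str  # "F" or "M"
    age: float
    education: float
    language: str
    cdr_global: float
    cdr_sob: float
    raw_scores: dict[str, float]  # missing cells absent (or NaN)

    @property
    def carrier(self) -> bool:
        return self.group != CONTROL_GROUP


@dataclass
class VisitHistory:
    """Ordered longitudinal CDR-staging record; first visit at time 0."""

    id: str
    visits: list[tuple[float, float]]  # (years from baseline, cdr_global)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.visits]
        if times and times[0] != 0.0:
            raise ValueError(f"{self.id}: first visit must be at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.id}: visit times must be strictly increasing")


def correlation_matrix(
    battery: TestBattery, within: float = 0.5, between: float = 0.2
) -> np.ndarray:
    """Block-exchangeable test-score correlation: `within` inside a cognitive
    domain, `between` across domains."""
    domains = np.array([t.domain for t in battery])
    same = domains[:, None] == domains[None, :]
    corr = np.where(same, within, between)
    np.fill_diagonal(corr, 1.0)
    return corr


def _cholesky_psd(corr: np.ndarray, battery: TestBattery) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # identify the offending leading block for the error message
        for k in range(2, corr.shape[0] + 1):
            if np.linalg.eigvalsh(corr[:k, :k]).min() < -1e-10:
                bad = battery.ids[:k]
                raise CohortConfigError(
                    f"correlation matrix is not positive semi-definite; "
                    f"offending leading block ends at test {bad[-1]!r}"
                ) from None
        raise CohortConfigError("correlation matrix is not positive semi-definite") from None


def _stage_moments(config: CohortConfig) -> tuple[dict[float, float], float]:
    """Normalized stage multipliers and their variance under the stage mix.

    Multipliers are rescaled so their mean under ``cdr_stage_probs`` is 1;
    the marginal carrier deficit mean then equals the configured profile mean
    exactly, while CDR 0.5 carriers are milder than CDR >= 1 carriers.
    """
    probs = config.cdr_stage_probs
    raw = config.stage_severity
    mean = sum(probs[s] * raw[s] for s in probs)
    if mean <= 0:
        raise CohortConfigError("stage_severity must have positive mean under cdr_stage_probs")
    mult = {s: raw[s] / mean for s in raw}
    var = sum(probs[s] * (mult[s] - 1.0) ** 2 for s in probs)
    return mult, var


def generate_cohort(
    config: CohortConfig,
    battery: TestBattery = DEFAULT_BATTERY,
    control_models: Mapping[str, ControlScoreModel] | None = None,
) -> list[Participant]:
    """Generate a cross-sectional cohort; deterministic given ``config.seed``.

    Latent z-deficits are drawn from a multivariate normal with the
    configured block correlation, per-test marginal mean/SD from the deficit
    profile (scaled by the normalized CDR-stage severity), then mapped to raw
    scores by inverting the normative transform of the true control model.
    """
    config.validate(battery)
    if control_models is None:
        control_models = default_control_models(battery)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    corr = correlation_matrix(battery, config.correlation_within, config.correlation_between)
    chol = _cholesky_psd(corr, battery)
    stage_mult, stage_var = _stage_moments(config)

    langs = sorted(config.language_probs)
    lang_p = np.array([config.language_probs[l] for l in langs], dtype=float)
    lang_p = lang_p / lang_p.sum()

    participants: list[Participant] = []
    p = len(battery)
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        dp = config.demographic_params[group]
        age = rng.normal(dp.age_mean, dp.age_sd, n)
        edu = np.clip(rng.normal(dp.education_mean, dp.education_sd, n), 5.0, 25.0)
        female = rng.random(n) < dp.female_fraction
        language = rng.choice(langs, size=n, p=lang_p)

        if group == CONTROL_GROUP:
            cdr = np.where(rng.random(n) < config.control_cdr05_fraction, 0.5, 0.0)
            sob = np.where(cdr > 0, np.clip(rng.normal(1.5, 0.8, n), 0.5, 3.0), 0.0)
            mean_z = np.zeros((n, p))
            within_sd = np.ones((n, p))
        else:
            stages = np.array(sorted(config.cdr_stage_probs))
            sprobs = np.array([config.cdr_stage_probs[s] for s in stages])
            cdr = rng.choice(stages, size=n, p=sprobs)
            sob_mean = {0.5: 2.0, 1.0: 5.5, 2.0: 9.0, 3.0: 13.0}
            sob_sd = {0.5: 1.2, 1.0: 2.0, 2.0: 3.0, 3.0: 3.0}
            sob = np.clip(
                rng.normal([sob_mean[c] for c in cdr], [sob_sd[c] for c in cdr]), 0.0, 24.0
            )
            prof_mean = np.array([config.deficit_profile[group][t][0] for t in battery.ids])
            prof_sd = np.array([config.deficit_profile[group][t][1] for t in battery.ids])
            mult = np.array([stage_mult[c] for c in cdr])[:, None]
            mean_z = prof_mean[None, :] * mult
            # within-stage SD chosen so the marginal SD matches the profile
            wvar = prof_sd**2 - stage_var * prof_mean**2
            within = np.sqrt(np.maximum(wvar, (0.1 * prof_sd) ** 2))
            within_sd = np.broadcast_to(within, (n, p))

        eps = rng.standard_normal((n, p)) @ chol.T
        z = mean_z + within_sd * eps

        raw = np.empty((n, p))
        for j, t in enumerate(battery):
            m = control_models[t.id]
            pred = m.predict(age, edu, (~female).astype(float), language)
            sign = -1.0 if t.timed else 1.0
            raw[:, j] = pred + sign * m.scale * z[:, j]

        miss = rng.random((n, p)) < config.missing_rate

        for i in range(n):
            scores = {
                t: raw[i, j] for j, t in enumerate(battery.ids) if not miss[i, j]
            }
            participants.append(
                Participant(
                    id=f"{group}-{i:05d}",
                    group=group,
                    sex="F" if female[i] else "M",
                    age=float(age[i]),
                    education=float(edu[i]),
                    language=str(language[i]),
                    cdr_global=float(cdr[i]),
                    cdr_sob=float(sob[i]),
                    raw_scores=scores,
                )
            )
    return participants


def _sample_conversion_times(rng: np.random.Generator, rates: Sequence[float], n: int) -> np.ndarray:
    """Inverse-transform sampling from a piecewise-constant hazard.

    Rates apply to successive 1-year intervals; the last rate extends to
    infinity.  Returns latent conversion times in years (inf if hazard 0).
    """
    rates = np.asarray(rates, dtype=float)
    edges = np.arange(len(rates) + 1, dtype=float)  # 0,1,...,K
    cumhaz = np.concatenate([[0.0], np.cumsum(rates)])  # H at edges
    target = rng.exponential(1.0, size=n)
    times = np.full(n, np.inf)
    for k, rate in enumerate(rates):
        lo, hi = cumhaz[k], cumhaz[k + 1]
        in_seg = (target >= lo) & (target < hi) if k < len(rates) - 1 else (target >= lo)
        if rate > 0:
            times[in_seg] = edges[k] + (target[in_seg] - lo) / rate
        # rate == 0 inside a finite segment: no conversions attributed here
    return times


def generate_followup(
    config: CohortConfig, baseline: Sequence[Participant]
) -> list[VisitHistory]:
    """Longitudinal CDR visit histories for prodromal (CDR 0.5) carriers.

    A converter's first visit with cdr_global >= 1 is the first scheduled
    visit at or after the latent conversion time; per-visit dropout censors
    all later visits.  Deterministic given ``config.seed``.
    """
    config.validate()
    eligible = [p for p in baseline if p.carrier and p.cdr_global == 0.5]
    if not eligible:
        logger.warning("generate_followup: no prodromal (CDR 0.5) carriers in baseline")
        return []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    conv = _sample_conversion_times(rng, config.annual_hazard, len(eligible))
    visit_times = config.visit_interval_years * np.arange(1, config.followup_visits + 1)
    histories: list[VisitHistory] = []
    for i, part in enumerate(eligible):
        visits: list[tuple[float, float]] = [(0.0, 0.5)]
        for t in visit_times:
            if rng.random() < config.dropout_rate:
                break
            if t >= conv[i]:
                visits.append((float(t), 1.0))
                break
            visits.append((float(t), 0.5))
        histories.append(VisitHistory(id=part.id, visits=visits))
    return histories


# ---------------------------------------------------------------------------
# Tabular I/O (CSV round trip; empty cell = missing score)

_META_COLS = ["id", "group", "carrier", "sex", "age", "education", "language", "cdr_global", "cdr_sob"]


def cohort_to_frame(
    participants: Sequence[Participant], battery: TestBattery = DEFAULT_BATTERY
) -> pd.DataFrame:
    rows = []
    for p in participants:
        row = {
            "id": p.id,
            "group": p.group,
            "carrier": p.carrier,
            "sex": p.sex,
            "age": p.age,
            "education": p.education,
            "language": p.language,
            "cdr_global": p.cdr_global,
            "cdr_sob": p.cdr_sob,
        }
        for t in battery.ids:
            row[t] = p.raw_scores.get(t, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLS + battery.ids)


def frame_to_cohort(
    frame: pd.DataFrame, battery: TestBattery = DEFAULT_BATTERY
) -> list[Participant]:
    out = []
    for _, row in frame.iterrows():
        scores = {
            t: float(row[t]) for t in battery.ids if t in row.index and pd.notna(row[t])
        }
        out.append(
            Participant(
                id=str(row["id"]),
                group=str(row["group"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                education=float(row["education"]),
                language=str(row["language"]),
                cdr_global=float(row["cdr_global"]),
                cdr_sob=float(row["cdr_sob"]),
                raw_scores=scores,
            )
        )
    return out


def write_cohort_csv(participants, path, battery: TestBattery = DEFAULT_BATTERY) -> None:
    cohort_to_frame(participants, battery).to_csv(path, index=False)


def read_cohort_csv(path, battery: TestBattery = DEFAULT_BATTERY) -> list[Participant]:
    return frame_to_cohort(pd.read_csv(path), battery)


def histories_to_frame(histories: Sequence[VisitHistory]) -> pd.DataFrame:
    rows = [
        {"id": h.id, "time_years": t, "cdr_global": c} for h in histories for t, c in h.visits
    ]
    return pd.DataFrame(rows, columns=["id", "time_years", "cdr_global"])


def frame_to_histories(frame: pd.DataFrame) -> list[VisitHistory]:
    out = []
    for pid, grp in frame.groupby("id", sort=False):
        grp = grp.sort_values("time_years")
        out.append(
            VisitHistory(
                id=str(pid),
                visits=[(float(t), float(c)) for t, c in zip(grp["time_years"], grp["cdr_global"])],
            )
        )
    return out


def write_histories_csv(histories, path) -> None:
    histories_to_frame(histories).to_csv(path, index=False)


def read_histories_csv(path) -> list[VisitHistory]:
    return frame_to_histories(pd.read_csv(path))
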