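"""Regression-based normative z-scoring against the control sample.

Each test's raw score is regressed on age, years of education and sex over
the mutation-negative controls (ordinary least squares); a participant's
z-score is their residual from that model divided by the control residual
standard deviation (unbiased n - p denominator).  Language-dependent tests
(FCSRT measures, phonemic fluency) additionally carry categorical
per-language intercept offsets, since test stimuli differ between languages.
Z-scores of timed tests are sign-inverted so that lower z = worse
performance on every test.  Extreme z-values are propagated untruncated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import DEFAULT_BATTERY, TestBattery
from .cohort import CONTROL_GROUP, Participant, cohort_to_frame

logger = logging.getLogger(__name__)

#: Sex coding in all normative design matrices: F = 0, M = 1.
SEX_CODES = {"F": 0.0, "M": 1.0}


class NormativeFitError(ValueError):
    """Raised when one or more per-test normative fits fail."""


class DegenerateModelError(NormativeFitError):
    """Control residual variance is (numerically) zero."""


@dataclass
class NormativeModel:
    """Per-test demographic regression fitted on controls."""

    test_id: str
    intercept: float
    slope_age: float
    slope_education: float
    slope_sex: float
    residual_sd: float
    n_controls: int
    language_offsets: dict[str, float] | None = None  # present iff language-dependent

    def predict(self, age, education, sex_male, language=None) -> np.ndarray:
        pred = (
            self.intercept
            + self.slope_age * np.asarray(age, dtype=float)
            + self.slope_education * np.asarray(education, dtype=float)
            + self.slope_sex * np.asarray(sex_male, dtype=float)
        )
        if self.language_offsets is not None and language is not None:
            offs = np.array(
                [self.language_offsets.get(str(l), 0.0) for l in np.atleast_1d(language)]
            )
            pred = pred + offs
        return pred

    def to_dict(self) -> dict:
        return {
            "test_id": self.test_id,
            "intercept": self.intercept,
            "slope_age": self.slope_age,
            "slope_education": self.slope_education,
            "slope_sex": self.slope_sex,
            "residual_sd": self.residual_sd,
            "n_controls": self.n_controls,
            "language_offsets": self.language_offsets,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormativeModel":
        return cls(**dict(d))


def _as_frame(participants, battery: TestBattery) -> pd.DataFrame:
    if isinstance(participants, pd.DataFrame):
        return participants
    return cohort_to_frame(list(participants), battery)


def fit_normative_models(
    controls: Sequence[Participant] | pd.DataFrame,
    battery: TestBattery = DEFAULT_BATTERY,
    min_controls: int = 20,
) -> dict[str, NormativeModel]:
    """Fit one OLS normative model per battery test on the control sample.

    Parameters
    ----------
    controls
        Control participants (list or cohort DataFrame).  Non-control rows
        are rejected.
    min_controls
        Minimum number of controls with a non-missing score required per
        test (default 20).

    Raises
    ------
    NormativeFitError
        If any test has fewer usable controls than ``min_controls``, listing
        the failing tests, or if a fitted model is degenerate (residual SD
        numerically zero).
    """
    frame = _as_frame(controls, battery)
    if (frame["group"] != CONTROL_GROUP).any():
        bad = frame.loc[frame["group"] != CONTROL_GROUP, "group"].unique().tolist()
        raise NormativeFitError(f"normative models must be fitted on controls only; got {bad}")

    models: dict[str, NormativeModel] = {}
    too_few: list[str] = []
    for t in battery:
        sub = frame.loc[frame[t.id].notna()]
        n = len(sub)
        if n < min_controls:
            too_few.append(f"{t.id} (n={n})")
            continue
        y = sub[t.id].to_numpy(dtype=float)
        sex = sub["sex"].map(SEX_CODES).to_numpy(dtype=float)
        cols = [np.ones(n), sub["age"].to_numpy(float), sub["education"].to_numpy(float), sex]
        lang_levels: list[str] = []
        if t.language_dependent:
            lang = sub["language"].astype(str)
            lang_levels = sorted(lang.unique())
            # reference level = first alphabetically; offsets for the rest
            for lev in lang_levels[1:]:
                cols.append((lang == lev).to_numpy(dtype=float))
        X = np.column_stack(cols)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - X.shape[1]
        if dof <= 0:
            too_few.append(f"{t.id} (n={n}, p={X.shape[1]})")
            continue
        residual_sd = float(np.sqrt(resid @ resid / dof))
        if residual_sd <= 1e-8 * max(1.0, float(np.std(y))):
            raise DegenerateModelError(
                f"{t.id}: control residual variance is zero; scores are an exact "
                "linear function of the demographic covariates"
            )
        offsets = None
        if t.language_dependent:
            offsets = {lang_levels[0]: 0.0}
            for k, lev in enumerate(lang_levels[1:]):
                offsets[lev] = float(beta[4 + k])
        models[t.id] = NormativeModel(
            test_id=t.id,
            intercept=float(beta[0]),
            slope_age=float(beta[1]),
            slope_education=float(beta[2]),
            slope_sex=float(beta[3]),
            residual_sd=residual_sd,
            n_controls=n,
            language_offsets=offsets,
        )
    if too_few:
        raise NormativeFitError(
            f"fewer than {min_controls} controls with scores for: {', '.join(too_few)}"
        )
    return models


def compute_z(
    participants: Sequence[Participant] | pd.DataFrame,
    models: Mapping[str, NormativeModel],
    battery: TestBattery = DEFAULT_BATTERY,
) -> pd.DataFrame:
    """Demographically corrected z-score table (index = participant id).

    z = (raw - model prediction) / control residual SD, multiplied by -1 for
    timed tests so lower z = worse everywhere.  Missing raw scores give
    missing z.
    """
    frame = _as_frame(participants, battery)
    missing_models = [t for t in battery.ids if t not in models]
    if missing_models:
        raise NormativeFitError(f"no normative model for tests: {missing_models}")
    covar = frame[["age", "education", "sex"]]
    bad = frame.loc[covar.isna().any(axis=1) | ~frame["sex"].isin(SEX_CODES), "id"]
    if len(bad):
        raise NormativeFitError(f"participants with missing/invalid covariates: {bad.tolist()}")

    sex = frame["sex"].map(SEX_CODES).to_numpy(dtype=float)
    out = pd.DataFrame(index=pd.Index(frame["id"], name="id"))
    for t in battery:
        m = models[t.id]
        pred = m.predict(
            frame["age"].to_numpy(float),
            frame["education"].to_numpy(float),
            sex,
            frame["language"].to_numpy() if t.language_dependent else None,
        )
        z = (frame[t.id].to_numpy(dtype=float) - pred) / m.residual_sd
        if t.timed:
            z = -z
        out[t.id] = z
    return out


def save_models_json(models: Mapping[str, NormativeModel], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=1)


def load_models_json(path) -> dict[str, NormativeModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: NormativeModel.from_dict(v) for k, v in raw.items()}
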