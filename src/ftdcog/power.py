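"""Sample-size estimation for a two-arm 1:1 trial on a change-score outcome.

Per-arm sample size for detecting a treatment effect on the change in a
cognitive score between baseline and follow-up:

    n = (1 - rho^2) * (2 * sigma^2) / delta^2 * f(alpha, beta)

where rho is the baseline/follow-up correlation of the outcome, sigma its SD
in the prodromal (CDR global 0.5) group, delta the treatment effect on the
outcome scale and f(alpha, beta) = (z_{1-alpha/2} + z_{power})^2.

The effect-size convention is a *fraction of the stage difference*: a 100%
treatment effect equals the cross-sectional difference in mean outcome
between the CDR 0.5 and CDR 1 groups, so delta = effect_size *
|mu_05 - mu_1|.  When only a fraction of the trial population is expected to
progress over the trial horizon, the planned effect size is multiplied by
that conversion probability (e.g. a 20% planned effect with ~50% expected
conversion is powered as a 10% effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class PowerInputError(ValueError):
    """Invalid sample-size inputs."""


class InfiniteSampleSizeError(PowerInputError):
    """delta = 0: equal stage means give an unbounded trial."""


@dataclass
class PowerInputs:
    """Parameter bundle for the per-arm sample-size formula."""

    rho: float
    sigma: float
    mu_05: float
    mu_1: float
    effect_size: float
    alpha: float = 0.05
    power: float = 0.80
    n_05: int | None = None  # sample counts behind the estimates, if known
    n_1: int | None = None
    degenerate: bool = False  # sigma estimated as 0

    def validate(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise PowerInputError(f"rho must be in (-1, 1), got {self.rho}")
        if self.sigma <= 0:
            raise PowerInputError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 < self.effect_size <= 1.0:
            raise PowerInputError(f"effect_size must be in (0, 1], got {self.effect_size}")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise PowerInputError("alpha and power must be in (0, 1)")
        if self.mu_05 == self.mu_1:
            raise InfiniteSampleSizeError(
                "stage means are equal (mu_05 == mu_1): treatment effect is zero "
                "and the required sample size is infinite"
            )


@dataclass
class SampleSizeResult:
    """Per-arm sample size with all intermediate quantities."""

    delta: float
    f_value: float
    n_raw: float
    n_per_arm: int
    rounding: str = "ceiling"
    inputs: PowerInputs | None = None


def f_alpha_beta(alpha: float = 0.05, power: float = 0.80) -> float:
    """Normal-quantile factor (z_{1-alpha/2} + z_{power})^2."""
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise PowerInputError("alpha and power must be in (0, 1)")
    return float((stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)) ** 2)


def effect_delta(inputs: PowerInputs) -> float:
    """Treatment effect on the outcome scale: effect_size * |mu_05 - mu_1|."""
    return inputs.effect_size * abs(inputs.mu_05 - inputs.mu_1)


def sample_size(inputs: PowerInputs) -> SampleSizeResult:
    """Evaluate the closed-form per-arm sample size (ceiling rounding)."""
    inputs.validate()
    delta = effect_delta(inputs)
    f_val = f_alpha_beta(inputs.alpha, inputs.power)
    n_raw = (1.0 - inputs.rho**2) * (2.0 * inputs.sigma**2) / delta**2 * f_val
    return SampleSizeResult(
        delta=delta,
        f_value=f_val,
        n_raw=n_raw,
        n_per_arm=max(1, math.ceil(n_raw)),
        inputs=inputs,
    )


def adjust_for_conversion(effect_size: float, conversion_prob: float) -> float:
    """Dilute a planned effect size by the expected conversion probability.

    Only converters express the stage-difference decline over the trial, so
    the population-level effect is effect_size * conversion_prob (a 20%
    planned effect with 50% conversion is powered as a 10% effect).
    """
    if not 0.0 < conversion_prob <= 1.0:
        raise PowerInputError(
            f"conversion_prob must be in (0, 1], got {conversion_prob}; "
            "with no expected progressors the outcome cannot show a treatment effect"
        )
    return effect_size * conversion_prob


def estimate_power_inputs(
    values: Sequence[float] | pd.Series,
    cdr: Sequence[float] | pd.Series,
    rho: float = 0.5,
    effect_size: float = 0.2,
    alpha: float = 0.05,
    power: float = 0.80,
) -> PowerInputs:
    """Estimate mu_05/sigma (CDR 0.5 group) and mu_1 (CDR 1 group) from data.

    ``values`` is an outcome column (individual-test z or composite) and
    ``cdr`` the matching CDR global stages; missing outcome values are
    dropped per group.  rho is supplied externally (default 0.5).
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(cdr, dtype=float)
    if len(v) != len(c):
        raise PowerInputError("values and cdr labels differ in length")
    g05 = v[(c == 0.5) & ~np.isnan(v)]
    g1 = v[(c == 1.0) & ~np.isnan(v)]
    for name, g in (("CDR 0.5", g05), ("CDR 1", g1)):
        if len(g) == 0:
            raise PowerInputError(f"stage group {name} is empty")
    sigma = float(np.std(g05, ddof=1)) if len(g05) > 1 else 0.0
    return PowerInputs(
        rho=rho,
        sigma=sigma if sigma > 0 else 1e-12,
        mu_05=float(np.mean(g05)),
        mu_1=float(np.mean(g1)),
        effect_size=effect_size,
        alpha=alpha,
        power=power,
        n_05=len(g05),
        n_1=len(g1),
        degenerate=sigma <= 0,
    )


def sample_size_table(
    outcomes: Mapping[str, pd.Series] | pd.DataFrame,
    cdr: Sequence[float] | pd.Series,
    rho: float = 0.5,
    effect_sizes: Iterable[float] = (0.1, 0.2, 0.4),
    alpha: float = 0.05,
    power: float = 0.80,
    conversion_prob: float | None = None,
) -> pd.DataFrame:
    """Per-arm sample sizes for each outcome column and effect size.

    If ``conversion_prob`` is given, every effect size is first diluted by
    it.  Outcomes whose stage means coincide or whose prodromal SD is
    degenerate get missing entries.
    """
    if isinstance(outcomes, pd.DataFrame):
        outcomes = {c: outcomes[c] for c in outcomes.columns}
    effect_sizes = list(effect_sizes)
    rows = []
    for name, values in outcomes.items():
        row: dict[str, object] = {"outcome": name}
        for es in effect_sizes:
            es_eff = adjust_for_conversion(es, conversion_prob) if conversion_prob else es
            try:
                inp = estimate_power_inputs(values, cdr, rho, es_eff, alpha, power)
                if inp.degenerate:
                    raise PowerInputError("degenerate sigma")
                row[f"es_{int(round(es * 100))}"] = sample_size(inp).n_per_arm
            except PowerInputError:
                row[f"es_{int(round(es * 100))}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("outcome")
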