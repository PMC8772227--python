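"""End-to-end pipeline: simulate -> score -> derive -> power -> survival.

Every run writes its artifacts (cohort, visit histories, z-scores,
coefficient/weight table, composites, sample-size table, survival curves)
plus a ``report.json`` carrying the seed and a SHA-256 hash of the resolved
configuration, so identical config+seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import composite as comp
from . import power as pw
from . import scoring
from . import survival as surv
from .battery import DEFAULT_BATTERY, TestBattery
from .cohort import (
    CARRIER_GROUPS,
    CONTROL_GROUP,
    CohortConfig,
    DemographicParams,
    cohort_to_frame,
    generate_cohort,
    generate_followup,
    histories_to_frame,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    outdir: str = "ftdcog_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    folds: int = 10
    lambda_rule: str = "min"
    n_lambda: int = 100
    alpha: float = 0.05
    power: float = 0.80
    rho: float = 0.5
    effect_sizes: tuple[float, ...] = (0.1, 0.2, 0.4)
    conversion_prob: float | None = None
    use_published: bool = False  # apply the published composites instead of refitting

    def validate(self) -> None:
        if any(not 0.0 < es <= 1.0 for es in self.effect_sizes):
            raise ValueError("effect sizes must be in (0, 1]")
        self.cohort.validate()

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "demographic_params" in c:
                c["demographic_params"] = {
                    g: DemographicParams(**v) if isinstance(v, dict) else v
                    for g, v in c["demographic_params"].items()
                }
            if "cdr_stage_probs" in c:
                c["cdr_stage_probs"] = {float(k): v for k, v in c["cdr_stage_probs"].items()}
            if "stage_severity" in c:
                c["stage_severity"] = {float(k): v for k, v in c["stage_severity"].items()}
            if "annual_hazard" in c:
                c["annual_hazard"] = tuple(c["annual_hazard"])
            d["cohort"] = CohortConfig(**c)
        if "effect_sizes" in d:
            d["effect_sizes"] = tuple(d["effect_sizes"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def apply_published_composites(
    z: pd.DataFrame, modes: tuple[str, ...] = ("weighted", "average")
) -> pd.DataFrame:
    """Per-gene composite values under the published (frozen) definitions.

    Columns are named ``<gene>_<mode>``.  Raises a schema error listing any
    battery tests the z table lacks.
    """
    out = pd.DataFrame(index=z.index)
    for mode in modes:
        for gene, definition in comp.published_definitions(mode).items():
            missing = [t for t in definition.tests if t not in z.columns]
            if missing:
                raise comp.CompositeError(
                    f"z table lacks columns required by the {gene} composite: {missing}"
                )
            out[f"{gene}_{mode}"] = comp.compute_composite(z, definition)
    return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig, battery: TestBattery = DEFAULT_BATTERY) -> dict[str, Any]:
    """Execute all stages in order and write artifacts under config.outdir.

    Returns the run report (also written as ``report.json``).
    """
    config.validate()
    config.cohort.seed = config.seed
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    report: dict[str, Any] = {"seed": config.seed, "config_hash": chash, "artifacts": []}

    def save(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        frame.to_csv(path, index=index, float_format="%.10g")
        report["artifacts"].append(name)

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def simulate():
        participants = generate_cohort(config.cohort, battery)
        histories = generate_followup(config.cohort, participants)
        save(cohort_to_frame(participants, battery), "cohort.csv")
        save(histories_to_frame(histories), "visits.csv")
        return participants, histories

    participants, histories = simulate()
    report["n_participants"] = len(participants)
    report["n_histories"] = len(histories)

    # -- normative scoring -------------------------------------------------
    @_stage("zscore")
    def zscore():
        controls = [p for p in participants if p.group == CONTROL_GROUP]
        models = scoring.fit_normative_models(controls, battery)
        z = scoring.compute_z(participants, models, battery)
        scoring.save_models_json(models, outdir / "normative_models.json")
        report["artifacts"].append("normative_models.json")
        save(z, "zscores.csv", index=True)
        return z

    z = zscore()
    frame = cohort_to_frame(participants, battery).set_index("id")

    # -- composite derivation ---------------------------------------------
    @_stage("derive")
    def derive():
        composites = pd.DataFrame(index=z.index)
        if config.use_published:
            composites = apply_published_composites(z)
            table = comp.published_coefficients()
        else:
            fits = {}
            for gene in CARRIER_GROUPS:
                mask = (frame["group"] == gene) | (frame["group"] == CONTROL_GROUP)
                labels = (frame.loc[mask, "group"] == gene).astype(int)
                fit = comp.fit_penalized_logistic(
                    z.loc[mask.to_numpy()],
                    labels.to_numpy(),
                    folds=config.folds,
                    seed=config.seed,
                    gene=gene,
                    n_lambda=config.n_lambda,
                    lambda_rule=config.lambda_rule,
                )
                fits[gene] = fit
                for mode, definition in (
                    ("weighted", comp.derive_weights(fit, battery)),
                    ("average", comp.average_definition(fit, battery)),
                ):
                    composites[f"{gene}_{mode}"] = comp.compute_composite(z, definition)
            table = comp.coefficient_table(fits, battery)
        save(table, "coefficients.csv")
        save(composites, "composites.csv", index=True)
        return composites

    composites = derive()

    # -- sample size -------------------------------------------------------
    @_stage("power")
    def power_stage():
        tables = []
        for gene in CARRIER_GROUPS:
            mask = frame["group"] == gene
            cdr = frame.loc[mask, "cdr_global"]
            outcomes: dict[str, pd.Series] = {t: z.loc[mask.to_numpy(), t] for t in battery.ids}
            for col in composites.columns:
                if col.startswith(gene):
                    outcomes[col] = composites.loc[mask.to_numpy(), col]
            tab = pw.sample_size_table(
                outcomes,
                cdr,
                rho=config.rho,
                effect_sizes=config.effect_sizes,
                alpha=config.alpha,
                power=config.power,
                conversion_prob=config.conversion_prob,
            )
            tab.insert(0, "gene", gene)
            tables.append(tab.reset_index())
        save(pd.concat(tables, ignore_index=True), "sample_sizes.csv")

    power_stage()

    # -- survival ----------------------------------------------------------
    @_stage("survival")
    def survival_stage():
        groups = {p.id: p.group for p in participants}
        records, excl = surv.build_survival_records(histories, groups, return_report=True)
        report["survival_exclusions"] = excl
        if records:
            pooled = surv.km_estimate(records, group="all")
            curves = [pooled.to_frame()]
            for g, curve in surv.km_by_group(records).items():
                curves.append(curve.to_frame())
            save(pd.concat(curves, ignore_index=True), "km_curves.csv")
            report["km_conversion_2y"] = pooled.cumulative_incidence_at(2.0)
            report["km_conversion_3y"] = pooled.cumulative_incidence_at(3.0)
            if len({r.group for r in records}) >= 2:
                lr = surv.logrank_test(records)
                report["logrank"] = {
                    "statistic": lr.statistic,
                    "df": lr.df,
                    "p_value": lr.p_value,
                }
        else:
            logger.warning("survival stage: no eligible records")

    survival_stage()

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
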