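"""End-to-end evidence-scoring pipeline for one risk–outcome pair.

Stages: read the extraction table → prioritization cascade → repeat SE
inflation → candidate bias-covariate matrix → step-wise Lasso covariate
selection → trimmed mixed-effects fit (with the selected covariates) →
conservative intervals, BPRF, ROS and star rating → Egger's test.  Each
stage's in/out counts are logged; all artifacts (evidence summary,
selected-covariate report, funnel CSV, cascade audit log, reproducibility
manifest) are plain CSV/JSON.

Sensitivity analyses rerun the identical pipeline on restricted inputs:
prospective-cohort studies only, never-smokers only, both restrictions
together, or children-only samples.  Trimming remains conditional on ten
or more observations, so small sensitivity subsets are fitted untrimmed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from . import __version__
from .cascade import (AuditEntry, SelectionConfig, adjust_se_for_repeats,
                      drop_subtype_outcomes, select_observations)
from .covariates import SelectionResult, build_candidate_matrix, select_bias_covariates
from .meta import MetaFit, fit_trimmed
from .observations import (Design, ObservationRecord, SmokingStatus,
                           read_extraction_table)
from .pubbias import EggerResult, eggers_test, export_funnel, make_funnel
from .scoring import Direction, EvidenceScore, score

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "SENSITIVITY_FILTERS"]

log = logging.getLogger(__name__)

SENSITIVITY_FILTERS = {
    "prospective_only": lambda r: r.design is Design.PROSPECTIVE_COHORT,
    "never_smokers_only": lambda r: r.smoking_status in (
        SmokingStatus.NEVER, SmokingStatus.ADJUSTED_NEVER),
    "both": lambda r: (r.design is Design.PROSPECTIVE_COHORT
                       and r.smoking_status in (SmokingStatus.NEVER,
                                                SmokingStatus.ADJUSTED_NEVER)),
    "children_only": lambda r: r.children_only,
}


@dataclass
class RunConfig:
    """Configuration of one risk–outcome pipeline run."""

    input_path: str
    outcome_id: str
    output_dir: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    candidate_covariates: list[str] | None = None  # None: all bias flags
    trim_fraction: float = 0.10
    alpha: float = 0.05
    direction: Direction = Direction.HARMFUL
    sensitivity: list[str] = field(default_factory=list)
    se_inflation: str = "sqrt_k"
    covariate_strategy: str = "lasso_stepwise"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        self.direction = Direction(self.direction)
        if isinstance(self.selection, dict):
            self.selection = SelectionConfig(**self.selection)
        unknown = set(self.sensitivity) - set(SENSITIVITY_FILTERS)
        if unknown:
            raise ValueError(f"unknown sensitivity filter(s): {sorted(unknown)}")


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    evidence: EvidenceScore | None
    fit: MetaFit | None
    covariate_selection: SelectionResult | None
    egger: EggerResult | None
    audit: list[AuditEntry]
    records_used: list[ObservationRecord]
    stage_counts: dict[str, int]
    sensitivity: dict[str, "PipelineResult"] = field(default_factory=dict)
    empty: bool = False


def _write_artifacts(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "burdenproof",
        "version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "selection"},
            "direction": config.direction.value,
        },
        "stage_counts": result.stage_counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(outdir / "audit.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["obs_id", "eliminated_by_rule"])
        for e in result.audit:
            w.writerow([e.obs_id, e.eliminated_by_rule])
    if result.empty:
        (outdir / "evidence.json").write_text(json.dumps(
            {"empty": True, "outcome_id": config.outcome_id,
             "stage_counts": result.stage_counts}, indent=2))
        return
    result.evidence.to_json(outdir / "evidence.json")
    result.fit.to_json(outdir / "fit.json")
    export_funnel(result.fit, result.records_used, outdir / "funnel.csv")
    with open(outdir / "covariates.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["covariate", "coefficient", "se", "p_value"])
        sel = result.covariate_selection
        for name in sel.selected:
            w.writerow([name, sel.coefs[name], sel.coef_se[name],
                        sel.p_values[name]])


def _run_once(records: list[ObservationRecord], config: RunConfig) -> PipelineResult:
    counts = {"input": len(records)}
    subtypes = set(config.selection.subtype_outcomes.get(config.outcome_id, []))
    records, audit0 = drop_subtype_outcomes(
        [r for r in records
         if r.outcome_id == config.outcome_id or r.outcome_id in subtypes],
        config.selection)
    # studies reporting only a subtype contribute it under the aggregate
    # outcome (their subtype-only bias covariate, if any, marks the shift)
    records = [replace(r, outcome_id=config.outcome_id)
               if r.outcome_id in subtypes else r for r in records]
    counts["outcome_matched"] = len(records)
    if not records:
        return PipelineResult(None, None, None, None, audit0, [], counts,
                              empty=True)

    selected, audit = select_observations(records, config.selection)
    audit = audit0 + audit
    counts["after_cascade"] = len(selected)
    selected = adjust_se_for_repeats(selected, factor=config.se_inflation)

    if len({r.study_id for r in selected}) < 2:
        log.warning("fewer than 2 studies after selection; empty report")
        return PipelineResult(None, None, None, None, audit, selected, counts,
                              empty=True)

    matrix, excluded = build_candidate_matrix(selected, seed=config.seed)
    if config.candidate_covariates is not None:
        keep = [n for n in matrix.covariate_names
                if n in config.candidate_covariates]
        matrix = matrix.subset(keep)
    counts["candidate_covariates"] = len(matrix.covariate_names)

    sel = select_bias_covariates(selected, matrix, alpha=config.alpha,
                                 strategy=config.covariate_strategy)
    design = matrix.subset(sel.selected) if sel.selected else None
    fit = fit_trimmed(selected, design, trim_fraction=config.trim_fraction)
    counts["trimmed"] = len(fit.trimmed_ids)
    counts["used_in_fit"] = fit.n_obs_used

    funnel = make_funnel(fit, selected)
    egger = eggers_test(funnel, alpha=config.alpha)
    evidence = score(
        fit, config.direction,
        publication_bias=egger.flagged if egger.evaluable else None,
        n_studies=len({r.study_id for r in selected
                       if r.obs_id not in fit.trimmed_ids}),
        selected_covariates=sel.selected,
    )
    return PipelineResult(evidence, fit, sel, egger, audit, selected, counts)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline (plus sensitivity variants) per ``config``.

    A pure function of the input table and config: identical inputs give
    identical outputs and artifacts.
    """
    records, row_errors = read_extraction_table(config.input_path)
    for e in row_errors:
        log.warning("row %d rejected: %s", e.row, e.message)

    result = _run_once(records, config)
    for name in config.sensitivity:
        pred = SENSITIVITY_FILTERS[name]
        result.sensitivity[name] = _run_once([r for r in records if pred(r)],
                                             config)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        _write_artifacts(result, config, outdir)
        for name, sub in result.sensitivity.items():
            _write_artifacts(sub, config, outdir / f"sensitivity_{name}")
    return result
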