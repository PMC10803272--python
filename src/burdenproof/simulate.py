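"""Synthetic extraction-table generator.

Emulates the generative structure the meta-regression assumes: study-level
random effects with variance ``true_gamma``, additive shifts from binary
bias covariates, heteroskedastic sampling noise, an optional contaminating
outlier fraction, optional non-mutually-exclusive repeated measurements,
and an optional one-sided censoring mode that mimics publication bias by
preferentially dropping unfavorable results from noisy studies.

Defaults echo the regime of the secondhand-smoke literature the pipeline
is designed for: pooled RR near 1.2, moderate heterogeneity, tens of
studies each contributing a handful of observations, and CI widths of the
magnitudes seen in published extraction tables.

A master seed fans out to per-study substreams, so increasing
``n_studies`` extends a table without perturbing earlier studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .observations import ObservationRecord, write_extraction_table

__all__ = ["SyntheticConfig", "Truth", "generate", "generate_table"]


@dataclass
class SyntheticConfig:
    """True generative parameters for one synthetic extraction table."""

    n_studies: int = 40
    obs_per_study: tuple[int, int] = (1, 3)  # inclusive uniform range
    true_beta0: float = math.log(1.2)
    true_gamma: float = 0.04
    bias_effects: dict[str, float] = field(default_factory=dict)
    covariate_prevalence: dict[str, float] = field(default_factory=dict)
    se_range: tuple[float, float] = (0.05, 0.3)  # log-uniform sampling SE
    outlier_fraction: float = 0.0
    outlier_shift: float = 2.0
    outlier_random_sign: bool = False  # True: shift applied with a ± sign
    repeat_prob: float = 0.0   # chance a study reports k repeats instead
    repeat_k: int = 2
    censor_small_negative: bool = False
    seed: int = 0
    outcome_id: str = "synthetic_outcome"

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.true_gamma < 0:
            raise ValueError("true_gamma must be non-negative")
        if not self.se_range[0] > 0:
            raise ValueError("se_range lower bound must be positive")
        for n, p in self.covariate_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {n!r} outside [0, 1]")
        missing = set(self.bias_effects) - set(self.covariate_prevalence)
        if missing:
            raise ValueError(
                f"bias_effects without prevalence: {sorted(missing)}")


@dataclass
class Truth:
    """Latent values behind a generated table."""

    config: SyntheticConfig
    study_effects: dict[str, float]
    outlier_ids: list[str]
    censored_ids: list[str]

    def to_json(self, path=None) -> str:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "study_effects": self.study_effects,
            "outlier_ids": self.outlier_ids,
            "censored_ids": self.censored_ids,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def generate(config: SyntheticConfig) -> tuple[list[ObservationRecord], Truth]:
    """Generate an extraction table and its truth record.

    For study s: u_s ~ Normal(0, true_gamma); for each observation the
    covariate indicators X are Bernoulli(prevalence), the sampling SE is
    log-uniform over ``se_range``, and

        y = true_beta0 + X @ bias_effects + u_s + Normal(0, se²),

    with outliers receiving an extra ±outlier_shift.  Emitted RR = exp(y)
    with a symmetric-in-log 95% CI.  Deterministic under a fixed seed.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_studies)
    cov_names = sorted(config.covariate_prevalence)
    lo, hi = config.obs_per_study

    records: list[ObservationRecord] = []
    study_effects: dict[str, float] = {}
    outlier_ids: list[str] = []
    censored_ids: list[str] = []

    for s, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        study_id = f"study_{s:04d}"
        u = rng.normal(0.0, math.sqrt(config.true_gamma)) if config.true_gamma > 0 else 0.0
        study_effects[study_id] = u

        repeats = rng.random() < config.repeat_prob
        n_obs = config.repeat_k if repeats else int(rng.integers(lo, hi + 1))
        for j in range(n_obs):
            obs_id = f"{study_id}_obs{j}"
            flags = {n: int(rng.random() < config.covariate_prevalence[n])
                     for n in cov_names}
            se = math.exp(rng.uniform(math.log(config.se_range[0]),
                                      math.log(config.se_range[1])))
            y = (config.true_beta0
                 + sum(config.bias_effects.get(n, 0.0) * flags[n] for n in cov_names)
                 + u + rng.normal(0.0, se))
            if rng.random() < config.outlier_fraction:
                sign = (1.0 if rng.random() < 0.5 else -1.0) \
                    if config.outlier_random_sign else 1.0
                y += sign * config.outlier_shift
                outlier_ids.append(obs_id)
            if config.censor_small_negative and y < config.true_beta0:
                # publication-bias mode: unfavorable results from the
                # noisier half of studies go unpublished
                if se > math.sqrt(config.se_range[0] * config.se_range[1]):
                    censored_ids.append(obs_id)
                    continue
            records.append(ObservationRecord(
                obs_id=obs_id,
                study_id=study_id,
                outcome_id=config.outcome_id,
                rr=math.exp(y),
                ci_lower=math.exp(y - 1.959963984540054 * se),
                ci_upper=math.exp(y + 1.959963984540054 * se),
                group_key=f"{study_id}_g0" if repeats else f"{study_id}_g{j}",
                mutually_exclusive=not repeats,
                bias_flags=flags,
            ))
    return records, Truth(config, study_effects, outlier_ids, censored_ids)


def generate_table(config: SyntheticConfig, path, truth_path=None) -> Truth:
    """Generate and write the CSV extraction table (and truth JSON)."""
    records, truth = generate(config)
    write_extraction_table(records, path)
    if truth_path is not None:
        truth.to_json(truth_path)
    return truth
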