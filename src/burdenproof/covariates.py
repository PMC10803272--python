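"""Bias-covariate candidate construction and step-wise Lasso selection.

Bias covariates are binary study characteristics (non-prospective design,
non-representative population, baseline-only exposure assessment,
self-reported outcome, weak confounding control, selection bias, not
controlled for smoking, mismatched exposure definition, female-only,
children-only, subtype-only outcome, ...) encoding deviation from a
gold-standard study; the gold standard is the all-zero level, and the
pooled effect is always reported at it.

Selection, in the default "lasso_stepwise" strategy, runs in two phases:

1. an L1-penalized weighted regression of log RR on the standardized
   candidate columns over a decreasing penalty path ranks covariates by
   order of entry into the active set;
2. covariates are added in that order to the unpenalized mixed model and
   each is retained only while its Wald test is significant at ``alpha``.

Two variants are provided: "stepwise" (forward selection by smallest Wald
p-value, no Lasso ranking) and "lasso_refit" (covariates active at the
BIC-optimal point of the path, refit unpenalized, then pruned at
``alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import lars_path

from . import meta
from .observations import ObservationRecord, to_log_scale

__all__ = ["BiasCovariateMatrix", "build_candidate_matrix",
           "select_bias_covariates", "SelectionResult"]


@dataclass
class BiasCovariateMatrix:
    """Per-observation 0/1 design of candidate bias covariates.

    The gold-standard level of every covariate is 0 by convention.
    """

    obs_ids: list[str]
    covariate_names: list[str]
    values: np.ndarray  # shape (n_obs, n_covariates), entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.obs_ids), len(self.covariate_names)):
            raise ValueError("values shape does not match ids/names")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("bias covariate values must be 0/1")

    def subset(self, names: list[str]) -> "BiasCovariateMatrix":
        idx = [self.covariate_names.index(n) for n in names]
        return BiasCovariateMatrix(
            obs_ids=list(self.obs_ids),
            covariate_names=list(names),
            values=self.values[:, idx].copy(),
        )


@dataclass
class ExcludedCovariate:
    name: str
    reason: str


def build_candidate_matrix(
    records: list[ObservationRecord], seed: int = 0
) -> tuple[BiasCovariateMatrix, list[ExcludedCovariate]]:
    """Assemble the eligible candidate matrix from the records' bias flags.

    A covariate is eligible only if at least two observations sit at each
    of its levels.  Among columns with identical value patterns exactly
    one is retained, chosen by a seeded random draw; the others are
    reported as excluded duplicates.
    """
    records = list(records)
    names = sorted({n for r in records for n in r.bias_flags})
    excluded: list[ExcludedCovariate] = []
    cols: dict[str, np.ndarray] = {}
    for n in names:
        col = np.array([float(r.bias_flags.get(n, 0)) for r in records])
        ones = int(col.sum())
        if ones < 2 or len(col) - ones < 2:
            excluded.append(ExcludedCovariate(
                n, f"ineligible: {ones} observation(s) at level 1, "
                   f"{len(col) - ones} at level 0 (need >= 2 each)"))
            continue
        cols[n] = col

    # collapse duplicate-valued columns with a seeded draw
    rng = np.random.default_rng(seed)
    groups: dict[bytes, list[str]] = {}
    for n in sorted(cols):
        groups.setdefault(cols[n].tobytes(), []).append(n)
    kept_names = []
    for dup_names in groups.values():
        pick = dup_names[rng.integers(len(dup_names))] if len(dup_names) > 1 \
            else dup_names[0]
        kept_names.append(pick)
        for n in dup_names:
            if n != pick:
                excluded.append(ExcludedCovariate(
                    n, f"duplicate of {pick!r} (random pick under seed)"))
    kept_names.sort()
    values = (np.column_stack([cols[n] for n in kept_names])
              if kept_names else np.empty((len(records), 0)))
    matrix = BiasCovariateMatrix(
        obs_ids=[r.obs_id for r in records],
        covariate_names=kept_names,
        values=values,
    )
    return matrix, excluded


@dataclass
class SelectionResult:
    """Outcome of bias-covariate selection."""

    selected: list[str]
    coefs: dict[str, float]
    coef_se: dict[str, float]
    p_values: dict[str, float]
    fit: "meta.MetaFit"
    entry_order: list[str] = field(default_factory=list)


def _lasso_entry_order(obs, candidates: BiasCovariateMatrix) -> list[str]:
    """Rank candidates by order of entry into the weighted Lasso path."""
    y = np.empty(len(obs))
    w = np.empty(len(obs))
    pos = {oid: i for i, oid in enumerate(candidates.obs_ids)}
    X = np.empty((len(obs), len(candidates.covariate_names)))
    for i, r in enumerate(obs):
        log_rr, se = to_log_scale(r)
        y[i] = log_rr
        w[i] = 1.0 / se**2
        X[i] = candidates.values[pos[r.obs_id]]
    # standardize columns to unit variance; constant columns cannot enter
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    # fold inverse-variance weights into the least-squares problem
    sw = np.sqrt(w / w.mean())
    yc = y - np.average(y, weights=w)
    _, active, _ = lars_path(Xs * sw[:, None], yc * sw, method="lasso")
    return [candidates.covariate_names[j] for j in active]


def _wald_p(fit: "meta.MetaFit", name: str) -> float:
    se = fit.bias_coef_se[name]
    if se == 0:
        return 1.0
    z = fit.bias_coefs[name] / se
    return 2.0 * float(stats.norm.sf(abs(z)))


def select_bias_covariates(
    obs,
    candidates: BiasCovariateMatrix,
    alpha: float = 0.05,
    strategy: str = "lasso_stepwise",
    method: str = "reml",
) -> SelectionResult:
    """Select statistically significant bias covariates at level ``alpha``.

    Significance is judged by a two-sided Wald test of the covariate's
    coefficient inside the unpenalized mixed model; no multiple-testing
    correction is applied.  Returns the retained covariates with their
    refit coefficients; the fit's ``beta_mean`` is the pooled log RR at
    the gold-standard level (all selected covariates at 0).
    """
    obs = list(obs)
    names = list(candidates.covariate_names)
    if not names:
        fit = meta.fit_mixed_model(obs, None, method=method)
        return SelectionResult([], {}, {}, {}, fit, [])

    if strategy in ("lasso_stepwise", "lasso_refit"):
        order = _lasso_entry_order(obs, candidates)
    elif strategy == "stepwise":
        order = list(names)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    selected: list[str] = []
    if strategy == "lasso_refit":
        # all path entrants refit jointly, then pruned by worst p-value
        selected = list(order)
        while selected:
            fit = meta.fit_mixed_model(obs, candidates.subset(selected),
                                       method=method)
            ps = {n: _wald_p(fit, n) for n in selected}
            worst = max(ps, key=lambda n: ps[n])
            if ps[worst] < alpha:
                break
            selected.remove(worst)
    elif strategy == "lasso_stepwise":
        for name in order:
            trial = selected + [name]
            fit = meta.fit_mixed_model(obs, candidates.subset(trial),
                                       method=method)
            if _wald_p(fit, name) < alpha:
                selected = trial
    else:  # pure forward step-wise by smallest p-value
        remaining = list(order)
        while remaining:
            best_name, best_p = None, 1.0
            for name in remaining:
                fit = meta.fit_mixed_model(obs, candidates.subset(selected + [name]),
                                           method=method)
                p = _wald_p(fit, name)
                if p < best_p:
                    best_name, best_p = name, p
            if best_name is None or best_p >= alpha:
                break
            selected.append(best_name)
            remaining.remove(best_name)

    fit = meta.fit_mixed_model(
        obs, candidates.subset(selected) if selected else None, method=method)
    return SelectionResult(
        selected=sorted(selected),
        coefs={n: fit.bias_coefs[n] for n in selected},
        coef_se={n: fit.bias_coef_se[n] for n in selected},
        p_values={n: _wald_p(fit, n) for n in selected},
        fit=fit,
        entry_order=order,
    )
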