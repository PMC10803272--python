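"""Evidence scoring: conservative intervals, BPRF, ROS and star ratings.

Given a fitted pooled log RR (beta, beta_se) and between-study variance
(gamma, gamma_sd), the published evidence summary consists of:

* ``ui_no_gamma`` — exp(beta ± 1.96·beta_se), the interval a conventional
  meta-analysis would report;
* ``ui_with_gamma`` — exp(beta ± 1.96·sqrt(beta_se² + gamma_q95)) with
  gamma_q95 the 95th-quantile heterogeneity, a conservative interval that
  also reflects inconsistency between studies;
* the burden-of-proof risk function (BPRF) — the 5% (harmful) or 95%
  (protective) quantile of the heterogeneity-inclusive risk closest to
  the null: the smallest effect consistent with the evidence;
* the risk–outcome score ROS = signed log(BPRF)/2 for a dichotomous
  exposure, and its 0–5 star translation.

Zero-star rule: when ``ui_no_gamma`` contains the null RR of 1, no BPRF or
ROS is computed and the pair is rated 0 stars.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

from .meta import MetaFit
from .observations import Z_95

__all__ = ["Direction", "EvidenceScore", "compute_intervals", "compute_bprf",
           "compute_ros", "assign_stars", "min_percent_change", "score",
           "round_ros", "ZeroStarError"]

Z_90 = 1.6448536269514722  # one-sided 95% normal quantile

STAR_THRESHOLDS = (0.0, 0.14, 0.41, 0.62)  # upper bounds for 1..4 stars


class Direction(str, enum.Enum):
    HARMFUL = "harmful"
    PROTECTIVE = "protective"


class ZeroStarError(ValueError):
    """BPRF requested for a pair whose no-gamma interval crosses the null."""


def gamma_q95(fit: MetaFit) -> float:
    """Normal-approximation 95th quantile of between-study heterogeneity,
    truncated below at the point estimate."""
    return max(fit.gamma, fit.gamma + Z_90 * fit.gamma_sd)


def compute_intervals(fit: MetaFit) -> tuple[tuple[float, float],
                                             tuple[float, float], float]:
    """Return ``(ui_no_gamma, ui_with_gamma, gamma_q95)`` on the RR scale."""
    g95 = gamma_q95(fit)
    half = Z_95 * fit.beta_se
    no_gamma = (math.exp(fit.beta_mean - half), math.exp(fit.beta_mean + half))
    half_g = Z_95 * math.sqrt(fit.beta_se**2 + g95)
    with_gamma = (math.exp(fit.beta_mean - half_g),
                  math.exp(fit.beta_mean + half_g))
    return no_gamma, with_gamma, g95


def compute_bprf(fit: MetaFit, direction: Direction) -> float:
    """Heterogeneity-inclusive risk quantile closest to the null.

    Harmful: exp(beta − 1.645·sqrt(beta_se² + gamma_q95)); protective uses
    the mirror-image 95th quantile.  Raises :class:`ZeroStarError` if the
    no-gamma interval contains 1 (the zero-star rule applies instead).
    """
    direction = Direction(direction)
    no_gamma, _, g95 = compute_intervals(fit)
    if no_gamma[0] <= 1.0 <= no_gamma[1]:
        raise ZeroStarError(
            "95% interval without gamma crosses the null; pair is zero-star "
            "and has no BPRF/ROS"
        )
    shift = Z_90 * math.sqrt(fit.beta_se**2 + g95)
    if direction is Direction.HARMFUL:
        return math.exp(fit.beta_mean - shift)
    return math.exp(fit.beta_mean + shift)


def compute_ros(bprf: float, direction: Direction) -> float:
    """Risk–outcome score: signed log(BPRF)/2 for a dichotomous risk."""
    if bprf <= 0:
        raise ValueError("bprf must be positive")
    direction = Direction(direction)
    ros = math.log(bprf) / 2.0
    return ros if direction is Direction.HARMFUL else -ros


def assign_stars(ros: float | None, zero_star: bool = False) -> int:
    """Translate a ROS into the 0–5 star rating.

    Bands are lower-exclusive / upper-inclusive: <=0 one star, (0, 0.14]
    two, (0.14, 0.41] three, (0.41, 0.62] four, above 0.62 five.
    """
    if zero_star:
        return 0
    if ros is None:
        raise ValueError("ros required unless zero_star")
    for stars, upper in enumerate(STAR_THRESHOLDS, start=1):
        if ros <= upper:
            return stars
    return 5


def min_percent_change(bprf: float, direction: Direction) -> int:
    """Conservative minimum percent change in risk implied by the BPRF:
    (BPRF − 1)·100 for harmful pairs (a minimum increase), (1 − BPRF)·100
    for protective ones (a minimum decrease), rounded to an integer."""
    direction = Direction(direction)
    if direction is Direction.HARMFUL:
        return round((bprf - 1.0) * 100.0)
    return round((1.0 - bprf) * 100.0)


def round_ros(ros: float) -> float:
    """Reporting convention: 2 decimals, 3 when |ros| < 0.01."""
    return round(ros, 3 if abs(ros) < 0.01 else 2)


def gamma_q95_draws(fit: MetaFit, n_draws: int = 100_000, seed: int = 0) -> float:
    """Draw-based alternative to :func:`gamma_q95`: the empirical 95th
    percentile of Normal(gamma, gamma_sd) draws truncated at 0."""
    import numpy as np

    rng = np.random.default_rng(seed)
    draws = np.maximum(rng.normal(fit.gamma, fit.gamma_sd, n_draws), 0.0)
    return float(np.quantile(draws, 0.95))


def compute_bprf_draws(fit: MetaFit, direction: Direction,
                       n_draws: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo cross-check of :func:`compute_bprf`: the empirical
    null-closest 5% quantile of exp(beta + u) with beta ~ Normal(beta_mean,
    beta_se) and u ~ Normal(0, gamma_q95).  Agrees with the analytic value
    to Monte-Carlo error."""
    import numpy as np

    direction = Direction(direction)
    g95 = gamma_q95(fit)
    rng = np.random.default_rng(seed)
    total = rng.normal(fit.beta_mean, math.sqrt(fit.beta_se**2 + g95), n_draws)
    q = 0.05 if direction is Direction.HARMFUL else 0.95
    return float(np.exp(np.quantile(total, q)))


@dataclass
class EvidenceScore:
    """Published evidence summary for one risk–outcome pair."""

    rr: float
    ui_no_gamma: tuple[float, float]
    ui_with_gamma: tuple[float, float]
    gamma_q95: float
    bprf: float | None
    ros: float | None
    stars: int
    direction: Direction
    min_percent_change: int | None
    publication_bias: bool | None = None
    n_studies: int | None = None
    selected_covariates: list[str] | None = None

    def to_dict(self) -> dict:
        d = {
            "rr": self.rr,
            "ui_no_gamma": list(self.ui_no_gamma),
            "ui_with_gamma": list(self.ui_with_gamma),
            "gamma_q95": self.gamma_q95,
            "bprf": self.bprf,
            "ros": self.ros,
            "stars": self.stars,
            "direction": self.direction.value,
            "min_percent_change": self.min_percent_change,
            "publication_bias": self.publication_bias,
            "n_studies": self.n_studies,
            "selected_covariates": self.selected_covariates,
        }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def score(fit: MetaFit, direction: Direction = Direction.HARMFUL,
          publication_bias: bool | None = None,
          n_studies: int | None = None,
          selected_covariates: list[str] | None = None) -> EvidenceScore:
    """Assemble the full evidence summary, applying the zero-star rule."""
    direction = Direction(direction)
    no_gamma, with_gamma, g95 = compute_intervals(fit)
    zero_star = no_gamma[0] <= 1.0 <= no_gamma[1]
    if zero_star:
        bprf = ros = mpc = None
        stars = 0
    else:
        bprf = compute_bprf(fit, direction)
        ros = compute_ros(bprf, direction)
        stars = assign_stars(ros)
        mpc = min_percent_change(bprf, direction)
    return EvidenceScore(
        rr=math.exp(fit.beta_mean),
        ui_no_gamma=no_gamma,
        ui_with_gamma=with_gamma,
        gamma_q95=g95,
        bprf=bprf,
        ros=ros,
        stars=stars,
        direction=direction,
        min_percent_change=mpc,
        publication_bias=publication_bias,
        n_studies=n_studies,
        selected_covariates=selected_covariates,
    )
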