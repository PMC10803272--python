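"""Publication-bias diagnostics: Egger's regression and funnel data export.

The diagnostics operate on post-trim, bias-adjusted model residuals (what
the modified funnel plots display), with each residual's total standard
deviation sqrt(se² + gamma) absorbing between-study heterogeneity.
Egger's test regresses residual on total SD, weighting by inverse total
variance; a significant slope indicates funnel asymmetry, which is flagged
but never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .meta import MetaFit, predict_residuals

__all__ = ["FunnelDatum", "EggerResult", "make_funnel", "eggers_test",
           "export_funnel"]


@dataclass
class FunnelDatum:
    obs_id: str
    residual: float
    residual_sd: float
    trimmed: bool = False

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise ValueError(f"{self.obs_id}: residual_sd must be positive")


@dataclass
class EggerResult:
    slope: float | None
    slope_se: float | None
    p_value: float | None
    flagged: bool
    evaluable: bool
    n_used: int


def make_funnel(fit: MetaFit, obs) -> list[FunnelDatum]:
    """Funnel data for all observations, trimmed ones marked."""
    out = []
    for r, (res, sd) in zip(obs, predict_residuals(fit, obs)):
        out.append(FunnelDatum(r.obs_id, res, sd, r.obs_id in fit.trimmed_ids))
    return out


def eggers_test(funnel, alpha: float = 0.05) -> EggerResult:
    """Weighted Egger regression of residual on residual SD.

    Only untrimmed observations enter.  Fewer than 3 of them yields a
    not-evaluable result (``evaluable=False``, nothing flagged).
    """
    data = [d for d in funnel if not d.trimmed]
    if len(data) < 3:
        return EggerResult(None, None, None, False, False, len(data))
    res = np.array([d.residual for d in data])
    sd = np.array([d.residual_sd for d in data])
    if np.ptp(sd) < 1e-12 * sd.mean():  # constant SDs: slope undefined
        return EggerResult(None, None, None, False, False, len(data))
    X = sm.add_constant(sd)
    wls = sm.WLS(res, X, weights=1.0 / sd**2).fit()
    slope = float(wls.params[1])
    p = float(wls.pvalues[1])
    return EggerResult(slope, float(wls.bse[1]), p, p < alpha, True, len(data))


def export_funnel(fit: MetaFit, obs, path) -> pd.DataFrame:
    """Write the funnel CSV (obs_id, residual, residual_sd, trimmed)."""
    funnel = make_funnel(fit, obs)
    df = pd.DataFrame(
        [{"obs_id": d.obs_id, "residual": d.residual,
          "residual_sd": d.residual_sd, "trimmed": d.trimmed} for d in funnel],
        columns=["obs_id", "residual", "residual_sd", "trimmed"],
    )
    df.to_csv(path, index=False)
    return df
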