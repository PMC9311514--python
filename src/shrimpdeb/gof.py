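"""Validation statistics comparing modelled to observed growth.

Conventions: mean bias is model minus observation (negative = the model
underestimates); the relative RMSE is expressed as a percentage of the mean
observed value; R² is computed about the observed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InvalidInput
from .estimation import loss_mre, loss_smse

__all__ = ["GofReport", "relative_error", "rmse_mb_r2", "compare_series", "compare_growth"]


@dataclass
class GofReport:
    """RE/MRE/SMSE/RMSE/MB/R² bundle for one predicted-vs-observed series."""

    re: float          # mean per-point relative error
    mre: float
    smse: float
    rmse: float        # units of the quantity
    rmse_pct: float    # 100·rmse/mean(observed)
    mb: float          # signed mean bias, model − observation
    r2: float
    n: int = 0
    quantity: str = ""

    def summary(self) -> str:
        return (f"{self.quantity or 'series'}: R2 = {self.r2:.4f}, "
                f"RMSE = {self.rmse:.4f} ({self.rmse_pct:.2f}%), "
                f"MB = {self.mb:.4f}, MRE = {self.mre:.4f}, "
                f"SMSE = {self.smse:.4f} (n = {self.n})")


def relative_error(pred: float, obs: float) -> float:
    """|pred − obs| / |obs| for a single pair."""
    if obs == 0:
        raise InvalidInput("relative error undefined for a zero observation")
    return abs(pred - obs) / abs(obs)


def rmse_mb_r2(pred, obs) -> tuple[float, float, float, float]:
    """(rmse, rmse_pct, mb, r2) for two equal-length series.

    rmse = sqrt(mean((p − d)²)); mb = mean(p − d); r2 = 1 − SS_res/SS_tot
    about the observed mean.  Constant observations leave R² undefined and
    raise.
    """
    p = np.asarray(pred, dtype=float)
    d = np.asarray(obs, dtype=float)
    if p.shape != d.shape or p.ndim != 1:
        raise InvalidInput("series must be equal-length 1-D")
    if p.size < 2:
        raise InvalidInput("at least two points are required")
    resid = p - d
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mb = float(np.mean(resid))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidInput("R2 undefined for constant observations")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    mean_obs = float(np.mean(d))
    if mean_obs == 0:
        raise InvalidInput("relative RMSE undefined when the observed mean is zero")
    return rmse, 100.0 * rmse / abs(mean_obs), mb, r2


def compare_series(pred, obs, quantity: str = "") -> GofReport:
    """Full report for one series."""
    p = np.asarray(pred, dtype=float)
    d = np.asarray(obs, dtype=float)
    rmse, rmse_pct, mb, r2 = rmse_mb_r2(p, d)
    return GofReport(re=loss_mre(p, d), mre=loss_mre(p, d),
                     smse=loss_smse(p, d), rmse=rmse, rmse_pct=rmse_pct,
                     mb=mb, r2=r2, n=p.size, quantity=quantity)


def compare_growth(pred_obs, obs) -> dict:
    """Reports for length and weight of two growth-observation tables.

    Both arguments carry ``day``, ``length_cm`` and ``weight_g``; the
    sampling days must match.
    """
    pd_days = np.asarray(pred_obs.day, float)
    ob_days = np.asarray(obs.day, float)
    if pd_days.shape != ob_days.shape or np.any(np.abs(pd_days - ob_days) > 1e-9):
        raise InvalidInput("prediction and observation sampling days differ")
    return {
        "length_cm": compare_series(pred_obs.length_cm, obs.length_cm, "length_cm"),
        "weight_g": compare_series(pred_obs.weight_g, obs.weight_g, "weight_g"),
    }
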