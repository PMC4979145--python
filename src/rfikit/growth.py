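"""Per-bird growth-curve fitting and feeding-trait derivation.

Body weight over a feeding trial on rapidly growing birds is well
described by a line in the day of test (DOT): ``BW = mu + a*DOT + e``.
The slope ``a`` is the average daily gain (ADG); the mid-test body weight
(MBW) is the predicted weight on day 21 of a 40-day test, and the
metabolic mid-test weight (MMBW) is MBW^0.75.  Average daily feed intake
(ADFI) is the mean of the recorded daily feed, and the feed conversion
ratio (FCR) is ADFI/ADG per bird.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GrowthFit", "UnfittableBirdError", "fit_growth_curve", "derive_feeding_traits", "fit_cohort"]


class UnfittableBirdError(ValueError):
    """A bird's weight series cannot support a linear growth fit."""


@dataclass(frozen=True)
class GrowthFit:
    intercept: float  # g (predicted weight at DOT = 0)
    adg: float  # g/day
    r2: float
    mbw: float  # g
    mmbw: float  # g^0.75
    low_fit_flag: bool


def fit_growth_curve(
    dot: np.ndarray,
    bw: np.ndarray,
    mid_day: int = 21,
    r2_flag_threshold: float = 0.80,
) -> GrowthFit:
    """Ordinary least squares of body weight on day of test.

    Birds whose growth line explains less than ``r2_flag_threshold`` of
    the weight variance are flagged (not removed): a low R² signals an
    unreliable ADG/MMBW estimate, e.g. from illness or scale errors.

    Raises :class:`UnfittableBirdError` for fewer than three distinct DOT
    values or a non-positive predicted mid-test weight.
    """
    dot = np.asarray(dot, dtype=float)
    bw = np.asarray(bw, dtype=float)
    if dot.shape != bw.shape:
        raise ValueError("dot and bw must have matching shapes")
    if np.unique(dot).size < 3:
        raise UnfittableBirdError("need at least 3 distinct days of test")

    A = np.column_stack([np.ones_like(dot), dot])
    coef, *_ = np.linalg.lstsq(A, bw, rcond=None)
    mu, a = float(coef[0]), float(coef[1])
    resid = bw - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((bw - bw.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)

    mbw = mu + a * mid_day
    if mbw <= 0:
        raise UnfittableBirdError(f"non-positive predicted mid-test weight ({mbw:.1f} g)")
    return GrowthFit(
        intercept=mu,
        adg=a,
        r2=r2,
        mbw=mbw,
        mmbw=mbw**0.75,
        low_fit_flag=bool(r2 < r2_flag_threshold),
    )


def derive_feeding_traits(feed_g: np.ndarray, fit: GrowthFit) -> dict:
    """ADFI, FCR and carried-forward growth traits for one bird.

    ADFI is the mean of the available daily feed records (missing days are
    tolerated and counted).  FCR = ADFI/ADG; when ADG <= 0 the ratio is
    undefined and reported as NaN with a warning.
    """
    feed = np.asarray(feed_g, dtype=float)
    valid = ~np.isnan(feed)
    if not valid.any():
        raise ValueError("feed series is empty")
    adfi = float(feed[valid].mean())
    if fit.adg > 0:
        fcr = adfi / fit.adg
    else:
        warnings.warn("non-positive ADG: FCR undefined", stacklevel=2)
        fcr = float("nan")
    return {
        "adg": fit.adg,
        "r2": fit.r2,
        "mbw": fit.mbw,
        "mmbw": fit.mmbw,
        "adfi": adfi,
        "fcr": fcr,
        "n_feed_days": int(valid.sum()),
        "low_fit_flag": fit.low_fit_flag,
    }


def fit_cohort(
    records: pd.DataFrame,
    mid_day: int = 21,
    r2_flag_threshold: float = 0.80,
) -> pd.DataFrame:
    """Fit every bird in a long-format record table.

    ``records`` columns: bird_id, sex, pen, dot, body_weight_g, feed_g.
    Returns one row per bird with growth and feeding traits plus the
    observed start/end body weights (earliest and latest recorded day).
    """
    rows = []
    for bird_id, sub in records.groupby("bird_id", sort=True):
        sub = sub.sort_values("dot")
        fit = fit_growth_curve(
            sub["dot"].to_numpy(),
            sub["body_weight_g"].to_numpy(),
            mid_day=mid_day,
            r2_flag_threshold=r2_flag_threshold,
        )
        row = {
            "bird_id": bird_id,
            "sex": sub["sex"].iloc[0],
            "pen": sub["pen"].iloc[0],
            "bw_start": float(sub["body_weight_g"].iloc[0]),
            "bw_end": float(sub["body_weight_g"].iloc[-1]),
        }
        row.update(derive_feeding_traits(sub["feed_g"].to_numpy(), fit))
        rows.append(row)
    return pd.DataFrame(rows)
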