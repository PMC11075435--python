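"""Mean generation time (MGT) from OD growth curves.

MGT is the time the population takes to double while in exponential phase:
a window is slid over ln(OD - blank) versus time, windows with a good
log-linear fit (r^2 above a guard) are candidates, and the maximum slope mu
among them gives MGT = ln2 / mu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dfmflow.synthetic_data.growth import GrowthCurve

__all__ = [
    "MGTEstimate",
    "estimate_mgt",
    "read_growth_csv",
    "write_growth_csv",
    "write_mgt_csv",
]


@dataclass
class MGTEstimate:
    """A fitted specific growth rate and its doubling time.

    ``window`` is the (start, stop) index pair of the winning window into
    the curve's valid (positive blanked-OD) points; ``valid`` is False when
    no window passed the r^2 guard with a positive slope.
    """

    mu: float
    mgt: float
    window: tuple
    r2: float
    valid: bool
    well: str = ""

    def __repr__(self) -> str:  # compact, for per-plate printouts
        if not self.valid:
            return f"MGTEstimate(well={self.well!r}, invalid)"
        return (
            f"MGTEstimate(well={self.well!r}, mgt={self.mgt:.3g} h, "
            f"mu={self.mu:.3g}/h, r2={self.r2:.4f})"
        )


def estimate_mgt(
    curve: GrowthCurve,
    window_size: int = 5,
    r2_min: float = 0.99,
    min_blanked_od: float = 0.0,
) -> MGTEstimate:
    """Sliding log-linear fit of a growth curve.

    Windows of ``window_size`` consecutive points with positive blanked OD
    are regressed as ln(od - blank) ~ t; among windows with r^2 >= r2_min
    and positive slope, the one with the largest slope wins.  Returns an
    invalid estimate (mu = NaN) when no window qualifies.

    ``min_blanked_od`` excludes readings below a noise floor (set it to
    about 3x the instrument noise SD for noisy plates): log-transformed
    noise near zero OD otherwise produces spuriously steep windows.
    """
    if window_size < 3:
        raise ValueError("window_size must be >= 3 for a meaningful fit")
    blanked = curve.od - curve.blank
    positive = blanked > max(0.0, min_blanked_od)
    t = curve.t[positive]
    y = np.log(blanked[positive])

    best_mu = -np.inf
    best = None
    for start in range(0, len(t) - window_size + 1):
        stop = start + window_size
        tw, yw = t[start:stop], y[start:stop]
        # skip windows spanning gaps? points are consecutive in the valid
        # subsequence; a flat window gives slope 0 and is rejected below
        slope, _, r, _, _ = stats.linregress(tw, yw)
        if not np.isfinite(slope) or slope <= 0:
            continue
        r2 = r * r
        if r2 >= r2_min and slope > best_mu:
            best_mu = slope
            best = (start, stop, r2)

    if best is None:
        return MGTEstimate(
            mu=float("nan"),
            mgt=float("nan"),
            window=(-1, -1),
            r2=float("nan"),
            valid=False,
            well=curve.well,
        )
    start, stop, r2 = best
    return MGTEstimate(
        mu=best_mu,
        mgt=float(np.log(2.0) / best_mu),
        window=(start, stop),
        r2=float(r2),
        valid=True,
        well=curve.well,
    )


def read_growth_csv(path) -> list:
    """Read plate-reader curves from a tidy CSV (columns well, t_h, od).

    An optional ``blank`` column sets the per-well blank; otherwise the
    minimum of the first three OD readings is used.  The fallback also
    subtracts the inoculum OD, which distorts the earliest readings -- for
    heuristic blanks, fit with a ``min_blanked_od`` floor.
    """
    df = pd.read_csv(path)
    required = {"well", "t_h", "od"}
    if not required.issubset(df.columns):
        raise ValueError(f"growth CSV must have columns {sorted(required)}")
    curves = []
    for well, group in df.groupby("well", sort=False):
        group = group.sort_values("t_h")
        if "blank" in group.columns:
            blank = float(group["blank"].iloc[0])
        else:
            blank = float(group["od"].head(3).min())
        curves.append(
            GrowthCurve(
                t=group["t_h"].to_numpy(),
                od=group["od"].to_numpy(),
                blank=blank,
                well=str(well),
            )
        )
    return curves


def write_growth_csv(curves, path) -> None:
    """Write curves as a tidy CSV (well, t_h, od, blank)."""
    pd.concat(
        [
            pd.DataFrame(
                {"well": c.well, "t_h": c.t, "od": c.od, "blank": c.blank}
            )
            for c in curves
        ],
        ignore_index=True,
    ).to_csv(path, index=False)


def write_mgt_csv(estimates, path) -> None:
    """Write per-well MGT estimates as CSV."""
    pd.DataFrame(
        [
            {
                "well": e.well,
                "mgt_h": e.mgt,
                "mu_per_h": e.mu,
                "r2": e.r2,
                "valid": e.valid,
            }
            for e in estimates
        ]
    ).to_csv(path, index=False)
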