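"""Generators for OD growth curves and colonisation time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dfmflow.synthetic_data.strains import DEFAULT_SEED

__all__ = ["GrowthCurve", "simulate_growth_curve", "simulate_colonisation_series"]


@dataclass
class GrowthCurve:
    """Plate-reader style OD time series.

    ``t`` in hours (strictly increasing), ``od`` the raw optical densities,
    ``blank`` the medium blank to subtract before log-linear fitting.
    """

    t: np.ndarray
    od: np.ndarray
    blank: float = 0.0
    well: str = "A1"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.t) != len(self.od):
            raise ValueError("t and od must have equal length")
        if len(self.t) > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("t must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("od must be >= 0")


def simulate_growth_curve(
    mgt: float,
    lag: float = 0.0,
    od0: float = 0.005,
    od_max: float = 1.0,
    dt: float = 0.25,
    t_end: float = 72.0,
    noise_sd: float = 0.0,
    blank: float = 0.0,
    seed: int = DEFAULT_SEED,
    well: str = "A1",
) -> GrowthCurve:
    """Logistic growth after a lag phase, with known generation time.

    The specific growth rate is ``mu = ln2 / mgt``, so during early
    exponential phase (od << od_max) the blanked OD doubles every ``mgt``
    hours.  Gaussian noise of SD ``noise_sd`` is added to the OD readings
    (clipped at zero); the recorded blank is added to every reading.
    """
    if mgt <= 0:
        raise ValueError(f"mgt must be > 0, got {mgt}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if od0 > od_max:
        raise ValueError(f"od0 ({od0}) must be <= od_max ({od_max})")
    mu = np.log(2.0) / mgt
    t = np.arange(0.0, t_end + dt / 2, dt)
    tau = np.clip(t - lag, 0.0, None)
    growth = od_max * od0 * np.exp(mu * tau) / (od_max + od0 * (np.exp(mu * tau) - 1.0))
    od = blank + growth
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=len(t))
    od = np.clip(od, 0.0, None)
    return GrowthCurve(t=t, od=od, blank=blank, well=well)


def simulate_colonisation_series(
    strains,
    timepoints,
    n_replicates: int = 4,
    carrying_capacity: float = 1e7,
    initial: float = 1e4,
    rates: dict | None = None,
    replicate_gsd: float = 1.5,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Synthetic per-replicate colonisation abundances with known dynamics.

    Each strain follows a logistic trajectory from ``initial`` towards
    ``carrying_capacity`` at its own rate (per unit time, default 1.0), with
    log-normal replicate noise of geometric SD ``replicate_gsd``.

    Returns a tidy frame with columns ``strain``, ``timepoint``,
    ``replicate``, ``egr_corrected``, ``expected`` (the noise-free mean).
    """
    rng = np.random.default_rng(seed)
    rates = rates or {}
    rows = []
    for strain in strains:
        r = float(rates.get(strain, 1.0))
        for tp in timepoints:
            expected = (
                carrying_capacity
                * initial
                * np.exp(r * tp)
                / (carrying_capacity + initial * (np.exp(r * tp) - 1.0))
            )
            noise = rng.lognormal(0.0, np.log(replicate_gsd), size=n_replicates)
            for rep in range(n_replicates):
                rows.append(
                    {
                        "strain": strain,
                        "timepoint": tp,
                        "replicate": rep,
                        "egr_corrected": expected * noise[rep],
                        "expected": expected,
                    }
                )
    return pd.DataFrame(rows)
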