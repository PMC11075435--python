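"""Seed-controlled simulation of flow-cytometry list-mode events.

The signal model: each expressed fluorophore contributes, in every channel,
its frozen primary-channel median (5000 FI x expression_scale x brightness)
scaled by the channel's relative spectral gain, multiplied by one per-event
log-normal expression factor shared across channels.  An additive per-channel
log-normal autofluorescence draw is added on top.  Doublets are channel-wise
sums of two singlet events with the aspect-ratio drawn below the 0.4 singlet
cut; debris events carry dispersed scatter and autofluorescence only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dfmflow.synthetic_data.fluorophores import (
    FluorophoreSpec,
    OpticalConfig,
    channel_gains,
    default_optics,
    default_panel,
)
from dfmflow.synthetic_data.strains import (
    SIGNAL_MEDIAN_FI,
    NoiseModel,
    StrainSpec,
    default_noise,
    root_background_noise,
)

__all__ = [
    "EventTable",
    "simulate_events",
    "simulate_mixture",
    "simulate_root_background",
]

SCATTER_COLUMNS = ("fsc", "ssc", "ar_ssc")

#: Relative spillover below this fraction of the primary-channel signal is
#: below detector resolution and treated as exactly zero.
SPILL_FLOOR = 1e-3


@dataclass
class EventTable:
    """Per-event scatter and fluorescence intensities.

    ``data`` holds one row per event with columns ``fsc``, ``ssc``,
    ``ar_ssc``, one intensity column per channel key, and an optional
    ``truth`` column carrying the generating strain id.
    """

    data: pd.DataFrame
    channels: tuple

    def __post_init__(self) -> None:
        missing = [c for c in SCATTER_COLUMNS + tuple(self.channels) if c not in self.data.columns]
        if missing:
            raise ValueError(f"EventTable missing columns: {missing}")
        intensities = self.data[list(self.channels)].to_numpy()
        if (intensities < 0).any():
            raise ValueError("fluorescence intensities must be >= 0")
        ar = self.data["ar_ssc"].to_numpy()
        if ((ar < 0) | (ar > 1)).any():
            raise ValueError("ar_ssc must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_truth(self) -> bool:
        return "truth" in self.data.columns

    def intensity(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()


def _lognormal(rng: np.random.Generator, median: float, gsd: float, n: int) -> np.ndarray:
    """Log-normal draw parameterised by median and geometric SD."""
    if gsd == 1.0:
        return np.full(n, float(median))
    return rng.lognormal(mean=np.log(median), sigma=np.log(gsd), size=n)


def _panel_map(panel) -> dict:
    return {f.name: f for f in panel}


def _median_signal_matrix(
    spec: StrainSpec, optics: OpticalConfig, panel_map: dict
) -> np.ndarray:
    """Median FI of each expressed fluorophore in each channel.

    Shape (n_expressed, n_channels).  Each fluorophore's row is its channel
    gain profile normalised so the primary channel hits the frozen 5000 FI
    calibration point (times brightness and expression scale).
    """
    rows = []
    for name in spec.expressed:
        if name not in panel_map:
            raise KeyError(f"fluorophore {name!r} not present in panel")
        fluor: FluorophoreSpec = panel_map[name]
        gains = channel_gains(fluor, optics)
        relative = gains / gains.max()
        relative[relative < SPILL_FLOOR] = 0.0
        rows.append(
            SIGNAL_MEDIAN_FI * spec.expression_scale * fluor.brightness * relative
        )
    if not rows:
        return np.zeros((0, len(optics.channels)))
    return np.vstack(rows)


def _draw_singlet_intensities(
    rng: np.random.Generator,
    medians: np.ndarray,
    noise: NoiseModel,
    optics: OpticalConfig,
    n: int,
) -> np.ndarray:
    """Signal + autofluorescence for n singlet events; shape (n, n_channels)."""
    intensities = np.zeros((n, len(optics.channels)))
    for row in medians:
        expr = _lognormal(rng, 1.0, noise.expr_gsd, n)
        intensities += np.outer(expr, row)
    for i, ch in enumerate(optics.channels):
        med, gsd = noise.autofluor.get(ch.key, (0.0, 1.0))
        if med > 0:
            intensities[:, i] += _lognormal(rng, med, gsd, n)
    return intensities


def simulate_events(
    spec: StrainSpec,
    n: int,
    optics: OpticalConfig | None = None,
    panel=None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> EventTable:
    """Simulate ``n`` events for a single strain.

    Parameters
    ----------
    spec : StrainSpec
        Strain to simulate; every expressed fluorophore must appear in
        ``panel``.
    n : int
        Number of events, >= 1.
    optics, panel, noise
        Instrument, fluorophore panel and noise model; package defaults when
        omitted.
    seed : int, optional
        Overrides ``noise.seed``.

    Returns
    -------
    EventTable
        Deterministic for a given seed; the truth column holds
        ``spec.strain_id``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    optics = optics or default_optics()
    panel = panel if panel is not None else default_panel()
    noise = noise or default_noise()
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    medians = _median_signal_matrix(spec, optics, _panel_map(panel))

    fsc = _lognormal(rng, *spec.fsc_params, n)
    ssc = _lognormal(rng, *spec.ssc_params, n)
    ar = rng.beta(*spec.ar_params, size=n)
    intensities = _draw_singlet_intensities(rng, medians, noise, optics, n)

    kind = rng.random(n)
    doublet = kind < noise.doublet_rate
    debris = (~doublet) & (kind < noise.doublet_rate + noise.debris_rate)

    n_doub = int(doublet.sum())
    if n_doub:
        # doublet = channel-wise sum of two singlets; shape stat below the cut
        fsc[doublet] += _lognormal(rng, *spec.fsc_params, n_doub)
        ssc[doublet] += _lognormal(rng, *spec.ssc_params, n_doub)
        intensities[doublet] += _draw_singlet_intensities(
            rng, medians, noise, optics, n_doub
        )
        ar[doublet] = rng.uniform(0.05, 0.4, size=n_doub)

    n_deb = int(debris.sum())
    if n_deb:
        fsc[debris] = _lognormal(rng, 400.0, 3.0, n_deb)
        ssc[debris] = _lognormal(rng, 300.0, 3.0, n_deb)
        ar[debris] = rng.uniform(0.0, 1.0, size=n_deb)
        # debris carries no expressed-fluorophore signal
        deb_int = np.zeros((n_deb, len(optics.channels)))
        for i, ch in enumerate(optics.channels):
            med, gsd = noise.autofluor.get(ch.key, (0.0, 1.0))
            if med > 0:
                deb_int[:, i] = _lognormal(rng, med, gsd, n_deb)
        intensities[debris] = deb_int

    data = pd.DataFrame({"fsc": fsc, "ssc": ssc, "ar_ssc": ar})
    for i, ch in enumerate(optics.channels):
        data[ch.key] = intensities[:, i]
    data["truth"] = spec.strain_id
    return EventTable(data=data, channels=optics.channel_keys)


def simulate_mixture(
    specs,
    proportions,
    n: int,
    optics: OpticalConfig | None = None,
    panel=None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> EventTable:
    """Simulate a mixed sample of several strains.

    Per-strain event counts are drawn multinomially from ``proportions``;
    events are shuffled so strain blocks are interleaved, with truth labels
    preserved.
    """
    if len(specs) != len(proportions):
        raise ValueError(
            f"got {len(specs)} specs but {len(proportions)} proportions"
        )
    proportions = np.asarray(proportions, dtype=float)
    if (proportions < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {proportions.sum()}")
    optics = optics or default_optics()
    panel = panel if panel is not None else default_panel()
    noise = noise or default_noise()
    seed = noise.seed if seed is None else seed

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, proportions)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(specs))

    frames = []
    for spec, count, child in zip(specs, counts, child_seeds):
        if count == 0:
            continue
        table = simulate_events(
            spec, int(count), optics=optics, panel=panel, noise=noise, seed=int(child)
        )
        frames.append(table.data)
    data = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(data))
    data = data.iloc[order].reset_index(drop=True)
    return EventTable(data=data, channels=optics.channel_keys)


def simulate_root_background(
    n: int,
    noise: NoiseModel | None = None,
    plant: str = "pea",
    optics: OpticalConfig | None = None,
    seed: int | None = None,
) -> EventTable:
    """Simulate uninoculated-root events: debris-like scatter, blue-shifted
    autofluorescence, truth label ``"background"``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    optics = optics or default_optics()
    noise = noise or root_background_noise(plant)
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    fsc = _lognormal(rng, 2000.0, 2.8, n)
    ssc = _lognormal(rng, 1500.0, 2.8, n)
    ar = rng.beta(2.0, 2.0, size=n)
    intensities = np.zeros((n, len(optics.channels)))
    for i, ch in enumerate(optics.channels):
        med, gsd = noise.autofluor.get(ch.key, (0.0, 1.0))
        if med > 0:
            intensities[:, i] = _lognormal(rng, med, gsd, n)

    data = pd.DataFrame({"fsc": fsc, "ssc": ssc, "ar_ssc": ar})
    for i, ch in enumerate(optics.channels):
        data[ch.key] = intensities[:, i]
    data["truth"] = "background"
    return EventTable(data=data, channels=optics.channel_keys)
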