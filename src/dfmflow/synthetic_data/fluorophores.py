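"""Fluorophore spectra and instrument optics.

Spectral shapes are approximated as Gaussians: a fluorophore is described by
its excitation/emission peak wavelengths and spectral widths.  The fraction
of emitted light collected by a bandpass filter is the Gaussian mass falling
inside the filter window; excitation efficiency at a laser line is the
Gaussian excitation profile evaluated at the laser wavelength.  This is a
deliberately simple model -- no maturation kinetics, photobleaching or
detector saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "CHANNEL_BLUE",
    "CHANNEL_YELLOW",
    "CHANNEL_RED",
    "CHANNEL_KEYS",
    "Channel",
    "FluorophoreSpec",
    "OpticalConfig",
    "channel_gains",
    "default_optics",
    "default_panel",
    "primary_channel",
]

#: Canonical channel keys: "<laser nm>-<filter centre>/<filter bandwidth>".
CHANNEL_BLUE = "405-456/51"
CHANNEL_YELLOW = "488-528/46"
CHANNEL_RED = "561-611/31"
CHANNEL_KEYS = (CHANNEL_BLUE, CHANNEL_YELLOW, CHANNEL_RED)


@dataclass(frozen=True)
class FluorophoreSpec:
    """Gaussian approximation of a fluorescent protein's spectra.

    Parameters
    ----------
    name : str
        Fluorophore identifier (e.g. ``"mCherry"``).
    ex_max, em_max : float
        Excitation / emission peak wavelengths in nm.  ``ex_max`` must be
        smaller than ``em_max`` (positive Stokes shift).
    ex_sigma, em_sigma : float
        Gaussian spectral widths in nm, strictly positive.
    brightness : float
        Relative fluorescence-intensity scale, strictly positive.
    """

    name: str
    ex_max: float
    em_max: float
    ex_sigma: float = 30.0
    em_sigma: float = 30.0
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if not self.ex_max < self.em_max:
            raise ValueError(
                f"{self.name}: ex_max ({self.ex_max}) must be < em_max "
                f"({self.em_max}); Stokes shift must be positive"
            )
        if self.ex_sigma <= 0 or self.em_sigma <= 0:
            raise ValueError(f"{self.name}: spectral sigmas must be > 0")
        if self.brightness <= 0:
            raise ValueError(f"{self.name}: brightness must be > 0")


@dataclass(frozen=True)
class Channel:
    """One detection channel: a laser line plus an emission bandpass filter."""

    laser_nm: float
    filter_centre_nm: float
    filter_bw_nm: float
    key: str

    @property
    def filter_lo(self) -> float:
        return self.filter_centre_nm - self.filter_bw_nm / 2.0

    @property
    def filter_hi(self) -> float:
        return self.filter_centre_nm + self.filter_bw_nm / 2.0


@dataclass(frozen=True)
class OpticalConfig:
    """Laser lines and detection channels of the instrument."""

    lasers: tuple = (405.0, 488.0, 561.0)
    channels: tuple = field(
        default=(
            Channel(405.0, 456.0, 51.0, CHANNEL_BLUE),
            Channel(488.0, 528.0, 46.0, CHANNEL_YELLOW),
            Channel(561.0, 611.0, 31.0, CHANNEL_RED),
        )
    )

    def __post_init__(self) -> None:
        keys = [ch.key for ch in self.channels]
        if len(set(keys)) != len(keys):
            raise ValueError(f"channel keys must be unique, got {keys}")

    @property
    def channel_keys(self) -> tuple:
        return tuple(ch.key for ch in self.channels)


def default_optics() -> OpticalConfig:
    """Three-laser instrument with the 405/488/561 nm channel set."""
    return OpticalConfig()


def default_panel() -> tuple:
    """The three-fluorophore panel: mTagBFP, sYFP2, mCherry.

    Peak wavelengths follow the fpbase reference spectra for these proteins
    (mTagBFP 399/456 nm, sYFP2 515/527 nm, mCherry 587/610 nm); the common
    30 nm sigma is a generator fixture, not a measured width.
    """
    return (
        FluorophoreSpec("mTagBFP", ex_max=399.0, em_max=456.0),
        FluorophoreSpec("sYFP2", ex_max=515.0, em_max=527.0),
        FluorophoreSpec("mCherry", ex_max=587.0, em_max=610.0),
    )


def channel_gains(fluor: FluorophoreSpec, optics: OpticalConfig) -> np.ndarray:
    """Relative signal of ``fluor`` in each channel of ``optics``.

    For channel *c* the gain is the product of the Gaussian excitation
    efficiency at the laser line and the emission probability mass captured
    by the bandpass filter:

        gain_c = exp(-(laser_c - ex_max)^2 / (2 ex_sigma^2))
                 * [Phi((hi_c - em_max)/em_sigma) - Phi((lo_c - em_max)/em_sigma)]

    Returns an array aligned with ``optics.channels``.
    """
    gains = np.empty(len(optics.channels))
    for i, ch in enumerate(optics.channels):
        ex = np.exp(-((ch.laser_nm - fluor.ex_max) ** 2) / (2.0 * fluor.ex_sigma**2))
        em = ndtr((ch.filter_hi - fluor.em_max) / fluor.em_sigma) - ndtr(
            (ch.filter_lo - fluor.em_max) / fluor.em_sigma
        )
        gains[i] = ex * em
    return gains


def primary_channel(fluor: FluorophoreSpec, optics: OpticalConfig) -> str:
    """Key of the channel in which ``fluor`` produces the most signal."""
    gains = channel_gains(fluor, optics)
    return optics.channels[int(np.argmax(gains))].key
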