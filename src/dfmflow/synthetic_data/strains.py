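"""Strain definitions and the event-level noise model.

A strain is characterised by which fluorophores it expresses (zero, one or
two of the panel -- the six single/double patterns plus an unlabelled
control) and by log-normal scatter distributions.  The calibration below is
frozen: expressed fluorophores give a median of 5000 FI in their primary
channel with geometric SD 2.0, and autofluorescence medians are 40/40/80 FI
(red/yellow/blue) with geometric SDs 2.0/2.0/2.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from dfmflow.synthetic_data.fluorophores import (
    CHANNEL_BLUE,
    CHANNEL_RED,
    CHANNEL_YELLOW,
)

__all__ = [
    "DEFAULT_SEED",
    "SIGNAL_MEDIAN_FI",
    "NoiseModel",
    "StrainSpec",
    "default_noise",
    "dfm_strain_specs",
    "oxcom6_patterns",
    "root_background_noise",
    "unlabelled_spec",
]

#: Default seed for every generator in the package.
DEFAULT_SEED = 3841

#: Frozen calibration: median FI of an expressed fluorophore in its primary
#: channel (before per-event expression noise).
SIGNAL_MEDIAN_FI = 5000.0

_PATTERN_TO_FLUOROPHORES = {
    "R": ("mCherry",),
    "Y": ("sYFP2",),
    "B": ("mTagBFP",),
    "RY": ("mCherry", "sYFP2"),
    "RB": ("mCherry", "mTagBFP"),
    "YB": ("sYFP2", "mTagBFP"),
}


@dataclass(frozen=True)
class StrainSpec:
    """A labelled (or unlabelled) strain and its scatter distributions.

    Parameters
    ----------
    strain_id : str
        Identifier placed in the truth column of simulated events.
    expressed : tuple of str
        Names of expressed fluorophores; 0, 1 or 2 entries for a valid DFM
        pattern (0 entries = unlabelled).
    expression_scale : float
        Multiplier on the frozen 5000-FI primary-channel median.
    fsc_params, ssc_params : (median, geometric SD)
        Log-normal scatter distributions.
    ar_params : (alpha, beta)
        Beta distribution of the aspect-ratio-of-SSC for singlets.
    """

    strain_id: str
    expressed: tuple = ()
    expression_scale: float = 1.0
    fsc_params: tuple = (20_000.0, 1.6)
    ssc_params: tuple = (15_000.0, 1.6)
    ar_params: tuple = (16.0, 3.0)

    def __post_init__(self) -> None:
        if len(self.expressed) > 2:
            raise ValueError(
                f"{self.strain_id}: a DFM pattern expresses at most two "
                f"fluorophores, got {self.expressed}"
            )
        if len(set(self.expressed)) != len(self.expressed):
            raise ValueError(f"{self.strain_id}: duplicate fluorophore in pattern")
        if self.expression_scale <= 0:
            raise ValueError(f"{self.strain_id}: expression_scale must be > 0")
        for name, (med, gsd) in (
            ("fsc_params", self.fsc_params),
            ("ssc_params", self.ssc_params),
        ):
            if med <= 0 or gsd < 1:
                raise ValueError(f"{self.strain_id}: invalid {name} ({med}, {gsd})")


@dataclass(frozen=True)
class NoiseModel:
    """Per-event noise: expression spread, autofluorescence, doublets, debris.

    ``autofluor`` maps channel key -> (median FI, geometric SD) of the
    additive log-normal autofluorescence background in that channel.
    """

    expr_gsd: float = 2.0
    autofluor: dict = field(
        default_factory=lambda: {
            CHANNEL_BLUE: (80.0, 2.2),
            CHANNEL_YELLOW: (40.0, 2.0),
            CHANNEL_RED: (40.0, 2.0),
        }
    )
    doublet_rate: float = 0.02
    debris_rate: float = 0.03
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.expr_gsd < 1:
            raise ValueError("expr_gsd (geometric SD) must be >= 1")
        for rate, name in ((self.doublet_rate, "doublet_rate"), (self.debris_rate, "debris_rate")):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.doublet_rate + self.debris_rate > 1.0:
            raise ValueError("doublet_rate + debris_rate must not exceed 1")
        for key, (med, gsd) in self.autofluor.items():
            if med < 0 or gsd < 1:
                raise ValueError(f"invalid autofluorescence for {key}: ({med}, {gsd})")


def default_noise(seed: int = DEFAULT_SEED) -> NoiseModel:
    """The frozen default noise calibration."""
    return NoiseModel(seed=seed)


def dfm_strain_specs() -> tuple:
    """The six single/double fluorophore patterns as StrainSpecs.

    Returns specs with ids ``R, Y, B, RY, RB, YB`` matching the combined
    population each should demultiplex into.
    """
    return tuple(
        StrainSpec(strain_id=pattern, expressed=fluors)
        for pattern, fluors in _PATTERN_TO_FLUOROPHORES.items()
    )


def unlabelled_spec(strain_id: str = "U") -> StrainSpec:
    """An unlabelled control strain (autofluorescence only)."""
    return StrainSpec(strain_id=strain_id, expressed=())


def oxcom6_patterns() -> dict:
    """Strain-id -> combined-pattern mapping for the six-member demo community."""
    return {
        "OpAA2": "R",
        "AoDQS-4": "Y",
        "PfSBW25": "B",
        "EcAA4": "RY",
        "Rlv3841": "RB",
        "AxAT1": "YB",
    }


def root_background_noise(plant: str = "pea", seed: int = DEFAULT_SEED) -> NoiseModel:
    """Noise model for uninoculated-root samples.

    Root debris autofluoresces predominantly in the blue channel (cell-wall
    lignin/suberin), so the blue median is elevated well above the cellular
    defaults; barley roots are modelled slightly dimmer than pea.
    """
    if plant == "pea":
        blue = (220.0, 2.5)
    elif plant == "barley":
        blue = (180.0, 2.5)
    else:
        raise ValueError(f"unknown plant {plant!r}; expected 'pea' or 'barley'")
    return NoiseModel(
        autofluor={
            CHANNEL_BLUE: blue,
            CHANNEL_YELLOW: (50.0, 2.1),
            CHANNEL_RED: (45.0, 2.1),
        },
        doublet_rate=0.0,
        debris_rate=0.0,
        seed=seed,
    )
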