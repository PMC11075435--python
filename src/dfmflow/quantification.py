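"""Absolute abundance conversion and background subtraction.

Gated event counts become events per mL (emL) through the analysed volume,
then events per gram of root (egr) through the harvest volume and the root
fresh mass.  Uninoculated-plant background is subtracted per (plant,
population) as a mean over background replicates, clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "AbundanceRecord",
    "SampleMeta",
    "abundance_table",
    "emL_to_egr",
    "events_to_emL",
    "subtract_background",
    "to_relative",
]

#: Low-speed / high-sensitivity flow rate of the default instrument.
DEFAULT_FLOW_RATE_UL_MIN = 3.66
DEFAULT_HARVEST_VOLUME_ML = 25.0


@dataclass(frozen=True)
class SampleMeta:
    """Acquisition and harvest metadata for one sample.

    Exactly one of ``analysed_volume_mL`` or the
    (``flow_rate_uL_min``, ``acquisition_time_min``) pair must be provided;
    instrument volumetric counting is preferred when both could apply.
    """

    sample_id: str
    timepoint: float = 0.0
    analysed_volume_mL: float | None = None
    flow_rate_uL_min: float | None = None
    acquisition_time_min: float | None = None
    harvest_volume_mL: float = DEFAULT_HARVEST_VOLUME_ML
    root_mass_g: float | None = None
    dilution_factor: float = 1.0
    plant: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        volumetric = self.analysed_volume_mL is not None
        timed = self.acquisition_time_min is not None
        if volumetric == timed:
            raise ValueError(
                f"{self.sample_id}: provide exactly one of analysed_volume_mL "
                "or flow_rate_uL_min x acquisition_time_min"
            )
        if volumetric and self.analysed_volume_mL <= 0:
            raise ValueError(f"{self.sample_id}: analysed volume must be > 0")
        if timed:
            rate = self.flow_rate_uL_min
            if rate is None:
                rate = DEFAULT_FLOW_RATE_UL_MIN
            if rate <= 0 or self.acquisition_time_min <= 0:
                raise ValueError(f"{self.sample_id}: flow rate and time must be > 0")
        if self.harvest_volume_mL <= 0:
            raise ValueError(f"{self.sample_id}: harvest volume must be > 0")
        if self.root_mass_g is not None and self.root_mass_g <= 0:
            raise ValueError(f"{self.sample_id}: root mass must be > 0")
        if self.dilution_factor <= 0:
            raise ValueError(f"{self.sample_id}: dilution factor must be > 0")

    @property
    def volume_mL(self) -> float:
        """Analysed volume in mL, from whichever source was supplied."""
        if self.analysed_volume_mL is not None:
            return self.analysed_volume_mL
        rate = self.flow_rate_uL_min
        if rate is None:
            rate = DEFAULT_FLOW_RATE_UL_MIN
        return rate * self.acquisition_time_min / 1000.0


@dataclass
class AbundanceRecord:
    """Abundance of one combined population in one sample."""

    population: str
    sample_id: str
    emL: float
    egr: float = float("nan")
    egr_corrected: float = float("nan")
    below_background: bool = False
    plant: str = ""
    timepoint: float = 0.0
    replicate: int = 0


def events_to_emL(count: int, meta: SampleMeta) -> float:
    """Events per mL: ``count * dilution_factor / analysed volume``."""
    if count < 0:
        raise ValueError(f"event count must be >= 0, got {count}")
    return count * meta.dilution_factor / meta.volume_mL


def emL_to_egr(emL: float, meta: SampleMeta) -> float:
    """Events per gram of root: ``emL * harvest volume / root mass``."""
    if meta.root_mass_g is None:
        raise ValueError(f"{meta.sample_id}: root mass required for egr")
    return emL * meta.harvest_volume_mL / meta.root_mass_g


def abundance_table(counts: dict, meta: SampleMeta) -> list:
    """Build AbundanceRecords from per-population event counts.

    ``counts`` maps combined-population label -> gated event count.  egr is
    filled when the sample has a root mass, otherwise left NaN (liquid
    samples are quantified as emL only).
    """
    records = []
    for population, count in counts.items():
        emL = events_to_emL(count, meta)
        egr = emL_to_egr(emL, meta) if meta.root_mass_g is not None else float("nan")
        records.append(
            AbundanceRecord(
                population=population,
                sample_id=meta.sample_id,
                emL=emL,
                egr=egr,
                plant=meta.plant,
                timepoint=meta.timepoint,
                replicate=meta.replicate,
            )
        )
    return records


def _background_means(background) -> dict:
    """Mean background egr keyed by (plant, population)."""
    sums: dict = {}
    for rec in background:
        key = (rec.plant, rec.population)
        total, n = sums.get(key, (0.0, 0))
        sums[key] = (total + rec.egr, n + 1)
    return {key: total / n for key, (total, n) in sums.items()}


def subtract_background(samples, background) -> list:
    """Subtract mean uninoculated-root background per (plant, population).

    Background replicates are pooled across timepoints.  Corrected values
    are clamped at zero, with ``below_background`` flagging the clamp.  A
    sample whose (plant, population) has no background entry is a hard
    error -- never a silent zero.
    """
    means = _background_means(background)
    corrected = []
    for rec in samples:
        key = (rec.plant, rec.population)
        if key not in means:
            raise KeyError(
                f"no background record for plant={rec.plant!r} "
                f"population={rec.population!r}"
            )
        raw = rec.egr - means[key]
        corrected.append(
            replace(rec, egr_corrected=max(0.0, raw), below_background=raw < 0)
        )
    return corrected


def to_relative(records, value: str = "egr_corrected") -> pd.DataFrame:
    """Per-sample relative abundances over the combined populations.

    Returns a tidy frame with ``fraction`` summing to 1 within each sample;
    all-zero samples get NaN fractions and ``undefined=True`` rather than an
    arbitrary split.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if df.empty:
        raise ValueError("empty abundance table")
    out = []
    for sample_id, group in df.groupby("sample_id", sort=False):
        total = group[value].sum()
        g = group.copy()
        if total > 0:
            g["fraction"] = g[value] / total
            g["undefined"] = False
        else:
            g["fraction"] = float("nan")
            g["undefined"] = True
        out.append(g)
    return pd.concat(out, ignore_index=True)


def records_to_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of a list of AbundanceRecords."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "plant": r.plant,
                "timepoint": r.timepoint,
                "replicate": r.replicate,
                "population": r.population,
                "emL": r.emL,
                "egr": r.egr,
                "egr_corrected": r.egr_corrected,
                "below_background": r.below_background,
            }
            for r in records
        ]
    )
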