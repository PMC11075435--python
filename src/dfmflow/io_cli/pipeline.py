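"""Pipeline driver: simulate -> gate -> demux -> quantify -> summarise.

Every stage failure is re-raised as a PipelineError tagged with the stage
name.  All randomness derives from the single configured seed; re-running
the same configuration reproduces outputs byte for byte (the run report
records the config hash and seed for that purpose).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

import dfmflow
from dfmflow.assembly_stats import summarise_series
from dfmflow.gating import COMBINED_CLASSES, GatingConfig, run_gating, score_assignments
from dfmflow.io_cli.config import RunConfig, config_hash
from dfmflow.quantification import (
    SampleMeta,
    abundance_table,
    records_to_frame,
    subtract_background,
    to_relative,
)
from dfmflow.synthetic_data import (
    NoiseModel,
    StrainSpec,
    default_noise,
    dfm_strain_specs,
    root_background_noise,
    simulate_mixture,
    simulate_root_background,
    unlabelled_spec,
)

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _noise_from_config(cfg: RunConfig, seed: int) -> NoiseModel:
    nc = cfg.noise
    base = default_noise(seed=seed)
    autofluor = (
        {k: tuple(v) for k, v in nc.autofluor.items()}
        if nc.autofluor is not None
        else base.autofluor
    )
    return NoiseModel(
        expr_gsd=nc.expr_gsd,
        autofluor=autofluor,
        doublet_rate=nc.doublet_rate,
        debris_rate=nc.debris_rate,
        seed=seed,
    )


def _gating_from_config(cfg: RunConfig) -> GatingConfig:
    gs = cfg.gating
    kwargs = dict(
        bacteria_mode=gs.bacteria_mode,
        density_fraction=gs.density_fraction,
        polygon=gs.polygon,
        singlet_fsc_min=gs.singlet_fsc_min,
        singlet_ar_min=gs.singlet_ar_min,
    )
    if gs.thresholds is not None:
        kwargs["colour_thresholds"] = {
            colour: (channel, float(fi)) for colour, (channel, fi) in gs.thresholds.items()
        }
    return GatingConfig(**kwargs)


def _strain_specs(cfg: RunConfig) -> list:
    by_pattern = {s.strain_id: s for s in dfm_strain_specs()}
    specs = []
    for strain_id, pattern in cfg.simulate.strains.items():
        if pattern == "U":
            specs.append(unlabelled_spec(strain_id))
        else:
            template = by_pattern[pattern]
            specs.append(
                StrainSpec(strain_id=strain_id, expressed=template.expressed)
            )
    return specs


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute the configured run and write the report bundle to ``outdir``.

    Writes ``abundance.csv`` (raw and background-corrected, tidy),
    ``relative.csv``, ``series_summary.csv``, ``confusion.json`` and
    ``report.json``; returns the report dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    specs = _strain_specs(cfg)
    patterns = cfg.simulate.strains
    proportions = cfg.simulate.proportions or [1.0 / len(specs)] * len(specs)
    gcfg = _gating_from_config(cfg)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(
        len(cfg.samples) + (cfg.background.replicates if cfg.background else 0) * 2
    )
    seed_iter = iter(int(s) for s in seeds)

    records = []
    confusion = {}
    for sample in cfg.samples:
        stage = f"simulate:{sample.sample_id}"
        try:
            noise = _noise_from_config(cfg, next(seed_iter))
            table = simulate_mixture(
                specs, proportions, sample.n_events, noise=noise
            )
        except Exception as exc:  # noqa: BLE001 - stage tagging
            raise PipelineError(stage, str(exc)) from exc

        stage = f"gate:{sample.sample_id}"
        try:
            labels = run_gating(table, gcfg)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"demux:{sample.sample_id}"
        try:
            summary = score_assignments(
                labels, table.data["truth"], expected=patterns
            )
            confusion[sample.sample_id] = summary.to_dict()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"quantify:{sample.sample_id}"
        try:
            assigned = labels.loc[labels["in_singlets"], "combined"]
            counts = {
                cls: int((assigned == cls).sum()) for cls in COMBINED_CLASSES
            }
            meta = SampleMeta(
                sample_id=sample.sample_id,
                timepoint=sample.timepoint,
                analysed_volume_mL=sample.analysed_volume_mL,
                flow_rate_uL_min=sample.flow_rate_uL_min,
                acquisition_time_min=sample.acquisition_time_min,
                harvest_volume_mL=sample.harvest_volume_mL,
                root_mass_g=sample.root_mass_g,
                dilution_factor=sample.dilution_factor,
                plant=sample.plant,
                replicate=sample.replicate,
            )
            records.extend(abundance_table(counts, meta))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    if cfg.subtract_background:
        stage = "background"
        try:
            bg_records = []
            for plant in sorted({s.plant for s in cfg.samples}):
                for rep in range(cfg.background.replicates):
                    seed = next(seed_iter)
                    bg_table = simulate_root_background(
                        cfg.background.n_events,
                        noise=root_background_noise(plant, seed=seed),
                        plant=plant,
                    )
                    bg_labels = run_gating(bg_table, gcfg)
                    bg_assigned = bg_labels.loc[bg_labels["in_singlets"], "combined"]
                    bg_counts = {
                        cls: int((bg_assigned == cls).sum())
                        for cls in COMBINED_CLASSES
                    }
                    bg_meta = SampleMeta(
                        sample_id=f"bg_{plant}_rep{rep}",
                        acquisition_time_min=cfg.background.acquisition_time_min,
                        root_mass_g=cfg.background.root_mass_g,
                        plant=plant,
                        replicate=rep,
                    )
                    bg_records.extend(abundance_table(bg_counts, bg_meta))
            records = subtract_background(records, bg_records)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc
        value_col = "egr_corrected"
    else:
        value_col = "egr" if all(s.root_mass_g for s in cfg.samples) else "emL"

    stage = "summarise"
    try:
        frame = records_to_frame(records)
        frame.to_csv(outdir / "abundance.csv", index=False)
        rel = to_relative(frame, value=value_col)
        rel.to_csv(outdir / "relative.csv", index=False)
        series = summarise_series(
            frame.rename(columns={"population": "strain"}), value=value_col
        )
        series.to_csv(outdir / "series_summary.csv", index=False)
        with open(outdir / "confusion.json", "w") as fh:
            json.dump(confusion, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    report = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_samples": len(cfg.samples),
        "subtract_background": cfg.subtract_background,
        "versions": {
            "dfmflow": dfmflow.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": [
            "abundance.csv",
            "confusion.json",
            "relative.csv",
            "series_summary.csv",
        ],
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
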