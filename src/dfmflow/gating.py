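"""Threshold-based gating chain and demultiplexing.

Chain: Bacteria (dense region of log FSC x log SSC) -> Singlets (FSC > 0 and
aspect-ratio of SSC > 0.4) -> three colour populations (per-channel strict
FI thresholds: red 550, yellow 500, blue 450) -> six mutually exclusive
combined populations R, Y, B, RY, RB, YB.  Events negative for all colours,
or positive for all three, are labelled Unassigned; no event is silently
dropped.  Thresholding happens on raw FI values -- log scaling is
display-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dfmflow.synthetic_data.events import EventTable
from dfmflow.synthetic_data.fluorophores import (
    CHANNEL_BLUE,
    CHANNEL_RED,
    CHANNEL_YELLOW,
)

__all__ = [
    "COMBINED_CLASSES",
    "COLOURS",
    "ConfusionSummary",
    "GatingConfig",
    "assign_colours",
    "assign_combined",
    "gate_bacteria",
    "gate_singlets",
    "run_gating",
    "score_assignments",
]

#: The six exclusive combined populations, plus the two reporting labels.
COMBINED_CLASSES = ("R", "Y", "B", "RY", "RB", "YB")
UNASSIGNED = "Unassigned"
NOT_SINGLET = "NotSinglet"
COLOURS = ("Red", "Yellow", "Blue")

_FLAGS_TO_COMBINED = {
    (True, False, False): "R",
    (False, True, False): "Y",
    (False, False, True): "B",
    (True, True, False): "RY",
    (True, False, True): "RB",
    (False, True, True): "YB",
    (False, False, False): UNASSIGNED,
    (True, True, True): UNASSIGNED,  # no triple-positive class is defined
}


@dataclass
class GatingConfig:
    """Gate definitions and fluorescence thresholds.

    All colour thresholds are strict (``intensity > threshold``), matching
    the "above N FI units" convention.  The bacteria gate is either the
    deterministic grid-density gate (``mode="density"``) or an explicit
    polygon in (log10 FSC, log10 SSC) space.
    """

    bacteria_mode: str = "density"
    density_fraction: float = 0.95
    polygon: list | None = None
    density_bins: int = 128
    singlet_fsc_min: float = 0.0
    singlet_ar_min: float = 0.4
    colour_thresholds: dict = field(
        default_factory=lambda: {
            "Red": (CHANNEL_RED, 550.0),
            "Yellow": (CHANNEL_YELLOW, 500.0),
            "Blue": (CHANNEL_BLUE, 450.0),
        }
    )

    def __post_init__(self) -> None:
        if self.bacteria_mode not in ("density", "polygon"):
            raise ValueError(f"unknown bacteria_mode {self.bacteria_mode!r}")
        if not 0.0 < self.density_fraction <= 1.0:
            raise ValueError("density_fraction must be in (0, 1]")
        if self.bacteria_mode == "polygon" and not self.polygon:
            raise ValueError("polygon mode requires polygon vertices")
        for colour, (_, thr) in self.colour_thresholds.items():
            if thr <= 0:
                raise ValueError(f"{colour} threshold must be positive, got {thr}")


def _new_labels(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "in_bacteria": np.zeros(n, dtype=bool),
            "in_singlets": np.zeros(n, dtype=bool),
            "red": np.zeros(n, dtype=bool),
            "yellow": np.zeros(n, dtype=bool),
            "blue": np.zeros(n, dtype=bool),
            "combined": np.full(n, NOT_SINGLET, dtype=object),
        }
    )


def gate_bacteria(events: EventTable, cfg: GatingConfig | None = None) -> pd.DataFrame:
    """Set ``in_bacteria`` by density or polygon gating on log scatter.

    Density mode bins (log10 FSC, log10 SSC) on a ``density_bins`` square
    grid over the data range, ranks bins by event count (stable ties) and
    retains events in the top bins whose cumulative share first reaches
    ``density_fraction``.  Events with non-positive FSC or SSC cannot be
    placed in log space and are excluded with a warning.
    """
    cfg = cfg or GatingConfig()
    n = len(events)
    if n == 0:
        raise ValueError("cannot gate an empty event table")
    labels = _new_labels(n)

    fsc = events.data["fsc"].to_numpy(dtype=float)
    ssc = events.data["ssc"].to_numpy(dtype=float)
    valid = (fsc > 0) & (ssc > 0)
    n_invalid = int((~valid).sum())
    if n_invalid:
        warnings.warn(
            f"{n_invalid} event(s) with non-positive FSC/SSC excluded from the "
            "bacteria gate (log scatter undefined)",
            stacklevel=2,
        )
    if not valid.any():
        raise ValueError("no events with positive FSC and SSC")

    x = np.log10(fsc[valid])
    y = np.log10(ssc[valid])

    if cfg.bacteria_mode == "polygon":
        from matplotlib.path import Path

        inside = Path(np.asarray(cfg.polygon, dtype=float)).contains_points(
            np.column_stack([x, y])
        )
        labels.loc[np.flatnonzero(valid)[inside], "in_bacteria"] = True
        return labels

    nb = cfg.density_bins
    counts, xedges, yedges = np.histogram2d(x, y, bins=nb)
    ix = np.clip(np.searchsorted(xedges, x, side="right") - 1, 0, nb - 1)
    iy = np.clip(np.searchsorted(yedges, y, side="right") - 1, 0, nb - 1)
    flat = ix * nb + iy
    counts_flat = counts.ravel()

    order = np.argsort(-counts_flat, kind="stable")
    cum = np.cumsum(counts_flat[order])
    target = cfg.density_fraction * valid.sum()
    k = int(np.searchsorted(cum, target - 1e-9))
    keep_bins = np.zeros(nb * nb, dtype=bool)
    keep_bins[order[: k + 1]] = True

    labels.loc[np.flatnonzero(valid)[keep_bins[flat]], "in_bacteria"] = True
    return labels


def gate_singlets(
    events: EventTable, labels: pd.DataFrame, cfg: GatingConfig | None = None
) -> pd.DataFrame:
    """Set ``in_singlets``: bacteria with FSC and aspect-ratio above the cuts
    (both strict)."""
    cfg = cfg or GatingConfig()
    labels = labels.copy()
    fsc = events.data["fsc"].to_numpy(dtype=float)
    ar = events.data["ar_ssc"].to_numpy(dtype=float)
    labels["in_singlets"] = (
        labels["in_bacteria"].to_numpy()
        & (fsc > cfg.singlet_fsc_min)
        & (ar > cfg.singlet_ar_min)
    )
    return labels


def assign_colours(
    events: EventTable, labels: pd.DataFrame, cfg: GatingConfig | None = None
) -> pd.DataFrame:
    """Set the red/yellow/blue flags for singlets by strict FI thresholds."""
    cfg = cfg or GatingConfig()
    labels = labels.copy()
    singlets = labels["in_singlets"].to_numpy()
    for colour, (channel, threshold) in cfg.colour_thresholds.items():
        if channel not in events.data.columns:
            raise KeyError(
                f"channel {channel!r} required for the {colour} population is "
                "missing from the event table"
            )
        positive = events.data[channel].to_numpy(dtype=float) > threshold
        labels[colour.lower()] = singlets & positive
    return labels


def assign_combined(labels: pd.DataFrame) -> pd.DataFrame:
    """Map colour-flag combinations onto the six exclusive combined classes.

    All-negative and triple-positive singlets become Unassigned; non-singlet
    events keep the NotSinglet marker.
    """
    labels = labels.copy()
    singlets = labels["in_singlets"].to_numpy()
    r = labels["red"].to_numpy()
    y = labels["yellow"].to_numpy()
    b = labels["blue"].to_numpy()
    combined = np.full(len(labels), NOT_SINGLET, dtype=object)
    for flags, cls in _FLAGS_TO_COMBINED.items():
        mask = singlets & (r == flags[0]) & (y == flags[1]) & (b == flags[2])
        combined[mask] = cls
    labels["combined"] = combined
    return labels


def run_gating(events: EventTable, cfg: GatingConfig | None = None) -> pd.DataFrame:
    """Run the full chain: bacteria -> singlets -> colours -> combined."""
    cfg = cfg or GatingConfig()
    labels = gate_bacteria(events, cfg)
    labels = gate_singlets(events, labels, cfg)
    labels = assign_colours(events, labels, cfg)
    return assign_combined(labels)


@dataclass
class ConfusionSummary:
    """Truth x assigned counts and the derived accuracy figures.

    ``matrix`` rows are truth strain ids, columns the combined classes plus
    Unassigned; counts cover singlets only.  ``per_class_accuracy`` is the
    fraction of each strain's singlets assigned its own combined label;
    ``colour_detection`` the fraction of each strain's singlets positive in
    each colour population.
    """

    matrix: pd.DataFrame
    per_class_accuracy: dict
    colour_detection: pd.DataFrame
    overall_accuracy: float

    def to_dict(self) -> dict:
        return {
            "matrix": {str(k): v for k, v in self.matrix.to_dict(orient="index").items()},
            "per_class_accuracy": dict(self.per_class_accuracy),
            "colour_detection": {
                str(k): v for k, v in self.colour_detection.to_dict(orient="index").items()
            },
            "overall_accuracy": self.overall_accuracy,
        }


def score_assignments(
    labels: pd.DataFrame,
    truth,
    expected: dict | None = None,
) -> ConfusionSummary:
    """Score demultiplexing against ground-truth strain labels.

    Parameters
    ----------
    labels : DataFrame
        Output of the full gating chain.
    truth : sequence of str
        Per-event generating strain id, aligned with ``labels``.
    expected : dict, optional
        Truth id -> expected combined class.  Defaults to the identity
        mapping for ids that already are combined-class names.
    """
    truth = np.asarray(truth, dtype=object)
    if len(truth) != len(labels):
        raise ValueError(
            f"truth has {len(truth)} entries but labels has {len(labels)} rows"
        )
    if expected is None:
        expected = {c: c for c in COMBINED_CLASSES}

    singlets = labels["in_singlets"].to_numpy()
    assigned = labels["combined"].to_numpy()[singlets]
    truth_s = truth[singlets]

    classes = list(COMBINED_CLASSES) + [UNASSIGNED]
    truth_ids = list(dict.fromkeys(truth_s))
    matrix = pd.DataFrame(0, index=truth_ids, columns=classes, dtype=int)
    for tid in truth_ids:
        sub = assigned[truth_s == tid]
        vals, counts = np.unique(sub, return_counts=True)
        for v, c in zip(vals, counts):
            matrix.loc[tid, v] = int(c)

    per_class = {}
    correct = 0
    total = 0
    for tid in truth_ids:
        if tid not in expected:
            continue
        row = matrix.loc[tid]
        n_tid = int(row.sum())
        if n_tid == 0:
            continue
        n_correct = int(row[expected[tid]])
        per_class[tid] = n_correct / n_tid
        correct += n_correct
        total += n_tid

    flag_cols = {"Red": "red", "Yellow": "yellow", "Blue": "blue"}
    detection = pd.DataFrame(index=truth_ids, columns=list(COLOURS), dtype=float)
    for tid in truth_ids:
        mask = truth_s == tid
        for colour, col in flag_cols.items():
            detection.loc[tid, colour] = float(
                labels[col].to_numpy()[singlets][mask].mean()
            )

    overall = correct / total if total else float("nan")
    return ConfusionSummary(
        matrix=matrix,
        per_class_accuracy=per_class,
        colour_detection=detection,
        overall_accuracy=overall,
    )
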