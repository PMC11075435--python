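"""Event-table and sequence file I/O.

Canonical channel keys are the laser-filter strings ``405-456/51``,
``488-528/46`` and ``561-611/31`` (ASCII hyphens).  Vendor names vary, so
``read_events`` accepts a ``channel_map`` from file column / $PnN names to
canonical keys; en-dashes and an ``Intensity_`` prefix are normalised
automatically.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dfmflow.io_cli.fcs import read_fcs, write_fcs
from dfmflow.synthetic_data.events import SCATTER_COLUMNS, EventTable
from dfmflow.synthetic_data.fluorophores import CHANNEL_KEYS
from dfmflow.synthetic_data.junctions import JunctionRecord

__all__ = [
    "read_events",
    "read_event_csv",
    "read_junction_fasta",
    "write_event_csv",
    "write_events_fcs",
    "write_junction_fasta",
]

_SCATTER_ALIASES = {"FSC": "fsc", "SSC": "ssc", "AR_SSC": "ar_ssc"}


def _normalise(name: str) -> str:
    name = name.strip().replace("–", "-")  # en-dash -> hyphen
    if name.startswith("Intensity_"):
        name = name[len("Intensity_") :]
    return _SCATTER_ALIASES.get(name, name)


def write_event_csv(table: EventTable, path) -> None:
    """Per-event CSV with scatter, channel-key and truth columns."""
    table.data.to_csv(path, index=False)


def read_event_csv(path, channel_map: dict | None = None) -> EventTable:
    df = pd.read_csv(path)
    return _frame_to_table(df, channel_map, source=str(path))


def write_events_fcs(table: EventTable, path) -> None:
    """FCS 3.1 list mode; the truth column is dropped (not representable)."""
    write_fcs(table.data, path, channels=table.channels)


def _frame_to_table(
    df: pd.DataFrame, channel_map: dict | None, source: str
) -> EventTable:
    rename = {c: _normalise(c) for c in df.columns}
    if channel_map:
        for raw, canonical in channel_map.items():
            key = _normalise(raw)
            for col, current in list(rename.items()):
                if current == key or col == raw:
                    rename[col] = _normalise(canonical)
    df = df.rename(columns=rename)
    missing = [c for c in SCATTER_COLUMNS if c not in df.columns]
    missing += [c for c in CHANNEL_KEYS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{source}: required column(s) {missing} absent after channel "
            "mapping; provide a channel_map entry for each"
        )
    return EventTable(data=df, channels=CHANNEL_KEYS)


def read_events(path, channel_map: dict | None = None) -> EventTable:
    """Read an FCS 3.x file or the per-event CSV dialect.

    Dispatches on the FCS magic bytes, falling back to CSV.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"FCS3":
        df, _ = read_fcs(path)
        return _frame_to_table(df, channel_map, source=str(path))
    return read_event_csv(path, channel_map)


def write_junction_fasta(records, path) -> None:
    """Write junction reads as FASTA (one record per strain)."""
    seq_records = [
        SeqRecord(Seq(r.read_seq), id=r.strain_id or f"junction_{i}", description="")
        for i, r in enumerate(records)
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_junction_fasta(reads_path, glms_ref: str, tn7r_seq: str) -> list:
    """Load junction reads, attaching the shared glmS / transposon references."""
    records = []
    for rec in SeqIO.parse(str(reads_path), "fasta"):
        records.append(
            JunctionRecord(
                read_seq=str(rec.seq).upper(),
                glms_ref=glms_ref.upper(),
                tn7r_seq=tn7r_seq.upper(),
                strain_id=rec.id,
            )
        )
    return records
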