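"""Transposon attB junction calling.

Calls the insertion offset -- the number of bases strictly between the last
base of the glmS stop codon and the first transposon base -- plus the
target-site duplication immediately upstream of the insertion point.
Anchoring is exact-substring by default (Sanger-quality reads); a Hamming
scan tolerating a small number of mismatches per anchor can be enabled.
Reads in either orientation are handled: if the glmS anchor is absent on
the forward strand, the reverse complement is searched.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from dfmflow.synthetic_data.junctions import JunctionRecord

__all__ = ["AttCall", "OffsetSummary", "call_att", "summarise_offsets", "write_att_csv"]

GLMS_ANCHOR_LEN = 30
TN7R_ANCHOR_LEN = 20
CANONICAL_OFFSET = 25


@dataclass
class AttCall:
    """One called junction: offset from the glmS stop codon and duplication."""

    strain_id: str
    offset_bp: int
    dup_seq: str
    valid: bool
    notes: str = ""

    @property
    def dup_len(self) -> int:
        return len(self.dup_seq)


def _find_all(haystack: str, needle: str, max_mismatches: int = 0) -> list:
    """Start positions of all (possibly approximate) matches of needle."""
    if max_mismatches == 0:
        positions = []
        start = haystack.find(needle)
        while start != -1:
            positions.append(start)
            start = haystack.find(needle, start + 1)
        return positions
    hay = np.frombuffer(haystack.encode(), dtype=np.uint8)
    ndl = np.frombuffer(needle.encode(), dtype=np.uint8)
    span = len(hay) - len(ndl) + 1
    if span <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(hay, len(ndl))
    mismatches = (windows != ndl).sum(axis=1)
    return list(np.flatnonzero(mismatches <= max_mismatches))


def _invalid(rec: JunctionRecord, notes: str) -> AttCall:
    return AttCall(
        strain_id=rec.strain_id, offset_bp=-1, dup_seq="", valid=False, notes=notes
    )


def call_att(
    rec: JunctionRecord,
    dup_len: int = 5,
    glms_anchor_len: int = GLMS_ANCHOR_LEN,
    tn7r_anchor_len: int = TN7R_ANCHOR_LEN,
    max_mismatches: int = 0,
) -> AttCall:
    """Call the insertion offset and target-site duplication for one read.

    The last ``glms_anchor_len`` bases of the glmS reference and the first
    ``tn7r_anchor_len`` bases of the transposon right end must each occur
    exactly once in the read, with the transposon anchor strictly downstream;
    any anchor failure yields ``valid=False`` with an explanatory note.
    """
    if glms_anchor_len > len(rec.glms_ref):
        return _invalid(rec, "glmS reference shorter than the anchor length")
    if tn7r_anchor_len > len(rec.tn7r_seq):
        return _invalid(rec, "transposon reference shorter than the anchor length")
    glms_anchor = rec.glms_ref[-glms_anchor_len:]
    tn7_anchor = rec.tn7r_seq[:tn7r_anchor_len]

    read = rec.read_seq
    orientation = "forward"
    glms_hits = _find_all(read, glms_anchor, max_mismatches)
    if not glms_hits:
        read = str(Seq(rec.read_seq).reverse_complement())
        orientation = "reverse"
        glms_hits = _find_all(read, glms_anchor, max_mismatches)
    if not glms_hits:
        return _invalid(rec, "glmS anchor not found in either orientation")
    if len(glms_hits) > 1:
        return _invalid(rec, f"glmS anchor found {len(glms_hits)} times")

    stop_end = glms_hits[0] + glms_anchor_len  # base after the stop codon
    tn7_hits = [p for p in _find_all(read, tn7_anchor, max_mismatches) if p >= stop_end]
    if not tn7_hits:
        # distinguish "absent" from "overlapping the glmS anchor"
        if _find_all(read, tn7_anchor, max_mismatches):
            return _invalid(rec, "transposon anchor overlaps the glmS anchor")
        return _invalid(rec, "transposon anchor not found downstream of glmS")
    if len(tn7_hits) > 1:
        return _invalid(rec, f"transposon anchor found {len(tn7_hits)} times")

    insertion = tn7_hits[0]
    offset = insertion - stop_end
    dup_start = insertion - dup_len
    if dup_start < stop_end - glms_anchor_len:
        return _invalid(rec, "duplication window extends past the read start")
    dup_seq = read[dup_start:insertion]
    notes = "" if orientation == "forward" else "called on reverse complement"
    return AttCall(
        strain_id=rec.strain_id,
        offset_bp=offset,
        dup_seq=dup_seq,
        valid=True,
        notes=notes,
    )


@dataclass
class OffsetSummary:
    """Offset histogram and duplication-conservation report across calls."""

    histogram: dict
    within_one_of_canonical: bool
    canonical: int
    dup_consensus: str
    dup_conserved: bool
    n_valid: int


def summarise_offsets(calls, canonical: int = CANONICAL_OFFSET) -> OffsetSummary:
    """Histogram valid offsets and tally duplication conservation.

    ``dup_consensus`` holds the base at positions where every duplication
    agrees and ``N`` elsewhere; ``dup_conserved`` is True only when the full
    duplicated sequence is identical across calls.
    """
    valid = [c for c in calls if c.valid]
    if not valid:
        raise ValueError("no valid attB calls to summarise")
    histogram = dict(sorted(Counter(c.offset_bp for c in valid).items()))
    within = all(abs(off - canonical) <= 1 for off in histogram)

    dups = [c.dup_seq for c in valid if c.dup_seq]
    if dups and len({len(d) for d in dups}) == 1:
        consensus = "".join(
            col[0] if len(set(col)) == 1 else "N" for col in zip(*dups)
        )
    else:
        consensus = ""
    conserved = bool(consensus) and "N" not in consensus and len(dups) > 1
    return OffsetSummary(
        histogram=histogram,
        within_one_of_canonical=within,
        canonical=canonical,
        dup_consensus=consensus,
        dup_conserved=conserved,
        n_valid=len(valid),
    )


def write_att_csv(calls, path) -> None:
    """Write one row per call: strain, offset, duplication, validity."""
    pd.DataFrame(
        [
            {
                "strain": c.strain_id,
                "offset_bp": c.offset_bp,
                "dup_seq": c.dup_seq,
                "dup_len": c.dup_len,
                "valid": c.valid,
                "notes": c.notes,
            }
            for c in calls
        ]
    ).to_csv(path, index=False)
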