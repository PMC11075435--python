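"""Construction of synthetic transposon-insertion junction reads.

A junction read is the genomic region running from the 3' end of the glmS
gene, across ``offset`` bases of downstream chromosome, into the right end
of the integrated transposon.  Integration duplicates the ``dup_len`` bases
immediately upstream of the insertion point; the generator records both the
offset and the duplicated bases as ground truth for the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dfmflow.synthetic_data.strains import DEFAULT_SEED

__all__ = [
    "DEFAULT_TN7R_ANCHOR",
    "JunctionRecord",
    "make_junction",
    "random_dna",
    "random_glms_fragment",
]

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))

#: Fixed 30-bp transposon right-end anchor used by the default generator.
DEFAULT_TN7R_ANCHOR = "TGTGGGCGGACAAAATAGTTGGGAACTGGG"


@dataclass(frozen=True)
class JunctionRecord:
    """One junction read plus the references needed to call it.

    ``glms_ref`` ends at (and includes) the glmS stop codon; ``tn7r_seq`` is
    the transposon right-end anchor.  ``truth_offset``/``truth_dup`` record
    the generating parameters when the read is synthetic.
    """

    read_seq: str
    glms_ref: str
    tn7r_seq: str
    truth_offset: int | None = None
    truth_dup: str | None = None
    strain_id: str = ""

    def __post_init__(self) -> None:
        for name, seq in (
            ("read_seq", self.read_seq),
            ("glms_ref", self.glms_ref),
            ("tn7r_seq", self.tn7r_seq),
        ):
            if set(seq) - set("ACGT"):
                raise ValueError(f"{name} contains non-ACGT characters")
        if self.glms_ref[-3:] not in _STOP_CODONS:
            raise ValueError(
                f"glms_ref must end with a stop codon, ends with {self.glms_ref[-3:]!r}"
            )


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(rng.choice(_BASES, size=length))


def random_glms_fragment(length: int = 200, seed: int = DEFAULT_SEED) -> str:
    """Random glmS 3' fragment of ``length`` bp ending in a TAA stop codon."""
    if length < 3:
        raise ValueError("fragment must be at least 3 bp to hold a stop codon")
    rng = np.random.default_rng(seed)
    return random_dna(length - 3, rng) + "TAA"


def make_junction(
    glms_ref: str,
    downstream: str,
    offset: int,
    dup_len: int = 5,
    tn7r_seq: str = DEFAULT_TN7R_ANCHOR,
    strain_id: str = "",
) -> JunctionRecord:
    """Build a junction read with a known insertion offset.

    The read is ``glms_ref + downstream[:offset] + tn7r_seq``; the
    ``dup_len`` bases immediately preceding the insertion point
    (``downstream[offset - dup_len : offset]``) are recorded as the
    target-site duplication.
    """
    if offset < 0:
        raise ValueError(f"offset must be >= 0, got {offset}")
    if dup_len < 0:
        raise ValueError(f"dup_len must be >= 0, got {dup_len}")
    if offset < dup_len:
        raise ValueError(
            f"offset ({offset}) must be >= dup_len ({dup_len}): the duplicated "
            "bases lie between the stop codon and the insertion point"
        )
    if offset > len(downstream):
        raise ValueError(
            f"offset ({offset}) exceeds downstream length ({len(downstream)})"
        )
    read = glms_ref + downstream[:offset] + tn7r_seq
    dup = downstream[offset - dup_len : offset]
    return JunctionRecord(
        read_seq=read,
        glms_ref=glms_ref,
        tn7r_seq=tn7r_seq,
        truth_offset=offset,
        truth_dup=dup,
        strain_id=strain_id,
    )
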