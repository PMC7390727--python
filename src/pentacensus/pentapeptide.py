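"""Detection of the C-terminal CheR/CheB-binding pentapeptide.

The motif is xZxxZ at the extreme C-terminus, where x is any residue and Z is
an aromatic residue F, W or Y (archetype: the NWETF pentapeptide of the
*E. coli* Tar and Tsr receptors).  No constraint is placed on the linker that
tethers the motif to the rest of the protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

log = logging.getLogger(__name__)

#: Residues accepted at the two constrained (Z) positions of the motif.
AROMATIC = frozenset("FWY")


@dataclass(frozen=True)
class PentapeptideHit:
    """A detected C-terminal pentapeptide on one protein.

    ``linker_length`` is the number of residues between the end of the
    reference domain (chosen by the classification layer) and the first
    pentapeptide residue; ``None`` when no domain reference is available or
    the annotation overlaps the motif.
    """

    protein_id: str
    pentapeptide: str
    linker_length: int | None = None

    def __post_init__(self) -> None:
        if len(self.pentapeptide) != 5:
            raise ValueError(f"{self.protein_id}: pentapeptide must have length 5")
        if self.pentapeptide[1] not in AROMATIC or self.pentapeptide[4] not in AROMATIC:
            raise ValueError(
                f"{self.protein_id}: positions 2 and 5 must be aromatic (F/W/Y), "
                f"got {self.pentapeptide!r}"
            )
        if self.linker_length is not None and self.linker_length < 0:
            raise ValueError(f"{self.protein_id}: negative linker length")


def match_cterm_motif(sequence: str) -> bool:
    """True iff the sequence ends with the xZxxZ motif.

    The two constrained positions accept only the literal letters F, W, Y;
    ambiguity codes (X, B, Z, ...) never satisfy them, while the three x
    positions accept any letter.  Sequences shorter than 5 never match.
    """
    if len(sequence) < 5:
        return False
    return sequence[-4] in AROMATIC and sequence[-1] in AROMATIC


def extract_pentapeptide(sequence: str) -> str | None:
    """Return the last five residues when the motif matches, else None."""
    if match_cterm_motif(sequence):
        return sequence[-5:]
    return None


def linker_length(sequence_length: int, reference_domain_end: int) -> int | None:
    """Residues between the reference domain end and the pentapeptide start.

    Computed as ``sequence_length - 5 - reference_domain_end`` (coordinates
    1-based inclusive).  Returns None, with a warning, when the annotation
    overlaps the motif (negative distance).
    """
    n = sequence_length - 5 - reference_domain_end
    if n < 0:
        log.warning(
            "domain end %d overlaps the C-terminal pentapeptide of a length-%d "
            "sequence; linker undefined",
            reference_domain_end,
            sequence_length,
        )
        return None
    return n


def scan_records(records: Iterable) -> list[PentapeptideHit]:
    """Scan protein records for the C-terminal motif.

    Returns one :class:`PentapeptideHit` per matching protein, without linker
    information (linkers require a domain reference; see the classify layer).
    """
    hits = []
    for rec in records:
        penta = extract_pentapeptide(rec.sequence)
        if penta is not None:
            hits.append(PentapeptideHit(protein_id=rec.protein_id, pentapeptide=penta))
    return hits
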