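"""Chemoreceptor identification and classification.

A protein is a chemoreceptor iff it carries an MCPsignal domain (Pfam
PF00015), the conserved cytoplasmic signaling domain of methyl-accepting
chemotaxis proteins.  Receptors are classified by membrane topology
(transmembrane iff at least one annotated membrane-spanning region),
ligand-binding-domain (LBD) family membership against an 18-family catalogue,
and domain architecture: whether a C-terminal pentapeptide is fused to the
signaling domain itself or to a sensor domain (such as CZB) that lies
C-terminal to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_tables import DomainHit, ProteinRecord, TMRegion
from .pentapeptide import extract_pentapeptide, linker_length

log = logging.getLogger(__name__)

#: Pfam accession of the MCPsignal (chemoreceptor signaling) domain.
MCPSIGNAL_ACCESSION = "PF00015"

#: Default catalogue of chemoreceptor ligand-binding-domain families,
#: the 18 most abundant LBDs found on chemoreceptors.
LBD_CATALOG: dict[str, str] = {
    "TarH": "PF02203",
    "CHASE3": "PF05227",
    "4HB_MCP_1": "PF12729",
    "PAS_9": "PF13426",
    "PAS_4": "PF08448",
    "PAS_3": "PF08447",
    "sCACHE_2": "PF17200",
    "sCACHE_3_3": "PF17202",
    "protoglobin": "PF11563",
    "CZB": "PF13682",
    "GAF": "PF01590",
    "PilJ": "PF13675",
    "dCACHE_2": "PF08269",
    "dCACHE_3": "PF14827",
    "HBM": "PF16591",
    "NIT": "PF08376",
    "Cache_3-Cache_2": "PF17201",
    "dCache_1": "PF02743",
}

TRANSMEMBRANE = "transmembrane"
CYTOSOLIC = "cytosolic"

PENTA_ON_SIGNALING = "pentapeptide_on_signaling_domain"
PENTA_ON_CTERMINAL_LBD = "pentapeptide_on_cterminal_lbd"
NO_PENTAPEPTIDE = "no_pentapeptide"

_ARCHITECTURES = (PENTA_ON_SIGNALING, PENTA_ON_CTERMINAL_LBD, NO_PENTAPEPTIDE)


@dataclass(frozen=True)
class ReceptorAnnotation:
    """The per-chemoreceptor verdict emitted by the classification stage."""

    protein_id: str
    proteome_id: str
    has_pentapeptide: bool
    pentapeptide: str | None
    topology: str
    lbd_families: frozenset[str]
    architecture: str
    linker_length: int | None = None
    is_chemoreceptor: bool = True

    def __post_init__(self) -> None:
        if not self.is_chemoreceptor:
            raise ValueError("only chemoreceptors are annotated; others are dropped")
        if self.has_pentapeptide != (self.pentapeptide is not None):
            raise ValueError(f"{self.protein_id}: pentapeptide flag/value mismatch")
        if self.pentapeptide is not None and len(self.pentapeptide) != 5:
            raise ValueError(f"{self.protein_id}: pentapeptide must have length 5")
        if self.topology not in (TRANSMEMBRANE, CYTOSOLIC):
            raise ValueError(f"{self.protein_id}: bad topology {self.topology!r}")
        if self.architecture not in _ARCHITECTURES:
            raise ValueError(f"{self.protein_id}: bad architecture {self.architecture!r}")
        if (self.architecture == NO_PENTAPEPTIDE) == self.has_pentapeptide:
            raise ValueError(f"{self.protein_id}: architecture/pentapeptide mismatch")


def is_chemoreceptor(hits: Iterable[DomainHit]) -> bool:
    """True iff at least one hit is the MCPsignal domain (PF00015)."""
    return any(h.family_accession == MCPSIGNAL_ACCESSION for h in hits)


def classify_topology(tm: Iterable[TMRegion]) -> str:
    """Transmembrane iff the protein has at least one TM region, else cytosolic."""
    return TRANSMEMBRANE if any(True for _ in tm) else CYTOSOLIC


def assign_lbd_families(
    hits: Iterable[DomainHit],
    catalog: Mapping[str, str] | None = None,
) -> frozenset[str]:
    """Catalogue LBD families with at least one hit on the protein.

    A receptor may carry several families; downstream per-family statistics
    count it once in each.
    """
    catalog = LBD_CATALOG if catalog is None else catalog
    by_accession = {acc: label for label, acc in catalog.items()}
    return frozenset(
        by_accession[h.family_accession]
        for h in hits
        if h.family_accession in by_accession
    )


def classify_architecture(
    hits: Iterable[DomainHit],
    has_pentapeptide: bool,
    catalog: Mapping[str, str] | None = None,
) -> tuple[str, int]:
    """Decide which domain the C-terminal pentapeptide is fused to.

    Let M be the most C-terminal MCPsignal hit.  A pentapeptide is fused to a
    C-terminal LBD when a catalogue LBD hit lies after M (starts beyond M's
    end, or overlaps M's end with its midpoint beyond M's midpoint — the
    overlap case is logged as ambiguous); otherwise it is fused to the
    signaling domain.  Returns the architecture label and the 1-based end
    coordinate of the reference domain, which feeds the linker computation.
    """
    catalog = LBD_CATALOG if catalog is None else catalog
    hits = list(hits)
    mcp_hits = [h for h in hits if h.family_accession == MCPSIGNAL_ACCESSION]
    if not mcp_hits:
        raise ValueError("classify_architecture requires an MCPsignal (PF00015) hit")
    m = max(mcp_hits, key=lambda h: (h.end, h.start))
    if not has_pentapeptide:
        return NO_PENTAPEPTIDE, m.end

    accessions = set(catalog.values())
    cterm_lbds = []
    for h in hits:
        if h.family_accession not in accessions:
            continue
        if h.start > m.end:
            cterm_lbds.append(h)
        elif h.start <= m.end < h.end and h.midpoint > m.midpoint:
            log.warning(
                "%s: LBD %s (%d..%d) overlaps the signaling domain end; treated "
                "as C-terminal by midpoint",
                h.protein_id, h.family_label, h.start, h.end,
            )
            cterm_lbds.append(h)
    if cterm_lbds:
        ref = max(cterm_lbds, key=lambda h: (h.end, h.start))
        return PENTA_ON_CTERMINAL_LBD, ref.end
    return PENTA_ON_SIGNALING, m.end


def annotate_receptors(
    records: Iterable[ProteinRecord],
    domain_hits: Iterable[DomainHit],
    tm_regions: Iterable[TMRegion] = (),
    catalog: Mapping[str, str] | None = None,
) -> list[ReceptorAnnotation]:
    """Run the full per-protein classification.

    Non-chemoreceptors (no PF00015 hit) are dropped.  For each receptor the
    pentapeptide is extracted from the sequence, topology from the TM table,
    LBD families and architecture from the domain coordinates, and the linker
    length from the reference-domain end chosen by the architecture rule.
    """
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    tm_by_protein: dict[str, list[TMRegion]] = {}
    for t in tm_regions:
        tm_by_protein.setdefault(t.protein_id, []).append(t)

    annotations: list[ReceptorAnnotation] = []
    for rec in records:
        hits = hits_by_protein.get(rec.protein_id, [])
        if not is_chemoreceptor(hits):
            continue
        penta = extract_pentapeptide(rec.sequence)
        architecture, ref_end = classify_architecture(hits, penta is not None, catalog)
        linker = (
            linker_length(len(rec.sequence), ref_end) if penta is not None else None
        )
        annotations.append(
            ReceptorAnnotation(
                protein_id=rec.protein_id,
                proteome_id=rec.proteome_id,
                has_pentapeptide=penta is not None,
                pentapeptide=penta,
                topology=classify_topology(tm_by_protein.get(rec.protein_id, [])),
                lbd_families=assign_lbd_families(hits, catalog),
                architecture=architecture,
                linker_length=linker,
            )
        )
    return annotations
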