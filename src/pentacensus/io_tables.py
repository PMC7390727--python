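"""Readers and writers for every external format the census touches.

Inputs are plain-text: protein FASTA, per-domain annotation tables (a native
TSV plus the hmmscan ``--domtblout`` dialect), transmembrane-region tables,
proteome metadata with a ranked taxonomic lineage, and strain-to-habitat
mappings.  Outputs are TSV census tables.

All coordinates are 1-based and inclusive (the Pfam/HMMER convention); the
conversion happens here, once, and nowhere else in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: Ranks carried by proteome metadata, most to least inclusive.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

#: Sentinel for a rank that is absent or blank in the metadata.
UNCLASSIFIED = "unclassified"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence, linked to its proteome of origin."""

    protein_id: str
    proteome_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: sequence must be non-empty")


@dataclass(frozen=True)
class DomainHit:
    """One occurrence of a domain family on a protein (1-based, inclusive)."""

    protein_id: str
    family_accession: str
    family_label: str
    start: int
    end: int
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.family_accession}: "
                f"bad coordinates {self.start}..{self.end}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class TMRegion:
    """One annotated membrane-spanning segment (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.protein_id}: bad TM coordinates")


@dataclass
class ProteomeMeta:
    """Ranked taxonomic lineage of one proteome."""

    proteome_id: str
    lineage: dict[str, str]
    strain_name: str | None = None

    def rank(self, rank: str) -> str:
        return self.lineage.get(rank, UNCLASSIFIED)


@dataclass
class HabitatAssignment:
    """Habitat categories of one proteome; a strain may carry several."""

    proteome_id: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"{self.proteome_id}: empty habitat category set")


class DomainTable(list):
    """List of :class:`DomainHit` plus a count of rejected rows."""

    def __init__(self, hits: Iterable[DomainHit] = (), n_rejected: int = 0):
        super().__init__(hits)
        self.n_rejected = n_rejected


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(
    path: str | Path,
    proteome_field: int = 1,
    field_delimiter: str = "|",
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The protein identifier is the first ``field_delimiter``-separated token of
    the header's first word; the proteome identifier is taken from token
    ``proteome_field`` (0-based; default the second ``|`` token) and is empty
    when the header has no such token.  Sequences are uppercased and a single
    trailing stop symbol ``*`` is stripped.

    Raises
    ------
    FormatError
        If sequence data precedes the first header (with the line number), or
        if a protein identifier occurs more than once.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.id.split(field_delimiter)
        protein_id = tokens[0]
        proteome_id = tokens[proteome_field] if len(tokens) > proteome_field else ""
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if protein_id in seen:
            raise FormatError(f"{path}: duplicate protein_id {protein_id!r}")
        seen.add(protein_id)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                proteome_id=proteome_id,
                sequence=seq,
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving the protein/proteome header layout."""
    out = []
    for r in records:
        ident = f"{r.protein_id}|{r.proteome_id}" if r.proteome_id else r.protein_id
        out.append(SeqRecord(Seq(r.sequence), id=ident, description=""))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# domain tables
# ---------------------------------------------------------------------------

_NATIVE_COLUMNS = ("protein_id", "family_accession", "family_label", "start", "end")


def read_domain_table(
    path: str | Path,
    dialect: str = "native",
    max_evalue: float | None = None,
) -> DomainTable:
    """Read per-domain hits from ``path``.

    ``dialect`` is ``"native"`` (TSV with a header row ``protein_id,
    family_accession, family_label, start, end[, evalue]``) or
    ``"hmmscan_domtblout"`` (the hmmscan ``--domtblout`` text table; envelope
    coordinates become start/end and accession version suffixes are removed).

    Rows with invalid coordinates (``start < 1`` or ``start > end``) are
    rejected with a logged warning; the number rejected is available as
    ``.n_rejected`` on the returned table.  Hits are not e-value filtered
    unless ``max_evalue`` is given.
    """
    if dialect == "native":
        table = _read_native_domains(Path(path))
    elif dialect == "hmmscan_domtblout":
        table = _read_domtblout(Path(path))
    else:
        raise ValueError(f"unknown domain-table dialect {dialect!r}")
    if max_evalue is not None:
        kept = [h for h in table if h.evalue is None or h.evalue <= max_evalue]
        table = DomainTable(kept, n_rejected=table.n_rejected)
    return table


def _read_native_domains(path: Path) -> DomainTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _NATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    hits: list[DomainHit] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            n_rejected += 1
            log.warning("%s: non-integer coordinates for %s; row rejected", path, row.protein_id)
            continue
        if not (1 <= start <= end):
            n_rejected += 1
            log.warning(
                "%s: invalid coordinates %d..%d for %s; row rejected",
                path, start, end, row.protein_id,
            )
            continue
        evalue = None
        if "evalue" in df.columns and getattr(row, "evalue", "") != "":
            evalue = float(row.evalue)
        hits.append(
            DomainHit(
                protein_id=row.protein_id,
                family_accession=row.family_accession,
                family_label=row.family_label,
                start=start,
                end=end,
                evalue=evalue,
            )
        )
    return DomainTable(hits, n_rejected=n_rejected)


def _read_domtblout(path: Path) -> DomainTable:
    # hmmscan --domtblout: whitespace-separated, 22 fixed columns + free-text
    # description; target (domain model) in cols 1-2, query (protein) in col 4,
    # independent E-value in col 13, envelope coordinates in cols 20-21.
    hits: list[DomainHit] = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, 22)
            if len(parts) < 22:
                n_rejected += 1
                log.warning("%s: truncated domtblout row rejected", path)
                continue
            accession = parts[1].split(".")[0]
            try:
                start, end = int(parts[19]), int(parts[20])
                evalue = float(parts[12])
            except ValueError:
                n_rejected += 1
                log.warning("%s: unparsable domtblout row rejected", path)
                continue
            if not (1 <= start <= end):
                n_rejected += 1
                log.warning("%s: invalid envelope %d..%d rejected", path, start, end)
                continue
            hits.append(
                DomainHit(
                    protein_id=parts[3],
                    family_accession=accession,
                    family_label=parts[0],
                    start=start,
                    end=end,
                    evalue=evalue,
                )
            )
    return DomainTable(hits, n_rejected=n_rejected)


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the native TSV dialect."""
    with open(path, "w") as fh:
        fh.write("protein_id\tfamily_accession\tfamily_label\tstart\tend\tevalue\n")
        for h in hits:
            ev = "" if h.evalue is None else repr(h.evalue)
            fh.write(
                f"{h.protein_id}\t{h.family_accession}\t{h.family_label}\t"
                f"{h.start}\t{h.end}\t{ev}\n"
            )


# ---------------------------------------------------------------------------
# TM regions
# ---------------------------------------------------------------------------


def read_tm_table(path: str | Path) -> list[TMRegion]:
    """Read transmembrane regions from a TSV (protein_id, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    regions: list[TMRegion] = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if not (1 <= start <= end):
            log.warning("%s: invalid TM coordinates for %s; row skipped", path, row.protein_id)
            continue
        regions.append(TMRegion(protein_id=row.protein_id, start=start, end=end))
    return regions


def write_tm_table(regions: Iterable[TMRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\n")
        for r in regions:
            fh.write(f"{r.protein_id}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# proteome metadata and habitat
# ---------------------------------------------------------------------------


def read_proteome_metadata(path: str | Path) -> dict[str, ProteomeMeta]:
    """Read proteome lineages; blank ranks become the ``unclassified`` sentinel.

    Duplicated rows with identical lineages merge silently; conflicting
    lineages for one proteome raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "proteome_id" not in df.columns:
        raise FormatError(f"{path}: missing proteome_id column")
    meta: dict[str, ProteomeMeta] = {}
    for row in df.itertuples(index=False):
        lineage = {
            rank: (getattr(row, rank, "") or UNCLASSIFIED).strip() or UNCLASSIFIED
            for rank in RANKS
        }
        strain = getattr(row, "strain_name", None) or None
        pid = row.proteome_id
        if pid in meta:
            if meta[pid].lineage != lineage:
                raise FormatError(f"{path}: conflicting lineages for proteome {pid!r}")
            continue
        meta[pid] = ProteomeMeta(proteome_id=pid, lineage=lineage, strain_name=strain)
    return meta


def write_proteome_metadata(meta: Mapping[str, ProteomeMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("proteome_id\t" + "\t".join(RANKS) + "\n")
        for pid, m in meta.items():
            cells = [m.lineage.get(r, UNCLASSIFIED) for r in RANKS]
            # blank out the sentinel on write; readers restore it
            cells = ["" if c == UNCLASSIFIED else c for c in cells]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def read_habitat_table(path: str | Path) -> dict[str, HabitatAssignment]:
    """Read (proteome_id, category) pairs, one row per pair."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    buckets: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        category = row.category.strip()
        if not category:
            log.warning("%s: blank habitat category for %s skipped", path, row.proteome_id)
            continue
        buckets.setdefault(row.proteome_id, set()).add(category)
    return {
        pid: HabitatAssignment(proteome_id=pid, categories=frozenset(cats))
        for pid, cats in buckets.items()
    }


def write_habitat_table(assignments: Mapping[str, HabitatAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("proteome_id\tcategory\n")
        for pid, a in assignments.items():
            for cat in sorted(a.categories):
                fh.write(f"{pid}\t{cat}\n")


# ---------------------------------------------------------------------------
# census output
# ---------------------------------------------------------------------------


def write_census(rows: Sequence, path: str | Path) -> None:
    """Write census rows as TSV; abundance printed with two decimals."""
    with open(path, "w") as fh:
        fh.write("group\ttotal_receptors\tpentapeptide_receptors\tabundance_percent\n")
        for r in rows:
            fh.write(
                f"{r.group}\t{r.total_receptors}\t{r.pentapeptide_receptors}\t"
                f"{r.abundance_percent:.2f}\n"
            )


# ---------------------------------------------------------------------------
# per-protein annotations (classify output / census input)
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = (
    "protein_id", "proteome_id", "has_pentapeptide", "pentapeptide",
    "topology", "lbd_families", "architecture", "linker_length",
)


def write_annotations(annotations: Iterable, path: str | Path) -> None:
    """Write per-receptor annotations as TSV (absent values printed as '-')."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    [
                        a.protein_id,
                        a.proteome_id,
                        "1" if a.has_pentapeptide else "0",
                        a.pentapeptide or "-",
                        a.topology,
                        ",".join(sorted(a.lbd_families)) or "-",
                        a.architecture,
                        "-" if a.linker_length is None else str(a.linker_length),
                    ]
                )
                + "\n"
            )


def read_annotations(path: str | Path) -> list:
    """Read per-receptor annotations written by :func:`write_annotations`."""
    from .classify import ReceptorAnnotation  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ReceptorAnnotation(
                protein_id=row.protein_id,
                proteome_id=row.proteome_id,
                has_pentapeptide=row.has_pentapeptide == "1",
                pentapeptide=None if row.pentapeptide == "-" else row.pentapeptide,
                topology=row.topology,
                lbd_families=frozenset()
                if row.lbd_families == "-"
                else frozenset(row.lbd_families.split(",")),
                architecture=row.architecture,
                linker_length=None if row.linker_length == "-" else int(row.linker_length),
            )
        )
    return out
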