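"""Synthetic proteome bundles with known ground truth.

Emulates the statistical structure the census assumes: clades with distinct
pentapeptide prevalence, overdispersed (negative-binomial) chemoreceptor
counts per genome, clade-specific LBD family composition, membrane topology
flags, an ~35-residue linker before the pentapeptide, and a configurable
pentapeptide letter distribution.  Domain and TM annotations are noise-free
by construction, so a round trip through scan + classify + census must
recover the generated labels exactly; a hook exists to drop a fraction of
domain rows for robustness testing.

Background residue composition is uniform over the 20 standard amino acids,
under which the analytic probability that a random C-terminus matches the
xZxxZ motif is exactly (3/20)^2 = 0.0225.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import (
    LBD_CATALOG,
    MCPSIGNAL_ACCESSION,
    NO_PENTAPEPTIDE,
    PENTA_ON_CTERMINAL_LBD,
    PENTA_ON_SIGNALING,
    CYTOSOLIC,
    TRANSMEMBRANE,
)
from .io_tables import (
    DomainHit,
    HabitatAssignment,
    ProteinRecord,
    ProteomeMeta,
    TMRegion,
    UNCLASSIFIED,
    RANKS,
    write_domain_table,
    write_fasta,
    write_habitat_table,
    write_proteome_metadata,
    write_tm_table,
)
from .motif import ALPHABET, MOTIF_LENGTH
from .pentapeptide import AROMATIC, match_cterm_motif

log = logging.getLogger(__name__)

_AA_BYTES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
_AROMATIC_IDX = np.array([ALPHABET.index(a) for a in "FWY"])


@dataclass
class CladeSpec:
    """Generating parameters for one clade of genomes.

    ``receptor_count_mean`` and ``receptor_count_dispersion`` parametrise the
    (zero-truncated) negative binomial receptor count per genome
    (variance = mean + mean^2 / dispersion).  ``pentapeptide_probability`` is
    the per-receptor chance of carrying the motif; ``pentapeptide_slope`` >= 0
    makes that chance decline with the genome's receptor count, centred on the
    clade mean so the clade-wide expectation stays at the configured value.
    ``lbd_family_weights`` may include the key ``"none"`` for LBD-less
    receptors.  ``czb_cterminal_fraction`` is the share of CZB-carrying
    receptors whose CZB lies C-terminal to the signaling domain.
    """

    name: str
    rank_path: dict[str, str]
    n_genomes: int
    receptor_count_mean: float
    receptor_count_dispersion: float
    pentapeptide_probability: float
    lbd_family_weights: dict[str, float]
    tm_fraction: float
    czb_cterminal_fraction: float = 0.39
    habitat_categories: tuple[str, ...] = ()
    pentapeptide_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError(f"{self.name}: n_genomes must be >= 1")
        if self.receptor_count_mean < 0 or self.receptor_count_dispersion <= 0:
            raise ValueError(f"{self.name}: bad receptor-count parameters")
        for p in (self.pentapeptide_probability, self.tm_fraction,
                  self.czb_cterminal_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: probability out of [0, 1]")
        if any(w < 0 for w in self.lbd_family_weights.values()):
            raise ValueError(f"{self.name}: negative LBD weight")
        unknown = set(self.lbd_family_weights) - set(LBD_CATALOG) - {"none"}
        if unknown:
            raise ValueError(f"{self.name}: unknown LBD families {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Generating labels for one emitted protein."""

    protein_id: str
    proteome_id: str
    clade: str
    is_chemoreceptor: bool
    has_pentapeptide: bool
    pentapeptide: str | None
    topology: str
    lbd_families: frozenset[str]
    architecture: str | None


@dataclass
class SyntheticBundle:
    """Paths of one generated input bundle."""

    out_dir: Path
    fasta: Path
    domains: Path
    tm: Path
    metadata: Path
    habitat: Path
    ground_truth: Path
    n_genomes: int
    n_receptors: int


def zero_truncated_nb_stats(mean: float, dispersion: float) -> tuple[float, float]:
    """Analytic mean and standard deviation of the zero-truncated negative
    binomial with the given untruncated mean and dispersion (size)."""
    r, m = dispersion, mean
    p0 = (r / (r + m)) ** r
    var = m + m * m / r
    tmean = m / (1 - p0)
    second_moment = (var + m * m) / (1 - p0)
    tvar = second_moment - tmean * tmean
    return tmean, float(np.sqrt(tvar))


def default_pentapeptide_pwm() -> np.ndarray:
    """Default generating letter distribution for the 5-mer.

    Tryptophan dominates position 2 and phenylalanine position 5 (all mass on
    F/W/Y at both, as the motif requires); acidic residues are enriched at the
    unconstrained positions, giving the peptides a predominantly negative net
    charge.
    """
    spec = [
        {"D": 0.22, "E": 0.18, "N": 0.14, "S": 0.10, "G": 0.08, "A": 0.08},
        {"W": 0.75, "F": 0.15, "Y": 0.10},
        {"E": 0.30, "D": 0.22, "T": 0.10, "N": 0.08, "S": 0.06},
        {"T": 0.20, "E": 0.20, "D": 0.14, "S": 0.10, "N": 0.08},
        {"F": 0.80, "W": 0.10, "Y": 0.10},
    ]
    pwm = np.zeros((MOTIF_LENGTH, len(ALPHABET)))
    for i, row in enumerate(spec):
        for aa, p in row.items():
            pwm[i, ALPHABET.index(aa)] = p
        leftover = 1.0 - sum(row.values())
        if leftover > 1e-12:
            rest = [j for j, aa in enumerate(ALPHABET) if aa not in row]
            pwm[i, rest] = leftover / len(rest)
    return pwm


def _validate_pwm(pwm: np.ndarray) -> None:
    if pwm.shape != (MOTIF_LENGTH, len(ALPHABET)):
        raise ValueError("pentapeptide PWM must be 5 x 20")
    if np.any(pwm < 0) or not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("pentapeptide PWM rows must be distributions")
    for pos in (1, 4):
        mask = np.ones(len(ALPHABET), dtype=bool)
        mask[_AROMATIC_IDX] = False
        if pwm[pos, mask].sum() > 1e-12:
            raise ValueError(
                "pentapeptide PWM must place all mass on F/W/Y at positions 2 and 5"
            )


def make_study_config(n_genomes: int = 2000) -> list[CladeSpec]:
    """The shipped default study regime: twelve clades spanning high
    (~35-40%), mid (~10-20%) and low (~0.2-3%) pentapeptide prevalence, with
    overdispersed receptor counts averaging ~14 per genome.  Low-prevalence
    clades carry the highest receptor counts, so pooled abundance declines
    with receptors per genome.
    """
    # (name, order, class, phylum, p, mean count, genome share, lbd weights,
    #  tm fraction, habitats)
    base = [
        ("Caulo_like", "Caulobacterales", "Alphaproteobacteria", "Proteobacteria",
         0.38, 9.0, 0.06,
         {"TarH": 0.15, "4HB_MCP_1": 0.10, "CZB": 0.04, "none": 0.71},
         0.80, ("freshwater",)),
        ("Xantho_like", "Xanthomonadales", "Gammaproteobacteria", "Proteobacteria",
         0.374, 10.0, 0.07,
         {"TarH": 0.10, "CHASE3": 0.10, "dCache_1": 0.10, "none": 0.70},
         0.80, ("plant-associated",)),
        ("Entero_like", "Enterobacterales", "Gammaproteobacteria", "Proteobacteria",
         0.364, 9.0, 0.16,
         {"TarH": 0.47, "4HB_MCP_1": 0.08, "CZB": 0.05, "none": 0.40},
         0.82, ("host-associated", "human intestinal microflora")),
        ("Rhizo_like", "Rhizobiales", "Alphaproteobacteria", "Proteobacteria",
         0.214, 12.0, 0.09,
         {"dCache_1": 0.15, "sCACHE_2": 0.08, "PAS_3": 0.06, "none": 0.71},
         0.78, ("soil", "plant-associated")),
        ("Burkho_like", "Burkholderiales", "Betaproteobacteria", "Proteobacteria",
         0.213, 13.0, 0.11,
         {"dCache_1": 0.15, "4HB_MCP_1": 0.06, "GAF": 0.05, "none": 0.74},
         0.78, ("soil", "freshwater")),
        ("Desulfo_like", "Desulfovibrionales", "Deltaproteobacteria", "Proteobacteria",
         0.14, 15.0, 0.07,
         {"PAS_3": 0.10, "PAS_9": 0.06, "protoglobin": 0.04, "none": 0.80},
         0.55, ("sediment",)),
        ("Spiro_like", "Spirochaetales", "Spirochaetes", "Spirochaetes",
         0.073, 16.0, 0.06,
         {"sCACHE_2": 0.10, "dCache_1": 0.08, "none": 0.82},
         0.70, ("host-associated",)),
        ("Altero_like", "Alteromonadales", "Gammaproteobacteria", "Proteobacteria",
         0.032, 18.0, 0.09,
         {"dCache_1": 0.18, "sCACHE_3_3": 0.05, "CZB": 0.03, "none": 0.74},
         0.78, ("marine",)),
        ("Vibrio_like", "Vibrionales", "Gammaproteobacteria", "Proteobacteria",
         0.016, 20.0, 0.09,
         {"dCache_1": 0.20, "CZB": 0.04, "NIT": 0.03, "none": 0.73},
         0.80, ("marine", "host-associated")),
        ("Pseudo_like", "Pseudomonadales", "Gammaproteobacteria", "Proteobacteria",
         0.012, 23.0, 0.11,
         {"dCache_1": 0.30, "PilJ": 0.08, "4HB_MCP_1": 0.06, "HBM": 0.03,
          "none": 0.53},
         0.80, ("soil", "freshwater")),
        ("Clostri_like", "Clostridiales", "Clostridia", "Firmicutes",
         0.029, 12.0, 0.05,
         {"sCACHE_2": 0.10, "dCACHE_2": 0.05, "none": 0.85},
         0.72, ("host-associated",)),
        ("Bacillus_like", "Bacillales", "Bacilli", "Firmicutes",
         0.002, 14.0, 0.04,
         {"sCACHE_2": 0.08, "Cache_3-Cache_2": 0.04, "none": 0.88},
         0.75, ()),
    ]
    clades = []
    for name, order, class_, phylum, p, mean, share, weights, tm, habitats in base:
        clades.append(
            CladeSpec(
                name=name,
                rank_path={
                    "superkingdom": "Bacteria",
                    "phylum": phylum,
                    "class": class_,
                    "order": order,
                    "family": f"{order[:-2]}ceae",
                },
                n_genomes=max(1, round(share * n_genomes)),
                receptor_count_mean=mean,
                receptor_count_dispersion=1.2,
                pentapeptide_probability=p,
                lbd_family_weights=weights,
                tm_fraction=tm,
                habitat_categories=habitats,
            )
        )
    return clades


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_AA_BYTES[rng.integers(0, len(ALPHABET), n)]).decode()


def _sample_pentapeptide(rng: np.random.Generator, pwm: np.ndarray) -> str:
    return "".join(
        ALPHABET[rng.choice(len(ALPHABET), p=pwm[i])] for i in range(MOTIF_LENGTH)
    )


def _truncated_nb(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    while True:
        k = int(rng.negative_binomial(dispersion, p))
        if k >= 1:
            return k


def _lbd_domain_length(rng: np.random.Generator) -> int:
    return int(rng.integers(100, 160))


def generate(
    clades: Sequence[CladeSpec],
    out_dir: str | Path,
    seed: int,
    pentapeptide_pwm: np.ndarray | None = None,
    linker_mean: float = 35.0,
    linker_sd: float = 4.0,
    n_background_per_genome: int = 2,
    drop_domain_fraction: float = 0.0,
) -> tuple[SyntheticBundle, list[GroundTruthRecord]]:
    """Emit a self-consistent input bundle plus its ground truth.

    Writes FASTA, domain TSV, TM TSV, metadata TSV, habitat TSV and a
    ground-truth TSV under ``out_dir``.  The same seed yields a byte-identical
    bundle.  Non-pentapeptide receptors have their C-terminus rejection-
    sampled to NOT match the motif; pentapeptide receptors end in a linker
    (normal around ``linker_mean`` residues) followed by a 5-mer drawn from
    ``pentapeptide_pwm`` (default: :func:`default_pentapeptide_pwm`).
    """
    pwm = default_pentapeptide_pwm() if pentapeptide_pwm is None else pentapeptide_pwm
    _validate_pwm(pwm)
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    tm_rows: list[TMRegion] = []
    metadata: dict[str, ProteomeMeta] = {}
    habitat: dict[str, HabitatAssignment] = {}
    truth: list[GroundTruthRecord] = []

    genome_index = 0
    n_receptors = 0
    for clade in clades:
        weights = dict(clade.lbd_family_weights)
        family_names = sorted(weights)
        w = np.array([weights[f] for f in family_names], dtype=float)
        if w.sum() <= 0:
            family_names, w = ["none"], np.array([1.0])
        w = w / w.sum()

        for _ in range(clade.n_genomes):
            genome_index += 1
            proteome_id = f"UP{genome_index:06d}"
            lineage = {rank: UNCLASSIFIED for rank in RANKS}
            lineage.update(clade.rank_path)
            metadata[proteome_id] = ProteomeMeta(proteome_id, lineage)
            if clade.habitat_categories:
                habitat[proteome_id] = HabitatAssignment(
                    proteome_id, frozenset(clade.habitat_categories)
                )

            count = _truncated_nb(
                rng, clade.receptor_count_mean, clade.receptor_count_dispersion
            )
            p_eff = float(
                np.clip(
                    clade.pentapeptide_probability
                    - clade.pentapeptide_slope
                    * (count - clade.receptor_count_mean),
                    0.0,
                    1.0,
                )
            )
            for j in range(count):
                n_receptors += 1
                protein_id = f"{proteome_id}_r{j + 1}"
                has_penta = bool(rng.random() < p_eff)
                family = family_names[rng.choice(len(family_names), p=w)]
                czb_cterm = family == "CZB" and rng.random() < clade.czb_cterminal_fraction
                is_tm = bool(rng.random() < clade.tm_fraction)
                seq, protein_hits, architecture, penta = _build_receptor(
                    rng, protein_id, has_penta, family, czb_cterm,
                    pwm, linker_mean, linker_sd,
                )
                records.append(
                    ProteinRecord(protein_id, proteome_id, seq, "synthetic receptor")
                )
                hits.extend(protein_hits)
                if is_tm:
                    tm_rows.append(TMRegion(protein_id, 4, 24))
                    tm_rows.append(TMRegion(protein_id, 30, 50))
                truth.append(
                    GroundTruthRecord(
                        protein_id=protein_id,
                        proteome_id=proteome_id,
                        clade=clade.name,
                        is_chemoreceptor=True,
                        has_pentapeptide=has_penta,
                        pentapeptide=penta,
                        topology=TRANSMEMBRANE if is_tm else CYTOSOLIC,
                        lbd_families=frozenset() if family == "none" else frozenset({family}),
                        architecture=architecture,
                    )
                )
            for j in range(n_background_per_genome):
                protein_id = f"{proteome_id}_b{j + 1}"
                seq = _random_seq(rng, int(rng.integers(60, 200)))
                records.append(
                    ProteinRecord(protein_id, proteome_id, seq, "synthetic background")
                )
                truth.append(
                    GroundTruthRecord(
                        protein_id=protein_id,
                        proteome_id=proteome_id,
                        clade=clade.name,
                        is_chemoreceptor=False,
                        has_pentapeptide=match_cterm_motif(seq),
                        pentapeptide=None,
                        topology=CYTOSOLIC,
                        lbd_families=frozenset(),
                        architecture=None,
                    )
                )

    if drop_domain_fraction > 0:
        keep = rng.random(len(hits)) >= drop_domain_fraction
        hits = [h for h, k in zip(hits, keep) if k]

    bundle = SyntheticBundle(
        out_dir=out_dir,
        fasta=out_dir / "proteins.fasta",
        domains=out_dir / "domains.tsv",
        tm=out_dir / "tm.tsv",
        metadata=out_dir / "metadata.tsv",
        habitat=out_dir / "habitat.tsv",
        ground_truth=out_dir / "ground_truth.tsv",
        n_genomes=genome_index,
        n_receptors=n_receptors,
    )
    write_fasta(records, bundle.fasta)
    write_domain_table(hits, bundle.domains)
    write_tm_table(tm_rows, bundle.tm)
    write_proteome_metadata(metadata, bundle.metadata)
    write_habitat_table(habitat, bundle.habitat)
    write_ground_truth(truth, bundle.ground_truth)
    log.info(
        "generated %d genomes, %d receptors, %d proteins under %s",
        bundle.n_genomes, bundle.n_receptors, len(records), out_dir,
    )
    return bundle, truth


def _build_receptor(
    rng: np.random.Generator,
    protein_id: str,
    has_penta: bool,
    family: str,
    czb_cterminal: bool,
    pwm: np.ndarray,
    linker_mean: float,
    linker_sd: float,
) -> tuple[str, list[DomainHit], str, str | None]:
    """Assemble one receptor sequence with exact domain coordinates."""
    segments: list[str] = []
    protein_hits: list[DomainHit] = []
    pos = 0

    def add(seg: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        segments.append(seg)
        pos += len(seg)
        return start, pos

    add(_random_seq(rng, int(rng.integers(15, 40))))
    if family != "none" and not czb_cterminal:
        start, end = add(_random_seq(rng, _lbd_domain_length(rng)))
        protein_hits.append(
            DomainHit(protein_id, LBD_CATALOG[family], family, start, end, 1e-20)
        )
        add(_random_seq(rng, int(rng.integers(5, 25))))
    start, end = add(_random_seq(rng, int(rng.integers(160, 220))))
    protein_hits.append(
        DomainHit(protein_id, MCPSIGNAL_ACCESSION, "MCPsignal", start, end, 1e-40)
    )
    if czb_cterminal:
        add(_random_seq(rng, int(rng.integers(5, 20))))
        start, end = add(_random_seq(rng, int(rng.integers(60, 120))))
        protein_hits.append(
            DomainHit(protein_id, LBD_CATALOG["CZB"], "CZB", start, end, 1e-20)
        )

    penta: str | None = None
    if has_penta:
        linker = max(0, int(round(rng.normal(linker_mean, linker_sd))))
        add(_random_seq(rng, linker))
        penta = _sample_pentapeptide(rng, pwm)
        add(penta)
        architecture = PENTA_ON_CTERMINAL_LBD if czb_cterminal else PENTA_ON_SIGNALING
    else:
        while True:
            tail = _random_seq(rng, int(rng.integers(5, 25)))
            if not match_cterm_motif(tail):
                break
        add(tail)
        architecture = NO_PENTAPEPTIDE
    return "".join(segments), protein_hits, architecture, penta


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------


def write_ground_truth(truth: Sequence[GroundTruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tproteome_id\tclade\tis_chemoreceptor\thas_pentapeptide\t"
            "pentapeptide\ttopology\tlbd_families\tarchitecture\n"
        )
        for t in truth:
            fh.write(
                "\t".join(
                    [
                        t.protein_id,
                        t.proteome_id,
                        t.clade,
                        "1" if t.is_chemoreceptor else "0",
                        "1" if t.has_pentapeptide else "0",
                        t.pentapeptide or "-",
                        t.topology,
                        ",".join(sorted(t.lbd_families)) or "-",
                        t.architecture or "-",
                    ]
                )
                + "\n"
            )


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            GroundTruthRecord(
                protein_id=row.protein_id,
                proteome_id=row.proteome_id,
                clade=row.clade,
                is_chemoreceptor=row.is_chemoreceptor == "1",
                has_pentapeptide=row.has_pentapeptide == "1",
                pentapeptide=None if row.pentapeptide == "-" else row.pentapeptide,
                topology=row.topology,
                lbd_families=frozenset()
                if row.lbd_families == "-"
                else frozenset(row.lbd_families.split(",")),
                architecture=None if row.architecture == "-" else row.architecture,
            )
        )
    return out
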