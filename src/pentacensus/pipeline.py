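"""End-to-end orchestration: scan -> classify -> census -> motif.

All analysis stages are deterministic and seed-free; randomness exists only
in the simulator.  Outputs are TSV tables plus a plain-text summary carrying
the configuration hash (and the simulation seed, when the inputs came from
the generator).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import census as census_mod
from . import io_tables, motif as motif_mod
from .classify import annotate_receptors

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Inputs, knobs and output location for one full pipeline run."""

    fasta: str
    domains: str
    tm: str
    metadata: str
    out_dir: str
    habitat: str | None = None
    dialect: str = "native"
    ranks: tuple[str, ...] = ("superkingdom", "phylum", "class", "order")
    pwm_pseudocount: float = 0.5
    min_genomes: int = 1
    cap_percentile: float = 99.5
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        missing = [
            p for p in (self.fasta, self.domains, self.tm, self.metadata)
            if not Path(p).exists()
        ]
        if self.habitat is not None and not Path(self.habitat).exists():
            missing.append(self.habitat)
        if missing:
            raise PipelineError(f"validation: missing input files {missing}")
        for rank in self.ranks:
            if rank not in census_mod.CENSUS_RANKS:
                raise PipelineError(f"validation: unsupported census rank {rank!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "ranks" in data:
        data["ranks"] = tuple(data["ranks"])
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_all(config: RunConfig) -> dict:
    """Run every stage and write all outputs under ``config.out_dir``.

    Returns a dict of headline numbers (global abundance, per-genome mean/sd,
    Pearson r, topology split) plus the paths written.  Raises
    :class:`PipelineError` naming the failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    t0 = time.time()
    try:
        records = io_tables.read_fasta(config.fasta)
        hits = io_tables.read_domain_table(config.domains, dialect=config.dialect)
        tm = io_tables.read_tm_table(config.tm)
        metadata = io_tables.read_proteome_metadata(config.metadata)
        habitat = (
            io_tables.read_habitat_table(config.habitat) if config.habitat else None
        )
        log.info("load: %d proteins, %d domain hits (%.1fs)",
                 len(records), len(hits), time.time() - t0)

        stage = "classify"
        annotations = annotate_receptors(records, hits, tm)
        io_tables.write_annotations(annotations, out / "annotations.tsv")
        log.info("classify: %d chemoreceptors", len(annotations))

        stage = "census"
        counts = census_mod.per_genome_counts(annotations)
        mean, sd = census_mod.genome_summary(counts)
        hist = census_mod.pentapeptide_histogram(counts)
        points, r = census_mod.abundance_vs_receptor_count(
            counts, min_genomes=config.min_genomes,
            cap_percentile=config.cap_percentile,
        )
        for rank in config.ranks:
            io_tables.write_census(
                census_mod.abundance_by_taxon(annotations, metadata, rank),
                out / f"census_{rank}.tsv",
            )
        io_tables.write_census(
            census_mod.abundance_by_topology(annotations), out / "census_topology.tsv"
        )
        io_tables.write_census(
            census_mod.abundance_by_lbd_family(annotations), out / "census_lbd.tsv"
        )
        if habitat is not None:
            io_tables.write_census(
                census_mod.abundance_by_habitat(annotations, habitat),
                out / "census_habitat.tsv",
            )
        with open(out / "genome_counts.tsv", "w") as fh:
            fh.write("proteome_id\ttotal_receptors\tpentapeptide_receptors\n")
            for c in sorted(counts, key=lambda c: c.proteome_id):
                fh.write(f"{c.proteome_id}\t{c.total_receptors}\t{c.pentapeptide_receptors}\n")
        with open(out / "abundance_vs_count.tsv", "w") as fh:
            fh.write("receptor_count\tpooled_abundance_percent\tn_genomes\n")
            for p in points:
                fh.write(f"{p.receptor_count}\t{p.pooled_abundance_percent:.4f}\t{p.n_genomes}\n")

        stage = "motif"
        pentapeptides = [a.pentapeptide for a in annotations if a.has_pentapeptide]
        consensus = charge = pwm = None
        if pentapeptides:
            pwm = motif_mod.build_pwm(pentapeptides, pseudocount=config.pwm_pseudocount)
            consensus = motif_mod.consensus_string(pwm)
            charge = motif_mod.charge_summary(pentapeptides)
            motif_mod.write_pwm(pwm, out / "pwm.tsv")
            motif_mod.export_logo_table(pwm, out / "logo.tsv")

        stage = "summary"
        n_total = len(annotations)
        n_penta = len(pentapeptides)
        global_abundance = 100.0 * n_penta / n_total if n_total else float("nan")
        by_superkingdom = census_mod.abundance_by_taxon(
            annotations, metadata, "superkingdom"
        )
        summary = {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "total_chemoreceptors": n_total,
            "pentapeptide_chemoreceptors": n_penta,
            "global_abundance_percent": global_abundance,
            "mean_receptors_per_proteome": mean,
            "sd_receptors_per_proteome": sd,
            "pearson_r_abundance_vs_count": r,
            "consensus": consensus,
            "mean_pentapeptide_charge": charge.mean_charge if charge else None,
            "fraction_net_negative": charge.fraction_net_negative if charge else None,
        }
        _write_summary(
            out / "summary.txt", summary, by_superkingdom, hist,
        )
        return {**summary, "out_dir": str(out)}
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - escalation path
        log.error("stage %r failed: %s", stage, exc)
        raise PipelineError(f"{stage}: {exc}") from exc


def _write_summary(path: Path, summary: dict, by_superkingdom, hist: dict) -> None:
    with open(path, "w") as fh:
        fh.write("pentapeptide census summary\n")
        fh.write(f"config_hash\t{summary['config_hash']}\n")
        if summary["seed"] is not None:
            fh.write(f"seed\t{summary['seed']}\n")
        fh.write(f"total_chemoreceptors\t{summary['total_chemoreceptors']}\n")
        fh.write(
            f"pentapeptide_chemoreceptors\t{summary['pentapeptide_chemoreceptors']}\n"
        )
        fh.write(f"global_abundance_percent\t{summary['global_abundance_percent']:.2f}\n")
        for row in by_superkingdom:
            fh.write(f"abundance_{row.group}\t{row.abundance_percent:.2f}\n")
        fh.write(f"mean_receptors_per_proteome\t{summary['mean_receptors_per_proteome']:.2f}\n")
        if summary["sd_receptors_per_proteome"] is not None:
            fh.write(f"sd_receptors_per_proteome\t{summary['sd_receptors_per_proteome']:.2f}\n")
        if summary["pearson_r_abundance_vs_count"] is not None:
            fh.write(
                f"pearson_r_abundance_vs_count\t{summary['pearson_r_abundance_vs_count']:.4f}\n"
            )
        if summary["consensus"] is not None:
            fh.write(f"consensus\t{summary['consensus']}\n")
            fh.write(f"mean_pentapeptide_charge\t{summary['mean_pentapeptide_charge']:.3f}\n")
            fh.write(f"fraction_net_negative\t{summary['fraction_net_negative']:.3f}\n")
        fh.write("pentapeptides_per_genome_histogram\n")
        for k, v in hist.items():
            fh.write(f"  {k}\t{v}\n")
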