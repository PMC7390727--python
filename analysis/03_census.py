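"""Aggregate the classified receptors into abundance tables: per taxon rank,
per LBD family, per topology class, per habitat, and per genome, plus the
pooled abundance-versus-receptor-count curve with its Pearson correlation.

Reads scratch/synthetic/ (run 01-02 first); writes census tables under
results/.
"""

from pathlib import Path

from pentacensus import census, io_tables

IN = Path("scratch/synthetic")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    annotations = io_tables.read_annotations(IN / "annotations.tsv")
    metadata = io_tables.read_proteome_metadata(IN / "metadata.tsv")
    habitat = io_tables.read_habitat_table(IN / "habitat.tsv")

    for rank in ("superkingdom", "phylum", "class", "order"):
        rows = census.abundance_by_taxon(annotations, metadata, rank)
        io_tables.write_census(rows, OUT / f"census_{rank}.tsv")
    io_tables.write_census(
        census.abundance_by_topology(annotations), OUT / "census_topology.tsv"
    )
    io_tables.write_census(
        census.abundance_by_lbd_family(annotations), OUT / "census_lbd.tsv"
    )
    io_tables.write_census(
        census.abundance_by_habitat(annotations, habitat), OUT / "census_habitat.tsv"
    )

    counts = census.per_genome_counts(annotations)
    mean, sd = census.genome_summary(counts)
    print(f"receptors per genome: {mean:.1f} +/- {sd:.1f} (n={len(counts)} genomes)")
    hist = census.pentapeptide_histogram(counts)
    mode = max(hist, key=hist.get)
    print(f"pentapeptide receptors per genome: mode {mode} "
          f"({hist[mode]} genomes), max {max(hist)}")
    points, r = census.abundance_vs_receptor_count(counts)
    with open(OUT / "abundance_vs_count.tsv", "w") as fh:
        fh.write("receptor_count\tpooled_abundance_percent\tn_genomes\n")
        for p in points:
            fh.write(f"{p.receptor_count}\t{p.pooled_abundance_percent:.4f}\t{p.n_genomes}\n")
    print(f"pooled abundance vs receptors per genome: Pearson r = {r:.2f} "
          f"over {len(points)} count values")
    order_rows = census.abundance_by_taxon(annotations, metadata, "order")
    top = sorted(order_rows, key=lambda r: -r.abundance_percent)[:3]
    print("highest-abundance orders: "
          + ", ".join(f"{r.group} {r.abundance_percent:.2f}%" for r in top))


if __name__ == "__main__":
    main()
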