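"""Scan every protein for the C-terminal xZxxZ motif, keep chemoreceptors
(MCPsignal/PF00015 carriers), and classify topology, LBD families and
pentapeptide architecture.

Reads scratch/synthetic/ (run 01 first); writes the per-receptor annotation
table next to the bundle (it is one row per receptor, so it lives in scratch
with the other large intermediates) and prints the global abundance and the
topology split.
"""

from collections import Counter
from pathlib import Path

from pentacensus import annotate_receptors, io_tables

IN = Path("scratch/synthetic")


def main() -> None:
    records = io_tables.read_fasta(IN / "proteins.fasta")
    hits = io_tables.read_domain_table(IN / "domains.tsv")
    tm = io_tables.read_tm_table(IN / "tm.tsv")
    annotations = annotate_receptors(records, hits, tm)
    io_tables.write_annotations(annotations, IN / "annotations.tsv")

    n = len(annotations)
    n_penta = sum(a.has_pentapeptide for a in annotations)
    print(f"{n} chemoreceptors among {len(records)} proteins; "
          f"{n_penta} carry a pentapeptide ({100 * n_penta / n:.2f}%)")
    topo = Counter(a.topology for a in annotations)
    print(f"topology: {topo['transmembrane']} transmembrane, "
          f"{topo['cytosolic']} cytosolic "
          f"({100 * topo['cytosolic'] / n:.1f}% cytosolic)")
    arch = Counter(
        a.architecture for a in annotations
        if a.has_pentapeptide and "CZB" in a.lbd_families
    )
    total_czb = sum(arch.values())
    if total_czb:
        n_sig = arch["pentapeptide_on_signaling_domain"]
        print(f"CZB receptors with pentapeptide: {total_czb}; "
              f"{100 * n_sig / total_czb:.0f}% fused to the signaling domain, "
              f"{100 * (total_czb - n_sig) / total_czb:.0f}% to the C-terminal CZB")
    linkers = [a.linker_length for a in annotations if a.linker_length is not None]
    print(f"median linker length: {sorted(linkers)[len(linkers) // 2]} residues")


if __name__ == "__main__":
    main()
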