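"""Build the pentapeptide consensus: position frequencies, information
content, consensus string, logo table and net-charge statistics.

Reads the annotations from scratch/synthetic/ (run 01-02 first); writes
results/pwm.tsv, results/logo.tsv and prints the consensus and charge summary.
"""

from pathlib import Path

from pentacensus import io_tables
from pentacensus.motif import (
    build_pwm,
    charge_summary,
    consensus_string,
    export_logo_table,
    write_pwm,
)

IN = Path("scratch/synthetic")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    annotations = io_tables.read_annotations(IN / "annotations.tsv")
    pentapeptides = [a.pentapeptide for a in annotations if a.has_pentapeptide]
    pwm = build_pwm(pentapeptides, pseudocount=0.5)
    write_pwm(pwm, OUT / "pwm.tsv")
    export_logo_table(pwm, OUT / "logo.tsv")

    consensus = consensus_string(pwm)
    print(f"{len(pentapeptides)} pentapeptides; consensus {consensus}")
    print("information content (bits/position): "
          + " ".join(f"{ic:.2f}" for ic in pwm.information_content))
    charges = charge_summary(pentapeptides)
    print(f"mean net charge {charges.mean_charge:+.2f}; "
          f"{100 * charges.fraction_net_negative:.1f}% net negative")


if __name__ == "__main__":
    main()
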