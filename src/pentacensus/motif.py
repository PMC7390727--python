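"""Pentapeptide consensus: position weight matrix, information content,
consensus string, logo export, and net-charge statistics.

All pentapeptides have length 5, so the multiple alignment underlying the
consensus is the identity map and the motif model reduces to per-position
residue frequencies.  Information content is log2(20) minus the Shannon
entropy of a position, in bits — the stack-height basis of a sequence logo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically; PWM column order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

MOTIF_LENGTH = 5
MAX_IC_BITS = float(np.log2(len(ALPHABET)))

#: Side-chain charges at neutral pH; histidine counted as neutral.
_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass
class PositionWeightMatrix:
    """Residue frequencies and information content of the 5-position motif.

    ``frequencies[i, j]`` is the pseudocount-smoothed frequency of residue
    ``ALPHABET[j]`` at motif position ``i`` (0-based); each row sums to 1.
    ``information_content[i]`` is in bits, bounded by [0, log2 20].
    """

    counts: np.ndarray
    pseudocount: float
    frequencies: np.ndarray
    information_content: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        if self.counts.shape != (MOTIF_LENGTH, len(ALPHABET)):
            raise ValueError("counts must be 5 x 20")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")
        if np.any(self.information_content < -1e-12) or np.any(
            self.information_content > MAX_IC_BITS + 1e-12
        ):
            raise ValueError("information content out of [0, log2 20]")


@dataclass
class ChargeSummary:
    """Net-charge statistics of a pentapeptide collection.

    The mean and the negative fraction are computed over the input list with
    multiplicity; ``per_peptide_charge`` maps each distinct peptide to its
    charge.
    """

    per_peptide_charge: dict[str, int]
    mean_charge: float
    fraction_net_negative: float


def build_pwm(
    pentapeptides: Iterable[str],
    pseudocount: float = 0.5,
    small_sample_correction: bool = False,
) -> PositionWeightMatrix:
    """Tally per-position residue counts and derive frequencies and IC.

    Peptides containing non-standard letters are dropped with a logged count;
    an input that is empty after filtering raises.  Frequencies are
    ``(count + pseudocount) / (n + 20 * pseudocount)``.  With
    ``small_sample_correction`` the asymptotic bias term (19 / (2 ln2 n)) is
    subtracted from each position's information content (clipped at 0);
    at census-scale n the correction is negligible and off by default.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = np.zeros((MOTIF_LENGTH, len(ALPHABET)), dtype=np.int64)
    n = 0
    dropped = 0
    for p in pentapeptides:
        if len(p) != MOTIF_LENGTH:
            raise ValueError(f"pentapeptide {p!r} does not have length 5")
        try:
            idx = [_AA_INDEX[aa] for aa in p]
        except KeyError:
            dropped += 1
            continue
        counts[np.arange(MOTIF_LENGTH), idx] += 1
        n += 1
    if dropped:
        log.warning("dropped %d pentapeptides with non-standard letters", dropped)
    if n == 0:
        raise ValueError("no pentapeptides over the standard alphabet")

    freqs = (counts + pseudocount) / (n + len(ALPHABET) * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logs).sum(axis=1)
    ic = MAX_IC_BITS - entropy
    if small_sample_correction:
        ic = ic - (len(ALPHABET) - 1) / (2 * np.log(2) * n)
    ic = np.clip(ic, 0.0, MAX_IC_BITS)
    return PositionWeightMatrix(
        counts=counts,
        pseudocount=pseudocount,
        frequencies=freqs,
        information_content=ic,
        n_sequences=n,
    )


def consensus_string(pwm: PositionWeightMatrix) -> str:
    """The modal residue per position; ties break alphabetically with a note."""
    letters = []
    for i in range(MOTIF_LENGTH):
        row = pwm.frequencies[i]
        best = float(row.max())
        winners = [ALPHABET[j] for j in range(len(ALPHABET)) if row[j] == best]
        if len(winners) > 1:
            log.info(
                "consensus position %d: %d-way tie, broken alphabetically (%s)",
                i + 1, len(winners), "".join(winners),
            )
        letters.append(winners[0])
    return "".join(letters)


def net_charge(pentapeptide: str) -> int:
    """Net side-chain charge: (#K + #R) - (#D + #E); H and non-standard are 0."""
    if len(pentapeptide) != MOTIF_LENGTH:
        raise ValueError("net_charge expects a length-5 peptide")
    charge = 0
    for aa in pentapeptide:
        if aa not in _AA_INDEX:
            log.warning("non-standard letter %r counted as neutral", aa)
        charge += _CHARGE.get(aa, 0)
    return charge


def charge_summary(pentapeptides: Sequence[str]) -> ChargeSummary:
    """Per-peptide net charges, mean charge, and the net-negative fraction."""
    if not pentapeptides:
        raise ValueError("charge_summary requires at least one pentapeptide")
    charges = [net_charge(p) for p in pentapeptides]
    return ChargeSummary(
        per_peptide_charge={p: c for p, c in zip(pentapeptides, charges)},
        mean_charge=float(np.mean(charges)),
        fraction_net_negative=float(np.mean([c < 0 for c in charges])),
    )


def export_logo_table(pwm: PositionWeightMatrix, path: str | Path) -> None:
    """Write (position, residue, stack_height) rows consumable by any logo
    renderer; stack heights are frequency x information content, so per
    position they sum to that position's IC (information-content height rule).
    """
    with open(path, "w") as fh:
        fh.write("position\tresidue\tstack_height\n")
        for i in range(MOTIF_LENGTH):
            for j, aa in enumerate(ALPHABET):
                height = pwm.frequencies[i, j] * pwm.information_content[i]
                fh.write(f"{i + 1}\t{aa}\t{height:.6f}\n")


def write_pwm(pwm: PositionWeightMatrix, path: str | Path) -> None:
    """Write the PWM as a TSV: rows = positions, columns = residues, plus IC."""
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(ALPHABET) + "\tinformation_content_bits\n")
        for i in range(MOTIF_LENGTH):
            cells = "\t".join(f"{f:.6f}" for f in pwm.frequencies[i])
            fh.write(f"{i + 1}\t{cells}\t{pwm.information_content[i]:.6f}\n")
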