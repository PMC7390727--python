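# Methods

## The census

Bacterial chemoreceptors (methyl-accepting chemotaxis proteins, MCPs) adapt
to persistent stimuli through reversible methylation by the CheR
methyltransferase and demethylation by the CheB methylesterase. In the
*E. coli* receptors Tar and Tsr, both enzymes dock at a five-residue motif at
the extreme C-terminus — the archetype is NWETF — tethered to the receptor's
signaling domain by an unstructured linker of roughly 35 residues. This
package implements a census of that pentapeptide across large protein
collections: which chemoreceptors carry it, how its prevalence varies across
genomes, taxa, receptor topologies, sensor-domain families and habitats, and
what the motif's consensus and net charge look like.

The operational definitions, fixed throughout:

- **Chemoreceptor** — any protein with an MCPsignal domain (Pfam PF00015).
- **Pentapeptide** — the C-terminal pattern xZxxZ with Z ∈ {F, W, Y} and x
  any residue, evaluated on the last five residues only; no constraint is
  placed on the linker. The two constrained positions accept only the literal
  letters F, W, Y, so ambiguity codes (X, B, Z, ...) never satisfy them —
  a conservative choice that avoids inflating counts from ambiguous
  translations. Under a uniform 20-letter background the motif's random match
  probability is exactly (3/20)² = 0.0225.
- **Topology** — transmembrane iff at least one annotated membrane-spanning
  region; cytosolic otherwise. Any TM row provided is treated as evidence;
  no distinction is drawn between predicted and experimental annotations
  (none is stated for the source data either).
- **LBD families** — an 18-entry catalogue of the Pfam ligand-binding-domain
  families most common on chemoreceptors (TarH, CHASE3, 4HB_MCP_1, the PAS
  and Cache families, protoglobin, CZB, GAF, PilJ, HBM, NIT). A receptor
  carrying several families is counted once in each family's stratum.
- **Abundance** — pentapeptide-carrying receptors as a percentage of all
  receptors within a stratum. Aggregations pool receptor counts (sum of
  pentapeptide receptors over sum of receptors), never averages of
  per-genome ratios; rows with zero receptors are never emitted, and
  receptors mapping to no stratum pool into an explicit `unclassified` row.

## Architecture resolution

A pentapeptide can be fused either to the signaling domain or to a sensor
domain (most prominently CZB) lying C-terminal to it. The rule, decided from
domain coordinates alone: let M be the most C-terminal PF00015 hit (the
signaling domain relevant to a C-terminal fusion is the one nearest the
C-terminus). If any catalogue LBD hit starts after M ends, the pentapeptide
is assigned to the most C-terminal such LBD; otherwise to the signaling
domain. An LBD that straddles M's end is treated as C-terminal only when its
midpoint lies beyond M's midpoint, and the case is logged as ambiguous —
coordinate overlaps have no canonical resolution, and the midpoint rule is
the least surprising tiebreak. The reference domain's end coordinate feeds
the linker length, `sequence_length − 5 − reference_end`, which is undefined
(with a warning) when the annotation overlaps the motif.

## Census statistics

- Receptors per genome are summarised by mean and sample (n−1) standard
  deviation.
- The abundance-versus-receptor-count curve takes, for every distinct
  per-genome receptor count, the pooled abundance over the genomes sharing
  that count. Counts above the 99.5th percentile of genome counts are
  dropped by default (the extreme tail holds too few genomes to estimate an
  abundance); both the percentile cap and a minimum-genomes-per-count filter
  are configurable. The Pearson correlation is computed unweighted over the
  retained (count, pooled abundance) points. Pooling rather than averaging
  per-genome ratios matches the receptor-level abundance definition used
  everywhere else; both interpretations remain reachable through the
  configuration.
- Habitat strata: receptors from proteomes without a habitat assignment are
  excluded by default rather than pooled as unclassified, because habitat
  databases cover only a subset of strains; a flag pools them instead.
- Domain hits are not e-value filtered by default (the upstream annotation
  is trusted); an optional maximum e-value is exposed on the readers.

## Consensus motif

All pentapeptides have length five, so the multiple alignment underlying the
consensus is the identity map and the motif model reduces to a 5 × 20
position weight matrix. Frequencies are pseudocount-smoothed,
`(count + c) / (n + 20c)` with c = 0.5 by default (a Jeffreys-like prior;
configurable). Information content per position is log₂ 20 minus the Shannon
entropy of the column, in bits, bounded by [0, log₂ 20 ≈ 4.32]. Logo stack
heights follow the information-content rule (height = frequency × IC, so a
position's heights sum to its IC); the choice is recorded in the output. An
optional asymptotic small-sample correction, 19/(2 ln 2 · n) bits, is off by
default — at census scale (thousands of peptides) it is negligible. Net
charge is (#K + #R) − (#D + #E) per peptide, histidine neutral; pH-dependent
charge is out of scope. Consensus ties break alphabetically with a logged
note. Peptides containing non-standard letters are dropped from the PWM with
a logged count.

## Synthetic study regime

The generator emits a fully self-consistent bundle — FASTA, domain TSV, TM
TSV, lineage metadata, habitat table — plus per-protein ground truth, from a
list of clade specifications. Per clade: number of genomes, a zero-truncated
negative-binomial receptor count per genome (variance = mean + mean²/r, with
dispersion r = 1.2 reproducing the strongly overdispersed
variance ≈ mean² regime of real genomes, where ~14 ± 14 receptors per
proteome is typical), a per-receptor pentapeptide probability, LBD family
weights (with a `"none"` option), a transmembrane fraction, a C-terminal-CZB
fraction (default 0.39), and habitat categories. Receptor sequences are
uniform random over the 20 standard residues — compositional realism is
irrelevant to every implemented statistic except the motif's false-positive
rate, which is exactly the analytic 0.0225 under uniformity, a useful check.
Pentapeptide receptors end in a linker drawn from a normal distribution
(mean 35, sd 4, rounded, floored at 0) followed by a 5-mer sampled from a
configurable letter distribution whose constrained positions carry all mass
on F/W/Y (default: W-dominant position 2, F-dominant position 5, acidic
residues enriched elsewhere). Non-pentapeptide receptors have their
C-terminus rejection-sampled to not match the motif. Domain and TM
annotations are noise-free — the census trusts its upstream annotation, so
annotation error is out of scope — but a hook drops a configurable fraction
of domain rows for robustness testing. Identical seeds give byte-identical
bundles.

The shipped default regime (`make_study_config`) spans twelve clades
from high (~38%) to near-zero (~0.2%) pentapeptide prevalence with receptor
counts averaging ~14 per genome. Prevalence is configured to decline with
the clade's receptor-count mean, which induces the negative pooled
abundance-versus-count correlation at the census level (r ≈ −0.8 at 2,000
genomes) while keeping each clade's pentapeptide count exactly binomial in
its configured probability — the within-clade slope knob exists
(`pentapeptide_slope`, centred on the clade's mean count so the clade-wide
expectation is preserved) but is zero in the default regime so that
calibration checks against the configured probabilities stay exact. The
transmembrane fractions are chosen to put roughly 23% of receptors in the
cytosolic class, matching the topology split reported for real collections.

**What passing tests show, and don't.** The generator emulates the
statistical structure the census assumes — strata with distinct prevalence,
overdispersed counts, exact annotations. It does not emulate annotation
noise, phylogenetic correlation between related genomes, biased residue
composition, or archaeal contamination. Exact round-trip recovery therefore
validates the pipeline's bookkeeping and classification logic, not the
robustness of upstream domain/TM annotation on real proteomes.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere; the hmmscan dialect uses
  envelope (not alignment) coordinates, HMMER's own recommended region
  estimate, and strips accession version suffixes.
- Non-standard residues are retained at parse time; their handling is
  decided at the motif layer.
- `pearson_r` is a direct product-moment computation; constant inputs raise
  rather than return NaN.
- Problem sizes: the full-scale checks run at 2,000 genomes (~30,000
  receptors), 10⁵ random sequences for the motif-oracle equivalence and 10⁶
  random 5-mers for the analytic match rate — large enough that the 3-SE
  calibration bands are tight (binomial SE on a clade of ~2,500 receptors is
  ~0.7 percentage points at p = 0.38), small enough to run in seconds.

## Limitations

- Everything downstream of domain annotation trusts that annotation; there
  is no de-novo HMM search, signal-peptide or topology prediction.
- The habitat census reproduces the aggregation logic only; real habitat
  assignments are many-to-many and noisy in ways the generator does not
  model.
- The architecture rule considers catalogue LBDs only; a pentapeptide fused
  to a non-catalogue C-terminal domain is attributed to the signaling
  domain.
- Global-scale absolute numbers (total receptor counts and percentages over
  a full sequence-database snapshot) depend on that snapshot and cannot be
  reproduced here; the package reproduces the method, and its statistical
  behaviour is validated on the synthetic regime.
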