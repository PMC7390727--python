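# pentacensus

A census pipeline for the C-terminal CheR/CheB-binding pentapeptide of
bacterial chemoreceptors.

Chemoreceptors (methyl-accepting chemotaxis proteins, MCPs) adapt through
methylation by CheR and demethylation by CheB. In *E. coli* Tar/Tsr both
enzymes dock at a C-terminal pentapeptide — archetype **NWETF**, pattern
**xZxxZ** with Z ∈ {F, W, Y} — tethered to the signaling domain by an
unstructured linker of ~35 residues. This package answers, for any protein
collection with domain and topology annotation: which chemoreceptors
(proteins with an MCPsignal / Pfam PF00015 domain) carry the pentapeptide,
how its abundance — pentapeptide receptors as a percentage of all receptors
— varies across genomes, taxa, topology classes, ligand-binding-domain (LBD)
families and habitats, whether the motif is fused to the signaling domain or
to a C-terminal sensor domain such as CZB, and what the motif's consensus,
information content and net charge are.

It is aimed at researchers in bacterial chemosensing and comparative
genomics who want the census machinery reusable and testable: every step is
a library function, the inputs are plain TSV/FASTA, and a synthetic proteome
generator with exact ground truth makes the whole pipeline verifiable end to
end.

## Layout

- `src/pentacensus/` — the library: `io_tables` (FASTA/TSV readers and
  writers, including the hmmscan `--domtblout` dialect), `pentapeptide`
  (motif scan, linker geometry), `classify` (chemoreceptor definition,
  topology, LBD catalogue, architecture), `census` (all abundance
  statistics), `motif` (PWM, information content, consensus, logo export,
  net charge), `simulate` (synthetic proteomes with ground truth),
  `pipeline` + `cli` (orchestration; `pentacensus --help`).
- `analysis/` — numbered drivers that run the study on the synthetic regime
  and write tables under `results/`.
- `docs/methods.md` — model, parameters, and design choices.

## Worked example

```bash
python analysis/01_simulate.py        # ~2,000 genomes under scratch/synthetic/
python analysis/02_scan_classify.py   # -> results/annotations.tsv
python analysis/03_census.py          # -> results/census_*.tsv
python analysis/04_consensus_motif.py # -> results/pwm.tsv, results/logo.tsv
```

Output of a run (seed 11):

```
29838 chemoreceptors among 33838 proteins; 3977 carry a pentapeptide (13.33%)
topology: 22927 transmembrane, 6911 cytosolic (23.2% cytosolic)
CZB receptors with pentapeptide: 77; 56% fused to the signaling domain, 44% to the C-terminal CZB
median linker length: 35 residues
receptors per genome: 14.9 +/- 14.8 (n=2000 genomes)
pentapeptide receptors per genome: mode 1 (392 genomes), max 21
pooled abundance vs receptors per genome: Pearson r = -0.82 over 73 count values
highest-abundance orders: Enterobacterales 37.41%, Xanthomonadales 37.35%, Caulobacterales 37.10%
3977 pentapeptides; consensus DWETF
information content (bits/position): 0.82 3.23 1.04 0.78 3.38
mean net charge -1.16; 76.8% net negative
```

Reading this: 13.33% of the synthetic chemoreceptors carry the motif
(pooled over clades configured from ~0.2% to ~38% prevalence); genome
receptor counts are strongly overdispersed (sd ≈ mean); pooled pentapeptide
abundance falls as genomes carry more receptors (r = −0.82); the consensus
DWETF has near-maximal information at the two constrained aromatic positions
(W at 2, F at 5) and a negative net charge driven by acidic residues at the
unconstrained positions.

The same pipeline runs on real inputs via the CLI, e.g.

```bash
pentacensus classify --fasta proteins.fasta --domains hits.domtblout \
    --dialect hmmscan_domtblout --tm tm.tsv --out annotations.tsv
pentacensus census --annotations annotations.tsv --metadata metadata.tsv \
    --group taxon --rank order --out-dir results/
```

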