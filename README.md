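# srnakit

A small-RNA discovery and annotation toolkit: from raw short reads to
curated miRNA candidates, endogenous siRNA classes, miRNA target
prediction, and stem-loop qPCR quantification — testable entirely
offline against truth-labelled synthetic data.

## What it does

| Module | Purpose |
| --- | --- |
| `srnakit.config` | One auditable `Thresholds` set for every stage (flat key=value config files) |
| `srnakit.synthetic_data` | Truth-labelled synthetic genomes: planted miRNA hairpins (verified against the package's own evaluator), 21-nt phased loci, repeat families, antisense gene pairs, contaminant genes; heavy-tailed read simulation |
| `srnakit.io_formats` | FASTA/FASTQ (collapsed `-countN` dialect), GFF3, BED, TSV reports; internal coordinates are 0-based half-open everywhere |
| `srnakit.read_processing` | Read collapsing, length and contaminant filters, length histograms |
| `srnakit.genome_index` | Exact both-strand read placement via a k-mer seed table |
| `srnakit.rna_fold` | MFE secondary-structure prediction under an embedded nearest-neighbor stacking model (numba-accelerated Zuker-style DP), constrained folding for site accessibility, intermolecular duplex energy, and an exhaustive enumeration oracle (n ≤ 18) |
| `srnakit.mirna_discovery` | Window scan around hits, hairpin curation (single loop, ≥50% paired, ≤4 mismatches / ≤2 bulges in the mature, MFE < −0.35×length), miRNA* duplex detection with 2-nt 3′ overhangs, abundance rules (≥3 with star, ≥100 without), context classification |
| `srnakit.target_prediction` | Plant-mode (weighted mismatches ≤3, site-opening energy ≤30) and animal-mode (perfect 2–8 seed, duplex < −20 kcal/mol) target search; GO level-2 clustering |
| `srnakit.sirna_annotation` | ra-siRNA repeat containment, ta-siRNA hypergeometric phasing scan (21-nt register, 231-nt windows, p ≤ 0.001), nat-siRNA antisense-exon calls and ≥25-nt overlapping gene pairs, piRNA k-mer Fisher discriminant, positional-bias diagnostics |
| `srnakit.expression_quant` | 2^−ΔCT, 2^−ΔΔCT, and standard-curve PCR efficiency |
| `srnakit.cli` | `srnakit` command with `simulate / collapse / mirna / sirna / targets / qpcr / report` subcommands, run manifests, deterministic seeding |

The folding energies come from a deliberately small stacking-only model
(Watson-Crick + G:U, hairpin-loop initiation classes, flat per-nucleotide
bulge penalties, fixed multiloop cost). Absolute energies differ from
full Turner-model folders; every screen in the pipeline is
threshold-relative and calibrated against this engine, and the model is
exhaustively verified against brute-force enumeration at n ≤ 16.

## CLI quick start

```bash
# truth-labelled synthetic dataset
srnakit simulate --seed 42 --out-dir run/sim

# miRNA discovery on it
srnakit mirna --genome run/sim/genome.fa --gff run/sim/genes.gff3 \
    --reads run/sim/reads.fa --contaminants run/sim/contaminants.fa \
    --out-dir run/mirna

# siRNA classes
srnakit sirna --genome run/sim/genome.fa --gff run/sim/genes.gff3 \
    --reads run/sim/reads.fa --repeats run/sim/repeats.bed \
    --out-dir run/sirna

# summary statistics over a candidate table
srnakit report --candidates run/mirna/candidates.tsv --out-dir run/report
```

Thresholds can be overridden with `--config file.cfg` (one
`key = value` per line; unknown keys are an error). Every output
directory receives a `manifest.json` recording the threshold snapshot,
input digests, and seed.

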