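# meicall

Detection of active non-reference **mobile element insertions** (MEIs — Alu,
L1, SVA, HERV-K) from coordinate-sorted short-read BAM files, together with a
truth-driven read simulator for measuring detection accuracy without external
data.

The caller combines two evidence types:

1. **Discordant read pairs** — a uniquely mapped anchor whose mate is
   unmapped, multi-mapped, inter-chromosomal, wrongly oriented, or at an
   aberrant insert size. Mate sequences are mapped against a small library of
   ME family consensus sequences (the *mobilome*).
2. **Soft-clipped reads** — uniquely mapped reads whose clipped tail maps to
   the mobilome or shows a terminal polyA/polyT stretch; clip positions give
   base-pair-precise breakpoints and signed target-site duplication (TSD) /
   deletion sizes.

Anchors are clustered per side (5′/3′, discordant/clipped), compatible
clusters are joined into events, clipped evidence refines discordant events,
and predictions are filtered (minimum support, proximity to same-family
reference MEs, satellite overlap, one-sided support), merged within 50 bp,
and reported with orientation inferred from the polyA side.

## Command line

```sh
# simulate a 2 Mb genome with 100 homozygous insertions at 10X
meicall simulate --seed 1 --coverage 10 --out-dir sim/

# call insertions with the paired-end WGS preset
meicall predict --bam sim/reads.bam --mobilome sim/mobilome.fa \
    --ref-mei-bed sim/reference_mei.bed --satellite-bed sim/satellite.bed \
    --reference sim/reference.fa --preset wgs-pe --out calls/ --vcf

# compare calls against the planted truth (50 bp window, family-matched)
meicall evaluate --calls calls/predictions.tsv --truth sim/truth.tsv

# empirical random-read mapping rates vs the mobilome
meicall random-reads --mobilome sim/mobilome.fa --out table.tsv
```

Presets: `wgs-pe` (paired-end WGS, double-sided support required), `wes-pe`
(paired-end WES, one-sided predictions allowed), `wes-se` (single-end,
clipped-read-only, 20 bp clips, 3 bp clip scatter). Every threshold can be
overridden via a flat `key = value` config file (`--config`); see
`src/meicall/config.py` for the full list and defaults.

`predict` writes into the output directory:

* `predictions.tsv` — pass-only report, 0-based half-open coordinates, fixed
  column order: `chrom, window_start, window_end, breakpoint, family,
  orientation, tsd_bp, support_total, support_disc_unique,
  support_disc_multimapped_mate, support_clipped, support_unmapped_mate,
  polyA_side, filters, gene_component`. `breakpoint` is either a point
  (`5000`) or an interval (`5000-5013`); `tsd_bp` is signed (positive =
  target-site duplication, negative = deletion, 0 = blunt).
* `audit.tsv` — same columns, including flagged predictions.
* `predictions.vcf` (with `--vcf`) — VCF 4.2 with symbolic `<INS:ME:*>` ALT
  alleles; POS is the 1-based leftmost window coordinate.
* `manifest.json` — version, config hash, input checksums, per-stage counts.

## Simulator

`meicall simulate` builds a random reference with embedded reference-ME
decoy copies and a satellite block, plants insertions with realistic
structure (TSD or target-site deletion, polyA tail, optional L1 5′
truncation, strand, zygosity), and emits a sorted, indexed BAM directly from
the known donor structure: junction-spanning reads are soft-clipped at the
true junction and reads inside the insertion become MAPQ-0 (placed at a
decoy) or unmapped records. All outputs are byte-deterministic for a given
seed. An interleaved FASTQ (`--fastq`) is available for end-to-end runs
through a real aligner.

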