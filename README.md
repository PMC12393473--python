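# autopod

A regulatory-element evolution toolkit for the developing hand and foot
(autopod) skeleton.  It implements, as a tested pipeline on synthetic
data with planted truth:

- **Interval plumbing** — BED-style interval algebra on 0-based
  half-open coordinates (merge, subtract, overlap counting, flank
  windows), UCSC-chain and TSV-chain parsing, and interval liftover with
  `min_match` / multiple-hit semantics (`autopod.intervals`,
  `autopod.chain`, `autopod.genome`).
- **Synthetic data** — a target/sister/outgroup genome trio with planted
  lineage-specific fixed substitutions, polymorphic sites with allele
  frequencies and deletion-induced chain gaps; an element × condition
  accessibility atlas with controllable sharing structure; score tracks
  with a planted mean shift; skeletal measurement tables
  (`autopod.simulate`).
- **Accessibility atlas** — brain-peak filtering, autopod/tissue
  specificity classification, partitioning along the limb,
  proximal–distal region, and timepoint axes, sharing profiles, and
  cross-species sharing fractions (`autopod.atlas`).
- **Feature overlaps** — element/feature overlap counting, flank-window
  reports, gene-proximity counts with an expression filter, Pearson
  correlation of per-gene counts, and expected differential-activity
  arithmetic (`autopod.overlap`).
- **Divergence survey** — the fixed-substitution procedure: standardize
  elements to 500 bp, mask common variants (MAF > 0.05 in any species)
  and blacklisted bases, require full-length single-locus liftover to
  both non-target genomes, gate on ≥25% sequence identity, and call a
  base derived on a lineage when that genome differs while the other two
  agree; plus the Wilcoxon rank-sum conservation-shift test
  (`autopod.divergence`).
- **Enrichment statistics** — per-base-pair feature and common-variant
  rates, pairwise Fisher exact comparisons with a permutation
  alternative (`autopod.enrichment`).
- **Anatomy proportions** — interspecific percent change on pooled
  skeletal measurements (`autopod.anatomy`).

## Command-line interface

```bash
autopod run-all --config configs/demo.yaml --out out/demo --seed 1
```

simulates every input, runs all stages, and writes TSV reports
(`divergence.tsv`, `enrichment_rates.tsv`, `partitions.tsv`,
`sharing_profile.tsv`, `percent_change.tsv`, …), each carrying a
provenance header with the tool version, seed, and config hash; the same
config + seed reproduces byte-identical outputs.  Individual stages run
standalone on files:

```bash
autopod simulate --out out/sim --seed 5
autopod atlas    --elements e.bed --matrix acc.tsv --brain brain.bed --out out/atlas
autopod overlap  --elements e.bed --features HAR=hars.bed --out overlaps.tsv
autopod diverge  --elements e.bed --target-fasta t.fa --sister-fasta s.fa \
                 --outgroup-fasta o.fa --chain-sister ts.chain.tsv \
                 --chain-outgroup to.chain.tsv --variants h=h.tsv ... --out out/div
autopod enrich   --elements e.bed --features HAR=hars.bed --out rates.tsv
autopod anatomy  --measurements m.csv --out percent_change.csv
autopod check    # bundled worked-example arithmetic self-checks
```

## Layout

```
src/autopod/     library modules (one per pipeline stage)
tests/           pytest suite; test_acceptance.py holds the acceptance
                 criteria, oracles.py the independent brute-force oracles
configs/         demo YAML configuration
scripts/         acceptance report generator
```
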