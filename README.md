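# otg

Preprocessing and evaluation tools for SNP calling on ion-semiconductor
(single-end, variable-length, homopolymer-error-prone) sequencing data:

- **rdast** — duplicate-read filtering by the integer alignment-score (`AS`)
  tag: reads sharing a 5′ mapped coordinate and strand form a pile; every
  read scoring above the threshold (default 160) is kept, and when none
  passes, the single best read is kept so no locus loses all coverage.
- **aos** — alignment optimization around homopolymer gaps: every reference
  column where a read disagrees with the reference is checked for a ≥ 3-base
  homopolymer context (in the reference or in a covering read); gaps whose
  pileup fraction is non-zero but under 0.2 are classed *improper* and either
  repaired in place (insertions excised, deletions converted back to
  reference bases) or dropped.
- **caller** — a minimal pileup-frequency SNP caller acting as the
  downstream consumer of the two filters (a stand-in for a full variant
  caller; gapped columns are treated as indel-ambiguous and skipped).
- **metrics** — FP/FN rates against control sets, overlap, genotype
  consensus, Ti/Tv, het/hom, known-site rate, sensitivity/specificity and a
  depth-saturation procedure based on seeded random subsampling.
- **simulate** — an ion-style read simulator producing a homopolymer-enriched
  reference, a diploid donor with planted SNPs, PCR-duplicate piles sharing
  pre-amplification errors, homopolymer over/undercall gaps (default 1 per
  100 aligned bases) and per-read alignment scores, plus full truth files.

All coordinates are 0-based half-open internally; SAM/VCF/BED conventions
are converted at file boundaries. Alignments are read and written with
pysam (plain-text SAM works everywhere; `.bam` is selected by extension).

## CLI

```sh
otg simulate --config sim.yaml --out-dir sim/         # ref.fa, reads.sam, truth.vcf, ...
otg rdast   --in sim/reads.sam --out dedup.sam --as-threshold 160 --stats rdast.tsv
otg aos     --in dedup.sam --out aos.sam --ref sim/ref.fa --min-homopolymer 3 --gap-ratio 0.2
otg call    --in aos.sam --ref sim/ref.fa --out calls.vcf --min-depth 8 --min-alt-fraction 0.2
otg eval    --calls calls.vcf --wgs-control sim/truth.vcf --genotyping-control sim/truth.vcf \
            --bed sim/target.bed --out report.tsv
otg run-all --out-dir run/ --seed 7                   # simulate → rdast → aos → call → eval
otg run-all --out-dir run_nordast/ --seed 7 --no-rdast   # ablation variants
```

`run-all` writes its full configuration next to the outputs
(`pipeline_config.yaml`) for provenance, plus per-stage stats TSVs and an
`ablation_metrics.tsv` with sensitivity/specificity against the simulated
truth. To substitute a production variant caller for the built-in one, stop
after `otg aos` and feed `aos.sam` to your caller of choice.

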