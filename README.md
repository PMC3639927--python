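# lce-cnvpop

Population-genetic analysis pipeline for a common deletion polymorphism
surveyed across worldwide human population samples:

* **Pooled aCGH CNV detection** — a rule-based caller (|log2| ≥ 0.25 on both
  the direct and dye-swap labels, with opposite signs, for ≥ 3 consecutive
  probes spanning ≥ 30 kb), an independent sliding-window caller, a
  reciprocal-overlap concordance filter, and BED feature-overlap annotation.
* **Per-population genotype statistics** — genotype/allele frequencies,
  uncorrected 1-df Hardy–Weinberg chi-square tests, reconstruction of integer
  genotype counts from published percentages, and Spearman rank correlation
  (midranks, two-sided t-approximate p) between pooled array intensity and
  deletion frequency.
* **CNV × SNP linkage disequilibrium** — EM estimation of the four two-locus
  haplotype frequencies from unphased diploid genotypes, with D, D′ and r².
* **Synthetic data** — a generator for individual genotypes (random union of
  gametes from configurable haplotype frequencies) and pooled dye-swap probe
  tables (expected log2 = attenuation × log2 of the pool copy-number ratio,
  plus Gaussian noise), with ground-truth regions for end-to-end testing.
* **Published-table fixtures** — the 13-population pooled-intensity /
  genotype-frequency table and the 31-population frequency/HWE/LD table are
  shipped as TSV package data and drive the calibration tests.

## Command line

All stages are exposed under one entry point:

```bash
lce-cnvpop run      --config config.json --seed 1 --out-dir out/   # full pipeline
lce-cnvpop simulate --config config.json --out-dir out/
lce-cnvpop call-cnv --probes out/probes_POP1_vs_REF.tsv --out calls.bed
lce-cnvpop popstats --genotypes out/genotypes.tsv --out summary.tsv
lce-cnvpop ld       --genotypes out/genotypes.tsv --out ld.tsv
lce-cnvpop correlate --summary out/population_summary.tsv
lce-cnvpop report   --genotypes out/genotypes.tsv
```

Exit codes: 0 success, 2 validation/configuration error, 3 stage failure.
A config file (JSON or TOML) names the populations (sample size + four
haplotype frequencies over {+A, +G, −A, −G}), the reference population,
the simulation parameters and the detection thresholds; see
`tests/test_pipeline.py::BASE_CONFIG` for a minimal example.  `run` writes a
bundle (genotypes, probe tables, truth/consensus BEDs, population summary,
LD table, correlation JSON) plus a manifest with SHA-256 digests; identical
config + seed reproduce the bundle byte for byte.

## Layout

```
src/lce_cnvpop/
  core.py            shared region/genotype types and errors
  io_formats.py      probe-table / genotype-table / BED / summary I/O
  synthetic_data.py  genotype + pooled-aCGH simulators
  cnv_detection.py   rule-based & window callers, consensus, annotation
  popgen_stats.py    frequencies, HWE, count reconstruction, Spearman
  ld_analysis.py     EM haplotype frequencies, D/D'/r², grid oracle
  pipeline.py        orchestration, manifest, report table
  cli.py             click CLI
  data/              published-table TSV fixtures
tests/               unit + property + acceptance suites
scripts/acceptance.py
```
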