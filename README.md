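# cnvrtool

Consensus CNV calling and copy-number-variable-region (CNVR) analysis for
SNP-array cohorts.

## The problem

Copy number variants (CNVs) called from Illumina-style SNP-array data are
noisy: any single calling algorithm produces many false positives. A widely
used remedy in population CNV surveys is **dual-algorithm consensus
calling** — keep a CNV only if two independent callers (a QuantiSNP-style
Bayes-factor HMM and a cnvPartition/GenomeStudio-style segmenter) detect an
event of the same type at the same locus with at least 50% overlapping
length — combined with strict per-call quality filters. The surviving
high-confidence calls are then clustered across individuals into **CNVRs**
(Redon-style regions: transitive merging of CNVs that overlap by at least
one base), which are the units for carrier-frequency spectra, between-group
sharing, and novelty assessment against a Database-of-Genomic-Variants-like
catalogue.

`cnvrtool` implements that whole workflow for cohort studies comparing two
population groups:

1. **Sample QC** — exclude samples with call rate < 98% or genome-wide
   SD(LRR) > 0.3.
2. **Call filtering** — QuantiSNP-style calls kept iff n_probes ≥ 7,
   MaxLogBF ≥ 30, SD(LRR) ∈ [0.1, 0.25] and SD(BAF) < 0.04;
   cnvPartition-style calls kept iff confidence ≥ 35 and n_probes ≥ 7.
3. **Consensus** — same sample, same chromosome, same CNV type
   (CN < 2 = deletion, CN > 2 = duplication), reciprocal overlap ≥ 50%;
   chromosome X excluded; consensus span = intersection of the pair.
4. **CNVR construction** — transitive one-base-overlap merging across
   samples; carrier frequency *f* = carriers / QC-passed cohort;
   rare (*f* < 1%), common (*f* ≥ 5%), singleton (one carrier).
5. **Comparative analysis** — shared vs group-specific non-singleton
   CNVRs, novelty flags (no overlap with the reference catalogue), gene
   overlap, cohort summary tables, Mann–Whitney–Wilcoxon size tests and
   Kendall's τ-b frequency correlation (α = 0.05).

Because raw genotype-level cohorts of this kind are not redistributable, a
first-class **synthetic-data module** simulates a two-group cohort with a
known ground-truth CNV landscape (shared polymorphic regions with a
rare/intermediate/common frequency spectrum plus private events) and
emulates both callers' noisy outputs (missed calls, false positives,
boundary jitter, quality metrics straddling the thresholds), so every stage
is testable end to end with known expected answers.

## Worked example

```python
from cnvrtool.synthetic_data import (
    SimulationConfig, CallerProfile, simulate_truth, emulate_caller,
    recovery_report,
)
from cnvrtool.qc_consensus import run_consensus_pipeline
from cnvrtool.cnvr_analysis import build_cnvrs, shared_cnvrs
from cnvrtool.stats_summary import cohort_summary

sim = simulate_truth(SimulationConfig(n_samples=100), seed=42)
calls_a = emulate_caller(sim, CallerProfile(), "ALG_A", seed=43)
calls_b = emulate_caller(sim, CallerProfile(), "ALG_B", seed=44)
passed, cnvs, log = run_consensus_pipeline(sim.samples, calls_a, calls_b)
cnvrs = build_cnvrs(cnvs, n_cohort=len(passed))
summary = cohort_summary(cnvs, cnvrs, passed)
report = recovery_report(sim, cnvs, cnvrs)
print(f"{log.n_consensus} consensus CNVs in {len(cnvrs)} CNVRs")
print(f"{summary.cnvs_per_person} CNVs/person, {summary.carrier_pct}% carriers")
print(f"{summary.dup_pct}% duplications / {summary.del_pct}% deletions")
print(f"median CNV size {summary.median_cnv_kb} kb, coverage {summary.genome_coverage_mb} Mb")
print(f"precision {report.precision:.2f}, recall {report.recall:.2f}, "
      f"frequency MAE {report.frequency_mae:.4f}")
```

prints

```
132 consensus CNVs in 101 CNVRs
1.32 CNVs/person, 78.0% carriers
34.8% duplications / 65.2% deletions
median CNV size 65.7 kb, coverage 10.5 Mb
precision 1.00, recall 0.71, frequency MAE 0.0057
```

Reading the numbers: the two emulated callers each miss ~5% of true events
and fail quality filters on ~10% of the rest, so the dual-caller rule
recovers about (0.95·0.9)² ≈ 0.73 of the planted truth — and, because the
two callers' false positives are placed independently, essentially none of
them replicate across callers, giving precision 1.00. The recovered CNVR
carrier frequencies track the planted design frequencies to well under one
carrier's worth of error (MAE 0.0057 at n = 100).

## Command line

Every stage is also exposed as a `cnvr-tool` subcommand over the library:

```sh
cnvr-tool simulate --seed 5 --out sim/            # manifest, truth, caller tables, pseudo-DGV BED
cnvr-tool consensus --alg-a sim/alg_a.tsv --alg-b sim/alg_b.tsv \
                    --manifest sim/manifest.tsv --out run
cnvr-tool cnvr --cnvs run.cnvs.tsv --manifest sim/manifest.tsv \
               --dgv sim/pseudo_dgv.bed --out run
cnvr-tool summarize --cnvs run.cnvs.tsv --manifest sim/manifest.tsv --out summary.tsv
cnvr-tool compare-groups --cnvs run.cnvs.tsv --manifest sim/manifest.tsv --out compare.json
```

Thresholds and caller column maps can be overridden with `--config
config.yaml` (keys `thresholds:`, plus per-dialect column maps; see
`cnvrtool.io_formats.DIALECTS` for the defaults).

## Acceptance script

`scripts/acceptance.py` regenerates a full synthetic cohort from scratch,
runs the complete pipeline (QC → filters → consensus → CNVRs → frequency,
sharing and novelty analysis → cohort summary → group tests), and prints
the recovery scores against the planted ground truth:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, parameter defaults, numerical
conventions and known limitations.
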