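# Methods

## Coordinate and interval conventions

All genomic records are held in 1-based, both-ends-inclusive coordinates
(the convention of array CNV callers and of printed CNV coordinates such as
`chr3:113598223–113659549`); an interval's length is `end − start + 1`.
BED input/output converts to and from 0-based half-open exactly once, at
the file boundary, and the conversion is an exact inverse (tested as a
round-trip identity).

CNVR construction merges intervals that share **at least one base**:
abutting intervals (`end_a + 1 = start_b`) do not merge. Merging is
transitive across samples, so a CNVR is the maximal region in which every
member CNV is connected to every other through a chain of overlaps. The
merge is a single sort-and-sweep; its correctness is checked in the tests
against a brute-force position-set union on thousands of random instances.

Kb/Mb sizes are reported with round-half-up (not banker's rounding):
percentages to 1 decimal, per-person rates to 2 decimals, call/region
sizes in kb to 1 decimal (the `size_kb` primitive itself carries 2), and
genome coverage in Mb to 1 decimal. Published kb values of this kind are
ambiguous between `end − start` and `end − start + 1` conventions at 2-dp
printing; we adopt `end − start + 1` (consistent with inclusive length)
and the worked-example region rounds to the same printed value either way.

## Quality thresholds

`FilterThresholds` collects every numeric rule, all user-overridable via
the YAML config:

| parameter | default | meaning |
|---|---|---|
| `min_call_rate` | 0.98 | sample excluded below this genotyping call rate |
| `max_sample_lrr_sd` | 0.3 | sample excluded above this genome-wide SD(LRR) |
| `min_probes` | 7 | consecutive-probe support required per call (both callers) |
| `min_max_log_bf` | 30 | QuantiSNP-style maximum log Bayes factor |
| `call_sd_lrr_range` | [0.1, 0.25] | acceptable per-call SD(LRR), closed range |
| `max_call_sd_baf` | 0.04 | per-call SD(BAF), strict upper bound |
| `min_confidence` | 35 | cnvPartition-style confidence score |
| `min_overlap_fraction` | 0.5 | cross-caller overlap rule |

Boundary inclusivity follows the printed comparators of the protocol the
defaults come from: boundary samples (call rate exactly 0.98, LRR SD
exactly 0.3) pass; calls at exactly MaxLogBF 30, confidence 35, SD(LRR)
0.1 or 0.25 are kept; SD(BAF) exactly 0.04 is rejected. Copy-neutral calls
(CN = 2, e.g. LOH segments) are dropped at parse time: the analysis
concerns deletions (CN < 2) and duplications (CN > 2) only.

## Consensus matching: open choices and how we resolved them

The "at least 50% overlapping length" rule does not by itself say whose
length. We default to the **reciprocal** reading (the overlap must cover
≥ 50% of *each* call) — the stricter, field-standard interpretation used
for structural-variant matching — and provide the single-sided reading
behind `FilterThresholds(reciprocal_overlap=False)` for sensitivity
analysis.

When a pair matches, the reported consensus span is the **intersection**
of the two calls: the conservative region both callers agree on. Union and
either-caller spans are available via `consensus_boundary` because
protocols differ and the choice shifts size statistics (intersection makes
consensus CNVs slightly smaller than either source call).

One call may overlap several calls from the other caller. We resolve this
with greedy one-to-one matching by descending overlap length, breaking
ties by lower overlap start and then by first-caller input order, so the
output is deterministic and independent of dict ordering. Each call
supports at most one consensus CNV; raising either caller's confidence
threshold therefore can only shrink the consensus set (tested as a
monotonicity property).

Probe support uses the caller-reported `n_probes` field; probe-map
adjacency is not re-verified. Chromosome X calls are removed before
matching (high array false-positive rate on X); chromosome Y is not
modelled at all.

## CNVR-level definitions

* **Frequency denominator**: all QC-passed samples of the analysed cohort,
  not the group size; group-level frequencies use group denominators.
* **Singleton**: evaluated at the CNVR level (one carrier) for the sharing
  analysis, and at the CNV level (a CNV is a singleton when its CNVR has
  one carrier) for the singleton/non-singleton call split; the two are
  computed by distinct functions (`Cnvr.is_singleton`,
  `cnv_carrier_counts`).
* **Sharing**: restricted to non-singleton CNVRs; a CNVR is SHARED when
  its carriers span both groups, which by construction means totally or
  partially overlapping CNVs from both groups. The analysis is strictly
  pairwise; more than two group labels is a hard error.
* **Type class**: DEL_ONLY / DUP_ONLY / MIXED by member types. We report
  the three-way counts rather than a two-way duplication/deletion split,
  whose denominator is ill-defined once MIXED regions exist.
* **Novelty**: an item is known when it overlaps *any* reference region by
  ≥ 1 base. This any-overlap criterion is deliberately permissive (a
  reciprocal-fraction mode would flag more items novel); the mode used is
  recorded in the result object so downstream reports can state it.

## Statistical tests

Size differences between groups use the two-sided Mann–Whitney–Wilcoxon
test on CNV-level size vectors (per-person aggregation is a plausible
alternative; CNV-level is what the summary tables describe). The exact
null distribution is used when both groups have n ≤ 20 and no ties,
otherwise the tie-corrected normal approximation (scipy's
`mannwhitneyu`). Frequency concordance uses Kendall's τ-b with tie
adjustment and a normal-approximation p-value, pairing per-CNVR group
frequencies over the union of non-singleton CNVRs with absent-in-group
frequency 0 — the pairing is a package choice, stated in the output
metadata, since frequency vectors from two groups have no canonical
pairing otherwise. α = 0.05 throughout; two tests, no multiple-testing
correction.

Both tests are cross-checked in the suite against independent oracles: an
exhaustive-permutation enumeration of the exact Mann–Whitney p, a 1000-
replicate type-I-error calibration, and an O(n²) concordant/discordant/tie
counting oracle for τ-b.

## The synthetic world

`SimulationConfig` defaults state the cohort the package is designed
around: 286 samples split 166/120 between two groups; 60 shared
polymorphic regions placed disjointly on GRCh37 autosomes; a frequency-
tier mixture of 57.5% rare (design frequency 0.4–1%), 1.1% common
(5–12%), the rest intermediate (1–5%); Bernoulli carrier draws at the
design frequency; ~0.7 private events per sample (Poisson); deletions
52.7% of events; log-normal sizes with median 78.2 kb and σ = 0.95,
clamped to 5 kb–1.4 Mb; and a 5% per-sample rate of chrX events included
specifically so tests can verify the pipeline removes them.

Private events avoid the *entire* shared-region pool, not just the
sample's own regions. This is required for identifiability: a private
event overlapping another sample's shared region would merge into that
region's CNVR and break the exact equality between recovered and planted
carrier frequencies that the perfect-caller tests assert.

`CallerProfile` emulates one caller: emission probability
(`sensitivity`, default 0.95), Poisson false positives per genome
(default 1.0), Gaussian boundary jitter per end (default SD 1 kb), and
quality metrics drawn conditional on a pass/fail coin
(`true_pass_prob` = 0.9, `fp_pass_prob` = 0.25) so the QC filters do
measurable work by default. Passing metrics are drawn inside the
acceptance windows (e.g. MaxLogBF = 30 + Exp(40), SD(LRR) ~ U[0.1, 0.25]);
failing draws violate one randomly chosen metric. Probe counts scale with
event length at ~1 probe / 3 kb with a floor of 7 for passing calls.

Boundary jitter is clamped to **20% of the event length per end** (not
40%): with per-end bound *b*·L, the worst cross-caller case is one call
shrunk to (1 − 2b)L against one grown to (1 + 2b)L, whose reciprocal
overlap fraction is (1 − 2b)/(1 + 2b); b = 0.2 gives 0.6/1.4 ≈ 0.43 < 0.5
only when *both* ends of *both* calls land at their extreme bounds, while
b ≤ 0.2 guarantees ≥ 50% overlap against the *truth* record
unconditionally. At the default jitter SD (1 kb on a ≥ 5 kb event) extreme
configurations are vanishingly rare, keeping the recall ≈ sensitivity²
limit clean for independent callers.

`recovery_report` scores a pipeline run against the planted truth: a
consensus CNV is a true positive when it reciprocally overlaps (≥ 50%) a
truth record of the same sample and type; recall is over autosomal truth
(chrX exclusion is intended behaviour, not a miss); and the CNVR
frequency error compares each shared region's recovered carrier frequency
with its realised (planted) carrier fraction. The expected number of
accidental cross-caller false-positive consensus pairs is computed
geometrically (`fp_reciprocal_collision_probability`) and is < 0.01 at
default settings, which is why independent false positives yield
precision 1.0.

## What a green synthetic test does and does not establish

The generator emulates call *tables*, not LRR/BAF signal: it does not
model probe-density variation along the genome, GC waves, batch effects,
correlated errors between callers (real callers share the same array
signal, so their errors are not independent), linkage between CNV loci,
or realistic gene/DGV content. Green end-to-end tests therefore establish
that the pipeline's logic is correct under its stated assumptions — exact
filtering semantics, matching, merging, counting and test statistics —
not that the default thresholds are optimal for any particular array
product.

## Degenerate inputs and numerical conventions

Empty caller tables parse to empty call lists; an empty CNVR list writes a
header-only table; an empty novelty reference flags everything novel with
a prominent warning; zero cohort size, empty test groups, fewer than two
frequency pairs and more-than-two-group sharing are hard errors. Skipped
input rows (copy-neutral, malformed, zero-length BED records) each
increment a named counter and are logged. All randomness flows through
`numpy.random.default_rng(seed)`; identical config + seed gives
byte-identical outputs.

## Known limitations

* Greedy overlap matching is not a maximum-weight matching; with heavily
  fragmented calls a different one-to-one assignment could pair one more
  call. In QC-filtered array data multi-overlap is rare, and determinism
  was judged more valuable than optimality.
* CNVR frequencies treat deletions and duplications at one locus as
  carriers of the same region (MIXED regions); allele-level frequencies
  are out of scope.
* The Mann–Whitney exact/asymptotic switch at n = 20 follows common
  practice; p-values near the switch can differ slightly between modes.
* chrY, mosaicism, and copy numbers beyond integer states are not
  modelled.
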