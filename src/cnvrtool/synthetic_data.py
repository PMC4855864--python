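"""Synthetic CNV cohorts with known ground truth and emulated callers.

Real SNP-array genotyping data of this kind cannot be redistributed, so the
pipeline is exercised on a stated synthetic world: a two-group cohort in
which each sample carries CNVs drawn from a shared pool of polymorphic
regions (with a rare/intermediate/common frequency spectrum) plus private
events, and two independent "callers" observe that truth with misses, false
positives, boundary jitter and quality metrics that straddle the QC
thresholds.

Defaults follow the published characteristics of a European-population
array survey: 286 samples split 166/120 between two groups, log-normal CNV
sizes with median ~78 kb clamped to 5 kb-1.4 Mb, deletions slightly more
abundant than duplications (52.7%/47.3%), a frequency spectrum dominated by
rare regions, and ~0.7 private (singleton) events per person.

Everything is driven by a ``numpy`` Generator; the same config and seed
always produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import AUTOSOMES, CHROM_X, CnvType, GenomicInterval, overlap_fraction, overlap_length
from .io_formats import ALG_A, ALG_B, CnvCall, ReferenceRegionSet, SampleRecord
from .qc_consensus import ConsensusCnv

# GRCh37 chromosome lengths (bp), the coordinate system of array CNV surveys
GRCH37_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}


@dataclass
class SimulationConfig:
    """The stated world: cohort design and ground-truth CNV landscape."""

    n_samples: int = 286
    group_fraction: float = 166 / 286          # fraction of samples in group A
    group_labels: tuple[str, str] = ("A", "B")
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(GRCH37_LENGTHS)
    )
    n_shared_regions: int = 60
    # frequency-tier mixture (rare <1%, common >=5%, rest intermediate)
    tier_rare: float = 0.575
    tier_common: float = 0.011
    rare_freq_range: tuple[float, float] = (0.004, 0.01)
    intermediate_freq_range: tuple[float, float] = (0.01, 0.05)
    common_freq_range: tuple[float, float] = (0.05, 0.12)
    private_rate: float = 0.7                  # Poisson mean per sample
    chrx_rate: float = 0.05                    # per-sample chrX event prob
    del_fraction: float = 0.527
    size_log_median_bp: float = 78_200.0
    size_log_sigma: float = 0.95
    size_min_bp: int = 5_000
    size_max_bp: int = 1_400_000
    sample_fail_rate: float = 0.0              # fraction failing array QC
    max_placement_retries: int = 1000

    def __post_init__(self) -> None:
        for p in (self.group_fraction, self.tier_rare, self.tier_common,
                  self.chrx_rate, self.del_fraction, self.sample_fail_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.private_rate < 0:
            raise ValueError("private_rate must be >= 0")
        if self.size_min_bp <= 0 or self.size_max_bp < self.size_min_bp:
            raise ValueError("size range must be positive and ordered")


@dataclass
class CallerProfile:
    """How one emulated caller corrupts the truth.

    ``true_pass_prob`` is the probability that a true call's quality
    metrics all clear the QC thresholds; ``fp_pass_prob`` the same for
    false positives (so the filters do measurable work by default).
    Boundary jitter is Gaussian per end, clamped to 20% of the event length
    so that a jittered call always keeps >=50% reciprocal overlap both with
    its truth record and with the other caller's jittered call.
    """

    sensitivity: float = 0.95
    fp_per_genome: float = 1.0
    jitter_sd_bp: float = 1_000.0
    jitter_max_frac: float = 0.2
    true_pass_prob: float = 0.9
    fp_pass_prob: float = 0.25
    probe_spacing_bp: float = 3_000.0

    @classmethod
    def perfect(cls, sensitivity: float = 1.0, fp_per_genome: float = 0.0,
                fp_pass_prob: float = 1.0) -> "CallerProfile":
        """No jitter, no metric failures: with sensitivity 1 and no false
        positives the emulated call set equals the truth exactly."""
        return cls(
            sensitivity=sensitivity,
            fp_per_genome=fp_per_genome,
            jitter_sd_bp=0.0,
            true_pass_prob=1.0,
            fp_pass_prob=fp_pass_prob,
        )


@dataclass(frozen=True)
class TruthCnv:
    """One ground-truth CNV of one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    copy_number: int
    region_id: str | None        # shared-pool region id, None for private


@dataclass
class SharedRegion:
    region_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    design_frequency: float
    carriers: set[str] = field(default_factory=set)


@dataclass
class SimulatedTruth:
    config: SimulationConfig
    samples: list[SampleRecord]
    truth: list[TruthCnv]
    regions: list[SharedRegion]

    @property
    def autosomal_truth(self) -> list[TruthCnv]:
        return [t for t in self.truth if t.interval.chrom != CHROM_X]


def _draw_size(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    size = rng.lognormal(np.log(cfg.size_log_median_bp), cfg.size_log_sigma)
    return int(np.clip(round(size), cfg.size_min_bp, cfg.size_max_bp))


def _draw_type(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[CnvType, int]:
    if rng.random() < cfg.del_fraction:
        return CnvType.DEL, (0 if rng.random() < 0.1 else 1)
    return CnvType.DUP, (4 if rng.random() < 0.1 else 3)


def _place_interval(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    chroms: Sequence[str],
    avoid: Sequence[GenomicInterval],
) -> GenomicInterval:
    """Uniformly place a new interval on the given chromosomes, avoiding
    overlap with every interval in ``avoid``; hard error when the genome is
    too crowded."""
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(cfg.max_placement_retries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        size = _draw_size(cfg, rng)
        if size >= cfg.chrom_lengths[chrom]:
            continue
        start = int(rng.integers(1, cfg.chrom_lengths[chrom] - size + 1))
        iv = GenomicInterval(chrom, start, start + size - 1)
        if all(overlap_length(iv, other) == 0 for other in avoid):
            return iv
    raise RuntimeError(
        "could not place a CNV without overlap after "
        f"{cfg.max_placement_retries} retries; lower the region density"
    )


def simulate_truth(
    config: SimulationConfig | None = None, seed: int | None = 0
) -> SimulatedTruth:
    """Draw the sample manifest and ground-truth CNV landscape.

    Shared regions are placed disjointly on the autosomes and assigned a
    design frequency from the rare/intermediate/common tier mixture;
    carriers are independent Bernoulli draws at that frequency.  Private
    CNVs (Poisson per sample) are placed avoiding the entire shared pool so
    that region-level carrier frequencies stay identifiable, and a small
    per-sample rate of chrX events exercises the pipeline's X exclusion.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    width = max(4, len(str(max(cfg.n_samples, 1))))
    n_a = int(round(cfg.n_samples * cfg.group_fraction))
    samples: list[SampleRecord] = []
    for i in range(cfg.n_samples):
        fails = rng.random() < cfg.sample_fail_rate
        if fails:
            # fail on call rate or genome-wide LRR SD, at random
            if rng.random() < 0.5:
                call_rate = float(rng.uniform(0.90, 0.979))
                lrr_sd = float(rng.uniform(0.05, 0.2))
            else:
                call_rate = float(rng.uniform(0.981, 0.999))
                lrr_sd = float(rng.uniform(0.31, 0.5))
        else:
            call_rate = float(rng.uniform(0.981, 0.999))
            lrr_sd = float(rng.uniform(0.05, 0.25))
        samples.append(
            SampleRecord(
                sample_id=f"S{i + 1:0{width}d}",
                group=cfg.group_labels[0] if i < n_a else cfg.group_labels[1],
                call_rate=call_rate,
                lrr_sd=lrr_sd,
            )
        )

    # shared polymorphic regions, disjoint on the autosomes
    regions: list[SharedRegion] = []
    placed: list[GenomicInterval] = []
    p_intermediate = 1.0 - cfg.tier_rare - cfg.tier_common
    for ridx in range(cfg.n_shared_regions):
        iv = _place_interval(cfg, rng, AUTOSOMES, placed)
        placed.append(iv)
        tier = rng.choice(3, p=[cfg.tier_rare, p_intermediate, cfg.tier_common])
        lo, hi = (cfg.rare_freq_range, cfg.intermediate_freq_range,
                  cfg.common_freq_range)[tier]
        freq = float(rng.uniform(lo, hi))
        ctype, _cn = _draw_type(cfg, rng)
        regions.append(
            SharedRegion(
                region_id=f"R{ridx + 1:03d}",
                interval=iv,
                cnv_type=ctype,
                design_frequency=freq,
            )
        )

    truth: list[TruthCnv] = []
    for region in regions:
        cn = 1 if region.cnv_type is CnvType.DEL else 3
        hits = rng.random(cfg.n_samples) < region.design_frequency
        for s, hit in zip(samples, hits):
            if hit:
                region.carriers.add(s.sample_id)
                truth.append(
                    TruthCnv(s.sample_id, region.interval, region.cnv_type,
                             cn, region.region_id)
                )

    # private events, avoiding the shared pool entirely
    for s in samples:
        n_private = int(rng.poisson(cfg.private_rate))
        mine: list[GenomicInterval] = []
        for _ in range(n_private):
            iv = _place_interval(cfg, rng, AUTOSOMES, placed + mine)
            mine.append(iv)
            ctype, cn = _draw_type(cfg, rng)
            truth.append(TruthCnv(s.sample_id, iv, ctype, cn, None))
        if rng.random() < cfg.chrx_rate:
            iv = _place_interval(cfg, rng, (CHROM_X,), mine)
            ctype, cn = _draw_type(cfg, rng)
            truth.append(TruthCnv(s.sample_id, iv, ctype, cn, None))

    truth.sort(key=lambda t: (t.sample_id, t.interval.chrom, t.interval.start))
    return SimulatedTruth(cfg, samples, truth, regions)


def _jitter(
    iv: GenomicInterval, profile: CallerProfile, rng: np.random.Generator
) -> GenomicInterval:
    if profile.jitter_sd_bp <= 0:
        return iv
    bound = int(profile.jitter_max_frac * iv.length_bp)
    d1 = int(np.clip(round(rng.normal(0, profile.jitter_sd_bp)), -bound, bound))
    d2 = int(np.clip(round(rng.normal(0, profile.jitter_sd_bp)), -bound, bound))
    return GenomicInterval(iv.chrom, max(1, iv.start + d1), iv.end + d2)


def _quality_kwargs(
    caller: str,
    passing: bool,
    length_bp: int,
    profile: CallerProfile,
    rng: np.random.Generator,
) -> dict:
    n_probes_ok = max(7, int(round(length_bp / profile.probe_spacing_bp)))
    if caller == ALG_A:
        if passing:
            return dict(
                n_probes=n_probes_ok,
                max_log_bf=30.0 + float(rng.exponential(40.0)),
                sd_lrr=float(rng.uniform(0.1, 0.25)),
                sd_baf=float(rng.uniform(0.002, 0.0395)),
            )
        # fail at least one metric; which ones is random
        which = rng.integers(0, 4)
        return dict(
            n_probes=int(rng.integers(3, 7)) if which == 0 else n_probes_ok,
            max_log_bf=float(rng.uniform(0.0, 29.9)) if which == 1
            else 30.0 + float(rng.exponential(40.0)),
            sd_lrr=float(rng.uniform(0.26, 0.45)) if which == 2
            else float(rng.uniform(0.1, 0.25)),
            sd_baf=float(rng.uniform(0.041, 0.1)) if which == 3
            else float(rng.uniform(0.002, 0.0395)),
        )
    if passing:
        return dict(
            n_probes=n_probes_ok,
            confidence=35.0 + float(rng.exponential(50.0)),
        )
    if rng.random() < 0.5:
        return dict(n_probes=int(rng.integers(3, 7)),
                    confidence=35.0 + float(rng.exponential(50.0)))
    return dict(n_probes=n_probes_ok, confidence=float(rng.uniform(5.0, 34.9)))


def emulate_caller(
    sim: SimulatedTruth,
    profile: CallerProfile,
    caller: str,
    seed: int | None = 0,
) -> list[CnvCall]:
    """One caller's noisy observation of the truth.

    Each true CNV is emitted with probability ``sensitivity``, its
    boundaries jittered, and its quality metrics drawn conditional on
    whether the call "passes" QC.  False positives are added as a Poisson
    count per genome, placed uniformly with sizes from the same
    distribution and metrics drawn from the false-positive profile.
    """
    if caller not in (ALG_A, ALG_B):
        raise ValueError(f"caller must be {ALG_A} or {ALG_B}")
    cfg = sim.config
    rng = np.random.default_rng(seed)
    calls: list[CnvCall] = []
    for t in sim.truth:
        if rng.random() >= profile.sensitivity:
            continue
        iv = _jitter(t.interval, profile, rng)
        passing = rng.random() < profile.true_pass_prob
        calls.append(
            CnvCall(
                sample_id=t.sample_id,
                caller=caller,
                interval=iv,
                copy_number=t.copy_number,
                **_quality_kwargs(caller, passing, iv.length_bp, profile, rng),
            )
        )
    all_chroms = list(cfg.chrom_lengths)
    for s in sim.samples:
        for _ in range(int(rng.poisson(profile.fp_per_genome))):
            iv = _place_interval(cfg, rng, all_chroms, ())
            ctype = CnvType.DEL if rng.random() < 0.5 else CnvType.DUP
            cn = 1 if ctype is CnvType.DEL else 3
            passing = rng.random() < profile.fp_pass_prob
            calls.append(
                CnvCall(
                    sample_id=s.sample_id,
                    caller=caller,
                    interval=iv,
                    copy_number=cn,
                    **_quality_kwargs(caller, passing, iv.length_bp, profile, rng),
                )
            )
    calls.sort(key=lambda c: (c.sample_id, c.interval.chrom, c.interval.start))
    return calls


def make_pseudo_dgv(
    sim: SimulatedTruth,
    known_fraction: float = 0.8,
    seed: int | None = 0,
) -> tuple[ReferenceRegionSet, set[str]]:
    """A DGV-like reference holding a random subset of the shared regions.

    Returns the reference set and the ids of the regions INCLUDED, so a
    test knows exactly which truth records must be flagged known vs novel.
    """
    rng = np.random.default_rng(seed)
    n_keep = int(round(known_fraction * len(sim.regions)))
    keep_idx = set(
        rng.choice(len(sim.regions), size=n_keep, replace=False).tolist()
    )
    regions = [sim.regions[i].interval for i in sorted(keep_idx)]
    ids = {sim.regions[i].region_id for i in keep_idx}
    return ReferenceRegionSet("pseudo-dgv", regions), ids


def fp_reciprocal_collision_probability(
    fp_a: Sequence[CnvCall],
    fp_b: Sequence[CnvCall],
    genome_bp: int,
    min_overlap_fraction: float = 0.5,
) -> float:
    """Expected number of accidental cross-caller FP consensus pairs.

    Two uniformly placed intervals of lengths L1 <= L2 overlap reciprocally
    at fraction f only when L1 >= f*L2, and the window of start offsets
    achieving it has width L1 + L2 - 2*f*L2; the per-pair probability is
    that width over the genome length.  Summed over all same-sample FP
    pairs this is the expected count of spurious consensus calls (an upper
    bound on the probability of at least one).
    """
    by_sample: dict[str, list[CnvCall]] = {}
    for c in fp_b:
        by_sample.setdefault(c.sample_id, []).append(c)
    total = 0.0
    for a in fp_a:
        for b in by_sample.get(a.sample_id, ()):
            l1, l2 = sorted((a.interval.length_bp, b.interval.length_bp))
            width = l1 + l2 - 2.0 * min_overlap_fraction * l2
            if width > 0:
                total += width / genome_bp
    return total


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    frequency_mae: float
    n_truth: int
    n_called: int
    n_true_positive: int


def recovery_report(
    sim: SimulatedTruth,
    consensus: Sequence[ConsensusCnv],
    cnvrs=None,
    min_overlap_fraction: float = 0.5,
) -> RecoveryReport:
    """Score pipeline output against the simulation's ground truth.

    A consensus CNV is a true positive when it reciprocally overlaps
    (both fractions >= ``min_overlap_fraction``) a truth record of the same
    sample and CNV type.  Recall is over autosomal truth records (the
    pipeline excludes chrX by design).  When CNVRs are supplied, the mean
    absolute error between each shared region's recovered carrier
    frequency and its realised design frequency (planted carriers / n) is
    also reported.
    """
    truth_by_sample: dict[str, list[TruthCnv]] = {}
    for t in sim.autosomal_truth:
        truth_by_sample.setdefault(t.sample_id, []).append(t)

    n_tp = 0
    matched: set[int] = set()
    for c in consensus:
        hit = None
        for t in truth_by_sample.get(c.sample_id, ()):
            if t.cnv_type is not c.cnv_type:
                continue
            fa, fb = overlap_fraction(c.interval, t.interval)
            if fa >= min_overlap_fraction and fb >= min_overlap_fraction:
                hit = t
                break
        if hit is not None:
            n_tp += 1
            matched.add(id(hit))

    n_truth = len(sim.autosomal_truth)
    n_called = len(consensus)
    precision = n_tp / n_called if n_called else 1.0
    recall = len(matched) / n_truth if n_truth else 1.0

    freq_mae = float("nan")
    if cnvrs is not None:
        n = len(sim.samples)
        errs = []
        for region in sim.regions:
            realised = len(region.carriers) / n
            recovered = 0.0
            for r in cnvrs:
                if overlap_length(r.interval, region.interval) > 0:
                    recovered = max(recovered, r.frequency)
            errs.append(abs(recovered - realised))
        freq_mae = float(np.mean(errs)) if errs else 0.0

    return RecoveryReport(precision, recall, freq_mae, n_truth, n_called, n_tp)
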