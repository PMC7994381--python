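"""Synthetic cohorts and ChIP-seq fixtures with planted ground truth.

The generator emulates the statistical structure the screens assume, so that
every downstream stage is exercisable without external downloads:

* segmental ploidy profiles on a toy chromosome with a recurrent distal-arm
  gain (prevalence ``p_gain``, default 0.5, inside the 38-65% incidence range
  reported for 17q gain in neuroblastoma),
* MYCN amplification labels (prevalence ``p_amp``, default 0.25) coupled to
  the gain through an odds multiplier (the two lesions are strongly
  associated in tumours),
* NB-distributed gene counts with copy-number dosage acting multiplicatively
  on the mean, an amplification effect on MYCN (x4) and on the planted driver
  (x 2**driver_amp_log2fc),
* right-censored exponential survival whose hazard depends on whether the
  planted driver's expression is above the cohort median,
* multi-mark promoter peak sets with one planted fully co-occupied,
  high-FE target gene, decoys with incomplete mark combinations or FE <= 5,
  and one boundary decoy at FE exactly 5.0.

Everything is deterministic given the config seed.  The distributional
choices are fixtures for exercising the screens, not claims about any real
tumour cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .io_formats import (
    CLINICAL_COLUMNS,
    GeneModel,
    GenomicInterval,
    GenomicSegment,
    PeakRecord,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "ChipFixture",
    "simulate_cohort",
    "simulate_chip_fixture",
    "null_config",
]

COHORT_CHROM = "chr17"
CHIP_CHROM = "chrT"
MYCN_GENE = "MYCN"

# layout constants: genes of 2 kb every 5 kb, segments of 100 kb
_GENE_LENGTH = 2_000
_GENE_SPACING = 5_000
_GENE_OFFSET = 1_000
_SEGMENT_LENGTH = 100_000

# expression scales (see docs/methods.md): typical bulk RNA-seq-like spread
_MU_LOG_MEAN = np.log(100.0)
_MU_LOG_SD = 1.2
_ANCHOR_MU = 200.0  # driver / MYCN baseline mean: a well-expressed gene
_SF_LOG_SD = 0.2
_MYCN_AMP_LOG2FC = 2.0  # amplification multiplies the MYCN mean by 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort and ChIP fixture."""

    n_samples: int = 200
    n_genes: int = 400
    n_region_genes: int = 60
    p_gain: float = 0.5
    p_amp: float = 0.25
    gain_amp_odds: float = 4.0
    dosage_exponent: float = 1.0
    driver_amp_log2fc: float = 1.5
    driver_hr: float = 2.5
    dispersion: float = 0.1
    baseline_hazard: float = 1.0 / 1500.0
    censor_time: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_gain", "p_amp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_samples", "n_genes", "n_region_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_region_genes > self.n_genes:
            raise ValueError("n_region_genes cannot exceed n_genes")
        for name in ("dispersion", "baseline_hazard", "censor_time", "gain_amp_odds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.driver_hr <= 0:
            raise ValueError("driver_hr must be > 0")


def null_config(config: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """The same conditions with every planted effect switched off."""
    base = config or SimulationConfig()
    return replace(
        base, dosage_exponent=0.0, driver_amp_log2fc=0.0, driver_hr=1.0, **overrides
    )


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for recovery checks."""

    driver_gene: str
    region: GenomicInterval
    gain: pd.Series
    amplified: pd.Series
    driver_amp_log2fc: float
    driver_hr: float
    dosage_exponent: float
    chip_target: str | None = None
    chip_boundary_gene: str | None = None

    def to_json(self) -> str:
        payload = {
            "driver_gene": self.driver_gene,
            "region": {
                "chrom": self.region.chrom,
                "start": self.region.start,
                "end": self.region.end,
            },
            "gain": {k: int(v) for k, v in self.gain.items()},
            "amplified": {k: int(v) for k, v in self.amplified.items()},
            "driver_amp_log2fc": self.driver_amp_log2fc,
            "driver_hr": self.driver_hr,
            "dosage_exponent": self.dosage_exponent,
            "chip_target": self.chip_target,
            "chip_boundary_gene": self.chip_boundary_gene,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass(frozen=True)
class SyntheticCohort:
    segments: list[GenomicSegment]
    counts: pd.DataFrame
    clinical: pd.DataFrame
    genes: list[GeneModel]
    truth: GroundTruth


@dataclass(frozen=True)
class ChipFixture:
    genes: list[GeneModel]
    peaks: dict[str, list[PeakRecord]]
    gene_set: list[str]
    counts: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------


def _gene_layout(n_genes: int, chrom: str, prefix: str) -> list[GeneModel]:
    genes = []
    for k in range(n_genes):
        start = k * _GENE_SPACING + _GENE_OFFSET
        strand = "+" if k % 2 == 0 else "-"
        genes.append(
            GeneModel(
                f"{prefix}{k + 1:04d}",
                GenomicInterval(chrom, start, start + _GENE_LENGTH, strand),
            )
        )
    return genes


def _joint_gain_amp(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Draw amplification, then gain with an odds multiplier, keeping the
    marginal gain prevalence at ``p_gain``."""
    amp = rng.random(config.n_samples) < config.p_amp
    p_gain, p_amp, odds_mult = config.p_gain, config.p_amp, config.gain_amp_odds
    if p_gain in (0.0, 1.0) or p_amp in (0.0, 1.0) or odds_mult == 1.0:
        q0 = q1 = p_gain
    else:
        def q1_of(q0: float) -> float:
            odds = odds_mult * q0 / (1.0 - q0)
            return odds / (1.0 + odds)

        def marginal_gap(q0: float) -> float:
            return p_amp * q1_of(q0) + (1.0 - p_amp) * q0 - p_gain

        eps = 1e-12
        q0 = optimize.brentq(marginal_gap, eps, 1.0 - eps)
        q1 = q1_of(q0)
    gain = rng.random(config.n_samples) < np.where(amp, q1, q0)
    return gain.astype(bool), amp.astype(bool)


def _segments(
    rng: np.random.Generator,
    sample_ids: list[str],
    gain: np.ndarray,
    region: GenomicInterval,
    chrom_length: int,
) -> list[GenomicSegment]:
    bounds = list(range(0, region.start, _SEGMENT_LENGTH)) + [region.start]
    region_bounds = list(range(region.start, chrom_length, _SEGMENT_LENGTH)) + [chrom_length]
    region_bounds = sorted(set(region_bounds))
    segments: list[GenomicSegment] = []
    for i, sample in enumerate(sample_ids):
        region_ploidy = rng.uniform(3.0, 4.0) if gain[i] else None
        for s, e in zip(bounds, bounds[1:]):
            p = max(rng.normal(2.0, 0.1), 0.0)
            segments.append(GenomicSegment(sample, GenomicInterval(region.chrom, s, e), p))
        for s, e in zip(region_bounds, region_bounds[1:]):
            if region_ploidy is None:
                p = max(rng.normal(2.0, 0.1), 0.0)
            else:
                p = region_ploidy
            segments.append(GenomicSegment(sample, GenomicInterval(region.chrom, s, e), p))
    return segments


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _survival_tables(
    rng: np.random.Generator,
    sample_ids: list[str],
    driver_expr: np.ndarray,
    amp: np.ndarray,
    config: SimulationConfig,
) -> pd.DataFrame:
    high = (driver_expr > np.median(driver_expr)).astype(int)
    log_hr = np.log(config.driver_hr)

    def endpoint(base_hazard: float) -> tuple[np.ndarray, np.ndarray]:
        hazard = base_hazard * np.exp(log_hr * high)
        event_time = rng.exponential(1.0 / hazard)
        censor = np.minimum(config.censor_time, rng.uniform(0, 2 * config.censor_time,
                                                            size=len(sample_ids)))
        time = np.maximum(np.minimum(event_time, censor), 1e-6)
        event = (event_time <= censor).astype(int)
        return time, event

    os_time, os_event = endpoint(config.baseline_hazard)
    efs_time, efs_event = endpoint(1.4 * config.baseline_hazard)
    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "efs_time": efs_time,
            "efs_event": efs_event,
            "stage_advanced": (rng.random(len(sample_ids)) < 0.45).astype(int),
            "age_over_18m": (rng.random(len(sample_ids)) < 0.55).astype(int),
            "mycn_amplified": amp.astype(int),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return clinical[CLINICAL_COLUMNS]


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a matched segment/counts/clinical cohort with ground truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    genes = _gene_layout(g, COHORT_CHROM, "G")
    chrom_length = g * _GENE_SPACING + _GENE_OFFSET
    region_start = (g - config.n_region_genes) * _GENE_SPACING
    region = GenomicInterval(COHORT_CHROM, region_start, chrom_length)
    driver = genes[g - config.n_region_genes + config.n_region_genes // 2].gene_id
    genes = genes + [
        GeneModel(MYCN_GENE, GenomicInterval("chr2", 1_000_000, 1_005_000, "+"))
    ]

    gain, amp = _joint_gain_amp(rng, config)
    segments = _segments(rng, sample_ids, gain, region, chrom_length)

    # per-gene, per-sample copy number taken directly from the generating
    # draws (identical to averaging the written segments over gene bodies)
    from .cnv_profile import copy_number_matrix  # local import avoids a cycle

    cn = copy_number_matrix(segments, genes[:-1]).reindex(columns=sample_ids)
    cn.loc[:, :] = np.nan_to_num(cn.to_numpy(), nan=2.0)

    mu = np.exp(rng.normal(_MU_LOG_MEAN, _MU_LOG_SD, size=g))
    gene_ids = [gm.gene_id for gm in genes[:-1]]
    driver_idx = gene_ids.index(driver)
    mu[driver_idx] = _ANCHOR_MU
    sf = np.exp(rng.normal(0.0, _SF_LOG_SD, size=n))

    dosage = np.power(cn.to_numpy() / 2.0, config.dosage_exponent)
    mean = sf[None, :] * mu[:, None] * dosage
    mean[driver_idx] *= np.power(2.0, config.driver_amp_log2fc * amp)
    mycn_mean = sf * _ANCHOR_MU * np.power(2.0, _MYCN_AMP_LOG2FC * amp)
    mean = np.vstack([mean, mycn_mean])

    counts = pd.DataFrame(
        _nb_counts(rng, mean, config.dispersion),
        index=pd.Index(gene_ids + [MYCN_GENE], name="gene_id"),
        columns=sample_ids,
        dtype=np.int64,
    )

    driver_expr = np.log2(counts.loc[driver].to_numpy() / sf + 1.0)
    clinical = _survival_tables(rng, sample_ids, driver_expr, amp, config)

    truth = GroundTruth(
        driver_gene=driver,
        region=region,
        gain=pd.Series(gain, index=sample_ids, name="gain"),
        amplified=pd.Series(amp, index=sample_ids, name="amplified"),
        driver_amp_log2fc=config.driver_amp_log2fc,
        driver_hr=config.driver_hr,
        dosage_exponent=config.dosage_exponent,
    )
    return SyntheticCohort(segments, counts, clinical, genes, truth)


# ---------------------------------------------------------------------------
# ChIP fixture
# ---------------------------------------------------------------------------


def _promoter_peak(
    rng: np.random.Generator,
    gene: GeneModel,
    mark: str,
    fe: float,
) -> PeakRecord:
    """A ~300 bp peak centred inside the gene's promoter window."""
    if gene.interval.strand == "-":
        lo, hi = gene.tss - 100, gene.tss + 1000
    else:
        lo, hi = gene.tss - 1000, gene.tss + 100
    center = int(rng.integers(lo + 150, hi - 150))
    start = max(center - 150, 0)
    return PeakRecord(
        GenomicInterval(gene.interval.chrom, start, center + 150),
        name=f"{mark}_{gene.gene_id}",
        fold_enrichment=float(fe),
        qvalue=4.0,
        summit_offset=center - start,
    )


def simulate_chip_fixture(config: SimulationConfig | None = None) -> ChipFixture:
    """Generate multi-mark peak sets with one planted co-occupied target.

    The planted target carries one peak per mark inside its promoter window
    with coactivator FE ~ Uniform(5.5, 10).  Decoys carry either an
    incomplete mark combination or a sub-threshold coactivator FE drawn
    Uniform(1, 5); one designated boundary decoy carries all five marks at FE
    exactly 5.0.  A matched expression/clinical cohort plants the target's
    survival and MYCN-correlation signal, and the functional gene-set file
    holds the target plus random decoys.
    """
    from . import chip_targets as ct  # local import avoids a cycle

    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1049]))
    g = config.n_genes
    genes = _gene_layout(g, CHIP_CHROM, "T")
    gene_ids = [gm.gene_id for gm in genes]
    target_idx = int(rng.integers(0, g))
    boundary_idx = int((target_idx + 1 + rng.integers(0, g - 1)) % g)
    target, boundary = gene_ids[target_idx], gene_ids[boundary_idx]

    peaks: dict[str, list[PeakRecord]] = {m: [] for m in ct.MARKS}
    for i, gm in enumerate(genes):
        if i == target_idx:
            marks, alyref_fe = set(ct.MARKS), rng.uniform(5.5, 10.0)
        elif i == boundary_idx:
            marks, alyref_fe = set(ct.MARKS), 5.0
        elif rng.random() < 0.3:  # full marks, sub-threshold coactivator FE
            marks, alyref_fe = set(ct.MARKS), rng.uniform(1.0, 5.0)
        else:  # at least one mark missing
            n_missing = int(rng.integers(1, len(ct.MARKS)))
            missing = rng.choice(len(ct.MARKS), size=n_missing, replace=False)
            marks = {m for j, m in enumerate(ct.MARKS) if j not in missing}
            alyref_fe = rng.uniform(1.0, 5.0)
        for mark in ct.MARKS:
            if mark not in marks:
                continue
            fe = alyref_fe if mark == "alyref" else rng.uniform(5.0, 30.0)
            peaks[mark].append(_promoter_peak(rng, gm, mark, fe))

    # expression + survival cohort over the fixture genes (no dosage layer:
    # the toy chromosome carries no copy-number profile)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    amp = rng.random(n) < config.p_amp
    mu = np.exp(rng.normal(_MU_LOG_MEAN, _MU_LOG_SD, size=g))
    mu[target_idx] = _ANCHOR_MU
    sf = np.exp(rng.normal(0.0, _SF_LOG_SD, size=n))
    mean = sf[None, :] * mu[:, None] * np.ones((g, n))
    mean[target_idx] *= np.power(2.0, config.driver_amp_log2fc * amp)
    mycn_mean = sf * _ANCHOR_MU * np.power(2.0, _MYCN_AMP_LOG2FC * amp)
    mean = np.vstack([mean, mycn_mean])
    counts = pd.DataFrame(
        _nb_counts(rng, mean, config.dispersion),
        index=pd.Index(gene_ids + [MYCN_GENE], name="gene_id"),
        columns=sample_ids,
        dtype=np.int64,
    )
    target_expr = np.log2(counts.loc[target].to_numpy() / sf + 1.0)
    clinical = _survival_tables(rng, sample_ids, target_expr, amp, config)

    decoy_pool = [gid for gid in gene_ids if gid != target]
    in_set = list(rng.choice(decoy_pool, size=min(10, len(decoy_pool)), replace=False))
    gene_set = sorted(in_set + [target])

    region = GenomicInterval(CHIP_CHROM, 0, g * _GENE_SPACING + _GENE_OFFSET)
    truth = GroundTruth(
        driver_gene=target,
        region=region,
        gain=pd.Series(False, index=sample_ids, name="gain"),
        amplified=pd.Series(amp, index=sample_ids, name="amplified"),
        driver_amp_log2fc=config.driver_amp_log2fc,
        driver_hr=config.driver_hr,
        dosage_exponent=0.0,
        chip_target=target,
        chip_boundary_gene=boundary,
    )
    return ChipFixture(genes, peaks, gene_set, counts, clinical, truth)


# ---------------------------------------------------------------------------
# on-disk fixture
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    from . import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_segments(cohort.segments, outdir / "segments.tsv")
    io.write_counts(cohort.counts, outdir / "counts.tsv")
    io.write_clinical(cohort.clinical, outdir / "clinical.tsv")
    io.write_gene_models(cohort.genes, outdir / "genes.gtf")


def write_chip_fixture(fixture: ChipFixture, outdir: str | Path) -> None:
    from . import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mark, peaks in fixture.peaks.items():
        io.write_narrowpeak(peaks, outdir / f"{mark}.narrowPeak")
    io.write_gene_models(fixture.genes, outdir / "genes.gtf")
    io.write_counts(fixture.counts, outdir / "counts.tsv")
    io.write_clinical(fixture.clinical, outdir / "clinical.tsv")
    (outdir / "gene_set.txt").write_text("\n".join(fixture.gene_set) + "\n")
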