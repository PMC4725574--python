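"""Synthetic Illumina-style SNP-array signal for cohorts with known karyotypes.

The generator emulates the two per-marker summaries a genotyping platform
exports — the log R ratio (LRR, total-intensity log2 ratio, mean ~0 at
diploid copy number) and the B allele frequency (BAF, in [0,1], with
diploid heterozygotes banding at 0.5) — for arbitrary karyotypes: sex
chromosome aneuploidies (45,X; 47,XXY; 47,XXX), whole-chromosome mosaics,
diploid/triploid mosaicism, whole-chromosome uniparental isodisomy (UPD,
optionally with distal resumption of heterozygosity), and segmental CNVs.

Signal model. A marker carrying b B alleles out of c copies has BAF mean
b/c (uniform noise when c = 0) and LRR mean ``lrr_mu(c)``. A mosaic with
cell fraction f carrying (c2, b2) against a background (c1, b1) mixes
intensities linearly:

    BAF mean = ((1-f)*b1 + f*b2) / ((1-f)*c1 + f*c2)
    LRR mean = lrr_mu evaluated at (1-f)*c1 + f*c2 by linear interpolation

so heterozygous sites split into two bands displaced symmetrically from
0.5 — the quantity the mosaic-fraction estimator downstream inverts.
Every stochastic operation takes an explicit seed; cohorts derive
per-sample child seeds from (seed, sample index) so any one sample can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AUTOSOMES,
    CHROMOSOMES,
    CnvCall,
    IntensityProfile,
    MarkerMap,
)

# Approximate chromosome lengths (bp), GRCh37 scale, used only to place markers.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

SEX_KARYOTYPES = ("XX", "XY", "X", "XXY", "XXX")
MOSAIC_CLASSES = ("monosomy_mosaic", "trisomy_mosaic", "triploid_mosaic")
GENOME_WIDE = "genome-wide"


@dataclass(frozen=True)
class MosaicSpec:
    """A second cell population differing by one chromosome copy.

    ``triploid_mosaic`` targets the whole genome (every chromosome gains a
    copy); the other classes target a single chromosome. ``fraction`` is the
    proportion f of cells carrying the anomaly; f=0 is the unmodified
    karyotype and f=1 the full (constitutional) anomaly.
    """

    klass: str
    target: str  # chromosome label or GENOME_WIDE
    fraction: float

    def __post_init__(self) -> None:
        if self.klass not in MOSAIC_CLASSES:
            raise ValueError(f"unknown mosaic class {self.klass!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("mosaic fraction must be in [0, 1]")
        if self.klass == "triploid_mosaic" and self.target != GENOME_WIDE:
            raise ValueError("triploid_mosaic is genome-wide")


@dataclass(frozen=True)
class KaryotypeSpec:
    """Ground-truth karyotype of one simulated sample."""

    sex_chromosomes: str = "XX"
    mosaic: MosaicSpec | None = None
    upd_chromosomes: tuple[tuple[str, float], ...] = ()
    cnvs: tuple[tuple[str, int, int, int], ...] = ()  # (chrom, start, end, cn)

    def __post_init__(self) -> None:
        if self.sex_chromosomes not in SEX_KARYOTYPES:
            raise ValueError(f"unknown sex karyotype {self.sex_chromosomes!r}")
        for chrom, p_r in self.upd_chromosomes:
            if not 0.0 <= p_r < 1.0:
                raise ValueError("UPD partial-recovery fraction must be in [0, 1)")


@dataclass(frozen=True)
class NoiseModel:
    """Per-marker noise and the copy-number -> mean-LRR response.

    Defaults are canonical Illumina-array expectations for blood-derived
    DNA: lrr_mu = {0: -3.5, 1: -0.66, 2: 0, 3: 0.40, 4: 0.68}, LRR SD 0.20,
    heterozygous-band BAF SD 0.03. Homozygous-band BAF noise is halved and
    reflected at the 0/1 boundary so clean samples show no spurious
    heterozygosity.
    """

    lrr_sd: float = 0.20
    baf_sd: float = 0.03
    lrr_mu: tuple[float, ...] = (-3.5, -0.66, 0.0, 0.40, 0.68)

    def __post_init__(self) -> None:
        if list(self.lrr_mu) != sorted(self.lrr_mu):
            raise ValueError("lrr_mu must be strictly increasing in copy number")
        if self.lrr_mu[2] != 0.0:
            raise ValueError("lrr_mu(2) must be 0 (diploid reference)")

    def lrr_mean(self, copy: np.ndarray | float) -> np.ndarray:
        """Mean LRR at (possibly fractional) copy number, linear interpolation."""
        return np.interp(copy, np.arange(len(self.lrr_mu)), self.lrr_mu)


def population_allele_freq(mmap: MarkerMap, seed: int = 0) -> np.ndarray:
    """Per-marker population B-allele frequency, Uniform(0.05, 0.95), fixed per map."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, len(mmap))))
    return rng.uniform(0.05, 0.95, size=len(mmap))


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------


def simulate_marker_map(
    n_autosomal: int, n_x: int, n_y: int, seed: int = 0
) -> MarkerMap:
    """Place markers uniformly: autosomal markers pick one of the 22 autosomes
    uniformly, then a uniform position on it; X/Y counts are explicit."""
    if min(n_autosomal, n_x, n_y) < 1:
        raise ValueError("marker counts must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_of = list(rng.choice(AUTOSOMES, size=n_autosomal))
    chrom_of += ["X"] * n_x + ["Y"] * n_y
    chroms, positions, ids = [], [], []
    counter = 0
    for c in CHROMOSOMES:
        k = sum(1 for x in chrom_of if x == c)
        if k == 0:
            continue
        pos = _distinct_positions(rng, CHROM_LENGTHS[c], k)
        for p in pos:
            ids.append(f"m{counter:06d}")
            counter += 1
        chroms += [c] * k
        positions += list(pos)
    return MarkerMap(
        marker_id=np.asarray(ids, dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
    )


def _distinct_positions(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=k))
    while len(pos) < k:  # collisions are vanishingly rare at array density
        extra = rng.integers(1, length + 1, size=k - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:k])


# ---------------------------------------------------------------------------
# per-sample signal
# ---------------------------------------------------------------------------


def _base_copies(sex: str) -> dict[str, int]:
    x = {"XX": 2, "XY": 1, "X": 1, "XXY": 2, "XXX": 3}[sex]
    y = {"XX": 0, "XY": 1, "X": 0, "XXY": 1, "XXX": 0}[sex]
    return {"X": x, "Y": y}


def simulate_sample(
    spec: KaryotypeSpec,
    mmap: MarkerMap,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sample_id: str = "S0",
    paf: np.ndarray | None = None,
) -> IntensityProfile:
    """Simulate one sample's LRR/BAF vectors over the map.

    Genotypes follow Hardy-Weinberg draws from the per-marker population
    B-allele frequency; UPD chromosomes are fully homozygous (one allele
    duplicated) except the distal fraction p_r of markers, which revert to
    population heterozygosity. Mosaic second populations lose or gain one
    uniformly chosen allele of the target chromosome(s).
    """
    noise = noise or NoiseModel()
    if paf is None:
        paf = population_allele_freq(mmap)
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)
    n = len(mmap)
    sex_copies = _base_copies(spec.sex_chromosomes)

    c1 = np.full(n, 2.0)
    for c in ("X", "Y"):
        if c in mmap._chrom_slices:
            c1[mmap.chrom_slice(c)] = sex_copies[c]

    # segmental CNVs override the base copy number
    for chrom, start, end, cn in spec.cnvs:
        lo, hi = mmap.chrom_span(chrom)
        if start < 1 or end > CHROM_LENGTHS.get(chrom, hi):
            raise ValueError(
                f"CNV {chrom}:{start}-{end} outside simulated chromosome range"
            )
        idx = mmap.markers_in(chrom, start, end)
        c1[idx] = cn

    # genotype draw: b1 B alleles out of c1 copies
    b1 = rng.binomial(c1.astype(int), paf).astype(float)

    upd_mask = np.zeros(n, dtype=bool)
    for chrom, p_r in spec.upd_chromosomes:
        sl = mmap.chrom_slice(chrom)
        m = sl.stop - sl.start
        homo = np.arange(sl.start, sl.stop)
        n_rec = int(np.ceil(p_r * m))
        if n_rec:
            homo = homo[:-n_rec]  # distal (q-terminal) markers keep HW genotypes
        upd_mask[homo] = True
    if upd_mask.any():
        c1[upd_mask] = 2.0
        b1[upd_mask] = 2.0 * rng.binomial(1, paf[upd_mask])

    # mosaic second cell population: +/- one uniformly chosen allele
    c2 = c1.copy()
    b2 = b1.copy()
    f = 0.0
    if spec.mosaic is not None and spec.mosaic.fraction > 0:
        mos = spec.mosaic
        f = mos.fraction
        if mos.target == GENOME_WIDE:
            affected = np.ones(n, dtype=bool)
        else:
            sl = mmap.chrom_slice(mos.target)
            affected = np.zeros(n, dtype=bool)
            affected[sl] = True
        delta = 1.0 if mos.klass in ("trisomy_mosaic", "triploid_mosaic") else -1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            p_b = np.where(c1 > 0, b1 / np.maximum(c1, 1), 0.0)
        # the lost/gained copy is a uniformly chosen existing allele
        change = rng.binomial(1, p_b)
        c2 = np.where(affected, np.maximum(c1 + delta, 0.0), c1)
        b2 = np.where(affected, np.clip(b1 + delta * change, 0.0, None), b1)
        b2 = np.minimum(b2, c2)

    c_eff = (1.0 - f) * c1 + f * c2
    b_eff = (1.0 - f) * b1 + f * b2
    with np.errstate(divide="ignore", invalid="ignore"):
        baf_mean = np.where(c_eff > 0, b_eff / np.where(c_eff > 0, c_eff, 1.0), np.nan)

    lrr = noise.lrr_mean(c_eff) + rng.normal(0.0, noise.lrr_sd, size=n)

    baf = np.empty(n)
    null = c_eff <= 0  # no genomic material: BAF is uniform noise
    baf[null] = rng.uniform(0.0, 1.0, size=int(null.sum()))
    mid = ~null & (baf_mean > 0) & (baf_mean < 1)
    baf[mid] = baf_mean[mid] + rng.normal(0.0, noise.baf_sd, size=int(mid.sum()))
    # homozygous bands: half-SD noise reflected inward at the boundary
    hom0 = ~null & (baf_mean <= 0)
    hom1 = ~null & (baf_mean >= 1)
    baf[hom0] = np.abs(rng.normal(0.0, noise.baf_sd / 2, size=int(hom0.sum())))
    baf[hom1] = 1.0 - np.abs(rng.normal(0.0, noise.baf_sd / 2, size=int(hom1.sum())))
    baf = np.clip(baf, 0.0, 1.0)

    return IntensityProfile(sample_id=sample_id, lrr=lrr, baf=baf, map_ref=mmap)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortClass:
    name: str
    spec: KaryotypeSpec
    proportion: float


@dataclass
class CohortConfig:
    classes: Sequence[CohortClass]
    n: int
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c.proportion for c in self.classes)
        if self.classes and abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort: one row per sample, one per CNV."""

    samples: pd.DataFrame  # sample_id, klass, sex_chromosomes, mosaic_*, upd_*
    cnvs: pd.DataFrame     # sample_id, chrom, start, end, cn, n_markers

    def spec_of(self, sample_id: str) -> KaryotypeSpec:
        row = self.samples.set_index("sample_id").loc[sample_id]
        mosaic = None
        if isinstance(row["mosaic_class"], str) and row["mosaic_class"]:
            mosaic = MosaicSpec(
                row["mosaic_class"], row["mosaic_target"], float(row["mosaic_fraction"])
            )
        upd: tuple[tuple[str, float], ...] = ()
        if isinstance(row["upd_chrom"], str) and row["upd_chrom"]:
            upd = ((row["upd_chrom"], float(row["upd_p_r"])),)
        cnvs = tuple(
            (r.chrom, int(r.start), int(r.end), int(r.cn))
            for r in self.cnvs[self.cnvs["sample_id"] == sample_id].itertuples()
        )
        return KaryotypeSpec(row["sex_chromosomes"], mosaic, upd, cnvs)


def _allocate_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment: deterministic, sums exactly to n."""
    raw = [p * n for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def simulate_cohort(
    config: CohortConfig, mmap: MarkerMap, paf: np.ndarray | None = None
) -> tuple[list[IntensityProfile], TruthTable]:
    """Simulate a cohort with deterministically apportioned class counts."""
    if paf is None:
        paf = population_allele_freq(mmap)
    counts = _allocate_counts([c.proportion for c in config.classes], config.n)
    profiles: list[IntensityProfile] = []
    sample_rows, cnv_rows = [], []
    i = 0
    for cls, k in zip(config.classes, counts):
        for _ in range(k):
            sid = f"S{i:04d}"
            child_seed = np.random.SeedSequence((config.seed, i))
            profiles.append(
                simulate_sample(
                    cls.spec, mmap, config.noise,
                    seed=child_seed, sample_id=sid, paf=paf,
                )
            )
            mos = cls.spec.mosaic
            upd = cls.spec.upd_chromosomes[0] if cls.spec.upd_chromosomes else None
            sample_rows.append(
                {
                    "sample_id": sid,
                    "klass": cls.name,
                    "sex_chromosomes": cls.spec.sex_chromosomes,
                    "mosaic_class": mos.klass if mos else "",
                    "mosaic_target": mos.target if mos else "",
                    "mosaic_fraction": mos.fraction if mos else np.nan,
                    "upd_chrom": upd[0] if upd else "",
                    "upd_p_r": upd[1] if upd else np.nan,
                }
            )
            for chrom, start, end, cn in cls.spec.cnvs:
                cnv_rows.append(
                    {
                        "sample_id": sid, "chrom": chrom, "start": start,
                        "end": end, "cn": cn,
                        "n_markers": mmap.n_markers_in(chrom, start, end),
                    }
                )
            i += 1
    samples = pd.DataFrame(
        sample_rows,
        columns=[
            "sample_id", "klass", "sex_chromosomes", "mosaic_class",
            "mosaic_target", "mosaic_fraction", "upd_chrom", "upd_p_r",
        ],
    )
    cnvs = pd.DataFrame(
        cnv_rows, columns=["sample_id", "chrom", "start", "end", "cn", "n_markers"]
    )
    return profiles, TruthTable(samples=samples, cnvs=cnvs)


# ---------------------------------------------------------------------------
# noisy per-algorithm call sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CallErrorModel:
    """Caller-disagreement model: per-sample false-positive rate (Poisson
    mean), per-call false-negative rate, and Gaussian boundary jitter (bp)."""

    fp_rate: float = 0.1
    fn_rate: float = 0.05
    boundary_jitter_sd: float = 5_000.0

    def __post_init__(self) -> None:
        if not (0 <= self.fp_rate and 0 <= self.fn_rate <= 1):
            raise ValueError("error rates must be valid probabilities/rates")


def simulate_callsets(
    truth: TruthTable,
    mmap: MarkerMap,
    algorithms: Sequence[str] = ("pennCNV", "quantiSNP", "iPattern"),
    error: CallErrorModel | None = None,
    seed: int = 0,
) -> dict[str, list[CnvCall]]:
    """Emit one noisy call set per algorithm from the CNV truth table.

    Each true CNV is emitted with probability 1-fn_rate, endpoints jittered;
    false positives are Poisson per sample, placed uniformly with log-uniform
    size 20-500 kb. Marker counts are recomputed from the map after jitter;
    calls whose jittered interval covers no marker are dropped.
    """
    error = error or CallErrorModel()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 911)))
    sample_ids = list(truth.samples["sample_id"])
    out: dict[str, list[CnvCall]] = {}
    for algo in algorithms:
        calls: list[CnvCall] = []
        for row in truth.cnvs.itertuples():
            if rng.uniform() < error.fn_rate:
                continue
            js, je = rng.normal(0, error.boundary_jitter_sd, size=2)
            start = max(1, int(round(row.start + js)))
            end = int(round(row.end + je))
            if end <= start:
                start, end = row.start, row.end
            nm = mmap.n_markers_in(row.chrom, start, end)
            if nm < 1:
                continue
            calls.append(
                CnvCall(
                    sample_id=row.sample_id, chrom=row.chrom, start=start,
                    end=end, cn=int(row.cn), n_markers=nm, algorithm=algo,
                    score=float(rng.uniform(10, 100)),
                )
            )
        autosomal_idx = np.flatnonzero(np.isin(mmap.chrom.astype(str), AUTOSOMES))
        for sid in sample_ids:
            for _ in range(rng.poisson(error.fp_rate)):
                # anchor at a random autosomal marker so the spurious call
                # covers >= 1 marker, as a real caller's would
                anchor = int(rng.choice(autosomal_idx))
                chrom = str(mmap.chrom[anchor])
                size = int(np.exp(rng.uniform(np.log(20_000), np.log(500_000))))
                start = max(1, int(mmap.pos[anchor]) - int(rng.integers(0, size)))
                end = start + size - 1
                nm = mmap.n_markers_in(chrom, start, end)
                if nm < 1:
                    continue
                calls.append(
                    CnvCall(
                        sample_id=sid, chrom=chrom, start=start, end=end,
                        cn=int(rng.choice([1, 3])), n_markers=nm,
                        algorithm=algo, score=float(rng.uniform(10, 100)),
                    )
                )
        out[algo] = calls
    return out


# ---------------------------------------------------------------------------
# default cohort: the study-condition mix used throughout the test suite
# ---------------------------------------------------------------------------


# Default map density for cohort-scale runs: ~1000 markers per autosome —
# a reduced-density emulation of a 550k-marker genotyping panel that keeps
# whole-cohort simulation fast while leaving every chromosome-scale
# statistic well resolved.
DEFAULT_MAP_PARAMS = dict(n_autosomal=22_000, n_x=1_000, n_y=200)


def default_marker_map(seed: int = 0) -> MarkerMap:
    return simulate_marker_map(seed=seed, **DEFAULT_MAP_PARAMS)


def default_cohort_classes() -> list[CohortClass]:
    """Karyotype-class mix for the default synthetic cohort.

    Normal karyotypes dominate; each anomaly class the detector must
    recognise is represented at a few percent so a 400-sample cohort holds
    a double-digit count of every class.
    """
    return [
        CohortClass("46,XX", KaryotypeSpec("XX"), 0.38),
        CohortClass("46,XY", KaryotypeSpec("XY"), 0.38),
        CohortClass("45,X", KaryotypeSpec("X"), 0.02),
        CohortClass("47,XXY", KaryotypeSpec("XXY"), 0.02),
        CohortClass("47,XXX", KaryotypeSpec("XXX"), 0.02),
        CohortClass(
            "45,X/46,XX",
            KaryotypeSpec("XX", mosaic=MosaicSpec("monosomy_mosaic", "X", 0.5)),
            0.03,
        ),
        CohortClass(
            "diploid_triploid",
            KaryotypeSpec("XX", mosaic=MosaicSpec("triploid_mosaic", GENOME_WIDE, 0.5)),
            0.03,
        ),
        CohortClass(
            "trisomy_mosaic_12",
            KaryotypeSpec("XY", mosaic=MosaicSpec("trisomy_mosaic", "12", 0.5)),
            0.02,
        ),
        CohortClass("upd_complete_4", KaryotypeSpec("XX", upd_chromosomes=(("4", 0.0),)), 0.05),
        CohortClass("upd_partial_21", KaryotypeSpec("XY", upd_chromosomes=(("21", 0.2),)), 0.05),
    ]
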