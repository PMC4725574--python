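"""Chromosome-level anomaly detection from per-chromosome LRR/BAF summaries.

The detector operationalizes the classic array-QC workflow: summarize each
chromosome by its mean log R ratio and its B-allele-frequency heterozygosity
rate, z-score each autosome against the other autosomes of the same sample
(leave-one-out, so a large anomaly cannot inflate its own reference), make
two independent sex predictions (X heterozygosity, Y intensity), and run an
explicit decision table over the evidence:

* diploid LRR + chromosome-wide loss of heterozygosity  -> uniparental
  isodisomy (complete, or partial-recovery when a terminal marker run
  regains heterozygosity);
* LRR z > +3 with the heterozygous band split toward 1/3 and 2/3 ->
  trisomy or mosaic trisomy, by band deviation;
* LRR z < -3 -> monosomy (band collapse) or mosaic monosomy (band split);
* band split at near-diploid LRR across many autosomes at once ->
  genome-wide diploid/triploid mosaicism.

An LRR z excursion with fully normal BAF evidence is treated as noise (the
call stays ``normal`` with a warning flag) — the conjunction of the two
evidence channels is what keeps the false-call rate near zero.

Mosaic cell fraction f displaces heterozygous BAF bands from 0.5 by
d = f / (2*(2-f)) for monosomy mosaics and d = f / (2*(2+f)) for trisomy
mosaics; ``estimate_mosaic_fraction`` inverts these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import AUTOSOMES, IntensityProfile, MarkerMap

GENOME_WIDE = "genome-wide"

ANOMALY_CLASSES = (
    "monosomy", "trisomy", "upd_complete", "upd_partial_recovery",
    "mosaic_monosomy", "mosaic_trisomy", "triploid_mosaic", "normal",
)
MOSAIC_ANOMALIES = ("mosaic_monosomy", "mosaic_trisomy", "triploid_mosaic")


@dataclass(frozen=True)
class AnomalyThresholds:
    """All tunable decision thresholds, exposed in config.

    Defaults are calibrated against the synthetic-signal model at its
    default noise (LRR SD 0.20, BAF SD 0.03).
    """

    het_window: tuple[float, float] = (0.25, 0.75)
    informative_window: tuple[float, float] = (0.08, 0.92)
    het_x_threshold: float = 0.05    # X BAF-het rate below => single X
    y_lrr_threshold: float = -1.0    # Y LRR mean above => Y present
    xxx_dosage_z: float = 5.0        # X LRR z above => XXX candidate
    z_aneuploidy: float = 3.0        # the |z| > 3 SD flag rule
    z_cn: float = 3.0                # |z_lrr| below => diploid copy number (UPD gate)
    z_het: float = 3.0               # het-rate z below -z_het => LOH candidate
    upd_het_max: float = 0.02        # residual het rate under complete LOH
    r_min: int = 25                  # min terminal markers for partial recovery
    g_min: int = 10                  # min split autosomes for triploid call
    d_min: float = 0.035             # min band deviation counted as a split
    full_fraction: float = 0.9       # f_hat at or above => constitutional
    terminal_het_rate: float = 0.15  # het rate defining a recovered terminal run
    min_markers: int = 10            # chromosomes below carry no z-scores
    min_informative_frac: float = 0.05


DEFAULT_THRESHOLDS = AnomalyThresholds()


@dataclass
class ChromSummary:
    sample_id: str
    chrom: str
    lrr_mean: float
    baf_het_rate: float
    n_markers: int
    z_lrr: float = math.nan
    z_het: float = math.nan


@dataclass
class SexCall:
    sample_id: str
    x_pred: str          # single_X | double_X_or_more | undetermined
    y_pred: str          # Y_present | Y_absent | undetermined
    combined: str        # XX | XY | X | XXY | XXX_candidate | inconsistent | undetermined
    x_het_rate: float
    y_lrr_mean: float
    x_dosage_z: float
    reported_sex: str | None = None
    concordant_with_reported: bool | None = None


@dataclass
class AnomalyCall:
    sample_id: str
    chrom: str           # chromosome label or "genome-wide"
    klass: str
    mosaic_fraction_hat: float = math.nan
    z_lrr: float = math.nan
    z_het: float = math.nan
    band_deviation: float = math.nan
    warning: str = ""


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_chromosomes(
    profile: IntensityProfile,
    het_window: tuple[float, float] = DEFAULT_THRESHOLDS.het_window,
    min_markers: int = DEFAULT_THRESHOLDS.min_markers,
) -> list[ChromSummary]:
    """Per-chromosome LRR mean and BAF heterozygosity with cross-autosome z.

    z-scores compare each autosome's statistic with the leave-one-out mean
    and SD over the sample's other autosomes; X is scored against all
    autosomes. Chromosomes with fewer than ``min_markers`` observed markers
    carry no z-scores.
    """
    mmap = profile.map_ref
    if not (profile.lrr_mask.any() or profile.baf_mask.any()):
        raise ValueError(f"profile {profile.sample_id}: no observed markers")
    lo, hi = het_window
    summaries: dict[str, ChromSummary] = {}
    for chrom in mmap.chromosomes:
        sl = mmap.chrom_slice(chrom)
        lrr = profile.lrr[sl]
        baf = profile.baf[sl]
        lrr_obs = lrr[~np.isnan(lrr)]
        baf_obs = baf[~np.isnan(baf)]
        summaries[chrom] = ChromSummary(
            sample_id=profile.sample_id,
            chrom=chrom,
            lrr_mean=float(np.mean(lrr_obs)) if len(lrr_obs) else math.nan,
            baf_het_rate=(
                float(np.mean((baf_obs >= lo) & (baf_obs <= hi)))
                if len(baf_obs) else math.nan
            ),
            n_markers=int(min(len(lrr_obs), len(baf_obs)))
            if len(lrr_obs) and len(baf_obs)
            else int(max(len(lrr_obs), len(baf_obs))),
        )
    auto = [
        s for c, s in summaries.items()
        if c in AUTOSOMES and s.n_markers >= min_markers
    ]
    if len(auto) >= 3:
        lrr_vals = np.array([s.lrr_mean for s in auto])
        het_vals = np.array([s.baf_het_rate for s in auto])
        for s in summaries.values():
            if s.n_markers < min_markers:
                continue
            if s.chrom in AUTOSOMES:
                i = next(j for j, a in enumerate(auto) if a is s)
                ref_l = np.delete(lrr_vals, i)
                ref_h = np.delete(het_vals, i)
            elif s.chrom == "X":
                ref_l, ref_h = lrr_vals, het_vals
            else:
                continue  # Y is judged on its absolute LRR only
            s.z_lrr = _z(s.lrr_mean, ref_l)
            s.z_het = _z(s.baf_het_rate, ref_h)
    return list(summaries.values())


def _z(x: float, ref: np.ndarray) -> float:
    mu = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1))
    if sd < 1e-12:
        return 0.0 if abs(x - mu) < 1e-12 else math.copysign(math.inf, x - mu)
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# sex prediction
# ---------------------------------------------------------------------------


def predict_sex(
    summaries: list[ChromSummary],
    reported_sex: str | None = None,
    thresholds: AnomalyThresholds = DEFAULT_THRESHOLDS,
) -> SexCall:
    """Two independent sex predictions (X BAF-het rate, Y LRR mean), combined.

    Discordance with a reported sex is flagged, never auto-corrected.
    """
    t = thresholds
    by_chrom = {s.chrom: s for s in summaries}
    sid = summaries[0].sample_id
    x = by_chrom.get("X")
    y = by_chrom.get("Y")
    if x is None or x.n_markers == 0 or math.isnan(x.baf_het_rate):
        return SexCall(sid, "undetermined", "undetermined", "undetermined",
                       math.nan, math.nan, math.nan, reported_sex, None)
    x_pred = "single_X" if x.baf_het_rate < t.het_x_threshold else "double_X_or_more"
    if y is None or y.n_markers == 0 or math.isnan(y.lrr_mean):
        y_pred = "undetermined"
    else:
        y_pred = "Y_present" if y.lrr_mean > t.y_lrr_threshold else "Y_absent"
    x_dosage_z = x.z_lrr
    combined = {
        ("double_X_or_more", "Y_absent"): "XX",
        ("double_X_or_more", "Y_present"): "XXY",
        ("single_X", "Y_present"): "XY",
        ("single_X", "Y_absent"): "X",
    }.get((x_pred, y_pred), "undetermined")
    if combined == "XX" and not math.isnan(x_dosage_z) and x_dosage_z > t.xxx_dosage_z:
        combined = "XXX_candidate"
    concordant = None
    if reported_sex is not None:
        expected = {"female": "XX", "male": "XY"}.get(reported_sex)
        concordant = combined == expected
    return SexCall(
        sample_id=sid, x_pred=x_pred, y_pred=y_pred, combined=combined,
        x_het_rate=x.baf_het_rate,
        y_lrr_mean=y.lrr_mean if y is not None else math.nan,
        x_dosage_z=x_dosage_z,
        reported_sex=reported_sex, concordant_with_reported=concordant,
    )


# ---------------------------------------------------------------------------
# mosaic fraction from band deviation
# ---------------------------------------------------------------------------


def estimate_mosaic_fraction(band_deviation: float, klass: str) -> float:
    """Invert the BAF band-displacement model to a cell fraction.

    Monosomy mosaics: d = f/(2*(2-f)) => f = 4d/(1+2d).
    Trisomy/triploid mosaics: d = f/(2*(2+f)) => f = 4d/(1-2d), capped at 1.
    """
    d = band_deviation
    if not 0.0 <= d <= 0.5:
        raise ValueError(f"band deviation {d} outside [0, 0.5]")
    if klass in ("mosaic_monosomy", "monosomy_mosaic", "monosomy"):
        return 4.0 * d / (1.0 + 2.0 * d)
    if klass in ("mosaic_trisomy", "trisomy_mosaic", "triploid_mosaic", "trisomy"):
        if d >= 0.5:
            return 1.0
        return min(4.0 * d / (1.0 - 2.0 * d), 1.0)
    raise ValueError(f"{klass!r} is not a mosaic class")


def band_deviation(
    baf: np.ndarray, thresholds: AnomalyThresholds = DEFAULT_THRESHOLDS
) -> tuple[float, float]:
    """(median |BAF - 0.5| over band-informative markers, informative fraction).

    Markers inside the informative window belong to the (possibly split)
    heterozygous band; homozygous clusters hug 0/1 and are excluded. Returns
    (nan, frac) when too few markers are informative to place a band.
    """
    lo, hi = thresholds.informative_window
    obs = baf[~np.isnan(baf)]
    if len(obs) == 0:
        return math.nan, 0.0
    inside = obs[(obs >= lo) & (obs <= hi)]
    frac = len(inside) / len(obs)
    if frac < thresholds.min_informative_frac or len(inside) < 10:
        return math.nan, frac
    return float(np.median(np.abs(inside - 0.5))), frac


# ---------------------------------------------------------------------------
# decision table
# ---------------------------------------------------------------------------


def classify_anomaly(
    summaries: list[ChromSummary],
    profile: IntensityProfile,
    thresholds: AnomalyThresholds = DEFAULT_THRESHOLDS,
    sex_call: SexCall | None = None,
) -> list[AnomalyCall]:
    """Run the evidence decision table over one sample's chromosomes.

    Autosomes are always classified; X is classified only for a sample whose
    combined sex call is XX (a diploid-X baseline), so hemizygous male X is
    never mistaken for monosomy; Y is covered by the sex call. A genome-wide
    diploid/triploid mosaic (band split at near-normal LRR on many autosomes)
    is emitted as a single ``genome-wide`` call.
    """
    t = thresholds
    mmap = profile.map_ref
    sid = profile.sample_id
    if sex_call is None:
        sex_call = predict_sex(summaries, thresholds=t)
    by_chrom = {s.chrom: s for s in summaries}
    dev: dict[str, tuple[float, float]] = {}
    for chrom in mmap.chromosomes:
        dev[chrom] = band_deviation(profile.baf[mmap.chrom_slice(chrom)], t)

    calls: list[AnomalyCall] = []

    # genome-wide triploid mosaic: many autosomes split at near-diploid LRR
    split_autosomes = [
        c for c in AUTOSOMES
        if c in by_chrom
        and not math.isnan(dev[c][0]) and dev[c][0] >= t.d_min
        and not math.isnan(by_chrom[c].z_lrr) and abs(by_chrom[c].z_lrr) < t.z_aneuploidy
    ]
    triploid = len(split_autosomes) >= t.g_min
    if triploid:
        d_med = float(np.median([dev[c][0] for c in split_autosomes]))
        calls.append(
            AnomalyCall(
                sample_id=sid, chrom=GENOME_WIDE, klass="triploid_mosaic",
                mosaic_fraction_hat=estimate_mosaic_fraction(d_med, "triploid_mosaic"),
                band_deviation=d_med,
            )
        )

    classify_x = sex_call.combined == "XX"
    for chrom in mmap.chromosomes:
        if chrom == "Y" or (chrom == "X" and not classify_x):
            continue
        s = by_chrom[chrom]
        if math.isnan(s.z_lrr):
            continue
        if triploid and chrom in split_autosomes:
            calls.append(AnomalyCall(sid, chrom, "normal",
                                     z_lrr=s.z_lrr, z_het=s.z_het,
                                     band_deviation=dev[chrom][0]))
            continue
        calls.append(
            _classify_one(sid, chrom, s, dev[chrom], profile, mmap, t)
        )
    return calls


def _classify_one(
    sid: str,
    chrom: str,
    s: ChromSummary,
    dev: tuple[float, float],
    profile: IntensityProfile,
    mmap: MarkerMap,
    t: AnomalyThresholds,
) -> AnomalyCall:
    d_hat, inf_frac = dev
    base = dict(sample_id=sid, chrom=chrom, z_lrr=s.z_lrr, z_het=s.z_het,
                band_deviation=d_hat)

    # UPD: diploid LRR with chromosome-wide loss of heterozygosity
    if chrom in AUTOSOMES and abs(s.z_lrr) <= t.z_cn and s.z_het <= -t.z_het:
        het = _het_indicator(profile, mmap, chrom, t)
        run = _terminal_het_run(het, t)
        if run > 0.6 * len(het):
            # "recovery" spanning most of the chromosome is just normal
            # heterozygosity, not a UPD with distal recombination
            run = 0
        core = het[:-run] if run > 0 else het
        core_rate = float(np.mean(core)) if len(core) else 0.0
        if core_rate < t.upd_het_max:
            if run >= t.r_min:
                return AnomalyCall(klass="upd_partial_recovery", **base)
            return AnomalyCall(klass="upd_complete", **base)
        return AnomalyCall(klass="normal",
                           warning="het depressed without full LOH", **base)

    if s.z_lrr > t.z_aneuploidy:
        if not math.isnan(d_hat) and d_hat >= t.d_min:
            f_hat = estimate_mosaic_fraction(min(d_hat, 0.5), "mosaic_trisomy")
            if f_hat >= t.full_fraction:
                return AnomalyCall(klass="trisomy", **base)
            return AnomalyCall(klass="mosaic_trisomy",
                               mosaic_fraction_hat=f_hat, **base)
        if inf_frac < t.min_informative_frac:
            # LRR says gain but the het band has collapsed: contradictory
            return AnomalyCall(klass="trisomy",
                               warning="LRR gain with BAF het collapse", **base)
        return AnomalyCall(klass="normal",
                           warning="LRR z excursion without BAF support", **base)

    if s.z_lrr < -t.z_aneuploidy:
        if inf_frac < t.min_informative_frac:
            return AnomalyCall(klass="monosomy", **base)
        if not math.isnan(d_hat) and d_hat >= t.d_min:
            f_hat = estimate_mosaic_fraction(min(d_hat, 0.5), "mosaic_monosomy")
            if f_hat >= t.full_fraction:
                return AnomalyCall(klass="monosomy", **base)
            return AnomalyCall(klass="mosaic_monosomy",
                               mosaic_fraction_hat=f_hat, **base)
        return AnomalyCall(klass="normal",
                           warning="LRR z excursion without BAF support", **base)

    return AnomalyCall(klass="normal", **base)


def _het_indicator(
    profile: IntensityProfile, mmap: MarkerMap, chrom: str, t: AnomalyThresholds
) -> np.ndarray:
    lo, hi = t.het_window
    baf = profile.baf[mmap.chrom_slice(chrom)]
    obs = baf[~np.isnan(baf)]
    return ((obs >= lo) & (obs <= hi)).astype(float)


def _terminal_het_run(het: np.ndarray, t: AnomalyThresholds) -> int:
    """q-terminal marker run over which heterozygosity has resumed.

    The boundary k maximizes (het count in last k markers) minus
    ``terminal_het_rate * k`` — the changepoint where local het density
    drops below the threshold rate; 0 when no suffix is het-enriched.
    """
    if len(het) == 0:
        return 0
    csum = np.cumsum(het[::-1])
    k = np.arange(1, len(het) + 1)
    obj = csum - t.terminal_het_rate * k
    best = int(np.argmax(obj))
    return best + 1 if obj[best] > 0 else 0


# ---------------------------------------------------------------------------
# sample-level karyotype label
# ---------------------------------------------------------------------------


def classify_karyotype(
    profile: IntensityProfile,
    thresholds: AnomalyThresholds = DEFAULT_THRESHOLDS,
    reported_sex: str | None = None,
) -> tuple[str, SexCall, list[AnomalyCall]]:
    """Combine sex call and anomaly calls into one karyotype-class label.

    Precedence: genome-wide triploid mosaic > UPD > autosomal aneuploidy or
    mosaic > X mosaic monosomy (45,X/46,XX) > plain sex karyotype.
    """
    summaries = summarize_chromosomes(profile, thresholds.het_window,
                                      thresholds.min_markers)
    sex = predict_sex(summaries, reported_sex, thresholds)
    anomalies = classify_anomaly(summaries, profile, thresholds, sex)
    label = _karyotype_label(sex, anomalies)
    return label, sex, anomalies


def _karyotype_label(sex: SexCall, anomalies: list[AnomalyCall]) -> str:
    abnormal = [a for a in anomalies if a.klass != "normal"]
    for a in abnormal:
        if a.klass == "triploid_mosaic":
            return "diploid_triploid"
    for a in abnormal:
        if a.klass == "upd_complete":
            return f"upd_complete_{a.chrom}"
        if a.klass == "upd_partial_recovery":
            return f"upd_partial_{a.chrom}"
    for a in abnormal:
        if a.chrom != "X" and a.klass in ("trisomy", "monosomy",
                                          "mosaic_trisomy", "mosaic_monosomy"):
            return f"{_KLASS_TAG[a.klass]}_{a.chrom}"
    for a in abnormal:
        if a.chrom == "X" and a.klass == "mosaic_monosomy":
            return "45,X/46,XX"
    return {
        "XX": "46,XX", "XY": "46,XY", "X": "45,X",
        "XXY": "47,XXY", "XXX_candidate": "47,XXX",
    }.get(sex.combined, sex.combined)


_KLASS_TAG = {
    "trisomy": "trisomy", "monosomy": "monosomy",
    "mosaic_trisomy": "trisomy_mosaic", "mosaic_monosomy": "monosomy_mosaic",
}


def plot_sample_evidence(profile: IntensityProfile, path: str) -> None:
    """Write the standard two-panel (LRR, BAF) genome plot for human review."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mmap = profile.map_ref
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(12, 5), sharex=True)
    x = np.arange(len(mmap))
    ax1.scatter(x, profile.lrr, s=1, c="steelblue")
    ax1.set_ylabel("LRR")
    ax2.scatter(x, profile.baf, s=1, c="firebrick")
    ax2.set_ylabel("BAF")
    ax2.set_xlabel("marker index (genome order)")
    for chrom in mmap.chromosomes:
        sl = mmap.chrom_slice(chrom)
        ax1.axvline(sl.start, color="grey", lw=0.3)
        ax2.axvline(sl.start, color="grey", lw=0.3)
    fig.suptitle(profile.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
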