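"""Detector behaviour on simulated ground truth: summaries, sex calls,
the anomaly decision table and the mosaic-fraction estimator."""

import math

import numpy as np
import pytest

from karyocnv.chrom_anomaly import (
    DEFAULT_THRESHOLDS,
    classify_anomaly,
    classify_karyotype,
    estimate_mosaic_fraction,
    predict_sex,
    summarize_chromosomes,
)
from karyocnv.io_formats import AUTOSOMES, MarkerMap
from karyocnv.synthetic_array import (
    GENOME_WIDE,
    KaryotypeSpec,
    MosaicSpec,
    NoiseModel,
    simulate_sample,
)


def _calls_by_chrom(profile):
    summaries = summarize_chromosomes(profile)
    sex = predict_sex(summaries)
    return {a.chrom: a for a in classify_anomaly(summaries, profile, sex_call=sex)}


class TestSummaries:
    def test_diploid_sample_rarely_flags(self, small_map, small_paf):
        """The 3 SD rule alone flags occasionally; anomaly calls never fire
        on clean diploid data (BAF evidence vetoes lone LRR excursions)."""
        n_flags = 0
        for seed in range(20):
            p = simulate_sample(KaryotypeSpec("XX"), small_map, seed=seed,
                                paf=small_paf, sample_id=f"D{seed}")
            summaries = summarize_chromosomes(p)
            for s in summaries:
                if s.chrom in AUTOSOMES and abs(s.z_lrr) > 3:
                    n_flags += 1
        # ~0.7% per autosome under the t-like null: a handful across 420
        assert n_flags <= 12

    def test_trisomy_21_flags_only_chr21(self, small_map, small_paf):
        spec = KaryotypeSpec("XX",
                             mosaic=MosaicSpec("trisomy_mosaic", "21", 1.0))
        p = simulate_sample(spec, small_map, seed=1, paf=small_paf)
        summaries = {s.chrom: s for s in summarize_chromosomes(p)}
        assert summaries["21"].z_lrr > 3
        others = [s.z_lrr for c, s in summaries.items()
                  if c in AUTOSOMES and c != "21"]
        assert max(abs(z) for z in others) < max(abs(z) for z in [summaries["21"].z_lrr])

    def test_upd_het_rate_zero_noiseless(self, small_map, small_paf):
        spec = KaryotypeSpec("XX", upd_chromosomes=(("4", 0.0),))
        p = simulate_sample(spec, small_map, NoiseModel(baf_sd=1e-12),
                            seed=2, paf=small_paf)
        summaries = {s.chrom: s for s in summarize_chromosomes(p)}
        assert summaries["4"].baf_het_rate == 0.0

    def test_empty_profile_rejected(self, small_map):
        from karyocnv.io_formats import IntensityProfile
        p = IntensityProfile("E", np.full(len(small_map), np.nan),
                             np.full(len(small_map), np.nan), small_map)
        with pytest.raises(ValueError, match="observed"):
            summarize_chromosomes(p)

    def test_marker_order_invariance(self, small_paf):
        """A map given in shuffled row order sorts identically, so summaries
        and the sex call do not depend on input marker order."""
        rng = np.random.default_rng(0)
        n = 400
        chroms = np.array(["1"] * 150 + ["2"] * 150 + ["X"] * 80 + ["Y"] * 20,
                          dtype=object)
        pos = np.concatenate([
            np.sort(rng.choice(10**7, 150, replace=False)) + 1,
            np.sort(rng.choice(10**7, 150, replace=False)) + 1,
            np.sort(rng.choice(10**7, 80, replace=False)) + 1,
            np.sort(rng.choice(10**7, 20, replace=False)) + 1,
        ])
        ids = np.array([f"m{i}" for i in range(n)], dtype=object)
        perm = rng.permutation(n)
        m_sorted = MarkerMap(ids, chroms, pos)
        m_shuffled = MarkerMap(ids[perm], chroms[perm], pos[perm])
        assert list(m_sorted.marker_id) == list(m_shuffled.marker_id)
        spec = KaryotypeSpec("XY")
        p1 = simulate_sample(spec, m_sorted, seed=3)
        p2 = simulate_sample(spec, m_shuffled, seed=3)
        s1 = predict_sex(summarize_chromosomes(p1))
        s2 = predict_sex(summarize_chromosomes(p2))
        assert s1.combined == s2.combined == "XY"


class TestPredictSex:
    @pytest.mark.parametrize("karyotype,expected", [
        ("XX", "XX"), ("XY", "XY"), ("X", "X"), ("XXY", "XXY"),
    ])
    def test_sex_karyotypes(self, small_map, small_paf, karyotype, expected):
        hits = 0
        for seed in range(20):
            p = simulate_sample(KaryotypeSpec(karyotype), small_map,
                                seed=seed, paf=small_paf)
            sex = predict_sex(summarize_chromosomes(p))
            hits += sex.combined == expected
        assert hits == 20

    def test_xxx_candidate_by_x_dosage(self, small_map, small_paf):
        p = simulate_sample(KaryotypeSpec("XXX"), small_map, seed=0, paf=small_paf)
        sex = predict_sex(summarize_chromosomes(p))
        assert sex.combined == "XXX_candidate"
        assert sex.x_dosage_z > DEFAULT_THRESHOLDS.xxx_dosage_z

    def test_discordance_flagged_not_corrected(self, small_map, small_paf):
        p = simulate_sample(KaryotypeSpec("X"), small_map, seed=1, paf=small_paf)
        sex = predict_sex(summarize_chromosomes(p), reported_sex="female")
        assert sex.combined == "X"
        assert sex.concordant_with_reported is False

    def test_missing_sex_chromosomes_undetermined(self):
        rng = np.random.default_rng(1)
        mm = MarkerMap(
            np.array([f"m{i}" for i in range(100)], dtype=object),
            np.array(["1"] * 100, dtype=object),
            np.sort(rng.choice(10**7, 100, replace=False)) + 1,
        )
        p = simulate_sample(KaryotypeSpec("XX"), mm, seed=0)
        sex = predict_sex(summarize_chromosomes(p))
        assert sex.combined == "undetermined"


class TestDecisionTable:
    def test_complete_upd_chr4_only(self, small_map, small_paf):
        spec = KaryotypeSpec("XX", upd_chromosomes=(("4", 0.0),))
        p = simulate_sample(spec, small_map, seed=3, paf=small_paf)
        calls = _calls_by_chrom(p)
        assert calls["4"].klass == "upd_complete"
        assert all(a.klass == "normal" for c, a in calls.items() if c != "4")

    def test_partial_recovery_upd_chr21(self, dense_map, dense_paf):
        spec = KaryotypeSpec("XY", upd_chromosomes=(("21", 0.2),))
        hits = 0
        for seed in range(5):
            p = simulate_sample(spec, dense_map, seed=seed, paf=dense_paf)
            calls = _calls_by_chrom(p)
            hits += calls["21"].klass == "upd_partial_recovery"
        assert hits == 5

    def test_diploid_all_normal(self, small_map, small_paf):
        p = simulate_sample(KaryotypeSpec("XY"), small_map, seed=4, paf=small_paf)
        assert all(a.klass == "normal" for a in _calls_by_chrom(p).values())

    def test_triploid_mosaic_genome_wide_call(self, dense_map, dense_paf):
        spec = KaryotypeSpec(
            "XX", mosaic=MosaicSpec("triploid_mosaic", GENOME_WIDE, 0.5)
        )
        p = simulate_sample(spec, dense_map, seed=5, paf=dense_paf)
        summaries = summarize_chromosomes(p)
        calls = classify_anomaly(summaries, p)
        gw = [a for a in calls if a.chrom == "genome-wide"]
        assert len(gw) == 1 and gw[0].klass == "triploid_mosaic"
        assert abs(gw[0].mosaic_fraction_hat - 0.5) < 0.1

    def test_x_mosaic_monosomy_detected_for_female(self, dense_map, dense_paf):
        spec = KaryotypeSpec("XX", mosaic=MosaicSpec("monosomy_mosaic", "X", 0.5))
        p = simulate_sample(spec, dense_map, seed=6, paf=dense_paf)
        label, sex, anoms = classify_karyotype(p)
        assert label == "45,X/46,XX"
        x = next(a for a in anoms if a.chrom == "X")
        assert x.klass == "mosaic_monosomy"
        assert abs(x.mosaic_fraction_hat - 0.5) < 0.08

    def test_male_hemizygous_x_not_flagged(self, small_map, small_paf):
        p = simulate_sample(KaryotypeSpec("XY"), small_map, seed=7, paf=small_paf)
        calls = _calls_by_chrom(p)
        assert "X" not in calls  # X skipped for non-XX sex calls
        assert "Y" not in calls


class TestMosaicFraction:
    def test_closed_form_inverse(self):
        # monosomy: d = f/(2(2-f)); at f=0.5 the bands sit at 1/3 and 2/3
        assert estimate_mosaic_fraction(1 / 6, "mosaic_monosomy") == pytest.approx(0.5)
        assert estimate_mosaic_fraction(0.0, "mosaic_monosomy") == 0.0
        assert estimate_mosaic_fraction(0.5, "mosaic_monosomy") == pytest.approx(1.0)
        # trisomy: d = f/(2(2+f)); full trisomy bands at 1/3, 2/3 => d = 1/6
        assert estimate_mosaic_fraction(1 / 6, "mosaic_trisomy") == pytest.approx(1.0)

    def test_monotone_in_f(self):
        ds = np.linspace(0, 0.5, 21)
        fs = [estimate_mosaic_fraction(d, "mosaic_monosomy") for d in ds]
        assert np.all(np.diff(fs) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="band deviation"):
            estimate_mosaic_fraction(0.6, "mosaic_monosomy")
        with pytest.raises(ValueError, match="mosaic class"):
            estimate_mosaic_fraction(0.1, "normal")

    def test_recovery_at_moderate_fraction(self, dense_map, dense_paf):
        f = 0.4
        errs = []
        for seed in range(5):
            spec = KaryotypeSpec("XY",
                                 mosaic=MosaicSpec("monosomy_mosaic", "9", f))
            p = simulate_sample(spec, dense_map, seed=seed, paf=dense_paf)
            calls = _calls_by_chrom(p)
            assert calls["9"].klass == "mosaic_monosomy"
            errs.append(abs(calls["9"].mosaic_fraction_hat - f))
        assert np.mean(errs) <= 0.05
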