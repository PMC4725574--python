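"""Consensus merging, filter tiers, rarity classes and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from karyocnv.cnv_consensus import (
    ConsensusCnv,
    QcThresholds,
    annotate,
    classify_rarity,
    filter_tier,
    merge_callsets,
    reciprocal_overlap,
    sample_qc,
)
from karyocnv.io_formats import CnvCall, Region, RegionSet
from karyocnv.synthetic_array import (
    CallErrorModel,
    CohortClass,
    CohortConfig,
    KaryotypeSpec,
    simulate_callsets,
    simulate_cohort,
    simulate_sample,
)


def _call(algo, start=1_000_000, end=2_000_000, cn=1, sid="S", chrom="5", nm=20):
    return CnvCall(sid, chrom, start, end, cn, nm, algo)


def _cons(sid="S", chrom="5", start=1, end=200_000, state="deletion",
          nm=15, support=("a", "b", "c"), genes=-1):
    return ConsensusCnv(sid, chrom, start, end, state, 1 if state == "deletion" else 3,
                        nm, frozenset(support), gene_count=genes)


class TestSampleQc:
    def test_default_noise_sample_passes(self, small_map, small_paf):
        p = simulate_sample(KaryotypeSpec("XX"), small_map, seed=0, paf=small_paf)
        qc = sample_qc(p, {"a": []})
        assert qc.passed and qc.failed_metrics == ()
        assert qc.lrr_sd < 0.25

    def test_noisy_sample_fails_with_metric_cited(self, small_map, small_paf):
        from karyocnv.synthetic_array import NoiseModel
        p = simulate_sample(KaryotypeSpec("XX"), small_map,
                            NoiseModel(lrr_sd=0.6), seed=0, paf=small_paf)
        qc = sample_qc(p, {"a": []})
        assert not qc.passed
        assert any("lrr_sd" in m for m in qc.failed_metrics)

    def test_excess_call_count_fails(self, small_map, small_paf):
        p = simulate_sample(KaryotypeSpec("XX"), small_map, seed=1, paf=small_paf,
                            sample_id="S0")
        calls = [_call("a", sid="S0", start=i * 10_000 + 1, end=i * 10_000 + 5_000)
                 for i in range(100)]
        qc = sample_qc(p, {"a": calls}, QcThresholds(max_call_count=30))
        assert not qc.passed
        assert any("call_count" in m for m in qc.failed_metrics)


class TestMerge:
    def test_identical_calls_full_support(self, small_map):
        sets = {a: [_call(a)] for a in ("p", "q", "i")}
        (m,) = merge_callsets(sets, small_map)
        assert m.support == frozenset({"p", "q", "i"})
        assert (m.start, m.end) == (1_000_000, 2_000_000)

    def test_min_support_drops_singletons(self, small_map):
        sets = {"p": [_call("p")], "q": [], "i": []}
        assert merge_callsets(sets, small_map, min_support=3) == []
        assert len(merge_callsets(sets, small_map, min_support=1)) == 1

    def test_mixed_states_never_merge(self, small_map):
        sets = {"p": [_call("p", cn=1)], "q": [_call("q", cn=3)]}
        merged = merge_callsets(sets, small_map)
        assert len(merged) == 2
        assert {m.state for m in merged} == {"deletion", "duplication"}

    def test_strict_rule_is_intersection(self, small_map):
        sets = {
            "p": [_call("p", start=1_000_000, end=2_000_000)],
            "q": [_call("q", start=1_200_000, end=2_400_000)],
        }
        (m,) = merge_callsets(sets, small_map)
        assert (m.start, m.end) == (1_200_000, 2_000_000)
        (outer,) = merge_callsets(sets, small_map, boundary_rule="outer")
        assert (outer.start, outer.end) == (1_000_000, 2_400_000)

    def test_jittered_callsets_recover_truth(self, small_map):
        classes = [
            CohortClass(
                "carrier",
                KaryotypeSpec("XX", cnvs=(("3", 10_000_000, 50_000_000, 1),)),
                1.0,
            )
        ]
        _, truth = simulate_cohort(CohortConfig(classes, n=15, seed=2), small_map)
        sets = simulate_callsets(
            truth, small_map,
            error=CallErrorModel(fp_rate=0, fn_rate=0, boundary_jitter_sd=5_000),
            seed=3,
        )
        merged = merge_callsets(sets, small_map, min_support=3)
        assert len(merged) == len(truth.cnvs)
        by_sample = {c.sample_id: c for c in merged}
        for calls in sets.values():
            for c in calls:
                m = by_sample[c.sample_id]
                assert c.start <= m.start and m.end <= c.end  # intersection inside

    def test_idempotent_and_order_invariant(self, small_map):
        rng = np.random.default_rng(4)
        calls = []
        for algo in ("p", "q", "i"):
            for _ in range(30):
                start = int(rng.integers(1, 50_000_000))
                end = start + int(rng.integers(10_000, 3_000_000))
                calls.append(_call(algo, start=start, end=end,
                                   cn=int(rng.choice([1, 3])),
                                   sid=f"S{rng.integers(3)}"))
        sets = {a: [c for c in calls if c.algorithm == a] for a in ("p", "q", "i")}
        merged = merge_callsets(sets, small_map)
        # merging the merged set again changes nothing
        as_calls = {
            "x": [CnvCall(m.sample_id, m.chrom, m.start, m.end, m.cn,
                          max(m.n_markers, 1), "x") for m in merged]
        }
        remerged = merge_callsets(as_calls, small_map)
        assert [(m.sample_id, m.start, m.end, m.state) for m in merged] == \
               [(m.sample_id, m.start, m.end, m.state) for m in remerged]
        # reversed input order gives identical output
        sets_rev = {a: list(reversed(v)) for a, v in sets.items()}
        merged_rev = merge_callsets(sets_rev, small_map)
        assert [(m.sample_id, m.start, m.end, m.state, m.support) for m in merged] == \
               [(m.sample_id, m.start, m.end, m.state, m.support) for m in merged_rev]


class TestFilterTier:
    def test_large_tier_bounds(self):
        keep = _cons(start=1, end=1_200_000, nm=150, support=("p",))
        edge = _cons(start=1, end=1_000_000, nm=150, support=("p",))
        few = _cons(start=1, end=1_200_000, nm=100, support=("p",))
        assert filter_tier([keep, edge, few], "large") == [keep]

    def test_phenotype_tier_bounds(self):
        keep = _cons(start=1, end=120_000, nm=10)
        small = _cons(start=1, end=100_000, nm=10)
        unsupported = _cons(start=1, end=120_000, nm=10, support=("p",))
        assert filter_tier([keep, small, unsupported], "phenotype") == [keep]

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError, match="tier"):
            filter_tier([], "huge")


class TestRarity:
    def test_singleton_common_rare(self):
        lone = _cons(sid="A", chrom="7", start=1, end=100_000)
        shared = [
            _cons(sid=f"S{i}", chrom="8", start=1, end=100_000) for i in range(60)
        ]
        out = classify_rarity([lone] + shared, n_samples=100, common_freq=0.01)
        assert out[0].rarity == "singleton"
        assert all(c.rarity == "common" for c in out[1:])

    def test_insufficient_reciprocal_overlap_keeps_separate(self):
        # 40% reciprocal overlap at threshold 0.5: two singletons
        a = _cons(sid="A", start=1, end=100_000)
        b = _cons(sid="B", start=60_001, end=160_000)
        assert reciprocal_overlap(a, b) == pytest.approx(0.4)
        out = classify_rarity([a, b], n_samples=10, overlap_frac=0.5)
        assert [c.rarity for c in out] == ["singleton", "singleton"]

    def test_matches_bruteforce_clustering(self):
        rng = np.random.default_rng(5)
        cnvs = []
        for i in range(120):
            start = int(rng.integers(1, 5_000_000))
            end = start + int(rng.integers(50_000, 1_000_000))
            cnvs.append(
                _cons(sid=f"S{rng.integers(40)}", chrom=str(rng.integers(1, 4)),
                      start=start, end=end,
                      state=str(rng.choice(["deletion", "duplication"])))
            )
        out = classify_rarity(cnvs, n_samples=40, overlap_frac=0.5)
        # brute-force transitive closure over all pairs
        parent = list(range(len(cnvs)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(len(cnvs)):
            for j in range(i + 1, len(cnvs)):
                if cnvs[i].state == cnvs[j].state and \
                        reciprocal_overlap(cnvs[i], cnvs[j]) >= 0.5:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        from collections import defaultdict
        clusters = defaultdict(list)
        for i in range(len(cnvs)):
            clusters[find(i)].append(i)
        for members in clusters.values():
            carriers = len({cnvs[i].sample_id for i in members})
            if len(members) == 1:
                want = "singleton"
            elif carriers / 40 > 0.01:
                want = "common"
            else:
                want = "rare"
            assert all(out[i].rarity == want for i in members)


class TestAnnotate:
    def test_gene_count_and_region_hits(self):
        genes = RegionSet("g", [
            Region("5", s, s + 9_999, f"G{i}")
            for i, s in enumerate([1, 20_000, 40_000, 300_000, 500_000])
        ])
        regions = RegionSet("r", [Region("5", 1, 50_000, "15q13.3")])
        cnv = _cons(start=5_000, end=45_000)
        (out,) = annotate([cnv], genes=genes, regions=regions)
        assert out.gene_count == 3
        assert out.region_hits == ("15q13.3",)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(6)
        genes = RegionSet("g", [
            Region(str(rng.integers(1, 5)), s := int(rng.integers(1, 10**7)),
                   s + int(rng.integers(1_000, 200_000)), f"G{i}")
            for i in range(300)
        ])
        cnvs = []
        for i in range(1000):
            start = int(rng.integers(1, 10**7))
            cnvs.append(_cons(sid=f"S{i}", chrom=str(rng.integers(1, 5)),
                              start=start, end=start + int(rng.integers(10_000, 10**6))))
        out = annotate(cnvs, genes=genes)
        for c_in, c_out in zip(cnvs, out):
            want = sum(
                1 for g in genes
                if g.chrom == c_in.chrom and g.start <= c_in.end and g.end >= c_in.start
            )
            assert c_out.gene_count == want
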