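"""Tests of the consensus merge and the tumor-naive filter cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cfhl.simulate import SimulationConfig, make_rule_violation_cohort, simulate_cohort
from cfhl.variants import (
    AnnotatedVariant,
    CallerVariant,
    FilterConfig,
    PanelOfNormals,
    apply_indel_mnv_rules,
    apply_annotation_filters,
    apply_primary_thresholds,
    build_pon,
    classify_alleles,
    consensus_merge,
    filter_cohort,
    gc_fraction,
    read_caller_vcf,
    run_cascade,
    write_caller_vcf,
)

from oracles import brute_force_filter

EMPTY_PON = PanelOfNormals(frozenset())


def cv(sample="S", caller="c1", chrom="chr1", pos=100, ref="A", alt="T",
       depth=500, alt_depth=25, bq=35.0):
    return CallerVariant(sample_id=sample, caller_id=caller, chrom=chrom, pos=pos,
                         ref=ref, alt=alt, read_depth=depth, alt_depth=alt_depth,
                         vaf=alt_depth / depth, base_quality=bq)


def av(**kw):
    base = dict(sample_id="S", chrom="chr1", pos=100, ref="A", alt="T",
                callers=("c1",), vaf=0.05, read_depth=500, alt_depth=25,
                base_quality=35.0)
    base.update(kw)
    base.setdefault("variant_class", classify_alleles(base["ref"], base["alt"]))
    return AnnotatedVariant(**base)


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "T", "SNV"),
            ("AC", "GT", "MNV"),
            ("ACG", "TGA", "MNV"),
            ("A", "AT", "InDel"),
            ("AGG", "A", "InDel"),
            ("A" * 25, "C" * 25, "InDel"),  # equal-length but too long for an MNV
        ],
    )
    def test_variant_class(self, ref, alt, expected):
        assert classify_alleles(ref, alt) == expected

    def test_gc_of_indel_computed_on_inserted_bases(self):
        v = av(ref="A", alt="A" + "GCGC")
        assert v.gc_content == 1.0
        v = av(ref="A" + "ATAT", alt="A")
        assert v.gc_content == 0.0
        assert gc_fraction("") == 0.0

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            cv(ref="A", alt="A")
        with pytest.raises(ValueError):
            cv(depth=10, alt_depth=11)


class TestConsensusMerge:
    def test_median_vaf_of_four_callers(self):
        records = [
            cv(caller=f"c{i}", alt_depth=ad, depth=1000)
            for i, ad in enumerate([30, 40, 50, 60])
        ]
        merged = consensus_merge(records)
        assert len(merged) == 1
        assert merged[0].vaf == pytest.approx(0.045)
        assert merged[0].callers == ("c0", "c1", "c2", "c3")

    def test_disjoint_loci_both_emitted(self):
        merged = consensus_merge([cv(caller="c1", pos=100), cv(caller="c2", pos=200)])
        assert [(m.pos, m.callers) for m in merged] == [(100, ("c1",)), (200, ("c2",))]

    def test_depth_from_deepest_record(self):
        merged = consensus_merge(
            [cv(caller="c1", depth=300, alt_depth=10), cv(caller="c2", depth=900, alt_depth=40)]
        )
        assert merged[0].read_depth == 900 and merged[0].alt_depth == 40

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            consensus_merge([cv(sample="A"), cv(sample="B")])

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["c1", "c2", "c3", "c4"]),
                st.integers(min_value=1, max_value=30),
                st.sampled_from(["A", "C"]),
                st.sampled_from(["G", "T"]),
                st.integers(min_value=1, max_value=400),
            ),
            max_size=60,
        )
    )
    def test_merged_loci_equal_union(self, raw):
        records = [
            cv(caller=c, pos=p, ref=r, alt=a, depth=500, alt_depth=min(ad, 500))
            for c, p, r, a, ad in raw
        ]
        merged = consensus_merge(records)
        assert {m.key for m in merged} == {r.key for r in records}
        assert len(merged) == len({m.key for m in merged})


class TestPrimaryThresholds:
    @pytest.mark.parametrize(
        "depth,vaf,alt,bq,expected",
        [
            (100, 0.05, 10, 30, "read_depth"),   # boundary is exclusive
            (101, 0.011, 8, 26, None),           # all strictly above
            (101, 0.01, 8, 26, "vaf"),
            (101, 0.02, 7, 26, "alt_depth"),
            (101, 0.02, 8, 25, "base_quality"),
        ],
    )
    def test_boundaries_strict(self, depth, vaf, alt, bq, expected):
        v = av(read_depth=depth, vaf=vaf, alt_depth=alt, base_quality=bq)
        assert apply_primary_thresholds(v, FilterConfig()) == expected

    @given(
        st.integers(50, 200), st.floats(0.0, 0.05), st.integers(0, 20),
        st.floats(15.0, 35.0),
    )
    def test_matches_one_line_recheck(self, depth, vaf, alt, bq):
        v = av(read_depth=depth, vaf=vaf, alt_depth=min(alt, depth), base_quality=bq)
        decision = apply_primary_thresholds(v, FilterConfig())
        ok = depth > 100 and vaf > 0.01 and min(alt, depth) > 7 and bq > 25
        assert (decision is None) == ok


class TestPanelOfNormals:
    def test_union_of_disjoint_singletons(self):
        controls = [[cv(sample=f"C{i}", pos=100 + i)] for i in range(7)]
        assert len(build_pon(controls)) == 7

    def test_shared_locus_counted_once(self):
        pon = build_pon([[cv(sample="C1", pos=5)], [cv(sample="C2", pos=5)]])
        assert len(pon) == 1

    def test_zero_controls_is_an_error(self):
        with pytest.raises(ValueError):
            build_pon([])

    def test_pon_from_synthetic_controls_equals_planted_loci(self, small_cohort):
        truth, bundle = small_cohort
        control_records = [
            [r for recs in by_caller.values() for r in recs]
            for by_caller in bundle.controls.values()
        ]
        pon = build_pon(control_records)
        planted = {
            v.key for vs in truth.controls.values() for v in vs
        }
        assert pon.loci <= planted  # callers drop, never invent


class TestMnvOverlap:
    def _cascade_status(self, records):
        result = run_cascade(records, EMPTY_PON, None, FilterConfig())
        return {v.key: v.filter_status for v in result.variants}

    def test_snv_inside_foreign_mnv_removed(self):
        records = [
            cv(caller="c1", pos=105),
            cv(caller="c2", pos=104, ref="ACG", alt="TGA"),
        ]
        status = self._cascade_status(records)
        assert status[("chr1", 105, "A", "T")] == "mnv_overlap"

    def test_adjacent_snv_retained(self):
        records = [
            cv(caller="c1", pos=103),
            cv(caller="c2", pos=104, ref="ACG", alt="TGA"),
        ]
        status = self._cascade_status(records)
        assert status[("chr1", 103, "A", "T")] == "PASS"

    def test_same_caller_mnv_does_not_remove_own_snv(self):
        records = [
            cv(caller="c1", pos=105),
            cv(caller="c1", pos=104, ref="ACG", alt="TGA"),
        ]
        status = self._cascade_status(records)
        assert status[("chr1", 105, "A", "T")] == "PASS"


class TestAnnotationFilters:
    def test_population_af_above_cutoff_removed(self):
        v = av(effect_class="coding_nonsynonymous", gnomad_af=0.002)
        assert apply_annotation_filters(v, FilterConfig()) == "population_af"

    def test_high_vaf_listed_removed(self):
        v = av(vaf=0.25, gnomad_af=1e-6, effect_class="coding_nonsynonymous")
        assert apply_annotation_filters(v, FilterConfig()) == "high_vaf_in_population_db"

    def test_high_vaf_unlisted_retained(self):
        v = av(vaf=0.25, effect_class="coding_nonsynonymous")
        assert apply_annotation_filters(v, FilterConfig()) is None

    @pytest.mark.parametrize("effect", ["synonymous", "utr5", "utr3", "intronic", "flanking_2kb"])
    def test_nonfunctional_effects_removed(self, effect):
        assert apply_annotation_filters(av(effect_class=effect), FilterConfig()) == "functional_effect"

    def test_effect_filter_disregarded_in_tracking_mode(self):
        cfg = FilterConfig.followup()
        assert apply_annotation_filters(av(effect_class="synonymous"), cfg) is None

    def test_af_zero_listed_does_not_trigger_high_vaf(self):
        v = av(vaf=0.25, gnomad_af=0.0, effect_class="coding_nonsynonymous")
        assert apply_annotation_filters(v, FilterConfig()) is None


class TestIndelRules:
    def test_long_gc_rich_insertion_removed(self):
        v = av(ref="A", alt="A" + "G" * 10 + "C" * 5)  # 15 bp, GC 100%
        assert apply_indel_mnv_rules(v, FilterConfig()) == "indel_gc"

    def test_very_long_deletion_removed_regardless_of_gc(self):
        v = av(ref="A" + "T" * 25, alt="A")  # 25 bp, AT-rich
        assert apply_indel_mnv_rules(v, FilterConfig()) == "indel_length"

    def test_equal_length_substitution_kept_as_mnv(self):
        v = av(ref="ACG", alt="TGA", variant_class=classify_alleles("ACG", "TGA"))
        assert v.variant_class == "MNV"
        assert apply_indel_mnv_rules(v, FilterConfig()) is None

    def test_short_at_insertion_kept(self):
        v = av(ref="A", alt="A" + "AT" * 6)  # 12 bp, GC 0%
        assert apply_indel_mnv_rules(v, FilterConfig()) is None


class TestCosmicRecurrence:
    def _cohort(self, in_cosmic, n_patients=3):
        records = {
            f"S{i}": [cv(sample=f"S{i}", pos=100)] for i in range(n_patients)
        }
        ann = pd.DataFrame(
            [{"chrom": "chr1", "pos": 100, "ref": "A", "alt": "T", "gene": "B2M",
              "effect_class": "coding_nonsynonymous", "gnomad_af": np.nan,
              "kg_af": np.nan, "cosmic": in_cosmic}]
        )
        baseline = {f"S{i}": f"P{i}" for i in range(n_patients)}
        return filter_cohort(records, EMPTY_PON, ann, baseline)

    def test_recurrent_non_cosmic_removed_everywhere(self):
        result = self._cohort(in_cosmic=False)
        for sid, r in result.results.items():
            assert r.variants[0].filter_status == "cosmic_recurrence"

    def test_cosmic_rescues_recurrent_variant(self):
        result = self._cohort(in_cosmic=True)
        assert all(r.variants[0].passed for r in result.results.values())

    def test_unique_variant_retained(self):
        result = self._cohort(in_cosmic=False, n_patients=1)
        assert result.results["S0"].variants[0].passed


class TestCascade:
    def test_per_rule_removal_counts_equal_planted_violations(self):
        k = 4
        records, pon_records, ann, baseline, expected = make_rule_violation_cohort(k=k, seed=2)
        pon = build_pon([pon_records])
        result = filter_cohort(records, pon, ann, baseline)
        counts = result.rule_counts()
        for rule, n in expected.items():
            assert counts.get(rule, 0) == n, f"rule {rule}: {counts.get(rule, 0)} != {n}"
        # MNV companions and the clean PASS variants survive
        assert sum(len(r.passed) for r in result.results.values()) == 3 * k

    def test_empty_input_empty_output(self):
        result = run_cascade([], EMPTY_PON, None, FilterConfig())
        assert result.variants == [] and result.passed == []
        assert (result.audit_table().removed_count == 0).all()

    def test_audit_completeness(self, small_cohort):
        truth, bundle = small_cohort
        sample = bundle.samples[0]
        records = [r for recs in sample.caller_records.values() for r in recs]
        result = run_cascade(records, EMPTY_PON, bundle.annotations, FilterConfig())
        input_keys = {r.key for r in records}
        audited = [v.key for v in result.variants]
        assert sorted(set(audited)) == sorted(audited)  # exactly once
        assert set(audited) == input_keys
        for v in result.variants:
            assert v.filter_status == "PASS" or v.filter_status in v.rule_trace

    def test_order_insensitivity(self, small_cohort, rng):
        truth, bundle = small_cohort
        sample = bundle.samples[1]
        records = [r for recs in sample.caller_records.values() for r in recs]
        shuffled = list(records)
        rng.shuffle(shuffled)
        r1 = run_cascade(records, EMPTY_PON, bundle.annotations, FilterConfig())
        r2 = run_cascade(shuffled, EMPTY_PON, bundle.annotations, FilterConfig())
        assert {v.key for v in r1.passed} == {v.key for v in r2.passed}

    def test_cascade_idempotent(self, small_cohort):
        truth, bundle = small_cohort
        sample = bundle.samples[2]
        records = [r for recs in sample.caller_records.values() for r in recs]
        first = run_cascade(records, EMPTY_PON, bundle.annotations, FilterConfig())
        surviving = [
            r for r in records if r.key in {v.key for v in first.passed}
        ]
        second = run_cascade(surviving, EMPTY_PON, bundle.annotations, FilterConfig())
        assert {v.key for v in second.passed} == {v.key for v in first.passed}

    def test_min_callers_knob(self):
        records = [cv(caller="c1", pos=100), cv(caller="c1", pos=200), cv(caller="c2", pos=200)]
        result = run_cascade(records, EMPTY_PON, None, FilterConfig(min_callers=2))
        status = {v.pos: v.filter_status for v in result.variants}
        assert status[100] == "min_callers" and status[200] == "PASS"


def _random_cohort_records(rng, n_samples=4, n_per_sample=120):
    """Fuzzed multi-caller records on a tiny locus space (forces collisions)."""
    callers = ["c1", "c2", "c3", "c4"]
    alleles = [("A", "T"), ("C", "G"), ("ACG", "TGA"), ("A", "ATTT"),
               ("A", "A" + "GC" * 7), ("A" + "T" * 25, "A"), ("G", "C")]
    records = {}
    ann_rows = {}
    for s in range(n_samples):
        sid = f"S{s}"
        recs = []
        for _ in range(n_per_sample):
            pos = int(rng.integers(1, 60))
            ref, alt = alleles[rng.integers(0, len(alleles))]
            depth = int(rng.integers(50, 3000))
            alt_depth = int(rng.integers(0, depth + 1))
            if rng.random() < 0.7:
                alt_depth = min(depth, int(rng.integers(0, 80)))
            recs.append(
                cv(sample=sid, caller=callers[rng.integers(0, 4)], pos=pos,
                   ref=ref, alt=alt, depth=depth, alt_depth=alt_depth,
                   bq=float(rng.uniform(15, 45)))
            )
            key = ("chr1", pos, ref, alt)
            if key not in ann_rows:
                ann_rows[key] = {
                    "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt,
                    "gene": "SOCS1" if pos % 3 else "B2M",
                    "effect_class": ["coding_nonsynonymous", "synonymous", "intronic"][int(rng.integers(0, 3))],
                    "gnomad_af": [np.nan, 0.0005, 0.01][int(rng.integers(0, 3))],
                    "kg_af": [np.nan, 0.002][int(rng.integers(0, 2))],
                    "cosmic": bool(rng.random() < 0.3),
                }
        records[sid] = recs
    ann = pd.DataFrame(list(ann_rows.values()))
    pon_keys = {("chr1", int(p), "A", "T") for p in rng.integers(1, 60, size=8)}
    return records, ann, pon_keys


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cascade_matches_brute_force(self, seed):
        """The composed cascade equals a monolithic predicate on fuzzed input."""
        rng = np.random.default_rng(seed)
        records, ann, pon_keys = _random_cohort_records(rng)
        pon = PanelOfNormals(frozenset(pon_keys))
        baseline = {sid: f"P{sid}" for sid in records}
        result = filter_cohort(records, pon, ann, baseline)
        ann_dict = {
            (r.chrom, r.pos, r.ref, r.alt): {
                "effect": r.effect_class, "gnomad": r.gnomad_af,
                "kg": r.kg_af, "cosmic": r.cosmic,
            }
            for r in ann.itertuples(index=False)
        }
        expected = brute_force_filter(records, pon_keys, ann_dict, baseline)
        for sid in records:
            got = {v.key for v in result.results[sid].passed}
            assert got == expected[sid]


class TestVcfRoundTrip:
    def test_write_then_read_preserves_records(self, tmp_path):
        records = [
            cv(pos=10, ref="A", alt="T", depth=812, alt_depth=33, bq=31.5),
            cv(pos=20, ref="AC", alt="GT", depth=500, alt_depth=9, bq=28.0),
            cv(pos=30, ref="A", alt="ATTG", depth=1200, alt_depth=60, bq=36.0),
        ]
        path = tmp_path / "S.c1.vcf"
        write_caller_vcf(records, path, caller_id="c1", sample_id="S",
                         contigs={"chr1": 1_000_000})
        back = read_caller_vcf(path)
        assert [(r.key, r.read_depth, r.alt_depth) for r in back] == [
            (r.key, r.read_depth, r.alt_depth) for r in records
        ]
        assert all(b.caller_id == "c1" and b.sample_id == "S" for b in back)
        assert back[0].base_quality == pytest.approx(31.5)

    def test_malformed_record_names_file(self, tmp_path):
        path = tmp_path / "bad.vcf"
        good = tmp_path / "ok.vcf"
        write_caller_vcf([cv()], good, "c1", "S", {"chr1": 1000})
        text = good.read_text().replace("0/1:500:475,25", "0/1:.:475,25")
        path.write_text(text)
        with pytest.raises(ValueError, match="bad.vcf"):
            read_caller_vcf(path)


class TestSyntheticRecovery:
    def test_sensitivity_and_pon_specificity(self, default_cohort):
        """>=95% of well-supported planted somatic variants survive; no
        artifact blacklisted by the panel of normals does."""
        from cfhl import pipeline

        truth, bundle = default_cohort
        analysis = pipeline.analyze_bundle(bundle)
        planted = survived = pon_survivors = 0
        for s in bundle.samples:
            if not s.pretreatment:
                continue
            pt = truth.patients[s.patient_id]
            merged = {v.key: v for v in analysis.filtered.results[s.sample_id].variants}
            passed = {v.key for v in analysis.passed(s.sample_id)}
            for tv in pt.somatic:
                mv = merged.get(tv.key)
                if tv.vaf > 0.02 and mv is not None and mv.read_depth > 200:
                    planted += 1
                    survived += tv.key in passed
            for tv in pt.artifacts:
                if tv.key in analysis.pon.loci and tv.key in passed:
                    pon_survivors += 1
        assert planted > 100
        assert survived / planted >= 0.95
        assert pon_survivors == 0

    def test_zero_tumor_fraction_sample_has_no_somatic_pass(self):
        from cfhl import pipeline

        cfg = SimulationConfig(n_patients=5, seed=9, no_ctdna_prob=1.0,
                               n_followup_patients=0, followup_missing_pre=0)
        truth, bundle = simulate_cohort(cfg)
        analysis = pipeline.analyze_bundle(bundle)
        for s in bundle.samples:
            somatic_keys = {v.key for v in truth.patients[s.patient_id].somatic}
            assert {v.key for v in analysis.passed(s.sample_id)} & somatic_keys == set()
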