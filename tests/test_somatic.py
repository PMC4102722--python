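import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, hypergeom

from mosatwin import somatic as som
from mosatwin.errors import AuditError, ConfigError
from mosatwin.io_formats import VariantRecord

from conftest import make_pileup, random_pileup


def enumeration_oracle(counts_a, counts_b):
    """Independent two-sided Fisher oracle via scipy's hypergeometric pmf."""
    ref_a, alt_a = counts_a
    ref_b, alt_b = counts_b
    n_a, n_b = ref_a + alt_a, ref_b + alt_b
    c_ref = ref_a + ref_b
    n = n_a + n_b
    rv = hypergeom(n, n_a, c_ref)
    support = np.arange(max(0, c_ref - n_b), min(n_a, c_ref) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(ref_a)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestFisher:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((10, 0), (10, 0), 1.0),
            ((10, 0), (5, 5), 0.0325077399),
            ((0, 10), (10, 0), 1.0825088e-05),
        ],
    )
    def test_reference_tables(self, a, b, expected):
        assert som.fisher_allele_test(a, b) == pytest.approx(expected, rel=1e-6)

    def test_matches_enumeration_for_small_margins(self):
        for n_a, n_b in itertools.product(range(1, 9), repeat=2):
            for ref_a in range(n_a + 1):
                for ref_b in range(n_b + 1):
                    a = (ref_a, n_a - ref_a)
                    b = (ref_b, n_b - ref_b)
                    p = som.fisher_allele_test(a, b)
                    assert p == pytest.approx(enumeration_oracle(a, b), rel=1e-9)

    def test_cross_check_against_scipy(self, rng):
        for _ in range(100):
            a = tuple(int(x) for x in rng.integers(0, 60, 2))
            b = tuple(int(x) for x in rng.integers(0, 60, 2))
            if sum(a) == 0 or sum(b) == 0:
                continue
            expected = fisher_exact([[a[0], a[1]], [b[0], b[1]]])[1]
            assert som.fisher_allele_test(a, b) == pytest.approx(expected, rel=1e-7)

    def test_symmetries(self, rng):
        for _ in range(50):
            a = tuple(int(x) for x in rng.integers(0, 30, 2))
            b = tuple(int(x) for x in rng.integers(0, 30, 2))
            if sum(a) == 0 or sum(b) == 0:
                continue
            p = som.fisher_allele_test(a, b)
            assert som.fisher_allele_test(b, a) == p  # swap samples
            assert som.fisher_allele_test(a[::-1], b[::-1]) == p  # swap alleles

    def test_empty_sample_is_undefined(self):
        assert som.fisher_allele_test((0, 0), (5, 5)) is None

    @given(
        a=st.tuples(st.integers(0, 50), st.integers(0, 50)),
        b=st.tuples(st.integers(0, 50), st.integers(0, 50)),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_invariances_hold_for_arbitrary_tables(self, a, b):
        if sum(a) == 0 or sum(b) == 0:
            return
        p = som.fisher_allele_test(a, b)
        assert 0 < p <= 1
        assert som.fisher_allele_test(b, a) == p
        assert som.fisher_allele_test(a[::-1], b[::-1]) == p

    def test_type_i_error_is_controlled(self, rng):
        """On identical-genotype het sites at 40x, P(p < 0.01) <= 0.01."""
        n_sites = 10_000
        hits = 0
        for _ in range(n_sites):
            ka, kb = rng.binomial(40, 0.5, size=2)
            p = som.fisher_allele_test((int(ka), 40 - int(ka)),
                                       (int(kb), 40 - int(kb)))
            hits += p < 0.01
        assert hits / n_sites <= 0.01


class TestSomaticScore:
    def test_identical_deep_homref_scores_zero(self):
        a, b = make_pileup("A" * 50), make_pileup("A" * 50)
        assert som.somatic_score(a, b) == 0

    def test_saturation_at_255(self):
        a = make_pileup("A" * 1000, bq=40)
        b = make_pileup("C" * 1000, bq=40)
        assert som.somatic_score(a, b) == som.SCORE_MAX

    def test_threshold_semantics(self):
        assert som.score_to_difference_probability(100) == pytest.approx(1 - 1e-10)

    def test_nocall_side_gives_no_score_not_zero(self):
        a = make_pileup("A" * 10, mq=5)  # all reads fail the MQ filter
        b = make_pileup("A" * 10)
        assert som.somatic_score(a, b, min_mq=10) is None

    def test_matches_posterior_oracle(self, rng):
        """Score equals the brute-force posterior dot product, rounded/capped."""
        from test_genotyping import linear_space_likelihoods

        for _ in range(50):
            a = random_pileup(rng, int(rng.integers(1, 20)), p_alt=rng.random())
            b = random_pileup(rng, int(rng.integers(1, 20)), p_alt=rng.random())
            raw_a = np.array(list(linear_space_likelihoods(a).values()))
            raw_b = np.array(list(linear_space_likelihoods(b).values()))
            p_same = float((raw_a / raw_a.sum()) @ (raw_b / raw_b.sum()))
            expected = min(255, round(-10 * np.log10(p_same)))
            assert som.somatic_score(a, b) == expected

    def test_monotone_in_vaf_separation(self):
        """Score never decreases as B's alt fraction moves away from A's."""
        depth = 60
        a = make_pileup("A" * depth)
        scores = []
        for n_alt in range(0, depth + 1, 6):
            b = make_pileup("A" * (depth - n_alt) + "C" * n_alt)
            s = som.somatic_score(a, b)
            assert 0 <= s <= 255
            scores.append(s)
        assert all(x <= y for x, y in zip(scores, scores[1:]))


class TestFilteredFisher:
    def test_stacked_alt_reads_are_zeroed(self):
        # 5 alt reads all sharing one start point -> alt count zeroed
        a = make_pileup("A" * 20 + "G" * 5,
                        starts=list(range(1, 21)) + [30] * 5)
        b = make_pileup("A" * 25)
        res = som.filtered_fisher_test(a, b, "G", min_unique_starts=3)
        assert res.counts_a == (20, 0)
        assert res.p_value == 1.0

    def test_reduces_to_raw_fisher_when_nothing_filtered(self):
        a = make_pileup("A" * 10 + "G" * 6)
        b = make_pileup("A" * 16)
        res = som.filtered_fisher_test(a, b, "G", min_bq=20, min_mq=20,
                                       min_unique_starts=3)
        assert res.p_value == som.fisher_allele_test((10, 6), (16, 0))

    def test_low_quality_alt_reads_removed(self):
        a = make_pileup("A" * 20 + "G" * 8, bq=[30] * 20 + [15] * 8)
        b = make_pileup("A" * 28)
        res = som.filtered_fisher_test(a, b, "G", min_bq=20)
        assert res.counts_a == (20, 0) and res.p_value == 1.0


ROLES = {
    "affected_blood": "cd_blood", "affected_biopsy": "cd_biopsy",
    "healthy_blood": "he_blood", "healthy_biopsy": "he_biopsy",
}


def record(pos, carriers, popfreq=None):
    gts = {
        s: (("A", "G") if role in carriers else ("A", "A"))
        for role, s in ROLES.items()
    }
    return VariantRecord("chr1", pos, "A", "G", gts, {},
                         population_frequency=popfreq)


class TestQueryPositionSelection:
    def test_variant_in_all_four_excluded(self):
        recs = [record(10, set(ROLES))]
        assert som.select_query_positions(recs, ROLES) == []

    def test_private_rare_variant_retained(self):
        recs = [record(10, {"affected_blood"}, popfreq=0.01)]
        assert som.select_query_positions(recs, ROLES) == [("chr1", 10)]

    def test_common_variant_excluded(self):
        recs = [record(10, {"affected_blood"}, popfreq=0.5)]
        assert som.select_query_positions(recs, ROLES) == []

    def test_missing_popfreq_passes(self):
        recs = [record(10, {"affected_biopsy"})]
        assert som.select_query_positions(recs, ROLES) == [("chr1", 10)]

    @pytest.mark.parametrize(
        "carriers", [{"affected_biopsy", "healthy_biopsy"},
                     {"affected_blood", "healthy_blood"}]
    )
    def test_cross_twin_shared_tissue_excluded(self, carriers):
        assert som.select_query_positions([record(10, carriers)], ROLES) == []

    def test_bad_roles_config_error(self):
        with pytest.raises(ConfigError):
            som.select_query_positions([], {"affected_blood": "x"})


def two_sample_pileups(pos=100, depth=40, alt_frac_test=0.5, alt_frac_ref=0.0):
    n_alt_t = int(depth * alt_frac_test)
    n_alt_r = int(depth * alt_frac_ref)
    test = make_pileup("A" * (depth - n_alt_t) + "G" * n_alt_t, pos=pos)
    ref = make_pileup("A" * (depth - n_alt_r) + "G" * n_alt_r, pos=pos)
    return {"test": {("chr1", pos): test}, "ref": {("chr1", pos): ref}}


class TestDetectDiscordances:
    def test_clonal_event_flagged_by_all_three_detectors(self):
        pileups = two_sample_pileups()
        calls = som.detect_discordances(pileups, [("test", "ref")])
        passing = {c.detector for c in calls if c.passes_threshold}
        assert passing == {"score", "fisher", "filtered_fisher"}

    def test_zero_p_max_passes_nothing(self):
        pileups = two_sample_pileups()
        thr = som.DetectorThresholds(p_max=0.0, score_min=255)
        calls = som.detect_discordances(pileups, [("test", "ref")], thr)
        assert not any(c.passes_threshold for c in calls
                       if c.detector in ("fisher", "filtered_fisher"))

    def test_fisher_requires_zero_alt_in_reference(self):
        pileups = two_sample_pileups(alt_frac_test=0.5, alt_frac_ref=0.1)
        calls = som.detect_discordances(pileups, [("test", "ref")])
        fisher = [c for c in calls if c.detector == "fisher"]
        assert fisher and not any(c.passes_threshold for c in fisher)

    def test_output_invariant_to_site_order(self, rng):
        pileups = {"test": {}, "ref": {}}
        for pos in [5, 50, 500]:
            pair = two_sample_pileups(pos=pos, alt_frac_test=rng.random() / 2)
            pileups["test"].update(pair["test"])
            pileups["ref"].update(pair["ref"])
        calls1 = som.detect_discordances(pileups, [("test", "ref")])
        shuffled = {
            s: dict(sorted(d.items(), key=lambda kv: -kv[0][1]))
            for s, d in pileups.items()
        }
        calls2 = som.detect_discordances(shuffled, [("test", "ref")])
        assert calls1 == calls2

    def test_unknown_sample_in_plan(self):
        with pytest.raises(ConfigError):
            som.detect_discordances({"a": {}}, [("a", "b")])


class TestMethodOverlap:
    def make_calls(self, detector, positions):
        return [
            som.DiscordanceCall("chr1", p, "t", "r", detector, 1.0, True)
            for p in positions
        ]

    def test_identical_lists_all_in_triple_intersection(self):
        lists = {
            d: self.make_calls(d, range(100))
            for d in ("score", "fisher", "filtered_fisher")
        }
        venn = som.method_overlap(lists)
        assert venn["all_three"] == 100 and venn["union"] == 100

    def test_disjoint_lists_have_empty_intersections(self):
        lists = {
            "score": self.make_calls("score", range(0, 100)),
            "fisher": self.make_calls("fisher", range(100, 200)),
            "filtered_fisher": self.make_calls("filtered_fisher", range(200, 300)),
        }
        venn = som.method_overlap(lists)
        assert venn["all_three"] == 0
        assert venn["score_fisher"] == 0
        assert venn["union"] == 300

    def test_region_counts_sum_to_union(self, rng):
        lists = {
            d: self.make_calls(d, rng.integers(0, 50, size=30).tolist())
            for d in ("score", "fisher", "filtered_fisher")
        }
        venn = som.method_overlap(lists)
        regions = [v for k, v in venn.items() if k != "union"]
        assert sum(regions) == venn["union"]


class TestArbitration:
    def passing_candidates(self, pileups):
        calls = som.detect_discordances(pileups, [("test", "ref")])
        return [c for c in calls if c.passes_threshold]

    def test_artifact_collapses_on_realignment(self):
        naive = two_sample_pileups(alt_frac_test=0.4)
        clean = two_sample_pileups(alt_frac_test=0.0)
        cands = self.passing_candidates(naive)
        assert cands
        verdicts = som.arbitrate_with_realignment(cands, naive, clean)
        assert all(v.arbitration == "artifact" for v in verdicts)

    def test_true_event_survives_realignment(self):
        pileups = two_sample_pileups(alt_frac_test=0.5)
        cands = self.passing_candidates(pileups)
        verdicts = som.arbitrate_with_realignment(cands, pileups, pileups)
        assert all(v.arbitration == "confirmed-candidate" for v in verdicts)

    def test_low_coverage_reference(self):
        # hom-alt test sample: overwhelming evidence even against 7 ref reads
        pileups = two_sample_pileups(alt_frac_test=1.0)
        shallow = make_pileup("A" * 7, pos=100)
        pileups["ref"][("chr1", 100)] = shallow
        cands = self.passing_candidates(pileups)
        verdicts = som.arbitrate_with_realignment(cands, pileups, pileups)
        assert cands and all(v.arbitration == "low-coverage" for v in verdicts)

    def test_cross_sample_veto(self):
        pileups = two_sample_pileups(alt_frac_test=0.5)
        pileups["held"] = {("chr1", 100): make_pileup("A" * 20 + "G" * 20, pos=100)}
        cands = self.passing_candidates(pileups)
        verdicts = som.arbitrate_with_realignment(
            cands, pileups, pileups, veto_map={("test", "ref"): ["held"]}
        )
        assert all(v.arbitration == "artifact" for v in verdicts)

    def test_never_promotes(self):
        pileups = two_sample_pileups(alt_frac_test=0.5)
        calls = som.detect_discordances(pileups, [("test", "ref")])
        verdicts = som.arbitrate_with_realignment(calls, pileups, pileups)
        for before, after in zip(calls, verdicts):
            assert after.passes_threshold == before.passes_threshold
            assert dataclasses.replace(after, arbitration="unreviewed") == before

    def test_missing_realigned_site_is_audit_error(self):
        pileups = two_sample_pileups(alt_frac_test=0.5)
        cands = self.passing_candidates(pileups)
        with pytest.raises(AuditError):
            som.arbitrate_with_realignment(cands, pileups, {"test": {}, "ref": {}})


class TestTruthEvaluation:
    def test_zero_planted_zero_confirmed(self):
        from mosatwin.simulate import TruthSet

        res = som.evaluate_against_truth([], TruthSet())
        assert res.sensitivity is None and res.false_discoveries == 0

    def test_bookkeeping(self):
        from mosatwin.simulate import SomaticEvent, TruthSet

        truth = TruthSet(somatic_events=[
            SomaticEvent("chr1", 10, "A", "G", frozenset(["s"]), 0.5),
            SomaticEvent("chr1", 20, "A", "G", frozenset(["s"]), 0.1),
        ])
        calls = [
            som.DiscordanceCall("chr1", 10, "t", "r", "fisher", 1e-8, True,
                                arbitration="confirmed-candidate"),
            som.DiscordanceCall("chr1", 99, "t", "r", "fisher", 1e-8, True,
                                arbitration="confirmed-candidate"),
            som.DiscordanceCall("chr1", 20, "t", "r", "fisher", 1e-8, True,
                                arbitration="artifact"),
        ]
        res = som.evaluate_against_truth(calls, truth)
        assert res.sensitivity == 0.5
        assert res.false_discoveries == 1
        assert res.per_vaf == {0.5: (1, 1), 0.1: (0, 1)}
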