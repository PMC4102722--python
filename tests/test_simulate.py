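import numpy as np
import pytest

from mosatwin import simulate as sim
from mosatwin import somatic as som
from mosatwin.errors import SizingError, ValidationError
from mosatwin.genotyping import genotype_likelihoods, pairwise_concordance, titv_ratio


def small_config(**kwargs):
    defaults = dict(genome_length=100_000, seed=7)
    defaults.update(kwargs)
    return sim.SimulationConfig(**defaults)


class TestReference:
    def test_deterministic_per_seed(self):
        cfg = small_config(seed=1)
        a = sim.generate_reference(cfg)
        b = sim.generate_reference(cfg)
        assert a.contigs == b.contigs and a.gene_model == b.gene_model

    def test_zero_cds_fraction_empty_gene_model(self):
        ref = sim.generate_reference(small_config(cds_fraction=0.0))
        assert ref.gene_model == []

    def test_cds_fraction_hits_target(self):
        cfg = small_config(genome_length=1_000_000, cds_fraction=0.02)
        ref = sim.generate_reference(cfg)
        total = sum(iv.end - iv.start for iv in ref.gene_model)
        assert 0.015 <= total / cfg.genome_length <= 0.025
        # CDS intervals non-overlapping, in bounds, phased
        prev_end = 0
        for iv in ref.gene_model:
            assert iv.start >= prev_end and iv.end <= cfg.genome_length
            assert (iv.end - iv.start) % 3 == 0
            prev_end = iv.end

    def test_too_small_genome_rejected(self):
        with pytest.raises(SizingError):
            sim.generate_reference(sim.SimulationConfig(genome_length=5000))


class TestGermlineVariants:
    def test_count_tracks_diversity(self):
        cfg = small_config(genome_length=1_000_000, diversity=0.001, seed=3)
        ref = sim.generate_reference(cfg)
        truth = sim.generate_germline_variants(ref, cfg)
        assert 900 <= len(truth.germline_variants) <= 1100

    def test_zero_diversity_empty(self):
        cfg = small_config(diversity=0.0)
        ref = sim.generate_reference(cfg)
        assert sim.generate_germline_variants(ref, cfg).germline_variants == []

    def test_genome_wide_titv_converges(self):
        """100k substitutions drawn at Ti/Tv 2.1 recover 2.1 +/- 0.05."""
        rng = sim.stage_rng(1, "titv-check")
        refs = rng.choice(list("ACGT"), size=100_000)
        alts = sim.draw_alt_alleles(refs.tolist(), 2.1, rng)
        assert titv_ratio(list(zip(refs, alts))) == pytest.approx(2.1, abs=0.05)

    def test_het_hom_ratio_defaults_to_two(self):
        cfg = small_config(genome_length=1_000_000, diversity=0.002, seed=5)
        ref = sim.generate_reference(cfg)
        truth = sim.generate_germline_variants(ref, cfg)
        hets = sum(v.genotype[0] != v.genotype[1] for v in truth.germline_variants)
        frac = hets / len(truth.germline_variants)
        assert frac == pytest.approx(2 / 3, abs=0.03)

    def test_twins_concordant_before_planting(self):
        cfg = small_config(diversity=0.002, seed=11)
        ref = sim.generate_reference(cfg)
        truth = sim.generate_germline_variants(ref, cfg)
        pileups = sim.simulate_pileups(ref, truth, cfg, ["twin1", "twin2"])
        calls = {
            s: {site: genotype_likelihoods(p) for site, p in sites.items()}
            for s, sites in pileups.items()
        }
        res = pairwise_concordance(calls["twin1"], calls["twin2"])
        assert res.fraction == 1.0


class TestPlanting:
    def setup_truth(self):
        cfg = small_config(diversity=0.001, seed=2)
        ref = sim.generate_reference(cfg)
        return ref, sim.generate_germline_variants(ref, cfg)

    def events(self, positions, samples, vaf=0.5, ref=None):
        return [
            sim.SomaticEvent("sim1", p, ref.contigs["sim1"][p - 1],
                             "A" if ref.contigs["sim1"][p - 1] != "A" else "G",
                             frozenset(samples), vaf)
            for p in positions
        ]

    def free_positions(self, truth, n, start=1):
        taken = {p for _, p in truth.germline_positions()}
        out = []
        pos = start
        while len(out) < n:
            if pos not in taken:
                out.append(pos)
            pos += 1
        return out

    def test_bookkeeping(self):
        ref, truth = self.setup_truth()
        pos = self.free_positions(truth, 10)
        planted = sim.plant_somatic_events(
            truth, self.events(pos, ["biopsy"], ref=ref), ["biopsy", "blood"]
        )
        assert len(planted.somatic_events) == 10
        assert truth.somatic_events == []  # input untouched

    def test_vaf_zero_rejected(self):
        ref, truth = self.setup_truth()
        pos = self.free_positions(truth, 1)
        with pytest.raises(ValidationError, match="VAF"):
            sim.plant_somatic_events(
                truth, self.events(pos, ["biopsy"], vaf=0.0, ref=ref),
                ["biopsy", "blood"],
            )

    def test_germline_collision_rejected(self):
        ref, truth = self.setup_truth()
        gpos = truth.germline_variants[0].pos
        with pytest.raises(ValidationError, match="collides"):
            sim.plant_somatic_events(
                truth, self.events([gpos], ["biopsy"], ref=ref), ["biopsy", "blood"]
            )

    def test_sample_subset_partition_preserved(self):
        ref, truth = self.setup_truth()
        pos = self.free_positions(truth, 10)
        events = (self.events(pos[:5], ["blood", "biopsy"], ref=ref)
                  + self.events(pos[5:], ["biopsy"], ref=ref))
        planted = sim.plant_somatic_events(truth, events,
                                           ["blood", "biopsy", "other"])
        subsets = [e.samples for e in planted.somatic_events]
        assert subsets.count(frozenset(["blood", "biopsy"])) == 5
        assert subsets.count(frozenset(["biopsy"])) == 5

    def test_full_sample_set_rejected(self):
        ref, truth = self.setup_truth()
        pos = self.free_positions(truth, 1)
        with pytest.raises(ValidationError, match="strict subset"):
            sim.plant_somatic_events(
                truth, self.events(pos, ["blood", "biopsy"], ref=ref),
                ["blood", "biopsy"],
            )


class TestPileups:
    def test_error_rate_and_vaf(self):
        cfg = small_config(genome_length=200_000, diversity=0.0, seed=13,
                           mean_depth=60.0)
        ref = sim.generate_reference(cfg)
        truth = sim.TruthSet()
        pos = list(range(1000, 3000))
        sites = [("sim1", p) for p in pos]
        somatic = [
            sim.SomaticEvent("sim1", p, ref.contigs["sim1"][p - 1],
                             "A" if ref.contigs["sim1"][p - 1] != "A" else "C",
                             frozenset(["biopsy"]), 0.5)
            for p in pos[:500]
        ]
        truth = sim.plant_somatic_events(truth, somatic, ["biopsy", "blood"])
        pileups = sim.simulate_pileups(ref, truth, cfg, ["biopsy", "blood"],
                                       positions=sites)
        # hom-ref sites in blood: non-ref fraction ~ Q30 error rate
        nonref = total = 0
        for (c, p), pu in pileups["blood"].items():
            nonref += int((pu.bases != pu.ref_base).sum())
            total += pu.depth
        assert nonref / total == pytest.approx(0.001, rel=0.5)
        # somatic sites: alt fraction ~ VAF in carrier, ~0 in other sample
        alt = tot = 0
        for ev in truth.somatic_events:
            pu = pileups["biopsy"][(ev.contig, ev.pos)]
            alt += int((pu.bases == ev.alt).sum())
            tot += pu.depth
        assert alt / tot == pytest.approx(0.5, abs=0.01)

    def test_mean_depth_matches_configuration(self):
        """Mean simulated depth within 2% of the configured mean at 1e5 sites."""
        cfg = small_config(genome_length=100_000, diversity=0.0, seed=17)
        ref = sim.generate_reference(cfg)
        sites = [("sim1", p) for p in range(1, 100_001)]
        pileups = sim.simulate_pileups(ref, sim.TruthSet(), cfg, ["s"],
                                       positions=sites)
        depths = np.fromiter((p.depth for p in pileups["s"].values()), dtype=float)
        assert depths.mean() == pytest.approx(40.0, rel=0.02)

    def test_byte_identical_across_runs(self, tmp_path):
        from mosatwin.io_formats import write_pileup

        cfg = small_config(diversity=0.001, seed=23)
        ref = sim.generate_reference(cfg)
        truth = sim.generate_germline_variants(ref, cfg)
        contents = []
        for run in range(2):
            pileups = sim.simulate_pileups(ref, truth, cfg, ["s"])
            path = tmp_path / f"run{run}.tsv"
            write_pileup([pileups["s"][k] for k in sorted(pileups["s"])], path)
            contents.append(path.read_bytes())
        assert contents[0] == contents[1]


class TestArtifactFixture:
    def test_insertion_allele(self):
        fx = sim.generate_indel_artifact_fixture(seed=1)
        assert fx.insertion_allele == "CGCAGCAGGGGCAGCAGGG"
        assert len(fx.insertion_allele) == 19

    def test_naive_pileups_reach_fisher_significance(self):
        fx = sim.generate_indel_artifact_fixture(seed=1)
        for pos in fx.artifact_positions:
            a = fx.naive_pileups["biopsy"][(fx.contig, pos)]
            b = fx.naive_pileups["blood"][(fx.contig, pos)]
            alt = som.infer_alt_allele([a, b])
            p = som.fisher_allele_test(a.allele_counts(alt), b.allele_counts(alt))
            assert p < 0.01

    def test_realigned_pileups_yield_zero_calls(self):
        fx = sim.generate_indel_artifact_fixture(seed=1)
        calls = som.detect_discordances(fx.realigned_pileups,
                                        [("biopsy", "blood")])
        assert not any(c.passes_threshold for c in calls)

    def test_truth_marks_artifacts_not_somatic(self):
        fx = sim.generate_indel_artifact_fixture(seed=1)
        assert fx.truth.somatic_events == []
        assert {a.pos for a in fx.truth.artifact_sites} == set(fx.artifact_positions)


class TestCnvDepth:
    def test_expected_ratios(self):
        cfg = small_config(seed=3, n_background_samples=10)
        loss = sim.CnvEvent(sim.Interval("sim1", 10_000, 15_000), "loss", 0.5,
                            frozenset(["s1"]))
        gain = sim.CnvEvent(sim.Interval("sim1", 50_000, 55_000), "gain", 1.5,
                            frozenset(["s1"]))
        matrix, truth = sim.simulate_cnv_depth(cfg, [loss, gain], ["s1", "s2"],
                                               n_windows=800)
        from mosatwin.cnv import normalize_depth

        ratios = normalize_depth(matrix)
        starts = np.array([w.start for w in matrix.windows])
        in_loss = (starts >= 10_000) & (starts < 15_000)
        in_gain = (starts >= 50_000) & (starts < 55_000)
        outside = ~in_loss & ~in_gain
        assert np.nanmean(ratios["s1"][in_loss]) == pytest.approx(0.5, abs=0.05)
        assert np.nanmean(ratios["s1"][in_gain]) == pytest.approx(1.5, abs=0.07)
        assert np.nanmean(ratios["s1"][outside]) == pytest.approx(1.0, abs=0.02)
        # s2 unaffected; 0.5 < 0.62 loss threshold, 1.5 > 1.38 gain threshold
        assert np.nanmean(ratios["s2"][in_loss]) == pytest.approx(1.0, abs=0.05)

    def test_overlapping_events_rejected(self):
        cfg = small_config(seed=3)
        a = sim.CnvEvent(sim.Interval("sim1", 0, 5000), "loss", 0.5, frozenset(["s"]))
        b = sim.CnvEvent(sim.Interval("sim1", 4000, 9000), "gain", 1.5, frozenset(["s"]))
        with pytest.raises(ValidationError, match="overlap"):
            sim.simulate_cnv_depth(cfg, [a, b], ["s"])


class TestControlCohort:
    def test_hwe_proportions(self):
        model = sim.make_risk_model(5, seed=1)
        cohort = sim.simulate_control_cohort(model, 50_000, seed=2)
        for locus in model.loci:
            f = locus.risk_allele_freq
            counts = cohort[locus.locus_id].value_counts(normalize=True)
            assert counts.get(2, 0) == pytest.approx(f * f, abs=0.01)
            assert counts.get(1, 0) == pytest.approx(2 * f * (1 - f), abs=0.01)

    def test_default_cohort_size(self):
        model = sim.make_risk_model(3, seed=1)
        cohort = sim.simulate_control_cohort(model, 1920, seed=1)
        assert cohort.shape == (1920, 3)

    def test_degenerate_frequency_rejected(self):
        from mosatwin.risk import RiskLocus, RiskModel

        model = RiskModel([RiskLocus("l", "c", 1, "A", "G", 1.2, 1.0)])
        with pytest.raises(ValidationError):
            sim.simulate_control_cohort(model, 10, seed=1)
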