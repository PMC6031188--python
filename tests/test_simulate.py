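"""Synthetic-cohort generator: determinism, load statistics, caller emulation."""

import numpy as np
import pytest

from crisprwgs import (
    CallerEmulationModel,
    CohortDesign,
    GuideSpec,
    MutationLoadModel,
    SampleSpec,
    default_cohort_design,
    emulate_callers,
    find_sites,
    plant_guide_edits,
    simulate_cohort,
    simulate_reference,
    simulate_truth_set,
)
from crisprwgs.simulate import _allele_catalog, _stream


class TestSimulateReference:
    def test_shape_and_determinism(self):
        g1 = simulate_reference(1, 10_000, 0.5, seed=7)
        g2 = simulate_reference(1, 10_000, 0.5, seed=7)
        assert g1.lengths == {"chr1": 10_000}
        assert g1.sequences == g2.sequences
        assert simulate_reference(1, 10_000, 0.5, seed=8).sequences != g1.sequences

    def test_gc_within_binomial_error(self):
        gc = 0.43
        n = 100_000
        g = simulate_reference(1, n, gc, seed=1)
        seq = g.sequences["chr1"]
        realized = (seq.count("G") + seq.count("C")) / n
        sd = np.sqrt(gc * (1 - gc) / n)
        assert abs(realized - gc) < 3 * sd

    def test_input_errors(self):
        with pytest.raises(ValueError):
            simulate_reference(1, 100, 0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_reference(1, 10_000, 1.2, seed=0)


class TestSimulateTruthSet:
    def test_zero_means_empty(self, small_genome):
        assert simulate_truth_set(small_genome, MutationLoadModel(0, 0), 1) == []

    def test_poisson_mean_recovered(self):
        """Sample mean of SNV counts over replicate draws matches the model mean."""
        genome = simulate_reference(1, 200_000, 0.43, seed=2)
        mean_snv, n_rep = 114, 200
        model = MutationLoadModel(mean_snv, 36)
        counts = [
            sum(1 for t in simulate_truth_set(genome, model, seed) if t.variant.kind == "SNV")
            for seed in range(n_rep)
        ]
        se = np.sqrt(mean_snv / n_rep)
        assert abs(np.mean(counts) - mean_snv) < 3 * se

    def test_af_modes(self, small_genome):
        het = simulate_truth_set(small_genome, MutationLoadModel(30, 10), 3)
        assert all(0.4 <= t.true_af <= 0.6 for t in het)
        som = simulate_truth_set(
            small_genome, MutationLoadModel(30, 10, af_mode="somatic"), 4
        )
        assert all(0.0 <= t.true_af < 0.25 for t in som)
        hom = simulate_truth_set(
            small_genome, MutationLoadModel(5, 0, af_mode="homozygous"), 5
        )
        assert all(t.true_af == 1.0 for t in hom)

    def test_no_position_collisions(self, small_genome):
        truth = simulate_truth_set(small_genome, MutationLoadModel(300, 100), 6)
        intervals = sorted(
            (t.variant.chrom,) + t.variant.interval() for t in truth
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(intervals, intervals[1:]):
            assert c1 != c2 or e1 <= s2

    def test_capacity_error(self):
        genome = simulate_reference(1, 1_000, 0.5, seed=0)
        with pytest.raises(ValueError, match="capacity"):
            simulate_truth_set(genome, MutationLoadModel(10_000, 0), 0)

    def test_determinism(self, small_genome):
        model = MutationLoadModel(50, 20)
        a = simulate_truth_set(small_genome, model, 9)
        b = simulate_truth_set(small_genome, model, 9)
        assert a == b


def _genome_with_sites(n_sites, seed=21):
    """Random genome with planted exact guide sites; returns genome, guide, sites."""
    proto = "GATTACAGATTACAGGCCTA"
    genome = simulate_reference(1, 60_000, 0.43, seed=seed)
    seq = genome.sequences["chr1"]
    for i in range(n_sites):
        pos = 2_000 + 4_000 * i
        seq = seq[:pos] + proto + "TGG" + seq[pos + 23 :]
    genome.sequences["chr1"] = seq
    guide = GuideSpec("g", proto)
    sites = find_sites(genome, guide, 0)
    assert len(sites) == n_sites
    return genome, guide, sites


class TestPlantGuideEdits:
    def test_full_efficiency_edits_every_site(self):
        genome, guide, sites = _genome_with_sites(12)
        reps = plant_guide_edits(genome, guide, sites, 1.0, 2, seed=1)
        assert [len(r) for r in reps] == [12, 12]

    def test_zero_efficiency_no_edits(self):
        genome, guide, sites = _genome_with_sites(3)
        reps = plant_guide_edits(genome, guide, sites, 0.0, 2, seed=1)
        assert [len(r) for r in reps] == [0, 0]

    def test_bad_efficiency_rejected(self):
        genome, guide, sites = _genome_with_sites(1)
        with pytest.raises(ValueError):
            plant_guide_edits(genome, guide, sites, 1.5, 1, seed=1)

    def test_replicates_draw_independent_alleles(self):
        """Shared-allele fraction across replicates matches 1/|catalog|."""
        genome, guide, sites = _genome_with_sites(12)
        cat_sizes = [len(_allele_catalog(genome, guide, s)) for s in sites]
        assert all(size >= 10 for size in cat_sizes)
        expected = np.mean([1 / size for size in cat_sizes])
        n_pairs, same = 60, 0
        for seed in range(n_pairs):
            a, b = plant_guide_edits(genome, guide, sites, 1.0, 2, seed=seed)
            keys_a = {t.variant.chrom: None for t in a}  # noqa: F841 (structure check)
            by_site_a = {t.variant.pos // 1_000: t.key for t in a}
            by_site_b = {t.variant.pos // 1_000: t.key for t in b}
            same += sum(by_site_a[k] == by_site_b[k] for k in by_site_a)
        rate = same / (n_pairs * len(sites))
        se = np.sqrt(expected * (1 - expected) / (n_pairs * len(sites)))
        assert abs(rate - expected) < 4 * se

    def test_edits_lie_at_cut_sites(self):
        genome, guide, sites = _genome_with_sites(5)
        (rep,) = plant_guide_edits(genome, guide, sites, 1.0, 1, seed=2)
        cuts = sorted(s.cut_position(guide) for s in sites)
        for t, cut in zip(sorted(rep, key=lambda t: t.variant.pos), cuts):
            s, e = t.variant.interval()
            assert s - 12 <= cut <= e + 12  # within catalog reach of the cut


class TestEmulateCallers:
    def test_noise_free_callers_equal_truth(self, small_genome):
        truth = simulate_truth_set(small_genome, MutationLoadModel(40, 15), 1)
        model = CallerEmulationModel(3, fp_rate=0.0, fn_rate=0.0, af_noise_sd=0.0)
        sets = emulate_callers(truth, model, small_genome, 1)
        truth_keys = {t.key for t in truth}
        for s in sets:
            assert set(s.keys()) == truth_keys
            for t in truth:
                assert s.calls[t.key].af == t.true_af

    def test_total_dropout_leaves_only_false_positives(self, small_genome):
        truth = simulate_truth_set(small_genome, MutationLoadModel(40, 15), 1)
        model = CallerEmulationModel(3, fp_rate=1e-4, fn_rate=1.0)
        truth_keys = {t.key for t in truth}
        for s in emulate_callers(truth, model, small_genome, 1):
            assert not (set(s.keys()) & truth_keys)

    def test_fp_count_matches_poisson_rate(self):
        """Mean FP count per caller over seeds matches fp_rate x genome length."""
        genome = simulate_reference(1, 100_000, 0.43, seed=4)
        fp_rate = 1e-4  # expect 10 per caller
        model = CallerEmulationModel(3, fp_rate=fp_rate, fn_rate=1.0)
        counts = []
        for seed in range(100):
            for s in emulate_callers([], model, genome, seed):
                counts.append(len(s))
        lam = fp_rate * genome.total_length
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_fp_never_coincides_with_truth(self, small_genome):
        truth = simulate_truth_set(small_genome, MutationLoadModel(100, 30), 2)
        model = CallerEmulationModel(3, fp_rate=1e-3, fn_rate=0.0)
        truth_pos = {(t.variant.chrom, t.variant.pos) for t in truth}
        truth_keys = {t.key for t in truth}
        for s in emulate_callers(truth, model, small_genome, 3):
            for call in s:
                if call.key not in truth_keys:
                    assert (call.variant.chrom, call.variant.pos) not in truth_pos


class TestCohortDesign:
    def test_default_design_shape(self):
        d = default_cohort_design()
        groups = {s.group for s in d}
        assert {"WT_G1", "WT_G2", "WT_G3", "TC_only", "Agro",
                "Cas9_backbone", "Cpf1_backbone", "Edited_T0", "Edited_T1"} == groups
        guides = {s.guide_id for s in d if s.guide_id}
        assert len(guides) == 15

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CohortDesign([SampleSpec("a", "WT_G1"), SampleSpec("a", "WT_G1")])

    def test_edited_without_guide_rejected(self):
        with pytest.raises(ValueError, match="guide_id"):
            CohortDesign([SampleSpec("a", "Edited_T0")])

    def test_pedigree_cycle_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign([
                SampleSpec("a", "WT_G1", parent_id="b"),
                SampleSpec("b", "WT_G2", parent_id="a"),
            ])

    def test_tsv_round_trip(self, tmp_path):
        d = default_cohort_design()
        p = tmp_path / "design.tsv"
        d.to_tsv(p)
        assert CohortDesign.from_tsv(p).samples == d.samples


@pytest.fixture(scope="module")
def sim():
    return simulate_cohort(5, genome_bp=400_000)


class TestSimulateCohort:
    def test_determinism(self, sim):
        again = simulate_cohort(5, genome_bp=400_000)
        assert again.genome.sequences == sim.genome.sequences
        sid = sim.design.samples[0].sample_id
        assert [t.key for t in again.truth[sid]] == [t.key for t in sim.truth[sid]]

    def test_adding_samples_preserves_existing_streams(self, sim):
        """Per-sample streams are keyed by id: a larger design reuses old draws."""
        design = default_cohort_design(n_t1=4)  # two extra T1 samples
        bigger = simulate_cohort(5, design=design, genome_bp=400_000)
        for sid in ("WT_G2_1", "TC_only_1", "Cas9-10_T0_1"):
            assert [t.key for t in bigger.truth[sid]] == [t.key for t in sim.truth[sid]]

    def test_pedigree_shares_identical_alleles(self, sim):
        """Pre-existing variants appear in parent and descendants with the same key."""
        child_keys = {t.key for t in sim.truth["WT_G3_1"]}
        parent_keys = {t.key for t in sim.truth["WT_G2_1"]}
        founder_keys = {t.key for t in sim.truth["WT_G1_1"]}
        assert founder_keys <= parent_keys <= child_keys

    def test_unsafe_guide_has_planted_sites(self, sim):
        assert len(sim.planted_offtargets[sim.unsafe_guide]) == 12
        for gid, sites in sim.planted_offtargets.items():
            if gid != sim.unsafe_guide:
                assert sites == []

    def test_edited_replicates_receive_offtarget_indels(self, sim):
        for suffix in ("_T0_1", "_T0_2"):
            truth = sim.truth[sim.unsafe_guide + suffix]
            off = [t for t in truth if t.klass == "off_target"]
            assert len(off) == 12
            assert all(t.variant.kind in ("INS", "DEL") for t in off)
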