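"""Scanner vs exhaustive oracle, PAM semantics, seed counting, bulge alignment."""

import numpy as np
import pytest

from crisprwgs import (
    GuideSpec,
    ReferenceGenome,
    count_seed_mismatches,
    find_sites,
    flank_align,
    guide_specificity,
    reverse_complement,
    simulate_reference,
)
from crisprwgs.guides import IUPAC


def brute_force_sites(genome, guide, max_mismatch):
    """Pure-Python window scan over both strands (independent oracle)."""
    hits = []
    w = guide.site_len
    plen = guide.pam_len
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        L = len(seq)
        for strand in "+-":
            frame = seq if strand == "+" else reverse_complement(seq)
            for i in range(L - w + 1):
                window = frame[i : i + w]
                if guide.pam_is_5prime:
                    pam, proto = window[:plen], window[plen:]
                else:
                    pam, proto = window[-plen:], window[:-plen]
                if not any(
                    all(b in IUPAC[c] for b, c in zip(pam, pat))
                    for pat in guide.pam_patterns
                ):
                    continue
                mm = sum(1 for a, b in zip(proto, guide.protospacer) if a != b)
                if mm <= max_mismatch:
                    start = i if strand == "+" else L - i - w
                    hits.append((chrom, start, strand, mm))
    return sorted(hits)


def scanner_tuples(sites):
    return sorted((s.chrom, s.start, s.strand, s.n_mismatch) for s in sites)


def plant(seq: str, pos: int, payload: str) -> str:
    return seq[:pos] + payload + seq[pos + len(payload) :]


GUIDE = "GATTACAGATTACAGGCCTA"  # 20 nt


class TestFindSites:
    def test_exact_site_found_once(self, small_genome):
        seq = plant(small_genome.sequences["chr1"], 10_000, GUIDE + "AGG")
        genome = ReferenceGenome({"chr1": seq})
        guide = GuideSpec("g", GUIDE)
        sites = find_sites(genome, guide, 0)
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.strand) == (10_000, 10_023, "+")
        assert s.n_mismatch == 0 and s.seed_mismatch == 0 and s.pam_canonical

    def test_silent_pam_change_is_zero_mismatch(self, small_genome):
        # same protospacer under CGG instead of TGG: still canonical NGG
        seq = plant(small_genome.sequences["chr1"], 10_000, GUIDE + "CGG")
        genome = ReferenceGenome({"chr1": seq})
        sites = find_sites(genome, GuideSpec("g", GUIDE), 0)
        assert len(sites) == 1
        assert sites[0].n_mismatch == 0 and sites[0].pam_canonical
        assert sites[0].pam_observed == "CGG"

    def test_minus_strand_coordinates(self, small_genome):
        payload = GUIDE + "TGG"
        seq = plant(small_genome.sequences["chr1"], 20_000, reverse_complement(payload))
        genome = ReferenceGenome({"chr1": seq})
        sites = find_sites(genome, GuideSpec("g", GUIDE), 0)
        assert [(s.start, s.strand) for s in sites] == [(20_000, "-")]

    @pytest.mark.parametrize("pam_patterns,proto_len", [
        (("NGG",), 20), (("NGG", "NAG"), 20), (("TTTV",), 23),
    ])
    def test_matches_brute_force_oracle(self, pam_patterns, proto_len):
        rng = np.random.default_rng(42)
        for trial in range(3):
            genome = simulate_reference(1, 5_000, 0.43, seed=100 + trial)
            proto = "".join(rng.choice(list("ACGT"), size=proto_len))
            nuclease = "Cpf1" if pam_patterns == ("TTTV",) else "Cas9"
            guide = GuideSpec("g", proto, nuclease, pam_patterns)
            for mm in (0, 3, 5):
                assert scanner_tuples(find_sites(genome, guide, mm)) == \
                    brute_force_sites(genome, guide, mm)

    def test_strand_symmetry(self, small_genome):
        guide = GuideSpec("g", GUIDE)
        fwd = find_sites(small_genome, guide, 5)
        flipped_genome = ReferenceGenome(
            {c: reverse_complement(s) for c, s in small_genome.sequences.items()}
        )
        rev = find_sites(flipped_genome, guide, 5)
        L = small_genome.lengths["chr1"]
        mirrored = sorted(
            (s.chrom, L - s.end, "-" if s.strand == "+" else "+", s.n_mismatch)
            for s in rev
        )
        assert scanner_tuples(fwd) == mirrored

    def test_mismatch_monotonicity(self, small_genome):
        guide = GuideSpec("g", GUIDE)
        prev: set = set()
        for mm in range(0, 7):
            cur = set(scanner_tuples(find_sites(small_genome, guide, mm)))
            assert prev <= cur
            prev = cur

    @pytest.mark.parametrize("pam,found", [
        ("AGG", True), ("CGG", True), ("GGG", True), ("TGG", True),
        ("CAG", False), ("ATG", False),
    ])
    def test_ngg_expansion(self, pam, found):
        base = simulate_reference(1, 2_000, 0.5, seed=9).sequences["chr1"]
        genome = ReferenceGenome({"chr1": plant(base, 500, GUIDE + pam)})
        sites = find_sites(genome, GuideSpec("g", GUIDE), 0)
        assert any(s.start == 500 for s in sites) is found

    def test_nag_opt_in(self):
        base = simulate_reference(1, 2_000, 0.5, seed=9).sequences["chr1"]
        genome = ReferenceGenome({"chr1": plant(base, 500, GUIDE + "CAG")})
        guide = GuideSpec("g", GUIDE, "Cas9", ("NGG", "NAG"))
        sites = [s for s in find_sites(genome, guide, 0) if s.start == 500]
        assert len(sites) == 1
        assert not sites[0].pam_canonical  # NAG is non-canonical

    @pytest.mark.parametrize("pam,found", [
        ("TTTA", True), ("TTTC", True), ("TTTG", True), ("TTTT", False),
    ])
    def test_tttv_expansion(self, pam, found):
        proto = "GATTACAGATTACAGGCCTAGCA"  # 23 nt
        base = simulate_reference(1, 2_000, 0.5, seed=10).sequences["chr1"]
        genome = ReferenceGenome({"chr1": plant(base, 500, pam + proto)})
        sites = find_sites(genome, GuideSpec("g", proto, "Cpf1"), 0)
        assert any(s.start == 500 for s in sites) is found

    def test_non_acgt_protospacer_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            GuideSpec("g", "GATTACAGATTACAGGCCTN")


class TestSeedMismatches:
    def _site_with_mismatch(self, positions_from_pam):
        proto = list(GUIDE)
        for p in positions_from_pam:  # Cas9: position 1 is adjacent to the 3' PAM
            idx = len(proto) - p
            proto[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[idx]]
        base = simulate_reference(1, 2_000, 0.5, seed=3).sequences["chr1"]
        genome = ReferenceGenome({"chr1": plant(base, 700, "".join(proto) + "TGG")})
        guide = GuideSpec("g", GUIDE)
        sites = [s for s in find_sites(genome, guide, 5) if s.start == 700]
        assert len(sites) == 1
        return sites[0], guide

    def test_perfect_match(self):
        site, guide = self._site_with_mismatch([])
        assert count_seed_mismatches(site, guide) == 0

    def test_pam_distal_mismatch_outside_seed(self):
        site, guide = self._site_with_mismatch([20])
        assert site.n_mismatch == 1
        assert count_seed_mismatches(site, guide, seed_len=18) == 0

    def test_one_of_three_in_seed(self):
        site, guide = self._site_with_mismatch([20, 19, 10])
        assert site.n_mismatch == 3
        assert count_seed_mismatches(site, guide, seed_len=18) == 1

    def test_shorter_seed_convention(self):
        site, guide = self._site_with_mismatch([11])
        assert count_seed_mismatches(site, guide, seed_len=12) == 1
        assert count_seed_mismatches(site, guide, seed_len=10) == 0


class TestFlankAlign:
    def _flank_with(self, payload, seed=7):
        base = simulate_reference(1, 2_000, 0.5, seed=seed).sequences["chr1"]
        flank = plant(base[:51], 15, payload)[:51]
        return flank

    def test_exact_protospacer_single_ungapped_hit(self):
        flank = self._flank_with(GUIDE)
        hits = flank_align(flank, GuideSpec("g", GUIDE), min_match=15)
        assert len(hits) == 1
        h = hits[0]
        assert (h.matches, h.mismatches, h.bulges) == (20, 0, 0)
        assert h.flank_start == 15 and h.strand == "+"

    def test_reverse_strand_hit(self):
        flank = self._flank_with(reverse_complement(GUIDE))
        hits = flank_align(flank, GuideSpec("g", GUIDE), min_match=18)
        assert hits and hits[0].strand == "-" and hits[0].matches == 20

    def test_single_deleted_base_yields_one_bulge(self):
        # the flank lacks one interior protospacer base -> one 1-nt gap
        damaged = GUIDE[:10] + GUIDE[11:]
        flank = self._flank_with(damaged)
        hits = flank_align(flank, GuideSpec("g", GUIDE), min_match=18)
        assert hits
        best = hits[0]
        assert best.bulges == 1 and best.matches == 19
        assert best.bulge_type == "rna"  # guide base left unpaired by the DNA

    def test_single_extra_base_yields_dna_bulge(self):
        damaged = GUIDE[:10] + "T" + GUIDE[10:]
        if damaged[10] == damaged[9]:
            damaged = GUIDE[:10] + "C" + GUIDE[10:]
        flank = self._flank_with(damaged)
        hits = flank_align(flank, GuideSpec("g", GUIDE), min_match=18)
        assert hits
        assert hits[0].bulges == 1 and hits[0].bulge_type == "dna"

    def test_random_flank_hit_rate_within_null(self):
        """Spurious hits on guide-unrelated flanks stay within the binomial null."""
        from scipy import stats

        guide = GuideSpec("g", GUIDE)
        rng = np.random.default_rng(123)
        n_flanks, hits = 300, 0
        for _ in range(n_flanks):
            flank = "".join(rng.choice(list("ACGT"), size=51))
            if flank_align(flank, guide, min_match=15):
                hits += 1
        # ~2,350 candidate alignments per flank; P(>=15 of 20 match) under
        # a uniform-base null, Bonferroni-style upper bound with 3x slack
        p_align = stats.binom.sf(14, 20, 0.25)
        bound = 3 * 2350 * p_align
        assert hits / n_flanks <= max(bound, 5 / n_flanks)


class TestGuideSpecificity:
    def test_unique_target_is_safe(self, small_genome):
        seq = plant(small_genome.sequences["chr1"], 10_000, GUIDE + "AGG")
        genome = ReferenceGenome({"chr1": seq})
        res = guide_specificity(genome, GuideSpec("g", GUIDE))
        assert res.safe and res.n_offtarget_sites == 0

    def test_second_perfect_site_is_unsafe(self, small_genome):
        seq = plant(small_genome.sequences["chr1"], 10_000, GUIDE + "AGG")
        seq = plant(seq, 30_000, GUIDE + "CGG")
        genome = ReferenceGenome({"chr1": seq})
        res = guide_specificity(genome, GuideSpec("g", GUIDE))
        assert not res.safe
        assert res.best_offtarget is not None
        assert res.best_offtarget.seed_mismatch == 0

    def test_all_mismatches_in_seed_is_safe(self, small_genome):
        mutated = list(GUIDE)
        for p in (1, 5, 9):  # PAM-proximal seed positions
            idx = len(mutated) - p
            mutated[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[idx]]
        seq = plant(small_genome.sequences["chr1"], 10_000, GUIDE + "AGG")
        seq = plant(seq, 30_000, "".join(mutated) + "TGG")
        genome = ReferenceGenome({"chr1": seq})
        res = guide_specificity(genome, GuideSpec("g", GUIDE))
        assert res.safe
        assert res.n_offtarget_sites == 1
        assert res.best_offtarget.seed_mismatch >= 2
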