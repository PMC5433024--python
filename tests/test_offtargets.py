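"""Protospacer/PAM homology search: IUPAC matching, mismatch counting,
region scanning and peak assignment, each against brute-force oracles."""

import random

import pytest

from guidepeak.dna import IUPAC, iupac_match, revcomp
from guidepeak.offtargets import (GuideSpec, count_guide_mismatches,
                                  count_pam_mismatches, scan_region,
                                  assign_site_to_peak)
from guidepeak.peakcall import MergedPeak
from guidepeak.simulate import build_site_sequence

GUIDE = "GACCCCCTCCACCCCGCCTC"


def _fetch(seq):
    return lambda chrom, start, end: seq[start:end]


def _embed(background, pos, insert):
    return background[:pos] + insert + background[pos + len(insert):]


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestIupacMatch:
    @pytest.mark.parametrize("mask,seq,expected", [
        ("NGG", "AGG", True),
        ("NNNNGATT", "ACGTGATT", True),   # NmCas9 PAM
        ("TTTN", "TGCA", False),          # AsCpf1 PAM
        ("NGG", "AGA", False),
        ("TTTN", "TTTC", True),
    ])
    def test_examples(self, mask, seq, expected):
        assert iupac_match(mask, seq) is expected

    def test_matches_classwise_oracle(self):
        rng = random.Random(3)
        masks = "ACGTRYSWKMBDHVN"
        for _ in range(500):
            mask = "".join(rng.choice(masks) for _ in range(6))
            seq = _random_seq(rng, 6)
            oracle = all(s in IUPAC[m] for m, s in zip(mask, seq))
            assert iupac_match(mask, seq) is oracle


class TestMismatchCounting:
    def test_identical_and_complemented(self):
        assert count_guide_mismatches(GUIDE, GUIDE) == (0, ())
        n, detail = count_guide_mismatches(GUIDE, revcomp(GUIDE)[::-1])
        assert n == len([1 for a, b in zip(GUIDE, revcomp(GUIDE)[::-1]) if a != b])

    def test_matches_naive_zip_oracle(self):
        rng = random.Random(4)
        for _ in range(200):
            a = _random_seq(rng, 24)
            b = _random_seq(rng, 24)
            n, detail = count_guide_mismatches(a, b)
            oracle = [(i + 1, x, y) for i, (x, y) in enumerate(zip(a, b)) if x != y]
            assert n == len(oracle)
            assert list(detail) == oracle

    def test_five_prime_pam_numbers_from_far_end(self):
        # with a 5' PAM the PAM-distal end is the guide's 3' end
        a = "AAAA"
        b = "CAAA"   # mismatch at index 0 = PAM-proximal for 5' PAM
        n, detail = count_guide_mismatches(a, b, pam_location="five_prime")
        assert detail == ((4, "A", "C"),)

    def test_pam_mismatches_classwise(self):
        assert count_pam_mismatches("NGG", "AGG") == 0
        assert count_pam_mismatches("NNNNGATT", "ACGTGCTT") == 1
        assert count_pam_mismatches("TTTN", "GTTA") == 1

    def test_pam_mismatch_matches_oracle(self):
        rng = random.Random(5)
        for _ in range(200):
            mask = "".join(rng.choice("ACGTN") for _ in range(4))
            seq = _random_seq(rng, 4)
            oracle = sum(1 for m, s in zip(mask, seq) if s not in IUPAC[m])
            assert count_pam_mismatches(mask, seq) == oracle


class TestScanRegion:
    def test_planted_exact_target_found(self, guide_spec):
        rng = random.Random(6)
        bg = _random_seq(rng, 200)
        seq = _embed(bg, 100, GUIDE + "TGG")
        sites = scan_region(_fetch(seq), "c", 0, 200, guide_spec)
        exact = [s for s in sites if s.n_mismatch_guide == 0]
        assert len(exact) == 1
        assert (exact[0].proto_start, exact[0].proto_end) == (100, 120)
        assert exact[0].strand == "+"
        assert exact[0].pam_seq == "TGG"
        # SpCas9 blunt cut 3 bp from the PAM
        assert exact[0].predicted_cut_pos == 117

    def test_nmcas9_budgets(self):
        spec = GuideSpec(guide_seq="G" * 24, guide_length=24, pam="NNNNGATT",
                         pam_size=8, pam_pattern=("NNNNGNNN",),
                         max_mismatch_guide=10, max_mismatch_pam=3)
        ok = "G" * 14 + "T" * 10 + "AAAA" + "GTAA"   # 10 guide mm, G at PAM pos 5
        bad = "G" * 13 + "T" * 11 + "AAAA" + "GTAA"  # 11 guide mm
        bad_pam = "G" * 14 + "T" * 10 + "AAAA" + "CTAA"  # C at PAM pos 5
        for seq, n_expected in ((ok, 1), (bad, 0), (bad_pam, 0)):
            region = "A" + seq + "A"
            sites = scan_region(_fetch(region), "c", 0, len(region), spec)
            plus = [s for s in sites if s.strand == "+" and s.proto_start == 1]
            assert len(plus) == n_expected

    def test_cpf1_five_prime_pam_orientation(self):
        spec = GuideSpec(guide_seq="ACGTACGTACGTACGTACGTACG", guide_length=23,
                         pam="TTTN", pam_size=4, pam_location="five_prime",
                         max_mismatch_guide=2, max_mismatch_pam=0)
        site = build_site_sequence(spec, (), "TTTC")
        assert site.startswith("TTTC")
        rng = random.Random(7)
        bg = _random_seq(rng, 150)
        seq = _embed(bg, 50, site)
        sites = [s for s in scan_region(_fetch(seq), "c", 0, 150, spec)
                 if s.n_mismatch_guide == 0]
        assert len(sites) == 1
        s = sites[0]
        assert s.strand == "+"
        assert (s.proto_start, s.proto_end) == (54, 77)
        assert s.pam_seq == "TTTC"

    def test_strand_symmetry(self, guide_spec):
        rng = random.Random(8)
        bg = _random_seq(rng, 300)
        seq = _embed(bg, 140, GUIDE + "AGG")
        fwd = scan_region(_fetch(seq), "c", 0, 300, guide_spec)
        rc = revcomp(seq)
        rev = scan_region(_fetch(rc), "c", 0, 300, guide_spec)
        def norm(sites, L):
            return sorted((L - s.proto_end, L - s.proto_start,
                           {"+": "-", "-": "+"}[s.strand], s.n_mismatch_guide)
                          for s in sites)
        assert norm(fwd, 300) == sorted((s.proto_start, s.proto_end, s.strand,
                                         s.n_mismatch_guide) for s in rev)

    def test_budget_monotonicity(self, guide_spec):
        rng = random.Random(9)
        seq = _embed(_random_seq(rng, 400), 200, GUIDE + "AGG")
        small = scan_region(_fetch(seq), "c", 0, 400,
                            GuideSpec(guide_seq=GUIDE, max_mismatch_guide=3))
        large = scan_region(_fetch(seq), "c", 0, 400,
                            GuideSpec(guide_seq=GUIDE, max_mismatch_guide=6))
        keys = lambda ss: {(s.proto_start, s.strand) for s in ss}
        assert keys(small) <= keys(large)

    def test_matches_exhaustive_reference(self, guide_spec):
        """scan_region equals an independent enumerate-and-filter scanner."""
        rng = random.Random(10)
        seq = _embed(_random_seq(rng, 2000), 1000, GUIDE + "CGG")
        got = {(s.proto_start, s.proto_end, s.strand, s.n_mismatch_guide,
                s.n_mismatch_pam) for s in scan_region(_fetch(seq), "c", 0, 2000,
                                                       guide_spec)}
        expected = set()
        L = 23
        for strand in "+-":
            view = seq if strand == "+" else revcomp(seq)
            for i in range(len(view) - L + 1):
                w = view[i:i + L]
                proto, pam = w[:20], w[20:]
                ng = sum(a != b for a, b in zip(GUIDE, proto))
                npam = sum(1 for m, b in zip("NGG", pam) if b not in IUPAC[m])
                if ng <= 6 and npam <= 2 and iupac_match("NGG", pam):
                    ws = i if strand == "+" else len(seq) - i - L
                    expected.add((ws, ws + 20, strand, ng, npam))
        assert got == expected

    def test_invalid_character_positioned_error(self, guide_spec):
        with pytest.raises(ValueError, match="position"):
            scan_region(_fetch("ACGT" * 10 + "X" + "ACGT" * 10), "c", 0, 81,
                        guide_spec)

    def test_region_clipping(self, guide_spec):
        seq = GUIDE + "TGG"
        sites = scan_region(_fetch(seq), "c", -50, 1000, guide_spec,
                            chrom_length=len(seq))
        assert any(s.proto_start == 0 and s.n_mismatch_guide == 0 for s in sites)


class TestAssignment:
    def _peak(self):
        return MergedPeak(chrom="c", start=90, end=130, minus_peak=None,
                          plus_peak=None, score=10, libraries=frozenset({"forward"}))

    def _site(self, start, nmm):
        from guidepeak.offtargets import OffTargetSite
        return OffTargetSite(chrom="c", proto_start=start, proto_end=start + 20,
                             strand="+", protospacer_seq="A" * 20, pam_seq="AGG",
                             n_mismatch_guide=nmm, mismatch_detail=(),
                             n_mismatch_pam=0, predicted_cut_pos=start + 17)

    def test_single_candidate_chosen(self):
        out = assign_site_to_peak(self._peak(), [self._site(100, 2)], peak_id="p")
        assert len(out) == 1 and out[0].peak_score == 10 and out[0].peak_id == "p"

    def test_fewest_guide_mismatches_wins(self):
        out = assign_site_to_peak(self._peak(),
                                  [self._site(100, 4), self._site(105, 2)])
        assert out[0].n_mismatch_guide == 2

    def test_no_candidates_returns_empty(self):
        assert assign_site_to_peak(self._peak(), []) == []

    def test_report_all_keeps_every_candidate_ranked(self):
        out = assign_site_to_peak(self._peak(),
                                  [self._site(100, 4), self._site(105, 2)],
                                  report_all=True)
        assert [s.n_mismatch_guide for s in out] == [2, 4]
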