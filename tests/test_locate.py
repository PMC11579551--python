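"""Domain profiles, local scanning, MT extraction and architecture calls."""

import math

import numpy as np
import pytest

from mtminer.composition import AA_INDEX, BACKGROUND_VECTOR
from mtminer.errors import (
    AmbiguousArchitectureError,
    SequenceAlphabetError,
    ValidationError,
)
from mtminer.locate import (
    DomainHit,
    SeedAlignment,
    build_profile,
    classify_architecture,
    consensus,
    extract_mt_domain,
    scan_protein,
)
from mtminer.synth import generate_background


def q(aa: str) -> float:
    return float(BACKGROUND_VECTOR[AA_INDEX[aa]])


class TestBuildProfile:
    def test_zero_pseudocount_identical_rows_closed_form(self):
        seed = SeedAlignment("MT", ["ACD", "ACD"])
        profile = build_profile(seed, pseudocount_weight=0.0)
        assert profile.scores[0, AA_INDEX["A"]] == pytest.approx(math.log2(1 / q("A")))

    def test_large_pseudocount_drives_scores_to_zero(self):
        seed = SeedAlignment("MT", ["ACD", "ACD"])
        profile = build_profile(seed, pseudocount_weight=1e9)
        assert np.max(np.abs(profile.scores)) < 1e-6

    def test_matches_hand_counted_frequency_table(self):
        # brute-force oracle: count residues per column over a 4-row toy seed
        rows = ["ACDE", "ACDF", "AGDE", "ACDE"]
        alpha = 0.7
        profile = build_profile(SeedAlignment("KS", rows), alpha)
        for c in range(4):
            col = [r[c] for r in rows]
            for aa in set(col):
                f = col.count(aa) / len(col)
                expected = math.log2((f + alpha * q(aa)) / ((1 + alpha) * q(aa)))
                assert profile.scores[c, AA_INDEX[aa]] == pytest.approx(expected)

    def test_majority_gap_columns_dropped(self):
        seed = SeedAlignment("AT", ["A-CD", "A-CD", "AEC-", "A--D"])
        profile = build_profile(seed)
        # column 2 has 3/4 gaps -> insert; columns 1,3,4 remain
        assert profile.length == 3

    def test_empty_seed_rejected(self):
        with pytest.raises(ValidationError):
            build_profile(SeedAlignment("MT", []))

    def test_consensus_majority_with_alphabetic_ties(self):
        assert consensus(SeedAlignment("PT", ["AC", "AD", "GC", "GD"])) == "AC"


@pytest.fixture(scope="module")
def acp_profile(profiles):
    return profiles["ACP"]


@pytest.fixture(scope="module")
def acp_consensus():
    from mtminer.locate import default_seed_alignments

    return consensus(default_seed_alignments()["ACP"])


class TestScanProtein:
    def test_planted_consensus_found_near_true_position(self, acp_profile, acp_consensus):
        background = generate_background(300, seed=5)
        protein = background[:100] + acp_consensus + background[100:]
        hits = scan_protein(protein, acp_profile)
        assert len(hits) == 1
        assert abs(hits[0].start - 101) <= 10

    def test_no_hits_on_background_at_high_threshold(self, acp_profile):
        assert scan_protein(generate_background(400, seed=6), acp_profile) == []

    def test_two_planted_copies_give_disjoint_envelopes(self, acp_profile, acp_consensus):
        bg = generate_background(260, seed=7)
        protein = bg[:80] + acp_consensus + bg[80:180] + acp_consensus + bg[180:]
        hits = sorted(scan_protein(protein, acp_profile), key=lambda h: h.start)
        assert len(hits) == 2
        assert hits[0].end < hits[1].start

    def test_non_amino_acid_characters_reported(self, acp_profile):
        with pytest.raises(SequenceAlphabetError, match="'B'"):
            scan_protein("ACDBXACD", acp_profile)

    def test_planted_score_beats_every_random_window(self, profiles):
        # per-family: the planted consensus outscores equal-length background
        from mtminer.locate import default_seed_alignments

        seeds = default_seed_alignments()
        for family in ("SAT", "ACP"):
            cons = consensus(seeds[family])
            profile = profiles[family]
            planted = scan_protein(cons, profile, threshold_bits=10.0)
            assert planted, family
            top = max(h.score for h in planted)
            bg_hits = scan_protein(
                generate_background(len(cons), seed=11), profile, threshold_bits=-100.0
            )
            if bg_hits:
                assert top > max(h.score for h in bg_hits)


class TestTruthRecovery:
    def test_planted_domains_recovered_within_15_residues(self, profiles, ref_fingerprint):
        from mtminer.synth import synth_pks

        n_ok = 0
        for seed in range(20):
            protein, truth = synth_pks(
                ["SAT", "KS", "AT", "PT", "ACP", "MT"],
                ref_fingerprint,
                seed=1000 + seed,
                substitution_rate=0.10,
            )
            hits = []
            for family, profile in profiles.items():
                hits.extend(scan_protein(protein, profile))
            found = {h.family: h for h in hits}
            ok = set(found) == {f for f, _, _ in truth.domains}
            if ok:
                for family, start, end in truth.domains:
                    h = found[family]
                    if abs((h.start + h.end) / 2 - (start + end) / 2) > 15:
                        ok = False
            n_ok += ok
        assert n_ok == 20


class TestExtractMTDomain:
    def test_thirty_residue_extension(self):
        protein = "A" * 400
        hit = DomainHit("MT", 101, 300, 50.0, extended_end=330)
        assert len(extract_mt_domain(protein, hit)) == 230

    def test_extension_clipped_at_protein_end(self):
        protein = "A" * 320
        hit = DomainHit("MT", 101, 300, 50.0, extended_end=320)
        assert extract_mt_domain(protein, hit) == protein[100:320]

    def test_whole_protein_envelope(self):
        protein = "ACDEFGHIKL"
        hit = DomainHit("MT", 1, 10, 50.0, extended_end=10)
        assert extract_mt_domain(protein, hit) == protein

    def test_non_mt_hit_rejected(self):
        with pytest.raises(ValidationError, match="MT"):
            extract_mt_domain("A" * 100, DomainHit("KS", 1, 50, 50.0, 50))


class TestClassifyArchitecture:
    def _hits(self, spans):
        return [DomainHit(f, s, e, 99.0, e) for f, s, e in spans]

    def test_full_nrpks_architecture(self):
        spans = [("SAT", 1, 80), ("KS", 100, 190), ("AT", 200, 280),
                 ("PT", 300, 380), ("ACP", 400, 440), ("MT", 460, 760)]
        arch, flag = classify_architecture(self._hits(spans))
        assert arch == "SAT-KS-AT-PT-ACP-MT"
        assert flag

    def test_partial_architecture_not_nrpks(self):
        arch, flag = classify_architecture(self._hits([("KS", 1, 90), ("AT", 100, 180)]))
        assert arch == "KS-AT"
        assert not flag

    def test_sat_is_optional_for_the_flag(self):
        spans = [("KS", 1, 90), ("AT", 100, 180), ("PT", 200, 280), ("ACP", 300, 340)]
        _, flag = classify_architecture(self._hits(spans))
        assert flag

    def test_output_sorted_regardless_of_input_order(self):
        spans = [("MT", 460, 760), ("SAT", 1, 80), ("ACP", 400, 440),
                 ("KS", 100, 190), ("PT", 300, 380), ("AT", 200, 280)]
        arch, _ = classify_architecture(self._hits(spans))
        assert arch == "SAT-KS-AT-PT-ACP-MT"

    def test_overlapping_families_are_ambiguous(self):
        with pytest.raises(AmbiguousArchitectureError):
            classify_architecture(self._hits([("KS", 1, 90), ("AT", 50, 140)]))
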