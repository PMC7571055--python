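"""Genotype caller: candidate windows, 1Bx7 classification, composition
calls on the curated cultivar panels, and optimality of the search."""

import pytest

import glutencaller as gc
from glutencaller.calling import classify_bx7, candidate_alleles
from glutencaller.errors import ValidationError

from helpers import (brute_force_scores, expected_composition,
                     peaks_from_row, study_evidence, truth_recovered)


def _row(lib, table, cultivar):
    df = getattr(lib, table)
    return df[df.cultivar == cultivar].iloc[0]


class TestCandidateAlleles:
    def test_overlapping_x_pair(self, lib):
        names = [n for n, _ in candidate_alleles(lib, 86_420, 300)]
        assert "1Ax2*" in names and "1Bx6" in names
        assert names[0] == "1Bx6"   # closer reference mean comes first

    def test_unique_y_subunit(self, lib):
        names = [n for n, _ in candidate_alleles(lib, 67_630, 300)]
        assert names == ["1Dy10"]

    def test_mass_below_all_windows(self, lib):
        assert candidate_alleles(lib, 50_000, 300) == []


class TestClassifyBx7:
    def test_group1_by_mass(self, lib):
        assert classify_bx7(lib, 82_410) == "group1"

    def test_high_mass_needs_pcr(self, lib):
        assert classify_bx7(lib, 83_067) == "group2_or_OE"
        neg = gc.EvidenceFlags(bx7_duplication_pcr=False)
        assert classify_bx7(lib, 83_067, neg) == "group2"
        pos = gc.EvidenceFlags(bx7_duplication_pcr=True)
        assert classify_bx7(lib, 83_113, pos) == "OE"

    def test_outside_window_rejected(self, lib):
        with pytest.raises(ValidationError):
            classify_bx7(lib, 90_000)


class TestCallGenotype:
    def test_four_peak_sample_with_silent_glu_a1(self, lib):
        pl = gc.PeakList([gc.Peak(m, 1.0) for m in
                          (83_488, 75_886, 87_493, 69_410)],
                         sample_id="Chinese Spring", calibrated=True)
        call = gc.call_genotype(lib, pl)
        assert call.composition_string == "N, 7+8, 2+12"
        assert call.bx7_classification == "group2_or_OE"

    def test_obligatory_b1x_forces_near_isobaric_choice(self, lib):
        """86,840 Da could be 1Ax2* by mass alone, but the Glu-B1 x slot is
        obligatory and no other x-type peak exists, so it must be 1Bx6."""
        pl = gc.PeakList([gc.Peak(m, 1.0) for m in
                          (86_840, 75_993, 87_431, 69_404)],
                         sample_id="Brimstone", calibrated=True)
        call = gc.call_genotype(lib, pl)
        assert call.composition_string == "N, 6+8*, 2+12"

    def test_five_peak_sample(self, lib):
        pl = gc.PeakList([gc.Peak(m, 1.0) for m in
                          (86_556, 82_824, 74_295, 88_450, 68_400)],
                         sample_id="Cheyenne", calibrated=True)
        call = gc.call_genotype(lib, pl)
        assert call.composition_string == "2*, 7+9, 5+10"
        assert call.bx7_classification == "group1"

    def test_empty_peak_list_is_uncallable(self, lib):
        call = gc.call_genotype(lib, gc.PeakList([], calibrated=True))
        assert call.status == "uncallable"

    def test_no_matching_window_is_uncallable_with_diagnostics(self, lib):
        pl = gc.PeakList([gc.Peak(61_000.0, 1.0)], calibrated=True)
        call = gc.call_genotype(lib, pl)
        assert call.status == "uncallable"
        assert call.unassigned_peaks == [61_000.0]

    def test_rphplc_resolves_8_star(self, lib):
        row = _row(lib, "korean", "Baekchal")
        bare = gc.call_genotype(lib, peaks_from_row(lib, row))
        assert bare.haplotype_labels["Glu-B1"] == "7+8"
        assert any("8/8*" in f for f in bare.flags)
        ev = gc.EvidenceFlags(rphplc_calls=frozenset({"8*"}))
        resolved = gc.call_genotype(lib, peaks_from_row(lib, row), evidence=ev)
        assert resolved.haplotype_labels["Glu-B1"] == "7+8*"
        assert not any("8/8*" in f for f in resolved.flags)

    def test_positive_duplication_pcr_selects_7oe_pair(self, lib):
        row = _row(lib, "standards", "Glenlea")
        ev = study_evidence(row)
        call = gc.call_genotype(lib, peaks_from_row(lib, row), evidence=ev)
        assert call.haplotype_labels["Glu-B1"] == "7OE+8*"
        assert call.bx7_classification == "OE"

    def test_linked_pair_identifies_near_isobaric_y(self, lib):
        """1By18 at 75,224 Da (corrected) sits in the 1By8* window too; the
        17+18 linkage is what identifies it."""
        row = _row(lib, "standards", "Manital")
        call = gc.call_genotype(lib, peaks_from_row(lib, row))
        assert call.composition_string == "2*, 17+18, 2+12"
        assert not any("8" in f for f in call.flags)


class TestPanels:
    def test_standards_with_study_evidence_all_exact(self, lib):
        for _, row in lib.standards.iterrows():
            call = gc.call_genotype(lib, peaks_from_row(lib, row),
                                    evidence=study_evidence(row))
            assert call.composition_string == expected_composition(row), \
                row["cultivar"]

    def test_standards_without_evidence(self, lib):
        """Only the cultivars the study itself needed PCR for (the 7OE
        carriers) come out different, and there the truth is flagged."""
        for _, row in lib.standards.iterrows():
            call = gc.call_genotype(lib, peaks_from_row(lib, row))
            exp = expected_composition(row)
            if row["bx7_group"] == "OE":
                assert call.composition_string != exp
                assert truth_recovered(call, exp), row["cultivar"]
            else:
                assert call.composition_string == exp, row["cultivar"]

    def test_korean_with_rphplc_for_7_8star_cultivars(self, lib):
        ev = {c: gc.EvidenceFlags(rphplc_calls=frozenset({"8*"}))
              for c in ("Baekchal", "Sinmichal")}
        samples = [peaks_from_row(lib, row)
                   for _, row in lib.korean.iterrows()]
        calls, _ = gc.call_cohort(lib, samples, evidence=ev)
        for call, (_, row) in zip(calls, lib.korean.iterrows()):
            assert call.composition_string == expected_composition(row), \
                row["cultivar"]

    def test_search_never_beaten_by_full_enumeration(self, lib):
        """Independent brute-force enumeration over all haplotype
        combinations: no combination scores better than the returned one
        except mass-ambiguous swaps that the call lists as alternatives."""
        import pandas as pd

        rows = pd.concat([lib.standards, lib.korean]).iterrows()
        for _, row in rows:
            pl = peaks_from_row(lib, row)
            call = gc.call_genotype(lib, pl)
            scores = brute_force_scores(lib, [p.mass for p in pl.peaks])
            best_score, best_labels = min(scores)
            assert call.score <= best_score + 300.0, row["cultivar"]
            if call.score > best_score + 1e-9:
                truth = ", ".join(best_labels)
                assert truth_recovered(call, truth), (row["cultivar"], truth)
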