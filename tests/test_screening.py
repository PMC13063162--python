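"""Suspect matching and the QC filter cascade (blank, replicate, RT)."""

import pytest

from pfas_screen.features import Feature
from pfas_screen.screening import (
    CandidateHit,
    ScreeningConfig,
    apply_blank_filter,
    apply_replicate_filter,
    confirm_rt,
    match_suspects,
)
from pfas_screen.suspects import StandardsRegistry, ReferenceStandard, SuspectEntry
from pfas_screen.chem import parse_formula

CFG = ScreeningConfig()

PFHXS = SuspectEntry.from_formula("PFHxS", "C6HF13O3S", class_label="PFSA")
PFBS = SuspectEntry.from_formula("PFBS", "C4HF9O3S", class_label="PFSA")


def _feature(mz, rt=4.8, area=5e5, snr=500.0, sample="S", rep=1):
    return Feature(
        mz=mz, rt_apex=rt, area=area, height=area, snr=snr,
        sample_id=sample, replicate=rep, rt_left=rt - 0.1, rt_right=rt + 0.1,
    )


def _hit(suspect, mz, rt=4.8, area=5e5, sample="S", rep=1):
    from pfas_screen.chem import ppm_error

    f = _feature(mz, rt=rt, area=area, sample=sample, rep=rep)
    return CandidateHit(
        suspect=suspect, sample_id=sample, features=(f,),
        ppm_error=ppm_error(mz, suspect.theoretical_mz),
    )


class TestMatchSuspects:
    def test_within_tolerance_signed_error(self):
        hits = match_suspects([_feature(398.93690)], [PFHXS, PFBS], 5.0)
        assert len(hits) == 1
        assert hits[0].suspect.name == "PFHxS"
        assert hits[0].ppm_error == pytest.approx(0.75, abs=0.01)

    def test_six_ppm_off_no_hit(self):
        mz = PFHXS.theoretical_mz * (1 + 6e-6)
        assert match_suspects([_feature(mz)], [PFHXS], 5.0) == []

    def test_empty_features(self):
        assert match_suspects([], [PFHXS], 5.0) == []

    def test_isomers_all_matched(self):
        iso = SuspectEntry.from_formula("branched-PFHxS", "C6HF13O3S")
        hits = match_suspects([_feature(398.9366)], [PFHXS, iso], 5.0)
        assert {h.suspect.name for h in hits} == {"PFHxS", "branched-PFHxS"}

    def test_tightening_tolerance_never_adds(self):
        feats = [_feature(398.93690), _feature(398.9380), _feature(298.9430)]
        wide = {
            (h.suspect.name, h.features[0].mz)
            for h in match_suspects(feats, [PFHXS, PFBS], 5.0)
        }
        for tol in (3.0, 1.0, 0.5):
            narrow = {
                (h.suspect.name, h.features[0].mz)
                for h in match_suspects(feats, [PFHXS, PFBS], tol)
            }
            assert narrow <= wide
            wide = narrow


class TestBlankFilter:
    def test_blank_counterpart_at_half_area_removes(self):
        hit = _hit(PFBS, 298.9430)
        blank = _feature(298.9430, rt=4.85, area=2.5e5)
        assert apply_blank_filter([hit], [blank], CFG) == []

    def test_no_blank_counterpart_retains(self):
        hit = _hit(PFBS, 298.9430)
        blank = _feature(412.9664, rt=4.8, area=5e5)  # different m/z
        assert len(apply_blank_filter([hit], [blank], CFG)) == 1

    def test_five_percent_blank_area_retains(self):
        hit = _hit(PFBS, 298.9430)
        blank = _feature(298.9430, rt=4.8, area=0.05 * 5e5)
        assert len(apply_blank_filter([hit], [blank], CFG)) == 1

    def test_rt_mismatch_retains(self):
        hit = _hit(PFBS, 298.9430, rt=4.8)
        blank = _feature(298.9430, rt=5.8, area=5e5)
        assert len(apply_blank_filter([hit], [blank], CFG)) == 1


class TestReplicateFilter:
    REPS = {"S": {1, 2}}

    def test_single_replicate_removed(self):
        hits = [_hit(PFBS, 298.9430, rep=1)]
        assert apply_replicate_filter(hits, self.REPS, CFG) == []

    def test_both_replicates_concordant_rt_merged(self):
        hits = [
            _hit(PFBS, 298.9430, rt=4.80, rep=1),
            _hit(PFBS, 298.9432, rt=4.82, rep=2),
        ]
        (merged,) = apply_replicate_filter(hits, self.REPS, CFG)
        assert merged.in_both_replicates
        assert len(merged.features) == 2
        assert merged.measured_mz == pytest.approx(298.9431)

    def test_discordant_rt_removed(self):
        hits = [
            _hit(PFBS, 298.9430, rt=4.8, rep=1),
            _hit(PFBS, 298.9430, rt=6.0, rep=2),
        ]
        assert apply_replicate_filter(hits, self.REPS, CFG) == []

    def test_missing_second_replicate_errors(self):
        with pytest.raises(ValueError, match="S2"):
            apply_replicate_filter([], {"S2": {1}}, CFG)


class TestConfirmRt:
    REGISTRY = StandardsRegistry(
        [
            ReferenceStandard("PFBS", parse_formula("C4HF9O3S"), 3.80),
            ReferenceStandard("PFOS", parse_formula("C8HF17O3S"), 6.60),
        ]
    )

    @pytest.mark.parametrize(
        "suspect,formula,rt,expected",
        [
            ("PFBS", "C4HF9O3S", 3.84, True),   # delta 0.04 min
            ("PFOS", "C8HF17O3S", 6.68, True),  # delta 0.08 min
            ("PFBS", "C4HF9O3S", 3.95, False),  # delta 0.15 min
        ],
    )
    def test_delta_rt_rule(self, suspect, formula, rt, expected):
        hit = _hit(SuspectEntry.from_formula(suspect, formula),
                   mz=SuspectEntry.from_formula(suspect, formula).theoretical_mz,
                   rt=rt)
        (out,) = confirm_rt([hit], self.REGISTRY, rt_tol=0.1)
        assert out.rt_standard_match is expected

    def test_empty_registry_no_confirmation(self):
        hit = _hit(PFBS, 298.9430, rt=3.80)
        (out,) = confirm_rt([hit], StandardsRegistry([]), rt_tol=0.1)
        assert not out.rt_standard_match


class TestFilterCommutation:
    def test_blank_and_replicate_filters_commute_on_disjoint_hits(self):
        reps = {"S": {1, 2}}
        blank = [_feature(298.9430, rt=3.8, area=5e5)]
        hits = [
            _hit(PFBS, 298.9430, rt=3.8, rep=1),     # removed by blank filter
            _hit(PFBS, 298.9430, rt=3.8, rep=2),
            _hit(PFHXS, 398.9366, rt=4.8, rep=1),    # survives both
            _hit(PFHXS, 398.9366, rt=4.82, rep=2),
        ]
        a = apply_replicate_filter(apply_blank_filter(hits, blank, CFG), reps, CFG)
        b = apply_blank_filter(apply_replicate_filter(hits, reps, CFG), blank, CFG)
        assert {h.suspect.name for h in a} == {h.suspect.name for h in b} == {"PFHxS"}


class TestScreeningConfig:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ScreeningConfig(ppm_tol=0.0)
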