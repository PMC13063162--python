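"""Synthetic-scenario generator: determinism, closure, parameter recovery."""

import numpy as np
import pytest

from pfas_screen.chem import ppm_error
from pfas_screen.features import build_features, filter_features
from pfas_screen.synth import (
    InjectedCompound,
    InjectedDecoy,
    SampleSpec,
    Scenario,
    build_runs,
    groundwater_scenario,
    simulate_runs,
)


def single_compound_scenario(seed, ppm=0.5, area=5e5, rt=1.0):
    compound = InjectedCompound(
        name="PFBS", theoretical_mz=298.9430, rt=rt, area=area, ppm=ppm,
        fragments=(("FO3S", -1.3), ("SO3", -1.5)),
    )
    return Scenario(
        samples={"S": SampleSpec(compounds=(compound,))},
        seed=seed,
        rt_span=(0.0, 2.0),
        n_blanks=1,
    )


class TestScenarioValidation:
    def test_benchmark_scenario_shape(self):
        sc = groundwater_scenario(seed=7)
        assert set(sc.samples) == {"Sample3", "Sample4", "Sample5"}
        assert len(sc.samples["Sample3"].compounds) == 6
        assert len(sc.samples["Sample4"].compounds) == 2
        assert len(sc.samples["Sample5"].compounds) == 11
        for spec in sc.samples.values():
            assert sorted(d.kind for d in spec.decoys) == [
                "blank_contaminant", "off_ppm", "single_replicate",
                "sub_area", "sub_snr",
            ]

    def test_fprsa_fragment_set(self):
        sc = groundwater_scenario(seed=7)
        fprsa = next(
            c for c in sc.samples["Sample5"].compounds if c.name == "FPrSA"
        )
        assert {f for f, _ in fprsa.fragments} == {"C3F7", "FO2S", "NO2S"}
        # offsets mimic measured-vs-theory deviations: small, nonzero
        assert all(0 < abs(off) <= 2.0 for _, off in fprsa.fragments)

    def test_rt_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            single_compound_scenario(seed=1, rt=5.0)

    def test_true_compound_ppm_capped(self):
        with pytest.raises(ValueError, match="ppm"):
            single_compound_scenario(seed=1, ppm=6.0)

    def test_off_ppm_decoy_must_exceed_tolerance(self):
        with pytest.raises(ValueError, match="off_ppm"):
            InjectedDecoy("off_ppm", "x", 300.0, rt=1.0, area=1e5, ppm=2.0)

    def test_unknown_decoy_kind_rejected(self):
        with pytest.raises(ValueError, match="decoy kind"):
            InjectedDecoy("nonsense", "x", 300.0, rt=1.0, area=1e5)


class TestDeterminism:
    def test_same_seed_identical_runs(self):
        a = build_runs(single_compound_scenario(seed=9))
        b = build_runs(single_compound_scenario(seed=9))
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            for sa, sb in zip(ra.spectra, rb.spectra):
                np.testing.assert_array_equal(sa.mz, sb.mz)
                np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_same_seed_byte_identical_files(self, tmp_path):
        sc = single_compound_scenario(seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_runs(sc, d1)
        simulate_runs(sc, d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_different_seeds_differ(self):
        a = build_runs(single_compound_scenario(seed=1))
        b = build_runs(single_compound_scenario(seed=2))
        assert not np.array_equal(a[0].spectra[0].mz, b[0].spectra[0].mz)


class TestGeneratorDetectorClosure:
    def test_area_recovered_within_5pct(self):
        runs = build_runs(single_compound_scenario(seed=3, area=5e5))
        sample = next(r for r in runs if r.role == "sample")
        feats = filter_features(build_features(sample, [298.9430]))
        assert len(feats) == 1
        assert feats[0].area == pytest.approx(5e5, rel=0.05)

    def test_blank_contaminant_present_in_blank_and_sample(self):
        sc = groundwater_scenario(seed=7)
        runs = build_runs(sc)
        pfoa_mz = next(
            d.theoretical_mz
            for d in sc.samples["Sample3"].decoys
            if d.kind == "blank_contaminant"
        )
        blank = next(r for r in runs if r.role == "blank")
        sample = next(r for r in runs if r.sample_id == "Sample3")
        bf = filter_features(build_features(blank, [pfoa_mz]))
        sf = filter_features(build_features(sample, [pfoa_mz]))
        assert bf and sf
        assert bf[0].rt_apex == pytest.approx(sf[0].rt_apex, abs=0.05)

    @pytest.mark.parametrize("seed", range(20))
    def test_parameter_recovery_across_seeds(self, seed):
        """Injected RT, m/z, and area are recovered within tolerance."""
        ppm_in, rt_in, area_in = 0.8, 1.2, 4e5
        sc = single_compound_scenario(seed=seed, ppm=ppm_in, rt=rt_in, area=area_in)
        runs = build_runs(sc)
        sample = next(r for r in runs if r.role == "sample")
        feats = filter_features(build_features(sample, [298.9430]))
        assert len(feats) == 1
        f = feats[0]
        assert f.rt_apex == pytest.approx(rt_in, abs=sc.scan_spacing)
        assert ppm_error(f.mz, 298.9430) == pytest.approx(ppm_in, abs=0.5)
        assert f.area == pytest.approx(area_in, rel=0.05)


class TestMs2Generation:
    def test_apex_ms2_contains_configured_fragments(self):
        from pfas_screen.chem import fragment_mz
        from pfas_screen.msio import ms2_for_precursor

        sc = single_compound_scenario(seed=5)
        runs = build_runs(sc)
        sample = next(r for r in runs if r.role == "sample")
        compound = sc.samples["S"].compounds[0]
        spectra = ms2_for_precursor(sample, compound.measured_mz, (1.0 - 0.2, 1.0 + 0.2))
        assert len(spectra) == sc.ms2_events_per_peak
        for s in spectra:
            assert s.collision_energies == (15.0, 30.0, 50.0)
            for formula, off in compound.fragments:
                expected = fragment_mz(formula) + off * 1e-3
                assert np.min(np.abs(s.mz - expected)) < 1e-9

    def test_blank_runs_have_no_ms2(self):
        runs = build_runs(single_compound_scenario(seed=5))
        blank = next(r for r in runs if r.role == "blank")
        assert blank.ms2() == []

    def test_ms1_range_respected(self):
        runs = build_runs(single_compound_scenario(seed=5))
        for r in runs:
            for s in r.ms1():
                assert s.mz.min() >= 70.0 and s.mz.max() <= 1040.0
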