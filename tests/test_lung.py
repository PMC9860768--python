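"""Whole-lung model: morphometry scaling, efficiencies, breath ledger."""
import numpy as np
import pytest

import aerodep as ad
from aerodep.lung import generation_efficiencies


@pytest.fixture(scope="module")
def reference_lung():
    return ad.build_lung_model(3.3)


@pytest.fixture(scope="module")
def pattern():
    return ad.BreathingPattern(FRC=3.3, Q_in=18.0, Q_ex=18.0, TV=1.0)


class TestMorphometry:
    def test_reference_frc_scale_is_unity(self, reference_lung):
        assert reference_lung.diameters[0] == pytest.approx(0.018, rel=1e-12)

    def test_subject_scale_factor(self):
        """FRC 2.67 L scales linear dimensions by (2.67/3.3)^(1/3) = 0.932."""
        lung = ad.build_lung_model(2.67)
        ref = ad.build_lung_model(3.3)
        ratio = lung.diameters[0] / ref.diameters[0]
        assert ratio == pytest.approx((2.67 / 3.3) ** (1 / 3), rel=1e-12)
        assert ratio == pytest.approx(0.932, abs=5e-4)

    def test_doubling_frc_scales_lengths_by_cbrt2(self):
        l1 = ad.build_lung_model(3.0)
        l2 = ad.build_lung_model(6.0)
        assert np.allclose(l2.lengths / l1.lengths, 2.0 ** (1 / 3),
                           rtol=1e-12)

    def test_counts_double_per_generation(self, reference_lung):
        assert np.all(np.diff(np.log2(reference_lung.counts)) == 1.0)

    def test_model_volume_equals_frc(self, reference_lung):
        total = (reference_lung.airway_volumes.sum()
                 + reference_lung.extra_alveolar_volume)
        assert total == pytest.approx(3.3e-3, rel=1e-12)


class TestGenerationEfficiencies:
    def test_vanishing_for_tracers_without_diffusion(self, reference_lung):
        eta = generation_efficiencies(reference_lung, 0.01, 18.0,
                                      include_diffusion=False)
        assert np.all(eta["eta_combined"] < 1e-4)

    def test_sedimentation_grows_with_residence_time(self, reference_lung):
        fast = generation_efficiencies(reference_lung, 5.0, 36.0)
        slow = generation_efficiencies(reference_lung, 5.0, 18.0)
        assert np.all(slow["eta_sedimentation"]
                      >= fast["eta_sedimentation"])
        assert np.any(slow["eta_sedimentation"]
                      > fast["eta_sedimentation"])

    def test_impaction_monotone_in_stokes_number(self, reference_lung):
        """Impaction efficiency grows with d_p^2 (Stokes number sweep)."""
        etas = np.array([
            generation_efficiencies(reference_lung, d, 45.0)["eta_impaction"]
            for d in (1.0, 3.0, 5.0, 10.0, 20.0)])
        assert np.all(np.diff(etas, axis=0) >= 0)

    def test_all_efficiencies_are_fractions(self, reference_lung):
        for d in (0.5, 5.0, 30.0):
            eta = generation_efficiencies(reference_lung, d, 45.0)
            for arr in eta.values():
                assert np.all((arr >= 0.0) & (arr <= 1.0))


class TestSimulateBreaths:
    def test_total_prefilter(self, reference_lung, pattern):
        """eta_oral_in = 1: everything lands orally, nothing enters."""
        r = ad.simulate_breaths(reference_lung, pattern, 5.0, 1.0, 0.5)
        assert r.f_oral_in == 1.0
        assert r.f_TB == r.f_alv == 0.0
        assert ad.retained_fraction(r) == 1.0

    def test_transparent_lung(self, reference_lung, pattern):
        """Zero efficiencies everywhere: the full breath is exhaled."""
        zeros = np.zeros(reference_lung.n_generations)
        r = ad.simulate_breaths(reference_lung, pattern, 5.0, 0.0, 0.0,
                                mixing_fraction=0.0,
                                generation_eta={"in": zeros, "ex": zeros})
        assert ad.retained_fraction(r) == pytest.approx(0.0, abs=1e-15)
        assert r.f_exhaled_out == pytest.approx(1.0, abs=1e-15)

    def test_mass_ledger_closes(self, reference_lung):
        """Ledger sums to 1 within 1e-12 over a pattern x size grid."""
        for tv in (0.5, 0.75, 1.0, 1.25, 1.5):
            p = ad.BreathingPattern(FRC=3.3, Q_in=20.0, Q_ex=19.0, TV=tv)
            for d in (1.0, 2.9, 5.0, 10.0, 20.0):
                r = ad.simulate_breaths(reference_lung, p, d, 0.2, 0.1)
                assert abs(r.ledger_sum() - 1.0) <= 1e-12

    def test_retained_is_complement_of_exhaled(self, reference_lung,
                                               pattern):
        r = ad.simulate_breaths(reference_lung, pattern, 2.9, 0.3, 0.2)
        assert ad.retained_fraction(r) == pytest.approx(
            1.0 - r.f_exhaled_out, abs=1e-14)

    def test_retention_monotone_in_pause(self, reference_lung):
        vals = []
        for pause in (0.0, 1.0, 3.0, 10.0):
            p = ad.BreathingPattern(FRC=3.3, Q_in=18.0, Q_ex=18.0, TV=1.0,
                                    pause=pause)
            vals.append(ad.retained_fraction(
                ad.simulate_breaths(reference_lung, p, 3.0, 0.05, 0.05)))
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] > vals[0]

    def test_retention_monotone_in_size_1_to_10um(self, reference_lung,
                                                  pattern):
        """Sedimentation and impaction dominate 1-10 um: retention rises."""
        vals = [ad.retained_fraction(
            ad.simulate_breaths(reference_lung, pattern, d,
                                float(ad.stahlhofen_eta(d, 300.0)), 0.1))
            for d in (1.0, 2.0, 3.0, 5.0, 7.0, 10.0)]
        assert np.all(np.diff(vals) >= 0)

    def test_oral_filter_changes_only_oral_terms_proportionally(
            self, reference_lung, pattern):
        """Swapping the oral-filter source rescales the intrathoracic terms
        by the entering mass only (coupling arithmetic check)."""
        r1 = ad.simulate_breaths(reference_lung, pattern, 3.0, 0.2, 0.1)
        r2 = ad.simulate_breaths(reference_lung, pattern, 3.0, 0.6, 0.1)
        assert r2.f_TB / r1.f_TB == pytest.approx(0.4 / 0.8, rel=1e-9)
        assert r2.f_alv / r1.f_alv == pytest.approx(0.4 / 0.8, rel=1e-9)

    def test_tidal_volume_validation(self, reference_lung):
        with pytest.raises(ValueError):
            ad.BreathingPattern(FRC=3.3, Q_in=18.0, Q_ex=18.0, TV=8.0)


class TestBreathingFixture:
    def test_table_shape_and_values(self):
        df = ad.load_breathing_patterns()
        assert len(df) == 28
        assert set(df["subject"]) == {f"H{i}" for i in range(1, 8)}
        h1 = df[(df.subject == "H1") & (df.d_um == 1.0)
                & (df.phase_speed == "slow")].iloc[0]
        assert h1["Q_in_lpm"] == 19.26
        assert df[df.subject == "H5"]["FRC_L"].unique().tolist() == [2.67]

    def test_frc_column_digit_for_digit(self):
        df = ad.load_breathing_patterns()
        frc = df.drop_duplicates("subject").set_index("subject")["FRC_L"]
        assert frc.to_dict() == {
            "H1": 3.26, "H2": 3.38, "H3": 3.44, "H4": 3.51,
            "H5": 2.67, "H6": 3.43, "H7": 3.31}

    def test_slow_1um_rows_digit_for_digit(self):
        df = ad.load_breathing_patterns()
        sel = df[(df.d_um == 1.0) & (df.phase_speed == "slow")]
        assert sel["Q_in_lpm"].tolist() == [
            19.26, 19.08, 19.86, 17.70, 18.72, 17.64, 18.18]
        assert sel["Q_ex_lpm"].tolist() == [
            20.94, 19.32, 20.10, 18.24, 18.66, 17.82, 17.76]
        assert sel["TV_L"].tolist() == [
            1.116, 1.073, 1.101, 0.979, 1.041, 0.984, 1.009]
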