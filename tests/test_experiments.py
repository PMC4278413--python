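import numpy as np
import pytest

import cbf3select as cs
from cbf3select.cbf_model import ArchitectureSpec, CBFParameters, CBFTrajectory, enumerate_ensemble
from cbf3select.clock_driver import GENOTYPES, REGIMES
from cbf3select.experiments import (
    ArrhythmicTrajectoryError,
    cold_gating_profile,
    mutant_fold_change,
    peak_phase,
    simulate_fitted,
)
from cbf3select.synthetic_data import cbf3_template

TOP = enumerate_ensemble()[0]
TOP_PARAMS = CBFParameters(
    v_max=1.0, K={"LHY_CCA1": 0.1, "EC": 0.05, "TOC1": 0.3}, d=2.0
)


class TestPeakPhase:
    def test_template_trajectory_peaks_at_zt8(self):
        t = np.arange(0.0, 96.25, 0.25)
        traj = CBFTrajectory(times=t, mrna=cbf3_template(REGIMES["12L/12D"], t))
        assert peak_phase(traj) == pytest.approx(8.0, abs=0.25)

    def test_constant_trajectory_is_arrhythmic(self):
        t = np.arange(0.0, 96.25, 0.25)
        traj = CBFTrajectory(times=t, mrna=np.full_like(t, 0.7))
        with pytest.raises(ArrhythmicTrajectoryError):
            peak_phase(traj)

    def test_translation_equivariance(self):
        t = np.arange(0.0, 96.25, 0.25)
        base = CBFTrajectory(times=t, mrna=cbf3_template(REGIMES["12L/12D"], t))
        shifted = CBFTrajectory(times=t, mrna=cbf3_template(REGIMES["12L/12D"], np.maximum(t - 4.0, 0.0)))
        assert peak_phase(shifted) == pytest.approx((peak_phase(base) + 4.0) % 24.0, abs=0.3)

    def test_short_trajectory_rejected(self):
        t = np.arange(0.0, 36.25, 0.25)
        traj = CBFTrajectory(times=t, mrna=cbf3_template(REGIMES["12L/12D"], t))
        with pytest.raises(ValueError, match="two cycles"):
            peak_phase(traj)


class TestMutantFoldChange:
    def test_wild_type_fold_is_exactly_one(self):
        pred = mutant_fold_change(TOP, TOP_PARAMS, cs.WILD_TYPE)
        assert pred.fold_change == 1.0
        assert pred.qualitative_class == "wild-type-like"

    def test_sole_activator_knockout_abolishes_expression(self):
        for arch in enumerate_ensemble():
            if arch.activators == ("LHY_CCA1",):
                params = CBFParameters(
                    v_max=1.0, K={sp: 0.3 for sp in arch.regulators}, d=1.0
                )
                pred = mutant_fold_change(arch, params, GENOTYPES["lhy cca1"])
                assert pred.qualitative_class == "abolished"
                assert pred.mutant_arrhythmic

    def test_knockout_of_unused_regulator_changes_nothing(self):
        arch = ArchitectureSpec(activators=("LHY_CCA1",), repressors=("EC",))
        params = CBFParameters(v_max=1.0, K={"LHY_CCA1": 0.3, "EC": 0.1}, d=1.0)
        pred = mutant_fold_change(arch, params, GENOTYPES["toc1"])
        assert pred.fold_change == 1.0

    def test_removing_a_repressor_elevates_expression(self):
        arch = ArchitectureSpec(activators=("LHY_CCA1",), repressors=("TOC1",))
        params = CBFParameters(v_max=1.0, K={"LHY_CCA1": 0.3, "TOC1": 0.05}, d=1.0)
        pred = mutant_fold_change(arch, params, GENOTYPES["toc1"])
        assert pred.fold_change > 1.0


class TestColdGatingProfile:
    def test_identity_pulse_has_zero_response(self):
        for mode in ("via_LHY", "direct"):
            prof = cold_gating_profile(TOP, TOP_PARAMS, mode, fold=1.0, normalise=False)
            assert all(v == 0.0 for v in prof.induction)

    def test_identity_pulse_absolute_reading_matches_ambient(self):
        via = cold_gating_profile(
            TOP, TOP_PARAMS, "via_LHY", fold=1.0, normalise=False, statistic="absolute"
        )
        direct = cold_gating_profile(
            TOP, TOP_PARAMS, "direct", fold=1.0, normalise=False, statistic="absolute"
        )
        np.testing.assert_array_equal(via.induction, direct.induction)

    @pytest.mark.parametrize("mode", ["via_LHY", "direct"])
    def test_induction_monotone_in_fold(self, mode):
        profiles = [
            cold_gating_profile(TOP, TOP_PARAMS, mode, fold=f, normalise=False)
            for f in (1.0, 2.0, 5.0)
        ]
        for lo, hi in zip(profiles, profiles[1:]):
            assert all(h >= l - 1e-12 for l, h in zip(lo.induction, hi.induction))

    def test_direct_response_proportional_to_ambient_waveform(self):
        """A clock-independent pulse scales the transcript in place, so its
        response profile must track the ambient waveform at the pulse times."""
        prof = cold_gating_profile(TOP, TOP_PARAMS, "direct", fold=5.0, normalise=False)
        traj = simulate_fitted(TOP, TOP_PARAMS, regime=REGIMES["24L/0D"], duration=96.0)
        ambient = np.interp(48.0 + np.asarray(prof.pulse_times), traj.times, traj.mrna)
        ratios = np.asarray(prof.induction) / ambient
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-6)

    def test_normalised_profile_peaks_at_one(self):
        prof = cold_gating_profile(TOP, TOP_PARAMS, "via_LHY", fold=5.0)
        assert max(prof.induction) == pytest.approx(1.0)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            cold_gating_profile(TOP, TOP_PARAMS, "via_LHY", fold=0.5)
        with pytest.raises(ValueError):
            cold_gating_profile(TOP, TOP_PARAMS, "sideways")
        with pytest.raises(ValueError):
            cold_gating_profile(TOP, TOP_PARAMS, "direct", pulse_duration_h=30.0)
        with pytest.raises(ValueError):
            cold_gating_profile(TOP, TOP_PARAMS, "direct", statistic="median")
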