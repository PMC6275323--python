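"""Assay algebra: ferrozine inversion, spectral deconvolution, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedakin.observables import (DegenerateAssayError, LinearCalibration,
                                 SpectralSystem, deconvolve_quinones,
                                 fe2_from_ferrozine, forward_absorbance,
                                 h2o2_from_dpd, predict_observable)


@pytest.fixture
def sys():
    return SpectralSystem(eps_FeIIIDA2_475=1500.0,
                          eps_FeIIFZ_562_fromFeII=28000.0,
                          eps_FeIIFZ_562_fromFeIII=2000.0)


class TestFerrozine:
    def test_all_ferric_baseline(self, sys):
        A = 2000.0 * 5e-6 * 10.0
        assert fe2_from_ferrozine(A, 5e-6, sys).value == pytest.approx(0.0, abs=1e-18)

    def test_all_ferrous(self, sys):
        A = 28000.0 * 5e-6 * 10.0
        res = fe2_from_ferrozine(A, 5e-6, sys)
        assert res.value == pytest.approx(5e-6)
        assert not res.flagged

    def test_hand_evaluated_formula(self, sys):
        # (0.8 - 2000*5e-6*10) / ((28000-2000)*10) = 0.7/260000
        res = fe2_from_ferrozine(0.8, 5e-6, sys)
        assert res.value == pytest.approx(0.7 / 260000.0, rel=1e-12)
        assert res.value == pytest.approx(2.69e-6, rel=1e-2)

    def test_affine_in_absorbance(self, sys):
        v = [fe2_from_ferrozine(a, 5e-5, sys).value for a in (0.5, 0.6, 0.7)]
        assert v[2] - v[1] == pytest.approx(v[1] - v[0], rel=1e-9)

    def test_clipping_flag_and_degenerate(self, sys):
        assert fe2_from_ferrozine(10.0, 5e-6, sys) == (5e-6, True)
        assert fe2_from_ferrozine(-1.0, 5e-6, sys) == (0.0, True)
        bad = SpectralSystem(eps_FeIIIDA2_475=1500.0,
                             eps_FeIIFZ_562_fromFeII=2000.0,
                             eps_FeIIFZ_562_fromFeIII=2000.0)
        with pytest.raises(DegenerateAssayError):
            fe2_from_ferrozine(0.5, 5e-6, bad)


class TestForwardAbsorbance:
    def test_zero_state(self, sys):
        assert forward_absorbance({}, sys) == (0.0, 0.0)

    def test_tabulated_absorptivities(self, sys):
        a475, a580 = forward_absorbance({"DAC": 1e-6}, sys)
        assert a475 == pytest.approx(3.245e-2)
        assert a580 == pytest.approx(4.39e-3)
        a475, a580 = forward_absorbance({"FeIIIDA2": 1e-6}, sys)
        assert a580 == pytest.approx(3.121e-2)


class TestDeconvolution:
    def test_round_trip_identity(self, sys):
        a475, a580 = forward_absorbance({"DAC": 1e-6, "FeIIIDA2": 2e-6}, sys)
        dac, fe = deconvolve_quinones(a475, a580, sys)
        assert dac.value == pytest.approx(1e-6, rel=1e-10)
        assert fe.value == pytest.approx(2e-6, rel=1e-10)

    def test_pure_dac_sample(self, sys):
        c = 3e-6
        dac, fe = deconvolve_quinones(3245.0 * c * 10, 439.0 * c * 10, sys)
        assert dac.value == pytest.approx(c, rel=1e-10)
        assert fe.value == pytest.approx(0.0, abs=1e-16)

    def test_hand_elimination_example(self, sys):
        # A475=0.05, A580=0.07, l=10: eliminate the bis complex via the 580 row
        # c_dac = (A475 - e_fe475*A580/e_fe580) / (e_dac475 - e_fe475*e_dac580/e_fe580) / l
        e = {"d475": 32450.0, "d580": 4390.0, "f475": 15000.0, "f580": 31210.0}
        c_dac = (0.05 - e["f475"] * 0.07 / e["f580"]) / (
            e["d475"] - e["f475"] * e["d580"] / e["f580"])
        c_fe = (0.07 - e["d580"] * c_dac) / e["f580"]
        dac, fe = deconvolve_quinones(0.05, 0.07, sys)
        assert dac.value == pytest.approx(c_dac, rel=1e-12)
        assert fe.value == pytest.approx(c_fe, rel=1e-12)

    def test_sequential_equals_joint_solve(self, sys):
        for a475, a580 in [(0.01, 0.02), (0.3, 0.05), (0.0, 0.1)]:
            seq = deconvolve_quinones(a475, a580, sys, method="sequential")
            joint = deconvolve_quinones(a475, a580, sys, method="joint")
            assert seq[0].value == pytest.approx(joint[0].value, rel=1e-10, abs=1e-18)
            assert seq[1].value == pytest.approx(joint[1].value, rel=1e-10, abs=1e-18)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(c_dac=st.floats(0, 1e-4), c_fe=st.floats(0, 1e-4),
           e_f475=st.floats(100.0, 1e4))
    def test_round_trip_property_random_absorptivities(self, c_dac, c_fe, e_f475):
        """deconvolve(forward(.)) is the identity on non-negative states."""
        system = SpectralSystem(eps_FeIIIDA2_475=e_f475)
        a475, a580 = forward_absorbance({"DAC": c_dac, "FeIIIDA2": c_fe}, system)
        dac, fe = deconvolve_quinones(a475, a580, system)
        assert dac.value == pytest.approx(c_dac, rel=1e-10, abs=1e-16)
        assert fe.value == pytest.approx(c_fe, rel=1e-10, abs=1e-16)

    def test_negative_solution_clipped_and_flagged(self, sys):
        dac, fe = deconvolve_quinones(0.0, 0.1, sys)
        assert dac.value == 0.0 and dac.flagged

    def test_singular_matrix_rejected(self):
        with pytest.raises(DegenerateAssayError):
            SpectralSystem(eps_FeIIIDA2_475=3245.0, eps_DAC_475=3245.0,
                           eps_FeIIIDA2_580=439.0, eps_DAC_580=439.0)


class TestDpd:
    def test_blank(self):
        cal = LinearCalibration(slope=4.5e4, intercept=0.01)
        assert h2o2_from_dpd(0.01, cal).value == 0.0

    def test_hand_inversion(self):
        cal = LinearCalibration(slope=4.5e4, intercept=0.01)
        assert h2o2_from_dpd(0.46, cal).value == pytest.approx(1.0e-5)

    def test_below_blank_clipped(self):
        cal = LinearCalibration(slope=4.5e4, intercept=0.01)
        res = h2o2_from_dpd(0.005, cal)
        assert res == (0.0, True)

    def test_extrapolation_flag_and_bad_slope(self):
        cal = LinearCalibration(slope=4.5e4, intercept=0.0,
                                valid_range=(0.0, 1e-5))
        assert h2o2_from_dpd(0.9, cal).flagged
        with pytest.raises(DegenerateAssayError):
            LinearCalibration(slope=0.0)


def test_predict_observable_sums_ferrozine_channels():
    class FakeTraj:
        times = np.array([0.0, 60.0])
        def __getitem__(self, s):
            return {"FeII": np.array([4e-6, 2e-6]),
                    "FeIIDA": np.array([1e-6, 0.5e-6])}.get(s, np.zeros(2))
    out = predict_observable(FakeTraj(), "FeII_ferrozine", [0.0, 60.0])
    assert out == pytest.approx([5e-6, 2.5e-6])
    with pytest.raises(KeyError):
        predict_observable(FakeTraj(), "unknown", [0.0])
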