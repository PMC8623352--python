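"""Spectrum prediction, type-II bands and constants fitting."""

import math

import numpy as np
import pytest

from amwspec import (ConstantsModel, DistortionSet, InvalidInputError,
                     LineSelection, MeasuredLine, NoiseSpec,
                     RotationalConstants, SpectrumModel, StateModel,
                     fit_constants, predict_spectrum, simulate_linelist,
                     type2_band_spacing)
from amwspec.datasets import hyperfine_params, state_constants
from amwspec.spectra import BOLTZMANN_MHZ_PER_K


@pytest.fixture(scope="module")
def amp_model(amp_0plus):
    rc, dist = amp_0plus
    return SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                         mu_a=0.166, mu_b=0.86, temperature=1.0)


class TestPrediction:
    def test_zero_dipoles_no_transitions(self, amp_0plus):
        rc, dist = amp_0plus
        m = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),))
        assert predict_spectrum(m, 4000, 20000, J_max=3) == []

    def test_selection_rules_by_dipole_component(self, amp_0plus):
        rc, dist = amp_0plus
        for mu, branch in ((dict(mu_a=1.0), "a"), (dict(mu_b=1.0), "b"),
                           (dict(mu_c=1.0), "c")):
            m = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                              temperature=2.0, **mu)
            trans = predict_spectrum(m, 2000, 40000, J_max=4)
            assert trans
            for t in trans:
                assert t.branch == branch
                dka = abs(t.upper[1] - t.lower[1]) % 2
                dkc = abs(t.upper[2] - t.lower[2]) % 2
                assert (dka, dkc) == {"a": (0, 1), "b": (1, 1),
                                      "c": (1, 0)}[branch]

    def test_low_j_intensity_ratio_closed_form(self, amp_0plus):
        """1_01 <- 0_00 (a-type) vs 1_11 <- 0_00 (b-type) share the lower
        level; their line strengths are exactly mu_a^2 and mu_b^2, so the
        intensity ratio reduces to the frequency/stimulated-emission
        factor, hand-computable from the rigid-rotor energies."""
        rc, _ = amp_0plus
        mu_a, mu_b, T = 0.166, 0.86, 1.0
        m = SpectrumModel(states=(StateModel(rc=rc),), mu_a=mu_a, mu_b=mu_b,
                          temperature=T)
        trans = predict_spectrum(m, 2000, 9000, J_max=1)
        by_upper = {t.upper: t for t in trans if t.lower == (0, 0, 0)}
        nu_a = rc.B + rc.C
        nu_b = rc.A + rc.C
        kT = BOLTZMANN_MHZ_PER_K * T
        expected = ((nu_a * mu_a**2 * (1 - math.exp(-nu_a / kT)))
                    / (nu_b * mu_b**2 * (1 - math.exp(-nu_b / kT))))
        ratio = by_upper[(1, 0, 1)].intensity / by_upper[(1, 1, 1)].intensity
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_invalid_window(self, amp_model):
        with pytest.raises(InvalidInputError):
            predict_spectrum(amp_model, 9000, 4000)


class TestTypeIIBands:
    def test_monomer_band_spacing_is_2c(self, amp_0plus):
        """High-J R-branch clumps repeat every 2C ~ 3.7 GHz."""
        rc, dist = amp_0plus
        m = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                          mu_a=0.166, mu_b=0.86, temperature=300.0,
                          partition="room")
        trans = predict_spectrum(m, 255000, 290000, J_max=95)
        assert type2_band_spacing(trans) == pytest.approx(2 * rc.C, abs=10.0)

    def test_synthetic_planar_prolate(self):
        rc = RotationalConstants(3000.0, 1500.0, 1000.0)  # exactly planar
        m = SpectrumModel(states=(StateModel(rc=rc),), mu_a=1.0,
                          temperature=300.0, partition="room")
        trans = predict_spectrum(m, 40000, 70000, J_max=45)
        assert type2_band_spacing(trans) == pytest.approx(2000.0, abs=10.0)

    def test_single_band_errors(self, amp_0plus):
        rc, dist = amp_0plus
        m = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                          mu_a=0.166, mu_b=0.86, temperature=300.0)
        trans = predict_spectrum(m, 258000, 259500, J_max=95)
        with pytest.raises(InvalidInputError):
            type2_band_spacing(trans)


def _measured_from_prediction(model, f_min, f_max, J_max, unc, source="FTMW",
                              n=None):
    trans = predict_spectrum(model, f_min, f_max, J_max=J_max)
    if n is not None:
        trans = sorted(trans, key=lambda t: -t.intensity)[:n]
    return [MeasuredLine(t.frequency, unc, t.upper, t.lower, t.state_label,
                         source=source) for t in trans]


class TestFitConstants:
    def test_noise_free_recovery(self, amp_0plus):
        """Perturbed start recovers the generating constants to <= 1 Hz
        with sigma_fit = 0."""
        rc, dist = amp_0plus
        model = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                              mu_a=0.166, mu_b=0.86, temperature=2.0)
        lines = _measured_from_prediction(model, 4000, 45000, 6, 0.002)
        start = ConstantsModel({rc.state_label: {
            "rc": RotationalConstants(rc.A * 1.001, rc.B * 0.999,
                                      rc.C * 1.001, rc.state_label),
            "distortion": dist}})
        free = [f"{rc.state_label}:{k}" for k in ("A", "B", "C")]
        res = fit_constants(lines, start, free)
        for key, truth in zip(free, (rc.A, rc.B, rc.C)):
            assert res.params[key] == pytest.approx(truth, abs=1e-6)
        assert res.sigma_fit_khz["FTMW"] == pytest.approx(0.0, abs=1e-6)

    def test_noisy_recovery_and_sigma(self, amw_parent):
        """100 lines at 2 kHz noise: sigma_fit within chi-square bounds
        and constants within 3 standard errors of truth."""
        rc, dist = amw_parent
        model = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                              mu_a=1.0, mu_b=0.4, temperature=2.0)
        sel = LineSelection(f_min=3000, f_max=25000, J_max=9, max_lines=100)
        lines = simulate_linelist(model, sel, NoiseSpec(seed=11), "FTMW")
        assert len(lines) == 100
        start = ConstantsModel({rc.state_label: {"rc": rc,
                                                 "distortion": dist}})
        free = [f"{rc.state_label}:{k}" for k in ("A", "B", "C")]
        res = fit_constants(lines, start, free)
        assert 1.4 <= res.sigma_fit_khz["FTMW"] <= 2.6
        for key, truth in zip(free, (rc.A, rc.B, rc.C)):
            assert abs(res.params[key] - truth) <= 3 * res.std_errors[key]

    def test_two_subset_global_fit(self, amp_0plus):
        """Mixed-accuracy data: per-subset rms lands near the respective
        noise levels (2 and 50 kHz)."""
        rc, dist = amp_0plus
        model = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                              mu_a=0.166, mu_b=0.86, temperature=2.0)
        ft = simulate_linelist(model,
                               LineSelection(4000, 25000, J_max=6,
                                             max_lines=60),
                               NoiseSpec(seed=3), "FTMW")
        mm = simulate_linelist(model,
                               LineSelection(150000, 200000, J_max=40,
                                             max_lines=120),
                               NoiseSpec(seed=4), "MMW")
        start = ConstantsModel({rc.state_label: {"rc": rc,
                                                 "distortion": dist}})
        free = [f"{rc.state_label}:{k}" for k in ("A", "B", "C")]
        res = fit_constants(ft + mm, start, free)
        assert 1.0 <= res.sigma_fit_khz["FTMW"] <= 3.0
        assert 35.0 <= res.sigma_fit_khz["MMW"] <= 65.0

    def test_all_fixed_reproduces_prediction_residuals(self, amp_0plus):
        rc, dist = amp_0plus
        model = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                              mu_a=0.166, mu_b=0.86, temperature=2.0)
        lines = _measured_from_prediction(model, 4000, 30000, 4, 0.002)
        cm = ConstantsModel({rc.state_label: {"rc": rc, "distortion": dist}})
        res = fit_constants(lines, cm, free=[])
        assert np.allclose(res.residuals["obs_minus_calc_mhz"], 0.0,
                           atol=1e-9)

    def test_doubling_uncertainties_scaling(self, amw_parent):
        """Uniformly doubled uncertainties: same values, doubled errors."""
        rc, dist = amw_parent
        model = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                              mu_a=1.0, mu_b=0.4, temperature=2.0)
        sel = LineSelection(f_min=3000, f_max=20000, J_max=7, max_lines=50)
        lines = simulate_linelist(model, sel, NoiseSpec(seed=7), "FTMW")
        doubled = [MeasuredLine(l.frequency, 2 * l.uncertainty, l.upper,
                                l.lower, l.state_label, source=l.source)
                   for l in lines]
        free = [f"{rc.state_label}:{k}" for k in ("A", "B", "C")]

        def run(ls):
            cm = ConstantsModel({rc.state_label: {"rc": rc,
                                                  "distortion": dist}})
            return fit_constants(ls, cm, free)

        r1, r2 = run(lines), run(doubled)
        for k in free:
            assert r2.params[k] == pytest.approx(r1.params[k], abs=1e-7)
            assert r2.std_errors[k] == pytest.approx(2 * r1.std_errors[k],
                                                     rel=1e-4)

    def test_sigma_invariant_under_reordering(self, amw_parent):
        rc, dist = amw_parent
        model = SpectrumModel(states=(StateModel(rc=rc, distortion=dist),),
                              mu_a=1.0, mu_b=0.4, temperature=2.0)
        sel = LineSelection(f_min=3000, f_max=20000, J_max=7, max_lines=40)
        lines = simulate_linelist(model, sel, NoiseSpec(seed=9), "FTMW")
        free = [f"{rc.state_label}:A"]

        def run(ls):
            cm = ConstantsModel({rc.state_label: {"rc": rc,
                                                  "distortion": dist}})
            return fit_constants(ls, cm, free).sigma_fit_khz["FTMW"]

        assert run(lines) == pytest.approx(run(lines[::-1]), abs=1e-9)

    def test_hyperfine_resolved_fit_recovers_coupling(self, amw_parent):
        """Synthetic F-resolved components refit the hyperfine
        combinations of both nitrogen nuclei."""
        from amwspec import (AsymmetricRotor, RotationalLevel,
                             hyperfine_pattern, tensor_from_fit_params)
        rc, dist = amw_parent
        params = hyperfine_params("amw", "parent")
        rotor = AsymmetricRotor(rc, dist)
        tensors = [tensor_from_fit_params(p) for p in params]
        lines = []
        for (upq, loq) in [((1, 0, 1), (0, 0, 0)), ((2, 0, 2), (1, 0, 1)),
                           ((2, 1, 2), (1, 1, 1)), ((3, 0, 3), (2, 0, 2)),
                           ((3, 1, 3), (2, 1, 2)), ((2, 1, 1), (1, 1, 0))]:
            up = RotationalLevel(*upq, 0.0, rc.state_label)
            lo = RotationalLevel(*loq, 0.0, rc.state_label)
            nu0 = (rotor.level_energy(*upq) - rotor.level_energy(*loq))
            for c in hyperfine_pattern(up, lo, tensors, rotor):
                if c.intensity < 0.02:
                    continue
                lines.append(MeasuredLine(
                    nu0 + c.offset, 0.002, upq, loq, rc.state_label,
                    hf_upper=(c.upper[3], c.upper[4]),
                    hf_lower=(c.lower[3], c.lower[4])))
        from dataclasses import replace
        # modest starting offset: component assignments must stay valid,
        # as in any real hyperfine analysis
        start_params = [replace(p, three_halves_chi_aa=p.three_halves_chi_aa
                                + 0.05) for p in params]
        cm = ConstantsModel({rc.state_label: {
            "rc": rc, "distortion": dist, "tensors": start_params}})
        free = [f"{rc.state_label}:{p.nucleus_label}:chi32aa" for p in params]
        res = fit_constants(lines, cm, free)
        for p in params:
            key = f"{rc.state_label}:{p.nucleus_label}:chi32aa"
            assert res.params[key] == pytest.approx(p.three_halves_chi_aa,
                                                    abs=1e-6)

    def test_empty_line_list_rejected(self, amw_parent):
        rc, dist = amw_parent
        cm = ConstantsModel({rc.state_label: {"rc": rc, "distortion": dist}})
        with pytest.raises(InvalidInputError):
            fit_constants([], cm, [f"{rc.state_label}:A"])
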