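"""XIC extraction, peak detection, RT calibration and isomer splitting."""

import random

import numpy as np
import pytest

from diahist.chemistry import monoisotopic_mass, precursor_mz
from diahist.dia import DIARun, Spectrum
from diahist.quant import (
    XICTrace,
    calibrate_rt,
    detect_peak,
    discriminating_ions,
    extract_xic,
    quantify_form,
    quantify_run,
    split_isobaric,
)
from diahist.simulate import FormTruth, simulate_run, truth_table
from diahist.targets import enumerate_forms, group_isobaric


def gaussian_trace(apex_rt=5.0, sigma=0.02, height=1e6, dt=0.0127,
                   span=0.5, mz=500.0):
    rt = np.arange(apex_rt - span, apex_rt + span, dt)
    inten = height * np.exp(-0.5 * ((rt - apex_rt) / sigma) ** 2)
    return XICTrace(mz=mz, ppm=10.0, rt=rt, intensity=inten)


class TestExtractXic:
    def test_no_signal_gives_zero_trace(self, small_truth_factory,
                                        mono_ac_quartet):
        form = mono_ac_quartet.forms[0]
        truth = small_truth_factory(
            [FormTruth(form=form, charge=2, rt_min=1.0, sigma_s=1.25,
                       area=1e6)]
        )
        run = simulate_run(truth)
        trace = extract_xic(run, 555.5, ppm=10.0)
        assert np.all(trace.intensity == 0)

    def test_apex_within_one_cycle_of_truth(self, small_truth_factory,
                                            mono_ac_quartet):
        form = mono_ac_quartet.forms[0]
        truth = small_truth_factory(
            [FormTruth(form=form, charge=2, rt_min=1.0, sigma_s=1.25,
                       area=1e6)]
        )
        run = simulate_run(truth)
        mz = precursor_mz(monoisotopic_mass(form), 2)
        trace = extract_xic(run, mz, ppm=10.0)
        apex_rt = trace.rt[np.argmax(trace.intensity)]
        assert abs(apex_rt - 1.0) <= truth.cycle_time_s / 60.0

    def test_targets_30ppm_apart_do_not_cross_talk(self):
        mz0 = 600.0
        mz1 = mz0 * (1 + 30e-6)
        spec = Spectrum(
            scan=1, ms_level=1, rt_min=0.1,
            mz=np.array([mz0, mz1]), intensity=np.array([10.0, 20.0]),
        )
        run = DIARun([spec])
        t0 = extract_xic(run, mz0, ppm=10.0)
        t1 = extract_xic(run, mz1, ppm=10.0)
        assert t0.intensity[0] == 10.0
        assert t1.intensity[0] == 20.0


class TestDetectPeak:
    def test_clean_gaussian_apex_and_area(self):
        sigma = 0.02
        height = 1e6
        trace = gaussian_trace(apex_rt=5.0, sigma=sigma, height=height)
        peak = detect_peak(trace, expected_rt=5.0, rt_tolerance=0.2)
        assert peak is not None
        assert peak.apex_rt == pytest.approx(5.0, abs=0.013)
        analytic = height * sigma * np.sqrt(2 * np.pi)
        assert peak.area == pytest.approx(analytic, rel=0.02)
        assert peak.left_rt < peak.apex_rt < peak.right_rt

    def test_all_zero_trace(self):
        trace = XICTrace(mz=500.0, ppm=10.0, rt=np.linspace(0, 1, 50),
                         intensity=np.zeros(50))
        assert detect_peak(trace, 0.5, 0.2) is None

    def test_tie_broken_toward_expected_rt(self):
        rt = np.linspace(0, 2, 201)
        inten = np.zeros_like(rt)
        for mu in (0.5, 1.5):
            inten += 1e5 * np.exp(-0.5 * ((rt - mu) / 0.03) ** 2)
        trace = XICTrace(mz=500.0, ppm=10.0, rt=rt, intensity=inten)
        peak = detect_peak(trace, expected_rt=1.4, rt_tolerance=1.5)
        assert peak.apex_rt == pytest.approx(1.5, abs=0.02)

    def test_noise_floor_suppresses_small_peaks(self):
        trace = gaussian_trace(height=50.0)
        assert detect_peak(trace, 5.0, 0.2, noise_floor=1e3) is None


class TestQuantifyForm:
    def test_area_recovery_within_two_percent(self, small_truth_factory,
                                              mono_ac_quartet):
        form = mono_ac_quartet.forms[1]
        truth = small_truth_factory(
            [FormTruth(form=form, charge=2, rt_min=1.0, sigma_s=1.25,
                       area=2.5e6)]
        )
        run = simulate_run(truth)
        rec, peak = quantify_form(run, form, 2, expected_rt=1.0)
        assert rec.detected
        assert rec.area == pytest.approx(2.5e6, rel=0.02)

    def test_absent_form_flagged(self, small_truth_factory, mono_ac_quartet):
        present, absent = mono_ac_quartet.forms[0], mono_ac_quartet.forms[1]
        truth = small_truth_factory(
            [FormTruth(form=present, charge=2, rt_min=1.0, sigma_s=1.25,
                       area=1e6)]
        )
        run = simulate_run(truth)
        rec, peak = quantify_form(run, absent, 3, expected_rt=1.0)
        assert not rec.detected
        assert rec.area == 0.0
        assert "not_detected" in rec.flags

    def test_sampling_rate_sets_points_across_peak(self, small_truth_factory,
                                                   mono_ac_quartet):
        """A 7.6-s-wide peak sampled at 0.761 s/cycle spans ~10 cycles."""
        from diahist.simulate import SyntheticTruth
        from diahist.windows import fixed_scheme

        sigma_s = 7.6 / (2 * 3.035)  # 1%-of-apex base width of 7.6 s
        form = mono_ac_quartet.forms[0]
        scheme = fixed_scheme(300, 1120, 40, 20, ms1_ms=100, ms2_ms=10,
                              overhead_ms=5.6)  # 42 windows
        truth = SyntheticTruth(
            forms=[FormTruth(form=form, charge=2, rt_min=1.0,
                             sigma_s=sigma_s, area=1e6)],
            scheme=scheme,
            gradient_min=2.0,
        )
        assert truth.cycle_time_s == pytest.approx(0.761, abs=1e-3)
        run = simulate_run(truth)
        mz = precursor_mz(monoisotopic_mass(form), 2)
        trace = extract_xic(run, mz, ppm=10.0)
        base = 3.035 * sigma_s / 60.0
        inside = np.abs(trace.rt - 1.0) <= base
        assert int(inside.sum()) == pytest.approx(10, abs=1)
        # detected boundaries widen slightly past the 1% base after smoothing
        rec, peak = quantify_form(run, form, 2, expected_rt=1.0)
        width_cycles = peak.width_min * 60.0 / truth.cycle_time_s
        # N inclusive samples span N-1 cycle intervals
        assert abs((peak.points - 1) - width_cycles) <= 1


class TestDiscriminatingIons:
    def test_toy_two_site_peptide(self):
        """AKGGKR mono-ac: b2..b4 (between K2 and K5) discriminate."""
        forms = enumerate_forms("AKGGKR", {"K": ["ac"]}, max_mods=1)
        (group,) = group_isobaric(forms, charge=2)
        ions = discriminating_ions(group)
        for label, ion_list in ions.items():
            names = {ion for ion, _ in ion_list}
            assert {"b2", "b3", "b4"}.issubset(names)
            assert {"y2", "y3", "y4"}.issubset(names)  # complements
            assert "b5" not in names and "y1" not in names

    def test_quartet_y10_discriminates_k8ac(self, mono_ac_quartet):
        ions = discriminating_ions(mono_ac_quartet)
        k8 = [f.label for f in mono_ac_quartet.forms if "K8ac" in f.label][0]
        names = {ion for ion, _ in ions[k8]}
        assert "y10" in names

    def test_quartet_b13_is_shared_by_all_members(self, mono_ac_quartet):
        """Every mono-ac member carries its acetyl inside b13, so b13 cannot
        separate them; it only separates ac from pseudo-isobaric me3 forms."""
        ions = discriminating_ions(mono_ac_quartet)
        for ion_list in ions.values():
            assert all(ion != "b13" for ion, _ in ion_list)

    def test_single_member_group_has_no_ions(self):
        (form,) = enumerate_forms("GAGR", {})
        (group,) = group_isobaric([form], charge=2)
        assert discriminating_ions(group) == {form.label: []}


def quartet_truth(factory, fractions=(0.4, 0.3, 0.2, 0.1), area=2e6,
                  rt=1.0, **kwargs):
    from diahist.targets import digest, load_histones

    h4 = load_histones()["H4"]
    (pep,) = [p for p in digest(h4, "H4") if p.span == (4, 17)]
    forms = enumerate_forms(pep, {"K": ["ac"]}, max_mods=1)
    return factory(
        [
            FormTruth(form=f, charge=2, rt_min=rt, sigma_s=1.25,
                      area=area * frac, group_id="q", fraction=frac)
            for f, frac in zip(forms, fractions)
        ],
        **kwargs,
    )


class TestSplitIsobaric:
    def test_noiseless_quartet_recovered_to_machine_precision(
        self, small_truth_factory, mono_ac_quartet
    ):
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        rec, peak = quantify_form(run, mono_ac_quartet.forms[0], 2,
                                  expected_rt=1.0)
        result = split_isobaric(mono_ac_quartet, run, peak)
        expected = {
            f"H4 4-17 K{site}ac": frac
            for site, frac in zip((5, 8, 12, 16), (0.4, 0.3, 0.2, 0.1))
        }
        for label, frac in result.fractions.items():
            assert frac == pytest.approx(expected[label], abs=1e-6)
        assert not result.low_confidence

    @pytest.mark.parametrize("n_members", [2, 3, 4])
    def test_exact_recovery_for_smaller_families(self, small_truth_factory,
                                                 n_members):
        fractions = np.arange(n_members, 0, -1.0)
        fractions /= fractions.sum()
        from diahist.targets import digest, load_histones

        h4 = load_histones()["H4"]
        (pep,) = [p for p in digest(h4, "H4") if p.span == (4, 17)]
        forms = enumerate_forms(pep, {"K": ["ac"]}, max_mods=1)[:n_members]
        truth = small_truth_factory(
            [
                FormTruth(form=f, charge=2, rt_min=1.0, sigma_s=1.25,
                          area=2e6 * frac, group_id="g", fraction=frac)
                for f, frac in zip(forms, fractions)
            ]
        )
        run = simulate_run(truth)
        (group,) = group_isobaric(forms, charge=2)
        rec, peak = quantify_form(run, forms[0], 2, expected_rt=1.0)
        result = split_isobaric(group, run, peak)
        got = [result.fractions[f.label] for f in forms]
        assert np.allclose(got, fractions, atol=1e-9)

    def test_nnls_agrees_with_spans_noiseless(self, small_truth_factory,
                                              mono_ac_quartet):
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        rec, peak = quantify_form(run, mono_ac_quartet.forms[0], 2,
                                  expected_rt=1.0)
        spans = split_isobaric(mono_ac_quartet, run, peak, method="spans")
        nnls = split_isobaric(mono_ac_quartet, run, peak, method="nnls")
        for label in spans.fractions:
            assert nnls.fractions[label] == pytest.approx(
                spans.fractions[label], abs=1e-6
            )

    def test_order_independent(self, small_truth_factory, mono_ac_quartet):
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        rec, peak = quantify_form(run, mono_ac_quartet.forms[0], 2,
                                  expected_rt=1.0)
        baseline = split_isobaric(mono_ac_quartet, run, peak).fractions
        rng = random.Random(3)
        members = list(mono_ac_quartet.forms)
        for _ in range(3):
            rng.shuffle(members)
            shuffled = type(mono_ac_quartet)(forms=tuple(members), charge=2)
            result = split_isobaric(shuffled, run, peak)
            assert result.fractions == pytest.approx(baseline)

    def test_fractions_sum_to_one(self, small_truth_factory, mono_ac_quartet):
        truth = quartet_truth(small_truth_factory,
                              fractions=(0.7, 0.1, 0.1, 0.1))
        run = simulate_run(truth, seed=9)
        rec, peak = quantify_form(run, mono_ac_quartet.forms[0], 2,
                                  expected_rt=1.0)
        result = split_isobaric(mono_ac_quartet, run, peak)
        assert sum(result.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_ms2_signal_gives_uniform_low_confidence(
        self, small_truth_factory, mono_ac_quartet
    ):
        # simulate only an MS1-visible singleton at the quartet's m/z by
        # zeroing MS2: run with quartet, then strip all MS2 peaks
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        stripped = DIARun(
            [
                s if s.ms_level == 1 else Spectrum(
                    scan=s.scan, ms_level=2, rt_min=s.rt_min,
                    mz=np.array([]), intensity=np.array([]),
                    window=s.window, precursor_mz=s.precursor_mz,
                )
                for s in run.spectra
            ]
        )
        rec, peak = quantify_form(stripped, mono_ac_quartet.forms[0], 2,
                                  expected_rt=1.0)
        result = split_isobaric(mono_ac_quartet, stripped, peak)
        assert result.low_confidence
        assert list(result.fractions.values()) == pytest.approx([0.25] * 4)

    def test_single_member_group_rejected(self, small_truth_factory):
        (form,) = enumerate_forms("GAGR", {})
        (group,) = group_isobaric([form], charge=2)
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        with pytest.raises(ValueError):
            split_isobaric(group, run, None)


class TestScaleInvariance:
    def test_global_intensity_scale_cancels(self, small_truth_factory,
                                            mono_ac_quartet):
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        scaled = DIARun(
            [
                Spectrum(scan=s.scan, ms_level=s.ms_level, rt_min=s.rt_min,
                         mz=s.mz, intensity=s.intensity * 37.0,
                         window=s.window, precursor_mz=s.precursor_mz)
                for s in run.spectra
            ]
        )
        rec_a, peak_a = quantify_form(run, mono_ac_quartet.forms[0], 2, 1.0)
        rec_b, peak_b = quantify_form(scaled, mono_ac_quartet.forms[0], 2, 1.0)
        assert rec_b.area == pytest.approx(rec_a.area * 37.0, rel=1e-9)
        frac_a = split_isobaric(mono_ac_quartet, run, peak_a).fractions
        frac_b = split_isobaric(mono_ac_quartet, scaled, peak_b).fractions
        assert frac_b == pytest.approx(frac_a)


class TestCalibration:
    def test_linear_drift_recovered(self, small_truth_factory,
                                    mono_ac_quartet):
        """Library RTs on a distorted scale are mapped onto observed RTs."""
        forms = [g for g in mono_ac_quartet.forms]
        truth = small_truth_factory(
            [
                FormTruth(form=forms[0], charge=2, rt_min=0.6, sigma_s=1.25,
                          area=2e6),
                FormTruth(form=forms[1], charge=3, rt_min=1.0, sigma_s=1.25,
                          area=2e6),
                FormTruth(form=forms[2], charge=4, rt_min=1.5, sigma_s=1.25,
                          area=2e6),
            ]
        )
        run = simulate_run(truth)
        # library RTs live on a different scale: obs = 0.5 * lib + 0.1
        anchors = []
        for ft in truth.forms:
            mz = precursor_mz(monoisotopic_mass(ft.form), ft.charge)
            anchors.append((mz, (ft.rt_min - 0.1) / 0.5))
        cal = calibrate_rt(run, anchors)
        for ft in truth.forms:
            lib = (ft.rt_min - 0.1) / 0.5
            assert cal(lib) == pytest.approx(ft.rt_min, abs=0.02)

    def test_identity_when_too_few_anchors(self, small_truth_factory,
                                           mono_ac_quartet):
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        cal = calibrate_rt(run, [])
        assert cal(3.21) == 3.21


class TestQuantifyRun:
    def test_empty_table(self, small_truth_factory):
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        import pandas as pd

        out = quantify_run(run, pd.DataFrame())
        assert out.empty

    def test_full_pipeline_recovers_fractions_and_ratios(
        self, small_truth_factory
    ):
        truth = quartet_truth(small_truth_factory)
        run = simulate_run(truth)
        table = truth_table(truth)
        out = quantify_run(run, table)
        merged = out.merge(table[["label", "true_fraction"]], on="label")
        assert np.allclose(
            merged["isomer_fraction"], merged["true_fraction"], atol=1e-6
        )
        assert merged.groupby(
            ["protein", "span_start", "span_end"]
        )["ratio"].sum().iloc[0] == pytest.approx(1.0, abs=1e-9)
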