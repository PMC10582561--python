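"""Contact mechanics, contact detection and channel extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanovote.forcecurve import (
    ContactDetectionError,
    FitError,
    ForceCurve,
    ProbeSpec,
    detect_contact_point,
    dimitriadis_force,
    extract_adhesion,
    fit_modulus,
    process_curve,
    zero_force_height,
)
from nanovote.synthdata import AcquisitionSpec, synthesize_force_curve


def _ramp_curve(n_baseline=50, n_contact=100, slope=0.05, offset=0.0, noise=None,
                rng=None):
    """Piecewise curve: flat baseline then a strictly rising contact part."""
    z = np.arange(n_baseline + n_contact, dtype=float) * 10.0
    f = np.zeros_like(z)
    f[n_baseline:] = slope * (z[n_baseline:] - z[n_baseline - 1])
    if noise:
        f += rng.normal(0.0, noise, len(f))
    f += offset
    seg = np.column_stack([z, f])
    return ForceCurve(approach=seg, retract=seg.copy())


class TestDimitriadisForce:
    def test_zero_indentation_gives_zero_force(self, probe):
        assert dimitriadis_force(0.0, 1000.0, 2000.0, probe) == 0.0

    def test_hertz_limit_for_thick_sample(self, probe):
        # as h -> infinity the correction polynomial -> 1
        delta = np.linspace(1.0, 2000.0, 50)
        h = 1e6 * np.sqrt(probe.radius * delta.max())
        hertz = (
            (4.0 / 3.0) * 1000.0 * np.sqrt(probe.radius) * delta**1.5
            / (1.0 - probe.poisson_ratio**2) * 1e-9
        )
        full = dimitriadis_force(delta, 1000.0, h, probe)
        assert np.all(np.abs(full - hertz) / hertz < 1e-4)

    def test_correction_factor_matches_polynomial(self, probe):
        # independent oracle: evaluate the polynomial directly
        delta, h = 500.0, 2000.0
        chi = np.sqrt(probe.radius * delta) / h
        expected = 1 + 1.009 * chi + 1.032 * chi**2 + 0.578 * chi**3 + 0.0048 * chi**4
        assert chi == pytest.approx(0.7906, abs=1e-4)
        assert expected == pytest.approx(2.7302, abs=1e-3)
        hertz = dimitriadis_force(delta, 1000.0, 1e12, probe)
        assert dimitriadis_force(delta, 1000.0, h, probe) / hertz == pytest.approx(
            expected, rel=1e-6
        )

    @settings(max_examples=50, deadline=None)
    @given(
        delta=st.floats(1.0, 3000.0),
        E=st.floats(10.0, 5000.0),
        h=st.floats(100.0, 10000.0),
        R=st.floats(500.0, 10000.0),
    )
    def test_strictly_increasing_in_each_argument(self, delta, E, h, R):
        probe = ProbeSpec(radius=R)
        base = dimitriadis_force(delta, E, h, probe)
        assert dimitriadis_force(delta * 1.01, E, h, probe) > base
        assert dimitriadis_force(delta, E * 1.01, h, probe) > base
        assert dimitriadis_force(delta, E, h, ProbeSpec(radius=R * 1.01)) > base

    def test_named_coefficient_sets_bracket_the_mean(self, probe):
        args = (800.0, 300.0, 1500.0, probe)
        bonded = dimitriadis_force(*args, coefficients="bonded")
        free = dimitriadis_force(*args, coefficients="free")
        mean = dimitriadis_force(*args, coefficients="mean")
        assert free < mean < bonded

    def test_nonpositive_height_rejected(self, probe):
        with pytest.raises(ValueError):
            dimitriadis_force(100.0, 1000.0, 0.0, probe)


class TestContactDetection:
    def test_noiseless_contact_at_first_rising_sample(self):
        curve = _ramp_curve(n_baseline=50)
        result = detect_contact_point(curve, refine=False)
        assert result.contact_index == 50

    def test_alignment_invariance_under_baseline_offset(self, rng):
        clean = _ramp_curve(noise=0.01, rng=np.random.default_rng(7))
        offset = ForceCurve(
            approach=clean.approach + [0.0, 1.0],
            retract=clean.retract + [0.0, 1.0],
        )
        r1 = detect_contact_point(clean)
        r2 = detect_contact_point(offset)
        assert r1.contact_index == r2.contact_index
        assert r2.baseline_offset == pytest.approx(r1.baseline_offset + 1.0, abs=0.01)

    @pytest.mark.parametrize("use_reference", [True, False])
    def test_noisy_contact_within_two_samples(self, probe, acq, use_reference):
        rng = np.random.default_rng(3)
        hits = 0
        n = 40
        for _ in range(n):
            h = rng.uniform(1000.0, 4800.0)
            curve = synthesize_force_curve(h, 300.0, 600.0, 0.3, probe, acq, rng)
            z = curve.approach[:, 0]
            true_idx = np.argmin(np.abs(z - (acq.reference_altitude - h)))
            kwargs = (
                {"probe": probe, "reference_altitude": acq.reference_altitude}
                if use_reference else {}
            )
            found = detect_contact_point(curve, **kwargs).contact_index
            hits += abs(found - true_idx) <= 2
        assert hits >= 0.9 * n

    def test_all_contact_curve_raises(self):
        z = np.linspace(0.0, 1000.0, 300)
        f = 1e-4 * z**1.5  # no baseline at all
        curve = ForceCurve(np.column_stack([z, f]), np.column_stack([z, f]))
        with pytest.raises(ContactDetectionError):
            detect_contact_point(curve)

    def test_flat_curve_raises(self):
        z = np.linspace(0.0, 1000.0, 200)
        f = np.zeros_like(z)
        curve = ForceCurve(np.column_stack([z, f]), np.column_stack([z, f]))
        with pytest.raises(ContactDetectionError):
            detect_contact_point(curve)


class TestModulusFit:
    @pytest.mark.parametrize("window", [(0.0, 0.3), (0.7, 1.0), (0.2, 0.8)])
    def test_noiseless_selfconsistency_any_window(self, probe, quiet_acq, window):
        E, h = 1000.0, 3000.0
        rng = np.random.default_rng(0)
        curve = synthesize_force_curve(h, E, E, 0.0, probe, quiet_acq, rng)
        contact = detect_contact_point(
            curve, probe=probe, reference_altitude=quiet_acq.reference_altitude
        )
        fitted = fit_modulus(curve, contact, window, h, probe)
        assert fitted == pytest.approx(E, rel=1e-3)

    def test_two_layer_windows_separate_the_layers(self, probe, quiet_acq):
        e1, e2, h = 200.0, 900.0, 3500.0
        rng = np.random.default_rng(1)
        curve = synthesize_force_curve(h, e1, e2, 0.3, probe, quiet_acq, rng)
        contact = detect_contact_point(
            curve, probe=probe, reference_altitude=quiet_acq.reference_altitude
        )
        mech_l = fit_modulus(curve, contact, (0.0, 0.3), h, probe)
        mech_h = fit_modulus(curve, contact, (0.7, 1.0), h, probe)
        assert mech_l == pytest.approx(e1, rel=0.05)
        assert e1 < mech_h < e2

    def test_two_layer_with_noise_stays_close(self, probe, acq):
        e1, e2, h = 200.0, 900.0, 3500.0
        fits = []
        for seed in range(7):
            rng = np.random.default_rng(seed)
            curve = synthesize_force_curve(h, e1, e2, 0.3, probe, acq, rng)
            contact = detect_contact_point(
                curve, probe=probe, reference_altitude=acq.reference_altitude
            )
            fits.append(fit_modulus(curve, contact, (0.0, 0.3), h, probe))
        assert np.median(fits) == pytest.approx(e1, rel=0.10)

    def test_too_few_samples_in_window_raises(self, probe):
        curve = _ramp_curve(n_baseline=100, n_contact=3)
        contact = detect_contact_point(curve, refine=False)
        with pytest.raises(FitError):
            fit_modulus(curve, contact, (0.7, 1.0), 2000.0, probe)


class TestAdhesion:
    def test_reversible_curve_has_zero_adhesion(self):
        curve = _ramp_curve()
        assert extract_adhesion(curve) == pytest.approx(0.0, abs=1e-9)

    def test_pulloff_well_depth_recovered(self, probe, acq):
        rng = np.random.default_rng(5)
        curve = synthesize_force_curve(3000.0, 400.0, 800.0, 0.35, probe, acq, rng)
        adh = extract_adhesion(curve)
        assert adh == pytest.approx(0.35, abs=3 * acq.noise_sigma)

    def test_offset_invariance(self, probe, acq):
        rng = np.random.default_rng(6)
        curve = synthesize_force_curve(3000.0, 400.0, 800.0, 0.35, probe, acq, rng)
        shifted = ForceCurve(
            approach=curve.approach.copy(),
            retract=curve.retract + [0.0, 0.2],
        )
        assert extract_adhesion(shifted) == pytest.approx(
            extract_adhesion(curve), abs=1e-6
        )


class TestZeroForceHeight:
    def test_rigid_substrate_maps_to_zero(self):
        contact = _contact(indentation=0.0)
        assert zero_force_height(0.0, contact) == 0.0

    def test_height_plus_indentation(self):
        contact = _contact(indentation=1030.0)
        assert zero_force_height(3500.0, contact) == pytest.approx(4530.0)

    def test_synthetic_cell_height_recovered(self, probe, acq):
        rng = np.random.default_rng(8)
        curve = synthesize_force_curve(5000.0, 300.0, 600.0, 0.3, probe, acq, rng)
        channels = process_curve(curve, probe, acq.reference_altitude)
        assert channels.Morpho == pytest.approx(5000.0, abs=50.0)


def _contact(indentation: float):
    from nanovote.forcecurve import ContactResult

    return ContactResult(
        contact_index=0, noise_sigma=1e-3, indentation_length=indentation,
        contact_z=0.0,
    )
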