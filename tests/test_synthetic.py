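"""Generator: profile shapes, analytic ground truth, cohorts, distortion."""

import dataclasses
import math

import numpy as np
import pytest

from limbkin.constants import GRAVITY
from limbkin.synthetic import (
    DEFAULT_CAL_MASSES_KG,
    PlatformModel,
    ProfileParams,
    apply_platform_distortion,
    bradypus_defaults,
    calibrated_zero_truncated,
    generate_calibration_dataset,
    generate_cohort,
    generate_contact_profile,
    half_sine_lobe_impulse,
    profile_truth,
    sample_cohort_params,
    zero_truncated_normal_params,
)
from limbkin.trace import ForceTrace, TrialMeta


def params(**overrides):
    base = dict(
        duration_s=2.0,
        vertical_peak=100.0,
        fore_aft_split_s=1.0,
        propulsive_peak=5.0,
        braking_peak=3.0,
        medial_peak=2.0,
        lateral_peak=4.0,
        ml_split_s=0.8,
    )
    base.update(overrides)
    return ProfileParams(**base)


class TestContactProfile:
    def test_half_sine_vertical_peak_at_midcontact(self):
        trace = generate_contact_profile(
            params(), body_weight_n=10.0, lead_s=0.0, trail_s=0.0
        )
        assert trace.fz.max() == pytest.approx(10.0, abs=1e-12)
        assert trace.t[trace.fz.argmax()] == pytest.approx(1.0, abs=1e-3)

    def test_propulsive_lobe_impulse_matches_closed_form(self):
        # independent oracle: trapezoid-integrate the sampled lobe at 1200 Hz
        trace = generate_contact_profile(
            params(propulsive_peak=50.0), body_weight_n=10.0,
            lead_s=0.0, trail_s=0.0,
        )
        numeric = np.trapezoid(np.clip(trace.fx, 0, None), dx=1.0 / trace.rate_hz)
        closed = half_sine_lobe_impulse(5.0, 1.0)  # 50 %BW of 10 N over 1 s
        assert closed == pytest.approx(2 * 5.0 * 1.0 / math.pi)
        assert numeric == pytest.approx(closed, rel=1e-3)

    def test_zero_amplitudes_give_all_zero_trace(self):
        trace = generate_contact_profile(
            params(vertical_peak=0, propulsive_peak=0, braking_peak=0,
                   medial_peak=0, lateral_peak=0),
            body_weight_n=10.0,
        )
        assert np.all(trace.forces == 0.0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(duration_s=-1.0),
            dict(fore_aft_split_s=2.5),
            dict(fore_aft_split_s=0.0),
            dict(vertical_peak=-5.0),
            dict(noise_sd=-0.1),
            dict(vertical_peak=float("nan")),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_contact_profile(params(**bad), body_weight_n=10.0)

    def test_rate_below_contact_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            generate_contact_profile(params(), body_weight_n=10.0, rate_hz=0.4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_truth_impulses_match_trapezoid_oracle(self, seed):
        # every analytic impulse agrees with numerical integration to 0.1%
        rng = np.random.default_rng(seed)
        p = params(
            duration_s=float(rng.uniform(1.5, 4.0)),
            vertical_peak=float(rng.uniform(40, 100)),
            propulsive_peak=float(rng.uniform(2, 25)),
            braking_peak=float(rng.uniform(2, 35)),
            medial_peak=float(rng.uniform(1, 12)),
            lateral_peak=float(rng.uniform(1, 12)),
        )
        p = dataclasses.replace(
            p, fore_aft_split_s=0.3 * p.duration_s, ml_split_s=0.6 * p.duration_s
        )
        bw = 37.0
        trace = generate_contact_profile(p, body_weight_n=bw, lead_s=0, trail_s=0)
        truth = trace.truth
        dt = 1.0 / trace.rate_hz
        scale = 100.0 / bw
        checks = {
            "jv": np.trapezoid(trace.fz, dx=dt) * scale,
            "jp": np.trapezoid(np.clip(trace.fx, 0, None), dx=dt) * scale,
            "jb": np.trapezoid(np.clip(trace.fx, None, 0), dx=dt) * scale,
            "jl": np.trapezoid(np.clip(trace.fy, 0, None), dx=dt) * scale,
            "jm": np.trapezoid(np.clip(trace.fy, None, 0), dx=dt) * scale,
        }
        for name, numeric in checks.items():
            assert getattr(truth, name) == pytest.approx(numeric, rel=1e-3), name


class TestTruncatedNormalCalibration:
    @pytest.mark.parametrize("mean,sd", [(82.0, 13.2), (6.5, 5.7), (5.0, 2.5)])
    def test_realized_mean_is_exact(self, mean, sd):
        mu, sigma = zero_truncated_normal_params(mean, sd)
        from scipy import stats

        a = -mu / sigma
        lam = stats.norm.pdf(a) / stats.norm.sf(a)
        assert mu + sigma * lam == pytest.approx(mean, rel=1e-9)

    def test_infeasible_dispersion_still_matches_mean(self, rng):
        # printed CV 7.5/6.1 exceeds what a zero-truncated normal can reach
        draws = calibrated_zero_truncated(6.1, 7.5, rng, size=200_000)
        assert draws.min() >= 0
        assert draws.mean() == pytest.approx(6.1, abs=3 * draws.std() / 448)

    def test_degenerate_sd_returns_constant(self, rng):
        assert np.all(calibrated_zero_truncated(5.0, 0.0, rng, size=4) == 5.0)


class TestCohort:
    def test_zero_spread_gives_identical_truths(self):
        spec = bradypus_defaults("forelimb")
        zero = dataclasses.replace(
            spec,
            n_contacts=3,
            vertical_peak=dataclasses.replace(spec.vertical_peak, sd=0),
            net_impulse=dataclasses.replace(spec.net_impulse, sd=0),
            lateral_peak=dataclasses.replace(spec.lateral_peak, sd=0),
            medial_peak=dataclasses.replace(spec.medial_peak, sd=0),
            minor_fore_aft_peak=dataclasses.replace(spec.minor_fore_aft_peak, sd=0),
            duration_s=dataclasses.replace(spec.duration_s, sd=0),
            body_mass_kg=dataclasses.replace(spec.body_mass_kg, sd=0),
        )
        contacts = generate_cohort(zero, seed=3)
        first = contacts[0].truth
        for c in contacts[1:]:
            for field in ("vpk", "ppk", "bpk", "lpk", "jv", "net_fore_aft"):
                assert getattr(c.truth, field) == pytest.approx(
                    getattr(first, field), abs=1e-12
                )

    def test_fixed_seed_reproduces_cohort_bitwise(self, small_fore_cohort_spec):
        a = generate_cohort(small_fore_cohort_spec, seed=42)
        b = generate_cohort(small_fore_cohort_spec, seed=42)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.trace.forces, cb.trace.forces)
            assert ca.truth == cb.truth
            assert ca.trace.meta == cb.trace.meta

    def test_hindlimb_vertical_peak_targets_pooled_mean(self):
        spec = dataclasses.replace(bradypus_defaults("hindlimb"), n_contacts=500)
        draws = sample_cohort_params(spec, np.random.default_rng(1))
        vpk = np.array([p.vertical_peak for p in draws])
        se = vpk.std(ddof=1) / math.sqrt(len(vpk))
        assert abs(vpk.mean() - 82.0) < 3 * se

    @pytest.mark.parametrize("limb,vpk,net,lpk", [
        ("forelimb", 68.6, 23.6, 6.5),
        ("hindlimb", 82.0, -40.7, 6.1),
    ])
    def test_cohort_moments_converge_to_spec_targets(self, limb, vpk, net, lpk):
        # law-of-large-numbers check at n=2000, 3-SE band
        spec = dataclasses.replace(bradypus_defaults(limb), n_contacts=2000)
        draws = sample_cohort_params(spec, np.random.default_rng(7))
        truths = [profile_truth(p, limb) for p in draws]
        for target, values in (
            (vpk, np.array([t.vpk for t in truths])),
            (net, np.array([t.net_fore_aft for t in truths])),
            (lpk, np.array([t.lpk for t in truths])),
        ):
            se = values.std(ddof=1) / math.sqrt(len(values))
            assert abs(values.mean() - target) < 3 * se


class TestPlatformDistortion:
    def _trace(self, forces):
        return ForceTrace(1200.0, np.asarray(forces, float), "raw")

    def test_identity_platform_is_transparent(self, identity_platform, rng):
        trace = self._trace(rng.normal(size=(50, 3)))
        out = apply_platform_distortion(trace, identity_platform, position_cm=0.0)
        assert np.allclose(out.forces, trace.forces)

    def test_diagonal_attenuation(self):
        platform = PlatformModel(
            diag_center=(0.9, 0.9, 0.8), diag_edge_drop=(0, 0, 0),
            zx_bend_gain=0, zy_gain_center=0, zy_gain_edge=0,
            xz_gain=0, yz_gain_edge=0,
            offsets_center_n=(0, 0, 0), oz_edge_n=0, noise_sd_n=0,
        )
        out = apply_platform_distortion(
            self._trace([[0.0, 0.0, 10.0]]), platform, position_cm=0.0
        )
        assert np.allclose(out.forces, [[0.0, 0.0, 8.0]])

    def test_vertical_load_bleeds_into_fore_aft_channel(self):
        platform = PlatformModel(
            diag_center=(1, 1, 1), diag_edge_drop=(0, 0, 0),
            zx_bend_gain=0.05, zy_gain_center=0, zy_gain_edge=0,
            xz_gain=0, yz_gain_edge=0,
            offsets_center_n=(0, 0, 0), oz_edge_n=0, noise_sd_n=0,
        )
        out = apply_platform_distortion(
            self._trace([[0.0, 0.0, 10.0]]), platform, position_cm=5.0
        )
        assert out.forces[0, 0] == pytest.approx(0.5)

    def test_true_gain_and_offset_invert_distortion_exactly(
        self, noiseless_platform, rng
    ):
        forces = rng.normal(scale=10.0, size=(200, 3))
        p = 3.1
        out = apply_platform_distortion(
            self._trace(forces), noiseless_platform, position_cm=p
        )
        g = noiseless_platform.gain_matrix(p)
        o = noiseless_platform.offset(p)
        recovered = np.linalg.solve(g, (out.forces - o).T).T
        assert np.allclose(recovered, forces, atol=1e-12)

    def test_position_outside_span_rejected(self, platform, rng):
        with pytest.raises(ValueError, match="range"):
            apply_platform_distortion(
                self._trace(rng.normal(size=(5, 3))), platform, position_cm=6.0
            )


class TestCalibrationDataset:
    def test_default_protocol_has_150_observations(self, noiseless_platform):
        obs = generate_calibration_dataset(noiseless_platform)
        assert len(obs) == 150  # 3 axes x 5 positions x 10 loads
        assert set(obs.loaded_axis) == {"x", "y", "z"}
        assert obs.position_cm.nunique() == 5

    def test_heaviest_load_matches_printed_span(self):
        w = max(DEFAULT_CAL_MASSES_KG) * GRAVITY
        assert w == pytest.approx(33.35, abs=0.01)

    def test_identity_platform_records_applied_weight(self, identity_platform):
        obs = generate_calibration_dataset(
            identity_platform, masses_kg=[1.0, 2.0, 3.0], positions_cm=[0.0]
        )
        z_rows = obs[obs.loaded_axis == "z"]
        row = z_rows[np.isclose(z_rows.applied_N, GRAVITY)].iloc[0]
        assert row.rz_N == pytest.approx(GRAVITY)
        assert row.rx_N == pytest.approx(0.0)
        assert row.ry_N == pytest.approx(0.0)

    def test_empty_protocol_rejected(self, platform):
        with pytest.raises(ValueError):
            generate_calibration_dataset(platform, masses_kg=[])
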