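"""Dose conversion, frame/dose mapping, FSC, Rosenthal-Henderson fit and
damage trajectories."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emdamage.dose import (
    DamageProbes,
    FSCCurve,
    damage_trajectory,
    dose_to_gray,
    frames_for_dose,
    fsc,
    resolution_at_threshold,
    rosenthal_henderson_fit,
)
from emdamage.model import DensityMap
from emdamage.synthetic import (
    DamageModel,
    RHDatasetSpec,
    ToyComplexSpec,
    build_toy_model,
    simulate_dose_series,
    simulate_rh_dataset,
)


class TestDoseConversion:
    def test_high_dose_is_307_mgy(self):
        assert round(dose_to_gray(83.0)["dose_mgy"]) == 307

    def test_low_dose_is_12_2_mgy(self):
        assert round(dose_to_gray(3.3)["dose_mgy"], 1) == 12.2

    def test_zero(self):
        out = dose_to_gray(0.0)
        assert out["dose_mgy"] == 0.0
        assert not out["exceeds_henderson_limit"]

    def test_henderson_comparison(self):
        assert dose_to_gray(83.0)["exceeds_henderson_limit"]
        assert dose_to_gray(83.0)["henderson_ratio"] == pytest.approx(
            307.1 / 20.0
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dose_to_gray(-1.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_linearity(self, a, b):
        f = lambda x: dose_to_gray(x)["dose_mgy"]
        assert f(a) + f(b) == pytest.approx(f(a + b), rel=1e-9, abs=1e-9)


class TestFramesForDose:
    @pytest.mark.parametrize(
        "target,k",
        [(83.0, 50), (40.0, 24), (20.0, 12), (10.0, 6), (5.0, 3), (3.3, 2)],
    )
    def test_printed_frame_table_reproduced(self, target, k):
        got_k, realized = frames_for_dose(83.0, 50, target)
        assert got_k == k
        assert realized == pytest.approx(k / 50 * 83.0)

    def test_realized_fluence_values(self):
        assert frames_for_dose(83.0, 50, 10.0)[1] == pytest.approx(9.96)
        assert frames_for_dose(83.0, 50, 3.3)[1] == pytest.approx(3.32)

    def test_minimum_one_frame(self):
        k, _ = frames_for_dose(83.0, 50, 0.1)
        assert k == 1

    def test_target_above_total_rejected(self):
        with pytest.raises(ValueError):
            frames_for_dose(83.0, 50, 84.0)


def noise_map(rng, shape=(32, 32, 32), voxel=1.0):
    return DensityMap(rng.normal(size=shape), voxel, (0, 0, 0))


class TestFSC:
    def test_map_against_itself_is_one(self, rng):
        m = noise_map(rng)
        curve = fsc(m, m)
        assert np.all(np.abs(curve.correlations - 1.0) < 1e-10)

    def test_map_against_negation_is_minus_one(self, rng):
        m = noise_map(rng)
        neg = m.copy()
        neg.grid *= -1.0
        curve = fsc(m, neg)
        assert np.all(np.abs(curve.correlations + 1.0) < 1e-10)

    def test_symmetric_and_scale_invariant(self, rng):
        a, b = noise_map(rng), noise_map(rng)
        c1 = fsc(a, b).correlations
        c2 = fsc(b, a).correlations
        assert np.allclose(c1, c2, atol=1e-12)
        a2, b2 = a.copy(), b.copy()
        a2.grid *= 3.0
        b2.grid *= 3.0
        assert np.allclose(fsc(a2, b2).correlations, c1, atol=1e-12)

    def test_snr_expectation(self):
        """Two half-maps sharing a signal with per-voxel SNR s should have
        FSC ~ s/(s+1) in every shell (flat white spectra)."""
        s = 2.0
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sig = rng.normal(size=(32, 32, 32)) * np.sqrt(s)
            h1 = DensityMap(sig + rng.normal(size=sig.shape), 1.0, (0, 0, 0))
            h2 = DensityMap(sig + rng.normal(size=sig.shape), 1.0, (0, 0, 0))
            vals.append(fsc(h1, h2).correlations)
        mean_fsc = np.mean(vals, axis=0)
        # ignore the lowest shells (few voxels, big variance)
        assert np.allclose(mean_fsc[3:], s / (s + 1.0), atol=0.05)

    def test_geometry_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fsc(noise_map(rng), noise_map(rng, voxel=0.5))


class TestResolutionAtThreshold:
    def test_identical_maps_flag_no_crossing(self, rng):
        m = noise_map(rng, voxel=0.8)
        est = resolution_at_threshold(fsc(m, m))
        assert not est.crossed
        assert est.flag == "no_crossing"
        # Nyquist-scale resolution for a 0.8 Å voxel
        assert est.resolution == pytest.approx(1.6, rel=0.1)

    def test_constructed_crossing_at_2_08(self):
        freqs = np.array([0.1, 0.2, 1.0 / 2.08, 0.6])
        corrs = np.array([0.9, 0.5, 0.143, 0.01])
        est = resolution_at_threshold(FSCCurve(freqs, corrs, np.ones(4)))
        assert est.crossed
        assert est.resolution == pytest.approx(2.08, rel=1e-9)

    def test_below_at_first_shell_flagged(self):
        curve = FSCCurve([0.1, 0.2], [0.05, 0.01], [10, 10])
        est = resolution_at_threshold(curve)
        assert est.flag == "below_at_first_shell"
        assert not est.crossed

    def test_planted_crossing_recovered_within_one_shell(self):
        """Signal whose per-frequency SNR is built to put the 0.143 FSC
        crossing at a planted frequency: the estimate must land within
        one shell width of the plant (closed-form FSC = SNR/(SNR+1))."""
        n, voxel = 48, 1.0
        f_cross = 1.0 / 3.0
        snr_at_cross = 0.143 / (1.0 - 0.143)
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            white = np.fft.rfftn(rng.normal(size=(n, n, n)))
            freqs = [np.fft.fftfreq(n, voxel), np.fft.fftfreq(n, voxel),
                     np.fft.rfftfreq(n, voxel)]
            fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
            fmag = np.sqrt(fx**2 + fy**2 + fz**2)
            snr = snr_at_cross * np.exp(-60.0 * (fmag - f_cross))
            sig = np.fft.irfftn(white * np.sqrt(snr), s=(n, n, n), axes=(0, 1, 2))
            h1 = DensityMap(sig + rng.normal(size=sig.shape), voxel, (0, 0, 0))
            h2 = DensityMap(sig + rng.normal(size=sig.shape), voxel, (0, 0, 0))
            curve = fsc(h1, h2)
            est = resolution_at_threshold(curve)
            shell_width = curve.frequencies[1] - curve.frequencies[0]
            hits.append(abs(1.0 / est.resolution - f_cross) <= shell_width)
        assert all(hits)


class TestRHFit:
    def test_noiseless_planted_b_recovered(self):
        pts = simulate_rh_dataset(
            RHDatasetSpec(true_B=43.3, resolution_noise_sigma=0.0)
        )
        fit = rosenthal_henderson_fit(pts)
        assert fit.physical
        assert fit.B == pytest.approx(43.3, abs=1e-9)
        assert fit.residual_se < 1e-12

    def test_two_points_fit_exactly(self):
        pts = [(1000, 4.0), (100000, 2.5)]
        fit = rosenthal_henderson_fit(pts)
        pred = fit.ln_n * (2.0 / fit.B) + fit.intercept
        assert np.allclose(pred, fit.inv_d2, atol=1e-12)

    def test_unbiased_over_200_seeds(self):
        fits = [
            rosenthal_henderson_fit(
                simulate_rh_dataset(
                    RHDatasetSpec(resolution_noise_sigma=0.004, seed=s)
                )
            ).B
            for s in range(200)
        ]
        se = np.std(fits, ddof=1) / np.sqrt(len(fits))
        assert abs(np.mean(fits) - 43.3) < 3 * se

    def test_scaling_counts_changes_intercept_only(self):
        pts = simulate_rh_dataset(RHDatasetSpec(resolution_noise_sigma=0.0))
        fit1 = rosenthal_henderson_fit(pts)
        fit2 = rosenthal_henderson_fit([(10 * n, d) for n, d in pts])
        assert fit2.B == pytest.approx(fit1.B, rel=1e-9)
        assert fit2.intercept != pytest.approx(fit1.intercept, abs=1e-3)

    def test_negative_slope_flagged_unphysical(self):
        fit = rosenthal_henderson_fit([(1000, 2.0), (100000, 4.0)])
        assert not fit.physical
        assert np.isnan(fit.B)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            rosenthal_henderson_fit([(1000, 2.0)])
        with pytest.raises(ValueError):
            rosenthal_henderson_fit([(1000, 2.0), (1000, 2.5)])


@pytest.fixture(scope="module")
def probed_stack():
    """Twelve-frame, 20 e-/A^2 stack, noiseless, with the disulfide break
    planted at 18.5 MGy (= 5 e-/A^2): frames 1-3 keep the bond, the rest
    lose it, so a dose-integrated map at the break dose is fully intact
    and one well past it is dominated by broken frames."""
    spec = ToyComplexSpec()
    model = build_toy_model(spec)
    damage = DamageModel(
        occupancy_dose_constant=800.0,
        adp_rate=0.0,
        drift_targets=[],
        bond_break_dose=18.5,
        noise_sigma_per_frame=0.0,
        damage_prone_labels=frozenset(
            a.label for a in model if a.resname in ("OEC", "HOH")
        ),
    )
    stack, _ = simulate_dose_series(spec, damage, 12, 20.0, seed=0)
    probes = DamageProbes(
        bonds={"SS": (model.by_label("SG1").xyz, model.by_label("SG2").xyz)},
        metal_sites={
            lbl: model.by_label(lbl).xyz
            for lbl in ("Mn1", "Mn2", "Mn3", "Mn4", "Ca")
        },
        distance_pairs=[("Mn2", "Mn3")],
    )
    return stack, probes


class TestDamageTrajectory:
    def test_bond_flips_after_planted_break_dose(self, probed_stack):
        """Intact at the planted break dose (all included frames still
        carry the bond), broken once the summed frames are dominated by
        post-break exposure — the flip interval brackets the plant."""
        stack, probes = probed_stack
        df = damage_trajectory(stack, [3.3, 5.0, 20.0], probes)
        assert bool(df.loc[0, "bond_SS_intact"])
        assert bool(df.loc[1, "bond_SS_intact"])
        assert not bool(df.loc[2, "bond_SS_intact"])

    def test_occupancy_proxy_monotone(self, probed_stack):
        stack, probes = probed_stack
        df = damage_trajectory(stack, [3.3, 5.0, 10.0, 20.0], probes)
        prox = df["occupancy_proxy_Mn1"].to_numpy()
        assert prox[0] == pytest.approx(1.0)
        assert np.all(np.diff(prox) < 0)

    def test_no_damage_stack_constant_metrics(self):
        spec = ToyComplexSpec()
        model = build_toy_model(spec)
        quiet = DamageModel(
            occupancy_dose_constant=float("inf"), adp_rate=0.0,
            drift_targets=[], bond_break_dose=float("inf"),
            noise_sigma_per_frame=0.0,
        )
        stack, _ = simulate_dose_series(spec, quiet, 6, 20.0, seed=0)
        probes = DamageProbes(
            metal_sites={"Mn1": model.by_label("Mn1").xyz},
            bonds={"SS": (model.by_label("SG1").xyz,
                          model.by_label("SG2").xyz)},
        )
        df = damage_trajectory(stack, [3.3, 5.0, 10.0], probes)
        assert np.allclose(df["occupancy_proxy_Mn1"], 1.0, atol=1e-9)
        assert np.allclose(df["sigma"], df["sigma"].iloc[0], atol=1e-9)
        assert df["bond_SS_intact"].all()

    def test_mgy_column_is_37x_fluence(self, probed_stack):
        stack, probes = probed_stack
        df = damage_trajectory(stack, [5.0, 10.0], probes)
        assert np.allclose(df["dose_mgy"], df["realized_fluence"] * 3.7)
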