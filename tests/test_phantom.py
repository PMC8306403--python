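"""Phantom generator: input curve, tissue model, rendering, cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dcekin import (
    AcquisitionSpec,
    AifModelParams,
    LesionSpec,
    PhantomScene,
    ProgressionEffect,
    generate_cohort,
    one_compartment_curve,
    population_aif,
    render_phantom,
    tissue_curve,
)
from dcekin.phantom import AortaSpec


class TestPopulationAif:
    def test_zero_before_arrival(self, aif_params):
        t = np.arange(0.0, aif_params.arrival_time_s, 1.0)
        assert np.all(population_aif(t, aif_params) == 0.0)

    def test_zero_amplitude_gives_zero_curve(self):
        p = AifModelParams(bolus_amplitude=0.0, recirc_amplitude=0.0)
        t = np.arange(0.0, 300.0, 2.4)
        assert np.all(population_aif(t, p) == 0.0)

    def test_non_negative_and_finite(self, aif_params):
        t = np.arange(-12.0, 300.0, 0.5)
        ca = population_aif(t, aif_params)
        assert np.all(ca >= 0) and np.all(np.isfinite(ca))

    def test_peak_matches_dense_grid_scan(self, aif_params):
        """Peak on a 0.1 s grid equals an independent dense brute-force scan."""
        t = np.arange(0.0, 300.0, 0.1)
        ca = population_aif(t, aif_params)
        # oracle: evaluate the closed form point by point, no vectorised path
        def closed_form(ti):
            tau = ti - aif_params.arrival_time_s
            if tau <= 0:
                return 0.0
            a = aif_params.shape
            bolus = (
                aif_params.bolus_amplitude
                * (tau / aif_params.time_to_peak_s) ** a
                * np.exp(a * (1 - tau / aif_params.time_to_peak_s))
            )
            rec = (
                aif_params.recirc_amplitude
                * (1 - np.exp(-tau / aif_params.recirc_rise_s))
                * np.exp(-tau / aif_params.washout_tau_s)
            )
            return bolus + rec

        brute = max(closed_form(ti) for ti in t)
        assert ca.max() == pytest.approx(brute, rel=1e-12)

    def test_non_monotone_times_rejected(self, aif_params):
        with pytest.raises(ValueError):
            population_aif(np.array([0.0, 2.0, 1.0]), aif_params)


class TestTissueCurve:
    def test_zero_ktrans_gives_zero(self, protocol, dynamic_aif):
        ct = tissue_curve(dynamic_aif, protocol.dynamic_times(), 0.0, 30.0)
        assert np.all(ct == 0.0)

    def test_constant_aif_closed_form(self):
        """Ca == 1, Ktrans 0.6/min, ECV 30 -> Ct(t) = 0.3 (1 - e^{-2t}), t in min."""
        t = np.arange(0.0, 241.0, 2.4)
        ct = tissue_curve(np.ones_like(t), t, 0.6, 30.0)
        t_min = t / 60.0
        expected = 0.3 * (1.0 - np.exp(-2.0 * t_min))
        np.testing.assert_allclose(ct, expected, atol=1e-10)
        assert ct[t == 60.0][0] == pytest.approx(0.2594, abs=5e-5)

    def test_ecv_zero_rejected(self, protocol, dynamic_aif):
        with pytest.raises(ValueError):
            tissue_curve(dynamic_aif, protocol.dynamic_times(), 0.5, 0.0)

    @pytest.mark.parametrize("ktrans,ecv", [(1.5, 10.0), (0.96, 40.0), (0.1, 60.0)])
    def test_matches_refined_grid_quadrature(self, protocol, dynamic_aif, ktrans, ecv):
        """Direct trapezoid quadrature on a 10x-refined grid agrees to 0.5%."""
        t = protocol.dynamic_times()
        ct = tissue_curve(dynamic_aif, t, ktrans, ecv)
        tf = np.linspace(t[0], t[-1], (len(t) - 1) * 10 + 1)
        caf = np.interp(tf, t, dynamic_aif)
        kep = ktrans / 60.0 / (ecv / 100.0)
        fine = np.array(
            [
                np.trapezoid(caf[: i + 1] * np.exp(-kep * (tf[i] - tf[: i + 1])), tf[: i + 1])
                for i in range(len(tf))
            ]
        ) * (ktrans / 60.0)
        oracle = fine[::10]
        sig = ct > 0.01 * ct.max()
        rel = np.abs(ct[sig] - oracle[sig]) / np.abs(oracle[sig])
        assert rel.max() < 0.005

    def test_plateau_for_constant_aif(self):
        """For Ca == A the curve saturates at (ecv/100) * A."""
        t = np.arange(0.0, 1200.0, 2.4)
        ct = tissue_curve(3.0 * np.ones_like(t), t, 1.0, 40.0)
        assert ct[-1] == pytest.approx(0.4 * 3.0, rel=1e-4)

    @given(
        ktrans=st.floats(0.05, 3.0),
        ecv=st.floats(5.0, 95.0),
    )
    def test_causality_and_nonnegativity(self, ktrans, ecv):
        t = np.arange(-12.0, 200.0, 2.4)
        ca = population_aif(t, AifModelParams())
        ct = one_compartment_curve(ca, t, ktrans, ecv)
        assert np.all(ct[t <= AifModelParams().arrival_time_s] == 0.0)
        assert np.all(ct >= -1e-12)


class TestRenderPhantom:
    def test_background_constant_without_noise(self, small_scene):
        series, masks, _ = render_phantom(small_scene)
        occupied = masks["aorta"].mask.copy()
        for k, m in masks.items():
            if k.startswith("lesion"):
                occupied |= m.mask
        bg = series.data[~occupied]
        assert np.all(bg == small_scene.s0)

    def test_seed_determinism(self, small_scene):
        from dataclasses import replace

        noisy = replace(small_scene, noise_sd=0.05)
        s1, _, _ = render_phantom(noisy)
        s2, _, _ = render_phantom(noisy)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_lesion_mean_matches_tissue_curve(self, small_scene):
        """Noiseless: mean enhancement over the true core equals the model curve."""
        series, masks, truth = render_phantom(small_scene)
        times = series.frame_times
        ca = population_aif(times, small_scene.aif_params)
        les = small_scene.lesions[0]
        expected = tissue_curve(ca, times, les.ktrans_true, les.ecv_true)
        core = masks["lesion_0"].mask  # lesion 0 has no rim
        mean_sig = series.data[core].mean(axis=0)
        enh = mean_sig / small_scene.s0 - 1.0
        np.testing.assert_allclose(enh, expected, atol=1e-10)

    def test_overlap_rejected(self):
        scene = PhantomScene(
            grid_shape=(20, 20, 8),
            acquisition=AcquisitionSpec(n_dynamic=10),
            aorta=AortaSpec(centre_xy=(10, 10), radius=3),
            lesions=(LesionSpec(centre=(10, 10, 4), radius=3, ktrans_true=0.5, ecv_true=30),),
        )
        with pytest.raises(ValueError, match="overlap"):
            render_phantom(scene)

    def test_truth_volume_uses_core_voxels(self, small_scene):
        _, masks, truth = render_phantom(small_scene)
        vv = small_scene.acquisition.voxel_volume
        # lesion 1 has a rim: its truth volume must count the core only
        rimmed = truth[truth["lesion_id"] == 1].iloc[0]
        n_full = masks["lesion_1"].n_voxels
        assert rimmed["volume_true_cm3"] < n_full * vv / 1000.0


class TestGenerateCohort:
    def test_study_design_counts(self):
        scenes, truth = generate_cohort(n_patients=14, n_progressors=3, seed=1)
        patients = truth.drop_duplicates("patient_id")
        assert len(patients) == 14
        assert (patients["progression"] == "yes").sum() == 3
        per_patient = truth.groupby("patient_id")["lesion_id"].nunique()
        assert per_patient.between(1, 5).all()
        # every lesion present at all three timepoints
        tp_counts = truth.groupby(["patient_id", "lesion_id"])["timepoint"].nunique()
        assert (tp_counts == 3).all()

    def test_zero_progressors_never_rise(self):
        _, truth = generate_cohort(n_patients=8, n_progressors=0, seed=3)
        wide = truth.pivot_table(
            index=["patient_id", "lesion_id"], columns="timepoint", values="ktrans_true"
        )
        assert (wide["week10"] <= wide["week4"]).all()
        assert (wide["week4"] < wide["baseline"]).all()

    def test_large_effect_separates_groups_perfectly(self):
        """True week-4 -> week-10 Ktrans changes rank-separate the groups (AUC 1)."""
        _, truth = generate_cohort(
            n_patients=14, n_progressors=3,
            effect=ProgressionEffect(ktrans_rise_factor=2.0), seed=5,
        )
        wide = truth.pivot_table(
            index=["patient_id", "lesion_id"], columns="timepoint", values="ktrans_true"
        ).reset_index()
        wide["change"] = wide["week10"] - wide["week4"]
        prog = truth.drop_duplicates("patient_id").set_index("patient_id")["progression"]
        wide["label"] = wide["patient_id"].map(prog) == "yes"
        pos = wide.loc[wide["label"], "change"].values
        neg = wide.loc[~wide["label"], "change"].values
        # empirical AUC by exhaustive pair comparison
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert wins / (len(pos) * len(neg)) == 1.0

    def test_seed_determinism(self):
        _, t1 = generate_cohort(n_patients=5, n_progressors=1, seed=9)
        _, t2 = generate_cohort(n_patients=5, n_progressors=1, seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_cohort(n_patients=2, n_progressors=3)
        with pytest.raises(ValueError):
            ProgressionEffect(ktrans_rise_factor=0.0)
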