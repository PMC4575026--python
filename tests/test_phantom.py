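"""Phantom generator: geometry, lesion placement, noise model, cohorts."""

import numpy as np
import pytest

from myorelax import (
    AcquisitionSpec,
    EllipseRegion,
    GeometryError,
    PhantomSpec,
    TissueSpec,
    build_labelmap,
    simulate_cohort,
    simulate_dual_echo,
    simulate_steam_decay,
    study,
)
from myorelax.phantom import LABEL_LESION, MUSCLE_LABELS


class TestBuildLabelmap:
    def test_deterministic_for_fixed_seed(self):
        spec = study.default_phantom(lesion_fraction=0.15, seed=42)
        a = build_labelmap(spec)
        b = build_labelmap(spec)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_zero_lesion_fraction_places_no_lesions(self):
        lm = build_labelmap(study.default_phantom(lesion_fraction=0.0))
        assert not (lm.labels == LABEL_LESION).any()

    def test_full_lesion_fraction_replaces_all_muscle(self):
        lm = build_labelmap(study.default_phantom(lesion_fraction=1.0, seed=1))
        assert not np.isin(lm.labels, MUSCLE_LABELS).any()
        assert (lm.labels == LABEL_LESION).any()

    @pytest.mark.parametrize("frac", [0.05, 0.2, 0.5])
    def test_achieved_fraction_within_voxel_rounding(self, frac):
        clean = build_labelmap(study.default_phantom(lesion_fraction=0.0))
        n_muscle = int(np.isin(clean.labels, MUSCLE_LABELS).sum())
        lm = build_labelmap(study.default_phantom(lesion_fraction=frac, seed=5))
        n_lesion = int((lm.labels == LABEL_LESION).sum())
        assert abs(n_lesion - frac * n_muscle) <= 0.5 + 1e-9

    def test_clustered_lesions_hit_exact_count_and_stay_in_muscle(self):
        spec = PhantomSpec(
            tissues=study.default_tissues(),
            lesion_fraction=0.1,
            seed=9,
            lesion_cluster_radius=2,
        )
        clean = build_labelmap(study.default_phantom())
        n_muscle = int(np.isin(clean.labels, MUSCLE_LABELS).sum())
        lm = build_labelmap(spec)
        n_lesion = int((lm.labels == LABEL_LESION).sum())
        assert n_lesion == round(0.1 * n_muscle)
        # lesions only where muscle used to be
        assert not ((lm.labels == LABEL_LESION) & (clean.labels == 0)).any()

    def test_overlapping_regions_rejected(self):
        bad = PhantomSpec(
            compartments=(
                EllipseRegion(1, (30.0, 32.0), (10.0, 10.0)),
                EllipseRegion(2, (32.0, 32.0), (10.0, 10.0)),
            ),
            tissues=study.default_tissues(),
        )
        with pytest.raises(GeometryError, match="overlap"):
            build_labelmap(bad)

    def test_region_exceeding_grid_rejected(self):
        bad = PhantomSpec(
            compartments=(EllipseRegion(1, (5.0, 32.0), (10.0, 10.0)),),
            tissues=study.default_tissues(),
        )
        with pytest.raises(GeometryError, match="exceeds"):
            build_labelmap(bad)


class TestSimulateDualEcho:
    def test_noise_free_echo_ratio_is_analytic(self, wt_phantom, dual_echo_acq):
        _, lm, vol = wt_phantom
        muscle = lm.mask_of([2])
        ratio = vol.si_te1[muscle] / vol.si_te2[muscle]
        np.testing.assert_allclose(ratio, np.exp(26.0 / study.T2_WT_MS), rtol=1e-12)

    def test_measured_muscle_snr_matches_request(self, dual_echo_acq):
        spec = study.default_phantom(seed=2)
        lm = build_labelmap(spec)
        clean = simulate_dual_echo(lm, spec.tissues, dual_echo_acq, np.inf)
        noisy = simulate_dual_echo(
            lm, spec.tissues, dual_echo_acq, snr_te14=33.0, seed=2
        )
        muscle = lm.mask_of(MUSCLE_LABELS)
        sigma = clean.si_te1[muscle].mean() / 33.0
        measured = noisy.si_te1[muscle].mean() / sigma
        # Rician bias at SNR 33 is ~0.015%; sampling error dominates
        assert measured == pytest.approx(33.0, rel=0.02)

    def test_zero_proton_density_gives_rayleigh_background(self, dual_echo_acq):
        tissues = study.default_tissues() + (
            TissueSpec(5, "void", proton_density=0.0, t2=10.0),
        )
        spec = PhantomSpec(
            compartments=study.default_phantom().compartments
            + (EllipseRegion(5, (30.0, 10.0), (3.0, 3.0)),),
            tissues=tissues,
            seed=3,
        )
        lm = build_labelmap(spec)
        noisy = simulate_dual_echo(lm, tissues, dual_echo_acq, snr_te14=33.0, seed=3)
        void = noisy.si_te1[lm.mask_of([5])]
        assert void.min() >= 0
        assert void.mean() > 0  # Rician floor
        clean = simulate_dual_echo(lm, tissues, dual_echo_acq, np.inf)
        sigma = clean.si_te1[lm.mask_of(MUSCLE_LABELS)].mean() / 33.0
        # Rayleigh mean = sigma * sqrt(pi/2)
        assert void.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.1)

    def test_missing_tissue_spec_is_a_mapping_error(self, dual_echo_acq):
        spec = study.default_phantom()
        lm = build_labelmap(spec)
        with pytest.raises(KeyError, match="TissueSpec"):
            simulate_dual_echo(lm, spec.tissues[:1], dual_echo_acq)

    def test_identical_seed_identical_noise(self, dual_echo_acq):
        spec = study.default_phantom(seed=8)
        lm = build_labelmap(spec)
        a = simulate_dual_echo(lm, spec.tissues, dual_echo_acq, 33.0, seed=8)
        b = simulate_dual_echo(lm, spec.tissues, dual_echo_acq, 33.0, seed=8)
        np.testing.assert_array_equal(a.si_te1, b.si_te1)
        np.testing.assert_array_equal(a.si_te2, b.si_te2)


class TestSimulateSteamDecay:
    def test_single_component_e_fold_at_t2(self):
        from dataclasses import replace

        acq = replace(study.STEAM_ACQ, te_list=(31.0, 62.0))
        curve = simulate_steam_decay([(1.0, 31.0)], acq)
        # amplitude 1.0 is the TE=0 extrapolation; one T2 later: 1/e
        assert curve.signal.real[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_two_component_value_at_first_te(self, steam_acq):
        curve = simulate_steam_decay([(0.7, 20.0), (0.3, 80.0)], steam_acq)
        expected = 0.7 * np.exp(-5 / 20) + 0.3 * np.exp(-5 / 80)
        assert curve.signal.real[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.82698, abs=1e-5)

    def test_noise_free_zero_phase_has_no_imaginary_part(self, steam_acq):
        curve = simulate_steam_decay([(1.0, 30.0), (0.5, 90.0)], steam_acq)
        np.testing.assert_array_equal(curve.signal.imag, 0.0)

    def test_empty_components_rejected(self, steam_acq):
        with pytest.raises(ValueError):
            simulate_steam_decay([], steam_acq)

    def test_default_te_list_is_the_29_point_schedule(self, steam_acq):
        assert len(steam_acq.te_list) == 29
        assert steam_acq.te_list[0] == 5.0 and steam_acq.te_list[-1] == 200.0


class TestSimulateCohort:
    def test_large_n_recovers_group_means(self):
        from dataclasses import replace

        spec = replace(study.WT_COHORT, n=10_000)
        _, table = simulate_cohort([spec], seed=0, render_volumes=False)
        weights = table.loc[table.measurement == "weight_g", "value"]
        se = study.WT_COHORT.weight_sd / np.sqrt(len(weights))
        assert abs(weights.mean() - 18.05) < 3 * se

    def test_zero_sd_makes_identical_animals(self):
        from dataclasses import replace

        spec = replace(
            study.WT_COHORT,
            n=5,
            weight_sd=0.0,
            muscle_t2_sd=0.0,
            mac1_sd=0.0,
            lesion_fraction_mean=0.0,
            ct_params={"col1a": (24.0, 0.0)},
        )
        _, table = simulate_cohort([spec], seed=1, render_volumes=False)
        for meas, grp in table.groupby("measurement"):
            assert grp["value"].nunique() == 1, meas

    def test_rendered_cohort_carries_truth_and_matches_table(self):
        from dataclasses import replace

        spec = replace(study.DYW_COHORT, n=2)
        animals, table = simulate_cohort([spec], seed=4)
        assert len(animals) == 2
        for a in animals:
            row = table[
                (table.animal == a.animal)
                & (table.measurement == "muscle_t2_ms")
            ]
            assert row["value"].iloc[0] == pytest.approx(a.truth["muscle_t2_ms"])
            assert (a.labelmap.labels == LABEL_LESION).any()

    def test_table_identical_with_and_without_rendering(self):
        from dataclasses import replace

        specs = [replace(study.WT_COHORT, n=3), replace(study.DYW_COHORT, n=2)]
        _, t_render = simulate_cohort(specs, seed=6, render_volumes=True)
        _, t_table = simulate_cohort(specs, seed=6, render_volumes=False)
        assert t_render.equals(t_table)

    def test_truncation_keeps_scalars_non_negative(self):
        from dataclasses import replace

        spec = replace(study.WT_COHORT, n=500, mac1_mean=0.5, mac1_sd=2.0)
        _, table = simulate_cohort([spec], seed=2, render_volumes=False)
        assert (table["value"] >= 0).all()


def test_acquisition_spec_validation():
    with pytest.raises(ValueError, match="increasing"):
        AcquisitionSpec(te_list=(40.0, 14.0), tr=2000.0, fov=(15.0, 15.0),
                        matrix=(128, 256), slice_thickness=1.0)
    vx = study.GRE_3D_ACQ.in_plane_voxel_mm
    np.testing.assert_allclose(vx, (15 / 256, 15 / 192, 15 / 96))
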