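"""DVH, conformity/gradient indices, V12 clustering, policy checks."""

import math

import numpy as np
import pytest

from srseval import (
    DoseGrid,
    PlanMetrics,
    PolicyLimits,
    StructureMask,
    StructureSet,
    TargetMetrics,
    VoxelGrid,
    check_policy,
    coverage_percent,
    cumulative_dvh,
    dose_at_volume_fraction,
    evaluate_plan,
    gradient_index,
    kernel_dose_grid,
    mean_dose,
    paddick_ci,
    sphere_mask,
    v12_cluster_volumes,
    volume_at_dose,
    KernelParams,
)
from conftest import step_dose


class TestDVH:
    def test_uniform_dose_gives_flat_curve(self, grid40, sphere5):
        dvh = cumulative_dvh(step_dose(grid40, sphere5, 20.0), sphere5, 0.5)
        assert dvh.cumulative_volume_cm3[0] == pytest.approx(sphere5.volume_cm3)
        assert dvh.volume_at(19.9) == pytest.approx(sphere5.volume_cm3)
        assert dvh.volume_at(20.0) == pytest.approx(sphere5.volume_cm3)
        assert dvh.volume_at(20.6) == 0.0

    def test_two_level_dose_steps_at_half_volume(self, grid40, sphere5):
        dose = np.zeros(grid40.shape)
        idx = np.nonzero(sphere5.voxels)
        half = len(idx[0]) // 2
        dose[tuple(i[:half] for i in idx)] = 10.0
        dose[tuple(i[half:] for i in idx)] = 20.0
        dvh = cumulative_dvh(DoseGrid(grid40, dose), sphere5, 1.0)
        v = sphere5.voxel_count
        assert dvh.volume_at(10.0) == pytest.approx(v * 1e-3)
        assert dvh.volume_at(11.0) == pytest.approx((v - half) * 1e-3)

    def test_dvh_nonincreasing_and_consistent_with_volume_at_dose(
        self, grid40, sphere5, rng
    ):
        dose = DoseGrid(grid40, rng.random(grid40.shape) * 25.0)
        dvh = cumulative_dvh(dose, sphere5, 0.5)
        assert (np.diff(dvh.cumulative_volume_cm3) <= 1e-12).all()
        for edge in dvh.dose_bins_Gy[::7]:
            assert dvh.volume_at(edge) == pytest.approx(
                volume_at_dose(dose, sphere5, edge)
            )

    def test_zero_bin_width_rejected(self, grid40, sphere5):
        with pytest.raises(ValueError):
            cumulative_dvh(step_dose(grid40, sphere5, 20.0), sphere5, 0.0)


class TestVolumeAtDose:
    def test_uniform_region_counts_fully_below_threshold(self, grid40):
        region = sphere_mask(grid40, (20, 20, 20), 13.4)  # ~10 cm³
        dose = step_dose(grid40, region, 13.0)
        brain = sphere_mask(grid40, (20, 20, 20), 19.0, name="brain", role="brain")
        for thr in (5, 8, 10, 12):
            assert volume_at_dose(dose, brain, thr) == pytest.approx(region.volume_cm3)

    def test_threshold_above_max_gives_zero(self, grid40, sphere5):
        assert volume_at_dose(step_dose(grid40, sphere5, 20.0), sphere5, 21.0) == 0.0

    def test_radial_kernel_isodose_volume_matches_closed_form(self):
        # outside the target, dose = PD (R/r)^k, so V(d) = 4/3 pi r(d)^3
        # with r(d) = R (PD/d)^(1/k)
        k, R, pd = 1.383, 5.0, 20.0
        grid = VoxelGrid((60, 60, 60))
        dose = kernel_dose_grid(grid, (30.0,) * 3, R, pd, KernelParams(k))
        every = StructureMask("all", "derived", grid, np.ones(grid.shape, bool))
        for d in (12.0, 15.0):
            r_d = R * (pd / d) ** (1 / k)
            expected = 4 / 3 * math.pi * r_d**3 / 1000
            assert volume_at_dose(dose, every, d) == pytest.approx(expected, rel=0.05)


class TestDoseAtVolumeFraction:
    def test_uniform_dose(self, grid40, sphere5):
        dose = step_dose(grid40, sphere5, 20.0)
        assert dose_at_volume_fraction(dose, sphere5, 0.02) == 20.0

    def test_hottest_voxels_set_d2(self, rng):
        grid = VoxelGrid((10, 10, 10))
        mask = StructureMask("m", "derived", grid, np.ones(grid.shape, bool))
        dose = np.full(grid.shape, 20.0)
        flat = dose.reshape(-1)
        hot = rng.choice(1000, size=20, replace=False)
        flat[hot] = 26.0
        assert dose_at_volume_fraction(DoseGrid(grid, dose), mask, 0.02) == 26.0

    def test_full_fraction_is_minimum(self, grid40, sphere5, rng):
        dose = DoseGrid(grid40, rng.random(grid40.shape) * 30)
        assert dose_at_volume_fraction(dose, sphere5, 1.0) == pytest.approx(
            dose.dose[sphere5.voxels].min()
        )

    def test_matches_sort_oracle(self, grid40, sphere5, rng):
        dose = DoseGrid(grid40, rng.random(grid40.shape) * 30)
        vals = np.sort(dose.dose[sphere5.voxels])[::-1]
        for frac in (0.02, 0.1, 0.5, 0.98):
            k = math.ceil(frac * vals.size)
            assert dose_at_volume_fraction(dose, sphere5, frac) == vals[k - 1]


class TestMeanAndCoverage:
    def test_mean_dose_against_direct_sum(self, grid40, sphere5, rng):
        dose = DoseGrid(grid40, rng.random(grid40.shape) * 30)
        expected = dose.dose[sphere5.voxels].sum() / sphere5.voxel_count
        assert mean_dose(dose, sphere5) == pytest.approx(expected, abs=1e-9)

    def test_coverage_extremes(self, grid40, sphere5):
        assert coverage_percent(step_dose(grid40, sphere5, 20.0), sphere5, 20.0) == 100.0
        assert coverage_percent(step_dose(grid40, sphere5, 19.0), sphere5, 20.0) == 0.0

    def test_coverage_counts_exact_voxels(self):
        grid = VoxelGrid((10, 10, 10))
        vox = np.zeros(grid.shape, bool)
        vox.reshape(-1)[:100] = True
        ptv = StructureMask("PTV", "PTV", grid, vox)
        dose = np.zeros(grid.shape)
        dose.reshape(-1)[:98] = 20.0
        assert coverage_percent(DoseGrid(grid, dose), ptv, 20.0) == 98.0


class TestPaddickCI:
    def test_perfect_conformity_is_exactly_one(self, grid40, sphere5):
        dose = np.full(grid40.shape, 19.0)
        dose[sphere5.voxels] = 20.0
        assert paddick_ci(DoseGrid(grid40, dose), sphere5, 20.0) == 1.0

    def test_concentric_spheres(self, grid40):
        # PTV r=5 fully covered, isodose r=6: CI = V_ptv/V_iso ~ 523.6/904.8
        ptv = sphere_mask(grid40, (20, 20, 20), 5.0, name="PTV", role="PTV")
        iso = sphere_mask(grid40, (20, 20, 20), 6.0)
        dose = step_dose(grid40, iso, 20.0)
        expected = (4 / 3 * math.pi * 125) / (4 / 3 * math.pi * 216)
        assert paddick_ci(dose, ptv, 20.0) == pytest.approx(expected, rel=0.05)

    def test_disjoint_isodose_gives_zero(self, grid40):
        ptv = sphere_mask(grid40, (10, 10, 10), 4.0, name="PTV", role="PTV")
        iso = sphere_mask(grid40, (30, 30, 30), 4.0)
        assert paddick_ci(step_dose(grid40, iso, 20.0), ptv, 20.0) == 0.0

    def test_no_isodose_warns_and_returns_zero(self, grid40, sphere5):
        dose = DoseGrid(grid40, np.full(grid40.shape, 5.0))
        with pytest.warns(UserWarning):
            assert paddick_ci(dose, sphere5, 20.0) == 0.0


class TestGradientIndex:
    def test_step_dose_gives_exactly_one(self, grid40):
        target = sphere_mask(grid40, (20, 20, 20), 7.0)
        assert gradient_index(step_dose(grid40, target, 20.0), 20.0) == 1.0

    @pytest.mark.parametrize("k,rel", [(3.0, 0.05), (1.3827, 0.05)])
    def test_radial_kernel_matches_closed_form(self, k, rel):
        grid = VoxelGrid((44, 44, 44))
        dose = kernel_dose_grid(grid, (22.0,) * 3, 7.0, 20.0, KernelParams(k))
        assert gradient_index(dose, 20.0) == pytest.approx(2 ** (3 / k), rel=rel)

    def test_no_prescription_isodose_raises(self, grid40):
        dose = DoseGrid(grid40, np.full(grid40.shape, 5.0))
        with pytest.raises(ValueError):
            gradient_index(dose, 20.0)


class TestV12Clusters:
    def _brain(self, grid):
        return sphere_mask(
            grid, tuple(s / 2 for s in grid.shape), min(grid.shape) / 2 - 1,
            name="brain", role="brain",
        )

    def test_isolated_lesions_give_one_cluster_each(self):
        grid = VoxelGrid((40, 40, 80))
        brain = sphere_mask(grid, (20, 20, 40), 19.0, name="brain", role="brain")
        g1 = sphere_mask(grid, (20, 20, 32), 3.0, name="GTV1", role="GTV")
        g2 = sphere_mask(grid, (20, 20, 48), 3.0, name="GTV2", role="GTV")
        shell1 = sphere_mask(grid, (20, 20, 32), 6.0)
        shell2 = sphere_mask(grid, (20, 20, 48), 6.0)
        dose = np.zeros(grid.shape)
        dose[shell1.voxels] = 13.0
        dose[shell2.voxels] = 13.0
        clusters = v12_cluster_volumes(DoseGrid(grid, dose), brain, [g1, g2])
        assert len(clusters) == 2
        assert all(not c.is_merged for c in clusters)
        vols = sorted(c.volume_cm3 for c in clusters)
        expected = shell1.volume_cm3 - g1.volume_cm3
        assert vols[0] == pytest.approx(expected, rel=0.05)

    def test_bridged_shells_merge_into_tagged_cluster(self):
        grid = VoxelGrid((40, 40, 40))
        brain = self._brain(grid)
        g1 = sphere_mask(grid, (20, 20, 15), 3.0, name="GTV1", role="GTV")
        g2 = sphere_mask(grid, (20, 20, 25), 3.0, name="GTV2", role="GTV")
        shell1 = sphere_mask(grid, (20, 20, 15), 6.0)
        shell2 = sphere_mask(grid, (20, 20, 25), 6.0)  # overlapping shells
        dose = np.zeros(grid.shape)
        dose[shell1.voxels | shell2.voxels] = 13.0
        clusters = v12_cluster_volumes(DoseGrid(grid, dose), brain, [g1, g2])
        assert len(clusters) == 1
        assert set(clusters[0].gtv_names) == {"GTV1", "GTV2"}

    def test_no_supra_threshold_dose_gives_empty_result(self, grid40):
        brain = self._brain(grid40)
        dose = DoseGrid(grid40, np.full(grid40.shape, 5.0))
        assert v12_cluster_volumes(dose, brain, []) == []

    def test_cluster_volumes_partition_total_v12(self, rng):
        grid = VoxelGrid((40, 40, 40))
        brain = self._brain(grid)
        gtvs = [
            sphere_mask(grid, tuple(rng.uniform(12, 28, 3)), 2.5,
                        name=f"GTV{i}", role="GTV")
            for i in range(3)
        ]
        dose = DoseGrid(grid, rng.random(grid.shape) * 16.0)
        clusters = v12_cluster_volumes(dose, brain, gtvs)
        healthy = brain.voxels.copy()
        for g in gtvs:
            healthy &= ~g.voxels
        total = (dose.dose[healthy] >= 12.0).sum() * 1e-3
        assert sum(c.volume_cm3 for c in clusters) == pytest.approx(total, abs=1e-3)


def _single_lesion_structures(grid, center, r_gtv=4.0, r_ptv=5.0):
    brain = sphere_mask(grid, center, min(grid.shape) / 2 - 2, name="brain", role="brain")
    gtv = sphere_mask(grid, center, r_gtv, name="GTV1", role="GTV")
    ptv = sphere_mask(grid, center, r_ptv, name="PTV1", role="PTV")
    return StructureSet(grid=grid, masks=[brain, gtv, ptv],
                        gtv_to_ptv_map={"GTV1": "PTV1"})


class TestEvaluatePlan:
    def test_step_dose_single_lesion_composite(self):
        grid = VoxelGrid((50, 50, 50))
        structures = _single_lesion_structures(grid, (25.0,) * 3)
        dose = step_dose(grid, structures["PTV1"], 20.0)
        m = evaluate_plan(dose, structures, {"PTV1": 20.0})
        assert m.coverage_percent == 100.0
        assert m.ci == 1.0
        assert m.gi == 1.0
        # the 12 Gy region is exactly the PTV; healthy-brain V12 is the
        # PTV−GTV shell and nothing beyond it
        shell = structures["PTV1"].volume_cm3 - structures["GTV1"].volume_cm3
        assert m.v12_cm3 == pytest.approx(shell, abs=1e-9)
        assert sum(c.volume_cm3 for c in m.v12_clusters) == pytest.approx(
            m.v12_cm3, abs=1e-9
        )
        assert m.policy_result.status == "pass"

    def test_brainstem_overdose_fails_policy_with_name(self):
        grid = VoxelGrid((50, 50, 50))
        structures = _single_lesion_structures(grid, (25.0,) * 3)
        stem = sphere_mask(grid, (10, 25, 25), 4.0, name="brainstem", role="brainstem")
        structures = StructureSet(
            grid=grid, masks=structures.masks + [stem],
            gtv_to_ptv_map={"GTV1": "PTV1"},
        )
        dose_arr = step_dose(grid, structures["PTV1"], 20.0).dose.copy()
        dose_arr[10, 25, 25] = 13.0
        m = evaluate_plan(DoseGrid(grid, dose_arr), structures, {"PTV1": 20.0})
        assert m.policy_result.status == "fail"
        assert any("brainstem" in r for r in m.policy_result.reasons)

    def test_mixed_prescriptions_use_local_reference(self):
        # two distant lesions at 18 and 20 Gy: each covered at its own PD
        grid = VoxelGrid((40, 40, 90))
        c1, c2 = (20.0, 20.0, 22.0), (20.0, 20.0, 68.0)
        brain = sphere_mask(grid, (20, 20, 45), 18, name="brain", role="brain")
        masks = [brain]
        for i, c in enumerate((c1, c2)):
            masks.append(sphere_mask(grid, c, 3.0, name=f"GTV{i+1}", role="GTV"))
            masks.append(sphere_mask(grid, c, 4.0, name=f"PTV{i+1}", role="PTV"))
        structures = StructureSet(
            grid=grid, masks=masks,
            gtv_to_ptv_map={"GTV1": "PTV1", "GTV2": "PTV2"},
        )
        dose = np.zeros(grid.shape)
        dose[sphere_mask(grid, c1, 5.0).voxels] = 18.0
        dose[sphere_mask(grid, c2, 5.0).voxels] = 20.0
        m = evaluate_plan(
            DoseGrid(grid, dose), structures, {"PTV1": 18.0, "PTV2": 20.0}
        )
        assert m.coverage_percent == 100.0
        for t in m.targets:
            assert t.coverage_percent == 100.0


class TestCheckPolicy:
    def _metrics(self, coverage=99.0, d2=24.0, d2_cum=24.0, oar=None):
        t = TargetMetrics(
            name="PTV1", prescription_Gy=20.0, coverage_percent=coverage,
            ci=0.8, d2_percent_Gy=d2, mean_Gy=22.0,
            v_pi_cm3=1.0, v_pi_ptv_cm3=0.9, v_ptv_cm3=1.0,
        )
        return PlanMetrics(
            targets=[t], ci=0.8, gi=4.5, coverage_percent=coverage,
            ptv_mean_Gy=22.0, d2_cumulative_Gy=d2_cum, brain_mean_Gy=2.0,
            v5_cm3=50.0, v8_cm3=20.0, v10_cm3=10.0, v12_cm3=5.0,
            v12_clusters=[], hippocampus_L_mean_Gy=1.0, hippocampus_R_mean_Gy=1.0,
            oar_max_Gy=oar or {}, reference_prescription_Gy=20.0,
        )

    def test_low_coverage_fails_and_names_target(self):
        res = check_policy(self._metrics(coverage=97.9))
        assert res.status == "fail"
        assert any("PTV1" in r for r in res.reasons)

    def test_two_tier_d2_rule_warns_but_does_not_reject(self):
        # per-PTV D2% at 132% of PD and cumulative at 133%: warn tier only
        res = check_policy(self._metrics(d2=26.4, d2_cum=26.6))
        assert res.status == "warn"
        assert res.passed

    def test_cumulative_d2_above_135_percent_rejects(self):
        res = check_policy(self._metrics(d2=26.4, d2_cum=27.2))
        assert res.status == "fail"

    def test_all_constraints_met_passes(self):
        res = check_policy(
            self._metrics(oar={"brainstem": 11.0, "optic_apparatus": 7.0, "lens": 1.0})
        )
        assert res.status == "pass" and res.reasons == []

    def test_oar_limits_enforced(self):
        for role, dose in (("brainstem", 12.5), ("optic_apparatus", 8.5), ("lens", 2.5)):
            res = check_policy(self._metrics(oar={role: dose}))
            assert res.status == "fail"
            assert any(role in r for r in res.reasons)


class TestInvariantsOnRandomFields:
    def test_v_thresholds_nonincreasing(self, grid40, rng):
        brain = sphere_mask(grid40, (20, 20, 20), 18, name="brain", role="brain")
        for _ in range(5):
            dose = DoseGrid(grid40, rng.random(grid40.shape) * 15)
            vols = [volume_at_dose(dose, brain, t) for t in (5, 8, 10, 12)]
            assert vols == sorted(vols, reverse=True)

    def test_gi_at_least_one_and_ci_in_unit_interval(self, grid40, rng):
        ptv = sphere_mask(grid40, (20, 20, 20), 5, name="PTV", role="PTV")
        for _ in range(5):
            dose = DoseGrid(grid40, rng.random(grid40.shape) * 25)
            if (dose.dose >= 20).any():
                assert gradient_index(dose, 20.0) >= 1.0
                assert 0.0 <= paddick_ci(dose, ptv, 20.0) <= 1.0
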