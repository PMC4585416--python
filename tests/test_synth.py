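"""Root-system generator: determinism, calibration, rasterization, re-spreading."""

import json

import numpy as np
import pytest

from shollroot import (
    GenotypeParams,
    InvalidParameterError,
    RasterParams,
    ShollGrid,
    analytic_sholl,
    auto_end_radius,
    default_params,
    derive_seed,
    extract_traits,
    rasterize,
    respread,
    sample_resolvable_system,
    sample_root_system,
    simulate_cohort,
)
from shollroot.synth import CohortSpec, default_cohort_spec

FAST = GenotypeParams(
    primary_length_mean=5.0,
    primary_length_sd=0.5,
    lateral_count_mean=40.0,
    lateral_length_log_mean=np.log(0.3),
    lateral_length_log_sd=0.3,
)


class TestSampling:
    def test_deterministic_given_seed(self):
        a, _ = sample_root_system(FAST, seed=7)
        b, _ = sample_root_system(FAST, seed=7)
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())

    def test_noise_free_limit_is_straight_vertical(self):
        params = GenotypeParams(
            primary_length_mean=5.0, primary_length_sd=0.0,
            lateral_count_mean=0.0, lateral_length_log_mean=0.0,
            lateral_length_log_sd=0.0, tortuosity_sd=0.0, gravitropism=1.0,
        )
        system, traits = sample_root_system(params, seed=1)
        assert traits.NLR == 0
        np.testing.assert_allclose(system.primary.points[:, 0], 0.0, atol=1e-12)
        assert traits.PRL == pytest.approx(5.0, abs=0.05)

    def test_poisson_lateral_count_mean(self):
        """Sample mean NLR over 2,000 draws within 3 Poisson standard errors."""
        n = 2000
        nlr = np.array(
            [sample_root_system(FAST, seed=s)[1].NLR for s in range(n)]
        )
        assert abs(nlr.mean() - 40.0) < 3 * np.sqrt(40.0 / n)

    def test_recorded_traits_equal_extraction(self):
        for seed in range(20):
            system, recorded = sample_root_system(FAST, seed=seed)
            assert extract_traits(system) == recorded

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            GenotypeParams(
                primary_length_mean=-1.0, primary_length_sd=0.1,
                lateral_count_mean=1.0, lateral_length_log_mean=0.0,
                lateral_length_log_sd=0.1,
            )
        with pytest.raises(InvalidParameterError):
            GenotypeParams(
                primary_length_mean=1.0, primary_length_sd=0.1,
                lateral_count_mean=1.0, lateral_length_log_mean=0.0,
                lateral_length_log_sd=0.1, branch_zone_fraction=0.0,
            )


class TestDefaultParams:
    def test_expected_mlrl_matches_phenotypes(self):
        assert default_params("DR", "control").expected_mlrl == pytest.approx(1.48)
        assert default_params("DR", "stress").expected_mlrl == pytest.approx(6.19)

    def test_stress_nlr_reductions(self):
        """Stress halves DR lateral count and cuts DS count by 40%."""
        assert default_params("DR", "stress").lateral_count_mean == pytest.approx(
            0.5 * default_params("DR", "control").lateral_count_mean
        )
        assert default_params("DS", "stress").lateral_count_mean == pytest.approx(
            0.6 * default_params("DS", "control").lateral_count_mean
        )

    def test_unknown_label(self):
        with pytest.raises(InvalidParameterError):
            default_params("XX", "control")

    @pytest.mark.parametrize(
        "genotype, treatment, target_extent",
        [("DR", "control", 26.0), ("DS", "control", 21.0),
         ("DR", "stress", 22.0), ("DS", "stress", 18.0)],
    )
    def test_extent_calibration(self, genotype, treatment, target_extent):
        """Mean outermost-tip distance tracks the calibrated group extents."""
        params = default_params(genotype, treatment)
        extents = [
            sample_root_system(params, derive_seed(5, genotype, treatment, i))[1].extent
            for i in range(40)
        ]
        assert np.mean(extents) == pytest.approx(target_extent, rel=0.10)


class TestCohort:
    def test_layout_and_determinism(self):
        spec = default_cohort_spec(n_replicates=2, seed=3)
        rows = simulate_cohort(spec)
        assert len(rows) == 8
        again = simulate_cohort(spec)
        for a, b in zip(rows, again):
            assert json.dumps(a["system"].to_dict()) == json.dumps(b["system"].to_dict())

    def test_unique_labels_required(self):
        params = default_params("DR", "control")
        with pytest.raises(InvalidParameterError):
            CohortSpec(groups=(("A", "x", params), ("A", "x", params)))

    def test_group_mlrl_converges_to_expectation(self):
        """Monte-Carlo check of the MLRL calibration at n = 500."""
        params = default_params("DR", "stress")
        vals = [
            sample_root_system(params, derive_seed(9, "mlrl", i))[1].MLRL
            for i in range(500)
        ]
        assert np.mean(vals) == pytest.approx(params.expected_mlrl, rel=0.05)

    def test_it_monotone_in_lateral_count(self):
        """More laterals means more total intersections (paired seeds, n = 500)."""
        from dataclasses import replace

        lo = FAST
        hi = replace(lo, lateral_count_mean=80.0)
        totals = {"lo": 0, "hi": 0}
        for i in range(500):
            for name, params in (("lo", lo), ("hi", hi)):
                system, _ = sample_root_system(params, derive_seed(2, "mono", i))
                grid = ShollGrid(auto_end_radius(system))
                totals[name] += analytic_sholl(system, grid).total
        assert totals["hi"] > totals["lo"]


class TestRasterize:
    def test_pixel_size(self):
        assert RasterParams(dpi=200).pixel_size == pytest.approx(0.0127)

    def test_horizontal_segment_run_length(self):
        """1 cm at 200 dpi is 78.74 px; the stroke is 79 +/- 1 px long."""
        from shollroot.geometry import Polyline, RootSystem

        system = RootSystem(Polyline([(0.0, 0.0), (0.0, 0.01), (1.0, 0.01)]))
        image = rasterize(system, RasterParams(dpi=200))
        run = image.mask.sum(axis=1).max()
        assert abs(run - 79) <= 1

    def test_axes_eight_connected(self, dr_control_system):
        """Each rasterized axis forms one 8-connected component."""
        from skimage.measure import label

        from shollroot.geometry import Polyline, RootSystem

        system, _ = dr_control_system
        for axis in system.axes[:5]:
            solo = RootSystem(Polyline(axis.points - axis.points[0]))
            img = rasterize(solo, RasterParams(dpi=200))
            assert label(img.mask, connectivity=2).max() == 1

    def test_skeleton_round_trip_length(self):
        """Tracing the raster back recovers the primary length within 2%."""
        from skimage.morphology import skeletonize

        params = GenotypeParams(
            primary_length_mean=10.0, primary_length_sd=0.0,
            lateral_count_mean=0.0, lateral_length_log_mean=0.0,
            lateral_length_log_sd=0.0,
        )
        system, traits = sample_root_system(params, seed=4)
        image = rasterize(system, RasterParams(dpi=200))
        skel = skeletonize(image.mask)
        # chain-length estimate with Kulpa's corrected step weights
        straight = (
            np.count_nonzero(skel[:, 1:] & skel[:, :-1])
            + np.count_nonzero(skel[1:, :] & skel[:-1, :])
        )
        diagonal = (
            np.count_nonzero(skel[1:, 1:] & skel[:-1, :-1])
            + np.count_nonzero(skel[1:, :-1] & skel[:-1, 1:])
        )
        length_cm = (0.948 * straight + 1.340 * diagonal) * image.pixel_size
        assert length_cm == pytest.approx(traits.PRL, rel=0.02)

    def test_size_guard(self):
        from shollroot.geometry import InvalidInputError, Polyline, RootSystem

        huge = RootSystem(Polyline([(0.0, 0.0), (0.0, 300.0)]))
        with pytest.raises(InvalidInputError):
            rasterize(huge, RasterParams(dpi=200))


class TestRespread:
    def test_traits_invariant(self, dr_control_system):
        system, traits = dr_control_system
        for seed in range(5):
            moved = extract_traits(respread(system, seed=seed))
            assert moved.NLR == traits.NLR
            for field in ("RL", "PRL", "LRL", "MLRL", "extent"):
                assert getattr(moved, field) == pytest.approx(
                    getattr(traits, field), abs=1e-9
                )

    def test_zero_angle_is_identity(self, dr_control_system):
        system, _ = dr_control_system
        same = respread(system, seed=0, angle_sd=0.0)
        np.testing.assert_allclose(same.primary.points, system.primary.points)

    def test_profiles_vary_but_mildly(self, dr_control_system):
        """Fig-7-style robustness: per-circle SD/mean stays small."""
        from shollroot.stats import align_profiles

        system, _ = dr_control_system
        profiles = []
        for seed in range(10):
            moved = respread(system, seed=seed)
            grid = ShollGrid(auto_end_radius(moved))
            profiles.append(analytic_sholl(moved, grid))
        _, mat = align_profiles(profiles)
        assert len({tuple(row) for row in mat}) > 1
        mean, sd = mat.mean(axis=0), mat.std(axis=0)
        busy = mean >= 2
        assert np.all(sd[busy] / mean[busy] < 0.5)


def test_resolvable_fixture_is_tangency_free():
    """The screened fixture generator yields systems with separated crossings."""
    from shollroot.geometry import circle_crossing_points

    system, _ = sample_resolvable_system(seed=0)
    grid = ShollGrid(auto_end_radius(system))
    px = 2.54 / 200.0
    for k, r in enumerate(grid.radii):
        hits = sorted(
            h for ax in system.axes for h in circle_crossing_points(ax, grid.radii)[k]
        )
        assert all(speed >= 0.25 for _, speed in hits)
        if len(hits) > 1:
            angs = np.array([a for a, _ in hits])
            gaps = np.append(np.diff(angs), angs[0] + 2 * np.pi - angs[-1])
            assert gaps.min() * r >= 3.5 * px
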