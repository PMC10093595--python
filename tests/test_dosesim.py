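"""Surrogate dose model, micro-window scoring and replicate noise."""

import numpy as np
import pytest

from mrtdose import dosesim, phantom
from mrtdose.dosesim import (
    BeamConfig,
    DoseGrid,
    MicroLattice,
    SurrogateParams,
    score_micro_lattice,
    simulate_replicates,
    surrogate_truth,
)
from mrtdose.phantom import AIR, BONE, WATER, MaterialGrid


def brute_force_score(micro: MicroLattice, beam: BeamConfig):
    """Independent oracle: scan every micro-bin against every window."""
    n_depth, n_bins = micro.deposition.shape
    extent = n_bins * micro.bin_um
    macro_um = beam.macrovoxel_mm * 1000.0
    n_macro = int(np.ceil((extent - 1e-9) / macro_um))
    peak = np.zeros((n_depth, n_macro))
    valley = np.zeros((n_depth, n_macro))
    for channel, width, offset, out in (
        ("peak", beam.peak_window_um, 0.0, peak),
        ("valley", beam.valley_window_um, beam.pitch_um / 2.0, valley),
    ):
        k_lo = int(np.floor((micro.origin_um - offset) / beam.pitch_um)) - 1
        k_hi = int(np.ceil((micro.origin_um + extent - offset) / beam.pitch_um)) + 1
        for k in range(k_lo, k_hi + 1):
            center = offset + k * beam.pitch_um
            if not (micro.origin_um <= center <= micro.origin_um + extent):
                continue
            lo_edge, hi_edge = center - width / 2.0, center + width / 2.0
            members = [
                b
                for b in range(n_bins)
                if lo_edge - 1e-9 <= micro.origin_um + (b + 0.5) * micro.bin_um < hi_edge - 1e-9
            ]
            if len(members) != int(round(width / micro.bin_um)):
                continue  # window extends beyond the lattice: dropped
            rel = center - micro.origin_um
            if rel % macro_um == 0 and rel > 0:
                m = int(rel // macro_um) - 1
            else:
                m = int(rel // macro_um)
            if 0 <= m < n_macro:
                for b in members:
                    out[:, m] += micro.deposition[:, b]
    return peak, valley


class TestScoring:
    def test_zero_deposition_scores_zero(self):
        micro = MicroLattice(np.zeros((4, 200)))
        peak, valley = score_micro_lattice(micro)
        assert not peak.any() and not valley.any()

    def test_uniform_deposition_single_macrovoxel(self):
        # one 0.5 mm macrovoxel = 50 bins spanning [-200, 300) um: contains
        # the peak window at 0 um (1 bin) and the valley window at 200 um
        # (mid-pitch, 10 bins)
        beam = BeamConfig()
        u = 3.0
        micro = MicroLattice(np.full((1, 50), u), origin_um=-200.0)
        peak, valley = score_micro_lattice(micro, beam)
        oracle_p, oracle_v = brute_force_score(micro, beam)
        np.testing.assert_allclose(peak, oracle_p, atol=1e-12)
        np.testing.assert_allclose(valley, oracle_v, atol=1e-12)
        assert peak[0, 0] == pytest.approx(u)
        assert valley[0, 0] == pytest.approx(10 * u)

    def test_uniform_lattice_peak_and_valley_window_sums(self):
        # 2 pitches of lattice: bins span [-200, 600) um; interior peak
        # windows at 0 and 400 um land in macrovoxels 0 and 1; the valley
        # window at 600 um extends beyond the lattice and is dropped
        beam = BeamConfig()
        u = 1.0
        micro = MicroLattice(np.full((1, 80), u), origin_um=-200.0)
        peak, valley = score_micro_lattice(micro, beam)
        assert peak[0, 0] == pytest.approx(u)
        assert peak[0, 1] == pytest.approx(u)
        assert valley[0, 0] == pytest.approx(10 * u)
        assert valley[0, 1] == 0.0

    def test_single_bin_mid_pitch_lands_only_in_valley(self):
        beam = BeamConfig()
        dep = np.zeros((1, 80))
        micro = MicroLattice(dep, origin_um=-200.0)
        dep[0, 40] = 5.0  # bin centre at 205 um, inside the valley window [150,250)
        peak, valley = score_micro_lattice(micro, beam)
        assert peak.sum() == 0
        assert valley[0, 0] == 5.0

    def test_matches_brute_force_oracle_on_random_lattices(self):
        rng = np.random.default_rng(3)
        beam = BeamConfig()
        for _ in range(100):
            n_depth = int(rng.integers(1, 4))
            n_bins = int(rng.integers(40, 400))
            origin = float(rng.choice([-200.0, -50.0, 0.0, 130.0]))
            micro = MicroLattice(
                rng.random((n_depth, n_bins)), origin_um=origin
            )
            peak, valley = score_micro_lattice(micro, beam)
            oracle_p, oracle_v = brute_force_score(micro, beam)
            np.testing.assert_allclose(peak, oracle_p, atol=1e-12)
            np.testing.assert_allclose(valley, oracle_v, atol=1e-12)

    def test_window_energy_conserved(self):
        rng = np.random.default_rng(4)
        beam = BeamConfig()
        micro = MicroLattice(rng.random((3, 300)), origin_um=-200.0)
        peak, valley = score_micro_lattice(micro, beam)
        oracle_p, oracle_v = brute_force_score(micro, beam)
        assert peak.sum() + valley.sum() == pytest.approx(
            oracle_p.sum() + oracle_v.sum(), rel=1e-12
        )

    def test_fractional_window_width_rejected(self):
        beam = BeamConfig(peak_window_um=15.0)
        micro = MicroLattice(np.ones((1, 100)), bin_um=10.0)
        with pytest.raises(ValueError, match="integer number"):
            score_micro_lattice(micro, beam)


class TestBeamConfig:
    def test_canonical_grid_shape(self):
        assert BeamConfig().grid_shape == (96, 16, 16)

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            BeamConfig(valley_window_um=500.0)

    def test_non_multiple_field_rejected(self):
        with pytest.raises(ValueError):
            BeamConfig(field_size_mm=8.3)


class TestSurrogateTruth:
    def test_air_phantom_negligible_attenuation(self):
        labels = np.full(phantom.CANONICAL_SHAPE, AIR, dtype=np.int8)
        peak, _ = surrogate_truth(MaterialGrid(labels=labels))
        # compare exit value with the value just past build-up (depth 5 mm)
        entry = peak.values[10, 8, 8]
        exit_ = peak.values[-1, 8, 8]
        assert abs(exit_ / entry - 1) < 0.01

    def test_water_depth_falloff_is_exponential(self, water_grid):
        peak, _ = surrogate_truth(water_grid)
        params = SurrogateParams()
        profile = np.log(peak.values[:, 8, 8])
        depth = (np.arange(96) + 0.5) * 0.5
        sel = depth > 20  # far beyond build-up
        slope = np.polyfit(depth[sel], profile[sel], 1)[0]
        assert slope == pytest.approx(-params.mu[WATER], abs=1e-6)

    def test_bone_layer_enhancement_ratio(self):
        labels = np.full(phantom.CANONICAL_SHAPE, WATER, dtype=np.int8)
        # bone on one lateral half of layer 40: same radiological depth as
        # the water half of the same layer
        labels[40, :, :8] = BONE
        peak, _ = surrogate_truth(MaterialGrid(labels=labels))
        params = SurrogateParams()
        ratio = peak.values[40, 8, 4] / peak.values[40, 8, 12]
        assert ratio == pytest.approx(params.multiplier[BONE] / params.multiplier[WATER], rel=1e-9)

    def test_channels_positive_and_pvdr_decreasing_in_water(self, water_grid):
        peak, valley = surrogate_truth(water_grid)
        assert (peak.values > 0).all() and (valley.values > 0).all()
        pvdr = peak.values / valley.values
        center = pvdr[:, 8, 8]
        assert (center > 1).all()
        depth = (np.arange(96) + 0.5) * 0.5
        beyond = center[depth > 2.0]
        assert (np.diff(beyond) <= 1e-12).all()
        # order tens in the useful depth range
        assert 10 < center[40] < 100

    def test_unknown_material_rejected(self):
        labels = np.full((8, 4, 4), 2, dtype=np.int8)
        grid = MaterialGrid(labels=labels)
        with pytest.raises(KeyError):
            surrogate_truth(grid, params=SurrogateParams(
                mu={AIR: 1e-4, WATER: 0.02},
                multiplier={AIR: 0.001, WATER: 1.0, BONE: 3.5},
            ))

    def test_deterministic(self, head):
        grid, _ = head
        p1, v1 = surrogate_truth(grid)
        p2, v2 = surrogate_truth(grid)
        np.testing.assert_array_equal(p1.values, p2.values)
        np.testing.assert_array_equal(v1.values, v2.values)


class TestReplicates:
    def test_large_event_budget_recovers_truth(self, water_grid):
        _, valley = surrogate_truth(water_grid)
        noisy = simulate_replicates(valley, 1e6, 20, seed=0)
        mask = noisy.in_field_mask()
        rel_err = np.abs(noisy.values[mask] / valley.values[mask] - 1)
        assert rel_err.max() < 0.005
        assert (noisy.se[mask] / noisy.values[mask]).max() < 0.002

    def test_relative_se_mode_matches_analytic_value(self):
        # 10^4 voxels at reference dose: SE/mean distribution peaks near
        # 1/sqrt(n * lambda)
        truth = DoseGrid(channel="valley", values=np.ones((100, 10, 10)))
        noisy = simulate_replicates(truth, 2.22, 20, seed=1, reference=1.0)
        rel = 100 * noisy.se[noisy.values > 0] / noisy.values[noisy.values > 0]
        mode = dosesim.relative_se_mode(rel, 1.0)
        assert abs(mode - 100 / np.sqrt(20 * 2.22)) <= 3.0

    def test_empirical_se_converges_to_analytic(self):
        truth = DoseGrid(channel="peak", values=np.ones((100, 10, 10)))
        lam, n = 50.0, 20
        noisy = simulate_replicates(truth, lam, n, seed=2, reference=1.0)
        analytic = 1.0 / np.sqrt(n * lam)
        assert abs(noisy.se.mean() / analytic - 1) < 0.05

    def test_same_seed_is_bitwise_identical(self, water_grid):
        _, valley = surrogate_truth(water_grid)
        a = simulate_replicates(valley, 2.22, 20, seed=5)
        b = simulate_replicates(valley, 2.22, 20, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.se, b.se)

    def test_too_few_replicates_rejected(self, water_grid):
        _, valley = surrogate_truth(water_grid)
        with pytest.raises(ValueError, match="replicates"):
            simulate_replicates(valley, 2.22, 1, seed=0)


@pytest.fixture(scope="module")
def four_sample_dataset(tmp_path_factory):
    from mrtdose import augment

    bases, split = {}, {}
    for i, part in enumerate(["train", "train", "val", "test"]):
        bases[f"b{i}"] = phantom.generate_synthetic_head(200 + i)
        split[f"b{i}"] = part
    cohort = augment.build_augmented_cohort(
        bases, {"train": 2, "val": 1, "test": 1}, split, seed=9
    )
    path = tmp_path_factory.mktemp("ds") / "high.h5"
    dosesim.make_dataset(cohort, bases, str(path), regime="high", seed=9)
    return path


class TestMakeDataset:
    def test_records_complete_and_valid(self, four_sample_dataset):
        from mrtdose.container import DoseDataset

        with DoseDataset(str(four_sample_dataset)) as ds:
            assert len(ds.sample_ids) == 4
            for sid in ds.sample_ids:
                rec = ds.read_sample(sid)
                for key in ("density", "materials", "tumor_mask",
                            "peak_mean", "peak_se", "valley_mean", "valley_se"):
                    assert rec[key].shape == (96, 16, 16)
                assert (rec["density"] > 0).all()
                assert (rec["peak_se"] >= 0).all()
                attrs = ds.sample_attrs(sid)
                assert attrs["partition"] in ("train", "val", "test")
                assert "transform" in attrs

    def test_collision_without_overwrite_rejected(self, four_sample_dataset):
        with pytest.raises(FileExistsError):
            dosesim.make_dataset([], {}, str(four_sample_dataset), regime="high")

    def test_high_noise_se_modes_match_regime(self, prepared_head):
        grid, _ = prepared_head
        peak, valley = surrogate_truth(grid)
        lam = dosesim.noise_lambdas("high")
        vn = simulate_replicates(valley, lam["valley"], 20, seed=21)
        pn = simulate_replicates(peak, lam["peak"], 20, seed=22)
        vm = valley.values > 0.05 * valley.values.max()
        pm = peak.values > 0.05 * peak.values.max()
        v_mode = dosesim.relative_se_mode(100 * vn.se[vm] / vn.values[vm], 1.0)
        p_mode = dosesim.relative_se_mode(100 * pn.se[pm] / pn.values[pm], 0.5)
        assert 12.0 <= v_mode <= 18.0
        assert 3.5 <= p_mode <= 6.5

    def test_low_noise_valley_se_below_two_percent(self, prepared_head):
        grid, _ = prepared_head
        peak, valley = surrogate_truth(grid)
        lam = dosesim.noise_lambdas("low")
        vn = simulate_replicates(valley, lam["valley"], 20, seed=23)
        vm = valley.values > 0.05 * valley.values.max()
        rel = 100 * vn.se[vm] / vn.values[vm]
        assert (rel < 2.0).mean() >= 0.95
        pn = simulate_replicates(peak, lam["peak"], 20, seed=24)
        pmask = peak.values > 0.05 * peak.values.max()
        relp = 100 * pn.se[pmask] / pn.values[pmask]
        assert (relp < 0.5).mean() >= 0.95
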