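import numpy as np
import pytest

import megjoint as mj
from megjoint.mesh import LEFT, RIGHT, geodesic_distances
from megjoint.simulate import (
    ConfigurationError,
    _hemifield_hemispheres,
    make_noise_cov,
    make_stimulus_layout,
    place_targets,
    simulate_evoked,
    simulate_experiment,
)


class TestStimulusLayout:
    def test_default_dartboard_has_24_regions(self):
        layout = make_stimulus_layout()
        assert layout.n_regions == 24
        assert layout.rings == 3 and layout.wedges == 8

    def test_single_region_layout(self):
        layout = make_stimulus_layout(rings=1, wedges=1, radii_deg=(0.5, 8.4))
        region = layout.regions[0]
        assert layout.n_regions == 1
        assert region.angle_end_deg - region.angle_start_deg == 360.0

    def test_wedge_spans_partition_the_circle(self):
        layout = make_stimulus_layout()
        for ring in range(1, 4):
            spans = [
                r.angle_end_deg - r.angle_start_deg
                for r in layout.regions if r.ring == ring
            ]
            assert np.isclose(sum(spans), 360.0)

    def test_vertical_meridian_wedges_are_bilateral(self):
        layout = make_stimulus_layout()
        bilateral_wedges = {r.wedge for r in layout.regions if r.bilateral}
        # top pair straddles 90 deg, bottom pair 270 deg
        assert bilateral_wedges == {2, 3, 6, 7}

    def test_radii_validation(self):
        with pytest.raises(ValueError):
            make_stimulus_layout(radii_deg=(0.5, 2.3, 2.3, 8.4))
        with pytest.raises(ValueError):
            make_stimulus_layout(radii_deg=(0.5, 2.3, 4.7))


class TestTargets:
    def test_contralateral_placement(self, mesh_ico2):
        layout = make_stimulus_layout()
        truth = place_targets(mesh_ico2, layout)
        for region in layout.regions:
            hemis = [h for h, _ in truth.region_targets(region)]
            if region.bilateral:
                assert sorted(hemis) == [LEFT, RIGHT]
            else:
                c = region.center_angle_deg % 360
                expected = RIGHT if 90 < c < 270 else LEFT
                assert hemis == [expected]
            for h, v in truth.region_targets(region):
                assert mesh_ico2.hemisphere[v] == h

    def test_eccentricity_orders_pole_distance(self):
        mesh = mj.build_template_space(3)
        layout = make_stimulus_layout()
        truth = place_targets(mesh, layout)
        d = geodesic_distances(mesh, truth.anchors[LEFT])
        for wedge in (1, 8):  # unilateral left-hemisphere wedges
            dists = [
                d[truth.targets[(r.index, LEFT)]]
                for r in layout.regions if r.wedge == wedge
            ]
            assert dists == sorted(dists)
            assert dists[0] < dists[-1]

    def test_neighbor_distances_match_direct_loop(self):
        mesh = mj.build_template_space(3)
        layout = make_stimulus_layout()
        truth = place_targets(mesh, layout)
        mean, mn = truth.neighbor_distances(mesh, 8, LEFT)
        v0 = truth.targets[(8, LEFT)]
        loop = [
            float(geodesic_distances(mesh, v0)[v])
            for (ri, h), v in truth.targets.items()
            if h == LEFT and ri != 8 and v != v0
        ]
        assert np.isclose(mean, np.mean(loop))
        assert np.isclose(mn, np.min(loop))

    def test_patch_too_small_raises(self, mesh_ico2):
        layout = make_stimulus_layout()
        with pytest.raises(ConfigurationError):
            place_targets(mesh_ico2, layout, ring_distances_mm=(10, 20, 90),
                          patch_radius_mm=40.0)


class TestEvoked:
    def test_noiseless_evoked_is_exact_forward_projection(
        self, mesh_ico2, leadfield_ico2, noise_cov
    ):
        layout = make_stimulus_layout()
        truth = place_targets(mesh_ico2, layout)
        region = layout.regions[8]
        Y, info = simulate_evoked(
            leadfield_ico2, noise_cov, mesh_ico2, truth, region,
            snr_target=None, noise_scale=0.0, seed=0, neighbor_leakage=0.0,
        )
        times = np.arange(-50.0, 451.0)
        v = info["target_vertices"][0]
        pulse = np.exp(-0.5 * ((times - info["peak_time_ms"]) / 10.0) ** 2)
        expected = info["amplitude"] * np.outer(leadfield_ico2.matrix[:, v], pulse)
        assert np.allclose(Y, expected)
        t, flag = mj.find_peak_time(Y, times)
        assert t == pytest.approx(info["peak_time_ms"], abs=1.0) and not flag

    def test_evoked_deterministic_given_seed(
        self, mesh_ico2, leadfield_ico2, noise_cov
    ):
        layout = make_stimulus_layout()
        truth = place_targets(mesh_ico2, layout)
        region = layout.regions[0]
        Y1, _ = simulate_evoked(leadfield_ico2, noise_cov, mesh_ico2, truth,
                                region, seed=9)
        Y2, _ = simulate_evoked(leadfield_ico2, noise_cov, mesh_ico2, truth,
                                region, seed=9)
        assert np.array_equal(Y1, Y2)

    def test_snr_calibration_hits_target(self, mesh_ico2, leadfield_ico2, noise_cov):
        """Realized amplitude SNR stays within 25% of the requested SNR 2."""
        layout = make_stimulus_layout()
        truth = place_targets(mesh_ico2, layout)
        region = layout.regions[8]
        times = np.arange(-50.0, 451.0)
        for seed in range(30):
            Y, _ = simulate_evoked(
                leadfield_ico2, noise_cov, mesh_ico2, truth, region,
                snr_target=2.0, seed=seed,
            )
            snr = mj.estimate_snr(Y, noise_cov, times)
            assert 1.5 <= snr <= 2.5


class TestExperiment:
    def test_flash_bookkeeping(self):
        cfg = mj.ExperimentConfig(subdivisions=1, ring_distances_mm=(12, 24, 36), patch_radius_mm=70.0)
        exp = simulate_experiment(1, config=cfg, master_seed=0)
        md = exp.metadata
        assert md["flashes_per_run"] == 258
        assert md["n_runs"] == 7
        assert md["flashes_per_region"] == 258 * 7 == 1806
        assert len(exp.subjects) == 1
        assert len(exp.subjects[0].evoked) == 24

    def test_reproducible_from_master_seed(self):
        cfg = mj.ExperimentConfig(subdivisions=1, ring_distances_mm=(12, 24, 36), patch_radius_mm=70.0)
        a = simulate_experiment(2, config=cfg, master_seed=5)
        b = simulate_experiment(2, config=cfg, master_seed=5)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.leadfield.matrix, sb.leadfield.matrix)
            for r in sa.evoked:
                assert np.array_equal(sa.evoked[r], sb.evoked[r])

    def test_eccentricity_attenuation_is_monotone(self, small_experiment):
        """Outer rings are simulated weaker: per-ring realized SNR decreases."""
        exp = small_experiment
        times = exp.subjects[0].times
        ring_snr = {}
        for region in exp.layout.regions:
            snrs = [
                mj.estimate_snr(s.evoked[region.index], s.noise_cov, times)
                for s in exp.subjects
            ]
            ring_snr.setdefault(region.ring, []).append(np.mean(snrs))
        means = [np.mean(ring_snr[r]) for r in (1, 2, 3)]
        assert means[0] > means[1] > means[2]

    def test_subject_target_jitter_bounded(self, small_experiment):
        exp = small_experiment
        bound = exp.config.target_jitter_mm
        for subj in exp.subjects:
            for region in exp.layout.regions:
                truths = [v for _, v in exp.truth.region_targets(region)]
                used = subj.info["regions"][region.index]["target_vertices"]
                for v_true, v_used in zip(truths, used):
                    d = geodesic_distances(exp.mesh, v_true)[v_used]
                    assert d <= bound + 1e-9

    def test_unilateral_regions_never_ipsilateral(self, small_experiment):
        exp = small_experiment
        for region in exp.layout.regions:
            if region.bilateral:
                continue
            (expected,) = _hemifield_hemispheres(region)
            for subj in exp.subjects:
                for v in subj.info["regions"][region.index]["target_vertices"]:
                    assert exp.mesh.hemisphere[v] == expected


def test_noise_cov_is_spd():
    cov = make_noise_cov(32, seed=1)
    assert np.allclose(cov, cov.T)
    assert np.linalg.eigvalsh(cov).min() > 0
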