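"""Synthetic phantom generator: determinism, recovery, coupling."""

import math

import numpy as np
import pytest
from scipy.stats import binom

import bodyquant as bq
from bodyquant.phantom import CLASS_METASTASIS, CLASS_TLS


def small_config(**overrides):
    defaults = dict(
        grid_shape=(40, 60, 60),
        n_metastases=6,
        n_tls=10,
        met_volume_lognormal=(0.0004, 0.3),
        tls_volume_lognormal=(0.0002, 0.3),
        coupling_scale_um=60.0,
        seed=11,
    )
    defaults.update(overrides)
    return bq.PhantomConfig(**defaults)


class TestObjectPhantom:
    def test_empty_config_gives_empty_truth(self):
        cfg = small_config(n_metastases=0, n_tls=0)
        _, annotation, _, truth = bq.generate_object_phantom(cfg)
        assert truth.objects == []
        assert annotation[CLASS_METASTASIS].data.max() == 0
        assert annotation[CLASS_TLS].data.max() == 0

    def test_same_seed_bit_identical(self):
        cfg = small_config()
        out1 = bq.generate_object_phantom(cfg)
        out2 = bq.generate_object_phantom(cfg)
        for cls in (CLASS_METASTASIS, CLASS_TLS):
            assert np.array_equal(out1[0][cls].data, out2[0][cls].data)
            assert np.array_equal(out1[1][cls].data, out2[1][cls].data)
        assert [o.center_um for o in out1[3].objects] == [
            o.center_um for o in out2[3].objects
        ]

    def test_different_seeds_differ(self):
        a = bq.generate_object_phantom(small_config(seed=1))[3]
        b = bq.generate_object_phantom(small_config(seed=2))[3]
        assert [o.center_um for o in a.objects] != [o.center_um for o in b.objects]

    def test_single_sphere_analytic_volume(self):
        # one 50 µm isotropic metastasis at 10 µm spacing: the analytic
        # truth is 4/3·π·0.05³ ≈ 5.24e-4 mm³ and the voxelization must
        # land within discretization tolerance of it
        cfg = bq.PhantomConfig(
            grid_shape=(30, 30, 30),
            spacing_um=(10, 10, 10),
            n_metastases=1,
            n_tls=0,
            met_volume_lognormal=(4 / 3 * math.pi * 0.05**3, 0.0),
            seed=4,
        )
        _, annotation, _, truth = bq.generate_object_phantom(cfg)
        obj = truth.objects[0]
        analytic = 4 / 3 * math.pi * 0.05**3
        assert obj.true_volume_mm3 == pytest.approx(analytic, rel=1e-9)
        vox = int((annotation[CLASS_METASTASIS].data > 0).sum())
        vox_mm3 = vox * 1000 / 1e9
        assert vox_mm3 == pytest.approx(analytic, rel=0.15)

    def test_component_count_recovery(self):
        cfg = small_config()
        _, annotation, _, truth = bq.generate_object_phantom(cfg)
        for cls, expected in ((CLASS_METASTASIS, 6), (CLASS_TLS, 10)):
            binary = bq.LabelVolume(
                (annotation[cls].data > 0).astype(np.uint8), cfg.spacing_um
            )
            _, n = bq.label_components(binary, connectivity=26)
            assert n == expected

    def test_region_priors_recovered(self):
        cfg = bq.PhantomConfig(
            grid_shape=(60, 100, 100),
            n_metastases=400,
            n_tls=0,
            met_volume_lognormal=(5e-6, 0.2),
            coupling_scale_um=None,
            seed=9,
        )
        _, _, _, truth = bq.generate_object_phantom(cfg)
        frac = sum(1 for o in truth.objects if o.region == "lung") / 400
        lo = binom.ppf(0.005, 400, 0.62) / 400
        hi = binom.ppf(0.995, 400, 0.62) / 400
        assert lo <= frac <= hi

    def test_coupled_tls_closer_than_uncoupled(self):
        wins = 0
        for seed in range(8):
            med_c = self._median_tls_met_distance(seed, coupling=50.0)
            med_u = self._median_tls_met_distance(seed, coupling=None)
            wins += med_c < med_u
        assert wins >= 7

    @staticmethod
    def _median_tls_met_distance(seed, coupling):
        cfg = small_config(
            grid_shape=(60, 92, 92),
            n_metastases=15,
            n_tls=25,
            seed=seed,
            coupling_scale_um=coupling,
        )
        truth = bq.generate_object_phantom(cfg)[3]
        met = bq.objects_from_truth(truth, CLASS_METASTASIS)
        tls = bq.objects_from_truth(truth, CLASS_TLS)
        tab = bq.nn_distances(tls, met)
        return tab["distance_um"].median()

    def test_overcrowded_raises_named_error(self):
        cfg = bq.PhantomConfig(
            grid_shape=(10, 10, 10),
            spacing_um=(10, 10, 10),
            n_metastases=50,
            n_tls=0,
            met_volume_lognormal=(1e-4, 0.1),
            seed=0,
        )
        with pytest.raises(bq.OvercrowdedError, match="metastasis"):
            bq.generate_object_phantom(cfg, max_tries_per_object=20)

    def test_bad_region_priors_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            bq.PhantomConfig(
                region_priors={"metastasis": {"lung": 0.5, "gut": 0.4}}
            ).validate()

    def test_priors_referencing_missing_region_rejected(self):
        cfg = small_config()
        regions = bq.LabelVolume(
            np.ones(cfg.grid_shape, dtype=np.int32),
            cfg.spacing_um,
            label_names={1: "body"},
        )
        with pytest.raises(ValueError, match="absent"):
            bq.generate_object_phantom(cfg, regions=regions)


class TestFilamentPhantom:
    def test_single_edge_truth_length(self):
        # grid sized so exactly two lattice nodes fit along x: one edge
        cfg = bq.PhantomConfig(
            grid_shape=(10, 12, 85), spacing_um=(10, 10, 10), seed=0
        )
        mask, truth = bq.generate_filament_phantom(
            cfg, lattice_pitch_um=400, dropout_fraction=0.0, tube_radius_um=15
        )
        assert len(truth.filaments) == 1
        assert truth.total_length_um == pytest.approx(400.0, abs=1e-9)
        assert mask.data.any()

    def test_truth_length_equals_polyline_sum(self):
        cfg = bq.PhantomConfig(grid_shape=(30, 60, 60), seed=3)
        _, truth = bq.generate_filament_phantom(cfg, 80.0, 0.2)
        total = sum(
            float(np.linalg.norm(p[1] - p[0])) for p in truth.filaments
        )
        assert truth.total_length_um == pytest.approx(total, abs=1e-6)

    def test_dropout_zero_is_full_lattice(self):
        cfg = bq.PhantomConfig(grid_shape=(30, 60, 60), seed=5)
        _, t0 = bq.generate_filament_phantom(cfg, 80.0, 0.0)
        for seed in (1, 2, 3):
            cfg2 = bq.PhantomConfig(grid_shape=(30, 60, 60), seed=seed)
            _, t1 = bq.generate_filament_phantom(cfg2, 80.0, 0.0)
            assert t1.total_length_um == t0.total_length_um

    def test_dropout_monotone_per_seed(self):
        for seed in range(5):
            cfg = bq.PhantomConfig(grid_shape=(30, 60, 60), seed=seed)
            _, t0 = bq.generate_filament_phantom(cfg, 80.0, 0.0)
            _, t6 = bq.generate_filament_phantom(cfg, 80.0, 0.6)
            assert t6.total_length_um < t0.total_length_um

    def test_dropout_expectation_over_seeds(self):
        cfg0 = bq.PhantomConfig(grid_shape=(20, 40, 40), seed=0)
        _, full = bq.generate_filament_phantom(cfg0, 80.0, 0.0)
        retained = []
        for seed in range(50):
            cfg = bq.PhantomConfig(grid_shape=(20, 40, 40), seed=seed)
            _, t = bq.generate_filament_phantom(cfg, 80.0, 0.5)
            retained.append(t.total_length_um / full.total_length_um)
        # mean retained fraction within a generous binomial-style band
        assert abs(np.mean(retained) - 0.5) < 0.05

    def test_unresolvable_pitch_rejected(self):
        cfg = bq.PhantomConfig(grid_shape=(20, 40, 40))
        with pytest.raises(ValueError, match="unresolvable"):
            bq.generate_filament_phantom(cfg, lattice_pitch_um=15.0)


class TestImagingModel:
    def test_identity_when_disabled(self, rng):
        cfg = small_config(noise_sd=0.0, attenuation_per_um=0.0)
        clean = bq.VolumeGrid(rng.random((10, 8, 8)) * 50, cfg.spacing_um)
        out = bq.apply_imaging_model(clean, cfg)
        assert np.array_equal(out.data, clean.data)

    def test_uniform_input_attenuates_exactly(self):
        lam = 0.002
        cfg = small_config(noise_sd=0.0, attenuation_per_um=lam)
        clean = bq.VolumeGrid(np.full((12, 6, 6), 40.0), cfg.spacing_um)
        out = bq.apply_imaging_model(clean, cfg, axis="z", entry="low")
        depths = (np.arange(12) + 0.5) * cfg.spacing_um[0]
        means = out.data.mean(axis=(1, 2))
        assert np.allclose(means, 40.0 * np.exp(-lam * depths), atol=1e-9)

    def test_noise_seed_contract(self, rng):
        clean = bq.VolumeGrid(rng.random((8, 6, 6)) * 50, (10, 6.5, 6.5))
        a = bq.apply_imaging_model(clean, small_config(noise_sd=1.0, seed=1))
        b = bq.apply_imaging_model(clean, small_config(noise_sd=1.0, seed=1))
        c = bq.apply_imaging_model(clean, small_config(noise_sd=1.0, seed=2))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        assert a.data.min() >= 0.0
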