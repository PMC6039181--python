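"""Background characterization, Z-maps, event maps, BDC and two-pass analysis."""

import numpy as np
import pytest
from scipy import stats

import ensemblemap as em
from ensemblemap.datasets import DatasetCohort, DatasetRecord
from ensemblemap.errors import (
    DegenerateCohortError,
    GridMismatchError,
    InsufficientDataError,
    NoEventError,
    ValidationError,
)


def _record(values, ds_id="d0"):
    return DatasetRecord(ds_id, em.DensityMap(np.asarray(values, dtype=float)))


def _cohort(arrays):
    return DatasetCohort(records=[_record(a, f"d{i}") for i, a in enumerate(arrays)])


class TestCharacterizeBackground:
    def test_identical_maps_have_zero_sd(self):
        arr = np.random.default_rng(0).normal(size=(4, 4, 4))
        bg = em.characterize_background(_cohort([arr, arr, arr]))
        assert np.allclose(bg.mean_map.values, arr)
        assert np.allclose(bg.sd_map.values, 0.0)

    def test_two_maps_population_convention(self):
        a, b = np.full((2, 2, 2), 1.0), np.full((2, 2, 2), 3.0)
        bg = em.characterize_background(_cohort([a, b]))
        assert np.allclose(bg.mean_map.values, 2.0)
        # population (1/n) sd of {a, b} is |a - b| / 2
        assert np.allclose(bg.sd_map.values, 1.0)

    def test_mean_map_close_to_truth_under_noise(self):
        cohort = em.simulate_soak_cohort(
            50, 0.0, (0.1, 0.3), em.SimulationConfig(seed=13, noise_sd=0.1))
        bg = em.characterize_background(cohort)
        err = np.abs(bg.mean_map.values - cohort.reference_maps["ground"].values)
        assert np.mean(err < 0.05) >= 0.99

    def test_single_dataset_rejected(self):
        with pytest.raises(InsufficientDataError):
            em.characterize_background(_cohort([np.zeros((2, 2, 2))]))

    def test_grid_mismatch_rejected(self):
        rec_a = _record(np.zeros((2, 2, 2)))
        rec_b = DatasetRecord("d1", em.DensityMap(np.zeros((3, 3, 3))))
        with pytest.raises(GridMismatchError):
            em.characterize_background(DatasetCohort(records=[rec_a, rec_b]))


class TestZMap:
    def test_zero_for_map_equal_to_mean(self):
        arr = np.random.default_rng(1).normal(size=(3, 3, 3))
        bg = em.characterize_background(_cohort([arr + 0.3, arr - 0.3]))
        z = em.z_map(_record(arr), bg)
        assert np.allclose(z.values, 0.0)

    def test_two_sigma_deviation_scores_two(self):
        mu = np.zeros((2, 2, 2))
        bg = em.characterize_background(_cohort([mu - 0.5, mu + 0.5]))  # sd = 0.5
        z = em.z_map(_record(mu + 1.0), bg)
        assert np.allclose(z.values, 2.0)

    def test_floor_caps_small_sd(self):
        mu = np.zeros((2, 2, 2))
        bg = em.characterize_background(_cohort([mu, mu]))  # sd = 0
        z = em.z_map(_record(mu + 0.1), bg, sd_floor=0.05)
        assert np.allclose(z.values, 2.0)

    def test_peak_z_near_planted_ligand(self, noisy_cohort):
        truth = noisy_cohort.ground_truth["binders"]
        bg = em.characterize_background(noisy_cohort, excluded_ids=tuple(truth))
        ds_id, info = next(iter(truth.items()))
        z = em.z_map(noisy_cohort.get(ds_id), bg)
        peak = z.index_to_position(np.unravel_index(np.argmax(z.values), z.shape))
        assert np.linalg.norm(peak - info["centroid"]) <= 2.0

    def test_pure_noise_z_values_standard_normal(self):
        # cohort of pure ground + noise; a held-out noise map scores ~N(0,1)
        cohort = em.simulate_soak_cohort(
            80, 0.0, (0.1, 0.3), em.SimulationConfig(seed=21, noise_sd=0.1))
        bg = em.characterize_background(cohort)
        rng = np.random.default_rng(99)
        ground = cohort.reference_maps["ground"]
        held_out = DatasetRecord(
            "held", ground.with_values(ground.values + rng.normal(0, 0.1, ground.shape)))
        z = em.z_map(held_out, bg, sd_floor=0.0).values.ravel()
        sample = rng.choice(z, size=5000, replace=False)
        assert stats.kstest(sample, "norm").pvalue > 0.01


class TestEventMap:
    def test_bdc_zero_is_identity(self, rng):
        arr = rng.normal(size=(3, 3, 3))
        bg = em.characterize_background(_cohort([arr + 1, arr - 1]))
        ev = em.compute_event_map(_record(arr), bg, bdc=0.0)
        assert np.allclose(ev.values, arr)

    def test_defining_formula_arithmetic(self):
        mu = np.full((2, 2, 2), 0.2)
        bg = em.characterize_background(_cohort([mu, mu]))
        ev = em.compute_event_map(_record(np.full((2, 2, 2), 0.5)), bg, bdc=0.85)
        assert np.allclose(ev.values, 2.2)

    def test_noise_free_mixture_recovers_bound_map(self, noise_free_cohort):
        cohort = noise_free_cohort
        ground = cohort.reference_maps["ground"]
        bound = cohort.reference_maps["bound"]
        bg = em.characterize_background(
            cohort, excluded_ids=tuple(cohort.ground_truth["binders"]))
        for f in np.arange(0.05, 0.51, 0.05):
            rec = _record((1 - f) * ground.values + f * bound.values)
            rec.map.origin, rec.map.spacing = ground.origin, ground.spacing
            ev = em.compute_event_map(rec, bg, bdc=1 - f)
            rms = np.sqrt(np.mean((ev.values - bound.values) ** 2))
            assert rms <= 1e-9

    def test_invalid_bdc_rejected(self, rng):
        arr = rng.normal(size=(2, 2, 2))
        bg = em.characterize_background(_cohort([arr, arr + 1]))
        with pytest.raises(ValidationError):
            em.compute_event_map(_record(arr), bg, bdc=1.0)


@pytest.fixture(scope="module")
def bdc_setup(noise_free_cohort):
    cohort = noise_free_cohort
    bg = em.characterize_background(
        cohort, excluded_ids=tuple(cohort.ground_truth["binders"]))
    ground = cohort.reference_maps["ground"]
    bound = cohort.reference_maps["bound"]
    region = ground.voxel_centers_mask_within(
        cohort.ground_truth["ligand_centroid"], 4.0)
    return bg, ground, bound, region


class TestEstimateBdc:

    @pytest.mark.parametrize("f", [0.10, 0.30])
    def test_noise_free_mixture_recovery(self, bdc_setup, f):
        bg, ground, bound, region = bdc_setup
        rec = DatasetRecord(
            "mix", ground.with_values((1 - f) * ground.values + f * bound.values))
        bdc = em.estimate_bdc(rec, bg, region, grid_step=0.01)
        assert bdc == pytest.approx(1 - f, abs=0.01 + 1e-9)

    def test_background_record_raises_no_event(self, bdc_setup):
        bg, ground, _, region = bdc_setup
        with pytest.raises(NoEventError):
            em.estimate_bdc(DatasetRecord("bgd", ground.copy()), bg, region)

    def test_empty_region_rejected(self, bdc_setup):
        bg, ground, bound, _ = bdc_setup
        rec = DatasetRecord(
            "mix", ground.with_values(0.7 * ground.values + 0.3 * bound.values))
        with pytest.raises(ValidationError):
            em.estimate_bdc(rec, bg, np.zeros(ground.shape, dtype=bool))

    def test_step_out_of_range_rejected(self, bdc_setup):
        bg, ground, bound, region = bdc_setup
        rec = DatasetRecord(
            "mix", ground.with_values(0.7 * ground.values + 0.3 * bound.values))
        with pytest.raises(ValidationError):
            em.estimate_bdc(rec, bg, region, grid_step=0.2)


class TestDetectEvents:
    def _zmap(self, values):
        return em.DensityMap(np.asarray(values, dtype=float))

    def test_zero_map_yields_no_events(self):
        assert em.detect_events(self._zmap(np.zeros((8, 8, 8)))) == []

    def test_single_blob_detected_with_centroid(self):
        vals = np.zeros((16, 16, 16))
        center = np.array([8, 8, 8])
        for idx in np.ndindex(7, 7, 7):
            pos = np.array(idx) + center - 3
            r2 = np.sum((pos - center) ** 2)
            vals[tuple(pos)] = 6.0 * np.exp(-r2 / 6.0)
        z = self._zmap(vals)
        events = em.detect_events(z, z_threshold=2.5, min_cluster_voxels=10)
        assert len(events) == 1
        assert events[0].peak_z == pytest.approx(6.0)
        assert np.linalg.norm(events[0].centroid - z.index_to_position(center)) <= 0.5

    def test_two_separated_blobs_ordered_by_peak(self):
        vals = np.zeros((24, 8, 8))
        vals[2:5, 2:5, 2:5] = 4.0
        vals[18:21, 2:5, 2:5] = 7.0
        events = em.detect_events(self._zmap(vals), z_threshold=2.5, min_cluster_voxels=8)
        assert len(events) == 2
        assert events[0].peak_z == pytest.approx(7.0)
        assert events[1].peak_z == pytest.approx(4.0)

    def test_small_clusters_filtered(self):
        vals = np.zeros((8, 8, 8))
        vals[4, 4, 4] = 10.0
        assert em.detect_events(self._zmap(vals), min_cluster_voxels=27) == []


class TestTwoPass:
    def test_no_binders_passes_are_identical(self):
        cohort = em.simulate_soak_cohort(
            6, 0.0, (0.1, 0.3), em.SimulationConfig(seed=31, noise_sd=0.05))
        bg1 = em.characterize_background(cohort)
        bg2, events = em.run_two_pass_analysis(cohort)
        assert events == {}
        assert bg2.excluded_ids == ()
        assert np.allclose(bg1.mean_map.values, bg2.mean_map.values)

    def test_recovers_planted_binders(self, noisy_cohort):
        truth = noisy_cohort.ground_truth["binders"]
        bg2, events = em.run_two_pass_analysis(noisy_cohort)
        assert set(events) == set(truth)
        for ds_id, evs in events.items():
            best = evs[0]
            assert abs(best.event_occupancy - truth[ds_id]["occupancy"]) <= 0.05
            assert np.linalg.norm(best.centroid - truth[ds_id]["centroid"]) <= 2.0

    def test_event_occupancy_complements_bdc(self, noisy_cohort):
        _, events = em.run_two_pass_analysis(noisy_cohort)
        for evs in events.values():
            for ev in evs:
                assert ev.event_occupancy == pytest.approx(1.0 - ev.bdc)

    def test_pass_two_background_closer_to_truth(self, noisy_cohort):
        ground = noisy_cohort.reference_maps["ground"].values
        bg1 = em.characterize_background(noisy_cohort)
        bg2, _ = em.run_two_pass_analysis(noisy_cohort)
        rms1 = np.sqrt(np.mean((bg1.mean_map.values - ground) ** 2))
        rms2 = np.sqrt(np.mean((bg2.mean_map.values - ground) ** 2))
        assert rms2 < rms1

    def test_all_event_cohort_rejected(self):
        # each dataset carries its own private blob, so every dataset is an
        # outlier against the cohort and pass 1 flags them all
        records = []
        for i in range(10):
            vals = np.zeros((32, 12, 12))
            vals[3 * i:3 * i + 3, 4:7, 4:7] = 10.0
            records.append(_record(vals, f"d{i}"))
        with pytest.raises((DegenerateCohortError, InsufficientDataError)):
            em.run_two_pass_analysis(DatasetCohort(records=records))
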