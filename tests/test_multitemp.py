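"""Occupancy fitting, minor-state density statistics and profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

import ensemblemap as em
from ensemblemap.errors import (
    DegenerateFitError,
    UndefinedScoreError,
    ValidationError,
)


@pytest.fixture(scope="module")
def conformers():
    model = em.make_two_state_model(4, 3.0, 0.5, seed=17)
    conf_a = [a.copy(occupancy=1.0) for a in model.atoms_with_altloc("A")]
    conf_b = [a.copy(occupancy=1.0) for a in model.atoms_with_altloc("B")]
    return conf_a, conf_b


def _mixture_map(conf_a, conf_b, occ, cfg):
    all_atoms = conf_a + conf_b
    origin, shape = em.simulate.auto_box(all_atoms, cfg.grid_spacing)
    map_a = em.render_density(em.MulticonformerModel(atoms=conf_a), cfg, origin, shape)
    map_b = em.render_density(em.MulticonformerModel(atoms=conf_b), cfg, origin, shape)
    return map_a.with_values(occ * map_a.values + (1 - occ) * map_b.values)


class TestTwoStateFit:
    def test_noise_free_mixture_recovered(self, conformers):
        conf_a, conf_b = conformers
        cfg = em.SimulationConfig(seed=0)
        m = _mixture_map(conf_a, conf_b, 0.65, cfg)
        fit = em.fit_two_state_occupancy(m, conf_a, conf_b, cfg)
        assert fit.occ_state_a == pytest.approx(0.65, abs=1e-6)
        assert fit.occ_state_a + fit.occ_state_b == pytest.approx(1.0, abs=1e-9)
        assert fit.mode == "two-conformer"

    def test_pure_state_a_gives_unity(self, conformers):
        conf_a, conf_b = conformers
        cfg = em.SimulationConfig(seed=0)
        m = _mixture_map(conf_a, conf_b, 1.0, cfg)
        fit = em.fit_two_state_occupancy(m, conf_a, conf_b, cfg)
        assert fit.occ_state_a == pytest.approx(1.0, abs=1e-6)

    def test_identical_conformers_rejected(self, conformers):
        conf_a, _ = conformers
        cfg = em.SimulationConfig(seed=0)
        m = _mixture_map(conf_a, conf_a, 0.5, cfg)
        with pytest.raises(DegenerateFitError):
            em.fit_two_state_occupancy(m, conf_a, list(conf_a), cfg)

    def test_recovery_across_occupancy_range(self, conformers):
        # |fitted - true| <= 0.03 for true in {0.1..0.9} at 0.05-sigma noise
        conf_a, conf_b = conformers
        cfg = em.SimulationConfig(seed=0)
        rng = np.random.default_rng(42)
        for true_occ in np.arange(0.1, 0.91, 0.1):
            m = _mixture_map(conf_a, conf_b, true_occ, cfg)
            noisy = m.with_values(
                m.values + rng.normal(0, 0.05 * m.values.std(), m.shape))
            fit = em.fit_two_state_occupancy(noisy, conf_a, conf_b, cfg)
            assert abs(fit.occ_state_a - true_occ) <= 0.03

    def test_temperature_ladder_recovery_monotone(self, temperature_series):
        cfg = em.SimulationConfig(seed=7, noise_sd=0.05)
        truth = temperature_series.ground_truth["occupancy_by_T"]
        conf_a = temperature_series.ground_truth["conf_a"]
        conf_b = temperature_series.ground_truth["conf_b"]
        fitted = []
        for rec in temperature_series.records:
            fit = em.fit_two_state_occupancy(rec.map, conf_a, conf_b, cfg)
            assert abs(fit.occ_state_a - truth[rec.temperature_K]) <= 0.03
            fitted.append(fit.occ_state_a)
        assert all(a < b for a, b in zip(fitted, fitted[1:]))


class TestOccupancyVsDisorder:
    def test_partial_occupancy_recovered(self, conformers):
        conf_a, _ = conformers
        cfg = em.SimulationConfig(seed=0)
        full = _mixture_map(conf_a, conf_a, 1.0, cfg)
        partial = full.with_values(0.4 * full.values)
        fit = em.fit_occupancy_vs_disorder(partial, conf_a, cfg)
        assert fit.occ_state_a == pytest.approx(0.4, abs=1e-6)
        assert fit.mode == "conformer-vs-disorder"

    def test_zero_map_gives_zero_occupancy(self, conformers):
        conf_a, _ = conformers
        cfg = em.SimulationConfig(seed=0)
        full = _mixture_map(conf_a, conf_a, 1.0, cfg)
        fit = em.fit_occupancy_vs_disorder(full.with_values(0 * full.values), conf_a, cfg)
        assert fit.occ_state_a == 0.0

    def test_decreasing_order_across_ladder(self, conformers):
        # helix melting: occupancy falls as temperature rises
        conf_a, _ = conformers
        cfg = em.SimulationConfig(seed=0)
        full = _mixture_map(conf_a, conf_a, 1.0, cfg)
        rng = np.random.default_rng(3)
        fits = []
        for occ in [0.9, 0.7, 0.5, 0.3]:
            noisy = full.with_values(
                occ * full.values + rng.normal(0, 0.02 * full.values.std(), full.shape))
            fits.append(em.fit_occupancy_vs_disorder(noisy, conf_a, cfg).occ_state_a)
        assert all(a > b for a, b in zip(fits, fits[1:]))


class TestUniqueMinorAtoms:
    def _atoms(self, coords):
        return [em.Atom(f"A{i}", "CA", "C", np.asarray(c, dtype=float))
                for i, c in enumerate(coords)]

    def test_identical_states_have_no_unique_atoms(self):
        a = self._atoms([[0, 0, 0], [1, 1, 1]])
        assert em.unique_minor_atoms(a, self._atoms([[0, 0, 0], [1, 1, 1]])) == []

    def test_displacement_threshold(self):
        major = self._atoms([[0, 0, 0], [3, 0, 0]])
        minor = self._atoms([[1.5, 0, 0], [3.0, 0.8, 0]])
        # first minor atom is 1.5 A from both major atoms -> unique;
        # second is 0.8 A from a major atom -> excluded
        uniq = em.unique_minor_atoms(major, minor)
        assert [a.residue_id for a in uniq] == ["A0"]

    def test_boundary_distance_included(self):
        major = self._atoms([[0, 0, 0]])
        minor = self._atoms([[1.0, 0, 0]])
        assert len(em.unique_minor_atoms(major, minor, cutoff=1.0)) == 1

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        major = self._atoms(rng.uniform(0, 5, (6, 3)))
        minor = self._atoms(rng.uniform(0, 5, (5, 3)))
        got = {a.residue_id for a in em.unique_minor_atoms(major, minor, 1.0)}
        d = cdist(np.stack([a.position for a in minor]),
                  np.stack([a.position for a in major]))
        expected = {minor[i].residue_id for i in range(5) if d[i].min() >= 1.0}
        assert got == expected


class TestDensityScore:
    def test_sum_over_atom_centers(self, small_map):
        atoms = [em.Atom("A1", "CA", "C", small_map.index_to_position((i, i, i)))
                 for i in range(3)]
        expected = sum(small_map.values[i, i, i] for i in range(3))
        assert em.minor_state_density_score(small_map, atoms) == pytest.approx(expected)

    def test_empty_set_is_an_error_not_zero(self, small_map):
        with pytest.raises(UndefinedScoreError):
            em.minor_state_density_score(small_map, [])

    def test_linear_ramp_closed_form(self, rng):
        ax = np.arange(8) * 1.0
        field = ax[:, None, None] + 0 * ax[None, :, None] + 0 * ax[None, None, :]
        m = em.DensityMap(field, spacing=np.ones(3))
        pts = rng.uniform(0.5, 6.5, (10, 3))
        atoms = [em.Atom(f"A{i}", "CA", "C", p) for i, p in enumerate(pts)]
        assert em.minor_state_density_score(m, atoms) == pytest.approx(pts[:, 0].sum())


class TestNormalizeProfile:
    def test_worked_example(self):
        norm, degenerate = em.normalize_profile([2, 4, 6, 10])
        assert np.allclose(norm, [0, 0.25, 0.5, 1.0])
        assert not degenerate

    def test_constant_scores_flagged(self):
        norm, degenerate = em.normalize_profile([3.3, 3.3, 3.3])
        assert np.allclose(norm, 0.0)
        assert degenerate

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=10, unique=True))
    def test_output_spans_unit_interval(self, scores):
        norm, degenerate = em.normalize_profile(scores)
        assert not degenerate
        assert norm.min() == 0.0 and norm.max() == 1.0

    def test_single_temperature_rejected(self):
        with pytest.raises(ValidationError):
            em.normalize_profile([1.0])


class TestProfiles:
    def test_rising_minor_state_gives_monotone_profile(self, temperature_series):
        truth = temperature_series.ground_truth
        pairs = {}
        for rid in ["A1", "A2"]:
            major = [a for a in truth["conf_b"] if a.residue_id == rid]
            minor = [a for a in truth["conf_a"] if a.residue_id == rid]
            pairs[rid] = (major, minor)
        profiles = em.residue_temperature_profiles(temperature_series, pairs)
        for prof in profiles.values():
            assert len(prof.scores_normalized) == 4
            assert not prof.degenerate
            diffs = np.diff(prof.scores_normalized)
            assert np.all(diffs >= -0.05)  # monotone up to noise tolerance

    def test_constant_occupancy_flags_degenerate(self):
        cfg = em.SimulationConfig(seed=19, noise_sd=0.0)
        series = em.simulate_temperature_series(
            {100.0: 0.5, 180.0: 0.5, 240.0: 0.5, 278.0: 0.5}, cfg)
        truth = series.ground_truth
        rid = "A1"
        pairs = {rid: ([a for a in truth["conf_b"] if a.residue_id == rid],
                       [a for a in truth["conf_a"] if a.residue_id == rid])}
        prof = em.residue_temperature_profiles(series, pairs)[rid]
        assert prof.degenerate or np.ptp(prof.scores_raw) < 1e-9


class TestBimodality:
    def test_edge_dominated_panel(self):
        frac, verdict = em.occupancy_bimodality([0.02, 0.97, 1.0, 0.05])
        assert frac == 1.0 and verdict == "single-state-panel"

    def test_central_panel_is_mixed(self):
        frac, verdict = em.occupancy_bimodality([0.5, 0.5, 0.5])
        assert frac == 0.0 and verdict == "mixed"

    def test_simulated_inhibitor_panel(self, rng):
        # 36 re-refined occupancies drawn near 0 and 1
        occ = np.concatenate([
            np.clip(rng.normal(0.03, 0.02, 18), 0, 1),
            np.clip(rng.normal(0.96, 0.02, 18), 0, 1),
        ])
        _, verdict = em.occupancy_bimodality(occ)
        assert verdict == "single-state-panel"

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            em.occupancy_bimodality([])
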