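import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spindlesim as ss
from spindlesim import forces
from spindlesim.state import initialize_state


class TestPolarEjection:
    def test_maximal_at_pole(self):
        assert forces.polar_ejection_force(0.0, 4.0, 5.0) == pytest.approx(4.0)

    def test_one_decay_length(self):
        assert forces.polar_ejection_force(5.0, 1.0, 5.0) == pytest.approx(
            0.36788, abs=1e-5)

    def test_strictly_decreasing(self):
        xs = np.linspace(0, 20, 50)
        vals = [forces.polar_ejection_force(x, 4.0, 5.0) for x in xs]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            forces.polar_ejection_force(-0.1, 4.0, 5.0)


class TestKmtKtSpring:
    def test_zero_at_rest_length(self):
        f, load = forces.kmt_kt_spring_force([1.1, 0, 0], [1.0, 0, 0],
                                             K_kmt_kt=20.0, l_kmt_kt=0.1)
        assert load == pytest.approx(0.0)
        assert np.allclose(f, 0.0)

    def test_linear_spring_magnitude(self):
        f, load = forces.kmt_kt_spring_force([0.6, 0, 0], [0.0, 0, 0],
                                             K_kmt_kt=1.0, l_kmt_kt=0.1)
        assert load == pytest.approx(0.5)
        # stretched: pulls the KT toward the tip (+x)
        assert f[0] == pytest.approx(0.5)

    def test_compression_pushes(self):
        f, load = forces.kmt_kt_spring_force([0.05, 0, 0], [0.0, 0, 0],
                                             K_kmt_kt=20.0, l_kmt_kt=0.1)
        assert load < 0 and f[0] < 0

    def test_symmetric_opposing_springs_cancel(self):
        kt = np.zeros(3)
        f1, _ = forces.kmt_kt_spring_force([1.0, 0, 0], kt, 5.0, 0.1)
        f2, _ = forces.kmt_kt_spring_force([-1.0, 0, 0], kt, 5.0, 0.1)
        assert np.allclose(f1 + f2, 0.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            forces.kmt_kt_spring_force([0, 0, 0], [0, 0, 0], 5.0, 0.1)


class TestCohesion:
    def test_zero_at_rest_length(self):
        f1, f2 = forces.cohesion_force([0, 0, 0], [1, 0, 0], 40.0, 1.0)
        assert np.allclose(f1, 0) and np.allclose(f2, 0)

    def test_restoring_magnitude(self):
        f1, f2 = forces.cohesion_force([0, 0, 0], [1.1, 0, 0], 2.0, 1.0)
        assert f1[0] == pytest.approx(0.2)      # pulled toward sister
        assert np.allclose(f1, -f2)             # Newton's third law

    def test_compression_separates(self):
        f1, f2 = forces.cohesion_force([0, 0, 0], [0.5, 0, 0], 40.0, 1.0)
        assert f1[0] < 0 and f2[0] > 0


class TestStericRepulsion:
    def test_pairwise_inverse_square(self):
        f = forces.interchromosome_repulsion([[0, 0, 0], [1, 0, 0]], 1.0)
        assert f[0, 0] == pytest.approx(-1.0)
        assert f[1, 0] == pytest.approx(1.0)

    def test_doubling_distance_quarters_force(self):
        f1 = forces.interchromosome_repulsion([[0, 0, 0], [1, 0, 0]], 1.0)
        f2 = forces.interchromosome_repulsion([[0, 0, 0], [2, 0, 0]], 1.0)
        assert f1[1, 0] == pytest.approx(4 * f2[1, 0])

    @given(st.integers(min_value=2, max_value=12), st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_zero_total_momentum_input(self, n, seed):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-5, 5, size=(n, 3))
        f = forces.interchromosome_repulsion(centers, 10.0)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)


class TestBoundaryRepulsion:
    def test_maximal_at_wall(self):
        assert forces.boundary_repulsion(0.0, 20.0, 5.0) == pytest.approx(20.0)

    def test_one_decay_length(self):
        assert forces.boundary_repulsion(5.0, 1.0, 5.0) == pytest.approx(
            0.36788, abs=1e-5)

    def test_outside_cell_rejected(self):
        with pytest.raises(ValueError):
            forces.boundary_repulsion(-0.5, 20.0, 5.0)


class TestAssembleForces:
    def test_centered_unattached_pair_feels_only_symmetric_terms(self):
        # a single pair at the exact midpoint: the two ejection terms cancel
        # along x, steric is absent, boundary is radial (here ~0 at centre)
        p = ss.preset("control").replace(n_ch=1, n_mt_per_pole=4)
        state = initialize_state(p, seed=0)
        state.ctr[:] = 0.0
        state.axis[:] = np.array([0.0, 0.0, 1.0])
        state.sep[:] = p.l_cohesion
        fa = forces.assemble_forces(state)
        assert fa.body[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fa.kt, 0.0, atol=1e-12)

    def test_kernel_steric_matches_vectorized_resummation(self):
        # the engine's O(n^2) loop vs the independent vectorised summation
        p = ss.preset("control").replace(
            n_ch=15, n_mt_per_pole=4, A_pe=1e-12, A_boundary=1e-12)
        state = initialize_state(p, seed=8)
        fa = forces.assemble_forces(state)
        expected = forces.interchromosome_repulsion(state.ctr, p.A_ch_ch)
        assert np.allclose(fa.body, expected, atol=1e-9)

    def test_all_forces_finite_on_random_evolved_state(self, small_params):
        state = initialize_state(small_params, seed=7)
        from spindlesim.engine import step
        for _ in range(100):
            step(state)
        fa = forces.assemble_forces(state)
        for arr in (fa.body, fa.kt, fa.kmt, fa.mt_load):
            assert np.isfinite(arr).all()

    def test_evaluation_is_side_effect_free(self, small_params):
        state = initialize_state(small_params, seed=3)
        before = (state.ctr.copy(), state.axis.copy(), state.sep.copy(),
                  state.mt_len.copy())
        forces.assemble_forces(state)
        after = (state.ctr, state.axis, state.sep, state.mt_len)
        for a, b in zip(before, after):
            assert np.array_equal(a, b)

    def test_removing_one_attached_mt_changes_only_that_spring_term(self):
        # brute-force re-summation oracle: difference of the two assemblies
        # equals the removed spring's bounded force
        from spindlesim.engine import step
        from spindlesim.mt import search_and_capture
        p = ss.preset("control").replace(n_ch=2, n_mt_per_pole=50)
        state = initialize_state(p, seed=5)
        # aim one MT straight at a KT and capture it deterministically
        kt0 = state.kt_positions()[1]
        pole = state.centrosomes[0]
        state.mt_dir[0] = (kt0 - pole) / np.linalg.norm(kt0 - pole)
        state.mt_len[0] = np.linalg.norm(kt0 - pole)
        assert search_and_capture(state) >= 1
        for _ in range(40):   # let the geometry evolve under load
            step(state)
        att = np.flatnonzero(state.mt_att >= 0)
        m = att[0]
        k = state.mt_att[m]
        full = forces.assemble_forces(state)
        state.mt_att[m] = -1
        state.reclassify()
        reduced = forces.assemble_forces(state)
        diff = full.kt[k] - reduced.kt[k]
        pole = state.centrosomes[state.mt_pole[m]]
        ktpos = state.kt_positions()[k]
        d = np.linalg.norm(ktpos - pole)
        f = max(p.K_kmt_kt * (d - state.mt_len[m] - p.l_kmt_kt), -p.f_push)
        expected = -f * (ktpos - pole) / d
        assert np.allclose(diff, expected, atol=1e-9)
        others = np.ones(2 * p.n_ch, dtype=bool)
        others[k] = False
        assert np.allclose(full.kt[others], reduced.kt[others])
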