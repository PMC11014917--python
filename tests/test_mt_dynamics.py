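import numpy as np
import pytest

import spindlesim as ss
from spindlesim import mt
from spindlesim._kernels import seed_rng
from spindlesim.engine import step
from spindlesim.state import AttachmentClass, initialize_state


class TestLoadedRates:
    def test_rescue_probability_zero_at_zero_load(self):
        assert mt.loaded_rescue_probability(0.0, 5.0) == pytest.approx(0.0)

    def test_rescue_probability_at_stall_force(self):
        assert mt.loaded_rescue_probability(5.0, 5.0) == pytest.approx(
            0.63212, abs=1e-5)

    def test_rescue_probability_monotone_and_bounded(self):
        fs = np.linspace(0, 100, 40)
        ps = [mt.loaded_rescue_probability(f, 5.0) for f in fs]
        assert all(b >= a for a, b in zip(ps, ps[1:]))
        assert all(0 <= p < 1 for p in ps)
        assert mt.loaded_rescue_probability(1e3, 5.0) == pytest.approx(1.0)

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError):
            mt.loaded_rescue_probability(-1.0, 5.0)

    def test_catastrophe_rate_proportional_to_length(self):
        assert mt.loaded_catastrophe_rate(0.0, 0.01) == 0.0
        assert mt.loaded_catastrophe_rate(10.0, 0.01) == pytest.approx(0.1)
        assert mt.loaded_catastrophe_rate(8.0, 0.05) == pytest.approx(
            2 * mt.loaded_catastrophe_rate(4.0, 0.05))


class TestLengthStepping:
    def test_growth_arithmetic(self, small_params):
        p = small_params.replace(f_c=0.0, f_r=0.0)
        state = initialize_state(p, seed=1)
        state.mt_len[:] = 1.0
        mt.step_mt_lengths_and_switching(state)
        assert np.allclose(state.mt_len, 1.0 + p.v_g * p.dt)

    def test_shrinking_clips_at_zero_and_renucleates(self, small_params):
        p = small_params.replace(f_c=0.0, f_r=0.0)
        state = initialize_state(p, seed=2)
        state.mt_len[:] = 0.01
        state.mt_grow[:] = False
        old_dir = state.mt_dir.copy()
        seed_rng(99)
        mt.step_mt_lengths_and_switching(state)
        assert (state.mt_len == 0.0).all()
        assert state.mt_grow.all()                      # re-nucleated
        assert not np.allclose(state.mt_dir, old_dir)   # fresh directions

    def test_tips_never_leave_the_cell(self, small_params):
        state = initialize_state(small_params, seed=3)
        for _ in range(400):
            step(state)
        tips = state.mt_tips()
        assert (np.linalg.norm(tips, axis=1)
                <= small_params.r_cell + 1e-9).all()

    def test_mt_count_conserved(self, small_params):
        state = initialize_state(small_params, seed=4)
        n0 = state.n_mt
        for _ in range(300):
            step(state)
        assert state.n_mt == n0
        assert (state.mt_pole == 0).sum() == small_params.n_mt_per_pole


class TestFreeSwitching:
    def test_zero_catastrophe_rate_never_switches(self, small_params):
        p = small_params.replace(f_c=0.0, R_cat_free=0.0)
        state = initialize_state(p, seed=5)
        seed_rng(5)
        for _ in range(50):
            mt.step_mt_lengths_and_switching(state)
        assert state.mt_grow.all()

    def test_switch_fraction_matches_exponential_waiting_time(self):
        # Monte-Carlo vs closed form over ~10^5 MT-steps
        p = ss.preset("control").replace(n_ch=1, n_mt_per_pole=500,
                                         f_c=0.08, dt=0.5)
        state = initialize_state(p, seed=6)
        state.ctr[:] = 0.0          # keep KTs away from MTs (no captures)
        state.mt_len[:] = 1.0
        seed_rng(123)
        switches = trials = 0
        for _ in range(200):
            growing_before = state.mt_grow.copy()
            mt.step_mt_lengths_and_switching(state)
            trials += growing_before.sum()
            switches += (growing_before & ~state.mt_grow).sum()
        p_expected = 1.0 - np.exp(-p.f_c * p.dt)
        sem = np.sqrt(p_expected * (1 - p_expected) / trials)
        assert trials > 9e4
        assert abs(switches / trials - p_expected) < 3 * sem

    def test_seeded_run_reproducible(self, small_params):
        runs = []
        for _ in range(2):
            state = initialize_state(small_params, seed=7)
            for _ in range(100):
                step(state)
            runs.append((state.mt_len.copy(), state.ctr.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])


class TestSearchAndCapture:
    def test_zero_capture_probability_never_attaches(self, small_params):
        p = small_params.replace(p_capture=0.0)
        state = initialize_state(p, seed=8)
        for _ in range(300):
            step(state)
        assert (state.mt_att == -1).all()
        assert (state.classes == int(AttachmentClass.unattached)).all()

    def test_straddling_mt_with_certain_capture_attaches_in_one_step(self):
        p = ss.preset("control").replace(n_ch=1, n_mt_per_pole=1,
                                         p_capture=1.0)
        state = initialize_state(p, seed=9)
        # aim the pole-0 MT straight at KT 0 and give it enough length
        kt = state.kt_positions()[0]
        pole = state.centrosomes[0]
        state.mt_dir[0] = (kt - pole) / np.linalg.norm(kt - pole)
        state.mt_len[0] = np.linalg.norm(kt - pole) + 0.2
        n_new = mt.search_and_capture(state)
        assert n_new == 1
        assert state.mt_att[0] == 0
        # converted to end-on: spring starts at rest, tip within r_kt
        d = np.linalg.norm(state.kt_positions()[0] - pole)
        assert state.mt_len[0] == pytest.approx(d - p.l_kmt_kt)

    def test_occupancy_never_exceeds_cap(self, small_params):
        state = initialize_state(small_params, seed=10)
        for _ in range(300):
            step(state)
            assert (state.counts.sum(axis=1) <= small_params.n_max).all()

    def test_no_new_attachment_to_amphitelic_pairs(self, small_params):
        # once a pair is amphitelic its occupancy is frozen for the run
        state = initialize_state(small_params, seed=11)
        frozen = {}
        for _ in range(400):
            step(state)
            amphi = np.flatnonzero(
                state.classes == int(AttachmentClass.amphitelic))
            for i in amphi:
                occ = (int(state.counts[2 * i].sum()),
                       int(state.counts[2 * i + 1].sum()))
                if i in frozen:
                    assert occ == frozen[i]
                else:
                    frozen[i] = occ
        assert frozen, "no amphitelic pair formed during the test window"
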