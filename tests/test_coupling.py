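"""Phase-locking values, condition contrasts and permutation statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import thetareplay as tr
from thetareplay import coupling as cp
from thetareplay.containers import grid_layout


class TestPLV:
    def test_identical_phases_give_one(self):
        assert cp.plv(np.full(8, 1.3)) == pytest.approx(1.0)

    def test_opposing_phasors_cancel(self):
        assert cp.plv(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair(self):
        assert cp.plv(np.array([0.0, np.pi / 2])) == pytest.approx(1 / np.sqrt(2))

    def test_single_event_excluded(self):
        with pytest.raises(ValueError, match="excluded"):
            cp.plv(np.array([0.5]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=30),
        st.floats(-10.0, 10.0),
    )
    def test_rotation_invariance(self, phases, rot):
        """PLV is unchanged by a global rotation of all phases."""
        p = np.asarray(phases)
        assert cp.plv(p + rot) == pytest.approx(cp.plv(p), abs=1e-9)

    @pytest.mark.parametrize("n", [5, 20])
    def test_uniform_phase_small_sample_bias(self, n):
        """For N uniform phases E[PLV] ~ sqrt(pi)/2 / sqrt(N): the known
        small-sample bias, which must not be mistaken for coupling."""
        rng = np.random.default_rng(n)
        vals = [cp.plv(rng.uniform(-np.pi, np.pi, n)) for _ in range(4000)]
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 4 * se + 0.01


class TestArcsine:
    @pytest.mark.parametrize("p,z", [(0.0, -np.pi / 2), (0.5, 0.0), (1.0, np.pi / 2)])
    def test_endpoints_and_midpoint(self, p, z):
        assert cp.arcsine_z(p) == pytest.approx(z)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff(cp.arcsine_z(grid)) > 0)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            cp.arcsine_z(1.2)


def synthetic_z_table(rng, n_subjects, n_sensors, effect_sensors=(), effect=0.0, n_trials=10):
    """Trial-level z table for two conditions, optional planted effect in
    condition A at the given sensors."""
    rows = []
    for subj in range(n_subjects):
        for cond in ("A", "B"):
            for trial in range(n_trials):
                base = rng.standard_normal(n_sensors) * 0.3
                if cond == "A" and effect:
                    base[list(effect_sensors)] += effect
                for s in range(n_sensors):
                    rows.append((subj, cond, trial, s, 6.0, 5, 0.5, base[s]))
    return pd.DataFrame(
        rows, columns=["subject", "condition", "trial", "sensor", "freq", "n_events", "plv", "z"]
    )


class TestCouplingContrast:
    def test_planted_cluster_carries_largest_t(self):
        rng = np.random.default_rng(0)
        tab = synthetic_z_table(rng, 8, 20, effect_sensors=range(5), effect=0.8)
        out = cp.coupling_contrast(tab, "A", "B")
        top5 = set(out.nlargest(5, "t")["sensor"])
        assert top5 == set(range(5))

    def test_null_type_one_rate(self):
        rng = np.random.default_rng(1)
        n_sig, n_tot = 0, 0
        for _ in range(30):
            tab = synthetic_z_table(rng, 8, 12)
            out = cp.coupling_contrast(tab, "A", "B")
            n_sig += int((out["p"] < 0.05).sum())
            n_tot += len(out)
        rate = n_sig / n_tot
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n_tot)

    def test_self_contrast_rejected(self):
        rng = np.random.default_rng(2)
        tab = synthetic_z_table(rng, 4, 6)
        dup = tab.copy()
        tab_aa = pd.concat(
            [tab[tab["condition"] == "A"], dup[dup["condition"] == "A"].assign(condition="B")]
        )
        with pytest.raises(ValueError, match="variance"):
            cp.coupling_contrast(tab_aa, "A", "B")

    def test_requires_two_subjects(self):
        rng = np.random.default_rng(3)
        tab = synthetic_z_table(rng, 1, 6)
        with pytest.raises(ValueError):
            cp.coupling_contrast(tab, "A", "B")


class TestClusterPermutation:
    def adjacency(self, n_side=6):
        return grid_layout(n_side * n_side).adjacency()

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(4)
        adj = self.adjacency()
        # 3x4 block of a 6x6 grid, strong consistent effect; 10 subjects
        # keep the sign-flip p-value floor (2 / 2^n) below the assertion
        block = [r * 6 + c for r in range(3) for c in range(4)]
        diffs = rng.standard_normal((10, 36)) * 0.15
        diffs[:, block] += 1.0
        out = cp.cluster_permutation(diffs, adj, n_perm=2000, seed=0)
        assert len(out) >= 1
        best = min(out, key=lambda c: c.p_value)
        assert best.p_value <= 0.01
        assert set(block) <= set(best.sensors)

    def test_seven_sensors_insufficient(self):
        """A significant patch below the 8-sensor minimum is not reported."""
        adj = self.adjacency()
        rng = np.random.default_rng(5)
        patch = [0, 1, 2, 6, 7, 8, 12]  # 7 mutually adjacent cells
        diffs = rng.standard_normal((8, 36)) * 0.05
        diffs[:, patch] += 2.0
        out = cp.cluster_permutation(diffs, adj, n_perm=500, seed=0)
        assert out == []

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError):
            cp.cluster_permutation(np.zeros((4, 9)), self.adjacency(3), n_perm=100)


class TestWithinSubjectPermutation:
    def make_phase(self, n_trials, n_sensors, n_times=1250, f=6.0, sfreq=250.0):
        t = np.arange(n_times) / sfreq
        base = np.angle(np.exp(2j * np.pi * f * t))
        return np.broadcast_to(base, (n_trials, n_sensors, n_times)).copy()

    def test_locked_events_yield_small_p(self):
        """Events locked to a frequency-wandering theta: circular shifts
        destroy the tracking, so the observed locking is extreme in the
        null.  (A perfectly stationary oscillation is the method's known
        blind spot: a shift is then a rigid rotation and PLV is
        rotation-invariant, which is also why the generator detunes
        non-coupled sensors.)"""
        rng = np.random.default_rng(12)
        n_trials, n_times, sfreq = 10, 1250, 250.0
        phases, events = [], []
        for _ in range(n_trials):
            f_inst = 6.0 + np.convolve(rng.standard_normal(n_times), np.ones(50) / 50, "same")
            ph = np.cumsum(2 * np.pi * f_inst / sfreq)
            wrapped = np.angle(np.exp(1j * ph))
            near_zero = np.flatnonzero(np.abs(wrapped) < 0.05)
            events.append(rng.choice(near_zero, size=15, replace=False))
            phases.append(wrapped)
        phase = np.asarray(phases)[:, None, :].repeat(2, axis=1)
        p = cp.within_subject_permutation(events, phase, n_perm=200, seed=0)
        assert np.all(p <= 0.01)

    def test_uniform_null_p_distribution(self):
        """Random event times: p-values are uniform on (0, 1] (KS test)."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(80):
            phase = self.make_phase(6, 1)
            events = [rng.integers(0, 1250, size=5) for _ in range(6)]
            p = cp.within_subject_permutation(events, phase, n_perm=120, seed=int(rng.integers(1 << 30)))
            pvals.append(p[0])
        d, pks = stats.kstest(pvals, "uniform")
        assert pks > 0.01

    def test_no_event_trials_rejected(self):
        phase = self.make_phase(3, 2)
        with pytest.raises(ValueError, match="event-bearing"):
            cp.within_subject_permutation([np.array([], int)] * 3, phase, n_perm=200)

    def test_min_permutations_enforced(self):
        phase = self.make_phase(2, 1)
        with pytest.raises(ValueError):
            cp.within_subject_permutation([np.arange(5)] * 2, phase, n_perm=50)


class TestBehaviorCorrelation:
    def test_perfect_linear_relation(self):
        acc = np.linspace(0.6, 0.9, 8)
        z = np.outer(acc, np.ones(5)) + np.arange(5)  # each sensor linear in acc
        table, _ = cp.behavior_correlation(z, acc)
        np.testing.assert_allclose(table["r"], 1.0)
        assert table["flagged"].all()

    def test_constant_accuracy_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cp.behavior_correlation(np.random.default_rng(0).random((5, 4)), np.full(5, 0.8))

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            cp.behavior_correlation(np.zeros((2, 4)), np.array([0.5, 0.6]))

    def test_cluster_reporting_respects_minimum(self):
        rng = np.random.default_rng(7)
        layout = grid_layout(36)
        acc = np.linspace(0.5, 0.9, 8)
        z = rng.standard_normal((8, 36)) * 0.15
        block = [r * 6 + c for r in range(3) for c in range(3)]  # 9 >= 8 sensors
        z[:, block] += np.outer(acc, np.ones(len(block))) * 6
        table, clusters = cp.behavior_correlation(z, acc, layout.adjacency())
        assert len(clusters) == 1
        assert set(block) <= set(clusters[0])


class TestGroundTruthPLVTable:
    def test_coupled_cluster_shows_higher_plv(self):
        params = tr.GeneratorParams(
            n_subjects=1, n_sensors=16, n_trials_per_category=10,
            coupling_kappa=12.0, rng_seed=3,
        )
        _, gt = tr.generate_subject(params, 0)
        tab = cp.plv_table_from_ground_truth(gt, 16)
        conf = tab[tab["condition"] == "configural"]
        couple = gt.coupling_clusters["configural"]
        in_c = conf[gt.cluster_of_sensor[conf["sensor"]] == couple]["plv"].mean()
        out_c = conf[gt.cluster_of_sensor[conf["sensor"]] != couple]["plv"].mean()
        assert in_c > 0.8
        assert out_c < 0.5
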