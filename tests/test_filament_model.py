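"""Rate-matrix structure, single-unit oracle, and filament simulation behavior.

The heavier ensemble checks (twitch decomposition, steady-state curve
directions) live in the acceptance suite; here the focus is structural
correctness of the generator, oracle equivalence, and reproducibility.
"""

import numpy as np
import pytest

from tropofil import filament_model as fm


@pytest.fixture(scope="module")
def wt():
    return fm.ModelParameters.preset("wt")


class TestParameters:
    def test_presets_differ_only_in_gamma_and_kbc(self):
        wt = fm.ModelParameters.preset("wt")
        mut = fm.ModelParameters.preset("s215l")
        assert (wt.gamma, wt.kbc) == (60.0, 0.76)
        assert (mut.gamma, mut.kbc) == (31.6, 0.97)
        assert fm.ModelParameters.preset("gamma_only").gamma == 31.6
        assert fm.ModelParameters.preset("kbc_only").kbc == 0.97
        with pytest.raises(ValueError, match="preset"):
            fm.ModelParameters.preset("nope")

    def test_yaml_roundtrip_with_published_symbols(self, tmp_path, wt):
        path = tmp_path / "params.yaml"
        wt.to_yaml(path)
        assert fm.ModelParameters.from_yaml(path) == wt
        alias = tmp_path / "alias.yaml"
        alias.write_text('"kCa+": 400\n"K_BC": 0.9\n"lambda": 0.01\n"krefBC": 500\n')
        p = fm.ModelParameters.from_yaml(alias)
        assert (p.k_ca_on, p.kbc, p.lambda_coupling, p.k_ref_bc) == (400, 0.9, 0.01, 500)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            fm.ModelParameters(kbc=0.0)
        with pytest.raises(ValueError):
            fm.ModelParameters(delta_split=1.5)
        with pytest.raises(ValueError):
            fm.ModelParameters(n_units=0)
        with pytest.raises(ValueError):
            fm.ModelParameters(k_ca_off=-1.0)


class TestStateEnumeration:
    def test_bijection_over_24_states(self):
        seen = set()
        for ca in (0, 1):
            for sp in (0, 1):
                for ip in (0, 1):
                    for tm in (0, 1, 2):
                        idx = fm.state_index(ca, sp, ip, tm)
                        assert fm.state_tuple(idx) == (ca, sp, ip, tm)
                        seen.add(idx)
        assert seen == set(range(24))


class TestRateMatrix:
    def test_generator_structure(self, wt):
        q = fm.build_rate_matrix(wt, 1.0)
        off = q - np.diag(np.diag(q))
        assert np.all(off >= 0)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-10)

    def test_single_factor_transitions_only(self, wt):
        q = fm.build_rate_matrix(wt, 0.5, neighbor_context=(1, 2))
        for s in range(24):
            for t in range(24):
                if s != t and q[s, t] > 0:
                    changed = sum(
                        a != b for a, b in zip(fm.state_tuple(s), fm.state_tuple(t))
                    )
                    assert changed == 1

    def test_neighbor_free_bc_equilibrium_is_kbc(self, wt):
        """With zero chain strain the B<->C rate ratio equals K_BC."""
        q = fm.build_rate_matrix(wt, 1.0)
        b = fm.state_index(1, 1, 0, fm.TM_B)
        c = fm.state_index(1, 1, 0, fm.TM_C)
        assert q[b, c] / q[c, b] == pytest.approx(wt.kbc, rel=1e-12)

    def test_calcium_zero_limit(self, wt):
        q = fm.build_rate_matrix(wt, 1e-12)
        on = fm.state_index(0, 0, 0, 0)
        off = fm.state_index(1, 0, 0, 0)
        assert q[on, off] == pytest.approx(0.0, abs=1e-6)
        assert q[off, on] == wt.k_ca_off

    def test_structural_zeros(self, wt):
        q = fm.build_rate_matrix(wt, 1.0, neighbor_context=(0, 2))
        for ca in (0, 1):
            for sp in (0, 1):
                # no direct B<->M moves
                assert q[fm.state_index(ca, sp, 0, 0), fm.state_index(ca, sp, 0, 2)] == 0
                assert q[fm.state_index(ca, sp, 0, 2), fm.state_index(ca, sp, 0, 0)] == 0
                # no entry into B while the inhibitory peptide is released
                assert q[fm.state_index(ca, sp, 1, 1), fm.state_index(ca, sp, 1, 0)] == 0
                # myosin binding requires the inhibitory peptide released
                assert q[fm.state_index(ca, sp, 0, 1), fm.state_index(ca, sp, 0, 2)] == 0
                # release requires switch peptide bound and tm out of B
                assert q[fm.state_index(ca, 0, 0, 1), fm.state_index(ca, 0, 1, 1)] == 0
                assert q[fm.state_index(ca, sp, 0, 0), fm.state_index(ca, sp, 1, 0)] == 0

    def test_strain_preserves_pair_equilibrium(self, wt):
        """Neighbor strain rescales B<->C kinetics but K equals kbc*exp(-dE)."""
        for ctx in [(0, 0), (1, 1), (2, 2), (0, 2), (None, 1)]:
            q = fm.build_rate_matrix(wt, 1.0, neighbor_context=ctx)
            b = fm.state_index(1, 1, 0, fm.TM_B)
            c = fm.state_index(1, 1, 0, fm.TM_C)
            left = fm.TM_NONE if ctx[0] is None else ctx[0]
            right = fm.TM_NONE if ctx[1] is None else ctx[1]
            de = fm._strain_rt(wt, fm.TM_C, left, right) - fm._strain_rt(
                wt, fm.TM_B, left, right
            )
            assert q[b, c] / q[c, b] == pytest.approx(wt.kbc * np.exp(-de), rel=1e-10)


class TestStationaryDistribution:
    def test_normalization_and_positivity(self, wt):
        pi = fm.stationary_distribution_single_unit(wt, 1.0)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pi >= 0)

    def test_transient_states_have_zero_mass(self, wt):
        pi = fm.stationary_distribution_single_unit(wt, 1.0)
        for ca in (0, 1):
            for sp in (0, 1):
                assert pi[fm.state_index(ca, sp, 1, fm.TM_B)] == 0.0

    def test_bc_flux_balance_without_myosin(self, wt):
        """With myosin attachment off, no net flux crosses the B|C cut."""
        p = wt.replace(k_md_on=0.0)
        q = fm.build_rate_matrix(p, 0.7)
        pi = fm.stationary_distribution_single_unit(p, 0.7)
        b_states = [s for s in range(24) if fm.state_tuple(s)[3] == fm.TM_B]
        flux_bc = sum(pi[s] * q[s, t] for s in b_states for t in range(24)
                      if fm.state_tuple(t)[3] != fm.TM_B)
        flux_cb = sum(pi[s] * q[s, t] for s in range(24) for t in b_states
                      if fm.state_tuple(s)[3] != fm.TM_B)
        assert flux_bc == pytest.approx(flux_cb, rel=1e-9, abs=1e-12)

    def test_m_occupancy_monotone_in_calcium(self, wt):
        pcas = np.linspace(9, 4, 21)
        pm = [
            fm.stationary_distribution_single_unit(wt, fm.pca_to_uM(p))[fm._TM_OF == 2].sum()
            for p in pcas
        ]
        assert np.all(np.diff(pm) > -1e-12)

    def test_truly_reducible_generator_reported(self, wt):
        # with release, escape and myosin paths all off, the tm factor splits
        p = wt.replace(k_ip_on=0.0, f_xy=0.0, k_md_on=0.0, k_ip_off=0.0)
        with pytest.raises(fm.ReducibleMatrixError) as err:
            fm.stationary_distribution_single_unit(p, 1.0)
        assert len(err.value.classes) > 1


class TestCalciumProtocol:
    def test_transient_peaks_at_requested_level(self):
        prot = fm.CalciumProtocol(mode="transient", stimulus_time=1.0)
        t = np.linspace(0, 3, 30_001)
        ca = prot.ca_at(t)
        assert ca[t <= 1.0].max() == pytest.approx(0.1)
        assert ca.max() == pytest.approx(1.0, rel=1e-6)
        assert ca[-1] < 0.11  # decayed back toward diastolic

    def test_invalid_protocols(self):
        with pytest.raises(ValueError):
            fm.CalciumProtocol(mode="ramp")
        with pytest.raises(ValueError):
            fm.CalciumProtocol(mode="transient", peak=0.05)
        with pytest.raises(ValueError):
            fm.CalciumProtocol(constant_ca=0.0)


class TestSimulation:
    def test_dt_guard_rejects_coarse_step(self, wt):
        prot = fm.CalciumProtocol(mode="constant", constant_ca=100.0)
        with pytest.raises(ValueError, match="dt guard"):
            fm.simulate_filament(wt, prot, duration=0.1, dt=1e-3, n_trajectories=1)

    def test_force_bounds_and_determinism(self, wt):
        prot = fm.CalciumProtocol(mode="constant", constant_ca=1.0)
        t1 = fm.simulate_filament(wt, prot, duration=0.2, n_trajectories=4, seed=5)
        t2 = fm.simulate_filament(wt, prot, duration=0.2, n_trajectories=4, seed=5)
        assert np.array_equal(t1.force, t2.force)
        assert np.all((t1.force >= 0) & (t1.force <= wt.n_units))
        t3 = fm.simulate_filament(wt, prot, duration=0.2, n_trajectories=4, seed=6)
        assert not np.array_equal(t1.force, t3.force)

    def test_diastolic_constant_protocol_stays_quiet(self, wt):
        """At the 0.1 uM diastolic level the force trace stays near zero."""
        prot = fm.CalciumProtocol(mode="constant", constant_ca=0.1)
        traj = fm.simulate_filament(wt, prot, duration=1.0, n_trajectories=16, seed=2)
        late = traj.force[traj.time > 0.3]
        assert late.mean() < 0.05 * wt.n_units
        assert np.ptp(late) < 0.1 * wt.n_units  # flat, no stimulus

    def test_single_unit_occupancy_matches_stationary_oracle(self, wt):
        """Monte-Carlo occupancy vs linear-algebra stationary law, TV < 0.02."""
        ca = 0.7
        occ = fm.occupancy_single_unit(wt, ca, n_steps=100_000, n_trajectories=48, seed=3)
        pi = fm.stationary_distribution_single_unit(wt, ca)
        tv = 0.5 * np.abs(occ - pi).sum()
        assert tv < 0.02

    def test_ensemble_noise_shrinks_with_trajectories(self, wt):
        """Ensemble-mean force SE scales roughly as 1/sqrt(n_trajectories)."""
        prot = fm.CalciumProtocol(mode="constant", constant_ca=0.8)

        def late_sd(n_traj, seed):
            traj = fm.simulate_filament(
                wt, prot, duration=0.6, n_trajectories=n_traj, seed=seed
            )
            return traj.force[traj.time > 0.4].std(ddof=1)

        sd_small = np.mean([late_sd(4, s) for s in range(4)])
        sd_big = np.mean([late_sd(36, s + 10) for s in range(4)])
        ratio = sd_small / sd_big
        assert 1.5 < ratio < 6.0  # expected 3.0 for sqrt(36/4)

    def test_hill_coefficient_increases_with_chain_stiffness(self):
        """Stronger neighbor coupling steepens the force-pCa relation."""
        from tropofil import observables as obs

        pcas = np.array([6.75, 6.25, 6.0, 5.5, 4.75])
        n_hills = []
        for gamma in (15.0, 31.6, 60.0):
            p = fm.ModelParameters(gamma=gamma, kbc=0.76)
            forces = fm.force_pca_curve(p, pcas, n_trajectories=12, seed=0)
            n_hills.append(obs.fit_hill(pcas, obs.force_to_velocity(forces)).n_hill)
        assert np.all(np.diff(n_hills) > 0)

    def test_trajectory_io_roundtrip(self, tmp_path, wt):
        prot = fm.CalciumProtocol(mode="constant", constant_ca=0.5)
        traj = fm.simulate_filament(wt, prot, duration=0.05, n_trajectories=2, seed=1)
        path = tmp_path / "traj.tsv"
        fm.write_trajectory(traj, path)
        back = fm.read_trajectory(path)
        assert np.allclose(back.time, traj.time)
        assert np.allclose(back.force, traj.force)
        assert back.n_trajectories == traj.n_trajectories

    def test_twitch_requires_transient(self, wt):
        prot = fm.CalciumProtocol(mode="constant", constant_ca=0.1)
        with pytest.raises(ValueError, match="transient"):
            fm.simulate_twitch(wt, protocol=prot, n_trajectories=1)
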