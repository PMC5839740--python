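"""World/filter simulation: truth generation, the estimation cycle, and the
behavioural signatures that distinguish active from passive motion."""

import numpy as np
import pytest

from selfmotion import (
    ablate_canal_internal_model,
    combine,
    fit_exponential_time_constant,
    generate_truth,
    make_preset,
    simulate,
    steady_state_gain,
)
from selfmotion.io import read_trajectory, write_trajectory
from selfmotion.protocols import PRESETS, step_protocol
from selfmotion.simulate import default_world, run_filter


class TestGenerateTruth:
    def test_canal_state_reaches_40pc_after_2s(self, params):
        """Constant 2-s rotation: C peaks near 1 - e^(-0.5) of the velocity."""
        prot = step_protocol(params, 2.0, mode="evar", channel="Omega", which="passive")
        world = default_world(prot, params)
        X, _ = generate_truth(world, prot)
        ratio = X[-1, world.state_labels.index("C")]
        assert ratio == pytest.approx(1 - np.exp(-0.5), abs=0.005)

    def test_canal_aftereffect_on_stop(self, params):
        prot = step_protocol(params, 4.0, mode="evar", channel="Omega",
                             which="passive", stim_duration=2.0)
        world = default_world(prot, params)
        X, S = generate_truth(world, prot)
        after = prot.t > 2.0 + params.dt
        V = S[:, world.sensor_labels.index("V")]
        C = X[:, world.state_labels.index("C")]
        assert np.all(V[after] < 0)
        assert np.allclose(V[after], -C[after])

    def test_zero_protocol_stays_at_rest(self, params):
        prot = make_preset("rotation_2s_active", params, amplitude=0.0)
        X, S = generate_truth(default_world(prot, params), prot)
        assert np.all(X == 0.0) and np.all(S == 0.0)

    def test_sensor_noise_only_with_seed(self, params):
        prot = make_preset("rotation_0p2s_passive", params)
        world = default_world(prot, params)
        _, S0 = generate_truth(world, prot)
        _, S1 = generate_truth(world, prot, seed=11)
        _, S2 = generate_truth(world, prot, seed=11)
        assert not np.array_equal(S0, S1)
        assert np.array_equal(S1, S2)

    def test_channel_mismatch_rejected(self, params, neck_model):
        prot = make_preset("rotation_0p2s_passive", params)
        with pytest.raises(ValueError, match="Omega_eps"):
            generate_truth(neck_model, prot)


class TestRunFilter:
    def test_bookkeeping_identity_holds_exactly(self, params):
        prot = make_preset("tilt_2s_passive", params)
        traj = simulate(default_world(prot, params), prot)
        recomposed = traj.X_pred + traj.feedback.sum(axis=2)
        assert np.array_equal(traj.X_hat, recomposed)

    def test_passive_estimate_carried_by_feedback(self, params, canal_gain):
        prot = make_preset("rotation_0p2s_passive", params)
        traj = simulate(default_world(prot, params), prot)
        plateau = np.abs(traj.state("Omega", "true")) > 0.999
        k = canal_gain.entry("Omega", "V")
        ratio = traj.state("Omega")[plateau] / traj.state("Omega", "true")[plateau]
        assert np.allclose(ratio, k, atol=0.02)
        # the prediction pathway stays silent
        assert np.max(np.abs(traj.state("Omega", "pred")[plateau])) < 0.01

    def test_translation_onset_acceleration_gain(self, params, tilt_gain):
        """At passive translation onset the otolith error equals A and the
        acceleration estimate picks it up with the near-unity gain."""
        prot = step_protocol(params, 1.0, mode="translation", channel="A", which="passive")
        traj = simulate(default_world(prot, params), prot)
        dF0 = traj.sensor("F", "err")[0]
        assert dF0 == pytest.approx(1.0)
        assert traj.state("A")[0] == pytest.approx(tilt_gain.entry("A", "F"))

    def test_grid_mismatch_rejected(self, params, canal_model):
        K = steady_state_gain(canal_model)
        with pytest.raises(ValueError):
            run_filter(canal_model, K, np.zeros((10, 1)), np.zeros((9, 1)))


class TestActiveZeroError:
    @pytest.mark.parametrize("base", sorted(PRESETS))
    def test_every_active_preset_has_silent_feedback(self, params, base):
        """Self-generated motion, noise off: sensory errors vanish and the
        estimate equals the truth, for every preset and model variant."""
        prot = make_preset(f"{base}_active", params)
        traj = simulate(default_world(prot, params), prot)
        assert np.max(np.abs(traj.dS)) < 1e-9
        assert np.max(np.abs(traj.X_hat - traj.X_true)) < 1e-9


class TestSuperposition:
    def test_trajectories_add_like_their_protocols(self, params):
        a = make_preset("rotation_gaussian_active", params)
        b = make_preset("rotation_2s_passive", params, amplitude=0.6)
        world = default_world(a, params)
        K = steady_state_gain(world)
        ta = simulate(world, a, K=K)
        tb = simulate(world, b, K=K)
        tc = simulate(world, combine(a, b), K=K)
        ts = ta + tb
        assert np.max(np.abs(tc.X_hat - ts.X_hat)) < 1e-9
        assert np.max(np.abs(tc.feedback - ts.feedback)) < 1e-9

    @pytest.mark.parametrize("mode_pair", [
        ("rotation_gaussian_active", "rotation_2s_passive"),
        ("tilt_gaussian_active", "tilt_2s_passive"),
        ("translation_gaussian_active", "translation_2s_passive"),
    ])
    def test_feedback_encodes_passive_component_only(self, params, mode_pair):
        """Superimposed active+passive motion: the feedback series equals the
        feedback of the passive protocol alone."""
        active_name, passive_name = mode_pair
        a = make_preset(active_name, params)
        b = make_preset(passive_name, params, amplitude=0.5)
        world = default_world(a, params)
        K = steady_state_gain(world)
        t_comb = simulate(world, combine(a, b), K=K)
        t_pass = simulate(world, b, K=K)
        assert np.max(np.abs(t_comb.feedback - t_pass.feedback)) < 1e-9
        assert np.max(np.abs(t_comb.dS - t_pass.dS)) < 1e-9


class TestDissociations:
    def test_tilt_translation_otolith_error_dissociation(self, params):
        """An identical otolith profile is near-fully explained when it comes
        from tilt but drives a large otolith error when it is a translation:
        the tilt error stays roughly an order of magnitude smaller."""
        from selfmotion.protocols import Protocol

        tilt = make_preset("tilt_0p2s_passive", params)
        world = default_world(tilt, params)
        K = steady_state_gain(world)
        t_tilt = simulate(world, tilt, K=K)
        # translation whose acceleration replays the tilt's otolith profile
        trans = Protocol(
            t=tilt.t, active={}, passive={"A_eps": t_tilt.sensor("F").copy()},
            mode="translation", name="matched_translation",
        )
        t_trans = simulate(world, trans, K=K)
        assert np.max(np.abs(t_trans.sensor("F"))) == pytest.approx(
            np.max(np.abs(t_tilt.sensor("F"))), rel=1e-9
        )
        ratio = np.max(np.abs(t_tilt.sensor("F", "err"))) / np.max(
            np.abs(t_trans.sensor("F", "err"))
        )
        assert ratio < 0.15

    def test_somatogravic_tilt_illusion_during_long_translation(self, params):
        """20-s passive acceleration: the tilt estimate rises toward the
        otolith signal while the acceleration estimate decays away."""
        prot = make_preset("translation_20s_passive", params)
        world = default_world(prot, params)
        traj = simulate(world, prot)
        G_hat, A_hat = traj.state("G"), traj.state("A")
        assert A_hat[0] > 0.9  # onset: interpreted as acceleration
        assert G_hat[-1] == pytest.approx(1.0, abs=0.05)  # settles on the otolith signal
        assert abs(A_hat[-1]) < 0.05
        # the tilt illusion develops within the first seconds
        early = traj.t <= 5.0
        assert G_hat[early][-1] > 0.8 and G_hat[early][0] < 0.05

    def test_velocity_storage_and_its_loss_without_canal_model(self, params):
        """The rotation estimate outlives the canal signal; removing the
        canal internal model collapses its decay back to tau_c."""
        prot = step_protocol(params, 60.0, mode="evar", channel="Omega", which="passive")
        world = default_world(prot, params)
        traj = simulate(world, prot)
        tau_hat = fit_exponential_time_constant(traj.t, traj.state("Omega"), (10, 40)).value
        assert tau_hat > params.tau_c
        abl = ablate_canal_internal_model(world)
        traj_abl = simulate(world, prot, filter_model=abl)
        tau_abl = fit_exponential_time_constant(
            traj_abl.t, traj_abl.state("Omega"), (10, 40)
        ).value
        assert tau_abl == pytest.approx(params.tau_c, rel=0.05)

    def test_ablated_filter_errs_during_active_rotation(self, params):
        prot = step_protocol(params, 4.0, mode="evar", channel="Omega",
                             which="active", stim_duration=2.0)
        world = default_world(prot, params)
        abl = ablate_canal_internal_model(world)
        traj = simulate(world, prot, filter_model=abl)
        assert np.max(np.abs(traj.dS)) > 0.1
        # the net estimate parallels the decaying canal signal, not the truth
        during = (prot.t > 1.5) & (prot.t < 2.0)
        V = traj.sensor("V")
        assert np.allclose(traj.state("Omega")[during] / V[during],
                           traj.state("Omega")[during].max() / V[during].max(), rtol=0.05)
        assert traj.state("Omega")[during].max() < 0.75

    def test_neck_proprioceptive_feedback_codes_trunk_velocity(self, params):
        """Trunk-under-head rotation: position-coding proprioceptors drive a
        velocity-coding trunk feedback with plateau gain in [0.8, 0.95]."""
        prot = make_preset("trunk_under_head_passive", params)
        world = default_world(prot, params)
        traj = simulate(world, prot)
        plateau = np.abs(traj.state("OmegaTS", "true")) > 0.999
        fb = traj.feedback_series("OmegaTS", "P")[plateau]
        gain = fb / traj.state("OmegaTS", "true")[plateau]
        assert 0.8 < gain.mean() < 0.95


class TestNoise:
    def test_noisy_runs_average_to_the_noise_free_trajectory(self, params):
        """The mean over 200 seeded noisy runs matches the noise-free run
        within 3 standard errors at every 10th sample."""
        prot = make_preset("rotation_2s_passive", params)
        world = default_world(prot, params)
        K = steady_state_gain(world)
        ref = simulate(world, prot, K=K).state("Omega")
        runs = np.array([
            simulate(world, prot, seed=1000 + i, K=K).state("Omega")
            for i in range(200)
        ])
        sel = slice(None, None, 10)
        mean = runs.mean(axis=0)[sel]
        se = runs.std(axis=0, ddof=1)[sel] / np.sqrt(runs.shape[0])
        assert np.all(np.abs(mean - ref[sel]) <= 3 * se + 1e-12)


def test_trajectory_round_trip(tmp_path, params):
    prot = make_preset("tilt_0p2s_passive", params)
    traj = simulate(default_world(prot, params), prot)
    path = tmp_path / "traj.csv"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    assert back.state_labels == traj.state_labels
    assert np.array_equal(back.X_hat, traj.X_hat)
    assert np.array_equal(back.feedback, traj.feedback)
    assert np.array_equal(back.dS, traj.dS)
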