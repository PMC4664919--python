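import numpy as np
import pytest

from spikeqp import (
    FeatureBasis,
    KernelSpec,
    NetworkParams,
    Observation,
    SimConfig,
    make_cosine_features,
    make_random_features,
    mistuning_ratios,
    perturb_connectivity,
    simulate,
    stability_check,
    tune_network,
)
from spikeqp.network import discrete_exp_kernel_weights


def single_neuron(g=10.0, theta=1.0, H=0.0, tau_m=np.inf, kernel=None):
    return NetworkParams(
        J=np.array([[H - theta]]), g=np.array([g]), theta=theta,
        H=np.array([H]), tau_m=tau_m,
        kernel=kernel if kernel is not None else KernelSpec(),
    )


class TestTuning:
    def test_unit_norm_basis_resets_to_zero(self):
        b = make_random_features(10, 10, 0, 1, seed=0)
        net = tune_network(b, Observation(np.zeros(10)), theta=1.0)
        assert np.allclose(np.diag(net.J), -1.0)
        assert np.allclose(net.H, 0.0)

    def test_l2_lowers_reset_by_beta(self):
        b = make_random_features(10, 10, 0, 1, seed=0)
        net = tune_network(b, Observation(np.zeros(10)), beta=0.5, theta=1.0)
        assert np.allclose(net.H, -0.5)

    def test_orthogonal_features_do_not_interact(self):
        net = tune_network(FeatureBasis(np.eye(3)), Observation(np.ones(3)))
        off = net.J[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_l1_is_global_inhibition_on_the_drive(self):
        b = FeatureBasis(np.eye(3))
        net = tune_network(b, Observation(np.ones(3)), alpha=10.0)
        assert np.allclose(net.g, 1.0 - 10.0)


class TestPerturbation:
    def test_zero_interval_is_identity(self):
        b = make_cosine_features(10)
        net = tune_network(b, Observation(np.zeros(2)))
        p = perturb_connectivity(net, 0.0, 0.0, seed=1)
        assert np.array_equal(p.J, net.J)

    def test_same_seed_same_perturbation(self):
        b = make_cosine_features(10)
        net = tune_network(b, Observation(np.zeros(2)))
        p1 = perturb_connectivity(net, -0.2, 0.0, seed=5)
        p2 = perturb_connectivity(net, -0.2, 0.0, seed=5)
        assert np.array_equal(p1.J, p2.J)
        assert not np.array_equal(p1.J, net.J)

    def test_negative_interval_shifts_mean_and_reset(self):
        b = make_cosine_features(100)
        net = tune_network(b, Observation(np.zeros(2)))
        p = perturb_connectivity(net, -0.2, 0.0, seed=2)
        assert np.mean(p.J - net.J) == pytest.approx(-0.1, abs=0.01)
        assert np.allclose(p.H, net.theta + np.diag(p.J))

    def test_ratio_report_has_three_conventions(self):
        b = make_cosine_features(50)
        net = tune_network(b, Observation(np.zeros(2)))
        p = perturb_connectivity(net, -0.2, 0.0, seed=3)
        out = mistuning_ratios(net.J, p.J)
        assert set(out) == {"mean_entrywise_ratio", "mean_abs_ratio",
                            "frobenius_ratio"}
        assert out["mean_abs_ratio"] == pytest.approx(0.1 / np.abs(net.J).mean(),
                                                      rel=0.1)


class TestStability:
    def test_tuned_network_has_no_positive_eigenvalues(self):
        b = make_random_features(50, 50, 0, 1, seed=1)
        net = tune_network(b, Observation(np.zeros(50)))
        rep = stability_check(net)
        assert rep["max_eigenvalue"] <= 1e-10
        assert not rep["unstable"]

    def test_zero_mean_mistuning_creates_positive_eigenvalues(self):
        b = make_cosine_features(100)
        net = tune_network(b, Observation(np.zeros(2)))
        flags = [
            stability_check(perturb_connectivity(net, -0.1, 0.1, seed=s))["unstable"]
            for s in range(5)
        ]
        assert all(flags)


class TestSimulate:
    def test_single_neuron_rate_is_drive_over_gap(self):
        # closed form: rate = g / (theta - H) for a non-leaky neuron
        ras = simulate(single_neuron(g=10.0), SimConfig(duration=5.0, seed=0))
        assert ras.n_spikes == pytest.approx(50, abs=1)

    def test_subthreshold_drive_never_spikes(self):
        ras = simulate(single_neuron(g=-1.0), SimConfig(duration=1.0, seed=0))
        assert ras.n_spikes == 0

    def test_seed_determinism_is_bit_exact(self):
        b = make_random_features(20, 20, 0, 1, seed=3)
        net = tune_network(b, Observation(5.0 * b.U[:, 2]))
        cfg = SimConfig(duration=2.0, seed=9, noise_var=0.01)
        r1, r2 = simulate(net, cfg), simulate(net, cfg)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.neurons, r2.neurons)

    def test_discrimination_leaves_only_the_stimulated_neuron(self):
        b = make_random_features(100, 100, 0, 1, seed=11)
        net = tune_network(b, Observation(50.0 * b.U[:, 9]))
        ras = simulate(net, SimConfig(duration=5.0, seed=3))
        late = ras.spike_counts(2.0, 3.0)
        assert late[9] / 3.0 == pytest.approx(50.0, rel=0.05)
        others = np.delete(late, 9)
        assert others.sum() <= 3  # at most stray spikes from other causes

    def test_reset_bookkeeping_integrated_drive_matches_gap(self):
        # non-leaky, no recurrence: between spikes the integrated input
        # equals theta - H up to one Euler step's worth of drive
        net = single_neuron(g=7.3)
        ras = simulate(net, SimConfig(duration=3.0, seed=1))
        isis = np.diff(ras.times)
        assert np.all(np.abs(isis * 7.3 - 1.0) <= 7.3 * 1e-5 + 1e-9)

    def test_exponential_kernel_weights_integrate_to_one(self):
        w = discrete_exp_kernel_weights(dt=1e-5, tau_s=5e-3)
        assert w.sum() * 1e-5 == pytest.approx(1.0, abs=1e-6)

    def test_delta_kernel_jump_is_delivered_next_step(self):
        # neuron 0 drives neuron 1 with a supra-threshold jump
        J = np.array([[-1.0, 0.0], [2.5, -1.0]])
        net = NetworkParams(J=J, g=np.array([10.0, 0.0]), theta=1.0,
                            H=np.zeros(2), kernel=KernelSpec(kind="delta"))
        cfg = SimConfig(duration=0.5, seed=0,
                        v0=np.array([0.0, 0.0]))
        ras = simulate(net, cfg)
        t0 = ras.times[ras.neurons == 0]
        t1 = ras.times[ras.neurons == 1]
        assert t1.size == t0.size  # every presynaptic spike triggers one
        assert np.allclose(t1 - t0[: t1.size], 1e-5, atol=1e-12)

    def test_carry_excess_config_changes_reset(self):
        J = np.array([[-1.0, 0.0], [2.5, -1.0]])
        net = NetworkParams(J=J, g=np.array([10.0, 0.0]), theta=1.0,
                            H=np.zeros(2), kernel=KernelSpec(kind="delta"))
        v0 = np.array([0.0, 0.0])
        n_plain = simulate(net, SimConfig(duration=0.5, seed=0, v0=v0)).n_spikes
        n_carry = simulate(net, SimConfig(duration=0.5, seed=0, v0=v0,
                                          carry_excess=True)).n_spikes
        # carried excess (1.5 above threshold) re-triggers neuron 1
        assert n_carry > n_plain

    def test_leak_pulls_voltage_down(self):
        # with a leak, constant drive g saturates at V = g * tau_m;
        # g * tau_m < theta means silence
        net = single_neuron(g=10.0, tau_m=0.05)
        ras = simulate(net, SimConfig(duration=1.0, seed=0))
        assert ras.n_spikes == 0
        net = single_neuron(g=30.0, tau_m=0.05)
        assert simulate(net, SimConfig(duration=1.0, seed=0)).n_spikes > 0

    def test_injected_noise_adds_variability(self):
        net = single_neuron(g=10.0)
        quiet = simulate(net, SimConfig(duration=5.0, seed=2))
        noisy = simulate(net, SimConfig(duration=5.0, seed=2, noise_var=0.3))
        cv = lambda r: np.diff(r.times).std() / np.diff(r.times).mean()
        assert cv(noisy) > 5 * max(cv(quiet), 1e-6)

    def test_voltage_recording(self):
        net = single_neuron(g=2.0)
        ras = simulate(net, SimConfig(duration=0.1, seed=0,
                                      record_voltages=True, record_stride=10))
        assert ras.voltages is not None
        assert ras.voltages.shape[0] == ras.voltage_times.size
        assert np.all(ras.voltages < net.theta + 1e-9)


def test_raster_csv_roundtrip(tmp_path):
    b = make_random_features(10, 10, 0, 1, seed=3)
    net = tune_network(b, Observation(5.0 * b.U[:, 2]))
    ras = simulate(net, SimConfig(duration=1.0, seed=4))
    p = tmp_path / "raster.csv"
    ras.to_csv(p, meta={"task": "smoke"})
    back = type(ras).from_csv(p)
    assert np.allclose(back.times, ras.times, atol=1e-8)
    assert np.array_equal(back.neurons, ras.neurons)
    assert back.duration == ras.duration
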