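"""The federated protocol: deltas, aggregation, reductions and isolation."""

import numpy as np
import pytest

from fedfilter import (ClientState, GlobalState, GradientDelta, ModelSpec,
                       ProtocolError, aggregate, client_update,
                       init_global_state, personalize, run_fedavg,
                       run_federated, standalone_train)
from fedfilter.params import ParamDict


def _spec(K=6):
    return ModelSpec(kind="feedforward", input_dim=K, hidden_dim=8, output_dim=1)


class TestClientUpdate:
    def test_zero_local_epochs_zero_delta(self, tiny_clients):
        spec = _spec()
        state = init_global_state(spec, 0)
        c = tiny_clients[0]
        c.local_epochs = 0
        d = client_update(state, c, spec, seed=0)
        assert d.d_theta.max_abs() == 0.0
        assert np.all(d.d_h == 0.0)

    def test_zero_learning_rate_zero_delta_and_phi_unchanged(self, tiny_clients):
        spec = _spec()
        state = init_global_state(spec, 0)
        c = tiny_clients[0]
        c.beta = 0.0
        d1 = client_update(state, c, spec, seed=0)
        phi_before = c.filter_stack.to_paramdict().copy()
        d2 = client_update(state, c, spec, seed=0)
        assert d2.d_theta.max_abs() == 0.0
        assert np.all(d2.d_h == 0.0)
        assert c.filter_stack.to_paramdict().equals(phi_before)
        assert d1.d_theta.max_abs() == 0.0

    def test_single_sample_delta_matches_finite_difference(self):
        # J=1, one sample, one Adam step: the delta direction must match the
        # finite-difference gradient of loss(model(filter(x))) sign-for-sign
        from fedfilter.compose import composed_loss_grads
        from fedfilter.filtering import init_filter_stack
        from fedfilter.synthetic import ClientDataset

        rng = np.random.default_rng(0)
        spec = _spec(K=3)
        X, y = rng.normal(size=(1, 4)), np.array([1.0])
        ds = ClientDataset(client_id="c", X=X, y=y,
                           feature_names=[f"f{i}" for i in range(4)])
        client = ClientState(client_id="c", data=ds, beta=1e-3, batch_size=8,
                             filter_depth=1)
        state = init_global_state(spec, 3)
        d = client_update(state, client, spec, seed=5)
        _, dtheta, dh, _ = composed_loss_grads(
            state.theta, spec, X, y, h=state.h, stack=client.filter_stack)
        eps = 1e-6
        for k in state.theta:
            grad = dtheta[k]
            # first Adam step is lr * sign(grad) (bias-corrected moments cancel)
            expect = 1e-3 * np.sign(grad)
            np.testing.assert_allclose(d.d_theta[k], expect, atol=2e-6)
        np.testing.assert_allclose(d.d_h, 1e-3 * np.sign(dh), atol=2e-6)

    def test_empty_training_split_rejected(self, tiny_clients):
        spec = _spec()
        c = tiny_clients[0]
        c.data.splits["train"][:] = False
        with pytest.raises(ProtocolError, match="empty training split"):
            client_update(init_global_state(spec, 0), c, spec, seed=0)

    def test_global_state_not_mutated(self, tiny_clients):
        spec = _spec()
        state = init_global_state(spec, 0)
        theta0, h0 = state.theta.copy(), state.h.copy()
        client_update(state, tiny_clients[0], spec, seed=0)
        assert state.theta.equals(theta0)
        np.testing.assert_array_equal(state.h, h0)


class TestAggregate:
    def _state(self, vals):
        return GlobalState(theta=ParamDict({"w": np.array(vals)}),
                           h=np.array([1.0, 2.0]), round_index=0)

    def test_zero_deltas_fixed_point(self):
        state = self._state([1.0, -2.0])
        d = GradientDelta(d_theta=ParamDict({"w": np.zeros(2)}),
                          d_h=np.zeros(2), client_id="a")
        new = aggregate(state, [d], eta=0.7)
        assert new.theta.equals(state.theta)
        np.testing.assert_array_equal(new.h, state.h)
        assert new.round_index == 1

    def test_single_client_eta_one_recovers_local_params(self):
        state = self._state([1.0, -2.0])
        theta_c = ParamDict({"w": np.array([0.25, -1.5])})
        d = GradientDelta(d_theta=state.theta - theta_c,
                          d_h=np.zeros(2), client_id="a")
        new = aggregate(state, [d], eta=1.0)
        np.testing.assert_array_equal(new.theta["w"], theta_c["w"])

    def test_two_scalar_deltas_arithmetic_mean(self):
        state = self._state([10.0])
        ds = [GradientDelta(ParamDict({"w": np.array([2.0])}), np.zeros(2), "a"),
              GradientDelta(ParamDict({"w": np.array([4.0])}), np.zeros(2), "b")]
        new = aggregate(state, ds, eta=0.5)
        np.testing.assert_array_equal(new.theta["w"], [10.0 - 1.5])

    def test_equals_brute_force_mean(self):
        rng = np.random.default_rng(8)
        spec = _spec()
        state = init_global_state(spec, 0)
        deltas = []
        for cid in "abcde":
            deltas.append(GradientDelta(
                d_theta=ParamDict({k: rng.normal(size=v.shape)
                                   for k, v in state.theta.items()}),
                d_h=rng.normal(size=state.h.shape), client_id=cid))
        eta = 0.3
        new = aggregate(state, deltas, eta)
        for k in state.theta:
            brute = state.theta[k] - eta * sum(d.d_theta[k] for d in deltas) / 5
            np.testing.assert_allclose(new.theta[k], brute, atol=1e-12)
        np.testing.assert_allclose(
            new.h, state.h - eta * sum(d.d_h for d in deltas) / 5, atol=1e-12)

    def test_order_invariance_bitexact(self):
        rng = np.random.default_rng(9)
        spec = _spec()
        state = init_global_state(spec, 0)
        deltas = [GradientDelta(
            d_theta=ParamDict({k: rng.normal(size=v.shape)
                               for k, v in state.theta.items()}),
            d_h=rng.normal(size=state.h.shape), client_id=cid)
            for cid in "abcd"]
        a = aggregate(state, deltas, eta=0.2)
        b = aggregate(state, deltas[::-1], eta=0.2)
        assert a.theta.equals(b.theta)
        np.testing.assert_array_equal(a.h, b.h)

    def test_empty_deltas_rejected(self):
        with pytest.raises(ProtocolError):
            aggregate(self._state([1.0]), [], eta=1.0)


class TestProtocolReductions:
    def test_zero_rounds_returns_initial_state(self, tiny_clients):
        spec = _spec()
        state, history = run_federated(tiny_clients, spec, rounds=0, seed=4)
        ref = init_global_state(spec, 4)
        assert state.theta.equals(ref.theta)
        assert history == []

    def test_one_client_eta_one_equals_local_training_bitexact(self, tiny_clients):
        """One round of the federated protocol at learning rate 1 with a single
        client is local training: theta - (theta - theta_c) = theta_c."""
        spec = _spec()
        seed = 13
        epochs = 3
        client = tiny_clients[0]
        client.local_epochs = epochs
        state, _ = run_federated([client], spec, rounds=1, eta=1.0, seed=seed)
        fresh = ClientState(client_id=client.client_id, data=client.data,
                            beta=client.beta, batch_size=client.batch_size,
                            filter_depth=client.filter_depth)
        local = standalone_train(fresh, spec, epochs=epochs, with_filtering=True,
                                 seed=seed)
        assert state.theta.equals(local.theta)
        np.testing.assert_array_equal(state.h, local.h)
        assert client.filter_stack.to_paramdict().equals(
            fresh.filter_stack.to_paramdict())

    def test_identical_clients_give_identical_deltas(self, tiny_clients):
        spec = _spec()
        state = init_global_state(spec, 0)
        base = tiny_clients[0]
        twin = ClientState(client_id=base.client_id, data=base.data,
                           beta=base.beta, batch_size=base.batch_size,
                           filter_depth=base.filter_depth)
        d1 = client_update(state, base, spec, seed=2)
        d2 = client_update(state, twin, spec, seed=2)
        assert d1.d_theta.equals(d2.d_theta)
        np.testing.assert_array_equal(d1.d_h, d2.d_h)
        # and the aggregate of the two equals either one alone
        both = aggregate(state, [d1, GradientDelta(d2.d_theta, d2.d_h, "other")],
                         eta=1.0)
        alone = aggregate(state, [d1], eta=1.0)
        for k in both.theta:
            np.testing.assert_allclose(both.theta[k], alone.theta[k], atol=1e-12)

    def test_full_run_reproducible_bitexact(self, tiny_clients):
        spec = _spec()
        s1, h1 = run_federated(tiny_clients, spec, rounds=3, eta=1.0, seed=21)
        fresh = [ClientState(client_id=c.client_id, data=c.data, beta=c.beta,
                             batch_size=c.batch_size, filter_depth=c.filter_depth)
                 for c in tiny_clients]
        s2, h2 = run_federated(fresh, spec, rounds=3, eta=1.0, seed=21)
        assert s1.theta.equals(s2.theta)
        np.testing.assert_array_equal(s1.h, s2.h)
        assert h1 == h2

    def test_client_order_does_not_change_run(self, tiny_clients):
        spec = _spec()
        s1, _ = run_federated(tiny_clients, spec, rounds=2, eta=1.0, seed=3)
        fresh = [ClientState(client_id=c.client_id, data=c.data, beta=c.beta,
                             batch_size=c.batch_size, filter_depth=c.filter_depth)
                 for c in reversed(tiny_clients)]
        s2, _ = run_federated(fresh, spec, rounds=2, eta=1.0, seed=3)
        assert s1.theta.equals(s2.theta)
        np.testing.assert_array_equal(s1.h, s2.h)


class TestFedAvg:
    def test_heterogeneous_dimensions_hard_error(self, tiny_clients):
        from dataclasses import replace
        a, b = tiny_clients
        b.data = replace(b.data, X=b.data.X[:, :7],
                         feature_names=b.data.feature_names[:7])
        spec = ModelSpec(kind="feedforward", input_dim=10, hidden_dim=8,
                         output_dim=1)
        with pytest.raises(ProtocolError, match="harmonise"):
            run_fedavg(tiny_clients, spec, rounds=1, seed=0)

    def test_runs_on_identical_views(self, tiny_clients):
        spec = ModelSpec(kind="feedforward", input_dim=10, hidden_dim=8,
                         output_dim=1)
        theta, history = run_fedavg(tiny_clients, spec, rounds=2, eta=1.0, seed=0)
        assert len(history) == 2
        assert np.isfinite(history[-1]["mean_train_loss"])

    def test_model_dim_must_match_view(self, tiny_clients):
        spec = _spec(K=6)
        with pytest.raises(ProtocolError, match="input dimension"):
            run_fedavg(tiny_clients, spec, rounds=1, seed=0)


class TestStandaloneAndPersonalize:
    def test_zero_epochs_returns_initialisation(self, tiny_clients):
        spec = _spec()
        m = standalone_train(tiny_clients[0], spec, epochs=0, with_filtering=True,
                             seed=9)
        ref = init_global_state(spec, 9)
        assert m.theta.equals(ref.theta)
        np.testing.assert_array_equal(m.h, ref.h)

    def test_input_dims_with_and_without_filtering(self, tiny_clients):
        c = tiny_clients[0]
        plain = standalone_train(
            c, ModelSpec(kind="feedforward", input_dim=10, hidden_dim=8,
                         output_dim=1), epochs=1, seed=0)
        filt = standalone_train(c, _spec(K=6), epochs=1, with_filtering=True,
                                seed=0)
        assert plain.theta["W1"].shape[0] == 10   # native view dimension
        assert filt.theta["W1"].shape[0] == 6     # knowledge dimension
        assert filt.stack is not None and plain.stack is None

    def test_separable_toy_data_reaches_high_auroc(self):
        from sklearn.metrics import roc_auc_score
        from fedfilter.synthetic import ClientDataset, split_dataset

        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([(2 * y - 1) * 2.0 + rng.normal(size=n),
                             rng.normal(size=n)])
        ds = split_dataset(ClientDataset(client_id="t", X=X, y=y,
                                         feature_names=["s", "n"]), seed=1)
        client = ClientState(client_id="t", data=ds, batch_size=32,
                             filter_depth=1)
        spec = _spec(K=4)
        m = standalone_train(client, spec, epochs=60, with_filtering=True, seed=0)
        ti = ds.split_indices("test")
        p = m.predict(spec, ds.X[ti])[:, 0]
        assert roc_auc_score(ds.y[ti], p) > 0.9

    def test_personalize_zero_epochs_keeps_global(self, tiny_clients):
        spec = _spec()
        state, _ = run_federated(tiny_clients, spec, rounds=1, eta=1.0, seed=0)
        m = personalize(state, tiny_clients[0], spec, epochs=0)
        assert m.theta.equals(state.theta)
        np.testing.assert_array_equal(m.h, state.h)

    def test_personalize_reduces_training_loss_on_average(self, tiny_clients):
        from fedfilter.compose import composed_loss_grads
        spec = _spec()
        diffs = []
        for seed in range(4):
            state, _ = run_federated(tiny_clients, spec, rounds=2, eta=1.0,
                                     seed=seed)
            c = tiny_clients[0]
            idx = c.data.split_indices("train")
            before, *_ = composed_loss_grads(state.theta, spec, c.data.X[idx],
                                             c.data.y[idx], h=state.h,
                                             stack=c.filter_stack)
            m = personalize(state, c, spec, epochs=3, seed=seed,
                            early_stopping=False)
            after, *_ = composed_loss_grads(m.theta, spec, c.data.X[idx],
                                            c.data.y[idx], h=m.h, stack=m.stack)
            diffs.append(before - after)
        assert np.mean(diffs) > 0

    def test_personalize_isolation_between_clients(self, tiny_clients):
        spec = _spec()
        state, _ = run_federated(tiny_clients, spec, rounds=1, eta=1.0, seed=0)
        a, b = tiny_clients
        phi_b = b.filter_stack.to_paramdict().copy()
        personalize(state, a, spec, epochs=2)
        assert b.filter_stack.to_paramdict().equals(phi_b)
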