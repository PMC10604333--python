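"""Aggregation arithmetic, federation dynamics and the data-privacy contract."""

import numpy as np
import pytest

from histofed.cae import build_cae, train_local
from histofed.federation import (
    ClientSpec,
    FedAdagradState,
    FederationConfig,
    FederationError,
    SchemaMismatchError,
    client_rng,
    fedadagrad_aggregate,
    fedavg_aggregate,
    run_federation,
)
from histofed.types import ModelWeights, PatchImage

from conftest import micro_config


def _mw(*scalars, shape=(2, 2)):
    return ModelWeights({f"t{i}": np.full(shape, s, dtype=float)
                         for i, s in enumerate(scalars)})


_SHAPES = [(2, 3), (4,), (3, 3)]


def _random_weights(rng):
    return ModelWeights({
        f"layer{i}/w": rng.standard_normal(shape) for i, shape in enumerate(_SHAPES)
    })


def _patches(n, seed):
    rng = np.random.default_rng(seed)
    return [PatchImage(rng.uniform(0, 1, (8, 8, 3)), patch_id=f"q{seed}-{i}")
            for i in range(n)]


class TestFedAvg:
    def test_single_update_returned_unchanged(self, rng):
        w = _random_weights(rng)
        out = fedavg_aggregate([(w, 17)])
        for name in w.names():
            np.testing.assert_array_equal(out[name], w[name])

    def test_opposite_weights_cancel(self):
        w = _mw(1.5, -2.0)
        neg = ModelWeights({k: -v for k, v in w.entries.items()})
        out = fedavg_aggregate([(w, 3), (neg, 3)])
        for name in out.names():
            np.testing.assert_array_equal(out[name], np.zeros((2, 2)))

    def test_weighted_mean_arithmetic(self):
        updates = [(_mw(3.0), 1), (_mw(6.0), 2), (_mw(9.0), 3)]
        out = fedavg_aggregate(updates)
        np.testing.assert_allclose(out["t0"], 7.0)  # (3 + 12 + 27) / 6

    def test_matches_independent_weighted_mean(self, rng):
        """Oracle: np.average over stacked tensors with sample-count weights."""
        for _ in range(30):
            m = int(rng.integers(1, 6))
            shapes = [(int(rng.integers(1, 5)), int(rng.integers(1, 5)))
                      for _ in range(3)]
            ns = [int(rng.integers(1, 100)) for _ in range(m)]
            ws = [
                ModelWeights({f"t{i}": rng.standard_normal(s)
                              for i, s in enumerate(shapes)})
                for _ in range(m)
            ]
            out = fedavg_aggregate(list(zip(ws, ns)))
            for i in range(3):
                expected = np.average([w[f"t{i}"] for w in ws], axis=0, weights=ns)
                np.testing.assert_allclose(out[f"t{i}"], expected, rtol=1e-12)

    def test_aggregate_lies_within_client_envelope(self, rng):
        ws = [_random_weights(np.random.default_rng(s)) for s in range(4)]
        out = fedavg_aggregate([(w, i + 1) for i, w in enumerate(ws)])
        for name in out.names():
            stack = np.stack([w[name] for w in ws])
            assert np.all(out[name] >= stack.min(axis=0) - 1e-12)
            assert np.all(out[name] <= stack.max(axis=0) + 1e-12)

    def test_client_order_does_not_matter(self, rng):
        ws = [(_random_weights(np.random.default_rng(s)), s + 1) for s in range(4)]
        a = fedavg_aggregate(ws)
        b = fedavg_aggregate(ws[::-1])
        for name in a.names():
            np.testing.assert_allclose(a[name], b[name], rtol=1e-12)

    def test_schema_mismatch_names_offending_client(self):
        a = _mw(1.0)
        b = ModelWeights({"other": np.ones(3)})
        with pytest.raises(SchemaMismatchError, match="uva"):
            fedavg_aggregate([(a, 1), (b, 1)], client_ids=["ty", "uva"])


class TestFedAdagrad:
    def test_zero_delta_is_fixed_point(self):
        g = _mw(2.0)
        state = FedAdagradState(g, tau=1e-3)
        acc_before = {k: v.copy() for k, v in state.accumulators.items()}
        out, state = fedadagrad_aggregate(state, g, [(g.copy(), 5)], server_lr=0.1)
        for name in g.names():
            np.testing.assert_array_equal(out[name], g[name])
            np.testing.assert_array_equal(state.accumulators[name], acc_before[name])

    def test_single_scalar_update_hand_computed(self):
        """tau=1, lr=1, delta=1: v = 1+1, step = 1/(sqrt(2)+1)."""
        g = _mw(0.0, shape=(1,))
        state = FedAdagradState(g, tau=1.0)
        upd = _mw(1.0, shape=(1,))
        out, _ = fedadagrad_aggregate(state, g, [(upd, 1)], server_lr=1.0)
        assert out["t0"][0] == pytest.approx(1.0 / (np.sqrt(2.0) + 1.0), rel=1e-12)

    def test_large_tau_limit_recovers_fedavg_step(self, rng):
        """With a huge frozen-scale accumulator and lr = 2*tau, the adaptive
        step reduces to the plain weighted-mean delta."""
        g = _random_weights(rng)
        upds = [(_random_weights(np.random.default_rng(s)), s + 1) for s in range(3)]
        tau = 1e8
        state = FedAdagradState(g, tau=tau)
        out, _ = fedadagrad_aggregate(state, g, upds, server_lr=2 * tau)
        mean = fedavg_aggregate(upds)
        for name in g.names():
            np.testing.assert_allclose(out[name], mean[name], rtol=1e-9, atol=1e-9)


class TestRunFederation:
    def _clients(self, n, samples=4, epochs=2, lr=0.05):
        return [
            ClientSpec(f"c{i}", _patches(samples, seed=i), epochs=epochs,
                       batch_size=2, lr=lr)
            for i in range(n)
        ]

    def test_single_client_federation_collapses_to_local_training(self):
        """M=1: R rounds of E epochs is bit-identical to R*E local epochs."""
        cfg = micro_config()
        data = _patches(4, seed=0)
        clients = [ClientSpec("solo", data, epochs=3, batch_size=2, lr=0.05)]
        fed_w, logs = run_federation(
            FederationConfig(rounds=2, seed=5), clients,
            lambda: build_cae(cfg, seed=5),
        )
        model = build_cae(cfg, seed=5)
        local_w, _ = train_local(model, model.get_weights(), data, epochs=6,
                                 batch_size=2, lr=0.05, rng=client_rng(5, 0))
        assert fed_w.schema_id == local_w.schema_id
        for name in fed_w.names():
            np.testing.assert_array_equal(fed_w[name], local_w[name])

    def test_zero_effective_step_preserves_initial_weights(self):
        cfg = micro_config()
        clients = [ClientSpec("c0", _patches(4, seed=0), epochs=1, batch_size=2,
                              lr=1e-300)]
        model = build_cae(cfg, seed=1)
        w0 = model.get_weights()
        # lr must be > 0 per the client contract; an effectively-zero rate and
        # an explicit zero-rate train_local both leave weights untouched
        w1, _ = train_local(model, w0, clients[0].data, 1, 2, lr=0.0, seed=0)
        for name in w0.names():
            np.testing.assert_array_equal(w0[name], w1[name])

    def test_identical_clients_aggregate_to_either_update(self):
        """Symmetry: equal data, seeds and n make FedAvg a no-op mixture."""
        cfg = micro_config()
        data = _patches(4, seed=9)
        model = build_cae(cfg, seed=2)
        w0 = model.get_weights()
        wa, _ = train_local(model, w0, data, 2, 2, 0.05, seed=77)
        wb, _ = train_local(model, w0, data, 2, 2, 0.05, seed=77)
        agg = fedavg_aggregate([(wa, 4), (wb, 4)])
        for name in wa.names():
            np.testing.assert_array_equal(wa[name], wb[name])
            np.testing.assert_allclose(agg[name], wa[name], rtol=1e-15)

    def test_round_logs_record_sampled_participants(self):
        clients = self._clients(4, samples=2, epochs=1)
        _, logs = run_federation(
            FederationConfig(rounds=3, sample_fraction=0.5, seed=3), clients,
            lambda: build_cae(micro_config(), seed=3),
        )
        for log in logs:
            assert len(log.client_ids) == 2  # ceil(0.5 * 4)
            assert set(log.client_ids) <= {c.client_id for c in clients}
            assert len(log.client_losses) == 2

    def test_heterogeneous_local_epochs_are_respected(self):
        clients = [
            ClientSpec("fast", _patches(4, seed=0), epochs=1, batch_size=2, lr=0.01),
            ClientSpec("slow", _patches(4, seed=1), epochs=3, batch_size=2, lr=0.01),
        ]
        _, logs = run_federation(
            FederationConfig(rounds=1, seed=0), clients,
            lambda: build_cae(micro_config(), seed=0),
        )
        assert len(logs[0].client_loss_traces["fast"]) == 1
        assert len(logs[0].client_loss_traces["slow"]) == 3

    def test_failing_client_aborts_round_with_context(self):
        bad = ClientSpec("broken", _patches(4, seed=0), epochs=1, batch_size=2,
                         lr=0.01)
        bad.data = []  # corrupt after validation to force a mid-round failure
        with pytest.raises(FederationError, match="round 1.*broken"):
            run_federation(
                FederationConfig(rounds=1, seed=0), [bad],
                lambda: build_cae(micro_config(), seed=0),
            )

    def test_clients_only_expose_weights_never_pixels(self):
        """Each client's images are read only during its own local update."""
        accesses: dict[str, int] = {"a": 0, "b": 0}

        class Tracking(list):
            def __init__(self, items, key):
                super().__init__(items)
                self.key = key

            def __iter__(self):
                accesses[self.key] += 1
                return super().__iter__()

        clients = [
            ClientSpec("a", Tracking(_patches(4, seed=0), "a"), epochs=1,
                       batch_size=2, lr=0.01),
            ClientSpec("b", Tracking(_patches(4, seed=1), "b"), epochs=1,
                       batch_size=2, lr=0.01),
        ]
        final, _ = run_federation(
            FederationConfig(rounds=2, seed=0), clients,
            lambda: build_cae(micro_config(), seed=0),
        )
        # one read per round per client, and the server output is weights only
        assert accesses == {"a": 2, "b": 2}
        assert isinstance(final, ModelWeights)
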