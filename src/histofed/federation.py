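"""Single-process simulation of federated auto-encoder training.

Each communication round the server broadcasts the current global weights to
a (possibly sampled) set of clients; every client runs its own local SGD
epochs on its private patches and returns only the updated weights; the
server aggregates the returned weight sets.  Aggregation is sample-count
weighted averaging (FedAvg),

    w_{r+1} = sum_m (n_m / n) w^m_{r+1},    n = sum_m n_m,

or, alternatively, server-side adaptive aggregation (FedAdagrad), which
treats the weighted-mean client delta as a pseudo-gradient and rescales it
by an accumulated squared-magnitude statistic.

The simulation is sequential in one process, but the data-privacy contract
of a real deployment is preserved: a client's images are touched only inside
its own local update, and only :class:`~histofed.types.ModelWeights` cross
the client/server boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cae import CAE, train_local
from .types import ModelWeights, PatchImage


class FederationError(RuntimeError):
    """A client failed mid-round; no partial aggregation is performed."""


class SchemaMismatchError(ValueError):
    """Weight sets with different parameter schemas cannot be aggregated."""


@dataclass
class ClientSpec:
    """One data-holding site and its local training hyperparameters."""

    client_id: str
    data: Sequence[PatchImage]
    epochs: int = 1
    batch_size: int = 32
    lr: float = 1e-6  # local learning rate; the printed default

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError(f"client {self.client_id!r} has no samples")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError(f"client {self.client_id!r}: epochs and batch size must be >= 1")
        if self.lr <= 0:
            raise ValueError(f"client {self.client_id!r}: learning rate must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.data)


@dataclass
class FederationConfig:
    rounds: int = 2
    sample_fraction: float = 1.0
    strategy: str = "fedavg"  # or "fedadagrad"
    seed: int = 0
    server_lr: float = 0.1  # FedAdagrad only
    server_tau: float = 1e-3  # FedAdagrad adaptivity floor

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must lie in (0, 1]")
        if self.strategy not in ("fedavg", "fedadagrad"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class RoundLog:
    round_index: int
    client_ids: list[str]
    client_losses: dict[str, float]  # final local epoch loss per client
    weight_norm: float
    client_loss_traces: dict[str, list[float]] = field(default_factory=dict)


def _check_schemas(updates: Sequence[tuple[ModelWeights, int]],
                   client_ids: Sequence[str] | None = None) -> None:
    if not updates:
        raise ValueError("need at least one client update to aggregate")
    ref = updates[0][0].schema_id
    for i, (w, n) in enumerate(updates):
        if n < 1:
            raise ValueError(f"update {i}: sample count must be >= 1")
        if w.schema_id != ref:
            who = client_ids[i] if client_ids else f"index {i}"
            raise SchemaMismatchError(
                f"client {who} submitted weights with schema {w.schema_id}, "
                f"expected {ref}"
            )


def fedavg_aggregate(
    updates: Sequence[tuple[ModelWeights, int]],
    client_ids: Sequence[str] | None = None,
) -> ModelWeights:
    """Sample-count weighted mean of client weight sets.

    Every tensor of the result equals ``sum_m (n_m / n) w_m`` with
    ``n = sum_m n_m``; a single update is returned unchanged (bit-exactly).
    """
    _check_schemas(updates, client_ids)
    n_total = sum(n for _, n in updates)
    out: dict[str, np.ndarray] = {}
    for name in updates[0][0].names():
        acc = np.zeros_like(updates[0][0][name])
        for w, n in updates:
            acc += (n / n_total) * w[name]
        out[name] = acc
    return ModelWeights(out)


class FedAdagradState:
    """Per-tensor squared-delta accumulators, initialised to tau**2."""

    def __init__(self, template: ModelWeights, tau: float):
        self.tau = tau
        self.accumulators = {
            name: np.full_like(template[name], tau * tau) for name in template.names()
        }


def fedadagrad_aggregate(
    state: FedAdagradState,
    global_weights: ModelWeights,
    updates: Sequence[tuple[ModelWeights, int]],
    server_lr: float,
    client_ids: Sequence[str] | None = None,
) -> tuple[ModelWeights, FedAdagradState]:
    """Adaptive server aggregation.

    The weighted-mean client delta acts as pseudo-gradient Delta; per tensor,

        v <- v + Delta**2
        w <- w + eta_s * Delta / (sqrt(v) + tau)

    with v initialised to tau**2.  Zero deltas leave both the weights and the
    accumulator state unchanged.
    """
    _check_schemas(updates, client_ids)
    mean = fedavg_aggregate(updates, client_ids)
    if mean.schema_id != global_weights.schema_id:
        raise SchemaMismatchError("client updates do not match the global weight schema")
    out: dict[str, np.ndarray] = {}
    for name in global_weights.names():
        delta = mean[name] - global_weights[name]
        v = state.accumulators[name]
        v += delta * delta
        out[name] = global_weights[name] + server_lr * delta / (np.sqrt(v) + state.tau)
    return ModelWeights(out), state


def client_rng(seed: int, client_index: int) -> np.random.Generator:
    """The shuffle stream run_federation assigns to client ``client_index``.

    Exposed so that a plain local run can reproduce a single-client
    federation exactly: train_local with ``rng=client_rng(seed, 0)`` for
    R*E epochs equals the R-round, E-epoch federated trajectory.
    """
    return np.random.default_rng([seed, client_index])


def run_federation(
    config: FederationConfig,
    clients: Sequence[ClientSpec],
    model_builder: Callable[[], CAE],
    initial_weights: ModelWeights | None = None,
    checkpoint_callback: Callable[[int, ModelWeights], None] | None = None,
) -> tuple[ModelWeights, list[RoundLog]]:
    """Run the full broadcast / local-update / aggregate loop.

    ``model_builder`` must return a freshly built (seeded) model; it is
    called once and reused for every client update, with the broadcast
    weights loaded before each update, so clients share structure but never
    share data.  Client sampling, when ``sample_fraction < 1``, is drawn
    without replacement from a dedicated seeded stream.
    """
    if not clients:
        raise ValueError("need at least one client")
    ids = [c.client_id for c in clients]
    if len(set(ids)) != len(ids):
        raise ValueError("client_ids must be unique")

    model = model_builder()
    global_weights = initial_weights if initial_weights is not None else model.get_weights()

    m = len(clients)
    n_sampled = math.ceil(config.sample_fraction * m)
    sampler = np.random.default_rng([config.seed, 999_983])
    rngs = {c.client_id: client_rng(config.seed, i) for i, c in enumerate(clients)}

    logs: list[RoundLog] = []
    for r in range(1, config.rounds + 1):
        if n_sampled == m:
            chosen = list(range(m))
        else:
            chosen = sorted(sampler.choice(m, size=n_sampled, replace=False))
        updates: list[tuple[ModelWeights, int]] = []
        losses: dict[str, float] = {}
        traces: dict[str, list[float]] = {}
        for i in chosen:
            spec = clients[i]
            try:
                w, trace = train_local(
                    model,
                    global_weights,
                    spec.data,
                    epochs=spec.epochs,
                    batch_size=spec.batch_size,
                    lr=spec.lr,
                    rng=rngs[spec.client_id],
                )
            except Exception as exc:
                raise FederationError(
                    f"round {r}: client {spec.client_id!r} failed: {exc}"
                ) from exc
            updates.append((w, spec.n_samples))
            losses[spec.client_id] = trace[-1]
            traces[spec.client_id] = trace

        chosen_ids = [clients[i].client_id for i in chosen]
        if config.strategy == "fedavg":
            global_weights = fedavg_aggregate(updates, chosen_ids)
        else:
            if r == 1:
                adagrad_state = FedAdagradState(global_weights, config.server_tau)
            global_weights, adagrad_state = fedadagrad_aggregate(
                adagrad_state, global_weights, updates, config.server_lr, chosen_ids
            )
        if checkpoint_callback is not None:
            checkpoint_callback(r, global_weights)
        logs.append(
            RoundLog(
                round_index=r,
                client_ids=chosen_ids,
                client_losses=losses,
                weight_norm=global_weights.norm(),
                client_loss_traces=traces,
            )
        )
    return global_weights, logs
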