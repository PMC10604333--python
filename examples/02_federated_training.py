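"""Train the auto-encoder across two simulated clients with FedAvg.

Each round: the server broadcasts weights, every client runs 5 local SGD
epochs on its private patches, and the server averages the returned weights
by sample count.  The printed per-client reconstruction losses fall across
rounds; only weights ever cross the client boundary.
"""

from histofed import (
    CAEConfig,
    ClientSpec,
    FederationConfig,
    SynthSpec,
    build_cae,
    generate_client_datasets,
    run_federation,
)

spec = SynthSpec(seed=1)  # two clients, 32 px patches, imbalanced classes
data = generate_client_datasets(spec)
cfg = CAEConfig.reduced(latent_dim=16, input_size=32, seed=1)
clients = [
    ClientSpec(cid, data[cid]["train"], epochs=5, batch_size=8, lr=0.01)
    for cid in spec.client_ids
]

final, logs = run_federation(
    FederationConfig(rounds=2, strategy="fedavg", seed=1),
    clients,
    lambda: build_cae(cfg, seed=1),
)

for log in logs:
    losses = ", ".join(f"{c}: {v:.4f}" for c, v in log.client_losses.items())
    print(f"round {log.round_index} | final local MSE  {losses}")
print(f"global model: {final.n_parameters} parameters, "
      f"schema {final.schema_id}")
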