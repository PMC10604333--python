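"""Index a client's patches, retrieve top-5 neighbours, and score ACC@5.

The encoder of the federated model embeds every training/validation patch
into a feature dictionary; each held-out test patch then queries it with an
exhaustive Euclidean search.  ACC@5 counts a query as correct when any of
its five nearest neighbours shares the query's benign/malignant label.
"""

from histofed import (
    CAEConfig,
    ClientSpec,
    FederationConfig,
    SynthSpec,
    build_cae,
    build_index,
    evaluate,
    generate_client_datasets,
    query,
    run_federation,
)

spec = SynthSpec(seed=1)
data = generate_client_datasets(spec)
cfg = CAEConfig.reduced(latent_dim=16, input_size=32, seed=1)
clients = [
    ClientSpec(cid, data[cid]["train"], epochs=5, batch_size=8, lr=0.01)
    for cid in spec.client_ids
]
final, _ = run_federation(
    FederationConfig(rounds=2, seed=1), clients, lambda: build_cae(cfg, seed=1)
)
model = build_cae(cfg, seed=1)
model.set_weights(final)

for cid in spec.client_ids:
    index = build_index(model, data[cid]["train"] + data[cid]["val"])
    queries = data[cid]["test"]
    results = [query(index, model, q, k=5) for q in queries]
    report = evaluate(queries, results, k=5)
    print(
        f"{cid}: N={report.n_queries}  ACC@5={report.acc_at_k:.3f}  "
        f"precision={report.precision:.3f}  F1={report.f1:.3f}"
    )
    print(f"  confusion matrix (rows true, cols predicted):\n"
          f"  {report.confusion_matrix.tolist()}")

example = results[0]
print(f"\nfirst query of {cid} -> nearest hits:")
for rank, hit in enumerate(example.hits, 1):
    print(f"  {rank}. {hit.patch_id}  distance {hit.distance:.3f}  "
          f"label {hit.label}")
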