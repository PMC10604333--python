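"""Query at one magnification, retrieve neighbours at all four.

Four simulated sites each hold patches at a single magnification (40x to
400x).  A 40x query is embedded once and searched independently in each
site's per-magnification index, so a pathologist with a low-magnification
scanner still sees similar cases at higher magnifications.
"""

from histofed import (
    CAEConfig,
    build_cae,
    build_index,
    generate_client_datasets,
    query_cross_magnification,
)
from histofed.synthetic import SynthSpec

spec = SynthSpec.four_magnifications(seed=3, n_train=12, n_val=4, n_test=4)
data = generate_client_datasets(spec)
model = build_cae(CAEConfig.reduced(latent_dim=16, input_size=32, seed=3), seed=3)

indexes = {
    spec.magnifications[cid]: build_index(model, data[cid]["train"] + data[cid]["val"])
    for cid in spec.client_ids
}
q = data["client_40x"]["test"][0]
print(f"query {q.patch_id} (label {q.label}, {q.magnification}x)")
for mag, result in query_cross_magnification(indexes, model, q, k=3).items():
    hits = ", ".join(f"{h.patch_id} (d={h.distance:.2f}, label {h.label})"
                     for h in result.hits)
    print(f"  top-3 at {mag:3d}x: {hits}")
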