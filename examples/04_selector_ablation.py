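"""Compare OOD scores as client-side selectors.

Each client scores every proxy sample; AUROC measures how well the
score separates the client's correct predictions (in-distribution
samples) from incorrect ones.  Density-ratio estimation succeeds; the
confidence and energy baselines fail here because one-class ReLU models
are most confident precisely far from their training data.
"""

import selectivefd as sfd

ds = sfd.make_blobs(C=10, per_class=100, d=8, separation=8, noise_sd=1, seed=7)
part = sfd.partition_clients(ds, K=10, classes_per_client=1, seed=3)
cfg = sfd.FederationConfig(K=10, C=10, T=8, label_mode="hard", proxy_batch=100, seed=1)

print(f"{'selector':15s} {'mean AUROC':>10s} {'final accuracy':>15s}")
for r in sfd.run_selector_ablation(ds, part, cfg):
    print(f"{r.selector_name:15s} {r.mean_auroc:10.3f} {r.final_accuracy:14.1f}%")
print("AUROC 0.5 = random; below 0.5 = systematically misleading score.")
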