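"""Sweep the two selection thresholds.

tau_client raises the bar for sharing a prediction (higher = fewer,
cleaner shares); tau_server caps the ambiguity of returned ensembles
(lower = stricter).  p_proxy is the fraction of the proxy pool that
carried knowledge over the whole run.
"""

import selectivefd as sfd

ds = sfd.make_blobs(C=10, per_class=100, d=8, separation=8, noise_sd=1, seed=7)
part = sfd.partition_clients(ds, K=10, classes_per_client=1, seed=3)
cfg = sfd.FederationConfig(K=10, C=10, T=8, label_mode="hard", proxy_batch=100, seed=1)

table = sfd.run_threshold_sweep(
    ds, part, cfg,
    tau_client_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    tau_server_grid=(0.4, 0.8, 1.2, 1.6, 2.0),
)
print(table.to_string(index=False))
print("Extremes hurt: tau_client=0 admits misleading predictions,")
print("tau_client=1 filters nearly everything out.")
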