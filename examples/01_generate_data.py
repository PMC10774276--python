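"""Generate a synthetic multi-class dataset and a federated non-IID split.

Ten Gaussian class blobs in 8 dimensions, centroids 8 noise-sd apart,
split into: a class-balanced test set, a stratified unlabeled proxy
pool, and 10 single-class clients (strong non-IID), each with a
validation slice for selector calibration.
"""

import numpy as np

import selectivefd as sfd

ds = sfd.make_blobs(C=10, per_class=100, d=8, separation=8, noise_sd=1, seed=7)
part = sfd.partition_clients(ds, K=10, classes_per_client=1, seed=3)

print(f"dataset: {ds.n_samples} samples, {ds.C} classes, {ds.dim} features")
print(f"test set: {len(part.test)} samples, "
      f"class counts {np.bincount(ds.labels[part.test]).tolist()}")
print(f"proxy pool: {len(part.proxy)} unlabeled samples")
for k in range(3):
    labels = set(int(c) for c in ds.labels[part.client_train[k]])
    print(f"client {k}: {len(part.client_train[k])} train / "
          f"{len(part.client_val[k])} val samples, classes {sorted(labels)}")
print("...")
print("Each client sees exactly one class; the proxy pool spans all ten —")
print("the regime in which unselected prediction sharing is misleading.")
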