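"""Synthetic labeled datasets and federated splits.

The generator produces ``C`` isotropic Gaussian class blobs whose centroids
are laid out on scaled coordinate axes so that any pair is at least
``separation * noise_sd`` apart.  Partitioning emulates the federated
settings used throughout the package: strong non-IID (one class per
client), weak non-IID (two classes per client) and IID clients, plus a
class-balanced held-out test set, a stratified unlabeled proxy pool and a
per-client validation split used for selector calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "FederatedPartition",
    "make_blobs",
    "partition_clients",
    "proxy_view",
    "save_csv",
    "load_csv",
]


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix plus integer class labels for ``C`` classes."""

    features: np.ndarray  # (n_samples, d)
    labels: np.ndarray  # (n_samples,) ints in [0, C)
    C: int
    seed: int | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("features must be (n, d) and labels (n,)")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        if y.size == 0:
            raise ValueError("dataset must be non-empty")
        if y.min() < 0 or y.max() >= self.C:
            raise ValueError(f"labels must lie in [0, {self.C})")
        if len(np.unique(y)) != self.C:
            raise ValueError("every class must have at least one sample")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(int))

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class FederatedPartition:
    """Disjoint index sets over a parent :class:`LabeledDataset`.

    ``proxy`` indices are treated as unlabeled by the training pipeline;
    their ground-truth labels are reachable only through the evaluation
    label oracle.
    """

    client_train: list[np.ndarray]
    client_val: list[np.ndarray]
    proxy: np.ndarray
    test: np.ndarray
    classes_per_client: int | str
    n_samples: int = field(default=0)

    def __post_init__(self) -> None:
        groups = (
            list(self.client_train)
            + list(self.client_val)
            + [self.proxy, self.test]
        )
        all_idx = np.concatenate([np.asarray(g, dtype=int) for g in groups])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("index families must be pairwise disjoint")
        if all_idx.min() < 0 or (self.n_samples and all_idx.max() >= self.n_samples):
            raise ValueError("indices out of range for the parent dataset")

    @property
    def K(self) -> int:
        return len(self.client_train)


def _centroids(C: int, d: int, spacing: float) -> np.ndarray:
    """C points with pairwise distances >= spacing, on scaled axis directions."""
    centers = np.zeros((C, d))
    for c in range(C):
        axis = c % d
        level = c // d + 1
        centers[c, axis] = spacing * level
    return centers


def make_blobs(
    C: int,
    per_class: int,
    d: int = 2,
    separation: float = 8.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> LabeledDataset:
    """Draw ``C * per_class`` points from isotropic Gaussian class blobs.

    Class ``c`` is sampled around a distinct centroid; centroids are at
    least ``separation * noise_sd`` apart, so ``separation`` directly
    controls class overlap in units of the noise scale.
    """
    if C < 1 or per_class < 1 or d < 1:
        raise ValueError("C, per_class and d must be positive")
    if separation <= 0 or noise_sd <= 0:
        raise ValueError("separation and noise_sd must be positive")
    rng = np.random.default_rng(seed)
    centers = _centroids(C, d, separation * noise_sd)
    X = np.empty((C * per_class, d))
    y = np.empty(C * per_class, dtype=int)
    for c in range(C):
        sl = slice(c * per_class, (c + 1) * per_class)
        X[sl] = centers[c] + rng.normal(scale=noise_sd, size=(per_class, d))
        y[sl] = c
    return LabeledDataset(features=X, labels=y, C=C, seed=seed)


def blob_centroids(C: int, d: int, separation: float = 8.0, noise_sd: float = 1.0) -> np.ndarray:
    """The exact centroid layout :func:`make_blobs` uses (for oracle checks)."""
    return _centroids(C, d, separation * noise_sd)


def _owned_classes(k: int, C: int, classes_per_client: int | str) -> list[int]:
    if classes_per_client == "all":
        return list(range(C))
    if classes_per_client == 1:
        return [k % C]
    if classes_per_client == 2:
        return [k % C, (k + 1) % C]
    raise ValueError("classes_per_client must be 1, 2 or 'all'")


def partition_clients(
    ds: LabeledDataset,
    K: int,
    classes_per_client: int | str,
    val_fraction: float = 0.2,
    proxy_fraction: float = 0.15,
    seed: int = 0,
    test_fraction: float = 0.15,
) -> FederatedPartition:
    """Split a dataset into per-client train/val, proxy and test index sets.

    The test set is drawn class-balanced first, then a stratified proxy
    pool of ``proxy_fraction`` of each class's remaining training data,
    then client pools by the non-IID rule:

    - strong non-IID (``classes_per_client=1``): client ``k`` owns class
      ``k mod C`` (requires ``K >= C`` so every class is owned);
    - weak non-IID (``classes_per_client=2``): client ``k`` owns classes
      ``{k mod C, (k+1) mod C}``;
    - IID (``"all"``): every class is spread round-robin over all clients.

    Each client reserves ``round(val_fraction * |client data|)`` (at least
    one) samples as a validation set for threshold calibration.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (0.0 < val_fraction < 1.0) or not (0.0 < proxy_fraction < 1.0):
        raise ValueError("val_fraction and proxy_fraction must lie in (0, 1)")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    if classes_per_client == 1 and K < ds.C:
        raise ValueError(
            "classes_per_client=1 requires K >= C so every class is owned"
        )
    rng = np.random.default_rng(seed)

    by_class = [np.flatnonzero(ds.labels == c) for c in range(ds.C)]
    test_per_class = min(int(round(test_fraction * len(idx))) for idx in by_class)
    test_per_class = max(test_per_class, 1)

    test_parts, proxy_parts, pool_by_class = [], [], []
    for c in range(ds.C):
        idx = rng.permutation(by_class[c])
        test_parts.append(idx[:test_per_class])
        rest = idx[test_per_class:]
        n_proxy = int(round(proxy_fraction * len(rest)))
        proxy_parts.append(rest[:n_proxy])
        pool_by_class.append(rest[n_proxy:])
        if len(pool_by_class[-1]) == 0:
            raise ValueError(f"class {c} has no samples left for clients")

    owners: list[list[int]] = [[] for _ in range(ds.C)]
    for k in range(K):
        for c in _owned_classes(k, ds.C, classes_per_client):
            owners[c].append(k)

    client_pool: list[list[np.ndarray]] = [[] for _ in range(K)]
    for c in range(ds.C):
        if not owners[c]:
            raise ValueError(f"class {c} is owned by no client")
        chunks = np.array_split(rng.permutation(pool_by_class[c]), len(owners[c]))
        for k, chunk in zip(owners[c], chunks):
            if len(chunk) == 0:
                raise ValueError(f"class {c} pool too small for its {len(owners[c])} owners")
            client_pool[k].append(chunk)

    client_train, client_val = [], []
    for k in range(K):
        idx = rng.permutation(np.concatenate(client_pool[k]))
        n_val = max(1, int(round(val_fraction * len(idx))))
        if n_val >= len(idx):
            raise ValueError(f"client {k} would have an empty training set")
        client_val.append(np.sort(idx[:n_val]))
        client_train.append(np.sort(idx[n_val:]))

    return FederatedPartition(
        client_train=client_train,
        client_val=client_val,
        proxy=np.sort(np.concatenate(proxy_parts)),
        test=np.sort(np.concatenate(test_parts)),
        classes_per_client=classes_per_client,
        n_samples=ds.n_samples,
    )


def proxy_view(ds: LabeledDataset, part: FederatedPartition) -> tuple[np.ndarray, np.ndarray]:
    """Unlabeled view of the proxy pool: (features, stable sample IDs).

    IDs are positions 0..m-1 into the (sorted) proxy index list and are
    stable across rounds.  No label channel is exposed; evaluation code
    uses :func:`selectivefd.evaluation.proxy_label_oracle` instead.
    """
    features = ds.features[part.proxy]
    ids = np.arange(len(part.proxy))
    return features, ids


def save_csv(ds: LabeledDataset, path: str) -> None:
    """Write features + integer label column as headered CSV."""
    df = pd.DataFrame(ds.features, columns=[f"x{j}" for j in range(ds.dim)])
    df["label"] = ds.labels
    df.to_csv(path, index=False)


def load_csv(path: str, C: int | None = None) -> LabeledDataset:
    """Read a dataset written by :func:`save_csv` (label column last)."""
    df = pd.read_csv(path)
    y = df["label"].to_numpy(dtype=int)
    X = df.drop(columns=["label"]).to_numpy(dtype=float)
    return LabeledDataset(features=X, labels=y, C=C if C is not None else int(y.max()) + 1)
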