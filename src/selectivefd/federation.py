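"""Federated distillation rounds with selective knowledge sharing.

The protocol: each client first fits a density-ratio selector on its
private data (once, before any communication) and pretrains a local
classifier.  Every round the server draws a batch of unlabeled proxy
samples; clients predict on them, drop predictions their selector flags
as out-of-distribution, and upload the rest; the server averages the
shared predictions per sample, drops ambiguous ensembles, and returns
the survivors as distillation targets; clients then take a local
training phase followed by a distillation phase on the returned targets.

Baselines on the same tasks: independent local training (no
communication), the same loop with both selectors disabled, and FedAvg
parameter averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .classifier import MLPClassifier
from .data import FederatedPartition, LabeledDataset, proxy_view
from .density_ratio import (
    ClientThreshold,
    KulsifConfig,
    RatioModel,
    calibrate_threshold,
    evaluate_ratio,
    fit_kulsif,
    sample_uniform_reference,
)
from .selectors import (
    SelectionMask,
    aggregate,
    client_select,
    confidence_score,
    energy_score,
    one_hot,
    server_select,
)

__all__ = [
    "FederationConfig",
    "ClientState",
    "RoundLog",
    "RunResult",
    "build_clients",
    "local_train",
    "distill",
    "generate_ensemble_predictions",
    "run_selective_fd",
    "run_fd_noselect",
    "run_indep",
    "run_fedavg",
    "prediction_bytes",
]

SELECTOR_KINDS = ("density-ratio", "confidence", "energy", "none")


@dataclass(frozen=True)
class FederationConfig:
    """Knobs of a federated run; defaults match the standard setting
    (tau_client=0.25, tau_server=2, soft labels)."""

    K: int = 10
    C: int = 10
    T: int = 10
    label_mode: str = "soft"  # "hard" | "soft"
    tau_client: float = 0.25
    tau_server: float = 2.0
    local_epochs: int = 5
    distill_epochs: int = 5
    pretrain_epochs: int = 30
    proxy_batch: int = 100
    learning_rate: float = 0.05
    batch_size: int = 32
    hidden: tuple[int, ...] = (32,)
    kulsif_beta: float = 1e-3
    kulsif_bandwidth: float | str = "median-heuristic"
    reference_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 0 or self.K < 1:
            raise ValueError("need T >= 0 and K >= 1")
        if self.label_mode not in ("hard", "soft"):
            raise ValueError("label_mode must be 'hard' or 'soft'")
        if not (0.0 <= self.tau_client <= 1.0):
            raise ValueError("tau_client must lie in [0, 1]")
        if not (0.0 < self.tau_server <= 2.0):
            raise ValueError("tau_server must lie in (0, 2]")
        object.__setattr__(self, "hidden", tuple(self.hidden))


@dataclass
class ClientState:
    """One participant: local classifier, OOD selector, private index sets."""

    model: MLPClassifier
    train_idx: np.ndarray
    val_idx: np.ndarray
    ratio_model: RatioModel | None = None
    threshold: ClientThreshold | None = None
    selector_kind: str = "density-ratio"
    score_threshold: float = -np.inf  # for confidence/energy selectors

    def ood_scores(self, X: np.ndarray) -> np.ndarray:
        """Higher score = more in-distribution, for every selector kind."""
        if self.selector_kind == "density-ratio":
            return evaluate_ratio(self.ratio_model, X)
        if self.selector_kind == "confidence":
            return np.asarray(confidence_score(self.model.predict_proba(X)))
        if self.selector_kind == "energy":
            return -np.asarray(energy_score(self.model.logits(X)))
        raise ValueError(f"unknown selector kind {self.selector_kind!r}")

    def select(self, X: np.ndarray) -> SelectionMask:
        if self.selector_kind == "none":
            return SelectionMask("client", np.ones(np.atleast_2d(X).shape[0], bool))
        if self.selector_kind == "density-ratio":
            return client_select(self.threshold, self.ood_scores(X))
        return SelectionMask("client", self.ood_scores(X) >= self.score_threshold)


@dataclass
class RoundLog:
    round: int
    p_proxy_round: float  # % of drawn proxy IDs surviving both selectors
    accuracy: np.ndarray  # per-client test accuracy, %
    bytes_up: int
    bytes_down: int
    n_drawn: int = 0
    n_survivors: int = 0
    n_no_sharer: int = 0
    client_kept: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))


@dataclass
class RoundDetail:
    """Full per-round selection record, kept when ``store_details=True``."""

    ids: np.ndarray
    ensemble: np.ndarray
    sharer_count: np.ndarray
    server_kept: np.ndarray  # bool over ids


@dataclass
class RunResult:
    logs: list[RoundLog]
    clients: list[ClientState]
    config: FederationConfig
    survivor_ids: set[int] = field(default_factory=set)
    details: list[RoundDetail] = field(default_factory=list)

    @property
    def final_accuracy(self) -> float:
        return self.logs[-1].mean_accuracy if self.logs else float("nan")

    @property
    def total_bytes(self) -> tuple[int, int]:
        return (
            sum(l.bytes_up for l in self.logs),
            sum(l.bytes_down for l in self.logs),
        )


def prediction_bytes(mode: str, C: int) -> int:
    """Wire size of one shared prediction: 4-byte sample ID plus either a
    4-byte class index (hard) or C 4-byte probabilities (soft)."""
    if mode == "hard":
        return 8
    if mode == "soft":
        return 4 + 4 * C
    raise ValueError("mode must be 'hard' or 'soft'")


def build_clients(
    ds: LabeledDataset,
    part: FederatedPartition,
    config: FederationConfig,
    selector: str = "density-ratio",
) -> list[ClientState]:
    """Initialize classifiers and fit the per-client selectors.

    Density-ratio selectors are fit once here and never updated — they
    depend only on the fixed private data, not on training state.
    Shared model initialization (one weight seed for all clients) keeps
    FedAvg and the distillation runs comparable.
    """
    if selector not in SELECTOR_KINDS:
        raise ValueError(f"selector must be one of {SELECTOR_KINDS}")
    ss = np.random.SeedSequence([config.seed, 0x5E1EC7])
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2 * part.K + 1)]
    init_seed = seeds[-1]
    clients: list[ClientState] = []
    for k in range(part.K):
        model = MLPClassifier(ds.dim, config.C, hidden=config.hidden, seed=init_seed)
        model._rng = np.random.default_rng(seeds[k])  # per-client batch shuffling
        st = ClientState(
            model=model,
            train_idx=part.client_train[k],
            val_idx=part.client_val[k],
            selector_kind=selector,
        )
        if selector == "density-ratio":
            X_train = ds.features[st.train_idx]
            S_u, box = sample_uniform_reference(
                X_train,
                n_u=len(st.train_idx),
                margin=config.reference_margin,
                seed=seeds[part.K + k],
            )
            st.ratio_model = fit_kulsif(
                X_train,
                S_u,
                KulsifConfig(
                    bandwidth=config.kulsif_bandwidth, beta=config.kulsif_beta
                ),
                box=box,
            )
            st.threshold = calibrate_threshold(
                st.ratio_model, ds.features[st.val_idx], config.tau_client
            )
        clients.append(st)
    return clients


def _calibrate_score_selectors(
    ds: LabeledDataset, clients: list[ClientState], tau_client: float
) -> None:
    """Quantile-calibrate confidence/energy selectors on validation scores.

    Done after local pretraining so the scores come from trained models,
    mirroring when the density-ratio thresholds are usable."""
    for st in clients:
        if st.selector_kind in ("confidence", "energy"):
            scores = st.ood_scores(ds.features[st.val_idx])
            st.score_threshold = float(
                np.quantile(scores, tau_client, method="inverted_cdf")
            )


def local_train(
    client: ClientState, ds: LabeledDataset, epochs: int, lr: float, batch_size: int = 32
) -> ClientState:
    """One local-training phase: cross-entropy on the private train split."""
    if len(client.train_idx) == 0:
        raise ValueError("client has no training samples")
    if epochs > 0:
        client.model.fit(
            ds.features[client.train_idx],
            ds.labels[client.train_idx],
            epochs=epochs,
            lr=lr,
            batch_size=batch_size,
        )
    return client


def distill(
    client: ClientState,
    kept_features: np.ndarray,
    targets: np.ndarray,
    epochs: int,
    lr: float,
    batch_size: int = 32,
) -> ClientState:
    """Distillation phase: cross-entropy toward the ensemble targets.

    No-op on an empty target set (a round where everything was filtered).
    """
    if len(kept_features) == 0 or epochs == 0:
        return client
    client.model.fit(kept_features, targets, epochs=epochs, lr=lr, batch_size=batch_size)
    return client


def generate_ensemble_predictions(
    clients: list[ClientState],
    proxy_features: np.ndarray,
    draw_ids: np.ndarray,
    config: FederationConfig,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Lines 10-14 of the round: predict, client-filter, average, server-filter.

    Returns ``(surviving_ids, targets, info)``; targets are simplex rows
    in soft mode and one-hot rows (argmax of the ensemble, ties toward
    the lowest class) in hard mode.  ``info`` carries the byte counts and
    the full ensemble for logging/diagnostics.
    """
    Xb = proxy_features[draw_ids]
    preds, masks = [], []
    for st in clients:
        if config.label_mode == "hard":
            preds.append(st.model.predict(Xb))
        else:
            preds.append(st.model.predict_proba(Xb))
        masks.append(st.select(Xb))
    ensemble, count = aggregate(preds, masks, config.C, mode=config.label_mode)

    has_sharer = count > 0
    smask = server_select(
        np.where(has_sharer[:, None], ensemble, one_hot(0, config.C)),
        config.tau_server,
    )
    kept = smask.kept & has_sharer

    per_pred = prediction_bytes(config.label_mode, config.C)
    client_kept = np.array([m.n_kept for m in masks])
    bytes_up = int(client_kept.sum()) * per_pred
    bytes_down = int(kept.sum()) * per_pred * len(clients)

    surviving = draw_ids[kept]
    if config.label_mode == "hard":
        targets = one_hot(np.argmax(ensemble[kept], axis=1), config.C)
    else:
        targets = ensemble[kept]
    info = {
        "bytes_up": bytes_up,
        "bytes_down": bytes_down,
        "client_kept": client_kept,
        "n_no_sharer": int((~has_sharer).sum()),
        "ensemble": ensemble,
        "sharer_count": count,
        "server_kept": kept,
    }
    return surviving, targets, info


class _ProxySampler:
    """Draw proxy IDs without replacement, reshuffling when exhausted."""

    def __init__(self, n_ids: int, seed: int):
        self.rng = np.random.default_rng(seed)
        self.n_ids = n_ids
        self.queue: list[int] = []

    def draw(self, size: int) -> np.ndarray:
        size = min(size, self.n_ids)
        out: list[int] = []
        while len(out) < size:
            if not self.queue:
                self.queue = list(self.rng.permutation(self.n_ids))
            out.append(self.queue.pop())
        return np.asarray(out, dtype=int)


def _test_accuracy(clients: list[ClientState], ds: LabeledDataset, part: FederatedPartition) -> np.ndarray:
    X, y = ds.features[part.test], ds.labels[part.test]
    return np.array(
        [100.0 * np.mean(st.model.predict(X) == y) for st in clients]
    )


def _run_fd(
    ds: LabeledDataset,
    part: FederatedPartition,
    config: FederationConfig,
    selector: str,
    store_details: bool,
) -> RunResult:
    clients = build_clients(ds, part, config, selector=selector)
    proxy_features, _ = proxy_view(ds, part)
    if config.proxy_batch > len(part.proxy):
        raise ValueError("proxy_batch exceeds proxy size")
    sampler = _ProxySampler(
        len(part.proxy),
        int(np.random.SeedSequence([config.seed, 0xBA7C4]).generate_state(1)[0] % 2**31),
    )
    for st in clients:
        local_train(st, ds, config.pretrain_epochs, config.learning_rate, config.batch_size)
    _calibrate_score_selectors(ds, clients, config.tau_client)

    result = RunResult(logs=[], clients=clients, config=config)
    for t in range(1, config.T + 1):
        draw = sampler.draw(config.proxy_batch)
        surviving, targets, info = generate_ensemble_predictions(
            clients, proxy_features, draw, config
        )
        for st in clients:
            local_train(st, ds, config.local_epochs, config.learning_rate, config.batch_size)
            distill(
                st,
                proxy_features[surviving],
                targets,
                config.distill_epochs,
                config.learning_rate,
                config.batch_size,
            )
        result.survivor_ids.update(int(i) for i in surviving)
        result.logs.append(
            RoundLog(
                round=t,
                p_proxy_round=100.0 * len(surviving) / len(draw),
                accuracy=_test_accuracy(clients, ds, part),
                bytes_up=info["bytes_up"],
                bytes_down=info["bytes_down"],
                n_drawn=len(draw),
                n_survivors=len(surviving),
                n_no_sharer=info["n_no_sharer"],
                client_kept=info["client_kept"],
            )
        )
        if store_details:
            result.details.append(
                RoundDetail(
                    ids=draw,
                    ensemble=info["ensemble"],
                    sharer_count=info["sharer_count"],
                    server_kept=info["server_kept"],
                )
            )
    return result


def run_selective_fd(
    ds: LabeledDataset,
    part: FederatedPartition,
    config: FederationConfig,
    selector: str = "density-ratio",
    store_details: bool = False,
) -> RunResult:
    """Full selective federated distillation (both selectors active)."""
    return _run_fd(ds, part, config, selector=selector, store_details=store_details)


def run_fd_noselect(
    ds: LabeledDataset,
    part: FederatedPartition,
    config: FederationConfig,
    store_details: bool = False,
) -> RunResult:
    """Same loop with both selectors forced to keep everything."""
    cfg = replace(config, tau_server=2.0)
    return _run_fd(ds, part, cfg, selector="none", store_details=store_details)


def run_indep(
    ds: LabeledDataset, part: FederatedPartition, config: FederationConfig
) -> RunResult:
    """Independent local training: no communication, bytes always zero."""
    clients = build_clients(ds, part, config, selector="none")
    for st in clients:
        local_train(st, ds, config.pretrain_epochs, config.learning_rate, config.batch_size)
    result = RunResult(logs=[], clients=clients, config=config)
    for t in range(1, config.T + 1):
        for st in clients:
            local_train(st, ds, config.local_epochs, config.learning_rate, config.batch_size)
        result.logs.append(
            RoundLog(
                round=t,
                p_proxy_round=0.0,
                accuracy=_test_accuracy(clients, ds, part),
                bytes_up=0,
                bytes_down=0,
            )
        )
    if config.T == 0:
        result.logs.append(
            RoundLog(0, 0.0, _test_accuracy(clients, ds, part), 0, 0)
        )
    return result


def run_fedavg(
    ds: LabeledDataset, part: FederatedPartition, config: FederationConfig
) -> RunResult:
    """FedAvg baseline: per-round parameter averaging weighted by train size.

    All clients must share the architecture (``config.hidden``); each
    uploads and downloads the full parameter vector (4 bytes/parameter)
    every round.
    """
    clients = build_clients(ds, part, config, selector="none")
    weights = np.array([len(st.train_idx) for st in clients], dtype=float)
    weights /= weights.sum()
    # parameter averaging needs one input scaling shared by all clients;
    # the server pools the first and second moments of the local data
    X_all = [ds.features[st.train_idx] for st in clients]
    mu = sum(w * X.mean(axis=0) for w, X in zip(weights, X_all))
    second = sum(w * (X**2).mean(axis=0) for w, X in zip(weights, X_all))
    sigma = np.maximum(np.sqrt(np.maximum(second - mu**2, 0.0)), 1e-8)
    for st in clients:
        st.model._mu, st.model._sigma = mu.copy(), sigma.copy()
    n_params = clients[0].model.n_parameters
    result = RunResult(logs=[], clients=clients, config=config)
    for st in clients:
        local_train(st, ds, config.pretrain_epochs, config.learning_rate, config.batch_size)
    for t in range(1, config.T + 1):
        for st in clients:
            local_train(st, ds, config.local_epochs, config.learning_rate, config.batch_size)
        avg = np.zeros(n_params)
        for w, st in zip(weights, clients):
            avg += w * st.model.get_parameters()
        for st in clients:
            st.model.set_parameters(avg)
        result.logs.append(
            RoundLog(
                round=t,
                p_proxy_round=0.0,
                accuracy=_test_accuracy(clients, ds, part),
                bytes_up=len(clients) * n_params * 4,
                bytes_down=len(clients) * n_params * 4,
            )
        )
    return result
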