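"""Metrics, ablation and sweep harnesses, and communication accounting.

The proxy pool is unlabeled to the training pipeline; evaluation code is
the only place allowed to look up the hidden proxy labels, via
:func:`proxy_label_oracle`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data import FederatedPartition, LabeledDataset, proxy_view
from .federation import (
    FederationConfig,
    RoundLog,
    RunResult,
    build_clients,
    local_train,
    prediction_bytes,
    run_selective_fd,
)

__all__ = [
    "AblationResult",
    "accuracy",
    "auroc_incorrect_detection",
    "p_proxy_cumulative",
    "comm_bytes",
    "proxy_label_oracle",
    "run_selector_ablation",
    "run_threshold_sweep",
]


def proxy_label_oracle(ds: LabeledDataset, part: FederatedPartition) -> np.ndarray:
    """Hidden ground-truth labels of the proxy pool, indexed by proxy ID.

    Evaluation-only back door: never used by any training or selection
    code path.
    """
    return ds.labels[part.proxy]


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Classification accuracy in percent."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length and non-empty")
    return 100.0 * float(np.mean(predicted == truth))


def auroc_incorrect_detection(scores: np.ndarray, is_correct: np.ndarray) -> float:
    """AUROC for detecting incorrect predictions from in-distribution scores.

    Orientation: higher score means predicted in-distribution / correct,
    so this is the probability that a random incorrect sample scores
    below a random correct one (ties at half credit — the Mann-Whitney
    form).  0.5 is the random-guess level.
    """
    scores = np.asarray(scores, dtype=float)
    is_correct = np.asarray(is_correct, dtype=bool)
    if scores.shape != is_correct.shape:
        raise ValueError("scores and is_correct must have equal length")
    if is_correct.all() or (~is_correct).all():
        raise ValueError("both correct and incorrect samples are required")
    return float(roc_auc_score(is_correct.astype(int), scores))


def p_proxy_cumulative(logs: list[RoundLog] | RunResult, proxy_size: int) -> float:
    """Percent of the proxy pool that survived both selectors in any round."""
    if isinstance(logs, RunResult):
        return 100.0 * len(logs.survivor_ids) / proxy_size
    # from bare logs only the per-round counts are known; a RunResult
    # carries the exact union of survivor IDs
    raise TypeError("pass the RunResult; per-round logs do not carry survivor IDs")


def comm_bytes(
    mode: str,
    C: int,
    shared_counts: list[tuple[int, int]],
    parameter_count: int,
    K: int,
    T: int,
) -> pd.DataFrame:
    """Closed-form per-round and cumulative byte totals.

    ``shared_counts`` holds per round ``(uploaded_predictions,
    surviving_predictions)`` for the distillation modes (ignored for
    fedavg).  Conventions: 4-byte floats and IDs; a hard-label
    prediction is ID + class index (8 bytes), a soft one ID + C floats;
    FedAvg moves the full parameter vector up and down per client per
    round.
    """
    rows = []
    if mode == "fedavg":
        per = K * parameter_count * 4
        for t in range(1, T + 1):
            rows.append({"round": t, "bytes_up": per, "bytes_down": per})
    elif mode in ("fd-hard", "fd-soft"):
        per_pred = prediction_bytes(mode.split("-")[1], C)
        if len(shared_counts) != T:
            raise ValueError("need one (uploads, survivors) pair per round")
        for t, (uploads, survivors) in enumerate(shared_counts, start=1):
            rows.append(
                {
                    "round": t,
                    "bytes_up": uploads * per_pred,
                    "bytes_down": K * survivors * per_pred,
                }
            )
    else:
        raise ValueError("mode must be 'fd-hard', 'fd-soft' or 'fedavg'")
    df = pd.DataFrame(rows, columns=["round", "bytes_up", "bytes_down"])
    df["cumulative_up"] = df["bytes_up"].cumsum()
    df["cumulative_down"] = df["bytes_down"].cumsum()
    return df


@dataclass(frozen=True)
class AblationResult:
    selector_name: str
    auroc_per_client: np.ndarray  # in [0, 1], one per client
    final_accuracy: float  # %, mean over clients after distillation

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc_per_client))


def run_selector_ablation(
    ds: LabeledDataset,
    part: FederatedPartition,
    config: FederationConfig,
    selectors: tuple[str, ...] = ("density-ratio", "confidence", "energy"),
) -> list[AblationResult]:
    """Compare OOD scores as client-side selectors (hard-label, non-IID setting).

    For each selector: score every (client, proxy sample), compute the
    per-client AUROC of the score against whether that client's
    prediction matches the hidden proxy label, then run the full
    distillation loop with that selector and record final mean accuracy.
    """
    cfg = replace(config, label_mode="hard")
    proxy_features, _ = proxy_view(ds, part)
    true_labels = proxy_label_oracle(ds, part)

    # trained-but-undistilled clients provide the predictions being scored
    clients = build_clients(ds, part, cfg, selector="density-ratio")
    for st in clients:
        local_train(st, ds, cfg.pretrain_epochs, cfg.learning_rate, cfg.batch_size)

    results = []
    for name in selectors:
        aurocs = []
        for st in clients:
            st_kind, st.selector_kind = st.selector_kind, name
            scores = st.ood_scores(proxy_features)
            st.selector_kind = st_kind
            is_correct = st.model.predict(proxy_features) == true_labels
            aurocs.append(auroc_incorrect_detection(scores, is_correct))
        full = run_selective_fd(ds, part, cfg, selector=name)
        results.append(
            AblationResult(
                selector_name=name,
                auroc_per_client=np.asarray(aurocs),
                final_accuracy=full.final_accuracy,
            )
        )
    return results


def run_threshold_sweep(
    ds: LabeledDataset,
    part: FederatedPartition,
    config: FederationConfig,
    tau_client_grid: tuple[float, ...] = (),
    tau_server_grid: tuple[float, ...] = (),
) -> pd.DataFrame:
    """One full run per grid point, the other threshold held at its default.

    Returns a tidy table (swept, tau, accuracy, p_proxy).  Each grid
    point reuses the master seed so runs differ only in the threshold.
    """
    if any(not (0.0 <= t <= 1.0) for t in tau_client_grid):
        raise ValueError("tau_client grid must lie in [0, 1]")
    if any(not (0.0 < t <= 2.0) for t in tau_server_grid):
        raise ValueError("tau_server grid must lie in (0, 2]")
    rows = []
    for tau in tau_client_grid:
        res = run_selective_fd(ds, part, replace(config, tau_client=tau))
        rows.append(
            {
                "swept": "tau_client",
                "tau": tau,
                "accuracy": res.final_accuracy,
                "p_proxy": p_proxy_cumulative(res, len(part.proxy)),
            }
        )
    for tau in tau_server_grid:
        res = run_selective_fd(ds, part, replace(config, tau_server=tau))
        rows.append(
            {
                "swept": "tau_server",
                "tau": tau,
                "accuracy": res.final_accuracy,
                "p_proxy": p_proxy_cumulative(res, len(part.proxy)),
            }
        )
    return pd.DataFrame(rows, columns=["swept", "tau", "accuracy", "p_proxy"])
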