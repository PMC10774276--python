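"""Two-stage selective knowledge sharing.

Client stage: a prediction on a proxy sample is shared only if the
client's estimated density ratio at that sample clears its calibrated
threshold — low-ratio samples are out-of-distribution for that client and
its prediction there is likely misleading.

Server stage: shared predictions are averaged into an ensemble simplex
vector per proxy sample; samples whose ensemble is ambiguous — l1
distance between the ensemble and its own one-hot argmax exceeding
``tau_server``, equivalently max probability below ``1 - tau_server/2``
— are dropped before distillation.

Also provides the confidence and energy scores used as baseline
out-of-distribution detectors in the selector ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .density_ratio import ClientThreshold

__all__ = [
    "SelectionMask",
    "client_select",
    "aggregate",
    "ambiguity",
    "server_select",
    "confidence_score",
    "energy_score",
    "one_hot",
    "check_simplex",
]


@dataclass(frozen=True)
class SelectionMask:
    """Boolean keep-mask over proxy IDs for one selection stage."""

    stage: str  # "client" | "server"
    kept: np.ndarray  # bool per proxy ID

    def __post_init__(self) -> None:
        if self.stage not in ("client", "server"):
            raise ValueError("stage must be 'client' or 'server'")
        object.__setattr__(self, "kept", np.asarray(self.kept, dtype=bool))

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def check_simplex(p: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Validate simplex vectors (rows sum to 1, entries >= 0)."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if (p < -atol).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must be probability vectors on the simplex")
    return p


def one_hot(class_index: np.ndarray | int, C: int) -> np.ndarray:
    """One-hot simplex vertex view of hard labels."""
    idx = np.atleast_1d(np.asarray(class_index, dtype=int))
    if (idx < 0).any() or (idx >= C).any():
        raise ValueError(f"class indices must lie in [0, {C})")
    out = np.zeros((idx.size, C))
    out[np.arange(idx.size), idx] = 1.0
    return out


def client_select(threshold: ClientThreshold, ratios: np.ndarray) -> SelectionMask:
    """Keep proxy IDs whose density ratio is >= the calibrated threshold.

    Ties share: with ``tau_client=0`` everything at or above the
    validation minimum passes, so nothing the client has seen in
    validation is treated as out-of-distribution.
    """
    ratios = np.asarray(ratios, dtype=float)
    return SelectionMask(stage="client", kept=ratios >= threshold.threshold_value)


def aggregate(
    local_predictions: list[np.ndarray],
    masks: list[SelectionMask],
    C: int,
    mode: str = "soft",
) -> tuple[np.ndarray, np.ndarray]:
    """Average shared client predictions into per-ID ensemble simplex vectors.

    ``local_predictions[k]`` holds client ``k``'s predictions for all
    proxy IDs in the round: simplex rows in soft mode, integer class
    indices in hard mode (the hard-label wire format; one-hots are
    reconstructed server-side).  Only entries kept by ``masks[k]`` enter
    the mean.  Returns ``(ensemble, sharer_count)`` over all IDs;
    IDs with zero sharers have an all-zero ensemble row and
    ``sharer_count == 0`` — callers drop them.
    """
    if len(local_predictions) != len(masks):
        raise ValueError("one mask per client required")
    n_ids = masks[0].kept.size
    total = np.zeros((n_ids, C))
    count = np.zeros(n_ids, dtype=int)
    for preds, mask in zip(local_predictions, masks):
        if mask.kept.size != n_ids:
            raise ValueError("masks must cover the same proxy IDs")
        if mode == "hard":
            rows = one_hot(np.asarray(preds, dtype=int), C)
        else:
            rows = check_simplex(preds)
            if rows.shape[1] != C:
                raise ValueError("inconsistent class count across clients")
        keep = mask.kept
        total[keep] += rows[keep]
        count += keep
    shared = count > 0
    ensemble = np.zeros_like(total)
    ensemble[shared] = total[shared] / count[shared, None]
    return ensemble, count


def ambiguity(p: np.ndarray) -> np.ndarray | float:
    """l1 distance between a simplex vector and its one-hot argmax.

    Equals ``2 * (1 - max(p))``; 0 for one-hot predictions, approaching
    ``2 (1 - 1/C)`` for the uniform vector.  Argmax ties break toward the
    lowest class index (the value is unaffected).
    """
    arr = check_simplex(p)
    out = 2.0 * (1.0 - arr.max(axis=1))
    return float(out[0]) if np.asarray(p).ndim == 1 else out


def server_select(ensemble: np.ndarray, tau_server: float) -> SelectionMask:
    """Keep IDs whose ensemble ambiguity is <= ``tau_server``.

    Exactly equivalent to the confidence rule
    ``max(p) >= 1 - tau_server / 2``.
    """
    if tau_server <= 0:
        raise ValueError("tau_server must be positive")
    amb = np.atleast_1d(ambiguity(ensemble))
    return SelectionMask(stage="server", kept=amb <= tau_server)


def confidence_score(p: np.ndarray) -> np.ndarray | float:
    """Maximum class probability; the confidence baseline OOD score."""
    arr = check_simplex(p)
    out = arr.max(axis=1)
    return float(out[0]) if np.asarray(p).ndim == 1 else out


def energy_score(logits: np.ndarray, temperature: float = 1.0) -> np.ndarray | float:
    """Logit-energy score ``-T log sum_c exp(logits_c / T)``.

    Lower energy indicates more in-distribution; computed with a
    max-shift for numerical stability.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    arr = np.atleast_2d(np.asarray(logits, dtype=float))
    if not np.isfinite(arr).all():
        raise ValueError("logits must be finite")
    out = -temperature * logsumexp(arr / temperature, axis=1)
    return float(out[0]) if np.asarray(logits).ndim == 1 else out
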