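"""Kernelized least-squares density-ratio estimation (KuLSIF).

Each client models the ratio ``w(x) = p_k(x) / u(x)`` between its local
data density and a uniform reference density over a compact box.  The
estimator minimizes, over a Gaussian-kernel RKHS ``W``,

    J(w) = 1/(2 n_u) sum_{x in S_u} w(x)^2
         - 1/n_k     sum_{x in S_k} w(x)
         + beta/2 ||w||_W^2,

whose minimizer has the closed form

    w = sum_{x_i in S_k} k(x_i, .) / (n_k beta) + sum_{x_j in S_u} gamma_j k(x_j, .),
    (K_uu + n_u beta I) gamma = -K_uk 1 / (n_k beta),

i.e. a single well-conditioned linear solve.  In-distribution points get
ratios near ``p_k(x)/u(x) > 0`` while far out-of-distribution points get
ratios near zero, which is what the client-side selector thresholds on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "KulsifConfig",
    "RatioModel",
    "ClientThreshold",
    "sample_uniform_reference",
    "median_bandwidth",
    "fit_kulsif",
    "evaluate_ratio",
    "calibrate_threshold",
    "kulsif_objective",
]


@dataclass(frozen=True)
class KulsifConfig:
    """Hyper-parameters of the ratio fit.

    bandwidth: Gaussian kernel length scale, or "median-heuristic" to use
        the median pairwise distance of the client sample.
    beta: ridge regularization on the RKHS norm (> 0).
    n_u: number of uniform reference draws (defaults to n_k at call sites).
    """

    bandwidth: float | str = "median-heuristic"
    beta: float = 1e-3
    n_u: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_u is not None and self.n_u < 1:
            raise ValueError("n_u must be >= 1")
        if not isinstance(self.bandwidth, str) and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass
class RatioModel:
    """Fitted ratio estimator; callable as ``model(X) -> ratios``."""

    support_points: np.ndarray  # (n_k + n_u, d)
    coefficients: np.ndarray  # (n_k + n_u,)
    bandwidth: float
    beta: float
    box: np.ndarray  # (d, 2) uniform reference domain [lo, hi]
    n_k: int
    n_u: int

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return evaluate_ratio(self, X)

    def to_json(self, path: str) -> None:
        payload = {
            "support_points": self.support_points.tolist(),
            "coefficients": self.coefficients.tolist(),
            "bandwidth": self.bandwidth,
            "beta": self.beta,
            "box": self.box.tolist(),
            "n_k": self.n_k,
            "n_u": self.n_u,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "RatioModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            support_points=np.asarray(d["support_points"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            bandwidth=float(d["bandwidth"]),
            beta=float(d["beta"]),
            box=np.asarray(d["box"], dtype=float),
            n_k=int(d["n_k"]),
            n_u=int(d["n_u"]),
        )


@dataclass(frozen=True)
class ClientThreshold:
    """Quantile threshold on validation ratios for the client-side selector."""

    tau_client: float
    threshold_value: float


def sample_uniform_reference(
    local_features: np.ndarray,
    n_u: int,
    margin: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_u`` uniform points over the (margin-widened) bounding box.

    The box is axis-aligned: per dimension ``[min - margin*range,
    max + margin*range]`` of the local features; it concretizes the
    compact support of the uniform reference density.  Returns
    ``(sample, box)`` with ``box`` of shape ``(d, 2)``.
    """
    X = np.asarray(local_features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("local_features must be a non-empty matrix")
    if n_u < 1:
        raise ValueError("n_u must be >= 1")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_width = hi - lo
    degenerate = rng_width == 0
    if degenerate.any() and margin == 0:
        warnings.warn(
            "zero-variance dimension with margin=0; widening by an "
            "epsilon-scaled amount",
            stacklevel=2,
        )
        eps = np.sqrt(np.finfo(float).eps) * np.maximum(1.0, np.abs(lo))
        lo = np.where(degenerate, lo - eps, lo)
        hi = np.where(degenerate, hi + eps, hi)
        rng_width = hi - lo
    lo = lo - margin * rng_width
    hi = hi + margin * rng_width
    rng = np.random.default_rng(seed)
    sample = rng.uniform(lo, hi, size=(n_u, X.shape[1]))
    return sample, np.column_stack([lo, hi])


def median_bandwidth(points: np.ndarray, max_points: int = 1000, seed: int = 0) -> float:
    """Median pairwise Euclidean distance (the median heuristic).

    Subsamples to ``max_points`` rows before the O(n^2) distance pass.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if X.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_points, replace=False)]
    med = float(np.median(pdist(X)))
    if med <= 0:
        raise ValueError("all points identical; bandwidth undefined")
    return med


def _gram(A: np.ndarray, B: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * bandwidth**2))


def fit_kulsif(
    S_k: np.ndarray,
    S_u: np.ndarray,
    config: KulsifConfig = KulsifConfig(),
    box: np.ndarray | None = None,
) -> RatioModel:
    """Fit the KuLSIF ratio estimator from a client sample and a reference sample.

    Solves the regularized least-squares objective in closed form; the
    solution lies in the span of Gaussian kernels centered at
    ``S_k ∪ S_u`` and is the exact minimizer over that subspace.
    """
    S_k = np.atleast_2d(np.asarray(S_k, dtype=float))
    S_u = np.atleast_2d(np.asarray(S_u, dtype=float))
    if S_k.shape[1] != S_u.shape[1]:
        raise ValueError("S_k and S_u must share the feature dimension")
    n_k, n_u = S_k.shape[0], S_u.shape[0]
    if n_k < 1 or n_u < 1:
        raise ValueError("both samples must be non-empty")
    if isinstance(config.bandwidth, str):
        if config.bandwidth != "median-heuristic":
            raise ValueError(f"unknown bandwidth rule {config.bandwidth!r}")
        # the heuristic targets the scale of the density being modelled
        sigma = median_bandwidth(S_k) if n_k >= 2 else median_bandwidth(
            np.vstack([S_k, S_u])
        )
    else:
        sigma = float(config.bandwidth)
    beta = config.beta

    K_uu = _gram(S_u, S_u, sigma)
    K_uk = _gram(S_u, S_k, sigma)
    rhs = -K_uk.sum(axis=1) / (n_k * beta)
    gamma = np.linalg.solve(K_uu + n_u * beta * np.eye(n_u), rhs)
    coef = np.concatenate([np.full(n_k, 1.0 / (n_k * beta)), gamma])

    if box is None:
        lo, hi = S_u.min(axis=0), S_u.max(axis=0)
        box = np.column_stack([lo, hi])
    return RatioModel(
        support_points=np.vstack([S_k, S_u]),
        coefficients=coef,
        bandwidth=sigma,
        beta=beta,
        box=np.asarray(box, dtype=float),
        n_k=n_k,
        n_u=n_u,
    )


def evaluate_ratio(model: RatioModel, X: np.ndarray) -> np.ndarray:
    """Evaluate ``w(x)`` row-wise; returns an empty vector for empty input."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0)
    X = np.atleast_2d(X)
    if X.shape[1] != model.support_points.shape[1]:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} vs {model.support_points.shape[1]}"
        )
    out = _gram(X, model.support_points, model.bandwidth) @ model.coefficients
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite ratio values")
    return out


def kulsif_objective(
    coef: np.ndarray, S_k: np.ndarray, S_u: np.ndarray, bandwidth: float, beta: float
) -> float:
    """The finite-dimensional KuLSIF objective over the representer subspace.

    Shared by the solver tests: any coefficient vector on the kernel
    sections at ``S_k ∪ S_u`` can be scored, so a generic quadratic
    minimizer provides an independent optimum to compare against.
    """
    P = np.vstack([S_k, S_u])
    K = _gram(P, P, bandwidth)
    w_all = K @ coef
    n_k, n_u = S_k.shape[0], S_u.shape[0]
    w_k, w_u = w_all[:n_k], w_all[n_k:]
    return float(
        w_u @ w_u / (2 * n_u) - w_k.sum() / n_k + 0.5 * beta * coef @ K @ coef
    )


def calibrate_threshold(
    model: RatioModel,
    validation_features: np.ndarray,
    tau_client: float,
) -> ClientThreshold:
    """Set the client threshold as the tau_client-quantile of validation ratios.

    Uses the lower (inverse-CDF) quantile so the threshold is an attained
    ratio value: tau_client=0 gives the validation minimum (nothing seen
    in validation is rejected), tau_client=1 the maximum.
    """
    if not (0.0 <= tau_client <= 1.0):
        raise ValueError("tau_client must lie in [0, 1]")
    ratios = evaluate_ratio(model, validation_features)
    if ratios.size == 0:
        raise ValueError("need at least one validation sample")
    value = float(np.quantile(ratios, tau_client, method="inverted_cdf"))
    return ClientThreshold(tau_client=tau_client, threshold_value=value)
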