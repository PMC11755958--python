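"""From-scratch fuzzy c-means (FCM) clustering.

FCM assigns every item a *membership degree* in [0, 1] to each of ``C``
clusters, with memberships summing to 1 per item.  For item ``x_j`` and
centers ``c_1 .. c_C`` the membership toward cluster ``i`` is

    mu_ij = 1 / sum_k ( ||x_j - c_i|| / ||x_j - c_k|| ) ** (2 / (m - 1))

and fitting minimises the objective

    J(U, C) = sum_i sum_j mu_ij**m * ||x_j - c_i||**2
    subject to sum_i mu_ij = 1 for every j

by alternating the membership update above with the stationary center
update ``c_i = sum_j mu_ij**m x_j / sum_j mu_ij**m``.  The fuzziness
exponent ``m > 1`` controls softness: m -> 1 gives crisp nearest-center
assignment, large m pushes memberships toward the uniform 1/C.

Here FCM plays two roles in the staging cascade: *fuzzification* of a
single biomarker (2 clusters on a 1-D feature, membership toward the
AD-like pole becomes the feature fed to a supervised classifier), and
*unsupervised stage-1 staging* (2 clusters on the hippocampal-volume
triple, the low-volume cluster being the symptomatic pole).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FCMModel",
    "fcm_membership",
    "fcm_memberships",
    "fcm_objective",
    "fcm_fit",
    "assign_crisp",
    "label_clusters",
    "AD_LIKE",
    "NC_LIKE",
    "LOWER_IS_AD_LIKE",
    "HIGHER_IS_AD_LIKE",
]

AD_LIKE = "AD_like"
NC_LIKE = "NC_like"
LOWER_IS_AD_LIKE = "lower_is_ad_like"
HIGHER_IS_AD_LIKE = "higher_is_ad_like"

_ZERO = 1e-300  # guard against 0/0 in the membership ratio


@dataclass
class FCMModel:
    """A fitted fuzzy c-means model.

    Attributes
    ----------
    centers : (C, d) array
        Cluster centers.
    m : float
        Fuzziness exponent, > 1.
    direction : str or None
        For biomarker fuzzifiers: which end of the feature axis is
        disease-like (``lower_is_ad_like`` for amyloid-beta 42 and for
        hippocampal volume, ``higher_is_ad_like`` for the taus and the
        CSF ratio).
    pole_map : dict[int, str] or None
        Cluster index -> ``AD_like`` / ``NC_like``; set by
        :func:`label_clusters`.
    """

    centers: np.ndarray
    m: float
    direction: str | None = None
    pole_map: dict[int, str] | None = None
    n_iter_: int = 0
    objective_: float = float("nan")
    objective_trace_: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def ad_like_index(self) -> int:
        if self.pole_map is None:
            raise ValueError("pole_map not set; call label_clusters first")
        for idx, pole in self.pole_map.items():
            if pole == AD_LIKE:
                return idx
        raise ValueError("pole_map has no AD_like cluster")

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "m": self.m,
            "direction": self.direction,
            "pole_map": {str(k): v for k, v in (self.pole_map or {}).items()},
            "n_iter": self.n_iter_,
            "objective": self.objective_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FCMModel":
        model = cls(
            centers=np.asarray(d["centers"], dtype=float),
            m=float(d["m"]),
            direction=d.get("direction"),
            pole_map={int(k): v for k, v in d["pole_map"].items()} or None,
        )
        model.n_iter_ = int(d.get("n_iter", 0))
        model.objective_ = float(d.get("objective", float("nan")))
        return model


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        x = x.reshape(1, 1)
    elif x.ndim == 1:
        x = x.reshape(-1, 1)
    return x


def fcm_memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix U (n, C) for items ``X`` given ``centers``.

    Items coinciding with a center get crisp membership there; if several
    centers coincide with the item the membership splits uniformly over
    them (the conventional resolution of the zero-distance singularity).
    """
    if m <= 1:
        raise ValueError(f"fuzziness exponent m must be > 1, got {m}")
    X = _as_2d(X)
    centers = _as_2d(centers)
    if centers.shape[0] < 2:
        raise ValueError("need at least 2 centers")
    # squared distances (n, C)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    power = 1.0 / (m - 1.0)
    # mu_ij = (1/d2_ij)^p / sum_k (1/d2_ik)^p  --  equivalent to the ratio
    # form; dividing by the per-row minimum distance first keeps the powers
    # in (0, 1] so extreme m never overflows
    d2_safe = np.maximum(d2, _ZERO)
    ratio = d2_safe / d2_safe.min(axis=1, keepdims=True)
    inv = ratio ** (-power)
    U = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.where(any_zero)[0]
        U[rows] = 0.0
        counts = zero[rows].sum(axis=1)
        U[rows] = zero[rows] / counts[:, None]
    return U


def fcm_membership(x, centers, m: float) -> np.ndarray:
    """Membership vector (length C) for a single item ``x``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return fcm_memberships(x.reshape(1, -1), centers, m)[0]


def fcm_objective(X, U, centers, m: float) -> float:
    """FCM objective J = sum_ij mu_ij^m ||x_j - c_i||^2.

    ``U`` must be row-normalised (each item's memberships sum to 1).
    """
    X = _as_2d(X)
    centers = _as_2d(centers)
    U = np.asarray(U, dtype=float)
    if U.shape != (X.shape[0], centers.shape[0]):
        raise ValueError(
            f"membership matrix shape {U.shape} inconsistent with "
            f"{X.shape[0]} items and {centers.shape[0]} centers"
        )
    if not np.allclose(U.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("memberships are not row-normalized")
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((U**m) * d2).sum())


def _quantile_init(X: np.ndarray, c: int) -> np.ndarray:
    # per-feature quantiles, evenly spread in [25, 75]; for c=2 this is
    # the 25th/75th percentile pair -- deterministic, no seed needed
    qs = np.linspace(25.0, 75.0, c)
    return np.stack([np.percentile(X, q, axis=0) for q in qs])


def fcm_fit(
    X,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    init: str = "quantile",
    seed: int | None = None,
    n_init: int = 1,
) -> FCMModel:
    """Fit fuzzy c-means by alternating optimization.

    Parameters
    ----------
    X : (n, d) array or length-n vector
    c : number of clusters (>= 2)
    m : fuzziness exponent (> 1)
    tol : convergence threshold on max absolute center displacement
    max_iter : iteration cap
    init : "quantile" (deterministic per-feature quantiles, default) or
        "random" (centers drawn from the data; requires ``seed`` for
        reproducibility, best of ``n_init`` restarts by objective)
    """
    X = _as_2d(X)
    n = X.shape[0]
    if n < c:
        raise ValueError(f"need at least c={c} items, got {n}")
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError(f"fuzziness exponent m must be > 1, got {m}")
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("all items identical: no separable centers exist")

    if init == "quantile":
        inits = [_quantile_init(X, c)]
    elif init == "random":
        rng = np.random.default_rng(seed)
        inits = []
        for _ in range(max(1, n_init)):
            idx = rng.choice(n, size=c, replace=False)
            inits.append(X[idx].copy())
    else:
        raise ValueError(f"unknown init {init!r}")

    best: FCMModel | None = None
    for centers0 in inits:
        centers = np.asarray(centers0, dtype=float).copy()
        trace: list[float] = []
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            U = fcm_memberships(X, centers, m)
            trace.append(fcm_objective(X, U, centers, m))
            w = U**m
            denom = w.sum(axis=0)
            # a cluster with zero total weight keeps its center
            new_centers = centers.copy()
            ok = denom > 0
            new_centers[ok] = (w.T[ok] @ X) / denom[ok, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < tol:
                break
        U = fcm_memberships(X, centers, m)
        obj = fcm_objective(X, U, centers, m)
        trace.append(obj)
        model = FCMModel(centers=centers, m=m)
        model.n_iter_ = n_iter
        model.objective_ = obj
        model.objective_trace_ = trace
        if best is None or model.objective_ < best.objective_:
            best = model
    assert best is not None
    return best


def assign_crisp(u: np.ndarray) -> int:
    """Crisp cluster index: argmax membership, ties to the lowest index."""
    u = np.asarray(u, dtype=float)
    return int(np.argmax(u))


def label_clusters(model: FCMModel, direction: str) -> dict[int, str]:
    """Map the two clusters of a fitted model to AD-like / NC-like poles.

    ``direction`` encodes the biology of the feature: hippocampal volume
    and amyloid-beta 42 fall with disease (``lower_is_ad_like``); total
    and phosphorylated tau, and the p-tau/abeta ratio, rise
    (``higher_is_ad_like``).  The mean of each center across features is
    compared; equal means indicate a degenerate fit and raise.
    """
    if model.n_clusters != 2:
        raise ValueError("pole labeling is defined for exactly 2 clusters")
    if direction not in (LOWER_IS_AD_LIKE, HIGHER_IS_AD_LIKE):
        raise ValueError(f"unknown direction {direction!r}")
    means = model.centers.mean(axis=1)
    if means[0] == means[1]:
        raise ValueError("degenerate fit: cluster centers have equal means")
    low, high = (0, 1) if means[0] < means[1] else (1, 0)
    if direction == LOWER_IS_AD_LIKE:
        pole = {low: AD_LIKE, high: NC_LIKE}
    else:
        pole = {high: AD_LIKE, low: NC_LIKE}
    model.direction = direction
    model.pole_map = pole
    return pole
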