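"""Linear twin support vector machine (TSVM).

A TSVM fits two nonparallel hyperplanes by solving two small quadratic
programs — each plane is pulled close to one class while pushed at least
unit distance from the other — and classifies a point by the smaller
normalized distance.  Because each plane is fitted against the *other*
class's constraints, the method does not assume the two classes share a
distribution and degrades gracefully on unbalanced data.

Primal problems (class A positive, class B negative, e = ones)::

    min  ½‖A w₁ + e b₁‖² + c₁ eᵀξ   s.t.  −(B w₁ + e b₁) + ξ ≥ e, ξ ≥ 0
    min  ½‖B w₂ + e b₂‖² + c₂ eᵀη   s.t.   (A w₂ + e b₂) + η ≥ e, η ≥ 0

Each dual is a box-constrained QP over the opposite class's multipliers;
the primal plane is recovered through the regularized normal equations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Hyperplane",
    "BinaryTSVM",
    "MulticlassTSVM",
    "solve_box_qp",
    "train_binary",
    "predict_binary",
    "train_multiclass",
    "predict_multiclass",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Hyperplane:
    """w·x + b = 0 with distance |w·x + b| / ‖w‖."""

    w: np.ndarray
    b: float

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.w))

    def distance(self, X: np.ndarray) -> np.ndarray:
        nrm = self.norm
        if nrm == 0.0:
            raise ValueError("degenerate hyperplane with zero-norm weight vector")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.abs(X @ self.w + self.b) / nrm


@dataclass(frozen=True)
class BinaryTSVM:
    plane_pos: Hyperplane
    plane_neg: Hyperplane
    c1: float
    c2: float
    eps: float
    dual_objectives: tuple[float, float] = (np.nan, np.nan)


def solve_box_qp(M: np.ndarray, q: np.ndarray, upper: float,
                 tol: float = 1e-10, max_iter: int | None = None) -> np.ndarray:
    """Minimize ½αᵀMα − qᵀα subject to 0 ≤ α ≤ upper.

    Primal active-set method for the box-constrained convex QP: on the
    current free set the Newton (equality-constrained) step is taken,
    truncated at the first blocking bound; when the free-subspace
    optimum is reached, the most violated KKT multiplier at a bound is
    released.  Exact on its final active set, deterministic, and finite
    for the small TSVM duals (M is symmetric PSD; singular free blocks
    are handled by a least-squares step).
    """
    M = np.asarray(M, dtype=float)
    q = np.asarray(q, dtype=float)
    n = len(q)
    if n == 0:
        return np.zeros(0)
    scale = max(1.0, float(np.abs(q).max()))
    kkt_tol = tol * scale
    alpha = np.zeros(n)
    status = np.zeros(n, dtype=int)  # -1 at lower bound, +1 at upper, 0 free
    if max_iter is None:
        max_iter = 20 * n + 100
    for _ in range(max_iter):
        g = M @ alpha - q
        free = status == 0
        p = np.zeros(n)
        if free.any():
            Mff = M[np.ix_(free, free)]
            rhs = -g[free]
            try:
                p_f = np.linalg.solve(Mff, rhs)
                if not np.all(np.isfinite(p_f)):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                p_f = np.linalg.lstsq(Mff, rhs, rcond=None)[0]
            p[free] = p_f
        if np.abs(p).max(initial=0.0) <= 1e-13 * max(1.0, np.abs(alpha).max()):
            # free-subspace optimum: check bound multipliers
            viol_lo = np.where((status == -1) & (g < -kkt_tol))[0]
            viol_hi = np.where((status == +1) & (g > kkt_tol))[0]
            if len(viol_lo) == 0 and len(viol_hi) == 0:
                break
            cand = [(-(-g[i]), i) for i in viol_lo] + [(-g[i], i) for i in viol_hi]
            _, worst = min(cand)
            status[worst] = 0
            continue
        # longest feasible step along p before a free variable hits a bound
        t = 1.0
        blocking = -1
        block_side = 0
        idx = np.where(free & (p != 0.0))[0]
        for i in idx:
            if p[i] < 0:
                ti = (0.0 - alpha[i]) / p[i]
                side = -1
            else:
                ti = (upper - alpha[i]) / p[i]
                side = +1
            if ti < t - 1e-15:
                t, blocking, block_side = ti, i, side
        alpha = np.clip(alpha + t * p, 0.0, upper)
        if blocking >= 0:
            alpha[blocking] = 0.0 if block_side < 0 else upper
            status[blocking] = block_side
    return alpha


def _dual_pieces(own: np.ndarray, other: np.ndarray, eps: float):
    """Matrices for one TSVM dual: own class augmented H, other class G."""
    H = np.hstack([own, np.ones((len(own), 1))])
    G = np.hstack([other, np.ones((len(other), 1))])
    S = H.T @ H + eps * np.eye(H.shape[1])
    SinvGT = np.linalg.solve(S, G.T)
    M = G @ SinvGT
    M = 0.5 * (M + M.T)
    return G, SinvGT, M


def dual_objective(M: np.ndarray, alpha: np.ndarray) -> float:
    """Value of the (maximized) dual: eᵀα − ½αᵀMα."""
    return float(alpha.sum() - 0.5 * alpha @ M @ alpha)


def train_binary(X_pos: np.ndarray, X_neg: np.ndarray, c1: float = 1.0,
                 c2: float = 1.0, eps: float = 1e-6) -> BinaryTSVM:
    """Fit both TSVM hyperplanes.

    ``eps`` is the Tikhonov ridge on the normal-equation matrices
    (HᵀH + eps·I), which keeps them invertible when a class has fewer
    points than features + 1.
    """
    X_pos = np.atleast_2d(np.asarray(X_pos, dtype=float))
    X_neg = np.atleast_2d(np.asarray(X_neg, dtype=float))
    if len(X_pos) == 0 or len(X_neg) == 0:
        raise ValueError("both classes need at least one sample")
    if not (np.all(np.isfinite(X_pos)) and np.all(np.isfinite(X_neg))):
        raise ValueError("features must be finite")
    if c1 <= 0 or c2 <= 0:
        raise ValueError("penalty parameters must be positive")
    if eps <= 0:
        raise ValueError("eps must be positive")

    # Plane 1: close to the positive class, >= 1 from the negative class.
    _, SinvGT1, M1 = _dual_pieces(X_pos, X_neg, eps)
    alpha = solve_box_qp(M1, np.ones(len(X_neg)), c1)
    u1 = -SinvGT1 @ alpha
    # Plane 2: close to the negative class, >= 1 from the positive class.
    _, SinvGT2, M2 = _dual_pieces(X_neg, X_pos, eps)
    gamma = solve_box_qp(M2, np.ones(len(X_pos)), c2)
    u2 = SinvGT2 @ gamma

    return BinaryTSVM(
        plane_pos=Hyperplane(w=u1[:-1], b=float(u1[-1])),
        plane_neg=Hyperplane(w=u2[:-1], b=float(u2[-1])),
        c1=float(c1), c2=float(c2), eps=float(eps),
        dual_objectives=(dual_objective(M1, alpha), dual_objective(M2, gamma)),
    )


def predict_binary(model: BinaryTSVM, X: np.ndarray):
    """Assign each point to the class whose plane is nearer.

    Returns (labels, distances) where labels are +1 / −1 and distances
    has columns (d_pos, d_neg).  Exact ties go to the positive class.
    """
    d_pos = model.plane_pos.distance(X)
    d_neg = model.plane_neg.distance(X)
    labels = np.where(d_pos <= d_neg, 1, -1)
    return labels, np.column_stack([d_pos, d_neg])


@dataclass
class MulticlassTSVM:
    """One-vs-rest assembly: one binary TSVM per class.

    A point is assigned to the class whose "own" hyperplane (the plane
    fitted close to that class) it lies nearest, after standardizing
    with the training-split location/scale.
    """

    per_class: dict[str, BinaryTSVM]
    class_names: list[str]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    c1: float = 1.0
    c2: float = 1.0

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_mean):
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the "
                f"model's {len(self.feature_mean)}"
            )
        return (X - self.feature_mean) / self.feature_scale

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "class_names": list(self.class_names),
            "c1": self.c1,
            "c2": self.c2,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "per_class": {
                name: {
                    "w_pos": m.plane_pos.w.tolist(), "b_pos": m.plane_pos.b,
                    "w_neg": m.plane_neg.w.tolist(), "b_neg": m.plane_neg.b,
                    "c1": m.c1, "c2": m.c2, "eps": m.eps,
                }
                for name, m in self.per_class.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "MulticlassTSVM":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')}")
        per_class = {
            name: BinaryTSVM(
                plane_pos=Hyperplane(np.asarray(m["w_pos"]), m["b_pos"]),
                plane_neg=Hyperplane(np.asarray(m["w_neg"]), m["b_neg"]),
                c1=m["c1"], c2=m["c2"], eps=m["eps"],
            )
            for name, m in d["per_class"].items()
        }
        return cls(per_class=per_class, class_names=list(d["class_names"]),
                   feature_mean=np.asarray(d["feature_mean"], dtype=float),
                   feature_scale=np.asarray(d["feature_scale"], dtype=float),
                   c1=d["c1"], c2=d["c2"])

    @classmethod
    def from_json(cls, s: str) -> "MulticlassTSVM":
        return cls.from_dict(json.loads(s))


def train_multiclass(X: np.ndarray, y, c1: float = 1.0, c2: float = 1.0,
                     eps: float = 1e-6,
                     class_names: list[str] | None = None) -> MulticlassTSVM:
    """One-vs-rest TSVM on standardized features (train statistics only)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if class_names is None:
        class_names = sorted(set(map(str, y)))
    if len(class_names) < 2:
        raise ValueError("need at least two classes")
    y = np.asarray([str(v) for v in y])
    missing = [c for c in class_names if not np.any(y == c)]
    if missing:
        raise ValueError(f"classes with zero training samples: {missing}")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    Z = (X - mean) / scale

    per_class = {}
    for name in class_names:
        mask = y == name
        per_class[name] = train_binary(Z[mask], Z[~mask], c1=c1, c2=c2, eps=eps)
    return MulticlassTSVM(per_class=per_class, class_names=list(class_names),
                          feature_mean=mean, feature_scale=scale, c1=c1, c2=c2)


def predict_multiclass(model: MulticlassTSVM, X: np.ndarray):
    """Class of the nearest own-class plane; ties break by class order."""
    Z = model.standardize(X)
    dists = np.column_stack([
        model.per_class[name].plane_pos.distance(Z) for name in model.class_names
    ])
    idx = np.argmin(dists, axis=1)  # argmin takes the first minimum: class order
    labels = np.asarray(model.class_names, dtype=object)[idx]
    return labels, dists
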