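"""PCA chemical space, active-curve fitting, and point-to-curve distances.

The screening idea: project all compounds into a low-dimensional principal
component space of their 2D descriptors; the known actives trace out a
region of that space.  Candidates are first constrained to the bounding box
of the actives on the first three components, then ranked by the shortest
Euclidean distance ``D_min`` from their (PC1, PC2) position to a polynomial
curve fitted through the actives.

The shortest distance to an explicit curve ``y = p(x)`` on a domain
``[x_M, x_N]`` is found by solving the stationarity condition of the
Lagrangian of the constrained minimization,

    (x - x0) + (p(x) - y0) * p'(x) = 0,

a polynomial of degree ``2*deg - 1`` whose real roots inside the open
domain are the interior candidate feet; ``D_min`` is the minimum distance
over those candidates and the two curve endpoints ``M``, ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted

from .compounds import DescriptorMatrix

CANDIDATE_KINDS = ("interior_root", "endpoint_M", "endpoint_N")

#: imaginary parts below this are treated as numerical noise on a real root
IMAG_TOL = 1e-9


@dataclass(frozen=True)
class ActiveCurve:
    """Polynomial curve y = p(x) through the known actives, with domain.

    ``coefficients`` are in ascending order (c0 + c1*x + ...); the domain is
    the PC1 range of the active points, and M/N are the curve points at the
    domain bounds.
    """

    coefficients: tuple[float, ...]
    domain: tuple[float, float]

    def __post_init__(self):
        if len(self.coefficients) < 2:
            raise ValueError("curve degree must be >= 1")
        if not self.domain[0] < self.domain[1]:
            raise ValueError("domain must satisfy x_M < x_N")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    @property
    def poly(self) -> Polynomial:
        return Polynomial(self.coefficients)

    def __call__(self, x):
        return self.poly(x)

    @property
    def M(self) -> tuple[float, float]:
        return (self.domain[0], float(self.poly(self.domain[0])))

    @property
    def N(self) -> tuple[float, float]:
        return (self.domain[1], float(self.poly(self.domain[1])))


@dataclass(frozen=True)
class BoundaryBox:
    """Componentwise [min, max] box over the known actives' scores."""

    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    def __post_init__(self):
        if len(self.mins) != len(self.maxs):
            raise ValueError("mins/maxs length mismatch")
        if any(lo > hi for lo, hi in zip(self.mins, self.maxs)):
            raise ValueError("box requires min <= max componentwise")

    @classmethod
    def from_points(cls, points: np.ndarray) -> "BoundaryBox":
        points = np.asarray(points, dtype=float)
        return cls(tuple(points.min(axis=0)), tuple(points.max(axis=0)))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inclusive containment per row, over the box's components."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = len(self.mins)
        p = points[:, :k]
        return np.all((p >= self.mins) & (p <= self.maxs), axis=1)


@dataclass(frozen=True)
class DistanceResult:
    """Shortest distance from one compound's (PC1, PC2) point to the curve."""

    compound_id: str
    d_min: float
    nearest: tuple[float, float]
    candidate_kind: str
    significant: bool

    def __post_init__(self):
        if self.d_min < 0:
            raise ValueError("d_min must be non-negative")
        if self.candidate_kind not in CANDIDATE_KINDS:
            raise ValueError(f"candidate_kind must be one of {CANDIDATE_KINDS}")


def fit_active_curve(x: Sequence[float], y: Sequence[float], degree: int = 3) -> ActiveCurve:
    """Least-squares polynomial of ``y`` on ``x`` through the active points.

    The domain is the x-range of the points.  Requires at least
    ``degree + 1`` points; repeated x-values are fine (ordinary LS).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if x.size < degree + 1:
        raise ValueError(f"need >= {degree + 1} points for degree {degree}, got {x.size}")
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    return ActiveCurve(tuple(float(c) for c in coeffs),
                       (float(x.min()), float(x.max())))


def shortest_distance(
    q: tuple[float, float],
    curve: ActiveCurve,
    compound_id: str = "",
    threshold: float = 0.2,
) -> DistanceResult:
    """Shortest Euclidean distance from point ``q`` to the fitted curve.

    Interior candidates are the real roots (|Im| < 1e-9, via the companion
    matrix) of the stationarity polynomial that fall strictly inside the
    domain; the distance is minimized over those and the endpoints.  Ties
    break toward ``interior_root``, then endpoint ``M``.
    """
    x0, y0 = float(q[0]), float(q[1])
    if not (np.isfinite(x0) and np.isfinite(y0)):
        raise ValueError("query point must be finite")
    p = curve.poly
    dp = p.deriv()
    # (x - x0) + (p(x) - y0) * p'(x), degree 2*deg - 1
    station = Polynomial([-x0, 1.0]) + (p - Polynomial([y0])) * dp
    roots = station.roots()
    lo, hi = curve.domain
    interior = [
        float(r.real)
        for r in roots
        if abs(r.imag) < IMAG_TOL and lo < r.real < hi
    ]

    candidates: list[tuple[float, int, str, tuple[float, float]]] = []
    for xr in sorted(interior):
        pt = (xr, float(p(xr)))
        candidates.append((float(np.hypot(xr - x0, pt[1] - y0)), 0, "interior_root", pt))
    for kind, pt, prio in (("endpoint_M", curve.M, 1), ("endpoint_N", curve.N, 2)):
        candidates.append((float(np.hypot(pt[0] - x0, pt[1] - y0)), prio, kind, pt))

    d, _, kind, pt = min(candidates, key=lambda c: (c[0], c[1]))
    return DistanceResult(compound_id=compound_id, d_min=d, nearest=pt,
                          candidate_kind=kind, significant=d < threshold)


def boundary_filter(
    points: pd.DataFrame, box: BoundaryBox
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition score rows into (retained, removed) by inclusive box test.

    ``points`` columns are component scores (pc1, pc2, pc3, ...); only the
    box's components are tested.
    """
    if points.empty:
        return points, points
    mask = box.contains(points.to_numpy(dtype=float))
    return points[mask], points[~mask]


def screen_by_distance(
    results: Sequence[DistanceResult], threshold: float = 0.2
) -> list[DistanceResult]:
    """Subset with ``d_min`` strictly below threshold, sorted ascending."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    hits = [r for r in results if r.d_min < threshold]
    return sorted(hits, key=lambda r: r.d_min)


class ChemSpaceScreen(BaseEstimator):
    """PCA chemical-space screen fitted on a labelled descriptor matrix.

    ``fit(X, y)`` takes the descriptor matrix of the full compound
    collection and a boolean mask ``y`` marking the known actives.  It
    standardizes the descriptors, fits the PCA on all compounds, builds the
    actives' bounding box on the first ``n_box_components`` scores and fits
    the active curve (PC2 on PC1).  ``predict(X)`` flags compounds that are
    inside the box and within ``threshold`` of the curve.

    Parameters
    ----------
    n_components : number of principal components kept (>= 3 so the
        boundary box can use PC1..PC3).
    degree : polynomial degree of the active curve (cubic by default).
    threshold : D_min significance cutoff (strict; scale depends on the
        descriptor set and scaling — 0.2 matches z-scored 2D descriptors).
    scale : z-score descriptors before PCA.
    n_box_components : components used by the boundary box.

    Attributes
    ----------
    scaler_ : fitted StandardScaler (None when scale=False)
    pca_ : fitted sklearn PCA
    box_ : BoundaryBox over the actives' leading scores
    curve_ : ActiveCurve through the actives' (PC1, PC2) points
    keep_mask_ : boolean mask of retained (non-constant) descriptor columns
    """

    def __init__(self, n_components: int = 3, degree: int = 3,
                 threshold: float = 0.2, scale: bool = True,
                 n_box_components: int = 3):
        self.n_components = n_components
        self.degree = degree
        self.threshold = threshold
        self.scale = scale
        self.n_box_components = n_box_components

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if y.sum() < self.degree + 1:
            raise ValueError(
                f"need >= {self.degree + 1} known actives for a degree-"
                f"{self.degree} curve, got {int(y.sum())}"
            )
        if self.n_components > min(X.shape):
            raise ValueError("n_components exceeds matrix rank")
        self.n_features_in_ = X.shape[1]
        self.keep_mask_ = X.std(axis=0) > 0
        Xk = X[:, self.keep_mask_]
        if self.scale:
            self.scaler_ = StandardScaler().fit(Xk)
            Xs = self.scaler_.transform(Xk)
        else:
            self.scaler_ = None
            Xs = Xk - Xk.mean(axis=0)
        self.pca_ = PCA(n_components=self.n_components, svd_solver="full").fit(Xs)
        scores = self.pca_.transform(Xs)
        active = scores[y]
        self.box_ = BoundaryBox.from_points(
            active[:, : min(self.n_box_components, self.n_components)]
        )
        self.curve_ = fit_active_curve(active[:, 0], active[:, 1], self.degree)
        self.active_mask_ = y
        return self

    def transform(self, X) -> np.ndarray:
        """Project descriptors to principal-component scores."""
        check_is_fitted(self, "pca_")
        X = check_array(X, dtype=float)
        Xk = X[:, self.keep_mask_]
        Xs = self.scaler_.transform(Xk) if self.scaler_ is not None \
            else Xk - self.pca_.mean_  # pragma: no cover - scale=False path
        return self.pca_.transform(Xs)

    def distances(self, X, ids: Sequence[str] | None = None) -> list[DistanceResult]:
        """D_min of each row's (PC1, PC2) score to the active curve."""
        scores = self.transform(X)
        if ids is None:
            ids = [str(i) for i in range(scores.shape[0])]
        return [
            shortest_distance((s[0], s[1]), self.curve_, compound_id=cid,
                              threshold=self.threshold)
            for cid, s in zip(ids, scores)
        ]

    def predict(self, X) -> np.ndarray:
        """True where a compound is in the actives' box and D_min < threshold."""
        scores = self.transform(X)
        in_box = self.box_.contains(scores)
        d = np.array([
            shortest_distance((s[0], s[1]), self.curve_).d_min for s in scores
        ])
        return in_box & (d < self.threshold)

    def screen(self, X, ids: Sequence[str]) -> pd.DataFrame:
        """Full per-compound screening table (scores, box, D_min, verdicts)."""
        scores = self.transform(X)
        in_box = self.box_.contains(scores)
        res = self.distances(X, ids)
        return pd.DataFrame(
            {
                "id": list(ids),
                **{f"pc{k + 1}": scores[:, k] for k in range(min(3, self.n_components))},
                "in_box": in_box,
                "d_min": [r.d_min for r in res],
                "candidate_kind": [r.candidate_kind for r in res],
                "significant": [in_b and r.significant for in_b, r in zip(in_box, res)],
            }
        )

    def to_dict(self) -> dict:
        """JSON-serializable model state (scaler, loadings, box, curve)."""
        check_is_fitted(self, "pca_")
        return {
            "params": self.get_params(),
            "keep_mask": self.keep_mask_.tolist(),
            "scaler_mean": self.scaler_.mean_.tolist() if self.scaler_ else None,
            "scaler_scale": self.scaler_.scale_.tolist() if self.scaler_ else None,
            "pca_mean": self.pca_.mean_.tolist(),
            "components": self.pca_.components_.tolist(),
            "explained_variance_ratio": self.pca_.explained_variance_ratio_.tolist(),
            "box": {"mins": list(self.box_.mins), "maxs": list(self.box_.maxs)},
            "curve": {"coefficients": list(self.curve_.coefficients),
                      "domain": list(self.curve_.domain)},
        }


def fit_chem_space(
    dm: DescriptorMatrix, labels: pd.Series | dict, n_components: int = 3,
    degree: int = 3, threshold: float = 0.2,
) -> tuple[ChemSpaceScreen, pd.DataFrame]:
    """Fit a ChemSpaceScreen from a DescriptorMatrix + role labels.

    Returns the fitted model and the score table for all compounds.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    roles = labels.reindex(dm.values.index)
    if roles.isna().any():
        raise ValueError("every compound needs a role label")
    y = (roles == "known_active").to_numpy()
    model = ChemSpaceScreen(n_components=n_components, degree=degree,
                            threshold=threshold).fit(dm.values.to_numpy(), y)
    scores = model.transform(dm.values.to_numpy())
    table = pd.DataFrame(
        scores, index=dm.values.index,
        columns=[f"pc{k + 1}" for k in range(n_components)],
    )
    return model, table
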