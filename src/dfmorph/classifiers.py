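"""Non-parallel-plane classifiers: linear SVM baseline, GEPSVM, and TSVM.

GEPSVM (generalized eigenvalue proximal SVM) fits two non-parallel planes
``w_i^T x - b_i = 0``, each as close as possible to one class and as far as
possible from the other, by minimising the Tikhonov-regularised Rayleigh
quotient

    min_{U != 0}  U^T P U / U^T Q U ,
    P = [X1 -o]^T [X1 -o] + t I ,   Q = [X2 -o]^T [X2 -o] ,

whose minimiser is the generalized eigenvector of the smallest eigenvalue of
``P U = lambda Q U``; the second plane solves the role-swapped problem.

TSVM (twin SVM) fits two planes ``w_i^T x + b_i = 0`` by solving two SVM-like
convex QPs; for plane 1 (proximal to class 1):

    min_{w,b,q}  1/2 ||X1 w + o b||^2 + c1 o^T q
    s.t.         -(X2 w + o b) + q >= o ,  q >= 0 ,

and symmetrically for plane 2 with the class roles exchanged.  The QPs are
solved through their box-constrained duals: with H = [X1 o], G = [X2 o],

    min_{0 <= a <= c1}  1/2 a^T G (H^T H)^{-1} G^T a - o^T a ,
    u = [w; b] = -(H^T H)^{-1} G^T a ,

with a small ridge on H^T H for numerical rank-deficiency.

Prediction for both models assigns the class of the nearer plane under the
norm-normalised distance |w_i^T x (-/+) b_i| / ||w_i||; ties break to class 1
(AD when the conventional labels (1, 0) are used), biasing toward sensitivity.
Linear kernels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from sklearn.svm import SVC

__all__ = [
    "GEPSVMModel", "TSVMModel", "LinearSVMModel",
    "fit_gepsvm", "predict_gepsvm",
    "fit_tsvm", "predict_tsvm", "tsvm_primal_objective",
    "fit_linear_svm", "predict_linear_svm", "svm_primal_objective",
]


@dataclass
class Plane:
    w: np.ndarray
    b: float

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.w))


@dataclass
class GEPSVMModel:
    plane1: Plane
    plane2: Plane
    tikhonov_t: float
    eigenvalues: tuple[float, float]
    eigen_residuals: tuple[float, float]    # ||P U - lambda Q U|| / ||U||
    labels: tuple = (1, 0)


@dataclass
class TSVMModel:
    plane1: Plane
    plane2: Plane
    c1: float
    c2: float
    slack_summaries: tuple[float, float]    # total slack per QP
    objectives: tuple[float, float]         # primal objective per QP
    kkt_residuals: dict = field(default_factory=dict)
    labels: tuple = (1, 0)


@dataclass
class LinearSVMModel:
    w: np.ndarray
    b: float
    C: float
    labels: tuple = (1, 0)


def _as_2d(X, name):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError(f"{name} must be a non-empty 2D sample matrix")
    return X


def _check_dim(X, p):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != p:
        raise ValueError(f"dimension mismatch: {X.shape[1]} features vs model {p}")
    return X


# ---------------------------------------------------------------------------
# GEPSVM


def _min_generalized_eig(P: np.ndarray, Q: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Smallest finite generalized eigenvalue of P U = lambda Q U.

    Solved by the QZ algorithm, which tolerates a singular denominator
    (directions in null(Q) surface as infinite eigenvalues and are skipped).
    Candidate eigenpairs are accepted only if their residual
    ||P U - lambda Q U|| is numerically clean; a pencil with no clean finite
    eigenpair raises with the suggestion to set the Tikhonov factor t > 0.
    Returns (eigenvalue, unit eigenvector, residual).
    """
    evals, evecs = linalg.eig(P, Q)  # QZ: robust to a singular denominator
    finite = np.isfinite(evals) & (np.abs(evals.imag) < 1e-8 * (1 + np.abs(evals.real)))
    evals = evals.real
    evecs = evecs.real
    if not np.any(finite):
        raise linalg.LinAlgError(
            "no finite generalized eigenvalue; set Tikhonov t > 0")
    scale = max(np.linalg.norm(P), np.linalg.norm(Q))
    best = None
    for idx in np.argsort(np.where(finite, evals, np.inf)):
        if not finite[idx]:
            break
        lam = float(evals[idx])
        vec = evecs[:, idx]
        vec = vec / np.linalg.norm(vec)
        resid = float(np.linalg.norm(P @ vec - lam * (Q @ vec)))
        if resid <= 1e-6 * max(scale, 1.0):
            return lam, vec, resid
        if best is None:
            best = (lam, vec, resid)
    # no numerically clean eigenpair: the pencil is effectively defective
    raise linalg.LinAlgError(
        "generalized eigenproblem is ill-conditioned (singular denominator); "
        "set Tikhonov t > 0")


def fit_gepsvm(X1, X2, t: float = 1e-4, labels: tuple = (1, 0)) -> GEPSVMModel:
    """Fit both GEPSVM planes by two generalized eigenvalue problems.

    ``t`` is the Tikhonov factor added to the numerator matrix of each
    Rayleigh quotient.  Raises when the denominator matrix is singular and
    ``t = 0`` (the quotient is then ill-posed; set ``t > 0``).
    """
    X1 = _as_2d(X1, "X1")
    X2 = _as_2d(X2, "X2")
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("X1 and X2 must share the feature dimension")
    if t < 0:
        raise ValueError("Tikhonov factor t must be >= 0")
    p = X1.shape[1]
    G1 = np.hstack([X1, -np.ones((X1.shape[0], 1))])
    G2 = np.hstack([X2, -np.ones((X2.shape[0], 1))])
    A = G1.T @ G1    # class-1 scatter (augmented)
    B = G2.T @ G2    # class-2 scatter (augmented)
    eye = np.eye(p + 1)

    planes, lams, resids = [], [], []
    for num, den in ((A, B), (B, A)):
        lam, vec, resid = _min_generalized_eig(num + t * eye, den)
        planes.append(Plane(w=vec[:p].copy(), b=float(vec[p])))
        lams.append(lam)
        resids.append(resid)
    return GEPSVMModel(plane1=planes[0], plane2=planes[1], tikhonov_t=float(t),
                       eigenvalues=(lams[0], lams[1]),
                       eigen_residuals=(resids[0], resids[1]), labels=labels)


def predict_gepsvm(model: GEPSVMModel, X) -> np.ndarray:
    """Assign each sample the class of the nearer plane (|w^T x - b|/||w||);
    ties go to class 1."""
    X = _check_dim(X, model.plane1.w.size)
    d1 = np.abs(X @ model.plane1.w - model.plane1.b) / model.plane1.norm
    d2 = np.abs(X @ model.plane2.w - model.plane2.b) / model.plane2.norm
    return np.where(d1 <= d2, model.labels[0], model.labels[1])


# ---------------------------------------------------------------------------
# TSVM


def _tsvm_qp(H: np.ndarray, G: np.ndarray, c: float):
    """Solve one twin-SVM QP through its box-constrained dual.

    min_u 1/2 ||H u||^2 + c 1^T q  s.t.  -G u + q >= 1, q >= 0.
    Returns (u, q, alpha, primal_objective, kkt) where kkt holds the duality
    gap, the maximum primal-feasibility violation and the maximum
    complementary-slackness product.
    """
    m = G.shape[0]
    K = H.T @ H
    K = K + (1e-8 * np.trace(K) + 1e-12) * np.eye(K.shape[0])
    cho = linalg.cho_factor(K)
    GKiGt = G @ linalg.cho_solve(cho, G.T)
    ones = np.ones(m)

    def fun(alpha):
        Ma = GKiGt @ alpha
        return 0.5 * alpha @ Ma - ones @ alpha, Ma - ones

    res = optimize.minimize(
        fun, x0=np.full(m, min(c, 1.0) / 2), jac=True, method="L-BFGS-B",
        bounds=[(0.0, c)] * m,
        options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"TSVM dual QP failed: {res.message}")
    alpha = np.clip(res.x, 0.0, c)
    u = -linalg.cho_solve(cho, G.T @ alpha)
    margins = G @ u                       # constraint: -margins + q >= 1
    q = np.maximum(0.0, 1.0 + margins)
    primal = 0.5 * float(u @ (K @ u)) + c * float(q.sum())
    dual = float(ones @ alpha) - 0.5 * float(alpha @ (GKiGt @ alpha))
    kkt = {
        "duality_gap": primal - dual,
        "primal_infeasibility": float(np.maximum(0.0, 1.0 + margins - q).max(initial=0.0)),
        "comp_slackness": float(np.abs((c - alpha) * q).max(initial=0.0)),
        "solver_status": res.message if isinstance(res.message, str) else str(res.message),
    }
    return u, q, alpha, primal, kkt


def fit_tsvm(X1, X2, c1: float = 1.0, c2: float = 1.0,
             labels: tuple = (1, 0)) -> TSVMModel:
    """Fit both TSVM planes by solving the pair of convex QPs (via duals)."""
    X1 = _as_2d(X1, "X1")
    X2 = _as_2d(X2, "X2")
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("X1 and X2 must share the feature dimension")
    if c1 <= 0 or c2 <= 0:
        raise ValueError("penalties c1, c2 must be positive")
    p = X1.shape[1]
    H1 = np.hstack([X1, np.ones((X1.shape[0], 1))])
    H2 = np.hstack([X2, np.ones((X2.shape[0], 1))])

    u1, q1, _, obj1, kkt1 = _tsvm_qp(H1, H2, c1)
    u2, q2, _, obj2, kkt2 = _tsvm_qp(H2, H1, c2)
    return TSVMModel(
        plane1=Plane(w=u1[:p].copy(), b=float(u1[p])),
        plane2=Plane(w=u2[:p].copy(), b=float(u2[p])),
        c1=float(c1), c2=float(c2),
        slack_summaries=(float(q1.sum()), float(q2.sum())),
        objectives=(obj1, obj2),
        kkt_residuals={"plane1": kkt1, "plane2": kkt2},
        labels=labels,
    )


def tsvm_primal_objective(X_own, X_other, w, b, c) -> float:
    """Primal objective of one twin-SVM QP at (w, b) with optimal slack."""
    X_own = _as_2d(X_own, "X_own")
    X_other = _as_2d(X_other, "X_other")
    prox = X_own @ w + b
    q = np.maximum(0.0, 1.0 + (X_other @ w + b))
    return 0.5 * float(prox @ prox) + c * float(q.sum())


def predict_tsvm(model: TSVMModel, X) -> np.ndarray:
    """Nearer plane (|w^T x + b|/||w||) wins; ties go to class 1."""
    X = _check_dim(X, model.plane1.w.size)
    d1 = np.abs(X @ model.plane1.w + model.plane1.b) / model.plane1.norm
    d2 = np.abs(X @ model.plane2.w + model.plane2.b) / model.plane2.norm
    return np.where(d1 <= d2, model.labels[0], model.labels[1])


# ---------------------------------------------------------------------------
# linear SVM baseline


def fit_linear_svm(X1, X2, C: float = 1.0, labels: tuple = (1, 0),
                   tol: float = 1e-3, max_iter: int = 200_000) -> LinearSVMModel:
    """Soft-margin linear SVM baseline (single maximum-margin hyperplane).

    Class 1 is the positive class.  Delegates the QP to libsvm's SMO solver.
    """
    X1 = _as_2d(X1, "X1")
    X2 = _as_2d(X2, "X2")
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("X1 and X2 must share the feature dimension")
    if C <= 0:
        raise ValueError("C must be positive")
    X = np.vstack([X1, X2])
    y = np.concatenate([np.ones(X1.shape[0]), -np.ones(X2.shape[0])])
    if X1.shape[0] == 0 or X2.shape[0] == 0 or np.allclose(X, X[0]):
        # degenerate geometry: no margin information; constant majority vote
        maj = 1.0 if X1.shape[0] >= X2.shape[0] else -1.0
        return LinearSVMModel(w=np.zeros(X.shape[1]), b=maj, C=float(C), labels=labels)
    clf = SVC(kernel="linear", C=C, tol=tol, max_iter=max_iter)
    clf.fit(X, y)
    sign = 1.0 if clf.classes_[1] == 1.0 else -1.0
    return LinearSVMModel(w=sign * clf.coef_.ravel().copy(),
                          b=float(sign * clf.intercept_[0]), C=float(C),
                          labels=labels)


def svm_primal_objective(model: LinearSVMModel, X1, X2) -> float:
    """1/2 ||w||^2 + C * sum hinge, evaluated at the fitted hyperplane."""
    X1 = _as_2d(X1, "X1")
    X2 = _as_2d(X2, "X2")
    m1 = X1 @ model.w + model.b
    m2 = X2 @ model.w + model.b
    hinge = np.sum(np.maximum(0.0, 1.0 - m1)) + np.sum(np.maximum(0.0, 1.0 + m2))
    return 0.5 * float(model.w @ model.w) + model.C * float(hinge)


def predict_linear_svm(model: LinearSVMModel, X) -> np.ndarray:
    X = _check_dim(X, model.w.size)
    return np.where(X @ model.w + model.b >= 0, model.labels[0], model.labels[1])
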