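"""Regularized Fisher discriminant analysis with PSO-selected shrinkage.

The binary target/non-target classifier maximizes

    J(w) = <w, m_t - m_nt>^2 / (w' S_w w + lambda ||w||^2)

where m_t, m_nt are the class means and S_w the pooled within-class
covariance. The maximizer (up to positive scale) is the closed form

    w = (S_w + lambda I)^{-1} (m_t - m_nt),

with a midpoint bias b = -w'(m_t + m_nt)/2 so that score w'x + b is the
signed distance from the decision hyperplane (positive = target). The
ridge term lambda is essential when the 1,600-dimensional features
outnumber the training epochs and S_w is singular; it is chosen by
global-best particle-swarm optimization of the inner 5-fold
cross-validated balanced accuracy over log10(lambda).

Implementation note: each training fold's scatter is eigendecomposed once
(thin-SVD Gram route when n < D), so w(lambda) for any lambda costs two
matrix-vector products. This makes the hundreds of lambda evaluations a
PSO run needs cheap, and is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SingularMatrixError, StratificationError

_RANK_TOL = 1e-10


@dataclass
class FDAModel:
    """Fitted discriminant: weights, bias, shrinkage and class summaries."""

    w: np.ndarray
    bias: float
    lam: float
    m_t: np.ndarray
    m_nt: np.ndarray
    n_t: int
    n_nt: int

    @property
    def dim(self) -> int:
        return self.w.size


@dataclass
class PsoConfig:
    """Global-best PSO settings for the log10(lambda) search.

    Defaults (20 particles, 30 iterations, omega = 0.72, c1 = c2 = 1.49,
    reflecting boundaries, velocity clamped to half the domain width) are
    standard constricted-swarm choices; the search domain spans
    log10(lambda) in [-6, 3].
    """

    n_particles: int = 20
    n_iterations: int = 30
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    log10_lambda_bounds: tuple[float, float] = (-6.0, 3.0)
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        lo, hi = self.log10_lambda_bounds
        if not np.isfinite([lo, hi]).all() or lo >= hi:
            raise ValueError("log10_lambda_bounds must be a finite interval")


def _class_split(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, bool)
    Xt, Xnt = X[y], X[~y]
    if Xt.shape[0] == 0 or Xnt.shape[0] == 0:
        raise ValueError("both classes must be present")
    return Xt, Xnt


def within_class_scatter(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled within-class covariance S_w, normalized by 1/(n - 2)."""
    Xt, Xnt = _class_split(np.asarray(X, float), y)
    n = Xt.shape[0] + Xnt.shape[0]
    ct = Xt - Xt.mean(axis=0)
    cnt = Xnt - Xnt.mean(axis=0)
    return (ct.T @ ct + cnt.T @ cnt) / (n - 2)


def fda_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray,
                  lam: float) -> float:
    """The Fisher criterion J(w) evaluated directly (test/oracle helper)."""
    Xt, Xnt = _class_split(np.asarray(X, float), y)
    d = Xt.mean(axis=0) - Xnt.mean(axis=0)
    S = within_class_scatter(X, y)
    w = np.asarray(w, float)
    denom = w @ S @ w + lam * (w @ w)
    return float((w @ d) ** 2 / denom)


class FdaSolver:
    """Eigendecomposition-cached closed-form rFDA solver for one dataset.

    Solves (S_w + lambda I) w = m_t - m_nt for any lambda after a single
    factorization. When the feature dimension exceeds the sample count the
    decomposition runs in the n-dimensional data subspace (thin SVD of the
    centered data), and the orthogonal complement -- where S_w acts as
    zero -- is handled analytically.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray) -> None:
        X = np.asarray(X, float)
        Xt, Xnt = _class_split(X, y)
        self.n_t, self.n_nt = Xt.shape[0], Xnt.shape[0]
        n, D = X.shape
        self.dim = D
        self.m_t = Xt.mean(axis=0)
        self.m_nt = Xnt.mean(axis=0)
        self.d = self.m_t - self.m_nt
        centered = np.vstack([Xt - self.m_t, Xnt - self.m_nt])
        norm = n - 2 if n > 2 else 1
        if D <= n:
            S = centered.T @ centered / norm
            evals, evecs = np.linalg.eigh(S)
            self.evals = np.clip(evals, 0.0, None)
            self.evecs = evecs
            self.rank_deficient = bool(
                self.evals.min() <= _RANK_TOL * max(self.evals.max(), 1.0)
            )
            self._subspace = False
        else:
            # Thin SVD of centered data: S_w = Q diag(s^2/(n-2)) Q'.
            _, s, vt = np.linalg.svd(centered, full_matrices=False)
            keep = s > _RANK_TOL * max(s[0] if s.size else 0.0, 1.0)
            self.Q = vt[keep].T                 # (D, r)
            self.evals = s[keep] ** 2 / norm
            self.rank_deficient = True          # complement always null
            self._subspace = True

    def solve(self, lam: float) -> np.ndarray:
        """w = (S_w + lam I)^{-1} (m_t - m_nt)."""
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        if lam == 0 and self.rank_deficient:
            raise SingularMatrixError(
                "S_w is singular with lambda = 0; use lambda > 0"
            )
        if not self._subspace:
            return self.evecs @ ((self.evecs.T @ self.d) / (self.evals + lam))
        proj = self.Q.T @ self.d
        w = self.Q @ (proj / (self.evals + lam))
        w += (self.d - self.Q @ proj) / lam
        return w

    def model(self, lam: float) -> FDAModel:
        w = self.solve(lam)
        bias = float(-w @ (self.m_t + self.m_nt) / 2.0)
        return FDAModel(w=w, bias=bias, lam=float(lam), m_t=self.m_t,
                        m_nt=self.m_nt, n_t=self.n_t, n_nt=self.n_nt)


def fit_fda(X: np.ndarray, y: np.ndarray, lam: float) -> FDAModel:
    """Closed-form regularized Fisher discriminant.

    ``y`` is boolean (True = target). Raises
    :class:`SingularMatrixError` when lambda = 0 and S_w is singular.
    """
    return FdaSolver(X, y).model(lam)


def score(model: FDAModel, x: np.ndarray) -> np.ndarray | float:
    """Signed hyperplane distance w'x + b; positive means target.

    Accepts a single feature vector or a (n, D) batch.
    """
    x = np.asarray(x, float)
    if x.shape[-1] != model.dim:
        raise ValueError(f"feature dim {x.shape[-1]} != model dim {model.dim}")
    out = x @ model.w + model.bias
    return float(out) if out.ndim == 0 else out


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Index folds with both classes represented in each."""
    y = np.asarray(y, bool)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    for f in folds:
        fy = y[np.asarray(f, int)] if f else np.array([], bool)
        if fy.size == 0 or fy.all() or not fy.any():
            raise StratificationError(
                "cannot form inner folds with both classes present"
            )
    return [np.sort(np.asarray(f, int)) for f in folds]


def _balanced_accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    pred = scores > 0
    tpr = np.mean(pred[y]) if y.any() else 0.0
    tnr = np.mean(~pred[~y]) if (~y).any() else 0.0
    return float((tpr + tnr) / 2.0)


def cv_fitness(lams: np.ndarray, solvers: list[FdaSolver],
               val_sets: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Inner-CV balanced accuracy of each lambda (vector-evaluated)."""
    out = np.zeros(len(lams))
    for i, lam in enumerate(lams):
        accs = []
        for solver, (Xv, yv) in zip(solvers, val_sets):
            model = solver.model(lam)
            accs.append(_balanced_accuracy(score(model, Xv), yv))
        out[i] = np.mean(accs)
    return out


def pso_select_lambda(
    X: np.ndarray, y: np.ndarray, config: PsoConfig | None = None
) -> tuple[float, pd.DataFrame]:
    """Select lambda by global-best PSO over log10(lambda).

    Fitness is the mean balanced classification accuracy (threshold 0)
    over ``config.inner_folds`` stratified folds of the training data.
    Deterministic given ``config.seed``. Returns the best lambda and a
    per-iteration trace (iteration, best_fitness, best_log10_lambda).
    """
    config = config if config is not None else PsoConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, bool)
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(y, config.inner_folds, rng)
    all_idx = np.arange(X.shape[0])
    solvers, val_sets = [], []
    for f in folds:
        train = np.setdiff1d(all_idx, f)
        solvers.append(FdaSolver(X[train], y[train]))
        val_sets.append((X[f], y[f]))

    lo, hi = config.log10_lambda_bounds
    width = hi - lo
    vmax = width / 2.0
    pos = rng.uniform(lo, hi, size=config.n_particles)
    vel = rng.uniform(-vmax, vmax, size=config.n_particles)
    fit = cv_fitness(10.0 ** pos, solvers, val_sets)
    pbest_pos, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmax(fit))
    gbest_pos, gbest_fit = float(pos[g]), float(fit[g])
    trace = [(0, gbest_fit, gbest_pos)]

    for it in range(1, config.n_iterations + 1):
        r1 = rng.random(config.n_particles)
        r2 = rng.random(config.n_particles)
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest_pos - pos)
               + config.social * r2 * (gbest_pos - pos))
        vel = np.clip(vel, -vmax, vmax)
        pos = pos + vel
        # Reflecting boundaries.
        over, under = pos > hi, pos < lo
        pos[over] = 2 * hi - pos[over]
        pos[under] = 2 * lo - pos[under]
        np.clip(pos, lo, hi, out=pos)
        vel[over | under] *= -1.0
        fit = cv_fitness(10.0 ** pos, solvers, val_sets)
        better = fit > pbest_fit
        pbest_pos[better] = pos[better]
        pbest_fit[better] = fit[better]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest_pos = float(pbest_pos[g])
        trace.append((it, gbest_fit, gbest_pos))

    trace_df = pd.DataFrame(trace, columns=["iteration", "best_fitness",
                                            "best_log10_lambda"])
    return 10.0 ** gbest_pos, trace_df
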