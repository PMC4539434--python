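"""Principal differential analysis for a second-order varying-coefficient ODE.

Curves x_i(t) and the two coefficient functions of the operator

    L(x) = x'' + w1(t) x' + w0(t) x

are expanded in one shared Fourier basis.  Estimation alternates between

1. penalized smoothing of each observed curve, where the roughness penalty
   is ``lam * int L(x_i)^2 dt`` for the current operator, and
2. a closed-form least-squares update of the operator's expansion
   coefficients given the smoothed curves,

until the coefficient vector stabilizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .basis import FourierBasis
from .coverage import ExpressionCurve

__all__ = [
    "OdeCoefficients",
    "StateFit",
    "PdaResult",
    "ode_penalty_matrix",
    "smooth_states",
    "estimate_coefficients",
    "sse_penalty",
    "fit_pda",
    "select_lambda",
]

#: condition number beyond which linear solves fall back to a pseudo-inverse
COND_LIMIT = 1e12


def _solve_psd(
    A: np.ndarray, b: np.ndarray, what: str, rcond: float = 1e-10
) -> tuple[np.ndarray, bool]:
    """Solve A x = b; pseudo-inverse fallback for ill-conditioned systems.

    ``rcond`` sets the relative singular-value cutoff of the fallback: the
    smoothing systems want an accurate solve (tiny cutoff), while the
    operator update is deliberately truncated hard — with few curves the
    weakly determined directions of that system carry no signal, only
    noise amplification, and keeping them makes the outer iteration diverge.
    """
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        warnings.warn(
            f"{what}: condition number {cond:.3g} exceeds {COND_LIMIT:.0e}; "
            "using Moore-Penrose pseudo-inverse",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.linalg.pinv(A, rcond=rcond) @ b, True
    return np.linalg.solve(A, b), False


@dataclass
class OdeCoefficients:
    """Basis-expansion coefficients of the operator weights w0(t), w1(t)."""

    h0: np.ndarray
    h1: np.ndarray
    basis: FourierBasis

    def __post_init__(self) -> None:
        self.h0 = np.asarray(self.h0, dtype=float)
        self.h1 = np.asarray(self.h1, dtype=float)
        K = self.basis.n_basis
        if self.h0.shape != (K,) or self.h1.shape != (K,):
            raise ValueError(f"h0 and h1 must be length-{K} vectors")
        if not (np.all(np.isfinite(self.h0)) and np.all(np.isfinite(self.h1))):
            raise ValueError("non-finite ODE coefficients")

    @classmethod
    def zero(cls, basis: FourierBasis) -> "OdeCoefficients":
        K = basis.n_basis
        return cls(h0=np.zeros(K), h1=np.zeros(K), basis=basis)

    @property
    def h(self) -> np.ndarray:
        """Stacked vector [h1, h0] (first-derivative block first)."""
        return np.concatenate([self.h1, self.h0])

    def _weight_function(self, h: np.ndarray):
        # direct trig evaluation; equivalent to basis.evaluate(t, 0) @ h but
        # cheap for the scalar calls made inside ODE integrators
        a, b = self.basis.domain
        P = b - a
        om = 2.0 * np.pi * np.arange(1, (self.basis.n_basis - 1) // 2 + 1) / P
        amp = np.sqrt(2.0 / P)
        c0 = h[0] / np.sqrt(P)
        hs = amp * h[1::2]
        hc = amp * h[2::2]

        def w(t, _a=a, _om=om, _c0=c0, _hs=hs, _hc=hc):
            arg = np.multiply.outer(np.asarray(t, dtype=float) - _a, _om)
            return _c0 + np.sin(arg) @ _hs + np.cos(arg) @ _hc

        return w

    @property
    def w0(self):
        """Callable w0(t) = h0^T phi(t)."""
        f = self.__dict__.get("_w0_fn")
        if f is None:
            f = self.__dict__["_w0_fn"] = self._weight_function(self.h0)
        return f

    @property
    def w1(self):
        """Callable w1(t) = h1^T phi(t)."""
        f = self.__dict__.get("_w1_fn")
        if f is None:
            f = self.__dict__["_w1_fn"] = self._weight_function(self.h1)
        return f


@dataclass
class StateFit:
    """Penalized-smoothing result: one expansion coefficient row per curve."""

    C: np.ndarray  # (n_samples, K)
    basis: FourierBasis
    lam: float
    rss: np.ndarray  # per-sample residual sum of squares
    pseudo_inverse_used: bool = False

    def evaluate(self, i: int, t: np.ndarray, deriv: int = 0) -> np.ndarray:
        """Fitted curve (or derivative) for sample ``i`` at points ``t``."""
        return self.basis.evaluate(t, deriv) @ self.C[i]


@dataclass
class PdaResult:
    states: StateFit
    coefficients: OdeCoefficients
    n_iter: int
    converged: bool
    sse_path: list[float] = field(default_factory=list)


def _psi_on_grid(basis: FourierBasis, coeffs: OdeCoefficients) -> np.ndarray:
    """Psi(t) = phi'' + phi' (phi^T h1) + phi (phi^T h0) on the quadrature grid."""
    D0 = basis.grid_matrix(0)
    D1 = basis.grid_matrix(1)
    D2 = basis.grid_matrix(2)
    return D2 + D1 * (D0 @ coeffs.h1)[:, None] + D0 * (D0 @ coeffs.h0)[:, None]


def ode_penalty_matrix(
    basis: FourierBasis, coeffs: OdeCoefficients | None = None
) -> np.ndarray:
    """Penalty matrix J = int Psi(t) Psi(t)^T dt (symmetric PSD).

    With ``coeffs=None`` (operator zero) this reduces to the plain
    second-derivative roughness penalty int phi'' phi''^T dt.
    """
    if coeffs is None:
        coeffs = OdeCoefficients.zero(basis)
    Psi = _psi_on_grid(basis, coeffs)
    return basis.inner_product(Psi, Psi)


def smooth_states(
    curves: Sequence[ExpressionCurve],
    basis: FourierBasis,
    coeffs: OdeCoefficients | None = None,
    lam: float = 0.0,
) -> StateFit:
    """Penalized least-squares smoothing of each curve.

    Per curve, ``C_i = (Phi^T Phi + lam J)^{-1} Phi^T y_i`` with ``Phi`` the
    basis evaluated at that curve's own observation points; curves decouple,
    so each is solved independently.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if len(curves) == 0:
        raise ValueError("no curves to smooth")
    J = ode_penalty_matrix(basis, coeffs)
    K = basis.n_basis
    C = np.empty((len(curves), K))
    rss = np.empty(len(curves))
    pinv_used = False
    for i, curve in enumerate(curves):
        Phi = basis.evaluate(curve.t, 0)
        A = Phi.T @ Phi + lam * J
        if lam == 0.0 and curve.t.size < K:
            raise np.linalg.LinAlgError(
                f"curve {curve.sample_id!r} has {curve.t.size} points < "
                f"{K} basis functions with lam=0; raise lam or lower n_basis"
            )
        c, used = _solve_psd(A, Phi.T @ curve.y, "smooth_states")
        pinv_used |= used
        C[i] = c
        r = curve.y - Phi @ c
        rss[i] = float(r @ r)
    return StateFit(C=C, basis=basis, lam=lam, rss=rss, pseudo_inverse_used=pinv_used)


def estimate_coefficients(
    fit: StateFit, basis: FourierBasis, rcond: float | None = None
) -> OdeCoefficients:
    """Closed-form update of the operator coefficients given smoothed curves.

    Solves the normal equations of ``min_h int || C* Psi_h(t) ||^2 dt``:

        h = - [ int G^T M G dt ]^{-1} [ int G^T M phi'' dt ],

    with ``M = C*^T C*`` and ``G(t) = [phi' phi^T, phi phi^T]``.

    ``rcond`` is the singular-value cutoff of the pseudo-inverse fallback
    for a (near-)singular system.  By default it is 1e-8, except for
    single-curve fits (1e-2): one noisy curve against 2K operator
    parameters leaves most directions signal-free, and without hard
    truncation the outer alternation can run away to exploding operators.
    """
    if fit.basis is not basis and fit.basis.n_basis != basis.n_basis:
        raise ValueError("StateFit basis does not match the supplied basis")
    Cs = fit.C
    if not np.any(Cs):
        raise ValueError("all-zero expansion coefficients: no signal to fit")
    if rcond is None:
        rcond = 1e-2 if Cs.shape[0] == 1 else 1e-8
    M = Cs.T @ Cs
    D0 = basis.grid_matrix(0)
    D1 = basis.grid_matrix(1)
    D2 = basis.grid_matrix(2)
    w = basis.quad_weights
    K = basis.n_basis

    # Block (a, b) of int G^T M G dt is  D0^T diag(w * s_ab) D0  where
    # s_ab(t) = d_a(t)^T M d_b(t) and d_1 = phi', d_0 = phi.
    s11 = np.einsum("ki,ij,kj->k", D1, M, D1)
    s10 = np.einsum("ki,ij,kj->k", D1, M, D0)
    s00 = np.einsum("ki,ij,kj->k", D0, M, D0)
    A = np.empty((2 * K, 2 * K))
    A[:K, :K] = D0.T @ (D0 * (w * s11)[:, None])
    A[:K, K:] = D0.T @ (D0 * (w * s10)[:, None])
    A[K:, :K] = A[:K, K:].T
    A[K:, K:] = D0.T @ (D0 * (w * s00)[:, None])

    u1 = np.einsum("ki,ij,kj->k", D1, M, D2)
    u0 = np.einsum("ki,ij,kj->k", D0, M, D2)
    rhs = np.concatenate([D0.T @ (w * u1), D0.T @ (w * u0)])

    h, _ = _solve_psd(A, rhs, "estimate_coefficients", rcond=rcond)
    h = -h
    return OdeCoefficients(h0=h[K:], h1=h[:K], basis=basis)


def sse_penalty(fit: StateFit, coeffs: OdeCoefficients) -> float:
    """Integrated squared operator residual  int sum_i L(x_i)^2 dt."""
    Psi = _psi_on_grid(fit.basis, coeffs)
    Lmat = Psi @ fit.C.T  # (n_quad, n_samples)
    return float(np.sum(fit.basis.quad_weights[:, None] * Lmat**2))


def fit_pda(
    curves: Sequence[ExpressionCurve],
    n_basis: int = 11,
    lam: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 20,
    basis: FourierBasis | None = None,
    estimate_rcond: float | None = None,
) -> PdaResult:
    """Alternate penalized smoothing and coefficient estimation to convergence.

    The operator starts at zero (pure curvature penalty).  Convergence is
    declared when the relative change ``||h_new - h_old|| / (1 + ||h_old||)``
    drops below ``tol``; with ``tol = inf`` exactly one
    smooth-then-estimate pass is performed.  Non-convergence is reported via
    the ``converged`` flag, not an exception.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    if basis is None:
        basis = FourierBasis(n_basis=n_basis)
    coeffs = OdeCoefficients.zero(basis)
    states = smooth_states(curves, basis, coeffs, lam)
    sse_path: list[float] = []
    converged = False
    n_iter = 0
    best: tuple[float, OdeCoefficients, StateFit] | None = None
    for n_iter in range(1, max_iter + 1):
        new_coeffs = estimate_coefficients(states, basis, rcond=estimate_rcond)
        sse_path.append(sse_penalty(states, new_coeffs))
        delta = np.linalg.norm(new_coeffs.h - coeffs.h) / (
            1.0 + np.linalg.norm(coeffs.h)
        )
        coeffs = new_coeffs
        states = smooth_states(curves, basis, coeffs, lam)
        # joint objective of Eq-style penalized smoothing: the alternation is
        # block coordinate descent on it, so it is the comparable score
        objective = float(states.rss.sum()) + lam * sse_penalty(states, coeffs)
        if best is None or objective < best[0]:
            best = (objective, coeffs, states)
        if delta < tol:
            converged = True
            break
    if not converged:
        if np.isfinite(tol):
            warnings.warn(
                f"fit_pda did not converge in {max_iter} iterations "
                f"(last relative change {delta:.3g}); returning the iterate "
                "with the smallest operator residual",
                RuntimeWarning,
            )
        # the alternation can cycle without contracting; hand back the
        # iterate that best annihilated the smoothed curves
        _, coeffs, states = best
    return PdaResult(
        states=states,
        coefficients=coeffs,
        n_iter=n_iter,
        converged=converged,
        sse_path=sse_path,
    )


def select_lambda(
    curves: Sequence[ExpressionCurve],
    n_basis: int,
    lambda_grid: Sequence[float],
    folds: int = 5,
    seed: int = 0,
    method: str = "reconstruction",
) -> float:
    """Choose the smoothing weight by sample-level cross-validation.

    ``method="reconstruction"`` scores a held-out curve by smoothing it with
    the operator trained on the remaining curves and measuring the squared
    error against its observations.  ``method="prediction"`` instead solves
    the trained ODE from the held-out curve's boundary values (the heavier,
    prediction-style protocol).  Deterministic given ``seed``.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda_grid is empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = len(curves)
    if n < folds:
        raise ValueError(f"{n} samples but {folds} folds requested")
    if method not in ("reconstruction", "prediction"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    if method == "prediction":
        from .bvp import predict_curve  # deferred: bvp depends on this module

    errors = np.zeros(len(lambda_grid))
    for li, lam in enumerate(lambda_grid):
        err = 0.0
        for f in range(folds):
            train = [c for c, g in zip(curves, fold_of) if g != f]
            test = [c for c, g in zip(curves, fold_of) if g == f]
            result = fit_pda(train, n_basis=n_basis, lam=lam)
            basis = result.coefficients.basis
            for c in test:
                if method == "reconstruction":
                    sf = smooth_states([c], basis, result.coefficients, lam)
                    yhat = sf.evaluate(0, c.t)
                else:
                    sol = predict_curve(result.coefficients, c, basis, lam=lam)
                    yhat = sol(c.t)
                err += float(np.mean((yhat - c.y) ** 2))
        errors[li] = err / n
    return float(lambda_grid[int(np.argmin(errors))])
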