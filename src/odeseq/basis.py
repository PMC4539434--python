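"""Orthonormal Fourier basis with analytic derivatives and quadrature.

All downstream estimation expands curves, ODE coefficient functions and
penalty operators in one shared basis on the canonical position domain.
The basis carries its own composite-Simpson quadrature grid so that every
inner product in the pipeline is computed with identical weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FourierBasis", "simpson_weights"]


def simpson_weights(n_points: int, a: float, b: float) -> np.ndarray:
    """Composite Simpson weights for ``n_points`` equispaced points on [a, b].

    ``n_points`` must be odd and >= 3.
    """
    if n_points < 3 or n_points % 2 == 0:
        raise ValueError("Simpson quadrature needs an odd number of points >= 3")
    h = (b - a) / (n_points - 1)
    w = np.ones(n_points)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


class FourierBasis:
    """Fourier basis on an interval, orthonormal under the L2 inner product.

    The system consists of the constant function plus sine/cosine pairs at
    integer multiples of the fundamental frequency, so ``n_basis`` must be
    odd.  With ``P = b - a``::

        phi_1(t)      = 1 / sqrt(P)
        phi_{2r}(t)   = sqrt(2/P) * sin(2 pi r (t - a) / P)
        phi_{2r+1}(t) = sqrt(2/P) * cos(2 pi r (t - a) / P)

    Derivatives of order 0, 1 and 2 are analytic (no finite differencing).

    Parameters
    ----------
    n_basis
        Odd number of basis functions, >= 3.
    domain
        Interval ``(a, b)`` with ``b > a``; defaults to the canonical
        rescaled gene interval [0, 100].
    n_quad
        Number of equispaced composite-Simpson quadrature points (odd).
    """

    def __init__(
        self,
        n_basis: int = 11,
        domain: tuple[float, float] = (0.0, 100.0),
        n_quad: int = 1001,
    ) -> None:
        if n_basis < 3:
            raise ValueError(f"n_basis must be >= 3, got {n_basis}")
        if n_basis % 2 == 0:
            raise ValueError(f"n_basis must be odd for a Fourier basis, got {n_basis}")
        a, b = float(domain[0]), float(domain[1])
        if not b > a:
            raise ValueError(f"domain must satisfy b > a, got ({a}, {b})")
        self.n_basis = int(n_basis)
        self.domain = (a, b)
        self.grid = np.linspace(a, b, n_quad)
        self.quad_weights = simpson_weights(n_quad, a, b)
        self._period = b - a

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, t: np.ndarray, deriv: int = 0) -> np.ndarray:
        """Evaluate all basis functions (or a derivative) at points ``t``.

        Returns an array of shape ``(len(t), n_basis)``.
        """
        if deriv not in (0, 1, 2):
            raise ValueError(f"deriv must be 0, 1 or 2, got {deriv}")
        t = np.atleast_1d(np.asarray(t, dtype=float))
        a, b = self.domain
        tol = 1e-9 * self._period
        if np.any(t < a - tol) or np.any(t > b + tol):
            raise ValueError(
                f"evaluation points outside the basis domain [{a}, {b}]"
            )
        P = self._period
        out = np.zeros((t.size, self.n_basis))
        amp = np.sqrt(2.0 / P)
        if deriv == 0:
            out[:, 0] = 1.0 / np.sqrt(P)
        for r in range(1, (self.n_basis - 1) // 2 + 1):
            om = 2.0 * np.pi * r / P
            arg = om * (t - a)
            s, c = np.sin(arg), np.cos(arg)
            if deriv == 0:
                out[:, 2 * r - 1] = amp * s
                out[:, 2 * r] = amp * c
            elif deriv == 1:
                out[:, 2 * r - 1] = amp * om * c
                out[:, 2 * r] = -amp * om * s
            else:
                out[:, 2 * r - 1] = -amp * om**2 * s
                out[:, 2 * r] = -amp * om**2 * c
        return out

    # cached design matrices on the quadrature grid; used heavily by pda
    def grid_matrix(self, deriv: int = 0) -> np.ndarray:
        key = f"_grid_d{deriv}"
        mat = getattr(self, key, None)
        if mat is None:
            mat = self.evaluate(self.grid, deriv)
            setattr(self, key, mat)
        return mat

    # -- quadrature ---------------------------------------------------------

    def inner_product(self, F: np.ndarray, G: np.ndarray) -> np.ndarray:
        """Quadrature inner-product matrix ``int F(t)^T G(t) dt``.

        ``F`` and ``G`` are function values on the quadrature grid, shape
        ``(n_quad, p)`` and ``(n_quad, q)``; the result is ``p x q``.
        Symmetric and PSD when ``F is G``.
        """
        F = np.atleast_2d(np.asarray(F, dtype=float))
        G = np.atleast_2d(np.asarray(G, dtype=float))
        if F.shape[0] != self.grid.size or G.shape[0] != self.grid.size:
            raise ValueError(
                "function values must be evaluated on the quadrature grid "
                f"({self.grid.size} points); got {F.shape[0]} and {G.shape[0]}"
            )
        M = (F * self.quad_weights[:, None]).T @ G
        if F is G:
            M = 0.5 * (M + M.T)
        return M

    def gram(self) -> np.ndarray:
        """Gram matrix of the basis under quadrature (identity by design)."""
        Phi = self.grid_matrix(0)
        return self.inner_product(Phi, Phi)

    def __repr__(self) -> str:  # pragma: no cover
        a, b = self.domain
        return f"FourierBasis(n_basis={self.n_basis}, domain=({a:g}, {b:g}))"
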