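"""Synthetic expression curves drawn from a known varying-coefficient ODE.

Each sample is an exact solution of  x'' + w1(t) x' + w0(t) x = 0  with
random boundary values, observed at equispaced positions with additive
iid Gaussian measurement noise.  Because the equation is linear, every
sample is a combination of the two fundamental solutions, which are
integrated once per specification; generation is therefore cheap enough
for Monte-Carlo calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .bvp import fundamental_solutions
from .coverage import ExpressionCurve

__all__ = [
    "SimulationSpec",
    "default_w0",
    "default_w1",
    "generate_curves",
    "generate_two_group",
]


def default_w0(t: np.ndarray) -> np.ndarray:
    """Default truth: (8*pi/100)^2 * (1 + 0.5 sin(2*pi*t/100)).

    The carrier frequency is four times the fundamental so that solutions
    oscillate several times across the domain; slower truths produce curves
    whose second derivative is too small relative to the representation
    error of a non-periodic function in a periodic basis, and the
    coefficient functions stop being recoverable.
    """
    return (8.0 * np.pi / 100.0) ** 2 * (1.0 + 0.5 * np.sin(2.0 * np.pi * np.asarray(t) / 100.0))


def default_w1(t: np.ndarray) -> np.ndarray:
    """Default truth: 0.01 * cos(2*pi*t/100)."""
    return 0.01 * np.cos(2.0 * np.pi * np.asarray(t) / 100.0)


@dataclass
class SimulationSpec:
    w0: Callable[[np.ndarray], np.ndarray] = default_w0
    w1: Callable[[np.ndarray], np.ndarray] = default_w1
    boundary_mean: tuple[float, float] = (1.0, 1.0)
    boundary_sd: tuple[float, float] = (1.0, 1.0)
    boundary_corr: float = 0.8
    noise_sd: float = 0.1
    n_samples: int = 20
    n_positions: int = 201
    domain: tuple[float, float] = (0.0, 100.0)
    seed: int = 0
    gene_id: str = "simulated"
    group: str | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_positions < 10:
            raise ValueError("n_positions must be >= 10")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if min(self.boundary_sd) < 0:
            raise ValueError("boundary_sd must be >= 0")
        if not -1.0 <= self.boundary_corr <= 1.0:
            raise ValueError("boundary_corr must lie in [-1, 1]")


# fundamental solutions are deterministic per (w0, w1, domain); Monte-Carlo
# experiments regenerate from the same truth thousands of times, so memoize
# on the callables themselves (hashed by identity)
_FUNDAMENTALS: dict = {}


def _cached_fundamentals(w0, w1, domain):
    key = (w0, w1, domain)
    try:
        sols = _FUNDAMENTALS.get(key)
    except TypeError:  # unhashable callables
        return fundamental_solutions((w0, w1), domain)
    if sols is None:
        sols = fundamental_solutions((w0, w1), domain)
        if len(_FUNDAMENTALS) < 64:
            _FUNDAMENTALS[key] = sols
    return sols


def generate_curves(
    spec: SimulationSpec,
) -> tuple[list[ExpressionCurve], np.ndarray, np.ndarray]:
    """Simulate noisy observations of ODE solutions.

    Returns ``(curves, t, truth)`` where ``truth`` holds the noise-free
    states (n_samples x n_positions) on the shared grid ``t``.  Output is
    reproducible bit for bit for a fixed spec.
    """
    a, b = spec.domain
    u, v = _cached_fundamentals(spec.w0, spec.w1, (a, b))
    vb = float(v.sol(b)[0])
    scale = max(1.0, float(np.max(np.abs(v.y[0]))))
    if abs(vb) < 1e-8 * scale:
        raise RuntimeError(
            "the chosen (w0, w1) are resonant on this domain: boundary values "
            "do not determine the solution; change the coefficients or domain"
        )
    ub = float(u.sol(b)[0])
    t = np.linspace(a, b, spec.n_positions)
    u_t = u.sol(t)[0]
    v_t = v.sol(t)[0]

    rng = np.random.default_rng(spec.seed)
    truth = np.empty((spec.n_samples, spec.n_positions))
    curves = []
    rho = spec.boundary_corr
    for i in range(spec.n_samples):
        # correlated endpoint draws: high correlation keeps the periodic
        # extension of each sample nearly continuous, which the Fourier
        # representation downstream relies on
        z1, z2 = rng.normal(size=2)
        xl = spec.boundary_mean[0] + spec.boundary_sd[0] * z1
        xr = spec.boundary_mean[1] + spec.boundary_sd[1] * (
            rho * z1 + np.sqrt(1.0 - rho**2) * z2
        )
        # x = alpha*u + beta*v with x(a)=xl, x(b)=xr; u(a)=1, v(a)=0
        alpha = xl
        beta = (xr - alpha * ub) / vb
        x = alpha * u_t + beta * v_t
        truth[i] = x
        noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else 0.0
        curves.append(
            ExpressionCurve(
                gene_id=spec.gene_id,
                sample_id=f"{spec.group or 'sample'}_{i:03d}",
                t=t.copy(),
                y=x + noise,
                group=spec.group,
            )
        )
    return curves, t, truth


def generate_two_group(
    spec_base: SimulationSpec,
    delta_w0: Callable[[np.ndarray], np.ndarray] | float = 0.0,
    delta_w1: Callable[[np.ndarray], np.ndarray] | float = 0.0,
    group_labels: tuple[str, str] = ("group1", "group2"),
    n_samples_2: int | None = None,
) -> tuple[list[ExpressionCurve], np.ndarray, np.ndarray]:
    """Simulate a labeled two-group dataset.

    Group 1 follows ``spec_base``; group 2 has its coefficient functions
    shifted by ``delta_w0`` / ``delta_w1`` (callables or constants) and an
    independent noise stream.  With zero deltas the two groups are draws
    from one distribution (an exchangeable null).
    """

    def _shift(f, d):
        if callable(d):
            return lambda t, f=f, d=d: f(t) + d(t)
        if d == 0.0:
            return f
        return lambda t, f=f, d=d: f(t) + d

    spec1 = replace(spec_base, group=group_labels[0])
    spec2 = replace(
        spec_base,
        w0=_shift(spec_base.w0, delta_w0),
        w1=_shift(spec_base.w1, delta_w1),
        group=group_labels[1],
        seed=spec_base.seed + 1,
        n_samples=n_samples_2 or spec_base.n_samples,
    )
    curves1, t, truth1 = generate_curves(spec1)
    curves2, _, truth2 = generate_curves(spec2)
    return curves1 + curves2, t, np.vstack([truth1, truth2])
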