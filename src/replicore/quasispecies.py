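"""Eigen quasi-species dynamics on a single-peak landscape with a
two-fidelity replication mixture.

The model tracks a binary-alphabet population of genomes of length ``L``
reduced to Hamming error classes ``0..L`` from the master sequence (the
landscape is permutation-invariant, so classes are sufficient statistics).
The master class has fitness ``sigma > 1``; every other class has fitness 1.
Replication copies each base with per-base error probability ``mu``, except
that a fraction ``p`` of replication events use an error-free polymerase
(``kernel = p*I + (1-p)*B(mu)``). ``p = 0`` recovers the classic uniform
error model; ``p > 0`` encodes a mixture of error-less and error-prone
polymerases — the abstraction of high-fidelity leading-strand synthesis.

The error threshold is defined operationally: the per-base rate ``mu_c`` at
which the stationary master-class frequency falls below ``epsilon`` (default
1e-3). In the classical model the genome-wide threshold sits near
``mu_c * L = ln(sigma)`` — about one mutation per genome per replication for
``sigma = e``. With ``p > 1/sigma`` the error-free channel alone sustains the
master above ``(sigma*p - 1)/(sigma - 1)`` at *any* error rate, so the
threshold disappears entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "SinglePeakLandscape",
    "ReplicationKernel",
    "ThresholdResult",
    "class_transition_matrix",
    "iterate",
    "solve_stationary",
    "find_error_threshold",
    "threshold_phase_table",
    "master_frequency_closed_form",
]

MAX_L = 1000


@dataclass(frozen=True)
class SinglePeakLandscape:
    """Single-peak fitness landscape: master fitness sigma, all others 1."""

    L: int
    sigma: float

    def __post_init__(self) -> None:
        if self.L < 1 or self.L > MAX_L:
            raise ValueError(f"L must be in 1..{MAX_L}, got {self.L}")
        if self.sigma <= 1:
            raise ValueError(f"sigma (master superiority) must be > 1, got {self.sigma}")

    @property
    def fitness(self) -> np.ndarray:
        f = np.ones(self.L + 1)
        f[0] = self.sigma
        return f


@dataclass(frozen=True)
class ReplicationKernel:
    """Per-base error rate ``mu`` and error-free event fraction ``p``."""

    mu: float
    p: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ValueError(f"mu must be in [0, 1), got {self.mu}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class ThresholdResult:
    """Location of the operational error threshold, if any.

    ``mu_critical`` is the per-base rate where the stationary master
    frequency crosses ``epsilon``; ``genome_wide_rate = mu_critical * L``.
    ``exists`` is False when the master stays above ``epsilon`` over the
    whole search range.
    """

    mu_critical: float | None
    genome_wide_rate: float | None
    exists: bool
    epsilon: float
    tol: float


def class_transition_matrix(L: int, kernel: ReplicationKernel) -> np.ndarray:
    """Column-stochastic mutation matrix over Hamming classes.

    ``M[j, i]`` is the probability that copying a class-``i`` parent yields a
    class-``j`` offspring. With per-base symmetric errors, ``k`` of the ``i``
    wrong positions flip back (Binomial(i, mu)) and ``m`` of the ``L - i``
    correct positions flip away (Binomial(L - i, mu)), independently, giving
    class ``j = i - k + m``; the error-free channel contributes ``p`` on the
    diagonal:  ``M = p*I + (1-p)*B(mu)``.
    """
    if L < 1 or L > MAX_L:
        raise ValueError(f"L must be in 1..{MAX_L}, got {L}")
    mu, p = kernel.mu, kernel.p
    if mu < 1e-12:
        # scipy's regularized-beta route is unstable for subnormal mu; the
        # flip probability per genome is < L*1e-12, indistinguishable from 0
        return np.eye(L + 1)

    B = np.zeros((L + 1, L + 1))
    for i in range(L + 1):
        # distribution of i - k over k = 0..i, and of m over 0..L-i
        back = binom.pmf(np.arange(i + 1), i, mu)  # P(k back-flips)
        away = binom.pmf(np.arange(L - i + 1), L - i, mu)  # P(m new errors)
        # convolve: offspring class j = (i - k) + m
        B[:, i] = np.convolve(back[::-1], away)
    M = p * np.eye(L + 1) + (1.0 - p) * B
    return M


def iterate(state: np.ndarray, landscape: SinglePeakLandscape, M: np.ndarray) -> np.ndarray:
    """One discrete quasi-species generation: select, mutate, renormalize."""
    x = np.asarray(state, dtype=float)
    if x.shape != (landscape.L + 1,):
        raise ValueError(f"state must have length L+1={landscape.L + 1}, got {x.shape}")
    y = M @ (landscape.fitness * x)
    total = y.sum()
    if total <= 0:
        raise ValueError("total fitness flux is zero; cannot renormalize")
    return y / total


def solve_stationary(
    landscape: SinglePeakLandscape,
    kernel: ReplicationKernel,
    tol: float = 1e-12,
    max_iter: int = 10**6,
    M: np.ndarray | None = None,
) -> np.ndarray:
    """Stationary error-class distribution (the quasi-species equilibrium).

    The equilibrium is the dominant (Perron) eigenvector of ``M @ diag(f)``,
    computed by a dense eigensolve and verified to be a fixed point of
    :func:`iterate` to within ``tol`` (sup-norm); a short power-iteration
    polish runs if the eigensolve residual is above ``tol``.
    """
    if M is None:
        M = class_transition_matrix(landscape.L, kernel)
    A = M * landscape.fitness[np.newaxis, :]

    eigvals, eigvecs = np.linalg.eig(A)
    lead = np.argmax(eigvals.real)
    x = np.abs(eigvecs[:, lead].real)
    x /= x.sum()

    # polish: the Perron vector is the unique normalized fixed point
    for _ in range(max_iter):
        x_next = iterate(x, landscape, M)
        if np.max(np.abs(x_next - x)) < tol:
            return x_next
        x = x_next
    raise RuntimeError(
        f"stationary solve did not converge within {max_iter} iterations "
        f"(residual {np.max(np.abs(iterate(x, landscape, M) - x)):.3e})"
    )


def master_frequency_closed_form(sigma: float, L: int, mu: float, p: float = 0.0) -> float:
    """No-backmutation approximation to the stationary master frequency.

    ``x0 = max(0, (sigma*Q_eff - 1)/(sigma - 1))`` with effective copy
    fidelity ``Q_eff = p + (1 - p)*(1 - mu)**L``. Exact as L -> infinity;
    used as an independent oracle for the full solver.
    """
    q_eff = p + (1.0 - p) * (1.0 - mu) ** L
    return max(0.0, (sigma * q_eff - 1.0) / (sigma - 1.0))


def _stationary_master(landscape: SinglePeakLandscape, mu: float, p: float) -> float:
    x = solve_stationary(landscape, ReplicationKernel(mu=mu, p=p))
    return float(x[0])


def find_error_threshold(
    landscape: SinglePeakLandscape,
    p: float = 0.0,
    mu_range: tuple[float, float] = (0.0, 0.5),
    epsilon: float = 1e-3,
    tol: float = 1e-5,
) -> ThresholdResult:
    """Locate the error threshold by bisection on the stationary master frequency.

    Searches ``mu_range`` for the per-base rate at which the master-class
    frequency drops below ``epsilon``. Returns ``exists=False`` when the
    master stays above ``epsilon`` over the whole range (e.g. whenever
    ``sigma * p > 1``, since the error-free channel alone keeps the master at
    ``(sigma*p - 1)/(sigma - 1)`` or above for any ``mu``).
    """
    lo, hi = mu_range
    if not (0.0 <= lo < hi <= 0.5):
        raise ValueError(f"mu_range must satisfy 0 <= lo < hi <= 0.5, got {mu_range}")
    f_lo = _stationary_master(landscape, lo, p)
    if f_lo < epsilon:
        raise ValueError(
            f"master frequency {f_lo:.3g} at mu={lo} is already below epsilon={epsilon}; "
            "range does not bracket the threshold"
        )
    f_hi = _stationary_master(landscape, hi, p)
    if f_hi >= epsilon:
        return ThresholdResult(None, None, False, epsilon, tol)

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _stationary_master(landscape, mid, p) >= epsilon:
            lo = mid
        else:
            hi = mid
    mu_c = 0.5 * (lo + hi)
    return ThresholdResult(mu_c, mu_c * landscape.L, True, epsilon, tol)


def threshold_phase_table(
    sigma_grid: list[float],
    p_grid: list[float],
    L: int,
    epsilon: float = 1e-3,
    tol: float = 1e-5,
):
    """Error-threshold location over a (sigma, p) grid.

    Returns a DataFrame with columns
    ``sigma, p, L, mu_critical, genome_wide_rate, exists``; ``mu_critical``
    is NaN where no threshold exists in ``mu in [0, 0.5]``. For fixed sigma
    the threshold is non-decreasing in p and disappears once ``p > 1/sigma``.
    """
    import pandas as pd

    if not sigma_grid or not p_grid:
        raise ValueError("sigma_grid and p_grid must be nonempty")
    rows = []
    for sigma in sigma_grid:
        landscape = SinglePeakLandscape(L=L, sigma=sigma)
        for p in p_grid:
            r = find_error_threshold(landscape, p=p, epsilon=epsilon, tol=tol)
            rows.append(
                (sigma, p, L,
                 r.mu_critical if r.exists else float("nan"),
                 r.genome_wide_rate if r.exists else float("nan"),
                 r.exists)
            )
    return pd.DataFrame(
        rows, columns=["sigma", "p", "L", "mu_critical", "genome_wide_rate", "exists"]
    )
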