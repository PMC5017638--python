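"""Linear network-control diagnostics for structural connectomes.

The structural matrix A is interpreted as the propagator of a noise-free
discrete-time linear system x(t+1) = A_norm x(t) + B u(t), with A_norm a
stabilized rescaling of A (spectral radius < 1) and B a single canonical
column selecting the stimulated region.  Three diagnostics of how strongly
one region can steer the whole system are computed region by region:

* **average controllability** — Trace of the infinite-horizon controllability
  Gramian W = sum_t A^t B B^T (A^t)^T, solved exactly from the discrete
  Lyapunov equation A W A^T - W + B B^T = 0.  Large values mean many nearby
  states are reachable with little input energy; empirically it tracks
  weighted degree.
* **modal controllability** — phi_i = sum_j (1 - lambda_j^2) v_ij^2 over the
  eigenmodes (lambda_j, v_j) of A_norm.  Large values mean the region can
  engage even the fast, hard-to-reach modes; it runs inversely to degree.
* **steady-state response** — x* = (I - A_norm)^{-1} e_i u, the asymptotic
  state under a constant unit input at region i (the linear analogue of
  constant-current stimulation), summarized by its largest and mean entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .connectome import StructuralNetwork

__all__ = [
    "ControllabilityProfile",
    "normalize_for_control",
    "controllability_gramian",
    "average_controllability",
    "modal_controllability",
    "steady_state_response",
    "controllability_profile",
]


@dataclass
class ControllabilityProfile:
    """Per-region control diagnostics plus weighted degree."""

    avg_ctrl: np.ndarray
    modal_ctrl: np.ndarray
    ss_largest: np.ndarray
    ss_mean: np.ndarray
    degree: np.ndarray


def _spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def normalize_for_control(
    net: StructuralNetwork | np.ndarray, epsilon: float = 0.0
) -> np.ndarray:
    """Rescale an adjacency matrix to a Schur-stable linear propagator.

    Returns ``A / (1 + epsilon + lambda_max)`` where ``lambda_max`` is the
    largest eigenvalue magnitude of A, guaranteeing spectral radius < 1 (so
    the controllability Gramian converges).  ``epsilon`` adds an optional
    extra stability margin; the default divisor is ``1 + lambda_max``.
    """
    A = net.weights if isinstance(net, StructuralNetwork) else np.asarray(net, float)
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if not np.any(A != 0):
        raise ValueError("cannot normalize an all-zero matrix")
    lam = _spectral_radius(A)
    return A / (1.0 + epsilon + lam)


def _check_stable(A_norm: np.ndarray) -> None:
    rho = _spectral_radius(A_norm)
    if rho >= 1.0:
        raise ValueError(
            f"linear propagator is not Schur-stable (spectral radius "
            f"{rho:.6g} >= 1); normalize first"
        )


def controllability_gramian(A_norm: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Infinite-horizon controllability Gramian of (A_norm, B).

    Solves ``A W A^T - W + B B^T = 0`` exactly (discrete Lyapunov equation);
    for Schur-stable A this equals the series ``sum_t A^t B B^T (A^t)^T``.
    The result is symmetrized and positive semidefinite.
    """
    A_norm = np.asarray(A_norm, dtype=float)
    B = np.asarray(B, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    _check_stable(A_norm)
    W = linalg.solve_discrete_lyapunov(A_norm, B @ B.T)
    return 0.5 * (W + W.T)


def average_controllability(A_norm: np.ndarray) -> np.ndarray:
    """Average controllability of every region: Trace(W) with B = e_i.

    Control nodes are taken one at a time; each region's score is the trace
    of its single-input Gramian.  All values are >= 1 (the B B^T term alone
    contributes 1 to the trace).
    """
    A_norm = np.asarray(A_norm, dtype=float)
    _check_stable(A_norm)
    N = A_norm.shape[0]
    out = np.empty(N)
    eye = np.eye(N)
    for i in range(N):
        W = linalg.solve_discrete_lyapunov(A_norm, np.outer(eye[i], eye[i]))
        out[i] = np.trace(W)
    return out


def modal_controllability(A_norm: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Modal controllability phi_i = sum_j (1 - lambda_j^2) v_ij^2.

    Requires a symmetric propagator (real eigendecomposition with an
    orthonormal eigenvector matrix V); undirected connectomes always satisfy
    this, and asymmetric input is rejected rather than silently reduced to a
    Schur form.
    """
    A_norm = np.asarray(A_norm, dtype=float)
    if not np.allclose(A_norm, A_norm.T, atol=atol):
        raise ValueError("modal controllability requires a symmetric matrix")
    _check_stable(A_norm)
    lam, V = np.linalg.eigh(A_norm)
    return ((1.0 - lam**2)[None, :] * V**2).sum(axis=1)


def steady_state_response(
    A_norm: np.ndarray, control_region: int, u: float = 1.0
) -> tuple[float, float, np.ndarray]:
    """Asymptotic state under a constant input u at one region.

    Returns ``(largest, mean, x*)`` with ``x* = (I - A_norm)^{-1} e_i u``, the
    fixed point of ``x <- A_norm x + e_i u``.  Stability of A_norm guarantees
    (I - A_norm) is invertible.
    """
    A_norm = np.asarray(A_norm, dtype=float)
    _check_stable(A_norm)
    N = A_norm.shape[0]
    if not 0 <= control_region < N:
        raise ValueError(f"control_region {control_region} out of range for N={N}")
    b = np.zeros(N)
    b[control_region] = u
    x = np.linalg.solve(np.eye(N) - A_norm, b)
    return float(x.max()), float(x.mean()), x


def controllability_profile(
    net: StructuralNetwork | np.ndarray, epsilon: float = 0.0, u: float = 1.0
) -> ControllabilityProfile:
    """All per-region diagnostics for one structural network."""
    A = net.weights if isinstance(net, StructuralNetwork) else np.asarray(net, float)
    A_norm = normalize_for_control(A, epsilon=epsilon)
    N = A.shape[0]
    ss_largest = np.empty(N)
    ss_mean = np.empty(N)
    for i in range(N):
        ss_largest[i], ss_mean[i], _ = steady_state_response(A_norm, i, u=u)
    return ControllabilityProfile(
        avg_ctrl=average_controllability(A_norm),
        modal_ctrl=modal_controllability(A_norm),
        ss_largest=ss_largest,
        ss_mean=ss_mean,
        degree=A.sum(axis=1),
    )
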