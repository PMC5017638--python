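"""Coupled, delayed, noisy Wilson-Cowan neural-mass dynamics.

Each brain region is a Wilson-Cowan oscillator: a pair of mean-field firing
rates, excitatory E and inhibitory I, coupled through a sigmoidal transfer
function.  Regions interact through their excitatory populations, weighted by
the structural connectivity matrix A and lagged by axonal conduction delays:

    tau dE_j/dt = -E_j + (S_e_max - E_j) * S_e(c1 E_j - c2 I_j
                      + c5 * sum_k A_jk E_k(t - tau_d_jk) + P_j(t)) + sigma w_j
    tau dI_j/dt = -I_j + (S_i_max - I_j) * S_i(c3 E_j - c4 I_j) + sigma v_j

with S(x) = 1/(1 + exp(-a(x - theta))) - 1/(1 + exp(a theta)), so S(0) = 0
and sup S = 1 - 1/(1 + exp(a theta)) =: S_max.  With the classical constants
(c1=16, c2=12, c3=15, c4=3, a_e=1.3, a_i=2, theta_e=4, theta_i=3.7) a single
uncoupled oscillator has three regimes as the constant drive P grows: a low
fixed point, a ~20 Hz limit cycle, and a high fixed point.  Stimulation of a
region is a constant current step P_j = 1.25 that pushes it into the limit
cycle.

Integration is fixed-step Euler with a ring history buffer for the delayed
excitatory rates (delays quantized to integer steps, round-half-to-even), and
per-step additive Gaussian noise sigma * N(0, 1) inside the right-hand side.
Fixed step size plus a single seeded generator makes every trajectory
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal, special

from .connectome import DelayMatrix, StructuralNetwork

__all__ = [
    "WCParams",
    "StimulusProtocol",
    "SimulationResult",
    "FixedPoint",
    "FrequencyEstimate",
    "sigmoid_transfer",
    "sigmoid_ceiling",
    "find_fixed_points",
    "simulate_network",
    "simulate_single",
    "estimate_dominant_frequency",
]


def sigmoid_transfer(x, a: float, theta: float):
    """Wilson-Cowan sigmoid, shifted so that S(0) = 0.

    ``S(x) = 1/(1 + exp(-a (x - theta))) - 1/(1 + exp(a theta))``.
    Monotone increasing with supremum ``1 - 1/(1 + exp(a theta))``.
    """
    if a <= 0:
        raise ValueError(f"sigmoid slope must be positive, got {a}")
    x = np.asarray(x, dtype=float)
    return special.expit(a * (x - theta)) - special.expit(-a * theta)


def sigmoid_ceiling(a: float, theta: float) -> float:
    """Supremum of the shifted sigmoid, ``1 - 1/(1 + exp(a theta))``."""
    return float(special.expit(a * theta))


@dataclass(frozen=True)
class WCParams:
    """Wilson-Cowan model constants.

    Defaults are the classical parameter set for which the uncoupled
    oscillator is tristable in P (low fixed point / limit cycle / high fixed
    point).  ``s_e_max``/``s_i_max`` default to the sigmoid suprema
    ``1 - 1/(1 + exp(a theta))``, the refractory ceiling of the original
    Wilson-Cowan construction; both are configurable.

    sigma is the additive noise amplitude applied per integration step
    (``sigma * N(0,1)`` inside the right-hand side, not a sqrt(dt)-scaled
    Wiener increment); see ``noise_mode``.
    """

    tau: float = 8.0  # ms
    c1: float = 16.0
    c2: float = 12.0
    c3: float = 15.0
    c4: float = 3.0
    c5: float = 1.0  # global coupling
    a_e: float = 1.3
    a_i: float = 2.0
    theta_e: float = 4.0
    theta_i: float = 3.7
    sigma: float = 1e-5
    s_e_max: float | None = None
    s_i_max: float | None = None
    noise_mode: str = "per_step"  # or "sqrt_dt" for Euler-Maruyama scaling

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.a_e <= 0 or self.a_i <= 0:
            raise ValueError("sigmoid slopes must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.c5 < 0:
            raise ValueError("c5 must be nonnegative")
        if self.noise_mode not in ("per_step", "sqrt_dt"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.s_e_max is None:
            object.__setattr__(self, "s_e_max", sigmoid_ceiling(self.a_e, self.theta_e))
        if self.s_i_max is None:
            object.__setattr__(self, "s_i_max", sigmoid_ceiling(self.a_i, self.theta_i))

    def with_(self, **kwargs) -> "WCParams":
        """Copy with fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StimulusProtocol:
    """Constant-current step stimulation of a single region.

    ``amplitude`` is added to ``target_region``'s external drive P for
    ``onset <= t < offset`` (ms).  ``baseline`` is a constant drive applied to
    every region for the whole simulation (scalar or per-region array).
    ``target_region=None`` means no stimulation.
    """

    target_region: int | None = None
    amplitude: float = 1.25
    onset: float = 0.0
    offset: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.target_region is not None and not self.onset < self.offset:
            raise ValueError(
                f"need onset < offset when a target is set, got "
                f"[{self.onset}, {self.offset})"
            )
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite")


@dataclass
class SimulationResult:
    """Firing-rate traces for all regions on a fixed time grid.

    ``E`` and ``I`` are (N, T) arrays including the initial condition at
    t = 0; ``times`` is the matching ms grid.
    """

    times: np.ndarray
    E: np.ndarray
    I: np.ndarray
    dt: float
    protocol: StimulusProtocol
    seed: int

    def window(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Excitatory traces for ``start_ms <= t < stop_ms`` as an (N, T') view."""
        i0 = int(round(start_ms / self.dt))
        i1 = int(round(stop_ms / self.dt))
        return self.E[:, i0:i1]


@dataclass(frozen=True)
class FixedPoint:
    E: float
    I: float
    stable: bool
    eigenvalues: tuple[complex, complex]


def _uncoupled_rhs(E, I, p: WCParams, P: float):
    fE = (-E + (p.s_e_max - E) * sigmoid_transfer(p.c1 * E - p.c2 * I + P, p.a_e, p.theta_e)) / p.tau
    fI = (-I + (p.s_i_max - I) * sigmoid_transfer(p.c3 * E - p.c4 * I, p.a_i, p.theta_i)) / p.tau
    return fE, fI


def _uncoupled_jacobian(E: float, I: float, p: WCParams, P: float) -> np.ndarray:
    """Analytic Jacobian of the uncoupled deterministic system."""

    xe = p.c1 * E - p.c2 * I + P
    xi = p.c3 * E - p.c4 * I
    se = special.expit(p.a_e * (xe - p.theta_e))
    si = special.expit(p.a_i * (xi - p.theta_i))
    Se = se - special.expit(-p.a_e * p.theta_e)
    Si = si - special.expit(-p.a_i * p.theta_i)
    dSe = p.a_e * se * (1.0 - se)
    dSi = p.a_i * si * (1.0 - si)
    J = np.empty((2, 2))
    J[0, 0] = (-1.0 - Se + (p.s_e_max - E) * dSe * p.c1) / p.tau
    J[0, 1] = ((p.s_e_max - E) * dSe * (-p.c2)) / p.tau
    J[1, 0] = ((p.s_i_max - I) * dSi * p.c3) / p.tau
    J[1, 1] = (-1.0 - Si + (p.s_i_max - I) * dSi * (-p.c4)) / p.tau
    return J


def find_fixed_points(
    params: WCParams,
    P: float = 0.0,
    grid_n: int = 40,
    tol: float = 1e-10,
) -> list[FixedPoint]:
    """Fixed points of a single uncoupled, noise-free oscillator.

    Intersections of the E- and I-nullclines inside the admissible rate box
    ``[0, S_e_max] x [0, S_i_max]`` are located by running a Newton-type root
    finder from a ``grid_n x grid_n`` lattice of starting points, de-duplicated,
    and classified stable/unstable by the eigenvalues of the analytic Jacobian.
    Returns an empty list (with a warning) if nothing converges.
    """
    eps = 0.02
    Es = np.linspace(-eps, params.s_e_max + eps, grid_n)
    Is = np.linspace(-eps, params.s_i_max + eps, grid_n)
    found: list[tuple[float, float]] = []

    def fun(z):
        fE, fI = _uncoupled_rhs(z[0], z[1], params, P)
        return [fE, fI]

    for e0 in Es:
        for i0 in Is:
            sol = optimize.root(fun, [e0, i0], method="hybr", tol=1e-12)
            if not sol.success:
                continue
            E, I = sol.x
            if not (-eps <= E <= params.s_e_max + eps and -eps <= I <= params.s_i_max + eps):
                continue
            if max(abs(v) for v in fun([E, I])) > tol:
                continue
            if any(abs(E - e) < 1e-7 and abs(I - i) < 1e-7 for e, i in found):
                continue
            found.append((E, I))
    if not found:
        warnings.warn("no fixed points found in the rate box", stacklevel=2)
        return []
    out = []
    for E, I in sorted(found):
        eig = np.linalg.eigvals(_uncoupled_jacobian(E, I, params, P))
        out.append(
            FixedPoint(
                E=float(E),
                I=float(I),
                stable=bool(np.all(eig.real < 0)),
                eigenvalues=(complex(eig[0]), complex(eig[1])),
            )
        )
    return out


def simulate_network(
    net: StructuralNetwork | np.ndarray,
    delays: DelayMatrix | np.ndarray,
    params: WCParams,
    protocol: StimulusProtocol,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    initial_E: float = 0.1,
    initial_I: float = 0.1,
    check_every: int = 500,
) -> SimulationResult:
    """Integrate the delayed stochastic Wilson-Cowan network.

    Fixed-step Euler at step ``dt`` (ms).  Delays are quantized to integer
    steps with round-half-to-even; the delay history before t = 0 is pre-filled
    with the initial condition.  Noise draws come from one
    ``numpy.random.default_rng(seed)`` stream in a fixed order, so identical
    arguments give bit-identical output.

    ``net`` may be a :class:`StructuralNetwork` or a bare (N, N) adjacency
    array (useful for edgeless configurations such as a single isolated
    oscillator); ``delays`` likewise accepts a bare (N, N) ms array.

    Preconditions enforced: ``dt <= tau/10`` (resolution of the intrinsic
    time constant) and ``dt`` no larger than the smallest positive delay
    between structurally connected regions (so every delayed interaction
    spans at least one step).
    """
    A = net.weights if isinstance(net, StructuralNetwork) else np.asarray(net, float)
    N = A.shape[0]
    tau_d = delays.tau_d if isinstance(delays, DelayMatrix) else np.asarray(delays, float)
    if tau_d.shape != (N, N):
        raise ValueError(
            f"delay matrix shape {tau_d.shape} does not match {N} regions"
        )
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.tau / 10.0:
        raise ValueError(
            f"dt = {dt} ms too coarse: must satisfy dt <= tau/10 = "
            f"{params.tau / 10.0} ms"
        )
    coupled = A > 0
    pos = tau_d[coupled & (tau_d > 0)]
    if pos.size and dt > pos.min() * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt} ms exceeds the smallest positive delay between "
            f"connected regions ({pos.min():.4g} ms)"
        )
    if protocol.target_region is not None:
        if not 0 <= protocol.target_region < N:
            raise ValueError(
                f"target_region {protocol.target_region} out of range for N={N}"
            )
        if duration < protocol.offset:
            raise ValueError(
                f"duration {duration} ms ends before stimulus offset "
                f"{protocol.offset} ms"
            )

    steps = int(round(duration / dt))
    D = np.rint(tau_d / dt).astype(np.int64)  # np.rint rounds half to even
    max_d = int(D.max()) if N > 1 else 0
    off = max_d  # history offset: row (off + t) holds E at step t

    E_hist = np.empty((off + steps + 1, N))
    E_hist[: off + 1] = initial_E
    I_out = np.empty((steps + 1, N))
    I_out[0] = initial_I

    rng = np.random.default_rng(seed)
    p = params
    inv_tau = dt / p.tau
    use_noise = p.sigma > 0
    noise_scale = p.sigma * (np.sqrt(dt) if p.noise_mode == "sqrt_dt" else 1.0)

    baseline = np.broadcast_to(np.asarray(protocol.baseline, dtype=float), (N,)).copy()
    stim_on = stim_off = -1
    if protocol.target_region is not None:
        stim_on = int(round(protocol.onset / dt))
        stim_off = int(round(protocol.offset / dt))

    rows_base = off - D  # (N, N); add t each step
    cols = np.broadcast_to(np.arange(N), (N, N))
    have_coupling = p.c5 > 0 and np.any(A > 0)

    E = E_hist[off].copy()
    I = I_out[0].copy()
    for t in range(steps):
        if have_coupling:
            E_del = E_hist[rows_base + t, cols]
            coupling = p.c5 * np.einsum("jk,jk->j", A, E_del)
        else:
            coupling = 0.0
        P_t = baseline
        if stim_on <= t < stim_off:
            P_t = baseline.copy()
            P_t[protocol.target_region] += protocol.amplitude
        xe = p.c1 * E - p.c2 * I + coupling + P_t
        xi = p.c3 * E - p.c4 * I
        dE = -E + (p.s_e_max - E) * sigmoid_transfer(xe, p.a_e, p.theta_e)
        dI = -I + (p.s_i_max - I) * sigmoid_transfer(xi, p.a_i, p.theta_i)
        if use_noise:
            dE = dE + noise_scale * rng.standard_normal(N)
            dI = dI + noise_scale * rng.standard_normal(N)
        E = E + inv_tau * dE
        I = I + inv_tau * dI
        E_hist[off + t + 1] = E
        I_out[t + 1] = I
        if (t + 1) % check_every == 0 and not (
            np.all(np.isfinite(E)) and np.all(np.isfinite(I))
        ):
            raise FloatingPointError(
                f"non-finite state at integration step {t + 1} "
                f"(t = {(t + 1) * dt:.3f} ms)"
            )
    if not (np.all(np.isfinite(E_hist[off:])) and np.all(np.isfinite(I_out))):
        bad = int(np.argmax(~np.all(np.isfinite(E_hist[off:]), axis=1)))
        raise FloatingPointError(f"non-finite state at integration step {bad}")

    times = np.arange(steps + 1) * dt
    return SimulationResult(
        times=times,
        E=E_hist[off:].T.copy(),
        I=I_out.T.copy(),
        dt=dt,
        protocol=protocol,
        seed=seed,
    )


def simulate_single(
    params: WCParams,
    P: float,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    initial_E: float = 0.1,
    initial_I: float = 0.1,
) -> SimulationResult:
    """Convenience wrapper: one uncoupled oscillator under constant drive P."""
    proto = StimulusProtocol(baseline=P)
    return simulate_network(
        np.zeros((1, 1)),
        np.zeros((1, 1)),
        params.with_(c5=0.0),
        proto,
        duration,
        dt=dt,
        seed=seed,
        initial_E=initial_E,
        initial_I=initial_I,
    )

    def __post_init__(self):  # pragma: no cover - never called
        pass


@dataclass
class FrequencyEstimate:
    """Dominant-frequency estimate with an oscillation flag.

    ``frequency_hz`` is 0 for flat (fixed-point) traces; ``consistent`` is
    False when the spectral and inter-peak estimators disagree by > 10 %.
    """

    frequency_hz: float
    oscillatory: bool
    spectral_hz: float = 0.0
    interpeak_hz: float = 0.0
    consistent: bool = True


def estimate_dominant_frequency(
    trace: np.ndarray,
    dt: float,
    discard: float = 1000.0,
    flat_atol: float = 1e-6,
) -> FrequencyEstimate:
    """Dominant oscillation frequency (Hz) of a firing-rate trace.

    The first ``discard`` ms are dropped as transient.  The spectral peak of
    the mean-removed trace (with parabolic interpolation around the peak bin)
    is cross-checked against the mean inter-peak interval from a time-domain
    peak finder; disagreement beyond 10 % is flagged.  A flat trace
    (peak-to-peak below ``flat_atol``) returns 0 Hz, flagged non-oscillatory.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    i0 = int(round(discard / dt))
    x = trace[i0:]
    if x.size < 16:
        raise ValueError("trace too short after discarding the transient")
    if np.ptp(x) < flat_atol:
        return FrequencyEstimate(0.0, oscillatory=False)
    x = x - x.mean()
    fs = 1000.0 / dt  # Hz
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=dt / 1000.0)
    k = int(np.argmax(spec[1:])) + 1
    if 1 <= k < spec.size - 1:  # parabolic refinement of the peak bin
        a, b, c = spec[k - 1], spec[k], spec[k + 1]
        denom = a - 2 * b + c
        shift = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        f_spec = float(freqs[k] + shift * (freqs[1] - freqs[0]))
    else:
        f_spec = float(freqs[k])

    peaks, _ = signal.find_peaks(x, prominence=0.1 * np.ptp(x))
    if peaks.size >= 3:
        ipi = np.diff(peaks) * dt / 1000.0  # s
        f_ipi = float(1.0 / ipi.mean())
    else:
        f_ipi = f_spec
    consistent = abs(f_spec - f_ipi) <= 0.1 * max(f_spec, f_ipi)
    if not consistent:
        warnings.warn(
            f"spectral ({f_spec:.2f} Hz) and inter-peak ({f_ipi:.2f} Hz) "
            "frequency estimates disagree by more than 10%",
            stacklevel=2,
        )
    return FrequencyEstimate(
        frequency_hz=f_spec,
        oscillatory=True,
        spectral_hz=f_spec,
        interpeak_hz=f_ipi,
        consistent=consistent,
    )
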