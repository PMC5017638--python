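"""Functional brain states and stimulation-effect statistics.

A functional brain state is the matrix of pairwise maximum normalized
cross-correlations between regional excitatory firing-rate traces: for each
region pair the Pearson correlation is evaluated at every signed lag up to a
maximum (default 250 ms, on a 1 s window) and the largest value is kept.
Three scalar statistics compare the state before stimulation with the state
during stimulation of one region:

* **functional effect** — mean |change| in pairwise functional connectivity
  over all region pairs: how far the stimulation moved the brain state.
* **structural effect** — change in the correlation between the structural
  matrix and the functional state (corr2 over region pairs): how much the
  stimulated state is pulled toward the anatomical wiring.
* **fractional activation** — fraction of pairs whose |change| exceeds a
  threshold (default 0.6): whether the impact was global or focal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import stats

from .connectome import StructuralNetwork

__all__ = [
    "FunctionalState",
    "StimulationOutcome",
    "functional_connectivity",
    "functional_effect",
    "structural_effect",
    "fractional_activation",
    "corr2",
]


@dataclass
class FunctionalState:
    """Pairwise maximum lagged cross-correlation matrix.

    ``fc`` is symmetric with unit diagonal.  ``boundary_pairs`` lists pairs
    whose maximum sat on a boundary lag (possible window-too-short artifact);
    ``zero_variance`` lists regions whose trace was flat, for which fc is 0.
    """

    fc: np.ndarray
    window: float
    max_lag: float
    boundary_pairs: list[tuple[int, int]] = field(default_factory=list)
    zero_variance: list[int] = field(default_factory=list)


@dataclass
class StimulationOutcome:
    """Effect statistics for stimulation of one region."""

    region: int
    functional_effect: float
    structural_effect: float
    fractional_activation: float
    fc_before: FunctionalState
    fc_during: FunctionalState


def _lagged_pearson(
    F: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    n: int,
    L: int,
    m: int,
) -> np.ndarray:
    """Exact signed-lag Pearson correlograms for a batch of trace pairs.

    For each pair (i, j), lag ``l > 0`` correlates ``x_i[0:n-l]`` with
    ``x_j[l:n]`` (trace j led by l samples) and lag ``-l`` the converse; both
    lag signs come from a single circular FFT correlation of the zero-padded
    traces (``F`` holds their rffts).  ``s1``/``s2`` are the (n+1)-long
    prefix sums of the traces and their squares, giving the exact moments of
    every overlapping segment, so each entry is the exact Pearson r over the
    overlap.  Returns an array of shape (len(ii), 2L + 1), lags -L..L.
    """
    mh, sh, mt, st_ = _segment_moments(s1, s2, n, L)
    cnt = (n - np.arange(L + 1))[None, :]
    # circular correlation c[l] = sum_t x_i[t] x_j[(t+l) mod m]; with zero
    # padding (m >= n + L) lag l reads c[l] and lag -l reads c[m-l]
    c = sp_fft.irfft(np.conj(F[ii]) * F[jj], m)
    cross_pos = c[:, : L + 1]
    cross_neg = np.concatenate([c[:, :1], c[:, m - L :][:, ::-1]], axis=1)

    def pearson(cross, i_side, j_side):
        num = cross / cnt - mh[i_side] * mt[j_side]
        denom = sh[i_side] * st_[j_side]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 1e-300, num / np.maximum(denom, 1e-300), 0.0)
        return np.clip(r, -1.0, 1.0)

    r_pos = pearson(cross_pos, ii, jj)   # lag +l: head of i vs tail of j
    r_neg = pearson(cross_neg, jj, ii)   # lag -l: head of j vs tail of i
    return np.concatenate([r_neg[:, 1:][:, ::-1], r_pos], axis=1)


def _segment_moments(s1: np.ndarray, s2: np.ndarray, n: int, L: int):
    """Per-trace, per-lag means and stds of head/tail overlap segments.

    ``head`` of trace i at lag l is ``x_i[0:n-l]``, ``tail`` is ``x_i[l:n]``;
    all four statistics are (N, L+1) arrays derived from prefix sums.
    """
    lags = np.arange(L + 1)[None, :]
    cnt = n - lags
    head = s1[:, n - lags[0]]
    head2 = s2[:, n - lags[0]]
    tail = s1[:, [n]] - s1[:, lags[0]]
    tail2 = s2[:, [n]] - s2[:, lags[0]]
    mh = head / cnt
    mt = tail / cnt
    sh = np.sqrt(np.maximum(head2 / cnt - mh**2, 0.0))
    st_ = np.sqrt(np.maximum(tail2 / cnt - mt**2, 0.0))
    return mh, sh, mt, st_


def functional_connectivity(
    E: np.ndarray,
    dt: float,
    window: float = 1000.0,
    max_lag: float = 250.0,
    use_abs: bool = False,
) -> FunctionalState:
    """Functional state from excitatory traces.

    Parameters
    ----------
    E : (N, T) ndarray
        Excitatory firing-rate traces; the first ``window/dt`` samples are
        used (``T * dt >= window`` required).
    dt : float
        Sample step in ms.  ``window/dt`` and ``max_lag/dt`` must be integral.
    window, max_lag : float
        Correlation window and maximum signed lag, ms.
    use_abs : bool
        If True, maximize |r| over lags instead of signed r.  The signed
        maximum is the default because these oscillators synchronize
        positively.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise ValueError("E must be a 2-D (regions x time) array")
    n = window / dt
    L = max_lag / dt
    if abs(n - round(n)) > 1e-9 or abs(L - round(L)) > 1e-9:
        raise ValueError("window/dt and max_lag/dt must be integral")
    n, L = int(round(n)), int(round(L))
    if E.shape[1] < n:
        raise ValueError(
            f"trace length {E.shape[1]} samples shorter than window "
            f"{n} samples"
        )
    if L >= n:
        raise ValueError("max_lag must be shorter than the window")
    N = E.shape[0]
    X = E[:, :n]

    flat = np.where(X.std(axis=1) < 1e-12)[0]
    if flat.size:
        warnings.warn(
            f"zero-variance trace(s) {flat.tolist()}: functional connectivity "
            "entries involving them are set to 0",
            stacklevel=2,
        )
    m = sp_fft.next_fast_len(n + L + 1)
    F = sp_fft.rfft(X, m)
    zeros = np.zeros((N, 1))
    s1 = np.concatenate([zeros, np.cumsum(X, axis=1)], axis=1)
    s2 = np.concatenate([zeros, np.cumsum(X**2, axis=1)], axis=1)

    fc = np.eye(N)
    boundary: list[tuple[int, int]] = []
    iu_i, iu_j = np.triu_indices(N, k=1)
    flat_mask = np.isin(iu_i, flat) | np.isin(iu_j, flat)
    chunk = max(1, int(2**24 // max(m, 1)))  # cap FFT workspace at ~256 MB
    for lo in range(0, iu_i.size, chunk):
        ii = iu_i[lo : lo + chunk]
        jj = iu_j[lo : lo + chunk]
        r_all = _lagged_pearson(F, s1, s2, ii, jj, n, L, m)  # lags -L..L
        if use_abs:
            r_all = np.abs(r_all)
        k = np.argmax(r_all, axis=1)
        vals = np.take_along_axis(r_all, k[:, None], axis=1)[:, 0]
        vals[flat_mask[lo : lo + chunk]] = 0.0
        fc[ii, jj] = fc[jj, ii] = vals
        for p in np.flatnonzero((k == 0) | (k == r_all.shape[1] - 1)):
            if not flat_mask[lo + p]:
                boundary.append((int(ii[p]), int(jj[p])))
    return FunctionalState(
        fc=fc,
        window=window,
        max_lag=max_lag,
        boundary_pairs=boundary,
        zero_variance=flat.tolist(),
    )


def _fc_matrix(state) -> np.ndarray:
    return state.fc if isinstance(state, FunctionalState) else np.asarray(state, float)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def functional_effect(fc_before, fc_during) -> float:
    """Mean absolute change in pairwise functional connectivity.

    Averaged over all unordered off-diagonal region pairs; zero means the
    stimulation left the functional state untouched.
    """
    a = _fc_matrix(fc_before)
    b = _fc_matrix(fc_during)
    _check_shapes(a, b)
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.abs(b[iu] - a[iu]).mean())


def corr2(a: np.ndarray, b: np.ndarray, include_diagonal: bool = False) -> float:
    """2-D Pearson correlation between two square matrices.

    By default computed over the upper-triangle off-diagonal entries only,
    which excludes the uninformative structural diagonal (always 0) and
    functional diagonal (always 1); ``include_diagonal=True`` correlates all
    entries (the MATLAB ``corr2`` convention).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_shapes(a, b)
    if include_diagonal:
        x, y = a.ravel(), b.ravel()
    else:
        iu = np.triu_indices(a.shape[0], k=1)
        x, y = a[iu], b[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("corr2 undefined for a constant matrix (zero variance)")
    return float(stats.pearsonr(x, y)[0])


def structural_effect(
    net: StructuralNetwork | np.ndarray,
    fc_before,
    fc_during,
    include_diagonal: bool = False,
) -> float:
    """Change in structure-function similarity caused by stimulation.

    ``corr2(A, fc_during) - corr2(A, fc_before)``: positive values mean the
    stimulated functional state resembles the anatomical wiring more than the
    resting state did, i.e. the structure constrains the effect.
    """
    A = net.weights if isinstance(net, StructuralNetwork) else np.asarray(net, float)
    before = _fc_matrix(fc_before)
    during = _fc_matrix(fc_during)
    _check_shapes(before, during)
    _check_shapes(A, before)
    return corr2(A, during, include_diagonal) - corr2(A, before, include_diagonal)


def fractional_activation(fc_before, fc_during, threshold: float = 0.6) -> float:
    """Fraction of region pairs whose |FC change| exceeds ``threshold``.

    1 means a global impact of stimulation, 0 a purely focal one.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    a = _fc_matrix(fc_before)
    b = _fc_matrix(fc_during)
    _check_shapes(a, b)
    iu = np.triu_indices(a.shape[0], k=1)
    return float(np.mean(np.abs(b[iu] - a[iu]) > threshold))
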