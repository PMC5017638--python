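"""Computational experiments on coupled neural-mass brain models.

Three orchestrated analyses:

1. **Transition sweep** — increase the global coupling c5 over a grid (default
   1.0 to 1.5 in steps of 0.05) and find the value at which the coupled
   network jumps from low-fixed-point fluctuations into collective
   oscillation.  The grid point immediately before the jump is the operating
   point for stimulation experiments.
2. **Reproducibility (ICC)** — intraclass correlation coefficients from a
   two-way ANOVA over a subjects x scans table of transition points,
   separating within-subject from between-subject consistency.
3. **Stimulation campaign** — at the operating point, stimulate each region in
   turn with a constant current, measure the functional effect, structural
   effect and fractional activation, and relate them to the linear
   controllability diagnostics by rank correlation; finally aggregate effects
   and connection densities by cognitive system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import DelayMatrix, RegionSet, StructuralNetwork
from .control import ControllabilityProfile, controllability_profile
from .dynamics import SimulationResult, StimulusProtocol, WCParams, simulate_network
from .states import (
    StimulationOutcome,
    fractional_activation,
    functional_connectivity,
    functional_effect,
    structural_effect,
)

__all__ = [
    "TransitionScan",
    "ReproducibilityReport",
    "CampaignResult",
    "DEFAULT_C5_GRID",
    "find_transition_point",
    "icc",
    "stimulation_campaign",
    "system_aggregate",
]

#: Standard global-coupling sweep grid: 1.0 to 1.5 in steps of 0.05.
DEFAULT_C5_GRID = np.round(np.arange(1.0, 1.5001, 0.05), 10)


def _child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    """Deterministic per-task seed derived from a base seed and an index key."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))


@dataclass
class TransitionScan:
    """Result of a coupling sweep.

    ``mean_rate[i, g]`` is region i's mean excitatory rate at grid point g
    (transient discarded).  ``c5_transition`` is None when no jump was
    detected within the grid (``found`` False); then ``c5_operating`` is None
    too.
    """

    c5_grid: np.ndarray
    mean_rate: np.ndarray
    c5_transition: float | None
    c5_operating: float | None
    found: bool
    transition_index: int | None = None


@dataclass
class ReproducibilityReport:
    """ICC-based reproducibility summary of an I-subjects x J-scans table.

    ``icc_within`` is high when repeat scans of the same subject agree
    (between-subject variance dominates error); ``icc_between`` is high only
    when different subjects agree with each other.  ``degenerate`` flags the
    0/0 case of a constant table.
    """

    icc_between: float
    icc_within: float
    var_between: float
    var_within: float
    I: int
    J: int
    subject_ms: float
    scan_ms: float
    error_ms: float
    degenerate: bool = False


@dataclass
class CampaignResult:
    """Per-region stimulation outcomes with controllability and aggregates."""

    outcomes: list[StimulationOutcome]
    profile: ControllabilityProfile
    correlations: pd.DataFrame
    system_summary: pd.DataFrame
    density_table: pd.DataFrame
    c5_operating: float
    network: StructuralNetwork | None = None

    def table(self) -> pd.DataFrame:
        """Long-format per-region table of all measures."""
        return pd.DataFrame(
            {
                "region": [o.region for o in self.outcomes],
                "degree": self.profile.degree,
                "avg_ctrl": self.profile.avg_ctrl,
                "modal_ctrl": self.profile.modal_ctrl,
                "ss_largest": self.profile.ss_largest,
                "ss_mean": self.profile.ss_mean,
                "functional_effect": [o.functional_effect for o in self.outcomes],
                "structural_effect": [o.structural_effect for o in self.outcomes],
                "fractional_activation": [
                    o.fractional_activation for o in self.outcomes
                ],
            }
        )


def find_transition_point(
    net: StructuralNetwork,
    delays: DelayMatrix,
    params: WCParams,
    c5_grid: np.ndarray = DEFAULT_C5_GRID,
    sim_seconds: float = 1.0,
    seed: int = 0,
    dt: float = 0.1,
    stabilize_seconds: float = 1.0,
    jump_factor: float = 3.0,
    rate_floor: float = 0.05,
) -> TransitionScan:
    """Locate the oscillatory transition of the coupled network.

    For each coupling value on the grid, the network is simulated with no
    stimulation for ``stabilize_seconds + sim_seconds``; the first second is
    discarded and each region's mean excitatory rate over the remaining
    window is recorded.  The transition is the first grid point whose
    across-region median mean-rate exceeds ``jump_factor`` times the previous
    point's median while more than half the regions sit above ``rate_floor``
    — operationalizing the "sudden increase in firing rate across most
    regions" signature of the jump into collective oscillation.  The
    operating point is the grid point immediately before the transition.
    """
    c5_grid = np.asarray(c5_grid, dtype=float)
    if c5_grid.ndim != 1 or c5_grid.size < 2 or np.any(np.diff(c5_grid) <= 0):
        raise ValueError("c5_grid must be a strictly increasing 1-D grid")
    N = net.n_regions
    G = c5_grid.size
    mean_rate = np.empty((N, G))
    discard = int(round(stabilize_seconds * 1000.0 / dt))
    duration = (stabilize_seconds + sim_seconds) * 1000.0
    protocol = StimulusProtocol()
    for g, c5 in enumerate(c5_grid):
        res = simulate_network(
            net,
            delays,
            params.with_(c5=float(c5)),
            protocol,
            duration,
            dt=dt,
            seed=np.random.default_rng(_child_seed(seed, g)).integers(2**31),
        )
        mean_rate[:, g] = res.E[:, discard + 1 :].mean(axis=1)

    medians = np.median(mean_rate, axis=0)
    tiny = 1e-12
    idx = None
    for g in range(1, G):
        jumped = medians[g] > jump_factor * max(medians[g - 1], tiny)
        majority = np.mean(mean_rate[:, g] > rate_floor) > 0.5
        if jumped and majority:
            idx = g
            break
    if idx is None:
        warnings.warn(
            "no oscillatory transition detected within the coupling grid; "
            "consider extending it",
            stacklevel=2,
        )
        return TransitionScan(c5_grid, mean_rate, None, None, found=False)
    return TransitionScan(
        c5_grid,
        mean_rate,
        c5_transition=float(c5_grid[idx]),
        c5_operating=float(c5_grid[idx - 1]),
        found=True,
        transition_index=idx,
    )


def icc(values: np.ndarray) -> ReproducibilityReport:
    """Intraclass correlation coefficients from an I x J measurement table.

    Rows are subjects (I >= 2), columns repeat scans (J >= 2); the design
    must be balanced (no missing cells).  A two-way ANOVA decomposes the
    table into subject, scan and error mean squares (RMS, SMS, EMS), and

        ICC_B = J (SMS - EMS) / (J SMS + I RMS + (IJ - I - J) EMS)
        ICC_W = I (RMS - EMS) / (J SMS + I RMS + (IJ - I - J) EMS)

    give the between- and within-subject reproducibility.  ``var_between``
    is the variance of per-subject means; ``var_within`` the per-subject
    variance averaged over subjects.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D subjects x scans table")
    I, J = x.shape
    if I < 2 or J < 2:
        raise ValueError(f"need at least 2 subjects and 2 scans, got {I}x{J}")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite cells: the design must be balanced")

    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    rms = J * ((row_means - gm) ** 2).sum() / (I - 1)  # between subjects
    sms = I * ((col_means - gm) ** 2).sum() / (J - 1)  # between scans
    resid = x - row_means[:, None] - col_means[None, :] + gm
    ems = (resid**2).sum() / ((I - 1) * (J - 1))  # error

    denom = J * sms + I * rms + (I * J - I - J) * ems
    degenerate = denom == 0
    if degenerate:
        warnings.warn(
            "all table cells identical: ICC is undefined (0/0)", stacklevel=2
        )
        icc_b = icc_w = float("nan")
    else:
        icc_b = float(J * (sms - ems) / denom)
        icc_w = float(I * (rms - ems) / denom)
    return ReproducibilityReport(
        icc_between=icc_b,
        icc_within=icc_w,
        var_between=float(row_means.var(ddof=1)),
        var_within=float(x.var(axis=1, ddof=1).mean()),
        I=I,
        J=J,
        subject_ms=float(rms),
        scan_ms=float(sms),
        error_ms=float(ems),
        degenerate=degenerate,
    )


_MEASURES = (
    "avg_ctrl",
    "modal_ctrl",
    "degree",
    "functional_effect",
    "structural_effect",
    "fractional_activation",
)


def stimulation_campaign(
    net: StructuralNetwork,
    delays: DelayMatrix,
    params: WCParams,
    c5_operating: float,
    seed: int = 0,
    dt: float = 0.1,
    stim_amplitude: float = 1.25,
    window: float = 1000.0,
    max_lag: float = 250.0,
    threshold: float = 0.6,
    regions_to_stimulate=None,
) -> CampaignResult:
    """Stimulate every region in turn and relate outcomes to controllability.

    Each 3 s simulation at the operating coupling runs 1 s of stabilization
    (discarded), a 1 s stimulation-free window, then 1 s with a constant
    current ``stim_amplitude`` injected into the target region.  Functional
    states are computed separately for the before- and during-stimulation
    windows; each region's outcome comprises the functional effect,
    structural effect and fractional activation.  Spearman rank correlations
    among all measures and the linear controllability profile of the same
    network complete the result.
    """
    N = net.n_regions
    p = params.with_(c5=float(c5_operating))
    targets = range(N) if regions_to_stimulate is None else regions_to_stimulate
    outcomes: list[StimulationOutcome] = []
    for r in targets:
        protocol = StimulusProtocol(
            target_region=int(r), amplitude=stim_amplitude, onset=2000.0, offset=3000.0
        )
        try:
            res = simulate_network(
                net,
                delays,
                p,
                protocol,
                duration=3000.0,
                dt=dt,
                seed=np.random.default_rng(_child_seed(seed, r)).integers(2**31),
            )
        except FloatingPointError as err:
            raise RuntimeError(
                f"simulation for stimulated region {r} aborted: {err}"
            ) from err
        fc_before = functional_connectivity(
            res.window(1000.0, 2000.0), dt, window=window, max_lag=max_lag
        )
        fc_during = functional_connectivity(
            res.window(2000.0, 3000.0), dt, window=window, max_lag=max_lag
        )
        outcomes.append(
            StimulationOutcome(
                region=int(r),
                functional_effect=functional_effect(fc_before, fc_during),
                structural_effect=structural_effect(net, fc_before, fc_during),
                fractional_activation=fractional_activation(
                    fc_before, fc_during, threshold=threshold
                ),
                fc_before=fc_before,
                fc_during=fc_during,
            )
        )

    profile = controllability_profile(net)
    idx = np.asarray([o.region for o in outcomes])
    measures = {
        "avg_ctrl": profile.avg_ctrl[idx],
        "modal_ctrl": profile.modal_ctrl[idx],
        "degree": profile.degree[idx],
        "functional_effect": np.array([o.functional_effect for o in outcomes]),
        "structural_effect": np.array([o.structural_effect for o in outcomes]),
        "fractional_activation": np.array(
            [o.fractional_activation for o in outcomes]
        ),
    }
    corr = pd.DataFrame(np.eye(len(_MEASURES)), index=_MEASURES, columns=_MEASURES)
    for i, a in enumerate(_MEASURES):
        for b in _MEASURES[i + 1 :]:
            rho = stats.spearmanr(measures[a], measures[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = rho

    summary, density = system_aggregate_arrays(
        net,
        net.regions,
        idx,
        measures["functional_effect"],
        measures["structural_effect"],
    )
    # restrict profile to the stimulated subset so table() rows align
    sub_profile = ControllabilityProfile(
        avg_ctrl=measures["avg_ctrl"],
        modal_ctrl=measures["modal_ctrl"],
        ss_largest=profile.ss_largest[idx],
        ss_mean=profile.ss_mean[idx],
        degree=measures["degree"],
    )
    return CampaignResult(
        outcomes=outcomes,
        profile=sub_profile,
        correlations=corr,
        system_summary=summary,
        density_table=density,
        c5_operating=float(c5_operating),
        network=net,
    )


def system_aggregate(
    result: CampaignResult, regions: RegionSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a campaign's effects and densities by cognitive system.

    Returns ``(system_summary, density_table)``; see
    :func:`system_aggregate_arrays` for the semantics.  The campaign must
    carry its structural network (``result.network``), which supplies the
    edge counts for the density table.
    """
    if result.network is None:
        raise ValueError("campaign result carries no structural network")
    idx = np.asarray([o.region for o in result.outcomes])
    fe = np.asarray([o.functional_effect for o in result.outcomes])
    se = np.asarray([o.structural_effect for o in result.outcomes])
    return system_aggregate_arrays(result.network, regions, idx, fe, se)


def system_aggregate_arrays(
    net: StructuralNetwork,
    regions: RegionSet,
    region_idx: np.ndarray,
    func_effect: np.ndarray,
    struct_effect: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-system effect summaries and the system-pair connection densities.

    ``system_summary`` holds the mean and standard error of the mean (SEM =
    sample SD / sqrt(n)) of the structural and functional effects over the
    regions of each system; singleton systems get NaN SEM with a warning.
    ``density_table[s, t]`` is the fraction of present edges (weight > 0)
    among all possible region pairs between systems s and t, with within-
    system pairs counted as n(n-1)/2.
    """
    systems = np.asarray(regions.systems)
    order = list(dict.fromkeys(regions.systems))
    rows = []
    for s in order:
        mask = systems[region_idx] == s
        n = int(mask.sum())
        if n == 0:
            continue
        fe, se = func_effect[mask], struct_effect[mask]
        if n == 1:
            warnings.warn(
                f"system {s!r} has a single stimulated region: SEM undefined",
                stacklevel=2,
            )
        rows.append(
            {
                "system": s,
                "n": n,
                "functional_effect_mean": fe.mean(),
                "functional_effect_sem": fe.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "structural_effect_mean": se.mean(),
                "structural_effect_sem": se.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    summary = pd.DataFrame(rows).set_index("system")

    present = net.weights > 0
    density = pd.DataFrame(0.0, index=order, columns=order)
    for a, s in enumerate(order):
        si = np.flatnonzero(systems == s)
        for t in order[a:]:
            ti = np.flatnonzero(systems == t)
            if s == t:
                n_pairs = len(si) * (len(si) - 1) // 2
                n_edges = int(np.triu(present[np.ix_(si, si)], k=1).sum())
            else:
                n_pairs = len(si) * len(ti)
                n_edges = int(present[np.ix_(si, ti)].sum())
            d = n_edges / n_pairs if n_pairs else np.nan
            density.loc[s, t] = density.loc[t, s] = d
    return summary, density
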