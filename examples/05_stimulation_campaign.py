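"""Stimulate every region in turn and relate the outcome to controllability.

At the operating coupling (just below the oscillatory transition) each
region receives a 1 s constant current P = 1.25 that pushes it into its
limit cycle.  Functional connectivity (maximum lagged cross-correlation,
1 s window, 250 ms max lag) is compared before versus during stimulation,
yielding per-region functional effect, structural effect and fractional
activation, which are then rank-correlated with the linear controllability
diagnostics.

Uses a 30-region single-system network so the whole campaign runs in about
a minute; the full-size analysis is identical with n_regions=83.
"""

import numpy as np

import netstim as ns
from netstim.experiments import find_transition_point, stimulation_campaign

net, regions = ns.generate_connectome(
    n_regions=30, n_systems=1, seed=3, density_profile=np.array([[0.3]])
)
delays = ns.compute_delays(regions.coords)

scan = find_transition_point(
    net, delays, ns.WCParams(), c5_grid=np.round(np.arange(0.6, 2.01, 0.1), 10),
    seed=1,
)
print(f"operating point: c5 = {scan.c5_operating}")

result = stimulation_campaign(net, delays, ns.WCParams(), scan.c5_operating, seed=2)

table = result.table()
print("\nper-region outcomes (first 5 rows):")
print(table.head().round(4).to_string(index=False))

c = result.correlations
print("\nSpearman rank correlations:")
for a, b in [
    ("functional_effect", "fractional_activation"),
    ("avg_ctrl", "functional_effect"),
    ("modal_ctrl", "functional_effect"),
    ("avg_ctrl", "structural_effect"),
]:
    print(f"  rho({a}, {b}) = {c.loc[a, b]:+.3f}")

# What the numbers mean: regions with high average controllability (hubs)
# move the whole functional state when stimulated (large functional effect)
# and do so globally (fractional activation tracks the functional effect
# almost perfectly); high-modal-controllability regions produce small, focal
# changes toward states less similar to the anatomy.
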