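"""Generate a synthetic structural connectome and inspect its anatomy.

Builds an 83-region network with the default four-system block structure
(sensory/association, higher-order cognitive, default mode, subcortical),
writes it to disk in the plain-text exchange formats, and reports the block
densities and the conduction-delay range implied by the region coordinates.
"""

import numpy as np

import netstim as ns
from netstim.experiments import system_aggregate_arrays

net, regions = ns.generate_connectome(n_regions=83, seed=0)

ns.write_network(net, "synthetic_network.txt")
ns.write_regions(regions, "synthetic_regions.tsv")
print("wrote synthetic_network.txt and synthetic_regions.tsv")

n = net.n_regions
deg = net.degree()
print(f"{n} regions, {np.count_nonzero(net.weights) // 2} edges, "
      f"degree max/median = {deg.max() / np.median(deg):.1f}")

_, density = system_aggregate_arrays(
    net, regions, np.arange(n), np.zeros(n), np.zeros(n)
)
print("\nrealized connection densities between cognitive systems:")
print(density.round(3).to_string())

delays = ns.compute_delays(regions.coords)  # 10 mm/ms transmission velocity
off = delays.tau_d[np.triu_indices(n, 1)]
print(f"\nconduction delays: {off.min():.2f} to {off.max():.2f} ms")

# What the numbers mean: the subcortical block is by far the densest
# subnetwork, the default-mode block next, matching the anatomy the
# generator emulates; delays span the physiological few-to-~15 ms range.
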