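"""Synthetic structural brain networks.

Weighted, undirected structural connectomes — region-by-region matrices of
white-matter streamline density — are the substrate on which every downstream
computation here operates.  Real connectomes of this kind are built by
deterministic tractography on diffusion imaging, parcellated into ~83 cortical
and subcortical regions, with streamline counts normalized by the volumes of
the connected regions.  This module generates networks with the same summary
statistics instead: sparse symmetric nonnegative matrices with a modular
block structure over a small number of coarse cognitive systems, heavy-tailed
(log-normal) edge weights, volume normalization, and spatially clustered 3-D
region coordinates from which axonal conduction delays are computed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "StructuralNetwork",
    "DelayMatrix",
    "DEFAULT_SYSTEMS",
    "DEFAULT_DENSITY_PROFILE",
    "DEFAULT_SYSTEM_PROPORTIONS",
    "generate_connectome",
    "volume_normalize",
    "compute_delays",
    "read_network",
    "write_network",
    "read_regions",
    "write_regions",
    "read_dataset",
]

#: Coarse cognitive-system labels used by the default generator, ordered as in
#: the density profile below.
DEFAULT_SYSTEMS = (
    "sensory_association",
    "higher_order_cognitive",
    "default_mode",
    "subcortical",
)

#: Default fraction of regions assigned to each coarse system.
DEFAULT_SYSTEM_PROPORTIONS = (0.40, 0.25, 0.17, 0.18)

#: Default within/between-system connection density targets.  The ordering
#: encodes the empirical picture for human connectomes at this parcellation
#: scale: subcortex is by far the densest subnetwork, the medial default-mode
#: system is the next densest and couples strongly to subcortex, and the
#: distributed cortical systems are sparse both internally and externally.
DEFAULT_DENSITY_PROFILE = np.array(
    [
        [0.054, 0.025, 0.059, 0.094],
        [0.025, 0.067, 0.046, 0.068],
        [0.059, 0.046, 0.257, 0.137],
        [0.094, 0.068, 0.137, 0.412],
    ]
)

#: Default overall weight scale, expressed as the expected spectral radius of
#: the generated adjacency matrix.  Real pipelines fix the total streamline
#: count per subject (tractography runs until a fixed number of streamlines),
#: which pins the overall magnitude of every subject's matrix to a common
#: scale; the generator emulates this by rescaling each network to a target
#: spectral radius with a small seeded log-normal jitter across seeds
#: (``spectral_jitter_sd``).  The default centers the oscillatory transition
#: of the coupled neural-mass model inside the standard global-coupling sweep
#: range (c5 in [1.0, 1.5]); see the methods note.
DEFAULT_WEIGHT_SCALE = 9.75

_REGION_COLUMNS = ("label", "x_mm", "y_mm", "z_mm", "volume", "system")


@dataclass
class RegionSet:
    """Per-region metadata: labels, 3-D coordinates, volumes, system tags.

    Parameters
    ----------
    labels : list of str
        Unique region names.
    coords : (N, 3) ndarray
        Region centroid positions in mm.
    volumes : (N,) ndarray
        Positive region volumes (arbitrary volume units; only ratios matter).
    systems : list of str
        Cognitive-system tag per region (non-empty strings).
    """

    labels: list[str]
    coords: np.ndarray
    volumes: np.ndarray
    systems: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.labels = list(self.labels)
        self.systems = list(self.systems)
        n = len(self.labels)
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} regions"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.volumes.shape != (n,) or np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive, one per region")
        if len(self.systems) != n or any(not s for s in self.systems):
            raise ValueError("systems must be non-empty strings, one per region")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def system_indices(self) -> dict[str, np.ndarray]:
        """Map each system tag to the array of region indices carrying it."""
        out: dict[str, np.ndarray] = {}
        systems = np.asarray(self.systems)
        for s in dict.fromkeys(self.systems):  # preserve first-seen order
            out[s] = np.flatnonzero(systems == s)
        return out


@dataclass
class StructuralNetwork:
    """Weighted undirected structural connectome.

    ``weights`` is the N x N symmetric nonnegative streamline-density matrix
    (zero diagonal); ``regions`` carries the matching metadata.
    """

    weights: np.ndarray
    regions: RegionSet

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = self.regions.n_regions
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} regions")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(w, w.T, rtol=0, atol=1e-12 * max(1.0, np.abs(w).max())):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if not np.any(w > 0):
            raise ValueError("network has no positive edge weight")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.regions.n_regions

    def degree(self) -> np.ndarray:
        """Weighted degree (row sum of the adjacency matrix)."""
        return self.weights.sum(axis=1)


@dataclass
class DelayMatrix:
    """Pairwise axonal conduction delays in ms (symmetric, zero diagonal)."""

    tau_d: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tau_d, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("delay matrix must be square")
        if not np.all(np.isfinite(t)):
            raise ValueError("delays contain non-finite values")
        if np.any(t < 0):
            raise ValueError("delays must be nonnegative")
        if not np.allclose(t, t.T):
            raise ValueError("delay matrix must be symmetric")
        if np.any(np.diag(t) != 0):
            raise ValueError("delay matrix must have a zero diagonal")
        self.tau_d = t


def volume_normalize(streamline_counts: np.ndarray, volumes: np.ndarray) -> np.ndarray:
    """Normalize streamline counts by the summed volume of each region pair.

    Entry (i, j) of the result is ``counts[i, j] / (volumes[i] + volumes[j])``,
    the standard conversion of raw streamline counts into streamline
    *densities* that removes the bias of large regions collecting more
    streamlines.  Symmetry of the input is preserved.
    """
    counts = np.asarray(streamline_counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes <= 0):
        raise ValueError("all volumes must be positive")
    if counts.shape != (volumes.size, volumes.size):
        raise ValueError(
            f"counts shape {counts.shape} incompatible with {volumes.size} volumes"
        )
    if np.any(counts < 0):
        raise ValueError("streamline counts must be nonnegative")
    return counts / (volumes[:, None] + volumes[None, :])


def compute_delays(coords: np.ndarray, velocity: float = 10.0) -> DelayMatrix:
    """Conduction delays from Euclidean inter-region distance.

    Parameters
    ----------
    coords : (N, 3) ndarray
        Region positions in mm.
    velocity : float
        Transmission velocity in mm/ms (10 mm/ms = 10 m/s, the standard
        value for myelinated long-range fibres).
    """
    if velocity <= 0:
        raise ValueError(f"velocity must be positive, got {velocity}")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain non-finite values")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    tau = dist / velocity
    np.fill_diagonal(tau, 0.0)
    return DelayMatrix(0.5 * (tau + tau.T))


def _system_assignment(n_regions: int, n_systems: int, proportions) -> np.ndarray:
    """Integer system index per region, contiguous blocks, sizes ~ proportions."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    sizes = np.floor(p * n_regions).astype(int)
    sizes[sizes == 0] = 1
    while sizes.sum() > n_regions:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_regions:
        sizes[np.argmin(sizes / p)] += 1
    return np.repeat(np.arange(n_systems), sizes)


def _sample_coords(
    rng: np.random.Generator,
    assignment: np.ndarray,
    n_systems: int,
    box_mm: float,
    cluster_sd_mm: float,
    min_separation_mm: float,
) -> np.ndarray:
    """Spatially clustered coordinates inside a cube of side ``box_mm``.

    System cluster centres sit well inside the box; regions scatter around
    their centre with isotropic Gaussian spread.  Pairs closer than
    ``min_separation_mm`` are re-drawn so every positive delay spans at least
    one integration step at the default dt.
    """
    lo, hi = 0.15 * box_mm, 0.85 * box_mm
    centers = rng.uniform(lo, hi, size=(n_systems, 3))
    # keep cluster centres apart so systems are genuinely clustered in space
    for _ in range(200):
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() >= 0.35 * box_mm:
            break
        i = np.unravel_index(np.argmin(d), d.shape)[0]
        centers[i] = rng.uniform(lo, hi, size=3)
    coords = centers[assignment] + rng.normal(0.0, cluster_sd_mm, size=(assignment.size, 3))
    coords = np.clip(coords, 0.0, box_mm)
    # enforce a minimum pairwise separation by jittered resampling
    for _ in range(200):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        too_close = np.unique(np.where(d < min_separation_mm)[0])
        if too_close.size == 0:
            break
        coords[too_close] = np.clip(
            centers[assignment[too_close]]
            + rng.normal(0.0, cluster_sd_mm, size=(too_close.size, 3)),
            0.0,
            box_mm,
        )
    else:
        raise RuntimeError("could not satisfy minimum region separation")
    return coords


def generate_connectome(
    n_regions: int = 83,
    n_systems: int = 4,
    seed: int = 0,
    density_profile: np.ndarray | None = None,
    weight_scale: float = DEFAULT_WEIGHT_SCALE,
    system_names=None,
    system_proportions=None,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 0.6,
    box_mm: float = 140.0,
    cluster_sd_mm: float = 18.0,
    min_separation_mm: float = 5.0,
    spectral_jitter_sd: float = 0.06,
) -> tuple[StructuralNetwork, RegionSet]:
    """Generate a synthetic structural connectome with region metadata.

    Edges are drawn independently per region pair with a probability given by
    the (system_i, system_j) entry of ``density_profile``; positive weights
    are log-normal streamline counts, volume-normalized by the summed region
    volumes, then rescaled so the matrix's spectral radius equals
    ``weight_scale`` times a per-seed log-normal jitter of spread
    ``spectral_jitter_sd`` (the synthetic analogue of tractography's fixed
    total streamline count, which pins every subject's matrix to a common
    overall magnitude up to individual variation).  Coordinates are sampled
    in a ``box_mm`` cube with same-system regions spatially clustered, which
    puts conduction delays in the ~1-15 ms range observed empirically.

    Returns the network and its region set (also reachable as
    ``network.regions``).  Deterministic for a fixed seed.
    """
    if n_regions < 2:
        raise ValueError(f"n_regions must be >= 2, got {n_regions}")
    if n_systems > n_regions:
        raise ValueError(
            f"n_systems ({n_systems}) cannot exceed n_regions ({n_regions})"
        )
    if density_profile is None:
        if n_systems == len(DEFAULT_SYSTEMS):
            density_profile = DEFAULT_DENSITY_PROFILE
        else:
            density_profile = np.full((n_systems, n_systems), 0.15)
    density_profile = np.asarray(density_profile, dtype=float)
    if density_profile.shape != (n_systems, n_systems):
        raise ValueError(
            f"density_profile shape {density_profile.shape} does not match "
            f"{n_systems} systems"
        )
    if np.any(density_profile <= 0) or np.any(density_profile > 1):
        raise ValueError("density_profile entries must lie in (0, 1]")
    if not np.allclose(density_profile, density_profile.T):
        raise ValueError("density_profile must be symmetric")
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    if system_names is None:
        system_names = (
            DEFAULT_SYSTEMS
            if n_systems == len(DEFAULT_SYSTEMS)
            else tuple(f"system_{k}" for k in range(n_systems))
        )
    if system_proportions is None:
        system_proportions = (
            DEFAULT_SYSTEM_PROPORTIONS
            if n_systems == len(DEFAULT_SYSTEMS)
            else np.full(n_systems, 1.0 / n_systems)
        )

    rng = np.random.default_rng(seed)
    assignment = _system_assignment(n_regions, n_systems, system_proportions)
    coords = _sample_coords(
        rng, assignment, n_systems, box_mm, cluster_sd_mm, min_separation_mm
    )
    volumes = rng.lognormal(mean=0.0, sigma=0.3, size=n_regions)

    p = density_profile[assignment[:, None], assignment[None, :]]
    iu = np.triu_indices(n_regions, k=1)
    edges = rng.random(iu[0].size) < p[iu]
    counts_u = np.where(
        edges, rng.lognormal(lognormal_mu, lognormal_sigma, size=iu[0].size), 0.0
    )
    counts = np.zeros((n_regions, n_regions))
    counts[iu] = counts_u
    counts += counts.T

    weights = volume_normalize(counts, volumes)
    radius = np.max(np.abs(np.linalg.eigvalsh(weights)))
    if radius > 0:
        target = weight_scale * rng.lognormal(0.0, spectral_jitter_sd)
        weights *= target / radius
    labels = [f"{system_names[assignment[i]]}_{i:03d}" for i in range(n_regions)]
    regions = RegionSet(
        labels=labels,
        coords=coords,
        volumes=volumes,
        systems=[system_names[a] for a in assignment],
    )
    return StructuralNetwork(weights=weights, regions=regions), regions


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str | None:
    """Comma-delimited if the first data line contains a comma, else whitespace."""
    return "," if "," in first_line else None


def write_network(net: StructuralNetwork, path) -> None:
    """Write the adjacency matrix as plain whitespace-delimited text."""
    np.savetxt(path, net.weights, fmt="%.17g")


def read_network(path, regions: RegionSet | None = None, atol: float = 1e-8):
    """Read a delimited N x N adjacency matrix.

    The delimiter (comma vs. whitespace) is sniffed from the first line.
    Asymmetric matrices (beyond ``atol``) and NaN entries are rejected rather
    than repaired.  If ``regions`` is given, a :class:`StructuralNetwork` is
    returned and the matrix dimension must match; otherwise the raw validated
    matrix is returned.
    """
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        text = fh.read()
    delim = _sniff_delimiter(first)
    w = np.loadtxt(io.StringIO(text), delimiter=delim, ndmin=2)
    if w.shape[0] != w.shape[1]:
        raise ValueError(
            f"matrix in {path} is {w.shape[0]}x{w.shape[1]}, expected square"
        )
    if np.any(np.isnan(w)):
        raise ValueError(f"matrix in {path} contains NaN entries")
    asym = np.abs(w - w.T).max()
    if asym > atol:
        raise ValueError(
            f"matrix in {path} is asymmetric (max |A - A^T| = {asym:.3g} > "
            f"atol {atol:.3g})"
        )
    w = 0.5 * (w + w.T)
    if np.abs(np.diag(w)).max() > atol:
        raise ValueError(f"matrix in {path} has nonzero diagonal entries")
    np.fill_diagonal(w, 0.0)
    if regions is not None:
        if w.shape[0] != regions.n_regions:
            raise ValueError(
                f"matrix is {w.shape[0]}x{w.shape[1]} but region file has "
                f"{regions.n_regions} regions"
            )
        return StructuralNetwork(weights=w, regions=regions)
    return w


def write_regions(rs: RegionSet, path) -> None:
    """Write region metadata as strict TSV with the canonical header."""
    df = pd.DataFrame(
        {
            "label": rs.labels,
            "x_mm": rs.coords[:, 0],
            "y_mm": rs.coords[:, 1],
            "z_mm": rs.coords[:, 2],
            "volume": rs.volumes,
            "system": rs.systems,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_regions(path) -> RegionSet:
    """Read region metadata from TSV (columns label, x_mm, y_mm, z_mm, volume, system)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region file {path} is missing columns: {missing}")
    return RegionSet(
        labels=df["label"].astype(str).tolist(),
        coords=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        volumes=df["volume"].to_numpy(dtype=float),
        systems=df["system"].astype(str).tolist(),
    )


def read_dataset(network_path, regions_path) -> StructuralNetwork:
    """Read matching network + region files, rejecting shape mismatches."""
    regions = read_regions(regions_path)
    return read_network(network_path, regions=regions)
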