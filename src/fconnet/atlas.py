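"""ROI atlas specification.

The analyses operate on a fixed parcellation of the brain into regions of
interest (ROIs), each assigned to one of six canonical resting-state
functional networks (the Dosenbach-160 scheme: cerebellum, cingulo-opercular,
default, fronto-parietal, occipital, sensorimotor). Coordinates are carried
as opaque MNI mm triples for reporting only; no image geometry is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six canonical functional networks, in canonical order.
CANONICAL_NETWORKS: tuple[str, ...] = (
    "cerebellum",
    "cingulo-opercular",
    "default",
    "fronto-parietal",
    "occipital",
    "sensorimotor",
)

#: Default per-network ROI counts for the 160-ROI atlas. The six network
#: names and the total of 160 are fixed by the parcellation scheme; the
#: individual counts are a configurable design choice.
DEFAULT_NETWORK_SIZES: dict[str, int] = {
    "cerebellum": 18,
    "cingulo-opercular": 32,
    "default": 34,
    "fronto-parietal": 21,
    "occipital": 22,
    "sensorimotor": 33,
}

# Rough network centroids (MNI mm), used only to give each synthetic ROI a
# plausible reporting coordinate.
_NETWORK_CENTROIDS: dict[str, tuple[float, float, float]] = {
    "cerebellum": (0.0, -65.0, -30.0),
    "cingulo-opercular": (0.0, 10.0, 30.0),
    "default": (0.0, -55.0, 25.0),
    "fronto-parietal": (0.0, 40.0, 30.0),
    "occipital": (0.0, -85.0, 5.0),
    "sensorimotor": (0.0, -25.0, 55.0),
}


class AtlasError(ValueError):
    """Raised for inconsistent atlas configuration."""


@dataclass(frozen=True)
class AtlasSpec:
    """An ROI parcellation: labels, network assignment, MNI coordinates.

    Attributes
    ----------
    labels : tuple of str
        Unique ROI names, one per node.
    networks : tuple of str
        Per-ROI functional network, drawn from :data:`CANONICAL_NETWORKS`.
    coords : ndarray of shape (n_rois, 3)
        Per-ROI MNI coordinate in mm (reporting only).
    """

    labels: tuple[str, ...]
    networks: tuple[str, ...]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise AtlasError(f"atlas needs at least 2 ROIs, got {n}")
        if len(self.networks) != n or self.coords.shape != (n, 3):
            raise AtlasError("labels, networks and coords must agree in length")
        if len(set(self.labels)) != n:
            raise AtlasError("ROI labels must be unique")
        bad = sorted(set(self.networks) - set(CANONICAL_NETWORKS))
        if bad:
            raise AtlasError(
                f"unknown network name(s) {bad}; allowed: {list(CANONICAL_NETWORKS)}"
            )

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    @property
    def network_names(self) -> tuple[str, ...]:
        """Networks present, in canonical order."""
        present = set(self.networks)
        return tuple(n for n in CANONICAL_NETWORKS if n in present)

    def network_indices(self, network: str) -> np.ndarray:
        """Indices of the ROIs assigned to ``network``."""
        return np.flatnonzero(np.asarray(self.networks) == network)


def scaled_network_sizes(n_rois: int) -> dict[str, int]:
    """Allocate ``n_rois`` over the six networks proportionally to the
    default 160-ROI partition (largest-remainder rounding)."""
    total = sum(DEFAULT_NETWORK_SIZES.values())
    exact = {k: v * n_rois / total for k, v in DEFAULT_NETWORK_SIZES.items()}
    sizes = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n_rois - sum(sizes.values())
    by_remainder = sorted(exact, key=lambda k: exact[k] - sizes[k], reverse=True)
    for k in by_remainder[:short]:
        sizes[k] += 1
    return {k: v for k, v in sizes.items() if v > 0}


def make_atlas(
    n_rois: int = 160, network_sizes: dict[str, int] | None = None
) -> AtlasSpec:
    """Build a deterministic synthetic atlas.

    ROIs are assigned to networks in canonical network order; labels are
    ``<network>_<k>``. Coordinates are a deterministic lattice spread around
    each network's centroid (synthetic, for reporting only).

    Parameters
    ----------
    n_rois : int
        Total number of ROIs (default 160).
    network_sizes : dict, optional
        Mapping network name -> ROI count; must sum to ``n_rois``. Defaults
        to the 160-ROI partition, scaled proportionally for other sizes.
    """
    if network_sizes is None:
        network_sizes = (
            dict(DEFAULT_NETWORK_SIZES) if n_rois == 160 else scaled_network_sizes(n_rois)
        )
    bad = sorted(set(network_sizes) - set(CANONICAL_NETWORKS))
    if bad:
        raise AtlasError(
            f"unknown network name(s) {bad}; allowed: {list(CANONICAL_NETWORKS)}"
        )
    total = sum(network_sizes.values())
    if total != n_rois:
        raise AtlasError(f"network sizes sum to {total}, expected n_rois={n_rois}")

    labels: list[str] = []
    networks: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for net in CANONICAL_NETWORKS:
        m = network_sizes.get(net, 0)
        cx, cy, cz = _NETWORK_CENTROIDS[net]
        for k in range(m):
            labels.append(f"{net}_{k + 1:03d}")
            networks.append(net)
            # 4x4 grid in x/y, stacked in z; alternate hemispheres in x
            side = 1 if k % 2 == 0 else -1
            coords.append(
                (
                    cx + side * (10.0 + 8.0 * ((k // 2) % 4)),
                    cy + 8.0 * ((k // 8) % 4),
                    cz + 6.0 * (k // 32),
                )
            )
    return AtlasSpec(tuple(labels), tuple(networks), np.asarray(coords, dtype=float))
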