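"""Group-representative, Euclidean-distance-weighted structural connectomes.

Two construction routes are supported: consensus binarization of individual
diffusion-style binary connectomes, and the tracer-table route used for
species where diffusion tractography is unreliable (directed ipsilateral /
contralateral injection records, symmetrized and mirrored across
hemispheres).  Either way, the resulting binary adjacency is weighted by the
Euclidean distance between region centroids, in millimeters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import FormatError, RegionTable

__all__ = [
    "StructuralConnectome",
    "consensus_binarize",
    "build_from_tracer",
    "euclidean_weighting",
    "connectivity_density",
    "TRACER_STRENGTH_THRESHOLD",
]

logger = logging.getLogger(__name__)

# Exclude tracer connections weaker than 10^-3.5 (normalized projection
# volume); suppresses false positives from segmentation artifacts.
TRACER_STRENGTH_THRESHOLD = 10.0 ** -3.5


@dataclass
class StructuralConnectome:
    """Undirected structural graph G = {V, W}.

    ``adjacency`` is binary symmetric with zero diagonal; ``weights`` holds
    the Euclidean inter-centroid distance (mm) on edges and +inf elsewhere.
    """

    adjacency: np.ndarray
    weights: np.ndarray
    regions: RegionTable

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise FormatError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise FormatError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise FormatError("adjacency diagonal must be zero")
        if not set(np.unique(a)).issubset({0, 1}):
            raise FormatError("adjacency must be binary")
        self.adjacency = a.astype(np.int8)
        w = np.asarray(self.weights, dtype=float)
        if not np.array_equal(np.isfinite(w), a.astype(bool)):
            raise FormatError("weights must be finite exactly on edges")
        on_edges = w[a.astype(bool)]
        if on_edges.size and np.any(on_edges <= 0):
            raise FormatError("edge weights must be strictly positive")
        if not np.array_equal(w, w.T):
            raise FormatError("weights must be symmetric")
        self.weights = w
        if a.shape[0] != self.regions.n_regions:
            raise FormatError("adjacency size does not match region table")
        if not self.is_connected():
            logger.warning(
                "structural connectome is disconnected; path queries between "
                "disconnected pairs will return empty ensembles"
            )

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def is_connected(self) -> bool:
        if self.n_regions == 0:
            return True
        return nx.is_connected(self.graph()) if self.n_edges else self.n_regions == 1

    def graph(self) -> nx.Graph:
        """The weighted networkx view (edge attribute ``weight``, mm)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        g.add_weighted_edges_from(
            (int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)
        )
        return g

    def density(self) -> float:
        return connectivity_density(self.adjacency)


def consensus_binarize(
    individual_adjacencies: list[np.ndarray], threshold: float = 1.0
) -> np.ndarray:
    """Keep an edge iff it is present in >= ``threshold`` fraction of subjects.

    The default 1.0 keeps only connections retrieved in all subjects,
    minimizing false positives in the group-representative network.
    """
    if not individual_adjacencies:
        raise ValueError("need at least one individual adjacency matrix")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    mats = [np.asarray(m) for m in individual_adjacencies]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise FormatError("individual adjacency shape mismatch")
        if not np.array_equal(m, m.T):
            raise FormatError("individual adjacency not symmetric")
        if not set(np.unique(m)).issubset({0, 1}):
            raise FormatError("individual adjacency not binary")
    frac = np.mean([m.astype(float) for m in mats], axis=0)
    out = (frac >= threshold).astype(np.int8)
    np.fill_diagonal(out, 0)
    return out


def _homologue_map(regions: RegionTable) -> dict[int, int]:
    """Pair each region with its opposite-hemisphere homologue.

    Homologues share the name stem obtained by stripping a trailing
    ``_L``/``_R`` hemisphere suffix.
    """
    if regions.hemisphere is None:
        raise FormatError("tracer construction requires a hemisphere column")
    stem: dict[tuple[str, str], int] = {}
    for idx, (name, hemi) in enumerate(zip(regions.names, regions.hemisphere)):
        if hemi not in ("L", "R"):
            raise FormatError(f"region {name!r} lacks hemisphere annotation")
        s = name[:-2] if name.endswith(("_L", "_R")) else name
        stem[(s, hemi)] = idx
    out: dict[int, int] = {}
    for (s, hemi), idx in stem.items():
        other = stem.get((s, "L" if hemi == "R" else "R"))
        if other is None:
            raise FormatError(f"no homologue for region {regions.names[idx]!r}")
        out[idx] = other
    return out


def build_from_tracer(
    table: pd.DataFrame,
    regions: RegionTable,
    strength_threshold: float = TRACER_STRENGTH_THRESHOLD,
    threshold_before_symmetrization: bool = True,
) -> np.ndarray:
    """Binary adjacency from directed tracer records.

    ``table`` columns: source, target, strength, laterality
    (ipsilateral/contralateral); records describe right-hemisphere
    injections.  Steps: drop sub-threshold records (by default before
    presence-symmetrization, the stricter order; set
    ``threshold_before_symmetrization=False`` to threshold after), OR-
    symmetrize ipsilateral edges, mirror them to the left hemisphere, and
    transpose contralateral edges to the left hemisphere.
    """
    required = {"source", "target", "strength", "laterality"}
    if not required.issubset(table.columns):
        raise FormatError(f"tracer table needs columns {sorted(required)}")
    if np.any(~np.isfinite(table["strength"])) or np.any(table["strength"] < 0):
        raise FormatError("tracer strengths must be finite and >= 0")
    homol = _homologue_map(regions)
    n = regions.n_regions
    hemi = regions.hemisphere
    assert hemi is not None

    def resolve(name: str) -> int:
        return regions.index_of(str(name))

    rows = table
    if threshold_before_symmetrization:
        rows = rows[rows["strength"] >= strength_threshold]

    # Directed presence among right-hemisphere sources, per laterality.
    ipsi = np.zeros((n, n), dtype=bool)
    contra = np.zeros((n, n), dtype=bool)
    strengths_ipsi = np.zeros((n, n))
    strengths_contra = np.zeros((n, n))
    for _, rec in rows.iterrows():
        s, t = resolve(rec["source"]), resolve(rec["target"])
        if hemi[s] != "R":
            continue  # step (i): right-hemisphere records only
        lat = str(rec["laterality"])
        if lat == "ipsilateral":
            ipsi[s, t] = True
            strengths_ipsi[s, t] = max(strengths_ipsi[s, t], float(rec["strength"]))
        elif lat == "contralateral":
            contra[s, t] = True
            strengths_contra[s, t] = max(
                strengths_contra[s, t], float(rec["strength"])
            )
        else:
            raise FormatError(f"unknown laterality {lat!r}")

    # step (ii): presence OR-symmetrization of ipsilateral connections
    ipsi_und = ipsi | ipsi.T
    contra_und = contra | contra.T
    if not threshold_before_symmetrization:
        smax_i = np.maximum(strengths_ipsi, strengths_ipsi.T)
        ipsi_und &= smax_i >= strength_threshold
        smax_c = np.maximum(strengths_contra, strengths_contra.T)
        contra_und &= smax_c >= strength_threshold

    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(n):
            if ipsi_und[i, j]:
                adj[i, j] = adj[j, i] = 1
                # step (iii): duplicate to the left hemisphere
                adj[homol[i], homol[j]] = adj[homol[j], homol[i]] = 1
            if contra_und[i, j]:
                adj[i, j] = adj[j, i] = 1
                # step (iv): transpose contralateral edges to the left hemisphere
                adj[homol[i], homol[j]] = adj[homol[j], homol[i]] = 1
    np.fill_diagonal(adj, 0)
    return adj


def euclidean_weighting(
    adjacency: np.ndarray, regions: RegionTable
) -> StructuralConnectome:
    """Weight edges by Euclidean inter-centroid distance, w_ij = ||c_i - c_j||."""
    adjacency = np.asarray(adjacency)
    dist = regions.pairwise_distances()
    edges = adjacency.astype(bool)
    zero = np.argwhere(edges & (dist <= 0))
    zero = zero[zero[:, 0] != zero[:, 1]] if zero.size else zero
    if zero.size:
        i, j = zero[0]
        raise FormatError(
            f"connected regions {regions.names[i]!r} and {regions.names[j]!r} "
            "have coincident centroids (zero-distance edge)"
        )
    weights = np.where(edges, dist, np.inf)
    np.fill_diagonal(weights, np.inf)
    return StructuralConnectome(adjacency=adjacency, weights=weights, regions=regions)


def connectivity_density(adjacency: np.ndarray) -> float:
    """Fraction of region pairs connected by an edge."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    if n < 2:
        return 0.0
    return float(np.triu(a, 1).sum() / (n * (n - 1) / 2))
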