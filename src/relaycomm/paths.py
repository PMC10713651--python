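"""k-shortest loopless structural paths and path-ensemble statistics.

Paths are sequences of pairwise connected, non-repeating nodes; path length
is the sum of Euclidean edge weights along the path (mm).  The k paths of
minimal total length per region pair form the ensemble used downstream for
data-processing-inequality screening.  The direct 1-hop edge, when present,
is enumerated as a candidate path (typically rank 1 under distance weights);
relay assessment downstream excludes it, since the inequality cannot be
evaluated on a single step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import h5py
import networkx as nx
import numpy as np

from .connectome import StructuralConnectome

__all__ = [
    "PathEnsemble",
    "k_shortest_paths",
    "all_pairs_ensemble",
    "hop_statistics",
    "edge_coverage",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 5  # edge participation in multi-step paths plateaus near k ~ 5


def _path_length(weights: np.ndarray, path: tuple[int, ...]) -> float:
    return float(sum(weights[a, b] for a, b in zip(path[:-1], path[1:])))


def k_shortest_paths(
    connectome: StructuralConnectome,
    i: int,
    j: int,
    k: int = DEFAULT_K,
    multi_step_only: bool = False,
    graph: nx.Graph | None = None,
) -> list[tuple[int, ...]]:
    """The k minimum-length simple paths from i to j, deterministically ranked.

    Yen's algorithm (networkx ``shortest_simple_paths``) supplies candidates
    in nondecreasing length; equal-length ties are broken by lexicographic
    order of the node-name sequence so output is platform-independent.  With
    ``multi_step_only`` the direct edge is skipped and k multi-hop paths are
    returned instead.  Disconnected pairs yield an empty list.
    """
    n = connectome.n_regions
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"region index out of range: {i}, {j}")
    if i == j:
        raise ValueError("source and target must differ")
    if k < 1:
        raise ValueError("k must be >= 1")
    g = graph if graph is not None else connectome.graph()
    w = connectome.weights
    names = connectome.regions.names
    try:
        gen = nx.shortest_simple_paths(g, i, j, weight="weight")
    except nx.NodeNotFound:  # isolated node
        return []

    # Drain the generator until a path strictly longer than the k-th
    # candidate appears, so every tie at the cutoff length is collected
    # before the deterministic re-sort.
    needed = k + 1 if (multi_step_only and connectome.adjacency[i, j]) else k
    candidates: list[tuple[float, tuple[str, ...], tuple[int, ...]]] = []
    kth_len: float | None = None
    try:
        for p in gen:
            path = tuple(int(v) for v in p)
            length = _path_length(w, path)
            if kth_len is not None and length > kth_len:
                break
            candidates.append((length, tuple(names[v] for v in path), path))
            if len(candidates) >= needed:
                kth_len = sorted(c[0] for c in candidates)[needed - 1]
    except nx.NetworkXNoPath:
        return []
    candidates.sort(key=lambda c: (c[0], c[1]))
    paths = [c[2] for c in candidates]
    if multi_step_only:
        paths = [p for p in paths if len(p) > 2]
    return paths[:k]


@dataclass
class PathEnsemble:
    """Ranked simple paths for every unordered region pair.

    ``paths[(i, j)]`` (i < j) is the ranked list of node sequences; lengths
    and hop counts are derived on construction.
    """

    k: int
    n_regions: int
    paths: dict[tuple[int, int], list[tuple[int, ...]]]
    lengths: dict[tuple[int, int], list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, plist in self.paths.items():
            i, j = pair
            for p in plist:
                if p[0] != i or p[-1] != j or len(set(p)) != len(p):
                    raise ValueError(f"invalid path {p} for pair {pair}")

    @classmethod
    def build(
        cls,
        connectome: StructuralConnectome,
        k: int = DEFAULT_K,
        multi_step_only: bool = False,
    ) -> "PathEnsemble":
        g = connectome.graph()
        n = connectome.n_regions
        paths: dict[tuple[int, int], list[tuple[int, ...]]] = {}
        lengths: dict[tuple[int, int], list[float]] = {}
        n_disconnected = 0
        for i in range(n):
            for j in range(i + 1, n):
                plist = k_shortest_paths(
                    connectome, i, j, k, multi_step_only=multi_step_only, graph=g
                )
                paths[(i, j)] = plist
                lengths[(i, j)] = [
                    _path_length(connectome.weights, p) for p in plist
                ]
                if not plist:
                    n_disconnected += 1
        if n_disconnected:
            logger.warning("%d region pairs are disconnected", n_disconnected)
        return cls(k=k, n_regions=n, paths=paths, lengths=lengths)

    def pair(self, i: int, j: int) -> list[tuple[int, ...]]:
        a, b = (i, j) if i < j else (j, i)
        return self.paths.get((a, b), [])

    def iter_paths(self):
        """Yield (pair, rank, path) over all enumerated paths; rank is 1-based."""
        for pair in sorted(self.paths):
            for rank, p in enumerate(self.paths[pair], start=1):
                yield pair, rank, p

    @property
    def n_disconnected_pairs(self) -> int:
        return sum(1 for p in self.paths.values() if not p)

    def to_hdf5(self, path: str | FsPath) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["k"] = self.k
            f.attrs["n_regions"] = self.n_regions
            for (i, j), plist in self.paths.items():
                grp = f.create_group(f"pair_{i}_{j}")
                for r, p in enumerate(plist):
                    grp.create_dataset(f"path_{r}", data=np.asarray(p, dtype=np.int32))
                grp.create_dataset(
                    "lengths", data=np.asarray(self.lengths[(i, j)], dtype=float)
                )

    @classmethod
    def from_hdf5(cls, path: str | FsPath) -> "PathEnsemble":
        paths: dict[tuple[int, int], list[tuple[int, ...]]] = {}
        lengths: dict[tuple[int, int], list[float]] = {}
        with h5py.File(path, "r") as f:
            k = int(f.attrs["k"])
            n = int(f.attrs["n_regions"])
            for key in f:
                _, si, sj = key.split("_")
                pair = (int(si), int(sj))
                grp = f[key]
                ranks = sorted(
                    (int(name.split("_")[1]), name)
                    for name in grp
                    if name.startswith("path_")
                )
                paths[pair] = [tuple(int(v) for v in grp[name][()]) for _, name in ranks]
                lengths[pair] = [float(v) for v in grp["lengths"][()]]
        return cls(k=k, n_regions=n, paths=paths, lengths=lengths)


def all_pairs_ensemble(
    connectome: StructuralConnectome,
    k: int = DEFAULT_K,
    multi_step_only: bool = False,
) -> PathEnsemble:
    """Ensembles for all N(N-1)/2 region pairs (see :meth:`PathEnsemble.build`)."""
    return PathEnsemble.build(connectome, k, multi_step_only)


def hop_statistics(
    ensemble: PathEnsemble, multi_step_only: bool = False
) -> dict:
    """Mean and sd of hop counts, overall and per path rank."""
    all_hops: list[int] = []
    per_rank: dict[int, list[int]] = {}
    for _, rank, p in ensemble.iter_paths():
        hops = len(p) - 1
        if multi_step_only and hops < 2:
            continue
        all_hops.append(hops)
        per_rank.setdefault(rank, []).append(hops)
    if not all_hops:
        raise ValueError("ensemble has no paths to summarize")
    return {
        "mean": float(np.mean(all_hops)),
        "sd": float(np.std(all_hops)),
        "n_paths": len(all_hops),
        "per_rank": {
            r: {"mean": float(np.mean(h)), "sd": float(np.std(h)), "n": len(h)}
            for r, h in sorted(per_rank.items())
        },
    }


def edge_coverage(
    ensemble: PathEnsemble,
    connectome: StructuralConnectome,
    multi_step_only: bool = True,
) -> float:
    """Fraction of structural edges used by at least one enumerated path."""
    used: set[tuple[int, int]] = set()
    for _, _, p in ensemble.iter_paths():
        if multi_step_only and len(p) <= 2:
            continue
        for a, b in zip(p[:-1], p[1:]):
            used.add((a, b) if a < b else (b, a))
    n_edges = connectome.n_edges
    if n_edges == 0:
        return 0.0
    return len(used) / n_edges
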