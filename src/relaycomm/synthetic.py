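"""Synthetic connectomes and relay-structured time series with ground truth.

The generator emulates the statistical structure the relay analysis assumes:
a sparse, spatially embedded connectome whose edges prefer short Euclidean
distances, and z-scored regional series in which designated chains carry an
additive-Gaussian relay process — each chain node's series is its
predecessor's plus independent noise, which is exactly Markov, so the data
processing inequality holds along the chain in expectation while MI decays
with hop count.  Non-chain regions receive independent noise.  Cohorts add
subject-specific chains at a controllable rate to support fingerprinting
experiments with a known individuality mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .connectome import StructuralConnectome, euclidean_weighting
from .infotheory import zscore
from .io import RegionTable, TimeSeriesPanel, rng_service

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "synth_connectome",
    "plant_chains",
    "plant_walk_chains",
    "synth_relay_panel",
    "synth_cohort",
    "recovery_metrics",
    "random_pcs_cohort",
    "DEFAULT_OPERATING_POINT",
]

# Relay-sensitivity operating point frozen from a pilot sweep over
# (hop_noise_sd, T) at the default generator conditions.
DEFAULT_OPERATING_POINT = 0.9

_SYSTEM_CYCLE = (
    ("VIS", "unimodal"),
    ("SM", "unimodal"),
    ("DA", "transmodal"),
    ("DMN", "transmodal"),
)


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    Defaults mirror the desk-scale conditions used throughout the test
    suite: 40 regions in a 100 mm cube at edge density 0.15, T = 800
    time points, per-hop noise sd 0.5.
    """

    n_regions: int = 40
    box_mm: float = 100.0
    density: float = 0.15
    n_chains: int = 6
    hop_noise_sd: float = 0.5
    n_timepoints: int = 800
    n_subjects: int = 10
    subject_effect: float = 0.0
    n_individual_chains: int = 3
    individual_chain_hops: int = 9
    seed: int | None = None

    def __post_init__(self) -> None:
        min_density = (self.n_regions - 1) / (
            self.n_regions * (self.n_regions - 1) / 2
        )
        if not (min_density <= self.density <= 1.0):
            raise ValueError(
                f"density {self.density} infeasible for N={self.n_regions}"
            )
        if not (0 <= self.subject_effect <= 1):
            raise ValueError("subject_effect must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted: relay chains, per-subject chains, individuality mask."""

    chains: list[tuple[int, ...]] = field(default_factory=list)
    subject_chains: dict[str, list[tuple[int, ...]]] = field(default_factory=dict)
    n_regions: int = 0

    @property
    def chain_nodes(self) -> set[int]:
        return {v for c in self.chains for v in c}

    @property
    def chain_pairs(self) -> set[tuple[int, int]]:
        return {
            (min(c[0], c[-1]), max(c[0], c[-1])) for c in self.chains
        }

    def independent_nodes(self) -> set[int]:
        return set(range(self.n_regions)) - self.chain_nodes

    def individuality_mask(self) -> np.ndarray:
        """Pairs whose endpoints carry any subject-specific chain."""
        mask = np.zeros((self.n_regions, self.n_regions), dtype=bool)
        for chains in self.subject_chains.values():
            for c in chains:
                i, j = c[0], c[-1]
                mask[i, j] = mask[j, i] = True
        return mask


def _default_regions(n: int, centroids: np.ndarray) -> RegionTable:
    names = [f"R{i:03d}" for i in range(n)]
    systems, modality = [], []
    for i in range(n):
        s, m = _SYSTEM_CYCLE[i % len(_SYSTEM_CYCLE)]
        systems.append(s)
        modality.append(m)
    return RegionTable(
        names=names, centroids=centroids, systems=systems, modality_class=modality
    )


def synth_connectome(
    n_regions: int = 40,
    density: float = 0.15,
    box_mm: float = 100.0,
    rng=None,
) -> StructuralConnectome:
    """Spatially embedded random connectome with guaranteed connectivity.

    Centroids are uniform in a cube of side ``box_mm``; the Euclidean
    minimum spanning tree forms a connected backbone, and the remaining
    edge budget is sampled without replacement with distance-decaying
    probability (scale box/4), so realized density matches the target up to
    rounding.
    """
    rng = rng_service(rng)
    centroids = rng.uniform(0, box_mm, size=(n_regions, 3))
    regions = _default_regions(n_regions, centroids)
    dist = regions.pairwise_distances()
    n_pairs = n_regions * (n_regions - 1) // 2
    m_target = int(round(density * n_pairs))
    if m_target < n_regions - 1:
        raise ValueError("density infeasible: below spanning-tree minimum")
    mst = minimum_spanning_tree(dist).toarray()
    adjacency = ((mst > 0) | (mst.T > 0)).astype(np.int8)
    iu = np.triu_indices(n_regions, 1)
    free = adjacency[iu] == 0
    n_extra = m_target - int(adjacency[iu].sum())
    if n_extra > 0:
        weights = np.exp(-dist[iu][free] / (box_mm / 4.0))
        idx_free = np.nonzero(free)[0]
        pick = rng.choice(
            idx_free, size=n_extra, replace=False, p=weights / weights.sum()
        )
        rows, cols = iu[0][pick], iu[1][pick]
        adjacency[rows, cols] = adjacency[cols, rows] = 1
    return euclidean_weighting(adjacency, regions)


def plant_chains(
    connectome: StructuralConnectome,
    n_chains: int,
    rng=None,
    hop_range: tuple[int, int] = (2, 3),
    disjoint: bool = True,
    exclude_nodes: set[int] | None = None,
    max_tries: int = 5000,
) -> list[tuple[int, ...]]:
    """Choose relay chains that are shortest structural paths of 2-3 hops.

    Each chain is the weighted shortest path between a random region pair,
    accepted when its hop count falls in ``hop_range`` (so it will appear in
    the pair's k-shortest ensemble at rank 1 among multi-step paths) and,
    with ``disjoint``, when it shares no node with earlier chains.
    """
    import networkx as nx

    rng = rng_service(rng)
    g = connectome.graph()
    n = connectome.n_regions
    used: set[int] = set(exclude_nodes or ())
    chains: list[tuple[int, ...]] = []
    for _ in range(max_tries):
        if len(chains) >= n_chains:
            break
        i, j = rng.choice(n, size=2, replace=False)
        try:
            sp = nx.dijkstra_path(g, int(i), int(j), weight="weight")
        except nx.NetworkXNoPath:
            continue
        hops = len(sp) - 1
        if not (hop_range[0] <= hops <= hop_range[1]):
            continue
        if disjoint and (set(sp) & used):
            continue
        chains.append(tuple(sp))
        used.update(sp)
    if len(chains) < n_chains:
        raise RuntimeError(
            f"could only place {len(chains)} of {n_chains} chains; "
            "lower n_chains or raise density"
        )
    return chains


def plant_walk_chains(
    connectome: StructuralConnectome,
    n_chains: int,
    n_hops: int,
    rng=None,
    exclude_nodes: set[int] | None = None,
    max_tries: int = 2000,
) -> list[tuple[int, ...]]:
    """Long relay chains as node-disjoint self-avoiding walks.

    Unlike :func:`plant_chains`, these chains need not be shortest paths;
    they exist to endow a panel with a stable MI structure over many region
    pairs (every within-chain pair carries elevated, hop-ordered MI), which
    is what makes a subject recognizable from split-half data.
    """
    rng = rng_service(rng)
    n = connectome.n_regions
    adjacency = connectome.adjacency
    excluded = set(exclude_nodes or ())
    # an early chain can strand the remaining nodes, so failed set
    # constructions are restarted from scratch
    for _ in range(50):
        used = set(excluded)
        chains: list[tuple[int, ...]] = []
        tries = 0
        while len(chains) < n_chains and tries < max_tries:
            tries += 1
            start = int(rng.integers(n))
            if start in used:
                continue
            walk = [start]
            for _ in range(n_hops):
                nbrs = [
                    int(v)
                    for v in np.nonzero(adjacency[walk[-1]])[0]
                    if v not in walk and v not in used
                ]
                if not nbrs:
                    break
                walk.append(nbrs[int(rng.integers(len(nbrs)))])
            if len(walk) == n_hops + 1:
                chains.append(tuple(walk))
                used.update(walk)
        if len(chains) == n_chains:
            return chains
    raise RuntimeError(
        f"could only place {len(chains)} of {n_chains} walk chains of "
        f"{n_hops} hops; lower the demand or raise density"
    )


def synth_relay_panel(
    connectome: StructuralConnectome,
    chains: list[tuple[int, ...]],
    hop_noise_sd: float,
    n_timepoints: int,
    rng=None,
    subject_id: str = "synthetic",
    allow_overlap: bool = False,
) -> tuple[TimeSeriesPanel, GroundTruth]:
    """Panel with additive-Gaussian relay processes along the given chains.

    Chain sources get iid N(0,1) series; each subsequent chain node is the
    previous node's series plus independent noise of sd ``hop_noise_sd``;
    everything is z-scored per column at the end.  A node appearing in more
    than one chain is an error unless ``allow_overlap``, in which case it
    receives the sum of its parents' contributions.
    """
    rng = rng_service(rng)
    n = connectome.n_regions
    adjacency = connectome.adjacency
    parents: dict[int, list[int]] = {}
    sources: set[int] = set()
    for c in chains:
        for a, b in zip(c[:-1], c[1:]):
            if not adjacency[a, b]:
                raise ValueError(f"chain step ({a}, {b}) is not a structural edge")
            parents.setdefault(b, []).append(a)
        sources.add(c[0])
    multi = [v for v, ps in parents.items() if len(ps) > 1]
    if multi and not allow_overlap:
        raise ValueError(f"node(s) {multi} lie on several chains")

    values = np.empty((n_timepoints, n))
    assigned = np.zeros(n, dtype=bool)
    for v in range(n):
        if v not in parents:
            values[:, v] = rng.standard_normal(n_timepoints)
            assigned[v] = v in sources or v not in parents
    # Propagate along chains in order so parents exist before children.
    pending = dict(parents)
    while pending:
        progressed = False
        for child in list(pending):
            ps = pending[child]
            if all(p not in pending for p in ps):
                sig = np.sum([values[:, p] for p in ps], axis=0)
                values[:, child] = sig + hop_noise_sd * rng.standard_normal(
                    n_timepoints
                )
                del pending[child]
                progressed = True
        if not progressed:
            raise ValueError("cyclic chain structure")
    panel = zscore(TimeSeriesPanel(subject_id, values))
    truth = GroundTruth(chains=list(chains), n_regions=n)
    return panel, truth


def synth_cohort(
    spec: SyntheticSpec, rng=None
) -> tuple[StructuralConnectome, list[TimeSeriesPanel], GroundTruth]:
    """Multi-subject cohort on a shared connectome.

    All subjects share ``spec.n_chains`` base chains (shortest structural
    paths); each subject additionally receives
    ``round(subject_effect * n_individual_chains)`` long relay chains of its
    own (self-avoiding walks of ``individual_chain_hops`` hops, disjoint
    from the base chains), which give the subject a stable, recognizable MI
    structure over many region pairs.
    """
    if spec.n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects")
    rng = rng_service(rng if rng is not None else spec.seed)
    conn = synth_connectome(spec.n_regions, spec.density, spec.box_mm, rng)
    base = plant_chains(conn, spec.n_chains, rng) if spec.n_chains else []
    base_nodes = {v for c in base for v in c}
    n_ind = int(round(spec.subject_effect * spec.n_individual_chains))
    panels: list[TimeSeriesPanel] = []
    truth = GroundTruth(chains=list(base), n_regions=spec.n_regions)
    for s in range(spec.n_subjects):
        sid = f"sub-{s:03d}"
        own: list[tuple[int, ...]] = []
        if n_ind > 0:
            own = plant_walk_chains(
                conn,
                n_ind,
                spec.individual_chain_hops,
                rng,
                exclude_nodes=set(base_nodes),
            )
        panel, _ = synth_relay_panel(
            conn,
            base + own,
            spec.hop_noise_sd,
            spec.n_timepoints,
            rng,
            subject_id=sid,
        )
        truth.subject_chains[sid] = own
        panels.append(panel)
    return conn, panels, truth


def recovery_metrics(
    ensemble,
    mi,
    truth: GroundTruth,
    mode: str = "bidirectional",
    labels: dict[tuple[int, ...], bool] | None = None,
) -> dict:
    """Sensitivity and specificity of relay labeling against planted truth.

    Sensitivity: fraction of planted chains, found among the enumerated
    multi-step paths, that are labeled relay.  Specificity: fraction of
    enumerated multi-step paths touching no chain node that are labeled
    non-relay.  ``labels`` may supply precomputed path labels; otherwise the
    DPI check is run on ``mi``.
    """
    from .relay import dpi_check

    chain_set = {c for c in truth.chains} | {c[::-1] for c in truth.chains}
    chain_nodes = truth.chain_nodes
    planted_hits = planted_total = 0
    null_ok = null_total = 0
    for _, _, p in ensemble.iter_paths():
        if len(p) <= 2:
            continue
        if labels is not None:
            is_relay = labels[p]
        else:
            is_relay = dpi_check(p, mi, mode).is_relay
        if p in chain_set:
            planted_total += 1
            planted_hits += is_relay
        elif not (set(p) & chain_nodes):
            null_total += 1
            null_ok += not is_relay
    if planted_total == 0:
        raise ValueError("no planted chain appears in the ensemble")
    if null_total == 0:
        raise ValueError("no chain-free multi-step path in the ensemble")
    return {
        "sensitivity": planted_hits / planted_total,
        "specificity": null_ok / null_total,
        "n_planted": planted_total,
        "n_null_paths": null_total,
    }


def random_pcs_cohort(
    n_subjects: int,
    n_regions: int,
    k: int = 5,
    rng=None,
    probs: np.ndarray | None = None,
):
    """Test/retest PCS matrices with no subject structure (chance cohorts).

    Every subject's test and retest matrices are drawn independently with
    iid upper-triangle entries from ``probs`` over {0..k} (uniform by
    default), so the only attainable identification rate is chance.
    """
    from .relay import PCSMatrix

    rng = rng_service(rng)
    if probs is None:
        probs = np.full(k + 1, 1.0 / (k + 1))
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    iu = np.triu_indices(n_regions, 1)

    def draw(sid: str) -> "PCSMatrix":
        vals = np.zeros((n_regions, n_regions), dtype=np.int64)
        entries = rng.choice(k + 1, size=len(iu[0]), p=probs)
        vals[iu] = entries
        vals[(iu[1], iu[0])] = entries
        return PCSMatrix(values=vals, subject_id=sid, k=k)

    test = [draw(f"sub-{s:03d}") for s in range(n_subjects)]
    retest = [draw(f"sub-{s:03d}") for s in range(n_subjects)]
    return test, retest
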