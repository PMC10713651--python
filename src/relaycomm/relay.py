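"""Data-processing-inequality screening of structural paths and PCS.

A multi-step structural path i - a - b - ... - j is compatible with relay
(Markovian) information transmission when the sequence of pairwise MI values
along it does not increase away from the anchor region.  Three inequality
sets are available:

* ``source`` — the source-anchored sequence
  Phi = (I(i,a), I(i,b), ..., I(i,j)) must be non-increasing;
* ``bidirectional`` (default) — additionally, the target-anchored sequence
  along the reversed path must be non-increasing, honoring the fact that an
  undirected Markov chain read backwards is also a Markov chain;
* ``all_triplets`` — I(u,w) <= min(I(u,v), I(v,w)) for every ordered triplet
  of positions u < v < w along the path.

All comparisons are non-strict on the computed doubles; exact ties satisfy
the inequality.  Note that ``source`` mode depends on the path's stored
orientation (ensembles anchor paths at the lower-index endpoint), whereas
``bidirectional`` and ``all_triplets`` are direction-symmetric.  The parallel communication score PCS_ij counts, among the
pair's k-shortest paths, the assessable (multi-step) ones labeled relay:
0 = no Markovian transmission, 1 = selective, >1 = parallel transmission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infotheory import MIMatrix
from .io import FormatError, RegionTable
from .paths import PathEnsemble

__all__ = [
    "DPIResult",
    "PCSMatrix",
    "CommunicationDensity",
    "DPI_MODES",
    "dpi_check",
    "pcs",
    "communication_density",
    "group_average_pcs",
    "nodal_pcs",
    "system_summary",
]

DPI_MODES = ("source", "bidirectional", "all_triplets")


@dataclass
class DPIResult:
    path: tuple[int, ...]
    phi_source: np.ndarray  # MI of each successive node with the source
    phi_target: np.ndarray  # MI of each successive node with the target, reversed path
    is_relay: bool
    assessable: bool  # multi-step paths only


@dataclass
class PCSMatrix:
    """Integer N x N matrix of parallel communication scores in [0, k].

    ``missing_mask`` flags pairs with no enumerated multi-step path, whose
    score of 0 is structural rather than observed.
    """

    values: np.ndarray
    subject_id: str
    k: int
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError("PCS matrix must be square")
        if not np.array_equal(v, v.T):
            raise FormatError("PCS matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise FormatError("PCS diagonal must be zero")
        if np.any(v < 0) or np.any(v > self.k):
            raise FormatError(f"PCS values must lie in [0, {self.k}]")
        self.values = v.astype(np.int64)
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self, exclude_missing: bool = False) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, 1)
        vals = self.values[iu]
        if exclude_missing:
            vals = vals[~self.missing_mask[iu]]
        return vals


@dataclass
class CommunicationDensity:
    """Percent of assessable paths satisfying the DPI, per path rank."""

    subject_id: str
    overall: float  # percent
    per_rank: dict[int, float] = field(default_factory=dict)
    n_assessable: int = 0


def _phi(path: tuple[int, ...], mi: np.ndarray, anchor: int) -> np.ndarray:
    return np.array([mi[anchor, v] for v in path if v != anchor])


def dpi_check(
    path: tuple[int, ...] | list[int],
    mi: MIMatrix | np.ndarray,
    mode: str = "bidirectional",
) -> DPIResult:
    """Label one structural path as relay (DPI-respecting) or not."""
    if mode not in DPI_MODES:
        raise ValueError(f"unknown dpi mode {mode!r}")
    path = tuple(int(v) for v in path)
    if len(path) < 2:
        raise ValueError("a path needs at least 2 nodes")
    m = mi.values if isinstance(mi, MIMatrix) else np.asarray(mi, dtype=float)
    for a in path:
        for b in path:
            if a != b and not np.isfinite(m[a, b]):
                raise ValueError(f"missing MI entry for pair ({a}, {b})")
    phi_s = _phi(path, m, anchor=path[0])
    phi_t = _phi(path[::-1], m, anchor=path[-1])
    if len(path) == 2:
        return DPIResult(path, phi_s, phi_t, is_relay=False, assessable=False)
    if mode == "source":
        ok = bool(np.all(np.diff(phi_s) <= 0))
    elif mode == "bidirectional":
        ok = bool(np.all(np.diff(phi_s) <= 0) and np.all(np.diff(phi_t) <= 0))
    else:  # all_triplets
        ok = True
        L = len(path)
        for u in range(L):
            for v in range(u + 1, L):
                for w in range(v + 1, L):
                    a, b, c = path[u], path[v], path[w]
                    if m[a, c] > min(m[a, b], m[b, c]):
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
    return DPIResult(path, phi_s, phi_t, is_relay=ok, assessable=True)


def pcs(
    ensemble: PathEnsemble,
    mi: MIMatrix,
    mode: str = "bidirectional",
) -> PCSMatrix:
    """Parallel communication scores: per pair, the number of DPI-respecting
    multi-step paths among its k-shortest paths."""
    n = ensemble.n_regions
    if mi.n_regions != n:
        raise FormatError(
            f"MI matrix over {mi.n_regions} regions, ensemble over {n}"
        )
    values = np.zeros((n, n), dtype=np.int64)
    missing = np.zeros((n, n), dtype=bool)
    m = mi.values
    for (i, j), plist in ensemble.paths.items():
        count = 0
        assessable = 0
        for p in plist:
            if len(p) <= 2:
                continue
            assessable += 1
            if dpi_check(p, m, mode).is_relay:
                count += 1
        values[i, j] = values[j, i] = count
        if assessable == 0:
            missing[i, j] = missing[j, i] = True
    return PCSMatrix(
        values=values, subject_id=mi.subject_id, k=ensemble.k, missing_mask=missing
    )


def communication_density(
    ensemble: PathEnsemble,
    mi: MIMatrix,
    mode: str = "bidirectional",
) -> CommunicationDensity:
    """Percent of assessable (multi-step) paths labeled relay, per rank.

    A path's rank is its 1-based position in the pair's k-shortest list; the
    denominator at each rank counts the assessable paths at that rank only.
    """
    m = mi.values
    n_ok: dict[int, int] = {}
    n_tot: dict[int, int] = {}
    for _, rank, p in ensemble.iter_paths():
        if len(p) <= 2:
            continue
        n_tot[rank] = n_tot.get(rank, 0) + 1
        if dpi_check(p, m, mode).is_relay:
            n_ok[rank] = n_ok.get(rank, 0) + 1
    total = sum(n_tot.values())
    if total == 0:
        raise ValueError("no assessable (multi-step) paths in ensemble")
    overall = 100.0 * sum(n_ok.values()) / total
    per_rank = {
        r: 100.0 * n_ok.get(r, 0) / n_tot[r] for r in sorted(n_tot)
    }
    return CommunicationDensity(
        subject_id=mi.subject_id,
        overall=overall,
        per_rank=per_rank,
        n_assessable=total,
    )


def group_average_pcs(pcs_list: list[PCSMatrix]) -> tuple[np.ndarray, dict]:
    """Entrywise mean PCS over subjects plus histogram / percentile summary."""
    if not pcs_list:
        raise ValueError("empty PCS list")
    n = pcs_list[0].n_regions
    k = pcs_list[0].k
    for p in pcs_list:
        if p.n_regions != n:
            raise FormatError("PCS matrices cover different region sets")
    avg = np.mean([p.values for p in pcs_list], axis=0)
    iu = np.triu_indices(n, 1)
    vals = avg[iu]
    hist, edges = np.histogram(vals, bins=np.arange(0, k + 1.25, 0.25))
    summary = {
        "median": float(np.median(vals)),
        "p5": float(np.percentile(vals, 5)),
        "p95": float(np.percentile(vals, 95)),
        "histogram": hist.tolist(),
        "histogram_edges": edges.tolist(),
        "n_subjects": len(pcs_list),
    }
    return avg, summary


def nodal_pcs(matrix: np.ndarray | PCSMatrix) -> np.ndarray:
    """Per-region mean PCS with all other regions (missing pairs excluded)."""
    if isinstance(matrix, PCSMatrix):
        values = matrix.values.astype(float)
        mask = matrix.missing_mask
    else:
        values = np.asarray(matrix, dtype=float)
        mask = np.zeros_like(values, dtype=bool)
    n = values.shape[0]
    out = np.empty(n)
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        sel = off[i] & ~mask[i]
        out[i] = values[i, sel].mean() if sel.any() else np.nan
    return out


def system_summary(
    matrix: np.ndarray | PCSMatrix, regions: RegionTable
) -> tuple[pd.DataFrame, dict]:
    """Block means over (system_i, system_j) pairs and modality-class scalars.

    Diagonal blocks average within-system region pairs only; returns the
    system-by-system block-mean table and scalars for within-unimodal,
    within-transmodal and cross-modal pairs.
    """
    values = matrix.values if isinstance(matrix, PCSMatrix) else np.asarray(matrix)
    values = values.astype(float)
    n = values.shape[0]
    if n != regions.n_regions:
        raise FormatError("matrix does not match region table")
    systems = sorted(set(regions.systems))
    sys_idx = {s: [i for i in range(n) if regions.systems[i] == s] for s in systems}
    block = pd.DataFrame(index=systems, columns=systems, dtype=float)
    for a in systems:
        for b in systems:
            ia, ib = sys_idx[a], sys_idx[b]
            if a == b:
                pairs = [
                    values[i, j] for x, i in enumerate(ia) for j in ia[x + 1:]
                ]
            else:
                pairs = [values[i, j] for i in ia for j in ib]
            block.loc[a, b] = float(np.mean(pairs)) if pairs else np.nan

    mod = regions.modality_class
    uni = [i for i in range(n) if mod[i] == "unimodal"]
    trans = [i for i in range(n) if mod[i] == "transmodal"]

    def _within(idx: list[int]) -> float:
        vals = [values[i, j] for x, i in enumerate(idx) for j in idx[x + 1:]]
        return float(np.mean(vals)) if vals else float("nan")

    cross = [values[i, j] for i in uni for j in trans]
    scalars = {
        "within_unimodal": _within(uni),
        "within_transmodal": _within(trans),
        "cross_modal": float(np.mean(cross)) if cross else float("nan"),
    }
    return block, scalars
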