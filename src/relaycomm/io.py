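"""Shared data containers, file I/O, configuration and seeded randomness.

Matrices are exchanged as delimited text (TSV) or HDF5; region tables as TSV
with columns ``name, x_mm, y_mm, z_mm, system, modality_class`` (optional
``hemisphere``).  Region indexing is 0-based internally; files always label
regions by name.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RegionTable",
    "TimeSeriesPanel",
    "AnalysisConfig",
    "FormatError",
    "read_connectome",
    "write_connectome",
    "read_region_table",
    "write_region_table",
    "read_timeseries",
    "write_timeseries",
    "rng_service",
    "spawn_seeds",
]

MODALITY_CLASSES = ("unimodal", "transmodal", "unassigned")


class FormatError(ValueError):
    """Raised when an input file violates the expected container format."""


@dataclass
class RegionTable:
    """Parcellation metadata: names, 3-D centroids (mm) and system labels.

    Every system label must map to exactly one modality class
    (unimodal / transmodal / unassigned).
    """

    names: list[str]
    centroids: np.ndarray  # (N, 3), mm
    systems: list[str]
    modality_class: list[str]
    hemisphere: list[str] | None = None  # "L"/"R", only needed for tracer builds

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        n = len(self.names)
        if self.centroids.shape != (n, 3):
            raise FormatError(
                f"centroids shape {self.centroids.shape} != ({n}, 3)"
            )
        if not np.all(np.isfinite(self.centroids)):
            raise FormatError("non-finite centroid coordinates")
        if len(set(self.names)) != n:
            raise FormatError("duplicate region names")
        if len(self.systems) != n or len(self.modality_class) != n:
            raise FormatError("systems/modality_class length mismatch")
        for m in self.modality_class:
            if m not in MODALITY_CLASSES:
                raise FormatError(f"unknown modality class {m!r}")
        sys2mod: dict[str, str] = {}
        for s, m in zip(self.systems, self.modality_class):
            if sys2mod.setdefault(s, m) != m:
                raise FormatError(
                    f"system {s!r} mapped to several modality classes"
                )
        if self.hemisphere is not None and len(self.hemisphere) != n:
            raise FormatError("hemisphere length mismatch")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown region name {name!r}") from None

    def pairwise_distances(self) -> np.ndarray:
        """Full matrix of Euclidean inter-centroid distances in mm."""
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionTable":
        required = {"name", "x_mm", "y_mm", "z_mm", "system", "modality_class"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"region table missing columns {sorted(missing)}")
        hemi = list(df["hemisphere"]) if "hemisphere" in df.columns else None
        return cls(
            names=[str(x) for x in df["name"]],
            centroids=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            systems=[str(x) for x in df["system"]],
            modality_class=[str(x) for x in df["modality_class"]],
            hemisphere=hemi,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "name": self.names,
                "x_mm": self.centroids[:, 0],
                "y_mm": self.centroids[:, 1],
                "z_mm": self.centroids[:, 2],
                "system": self.systems,
                "modality_class": self.modality_class,
            }
        )
        if self.hemisphere is not None:
            df["hemisphere"] = self.hemisphere
        return df


@dataclass
class TimeSeriesPanel:
    """A subject's T x N regional time-series matrix.

    ``zscored`` marks panels whose columns have zero mean and unit
    (population) standard deviation.
    """

    subject_id: str
    values: np.ndarray  # (T, N)
    sampling_interval: float = 1.0  # TR, seconds
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("time series must be a 2-D T x N matrix")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("time series contain non-finite values")
        if self.zscored:
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0)
            if np.any(np.abs(mu) > 1e-8) or np.any(np.abs(sd - 1.0) > 1e-8):
                raise FormatError("panel flagged zscored but columns are not")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class AnalysisConfig:
    """Defaults for the full relay-communication analysis.

    k=5 shortest paths, histogram bin width 0.5 on z-scored series,
    bidirectional data-processing-inequality mode, consensus threshold 1.0
    (edges present in all subjects), 3000 region-shuffle replicates, 100
    Gaussian simulations, 100 variogram permutation runs, fingerprint
    stratification threshold 1.3.
    """

    k: int = 5
    bin_width: float = 0.5
    dpi_mode: str = "bidirectional"
    consensus_threshold: float = 1.0
    null_reps_shuffle: int = 3000
    null_reps_gaussian: int = 100
    variogram_n_bins: int = 25
    variogram_n_runs: int = 100
    similarity_variant: str = "match_fraction"
    pcs_threshold: float = 1.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if not (0 < self.consensus_threshold <= 1):
            raise ValueError("consensus_threshold must lie in (0, 1]")
        if self.dpi_mode not in ("source", "bidirectional", "all_triplets"):
            raise ValueError(f"unknown dpi_mode {self.dpi_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# Matrix / panel I/O
# ---------------------------------------------------------------------------

def _check_square(m: np.ndarray, what: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{what} is not square: shape {m.shape}")
    bad = np.argwhere(~np.isfinite(m) & ~np.isinf(m))
    if bad.size:
        r, c = bad[0]
        raise FormatError(f"{what} has NaN entry at row {r}, col {c}")


def _first_asymmetric(m: np.ndarray) -> tuple[int, int] | None:
    d = m - m.T
    bad = np.argwhere(d != 0)
    if bad.size:
        r, c = bad[0]
        return int(r), int(c)
    return None


def read_connectome(
    path: str | Path,
    format: str = "delimited",
    allow_asymmetric: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an adjacency (and optional weight) matrix.

    Asymmetric input is rejected unless ``allow_asymmetric`` is set (only
    used for raw tracer-style material).
    """
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            adjacency = np.asarray(f["adjacency"])
            weights = np.asarray(f["weights"]) if "weights" in f else None
    elif format == "delimited":
        try:
            adjacency = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as e:
            raise FormatError(f"non-numeric cell in {path}: {e}") from e
        weights = None
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_square(adjacency, "adjacency")
    if np.any(adjacency < 0):
        r, c = np.argwhere(adjacency < 0)[0]
        raise FormatError(f"negative entry at row {r}, col {c}")
    if not allow_asymmetric:
        pos = _first_asymmetric(adjacency)
        if pos is not None:
            raise FormatError(f"asymmetric matrix at row {pos[0]}, col {pos[1]}")
        if weights is not None and _first_asymmetric(weights) is not None:
            raise FormatError("asymmetric weight matrix")
    if weights is not None:
        _check_square(weights, "weights")
    return adjacency, weights


def write_connectome(
    path: str | Path,
    adjacency: np.ndarray,
    weights: np.ndarray | None = None,
    format: str = "delimited",
) -> None:
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("adjacency", data=np.asarray(adjacency))
            if weights is not None:
                f.create_dataset("weights", data=np.asarray(weights))
    elif format == "delimited":
        fmt = "%d" if np.issubdtype(np.asarray(adjacency).dtype, np.integer) else "%.17g"
        np.savetxt(path, np.asarray(adjacency), delimiter="\t", fmt=fmt)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_region_table(path: str | Path) -> RegionTable:
    df = pd.read_csv(path, sep="\t")
    return RegionTable.from_dataframe(df)


def write_region_table(path: str | Path, regions: RegionTable) -> None:
    regions.to_dataframe().to_csv(path, sep="\t", index=False)


def read_timeseries(
    path: str | Path,
    regions: RegionTable | None = None,
    subject_id: str | None = None,
    sampling_interval: float = 1.0,
) -> TimeSeriesPanel:
    """Read a T x N delimited table, aligning columns to ``regions``.

    When a header of region names is present, columns are reordered to match
    the region table; otherwise positional order is used.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None)
    header: list[str] | None = None
    first = df.iloc[0]
    if any(not _is_number(v) for v in first):
        header = [str(v) for v in first]
        df = df.iloc[1:].reset_index(drop=True)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise FormatError(f"non-numeric cell in {path}: {e}") from e
    if regions is not None:
        if values.shape[1] != regions.n_regions:
            raise FormatError(
                f"column count {values.shape[1]} != {regions.n_regions} regions"
            )
        if header is not None:
            unknown = [h for h in header if h not in regions.names]
            if unknown:
                raise FormatError(f"unknown region name(s) in header: {unknown}")
            order = [header.index(name) for name in regions.names]
            values = values[:, order]
    return TimeSeriesPanel(
        subject_id=subject_id or path.stem,
        values=values,
        sampling_interval=sampling_interval,
    )


def write_timeseries(
    path: str | Path, panel: TimeSeriesPanel, regions: RegionTable | None = None
) -> None:
    with open(path, "w") as f:
        if regions is not None:
            f.write("\t".join(regions.names) + "\n")
        np.savetxt(f, panel.values, delimiter="\t", fmt="%.17g")


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# Randomness
# ---------------------------------------------------------------------------

def rng_service(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a reproducible random generator for the given seed.

    Passing an existing Generator returns it unchanged so that library code
    can accept either a seed or a live stream.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
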