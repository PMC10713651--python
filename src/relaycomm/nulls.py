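"""Null models for parallel communication scores.

Three nulls are implemented:

1. ``region_shuffle`` — permute the regional time series across network
   nodes, preserving both the structural connectivity and the multivariate
   statistics of the functional data (default 3000 replicates);
2. ``iid_gaussian`` — populate the nodes with iid standard normal noise of
   matched length, the absent-communication scenario (default 100
   simulations);
3. ``variogram_matched`` — permute each subject's MI matrix and restore its
   spatial autocorrelation with respect to inter-centroid distance by
   Gaussian-kernel smoothing plus a variogram regression, keeping the
   best-fitting of (default) 100 permutation runs.

Real group-average PCS matrices are screened against a null ensemble by
z-scoring (|z| > 1.96) and by empirical p-values with Benjamini-Hochberg
FDR control at 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .connectome import StructuralConnectome
from .infotheory import MIMatrix, mi_matrix, zscore
from .io import TimeSeriesPanel, rng_service
from .paths import PathEnsemble
from .relay import PCSMatrix, group_average_pcs, pcs

__all__ = [
    "NullEnsemble",
    "ScreeningResult",
    "null_region_shuffle",
    "null_gaussian",
    "variogram",
    "variogram_matched_null",
    "pcs_null_distribution",
    "screen_pcs",
]

logger = logging.getLogger(__name__)

DEFAULT_REPS = {"region_shuffle": 3000, "iid_gaussian": 100}
DEFAULT_VARIOGRAM_RUNS = 100


@dataclass
class NullEnsemble:
    """Stack of replicate group-average PCS matrices under one null model."""

    model: str
    replicates: np.ndarray  # (R, N, N)
    seed: int | None = None

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]


@dataclass
class ScreeningResult:
    z: np.ndarray
    p: np.ndarray
    mask_z: np.ndarray
    mask_fdr: np.ndarray
    z_threshold: float
    fdr_q: float
    degenerate: np.ndarray = field(default=None)  # pairs with zero null sd


def null_region_shuffle(
    panel: TimeSeriesPanel, rng=None
) -> tuple[TimeSeriesPanel, np.ndarray]:
    """Shuffle time series across regions; time courses stay intact.

    Returns the surrogate panel and the drawn permutation ``perm`` such that
    surrogate column ``i`` holds the original column ``perm[i]``.
    """
    rng = rng_service(rng)
    perm = rng.permutation(panel.n_regions)
    return (
        TimeSeriesPanel(
            subject_id=panel.subject_id,
            values=panel.values[:, perm],
            sampling_interval=panel.sampling_interval,
            zscored=panel.zscored,
        ),
        perm,
    )


def null_gaussian(
    n_regions: int, n_timepoints: int, rng=None, subject_id: str = "gaussian-null"
) -> TimeSeriesPanel:
    """iid N(0, 1) panel of matched size: the absent-communication scenario."""
    if n_regions < 1 or n_timepoints < 2:
        raise ValueError("dimensions must be positive (T >= 2)")
    rng = rng_service(rng)
    return TimeSeriesPanel(
        subject_id=subject_id,
        values=rng.standard_normal((n_timepoints, n_regions)),
    )


# ---------------------------------------------------------------------------
# Variogram-matched surrogate
# ---------------------------------------------------------------------------

def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


def variogram(
    values: np.ndarray,
    distances: np.ndarray,
    n_bins: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical semivariogram of a 1-D field over inter-regional distance.

    ``values`` and ``distances`` are matched vectors over region pairs (the
    vectorized upper triangle); the lag between two entries a, b is
    |d_a - d_b| and the semivariance at a lag bin is the mean of
    (v_a - v_b)^2 / 2 over entry pairs falling in it.  Bins holding fewer
    than 2 entry pairs are dropped with a warning.  Returns (lag centers,
    semivariance).
    """
    v = np.asarray(values, dtype=float).ravel()
    d = np.asarray(distances, dtype=float).ravel()
    if v.shape != d.shape:
        raise ValueError("values and distances must be matched vectors")
    order = np.argsort(d)
    ds, vs = d[order], v[order]
    max_lag = ds[-1] - ds[0]
    if max_lag <= 0:
        raise ValueError("degenerate distance index (single lag)")
    edges = np.linspace(0, max_lag, n_bins + 1)
    lag = np.abs(ds[:, None] - ds[None, :])
    gamma = 0.5 * (vs[:, None] - vs[None, :]) ** 2
    iu = np.triu_indices(len(vs), 1)
    lag_v, gamma_v = lag[iu], gamma[iu]
    which = np.clip(np.digitize(lag_v, edges) - 1, 0, n_bins - 1)
    centers, semis = [], []
    for b in range(n_bins):
        sel = which == b
        n_in = int(sel.sum())
        if n_in < 2:
            logger.warning("variogram bin %d dropped (%d entry pairs)", b, n_in)
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        semis.append(float(gamma_v[sel].mean()))
    return np.asarray(centers), np.asarray(semis)


def variogram_matched_null(
    mi: MIMatrix,
    distances: np.ndarray,
    n_runs: int = DEFAULT_VARIOGRAM_RUNS,
    rng=None,
    n_bins: int = 25,
) -> tuple[MIMatrix, np.ndarray, int]:
    """Spatial-autocorrelation-preserving surrogate of an MI matrix.

    Per run: permute the upper-triangle MI values, smooth them with a
    Gaussian kernel over pairwise lag (bandwidth drawn log-uniformly between
    the 5th and 95th percentile of observed lags), rescale by the OLS
    regression of the original variogram on the surrogate variogram
    (v' = beta * v + alpha), and record the SSE of that fit.  The minimum-SSE
    surrogate over all runs is returned, symmetrized, with the per-run SSE
    log.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = rng_service(rng)
    n = mi.n_regions
    iu = np.triu_indices(n, 1)
    v0 = mi.values[iu]
    d = np.asarray(distances)
    d = d[iu] if d.ndim == 2 else d.ravel()
    lag_c, gamma0 = variogram(v0, d, n_bins=n_bins)
    if np.allclose(gamma0.std(), 0):
        raise ValueError("degenerate regression: original variogram has zero variance")
    lags = np.abs(d[:, None] - d[None, :])
    lo, hi = np.percentile(lags[lags > 0], [5, 95])
    best_sse = np.inf
    best_vals: np.ndarray | None = None
    best_run = -1
    sse_log = np.empty(n_runs)
    for run in range(n_runs):
        perm = rng.permutation(v0.size)
        vp = v0[perm]
        bw = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        kern = np.exp(-0.5 * (lags / bw) ** 2)
        smooth = kern @ vp / kern.sum(axis=1)
        _, gamma_s = variogram(smooth, d, n_bins=n_bins)
        # OLS of original variogram on the surrogate variogram
        A = np.column_stack([gamma_s, np.ones_like(gamma_s)])
        (beta, alpha), *_ = np.linalg.lstsq(A, gamma0, rcond=None)
        fitted = beta * gamma_s + alpha
        sse = float(np.sum((gamma0 - fitted) ** 2))
        sse_log[run] = sse
        if sse < best_sse:
            best_sse = sse
            best_vals = beta * smooth + alpha
            best_run = run
    assert best_vals is not None
    out = np.full((n, n), np.nan)
    out[iu] = np.maximum(best_vals, 0.0)  # MI is nonnegative
    out[(iu[1], iu[0])] = out[iu]
    return (
        MIMatrix(
            values=out,
            subject_id=mi.subject_id,
            bin_width=mi.bin_width,
            n_timepoints=mi.n_timepoints,
        ),
        sse_log,
        best_run,
    )


# ---------------------------------------------------------------------------
# Null PCS ensembles and screening
# ---------------------------------------------------------------------------

def pcs_null_distribution(
    cohort: list[TimeSeriesPanel],
    connectome: StructuralConnectome,
    ensemble: PathEnsemble,
    model: str = "region_shuffle",
    reps: int | None = None,
    rng=None,
    bin_width: float = 0.5,
    dpi_mode: str = "bidirectional",
    n_variogram_runs: int = DEFAULT_VARIOGRAM_RUNS,
) -> NullEnsemble:
    """Replicate group-average PCS matrices under one of the three nulls."""
    if model not in ("region_shuffle", "iid_gaussian", "variogram_matched"):
        raise ValueError(f"unknown null model {model!r}")
    if reps is None:
        reps = DEFAULT_REPS.get(model, 100)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = rng_service(rng)
    n = connectome.n_regions
    dist = connectome.regions.pairwise_distances()
    real_mi = None
    if model == "variogram_matched":
        real_mi = [mi_matrix(zscore(p), bin_width) for p in cohort]
    replicates = np.empty((reps, n, n))
    for r in range(reps):
        pcs_subjects: list[PCSMatrix] = []
        for s, panel in enumerate(cohort):
            if model == "region_shuffle":
                surrogate, _ = null_region_shuffle(panel, rng)
                m = mi_matrix(zscore(surrogate), bin_width)
            elif model == "iid_gaussian":
                g = null_gaussian(n, panel.n_timepoints, rng, panel.subject_id)
                m = mi_matrix(zscore(g), bin_width)
            else:
                m, _, _ = variogram_matched_null(
                    real_mi[s], dist, n_runs=n_variogram_runs, rng=rng
                )
            pcs_subjects.append(pcs(ensemble, m, dpi_mode))
        replicates[r], _ = group_average_pcs(pcs_subjects)
    return NullEnsemble(model=model, replicates=replicates)


def screen_pcs(
    real_group_pcs: np.ndarray,
    null: NullEnsemble,
    z_threshold: float = 1.96,
    fdr_q: float = 0.05,
) -> ScreeningResult:
    """z-scores and add-one empirical p-values of real PCS against the null.

    p = (#{null >= real} + 1) / (R + 1); the FDR mask applies
    Benjamini-Hochberg over the upper-triangle p-values.
    """
    reps = null.replicates
    R = reps.shape[0]
    if R == 0:
        raise ValueError("empty null ensemble")
    real = np.asarray(real_group_pcs, dtype=float)
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (real - mean) / sd
    z[degenerate] = np.nan
    p = (np.sum(reps >= real[None], axis=0) + 1) / (R + 1)
    n = real.shape[0]
    iu = np.triu_indices(n, 1)
    mask_fdr = np.zeros_like(real, dtype=bool)
    rej, *_ = multipletests(p[iu], alpha=fdr_q, method="fdr_bh")[:1]
    mask_fdr[iu] = rej
    mask_fdr |= mask_fdr.T
    mask_z = np.zeros_like(real, dtype=bool)
    with np.errstate(invalid="ignore"):
        mask_z[~degenerate] = z[~degenerate] > z_threshold
    np.fill_diagonal(mask_z, False)
    np.fill_diagonal(mask_fdr, False)
    return ScreeningResult(
        z=z, p=p, mask_z=mask_z, mask_fdr=mask_fdr,
        z_threshold=z_threshold, fdr_q=fdr_q, degenerate=degenerate,
    )
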