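"""Split-half PCS fingerprinting: identifiability, success rate, nodal SNR.

Each subject's time series is split into two halves (test / retest); PCS
matrices computed per half are compared across subjects with a
match-fraction similarity — the fraction of region pairs carrying exactly
the same integer score.  A subject is correctly identified when its
test-retest self-similarity is the strict maximum of its row of the
identifiability matrix; the success rate (SR) is the percentage of subjects
identified.  Region pairs can be stratified by group-average PCS (low vs
high, threshold 1.3) to localize where individuality lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .infotheory import zscore
from .io import FormatError, TimeSeriesPanel
from .relay import PCSMatrix

__all__ = [
    "IdentifiabilityMatrix",
    "FingerprintReport",
    "split_half",
    "pcs_similarity",
    "identifiability",
    "success_rate",
    "stratified_success_rate",
    "nodal_snr",
    "snr_pcs_association",
    "DEFAULT_PCS_THRESHOLD",
]

SIMILARITY_VARIANTS = ("match_fraction", "nonzero_jaccard")
DEFAULT_PCS_THRESHOLD = 1.3


@dataclass
class IdentifiabilityMatrix:
    """S x S test/retest similarity matrix (rows = test subjects)."""

    values: np.ndarray
    subject_ids: list[str]
    variant: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError("identifiability matrix must be square")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise FormatError("similarities must lie in [0, 1]")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def iself(self) -> np.ndarray:
        return np.diag(self.values).copy()

    def iothers(self) -> np.ndarray:
        off = ~np.eye(self.n_subjects, dtype=bool)
        return np.array(
            [self.values[s, off[s]].mean() for s in range(self.n_subjects)]
        )


@dataclass
class FingerprintReport:
    iself: np.ndarray
    iothers: np.ndarray
    success_rate: float  # percent
    stratified: dict = field(default_factory=dict)


def split_half(panel: TimeSeriesPanel) -> tuple[TimeSeriesPanel, TimeSeriesPanel]:
    """First and last floor(T/2) samples as test / retest, re-z-scored.

    For odd T the middle sample belongs to neither half.
    """
    t = panel.n_timepoints
    if t < 4:
        raise ValueError("need at least 4 time points to split")
    h = t // 2
    mk = lambda v: zscore(
        TimeSeriesPanel(panel.subject_id, v, panel.sampling_interval)
    )
    return mk(panel.values[:h]), mk(panel.values[t - h:])


def pcs_similarity(
    a: PCSMatrix,
    b: PCSMatrix,
    variant: str = "match_fraction",
    pair_mask: np.ndarray | None = None,
) -> float:
    """Fraction of region pairs with exactly the same integer PCS.

    ``match_fraction`` scores agreement over all (masked) upper-triangle
    pairs; ``nonzero_jaccard`` restricts both the matches and the
    denominator to pairs where at least one matrix is nonzero.
    """
    if variant not in SIMILARITY_VARIANTS:
        raise ValueError(f"unknown similarity variant {variant!r}")
    if a.n_regions != b.n_regions:
        raise FormatError("PCS matrices cover different region sets")
    n = a.n_regions
    iu = np.triu_indices(n, 1)
    va, vb = a.values[iu], b.values[iu]
    if pair_mask is not None:
        sel = np.asarray(pair_mask, dtype=bool)[iu]
        if not sel.any():
            raise ValueError("empty pair mask")
        va, vb = va[sel], vb[sel]
    if variant == "match_fraction":
        return float(np.mean(va == vb))
    union = (va != 0) | (vb != 0)
    if not union.any():
        return 1.0  # both all-zero patterns are identical
    return float(np.sum((va == vb) & union) / union.sum())


def identifiability(
    test_pcs: list[PCSMatrix],
    retest_pcs: list[PCSMatrix],
    variant: str = "match_fraction",
    pair_mask: np.ndarray | None = None,
) -> IdentifiabilityMatrix:
    """Similarity of every test subject against every retest subject."""
    if len(test_pcs) != len(retest_pcs):
        raise ValueError("test and retest subject lists differ in length")
    ids_t = [p.subject_id for p in test_pcs]
    ids_r = [p.subject_id for p in retest_pcs]
    if ids_t != ids_r:
        raise ValueError("test/retest subject order mismatch")
    s = len(test_pcs)
    values = np.empty((s, s))
    for i in range(s):
        for j in range(s):
            values[i, j] = pcs_similarity(
                test_pcs[i], retest_pcs[j], variant, pair_mask
            )
    return IdentifiabilityMatrix(values=values, subject_ids=ids_t, variant=variant)


def success_rate(idm: IdentifiabilityMatrix) -> float:
    """Percent of test subjects whose self-similarity is the strict row max.

    Ties count as misidentification.
    """
    v = idm.values
    s = idm.n_subjects
    correct = 0
    for i in range(s):
        row = v[i]
        if np.sum(row >= row[i]) == 1:  # diagonal strictly dominates
            correct += 1
    return 100.0 * correct / s


def fingerprint_report(
    test_pcs: list[PCSMatrix],
    retest_pcs: list[PCSMatrix],
    variant: str = "match_fraction",
    group_avg_pcs: np.ndarray | None = None,
    pcs_threshold: float = DEFAULT_PCS_THRESHOLD,
) -> FingerprintReport:
    idm = identifiability(test_pcs, retest_pcs, variant)
    stratified: dict = {}
    if group_avg_pcs is not None:
        sr_low, sr_high = stratified_success_rate(
            test_pcs, retest_pcs, group_avg_pcs, pcs_threshold, variant
        )
        stratified = {
            "sr_low": sr_low, "sr_high": sr_high, "threshold": pcs_threshold
        }
    return FingerprintReport(
        iself=idm.iself(),
        iothers=idm.iothers(),
        success_rate=success_rate(idm),
        stratified=stratified,
    )


def stratified_success_rate(
    test_pcs: list[PCSMatrix],
    retest_pcs: list[PCSMatrix],
    group_avg_pcs: np.ndarray,
    threshold: float = DEFAULT_PCS_THRESHOLD,
    variant: str = "match_fraction",
) -> tuple[float, float]:
    """SR over low-PCS (avg <= threshold) and high-PCS (avg > threshold) pairs."""
    avg = np.asarray(group_avg_pcs, dtype=float)
    low = avg <= threshold
    high = avg > threshold
    np.fill_diagonal(low, False)
    np.fill_diagonal(high, False)
    iu = np.triu_indices(avg.shape[0], 1)
    if not low[iu].any():
        raise ValueError("low-PCS stratum is empty at this threshold")
    if not high[iu].any():
        raise ValueError("high-PCS stratum is empty at this threshold")
    sr_low = success_rate(identifiability(test_pcs, retest_pcs, variant, low))
    sr_high = success_rate(identifiability(test_pcs, retest_pcs, variant, high))
    return sr_low, sr_high


def nodal_snr(panel: TimeSeriesPanel) -> np.ndarray:
    """Low- over high-frequency power ratio per region.

    The periodogram is split at half the Nyquist frequency; the boundary
    frequency counts toward the high band.  Slow, hemodynamics-like signals
    yield ratios above 1, broadband noise close to 1.
    """
    if panel.n_timepoints < 8:
        raise ValueError("need at least 8 time points for the periodogram")
    fs = 1.0 / panel.sampling_interval
    freqs, pxx = sps.periodogram(panel.values, fs=fs, axis=0)
    cutoff = fs / 4.0  # half of Nyquist
    low = (freqs > 0) & (freqs < cutoff)
    high = freqs >= cutoff
    high_power = pxx[high].sum(axis=0)
    if np.any(high_power == 0):
        raise ValueError("zero high-band power; SNR ratio undefined")
    return pxx[low].sum(axis=0) / high_power


def snr_pcs_association(
    snr_per_subject: list[np.ndarray],
    nodal_pcs_per_subject: list[np.ndarray],
) -> dict:
    """Per-subject Spearman correlation of nodal SNR with nodal PCS."""
    if len(snr_per_subject) != len(nodal_pcs_per_subject):
        raise ValueError("subject list mismatch")
    rhos: list[float] = []
    flagged: list[int] = []
    for s, (snr, npcs) in enumerate(zip(snr_per_subject, nodal_pcs_per_subject)):
        snr = np.asarray(snr, dtype=float)
        npcs = np.asarray(npcs, dtype=float)
        if snr.shape != npcs.shape:
            raise ValueError(f"region-set mismatch for subject {s}")
        if np.all(npcs == npcs[0]) or np.all(snr == snr[0]):
            flagged.append(s)
            rhos.append(np.nan)
            continue
        rho, _ = stats.spearmanr(snr, npcs)
        rhos.append(float(rho))
    arr = np.asarray(rhos)
    valid = arr[~np.isnan(arr)]
    return {
        "rho": arr,
        "flagged_constant": flagged,
        "mean": float(valid.mean()) if valid.size else float("nan"),
        "sd": float(valid.std()) if valid.size else float("nan"),
    }
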