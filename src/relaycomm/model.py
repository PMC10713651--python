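"""Model/Results interface over the relay-communication pipeline.

`RelayCommunicationModel` bundles a structural connectome with a cohort of
regional time-series panels; `fit()` enumerates the k-shortest path
ensemble, estimates per-subject MI matrices, screens every multi-step path
with the data processing inequality, and returns a
`RelayCommunicationResults` carrying per-subject and group-average parallel
communication scores, communication densities, nodal and system summaries.
Null screening, fingerprinting, and plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fingerprint as fp
from . import nulls as nulls_mod
from .connectome import StructuralConnectome
from .infotheory import DEFAULT_BIN_WIDTH, MIMatrix, mi_matrix, zscore
from .io import TimeSeriesPanel, rng_service
from .paths import DEFAULT_K, PathEnsemble, edge_coverage, hop_statistics
from .relay import (
    CommunicationDensity,
    PCSMatrix,
    communication_density,
    group_average_pcs,
    nodal_pcs,
    pcs,
    system_summary,
)

__all__ = ["RelayCommunicationModel", "RelayCommunicationResults"]


class RelayCommunicationModel:
    """Relay-communication analysis of a cohort on a structural connectome.

    Parameters
    ----------
    connectome : StructuralConnectome
        Euclidean-distance-weighted structural graph.
    panels : list of TimeSeriesPanel
        One regional time-series panel per subject.
    k : int
        Number of shortest paths per region pair (default 5).
    bin_width : float
        Histogram bin width on z-scored series (default 0.5).
    dpi_mode : str
        Inequality set: "source", "bidirectional" (default) or
        "all_triplets".
    """

    def __init__(
        self,
        connectome: StructuralConnectome,
        panels: list[TimeSeriesPanel],
        k: int = DEFAULT_K,
        bin_width: float = DEFAULT_BIN_WIDTH,
        dpi_mode: str = "bidirectional",
    ) -> None:
        if not panels:
            raise ValueError("need at least one subject panel")
        for p in panels:
            if p.n_regions != connectome.n_regions:
                raise ValueError(
                    f"panel {p.subject_id!r} has {p.n_regions} regions, "
                    f"connectome has {connectome.n_regions}"
                )
        self.connectome = connectome
        self.panels = panels
        self.k = k
        self.bin_width = bin_width
        self.dpi_mode = dpi_mode

    def fit(self, ensemble: PathEnsemble | None = None) -> "RelayCommunicationResults":
        """Run paths -> MI -> DPI -> PCS for every subject."""
        if ensemble is None:
            ensemble = PathEnsemble.build(self.connectome, self.k)
        mi_list = [mi_matrix(zscore(p), self.bin_width) for p in self.panels]
        pcs_list = [pcs(ensemble, m, self.dpi_mode) for m in mi_list]
        densities = [
            communication_density(ensemble, m, self.dpi_mode) for m in mi_list
        ]
        return RelayCommunicationResults(
            model=self,
            ensemble=ensemble,
            mi_matrices=mi_list,
            pcs_matrices=pcs_list,
            densities=densities,
        )


@dataclass
class RelayCommunicationResults:
    """Fitted quantities of a relay-communication analysis."""

    model: RelayCommunicationModel
    ensemble: PathEnsemble
    mi_matrices: list[MIMatrix]
    pcs_matrices: list[PCSMatrix]
    densities: list[CommunicationDensity]
    _group: tuple[np.ndarray, dict] | None = field(default=None, repr=False)

    @property
    def group_average(self) -> np.ndarray:
        if self._group is None:
            self._group = group_average_pcs(self.pcs_matrices)
        return self._group[0]

    @property
    def group_summary(self) -> dict:
        if self._group is None:
            self._group = group_average_pcs(self.pcs_matrices)
        return self._group[1]

    def nodal(self) -> np.ndarray:
        return nodal_pcs(self.group_average)

    def systems(self):
        return system_summary(self.group_average, self.model.connectome.regions)

    def hop_stats(self, multi_step_only: bool = True) -> dict:
        return hop_statistics(self.ensemble, multi_step_only=multi_step_only)

    def edge_coverage(self, multi_step_only: bool = True) -> float:
        return edge_coverage(self.ensemble, self.model.connectome, multi_step_only)

    def screen(
        self,
        null_model: str = "region_shuffle",
        reps: int | None = None,
        rng=None,
        z_threshold: float = 1.96,
        fdr_q: float = 0.05,
    ):
        """Screen the group-average PCS against a null ensemble."""
        null = nulls_mod.pcs_null_distribution(
            self.model.panels,
            self.model.connectome,
            self.ensemble,
            model=null_model,
            reps=reps,
            rng=rng_service(rng),
            bin_width=self.model.bin_width,
            dpi_mode=self.model.dpi_mode,
        )
        return nulls_mod.screen_pcs(self.group_average, null, z_threshold, fdr_q)

    def fingerprint(
        self,
        variant: str = "match_fraction",
        pcs_threshold: float = fp.DEFAULT_PCS_THRESHOLD,
        stratify: bool = True,
    ) -> fp.FingerprintReport:
        """Split-half PCS fingerprinting of the cohort."""
        halves = [fp.split_half(p) for p in self.model.panels]
        test = [
            pcs(self.ensemble, mi_matrix(a, self.model.bin_width), self.model.dpi_mode)
            for a, _ in halves
        ]
        retest = [
            pcs(self.ensemble, mi_matrix(b, self.model.bin_width), self.model.dpi_mode)
            for _, b in halves
        ]
        return fp.fingerprint_report(
            test,
            retest,
            variant=variant,
            group_avg_pcs=self.group_average if stratify else None,
            pcs_threshold=pcs_threshold,
        )

    def plot_group_average(self, ax=None):
        """Heatmap of the group-average PCS matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.group_average, cmap="YlOrBr", vmin=0, vmax=self.model.k)
        ax.set_xlabel("region")
        ax.set_ylabel("region")
        ax.figure.colorbar(im, ax=ax, label="parallel communication score")
        return ax

    def summary(self) -> str:
        """Plain-text summary table of the fitted analysis."""
        s = self.group_summary
        dens = np.array([d.overall for d in self.densities])
        lines = [
            "Relay communication analysis",
            "=" * 60,
            f"regions:                {self.model.connectome.n_regions}",
            f"subjects:               {len(self.model.panels)}",
            f"k (paths per pair):     {self.model.k}",
            f"MI bin width:           {self.model.bin_width}",
            f"DPI mode:               {self.model.dpi_mode}",
            f"connectome density:     {self.model.connectome.density():.3f}",
            "-" * 60,
            f"communication density:  {dens.mean():.1f} +/- {dens.std():.1f} % "
            "(mean +/- sd across subjects)",
            f"group PCS median [5%, 95%]: {s['median']:.2f} "
            f"[{s['p5']:.2f}, {s['p95']:.2f}]",
            f"edge coverage (multi-step): {100 * self.edge_coverage():.1f} %",
        ]
        hop = self.hop_stats()
        lines.append(
            f"hops per multi-step path:   {hop['mean']:.2f} ({hop['sd']:.2f})"
        )
        per_rank = {r: f"{v:.1f}" for r, v in self.densities[0].per_rank.items()}
        lines.append(f"per-rank density, subject 1 (%): {per_rank}")
        lines.append("=" * 60)
        return "\n".join(lines)
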