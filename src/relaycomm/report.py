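"""Group comparisons, nodal regression, and end-to-end pipeline runs.

The bespoke quantities (PCS, DPI labels, nulls, fingerprints) come from the
other modules; the comparisons here delegate to standard statistical
routines (scipy.stats tests, statsmodels OLS).
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .io import AnalysisConfig, rng_service, spawn_seeds
from .model import RelayCommunicationModel
from .synthetic import SyntheticSpec, synth_cohort

__all__ = [
    "GroupComparisonReport",
    "compare_groups",
    "pcs_regression",
    "run_pipeline",
]


@dataclass
class GroupComparisonReport:
    comparisons: pd.DataFrame
    regression: pd.DataFrame | None = None
    r_squared: float | None = None


def compare_groups(
    groups: dict[str, np.ndarray], test: str = "ks"
) -> GroupComparisonReport:
    """Pairwise (KS, Mann-Whitney) or omnibus (Kruskal-Wallis) comparison of
    per-group PCS value vectors."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    names = list(groups)
    if test == "kruskal":
        stat, p = stats.kruskal(*[groups[g] for g in names])
        rows.append(
            {
                "comparison": " vs ".join(names),
                "test": "kruskal",
                "statistic": float(stat),
                "p": float(p),
                "n": tuple(len(groups[g]) for g in names),
            }
        )
    elif test in ("ks", "mannwhitney"):
        for a_idx in range(len(names)):
            for b_idx in range(a_idx + 1, len(names)):
                a, b = names[a_idx], names[b_idx]
                if test == "ks":
                    res = stats.ks_2samp(groups[a], groups[b])
                else:
                    res = stats.mannwhitneyu(
                        groups[a], groups[b], alternative="two-sided"
                    )
                rows.append(
                    {
                        "comparison": f"{a} vs {b}",
                        "test": test,
                        "statistic": float(res.statistic),
                        "p": float(res.pvalue),
                        "n": (len(groups[a]), len(groups[b])),
                    }
                )
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparisonReport(comparisons=pd.DataFrame(rows))


def pcs_regression(
    nodal_pcs: np.ndarray,
    species: list[str],
    degree: np.ndarray,
    mean_connection_length: np.ndarray,
    functional_strength: np.ndarray,
    bonferroni: bool = True,
) -> GroupComparisonReport:
    """OLS of nodal PCS on species (categorical) plus three nodal
    connectivity measures, with Bonferroni correction over predictors."""
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "pcs": np.asarray(nodal_pcs, dtype=float),
            "species": species,
            "degree": np.asarray(degree, dtype=float),
            "length": np.asarray(mean_connection_length, dtype=float),
            "fstrength": np.asarray(functional_strength, dtype=float),
        }
    )
    fit = smf.ols("pcs ~ C(species) + degree + length + fstrength", data=df).fit()
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "p": fit.pvalues,
        }
    )
    if bonferroni:
        m = len(table) - 1  # predictors, intercept excluded
        table["p_bonferroni"] = np.minimum(
            table["p"] * max(m, 1), 1.0
        )
        table.loc["Intercept", "p_bonferroni"] = np.nan
    return GroupComparisonReport(
        comparisons=pd.DataFrame(), regression=table, r_squared=float(fit.rsquared)
    )


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    synthetic_spec: SyntheticSpec | None = None,
    null_reps: int | None = None,
) -> dict:
    """End-to-end run on a synthetic cohort; writes tables and a manifest.

    Stages: connectome -> paths -> MI -> PCS -> region-shuffle null screening
    -> split-half fingerprinting.  Each output is stamped with the seed and
    parameters; the returned manifest carries content hashes so reruns with
    the same seed can be verified bitwise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic_spec or SyntheticSpec(seed=config.rng_seed)
    seeds = spawn_seeds(config.rng_seed, 3)
    conn, panels, truth = synth_cohort(spec, rng_service(seeds[0]))

    model = RelayCommunicationModel(
        conn, panels, k=config.k, bin_width=config.bin_width, dpi_mode=config.dpi_mode
    )
    res = model.fit()

    np.savetxt(out / "group_average_pcs.tsv", res.group_average, delimiter="\t")
    dens = pd.DataFrame(
        [
            {"subject": d.subject_id, "overall_pct": d.overall, **{
                f"rank_{r}_pct": v for r, v in d.per_rank.items()
            }}
            for d in res.densities
        ]
    )
    dens.to_csv(out / "communication_density.tsv", sep="\t", index=False)

    reps = null_reps if null_reps is not None else config.null_reps_shuffle
    screening = res.screen("region_shuffle", reps=reps, rng=rng_service(seeds[1]))
    np.savetxt(out / "screening_z.tsv", screening.z, delimiter="\t")

    report = res.fingerprint(variant=config.similarity_variant,
                             pcs_threshold=config.pcs_threshold)

    manifest = {
        "version": __version__,
        "seed": config.rng_seed,
        "parameters": {
            "k": config.k,
            "bin_width": config.bin_width,
            "dpi_mode": config.dpi_mode,
            "null_reps": reps,
        },
        "n_regions": conn.n_regions,
        "n_subjects": len(panels),
        "group_pcs_median": res.group_summary["median"],
        "success_rate_pct": report.success_rate,
        "stratified": report.stratified,
        "hashes": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
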