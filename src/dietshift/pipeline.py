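"""End-to-end analysis: count table in, seasonality indicators and
allometric fits out. Thin orchestration over the other modules; the CLI
and example scripts call these functions."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, community, multivariate
from .allometry import SubsampleDesign
from .diet_table import DietTable, FunctionalAnnotation


def analyze(
    table: DietTable,
    masses_kg: dict,
    design: SubsampleDesign | None = None,
    annot: FunctionalAnnotation | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    run_permanova: bool = True,
) -> dict:
    """Run the seasonal diet-switching analysis on a prepared table.

    Returns a dict with the indicator table, the turnover regression, one
    ANCOVA per remaining indicator, richness log-response ratios and (by
    default) the perMANOVA of Bray-Curtis against species x season.
    """
    design = design or SubsampleDesign(seed=seed)
    focal = table.season_filter(design.seasons)
    indicators = allometry.run_indicators(table, design)

    results: dict = {"indicators": indicators}
    results["turnover_fit"] = allometry.turnover_allometry(indicators, masses_kg)
    results["ancova"] = {
        resp: allometry.ancova_type3(indicators, resp, masses_kg)
        for resp in allometry.RESPONSES
    }

    means = indicators.replicate_means()["herd_richness"].unstack("season")
    results["richness_lrr"] = allometry.log_response_ratio(
        means["summer"], means["winter"]
    )

    if run_permanova:
        D = community.bray_curtis(focal.counts.values, labels=focal.sample_ids)
        results["permanova"] = multivariate.permanova(
            D,
            focal.sample_meta[["species", "season"]],
            n_perm=n_perm,
            seed=seed,
        )
        disp = multivariate.dispersion(D, focal.sample_meta["season"].values)
        results["dispersion_season"] = disp
        results["dispersion_season_p"] = multivariate.permutest(
            disp, n_perm=n_perm, seed=seed
        )
    return results


def fit_summary(results: dict) -> dict:
    """JSON-serializable summary of the fitted models."""
    turn = results["turnover_fit"]
    out = {
        "turnover": {
            "slope": turn.slope,
            "intercept": turn.intercept,
            "r2": turn.r2,
            "p": turn.p,
        },
        "ancova": {},
        "richness_lrr": {k: float(v) for k, v in results["richness_lrr"].items()},
    }
    for resp, fit in results["ancova"].items():
        out["ancova"][resp] = {
            "final_model": fit.final_model,
            "slope": None if np.isnan(fit.slope) else fit.slope,
            "r2": None if np.isnan(fit.r2) else fit.r2,
            "chain": [
                {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v) if isinstance(v, (int, float, np.floating)) else v)
                 for k, v in step.items()}
                for step in fit.chain
            ],
        }
    if "permanova" in results:
        out["permanova"] = json.loads(
            results["permanova"].table.reset_index().to_json(orient="records")
        )
        out["dispersion_season_p"] = results["dispersion_season_p"]
    return out


def write_outputs(results: dict, out_dir) -> None:
    """Write indicators.tsv, fits.json and lrr.tsv to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["indicators"].to_tsv(out / "indicators.tsv")
    results["richness_lrr"].rename_axis("species").reset_index().to_csv(
        out / "lrr.tsv", sep="\t", index=False
    )
    with open(out / "fits.json", "w") as fh:
        json.dump(fit_summary(results), fh, indent=2, sort_keys=True)
    means = results["indicators"].replicate_means().reset_index()
    means.to_csv(out / "indicator_means.tsv", sep="\t", index=False)
    turn = results["indicators"].turnover_means().rename("turnover_BC")
    turn.reset_index().to_csv(out / "turnover_means.tsv", sep="\t", index=False)
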