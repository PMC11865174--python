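"""End-to-end pipeline: simulate -> derive -> screen -> model -> ordinate.

Builds the long-format trait table from the raw cohort tables through the
derivation modules, screens it for extreme outliers within species x
treatment cells, fits the per-trait models (mixed models for repeated
traits, linear models for once-measured traits), runs Tukey date
comparisons where the date effect holds, and finishes with the trait PCA.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import derive_allometry
from .config import CohortConfig, load_paper_defaults
from .gas_exchange import derive_gas_exchange
from .hydraulics import derive_ksth_table
from .pv_analysis import fit_pv_table
from .stats_pipeline import (
    ModelResult,
    ModelSpec,
    fit_lm_oneshot,
    fit_lmm_backward,
    run_pca,
    screen_trait_table,
    tukey_dates,
)
from .synthetic_cohort import CohortData, generate_cohort

__all__ = ["build_trait_table", "run_pipeline", "PipelineResult"]

#: repeated traits modelled with treatment x species x date mixed models
REPEATED_TRAITS = (
    "psi_pd",
    "psi_md",
    "a_area",
    "g_s",
    "c_i",
    "etr",
    "iwue",
    "lma",
    "a_mass",
    "c_conc",
    "n_conc",
    "d13c",
    "d15n",
)
#: pressure-volume traits, one curve per plant per late-summer campaign
PV_TRAITS = ("rwc_tlp", "r_sym", "r_apo", "pi_100", "pi_0", "dw_tw", "eps_max")
#: once-measured, two-way (treatment x species) traits
TWOWAY_TRAITS = ("sa_la", "sksth_2017", "sksth_2018", "sksth_2019")
#: once-measured, one-way traits of the root-excavated species
ONEWAY_TRAITS = (
    "root_shoot",
    "root_depth",
    "rb",
    "sb",
    "rksth_2017",
    "rksth_2018",
    "rksth_2019",
)


def build_trait_table(cohort: CohortData) -> pd.DataFrame:
    """Derive every response trait and stack them in long format.

    One row per plant x date x trait for repeated traits; once-measured
    traits carry a null date.
    """
    rows: list[pd.DataFrame] = []

    def add(df: pd.DataFrame, trait: str, value_col: str, date: bool = True) -> None:
        cols = {"plant_id": df["plant_id"], "species": df["species"],
                "treatment": df["treatment"],
                "date": df["date"] if date else pd.NA,
                "trait": trait, "value": df[value_col]}
        rows.append(pd.DataFrame(cols))

    wp = cohort.water_potential
    add(wp, "psi_pd", "psi_pd_MPa")
    add(wp, "psi_md", "psi_md_MPa")

    gasex = derive_gas_exchange(cohort.gas_exchange)
    for trait, col in [
        ("a_area", "A_area"), ("g_s", "g_s"), ("c_i", "C_i"),
        ("etr", "etr"), ("iwue", "iwue"), ("lma", "lma"), ("a_mass", "a_mass"),
    ]:
        add(gasex, trait, col)

    bio = cohort.biochem
    for trait, col in [
        ("c_conc", "C_mg_g"), ("n_conc", "N_mg_g"),
        ("d13c", "d13C_permil"), ("d15n", "d15N_permil"),
    ]:
        add(bio, trait, col)

    pv = fit_pv_table(cohort.pv_curves)
    pv_ok = pv[pv["error"] == ""]
    for trait, col in [
        ("pi_100", "pi_100"), ("pi_0", "pi_0"), ("rwc_tlp", "rwc_tlp"),
        ("r_apo", "r_a"), ("r_sym", "r_s"), ("dw_tw", "dw_tw"),
        ("eps_max", "eps_max"),
    ]:
        add(pv_ok, trait, col)

    allo = derive_allometry(cohort.biomass)
    add(allo, "sa_la", "sa_la", date=False)
    add(allo, "leaf_area", "leaf_area_cm2", date=False)
    add(allo, "sb", "shoot_dry_mass_g", date=False)
    fagus = allo[np.isfinite(allo["root_dry_mass_g"])]
    if len(fagus):
        add(fagus, "root_shoot", "r_s", date=False)
        add(fagus, "rb", "root_dry_mass_g", date=False)
        add(fagus, "root_depth", "root_depth_cm", date=False)

    k = derive_ksth_table(cohort.vessels)
    for organ, prefix in [("STEM", "sksth"), ("ROOT", "rksth")]:
        sub = k[k["organ"] == organ]
        for year, grp in sub.groupby("ring_year"):
            add(grp.assign(date=pd.NA), f"{prefix}_{year}", "k_sth", date=False)

    table = pd.concat(rows, ignore_index=True)
    table["value"] = table["value"].astype(float)
    return table


@dataclass
class PipelineResult:
    cohort: CohortData
    trait_table: pd.DataFrame
    outlier_report: pd.DataFrame
    models: dict[str, ModelResult]
    tukey: dict[str, pd.DataFrame]
    tukey_letters: dict[str, dict[str, str]]
    pca: object = None
    errors: dict[str, str] = field(default_factory=dict)

    def models_summary(self) -> dict:
        out = {}
        for trait, m in self.models.items():
            out[trait] = {
                "retained": m.retained,
                "pvalues": m.pvalues,
                "path": m.path,
                "transform": m.transform,
                "random_intercept": m.random_intercept,
                "diagnostics": m.diagnostics,
            }
        return out

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.trait_table.to_csv(os.path.join(outdir, "traits.csv"), index=False)
        self.outlier_report.to_csv(os.path.join(outdir, "outliers.csv"), index=False)
        with open(os.path.join(outdir, "models.json"), "w") as fh:
            json.dump(self.models_summary(), fh, indent=2, default=float)
        if self.tukey:
            pd.concat(
                [t.assign(trait=k) for k, t in self.tukey.items()], ignore_index=True
            ).to_csv(os.path.join(outdir, "tukey.csv"), index=False)
        if self.pca is not None:
            self.pca.loadings.to_csv(os.path.join(outdir, "pca_loadings.csv"))
            self.pca.scores.to_csv(os.path.join(outdir, "pca_scores.csv"), index=False)
            np.savetxt(
                os.path.join(outdir, "pca_variance_fractions.txt"),
                self.pca.explained_variance_ratio,
            )


def run_pipeline(
    config: CohortConfig | None = None,
    seed: int = 42,
    fit_models: bool = True,
    with_pca: bool = True,
) -> PipelineResult:
    """Run the full synthetic-cohort analysis chain."""
    config = config or load_paper_defaults()
    cohort = generate_cohort(config, seed)
    table = build_trait_table(cohort)
    clean, report = screen_trait_table(table)

    models: dict[str, ModelResult] = {}
    tukey: dict[str, pd.DataFrame] = {}
    letters: dict[str, dict[str, str]] = {}
    errors: dict[str, str] = {}
    multi_species = len(config.species) > 1
    if fit_models:
        plans: list[tuple[str, ModelSpec]] = []
        for t in REPEATED_TRAITS + PV_TRAITS:
            factors = ("T", "S", "D") if multi_species else ("T", "D")
            plans.append((t, ModelSpec(response=t, factors=factors)))
        for t in TWOWAY_TRAITS:
            factors = ("T", "S") if multi_species else ("T",)
            plans.append(
                (t, ModelSpec(response=t, factors=factors, random_intercept=False))
            )
        for t in ONEWAY_TRAITS:
            plans.append(
                (t, ModelSpec(response=t, factors=("T",), random_intercept=False))
            )
        for trait, spec in plans:
            sub = clean[clean["trait"] == trait]
            if trait in ONEWAY_TRAITS and multi_species:
                # root-linked and harvest contrasts follow the excavated species
                sub = sub[sub["species"] == "FAGUS"]
            if not len(sub):
                continue
            try:
                if "D" in spec.factors:
                    models[trait] = fit_lmm_backward(sub, spec)
                    if models[trait].term_significant("D"):
                        tukey[trait], letters[trait] = tukey_dates(models[trait], sub)
                else:
                    models[trait] = fit_lm_oneshot(sub, spec)
            except (ValueError, np.linalg.LinAlgError) as exc:
                errors[trait] = str(exc)

    pca = None
    if with_pca:
        pca = run_pca(clean)

    return PipelineResult(
        cohort=cohort,
        trait_table=clean,
        outlier_report=report,
        models=models,
        tukey=tukey,
        tukey_letters=letters,
        pca=pca,
        errors=errors,
    )
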