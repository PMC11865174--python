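"""Synthetic study-cohort generator.

Emulates the raw measurement tables of a two-species browsing-legacy field
study: plant metadata, repeated water-potential / gas-exchange / biochemical
records, pressure-volume dehydration sequences, vessel-diameter sets and a
final biomass harvest.  Raw observables are generated *from* latent trait
values through the same identities the derivation modules invert, so a
noise-free cohort round-trips exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import (
    CohortConfig,
    ConfigError,
    TraitSpec,
    campaign_year,
    is_late_summer,
    load_paper_defaults,
)

__all__ = [
    "CohortData",
    "generate_cohort",
    "generate_pv_sequence",
    "generate_vessel_set",
    "load_paper_defaults",
]


class PVParameterError(ValueError):
    """Raised when pressure-volume forward-model parameters are unphysical."""


@dataclass
class CohortData:
    """Container for all generated measurement tables (tidy DataFrames)."""

    plants: pd.DataFrame
    water_potential: pd.DataFrame
    gas_exchange: pd.DataFrame
    biochem: pd.DataFrame
    pv_curves: pd.DataFrame
    pv_latents: pd.DataFrame
    vessels: pd.DataFrame
    biomass: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    _TABLES = (
        "plants",
        "water_potential",
        "gas_exchange",
        "biochem",
        "pv_curves",
        "vessels",
        "biomass",
    )

    def write(self, outdir: str, include_latents: bool = False) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
        if include_latents:
            self.pv_latents.to_csv(os.path.join(outdir, "pv_latents.csv"), index=False)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2)


# --------------------------------------------------------------------------
# pressure-volume forward model
# --------------------------------------------------------------------------

def generate_pv_sequence(
    pi_100: float,
    eps: float,
    r_a: float,
    dry_mass: float,
    turgid_mass: float,
    n_points: int = 14,
    noise_mass_sd: float = 0.0,
    noise_psi_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one bench-dehydration sequence of a rehydrated leaf.

    The leaf water potential is the sum of osmotic potential and turgor
    pressure.  With relative symplastic content ``R = (RWC - R_a)/(1 - R_a)``,

    - osmotic potential follows the dilution law  ``pi = pi_100 / R``,
    - turgor declines linearly with elastic modulus ``eps``:
      ``P = max(0, -pi_100 + eps * (R - 1))``.

    Turgor vanishes at ``R_tlp = 1 + pi_100 / eps``; the sampling grid places
    one observation exactly at the turgor-loss point and six points beyond
    it, mimicking a protocol that keeps drying until at least five post-TLP
    measurements are on record.

    Returns a DataFrame with columns ``step, fresh_mass_g, psi_MPa``.
    """
    if not turgid_mass > dry_mass > 0:
        raise PVParameterError("need turgid_mass > dry_mass > 0")
    if not 0 <= r_a < 1:
        raise PVParameterError("apoplastic fraction must lie in [0, 1)")
    if pi_100 >= 0 or eps <= 0:
        raise PVParameterError("need pi_100 < 0 and eps > 0")
    if n_points < 8:
        raise PVParameterError("need at least 8 points per curve")
    r_tlp = 1.0 + pi_100 / eps  # relative symplastic content at turgor loss
    if r_tlp <= 0:
        raise PVParameterError(
            "turgor-loss point at or below the apoplastic limit (eps <= |pi_100|)"
        )
    rng = _as_rng(seed)

    n_post = 6
    n_pre = n_points - n_post  # includes the point at the TLP itself
    pre = np.linspace(0.995, r_tlp, n_pre)
    step = min(0.03, 0.2 * r_tlp)
    post = r_tlp - step * np.arange(1, n_post + 1)
    r_sym = np.concatenate([pre, post])

    pi = pi_100 / r_sym
    turgor = np.maximum(0.0, -pi_100 + eps * (r_sym - 1.0))
    psi = turgor + pi
    rwc = r_a + (1.0 - r_a) * r_sym
    mass = dry_mass + rwc * (turgid_mass - dry_mass)

    if noise_mass_sd > 0:
        mass = mass + rng.normal(0.0, noise_mass_sd, size=mass.size)
    if noise_psi_sd > 0:
        psi = psi + rng.normal(0.0, noise_psi_sd, size=psi.size)
    psi = np.minimum(psi, -1e-6)

    return pd.DataFrame(
        {"step": np.arange(n_points), "fresh_mass_g": mass, "psi_MPa": psi}
    )


def generate_vessel_set(
    mu_log: float,
    sigma_log: float,
    n: int = 120,
    sapwood_area_mm2: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw ``n`` lognormal equivalent circular vessel diameters (um)."""
    if n < 1:
        raise ValueError("need at least one vessel")
    if sapwood_area_mm2 <= 0:
        raise ValueError("sapwood area must be positive")
    rng = _as_rng(seed)
    d = np.exp(rng.normal(mu_log, sigma_log, size=n)) if sigma_log > 0 else np.full(
        n, np.exp(mu_log)
    )
    return pd.DataFrame({"diameter_um": d, "sapwood_area_mm2": sapwood_area_mm2})


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, seed: int) -> CohortData:
    """Generate a full synthetic cohort, deterministic given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)

    plants = _generate_plants(config, rng)
    plant_devs = _draw_plant_deviations(config, plants, rng)

    wp = _generate_water_potential(config, plants, rng)
    gasex = _generate_gas_exchange(config, plants, plant_devs, rng)
    biochem = _generate_biochem(config, plants, plant_devs, rng)
    pv_curves, pv_latents = _generate_pv(config, plants, rng)
    vessels = _generate_vessels(config, plants, rng)
    biomass = _generate_biomass(config, plants, plant_devs, rng)

    manifest = {"seed": int(seed), "config_hash": config.config_hash()}
    return CohortData(
        plants=plants,
        water_potential=wp,
        gas_exchange=gasex,
        biochem=biochem,
        pv_curves=pv_curves,
        pv_latents=pv_latents,
        vessels=vessels,
        biomass=biomass,
        manifest=manifest,
    )


def _generate_plants(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    meta = config.plant_meta
    rows = []
    for sp in config.species:
        for tr in config.treatments:
            for i in range(config.n_plants_per_cell):
                pid = f"{sp[0]}{tr[0]}{i + 1:03d}"
                h_m, h_s = meta.height_cm[tr]
                d_m, d_s = meta.diameter_mm[tr]
                a_m, a_s = meta.age_years[tr]
                rows.append(
                    {
                        "plant_id": pid,
                        "species": sp,
                        "treatment": tr,
                        "height_cm": max(10.0, rng.normal(h_m, h_s)),
                        "basal_diameter_mm": max(3.0, rng.normal(d_m, d_s)),
                        "age_years": max(3.0, rng.normal(a_m, a_s)),
                        "global_site_factor": rng.uniform(*meta.gsf_range),
                    }
                )
    return pd.DataFrame(rows)


def _draw_plant_deviations(
    config: CohortConfig, plants: pd.DataFrame, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Plant-level random intercepts for every repeated trait.

    Half the within-cell variance sits at the plant level, half at the
    record level, giving the repeated-measures structure the mixed models
    downstream assume.
    """
    devs: dict[str, np.ndarray] = {}
    names = list(config.gas_exchange.traits) + list(config.biochem)
    sp_arr = plants["species"].to_numpy()
    for name in names:
        spec = config.repeated_trait(name)
        sd = np.array([spec.sd[s] for s in sp_arr]) / np.sqrt(2.0)
        devs[name] = rng.normal(0.0, 1.0, size=len(plants)) * sd
    return devs


def _record_values(
    spec: TraitSpec,
    plants: pd.DataFrame,
    dev: np.ndarray,
    dates: Iterable[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    sp_arr = plants["species"].to_numpy()
    tr_arr = plants["treatment"].to_numpy()
    cell = np.array([spec.cell_mean(s, t) for s, t in zip(sp_arr, tr_arr)])
    sd_rec = np.array([spec.sd[s] for s in sp_arr]) / np.sqrt(2.0)
    frames = []
    for d_idx, date in enumerate(dates):
        if spec.date_profile is not None:
            mod = spec.date_profile[d_idx]
            m = cell + mod if spec.date_mode == "absolute" else cell * (1.0 + mod)
        else:
            m = cell
        vals = m + dev + rng.normal(0.0, 1.0, size=len(plants)) * sd_rec
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": plants["plant_id"],
                    "species": sp_arr,
                    "treatment": tr_arr,
                    "date": date,
                    "value": spec.clip(vals),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _generate_water_potential(
    config: CohortConfig, plants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    wp = config.water_potential
    sp_arr = plants["species"].to_numpy()
    tr_arr = plants["treatment"].to_numpy()
    gap_mean = np.array([wp.gap_mean(s) for s in sp_arr])
    frames = []
    for d_idx, date in enumerate(config.dates):
        base = wp.psi_pd_date_means[d_idx] + rng.normal(0.0, wp.base_sd, size=len(plants))
        offset = np.array(
            [
                wp.browsing_offset(s, d_idx) if t == "BROWSED" else 0.0
                for s, t in zip(sp_arr, tr_arr)
            ]
        )
        gap = np.maximum(
            wp.gap_floor, gap_mean * (1.0 + rng.normal(0.0, wp.gap_cv, size=len(plants)))
        )
        psi_md = np.minimum(base, -0.02) - gap
        psi_pd = np.minimum(base + offset, -0.01)
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": plants["plant_id"],
                    "species": sp_arr,
                    "treatment": tr_arr,
                    "date": date,
                    "psi_pd_MPa": psi_pd,
                    "psi_md_MPa": psi_md,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _generate_gas_exchange(
    config: CohortConfig,
    plants: pd.DataFrame,
    devs: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    ge = config.gas_exchange
    latents = {
        name: _record_values(ge.traits[name], plants, devs[name], config.dates, rng)
        for name in ("lma", "a_mass", "g_s", "c_i", "phi_psii")
    }
    out = latents["lma"][["plant_id", "species", "treatment", "date"]].copy()
    lma = latents["lma"]["value"].to_numpy()
    a_mass = latents["a_mass"]["value"].to_numpy()
    g_s = latents["g_s"]["value"].to_numpy()
    c_i = latents["c_i"]["value"].to_numpy()
    phi = latents["phi_psii"]["value"].to_numpy()
    n = len(out)

    noise = ge.measurement_rel_noise
    sp_arr = out["species"].to_numpy()
    area_mean = np.array([ge.leaf_area_means[s] for s in sp_arr])
    leaf_area = area_mean * np.exp(rng.normal(0.0, ge.leaf_area_cv, size=n))
    # raw observables derived from latents: the derivation modules invert these
    leaf_dry_mass = lma * leaf_area * 1e-4 * (1.0 + rng.normal(0.0, noise, size=n))
    a_area = a_mass * lma / 1000.0 * (1.0 + rng.normal(0.0, noise, size=n))
    f_s = ge.fs_base * np.exp(rng.normal(0.0, ge.fs_cv, size=n))
    f_m_prime = f_s / (1.0 - phi)

    out["A_area"] = a_area
    out["g_s"] = g_s
    out["C_i"] = c_i
    out["F_s"] = f_s
    out["F_m_prime"] = f_m_prime
    out["PPFD"] = ge.ppfd
    out["leaf_area_cm2"] = leaf_area * (1.0 + rng.normal(0.0, noise, size=n))
    out["leaf_dry_mass_g"] = leaf_dry_mass
    return out


def _generate_biochem(
    config: CohortConfig,
    plants: pd.DataFrame,
    devs: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    cols = {}
    base = None
    mapping = {
        "c_conc": "C_mg_g",
        "n_conc": "N_mg_g",
        "d13c": "d13C_permil",
        "d15n": "d15N_permil",
    }
    for name, col in mapping.items():
        table = _record_values(config.biochem[name], plants, devs[name], config.dates, rng)
        if base is None:
            base = table[["plant_id", "species", "treatment", "date"]].copy()
        cols[col] = table["value"].to_numpy()
    assert base is not None
    for col, vals in cols.items():
        base[col] = vals
    return base


def _generate_pv(
    config: CohortConfig, plants: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    pv = config.pv
    curves = []
    latents = []
    lo, hi = pv.n_points
    for row in plants.itertuples():
        for date in config.late_summer_dates:
            year = campaign_year(date)
            pi100 = min(
                -0.3,
                rng.normal(pv.pi100_treatment_means[row.treatment], pv.pi100_sd),
            )
            eps = max(
                -pi100 + 3.0,
                rng.normal(pv.eps_treatment_means[row.treatment], pv.eps_sd),
            )
            ra = float(
                np.clip(rng.normal(pv.ra_mean, pv.ra_sd), *pv.ra_bounds)
            )
            dwtw_mean = pv.dwtw.cell_mean(row.species, row.treatment)
            dwtw_mean += pv.dwtw_year_offsets.get(year, 0.0)
            dwtw = float(
                np.clip(
                    rng.normal(dwtw_mean, pv.dwtw.sd[row.species]),
                    pv.dwtw.lo,
                    pv.dwtw.hi,
                )
            )
            turgid = pv.turgid_mass_means[row.species] * np.exp(
                rng.normal(0.0, pv.turgid_mass_cv)
            )
            dry = dwtw * turgid
            n_points = int(rng.integers(lo, hi + 1))
            seq = generate_pv_sequence(
                pi100,
                eps,
                ra,
                dry,
                turgid,
                n_points=n_points,
                noise_mass_sd=pv.noise_mass_sd,
                noise_psi_sd=pv.noise_psi_sd,
                seed=rng,
            )
            seq.insert(0, "plant_id", row.plant_id)
            seq.insert(1, "species", row.species)
            seq.insert(2, "treatment", row.treatment)
            seq.insert(3, "date", date)
            seq["dry_mass_g"] = dry
            curves.append(seq)
            latents.append(
                {
                    "plant_id": row.plant_id,
                    "species": row.species,
                    "treatment": row.treatment,
                    "date": date,
                    "pi_100": pi100,
                    "eps": eps,
                    "r_a": ra,
                    "dw_tw": dwtw,
                    "turgid_mass_g": turgid,
                    "dry_mass_g": dry,
                }
            )
    return pd.concat(curves, ignore_index=True), pd.DataFrame(latents)


def _generate_vessels(
    config: CohortConfig, plants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    vc = config.vessels
    frames = []
    for row in plants.itertuples():
        organs = ["STEM"] + (["ROOT"] if row.species == "FAGUS" else [])
        plant_factor = np.exp(rng.normal(0.0, vc.plant_cv))
        for organ in organs:
            key = (row.species, organ)
            if key not in vc.mu_log:
                continue
            area = vc.n_vessels / vc.density_per_mm2[key]
            for year in vc.ring_years:
                mu = vc.mu_log[key] + np.log(vc.ring_factors[year] * plant_factor)
                vs = generate_vessel_set(
                    mu, vc.sigma_log[key], vc.n_vessels, area, seed=rng
                )
                vs.insert(0, "plant_id", row.plant_id)
                vs.insert(1, "species", row.species)
                vs.insert(2, "treatment", row.treatment)
                vs.insert(3, "organ", organ)
                vs.insert(4, "ring_year", year)
                frames.append(vs)
    return pd.concat(frames, ignore_index=True)


def _generate_biomass(
    config: CohortConfig,
    plants: pd.DataFrame,
    devs: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    bio = config.biomass
    lma_spec = config.gas_exchange.traits["lma"]
    noise = bio.measurement_rel_noise
    rows = []
    for i, row in enumerate(plants.itertuples()):
        cell = (row.species, row.treatment)
        sb = _lognormal_mean_sd(rng, *bio.sb_cells[cell])
        la = _lognormal_mean_sd(rng, bio.la_cells[cell], bio.la_cells[cell] * bio.la_cv)
        sala = max(
            1e-5,
            rng.normal(
                bio.sala_cells[cell], bio.sala_rel_sd * bio.sala_cells[cell]
            ),
        )
        # plant-level LMA ties the leaf-area subsample to the harvest masses
        lma_plant = max(5.0, lma_spec.cell_mean(row.species, row.treatment) + devs["lma"][i])
        total_leaf_mass = la * lma_plant * 1e-4
        frac = rng.uniform(*bio.subsample_frac)
        sub_area = la * frac * (1.0 + rng.normal(0.0, noise))
        sub_mass = total_leaf_mass * frac * (1.0 + rng.normal(0.0, noise))
        cross_section = sala * la

        rec = {
            "plant_id": row.plant_id,
            "species": row.species,
            "treatment": row.treatment,
            "shoot_dry_mass_g": sb * (1.0 + rng.normal(0.0, noise)),
            "total_leaf_dry_mass_g": total_leaf_mass * (1.0 + rng.normal(0.0, noise)),
            "subsample_leaf_area_cm2": sub_area,
            "subsample_leaf_dry_mass_g": sub_mass,
            "subsample_n_leaves": bio.subsample_n_leaves,
            "basal_cross_section_cm2": cross_section * (1.0 + rng.normal(0.0, noise)),
        }
        if row.species == "FAGUS":
            rs_m, rs_s = bio.rs_treatment[row.treatment]
            rs = max(bio.rs_floor, rng.normal(rs_m, rs_s))
            rd_m, rd_s = bio.rd_treatment[row.treatment]
            rec["root_dry_mass_g"] = rs * sb * (1.0 + rng.normal(0.0, noise))
            rec["root_depth_cm"] = max(bio.rd_floor, rng.normal(rd_m, rd_s))
        else:
            rec["root_dry_mass_g"] = np.nan
            rec["root_depth_cm"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def _lognormal_mean_sd(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    """One lognormal draw parameterised by its arithmetic mean and sd."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - 0.5 * sigma2
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))
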