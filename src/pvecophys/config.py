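"""Cohort configuration and the packaged field-calibrated defaults.

The study design is a 2 species x 2 browsing-history x 5 plants factorial,
measured on six campaigns (late spring, midsummer and late summer of two
consecutive growing seasons).  Trait calibrations are stored as species and
treatment *marginal* means together with a within-cell dispersion; cell means
are reconstructed additively (or multiplicatively for strictly positive,
strongly species-structured traits) so that both printed marginals are
recovered by a balanced cohort.

Dispersions are reconstructed from published standard errors as
``sd = SE * sqrt(n)``; the ``n_basis`` recorded with each trait states the
sample size assumed for that conversion (5 plants for harvest traits, 10
leaf curves for pressure-volume traits, 30 plant x date records for traits
measured three times per season).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

SPECIES = ("FAGUS", "ILEX")
TREATMENTS = ("BROWSED", "UNBROWSED")

#: campaign labels in chronological order
DEFAULT_DATES = (
    "2018_late_spring",
    "2018_midsummer",
    "2018_late_summer",
    "2019_late_spring",
    "2019_midsummer",
    "2019_late_summer",
)


class ConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


def is_late_summer(date: str) -> bool:
    return "late_summer" in date


def campaign_year(date: str) -> int:
    return int(date.split("_", 1)[0])


# seasonal modulation profiles (relative, zero-sum over the six campaigns)
MOISTURE_PROFILE = (0.10, 0.00, -0.12, 0.08, 0.02, -0.08)
LMA_PROFILE = (-0.06, 0.01, 0.05, -0.05, 0.01, 0.04)
CI_PROFILE = (0.03, 0.00, -0.04, 0.02, 0.01, -0.02)
N_PROFILE = (0.05, 0.00, -0.06, 0.04, 0.01, -0.04)


@dataclass
class TraitSpec:
    """Calibration of one scalar trait over the species x treatment design.

    ``species_means`` and (optionally) ``treatment_means`` are marginal means
    in the trait's units.  ``combine`` selects how the two marginals are
    folded into a cell mean:

    - ``additive``:        cell = m_species + (m_treatment - grand)
    - ``multiplicative``:  cell = m_species * m_treatment / grand

    ``sd`` is the total within-cell standard deviation per species, split
    evenly (in variance) between a plant-level and a record-level component
    for repeatedly measured traits.
    """

    name: str
    units: str
    species_means: dict[str, float]
    sd: dict[str, float]
    treatment_means: dict[str, float] | None = None
    combine: str = "additive"
    date_profile: tuple[float, ...] | None = None
    date_mode: str = "relative"  # or "absolute"
    n_basis: int = 30
    lo: float | None = None
    hi: float | None = None
    fagus_only: bool = False

    def _treatment_grand(self) -> float:
        assert self.treatment_means is not None
        return float(np.mean(list(self.treatment_means.values())))

    def cell_mean(self, species: str, treatment: str) -> float:
        m = self.species_means[species]
        if self.treatment_means is None:
            return m
        mt = self.treatment_means[treatment]
        g = self._treatment_grand()
        if self.combine == "additive":
            return m + (mt - g)
        if self.combine == "multiplicative":
            return m * mt / g
        raise ConfigError(f"unknown combine rule {self.combine!r}")

    def mean(self, species: str, treatment: str, date_idx: int | None = None) -> float:
        m = self.cell_mean(species, treatment)
        if date_idx is not None and self.date_profile is not None:
            d = self.date_profile[date_idx]
            m = m + d if self.date_mode == "absolute" else m * (1.0 + d)
        return m

    def treatment_marginal(self, treatment: str, species: tuple[str, ...] = SPECIES) -> float:
        return float(np.mean([self.cell_mean(s, treatment) for s in species]))

    def species_marginal(self, species: str) -> float:
        if self.treatment_means is None:
            return self.species_means[species]
        return float(np.mean([self.cell_mean(species, t) for t in TREATMENTS]))

    def clip(self, values: np.ndarray) -> np.ndarray:
        if self.lo is not None or self.hi is not None:
            return np.clip(values, self.lo, self.hi)
        return values

    def validate(self) -> None:
        for sp, s in self.sd.items():
            if not s > 0:
                raise ConfigError(f"{self.name}: sd for {sp} must be > 0")
        if self.date_profile is not None and abs(sum(self.date_profile)) > 1e-9:
            raise ConfigError(f"{self.name}: date profile must sum to zero")


@dataclass
class WaterPotentialConfig:
    """Predawn / midday leaf water potential calibration (MPa, <= 0).

    A shared latent base follows the seasonal predawn trajectory; midday
    potential subtracts a positive species-specific diurnal drawdown, so the
    predawn >= midday ordering holds record by record.  The browsing legacy
    enters as a positive predawn offset confined to the late-summer campaign
    of the first (drier) year, attenuated offsets for the evergreen in the
    second year.
    """

    psi_pd_date_means: tuple[float, ...] = (-0.35, -0.55, -0.85, -0.35, -0.50, -0.70)
    base_sd: float = 0.18
    psi_md_species_means: dict[str, float] = field(
        default_factory=lambda: {"FAGUS": -1.72, "ILEX": -1.04}
    )
    #: (species or "*", date index) -> browsed-minus-unbrowsed predawn offset
    browsing_offsets: dict[tuple[str, int], float] = field(
        default_factory=lambda: {("*", 2): 0.25, ("ILEX", 3): 0.10, ("ILEX", 5): 0.10}
    )
    gap_cv: float = 0.12
    gap_floor: float = 0.05
    n_basis: int = 30

    def gap_mean(self, species: str) -> float:
        """Diurnal drawdown sized so the midday marginal matches calibration."""
        base = float(np.mean(self.psi_pd_date_means))
        gap = base - self.psi_md_species_means[species]
        if gap <= 0:
            raise ConfigError("midday potential must be below the predawn mean")
        return gap

    def browsing_offset(self, species: str, date_idx: int) -> float:
        return self.browsing_offsets.get(
            (species, date_idx), self.browsing_offsets.get(("*", date_idx), 0.0)
        )


@dataclass
class PVConfig:
    """Pressure-volume latent parameters and dehydration-sequence noise."""

    pi100_treatment_means: dict[str, float] = field(
        default_factory=lambda: {"BROWSED": -1.60, "UNBROWSED": -1.80}
    )
    pi100_sd: float = 0.12
    eps_treatment_means: dict[str, float] = field(
        default_factory=lambda: {"BROWSED": 9.5, "UNBROWSED": 12.5}
    )
    eps_sd: float = 1.3
    ra_mean: float = 0.30
    ra_sd: float = 0.04
    ra_bounds: tuple[float, float] = (0.05, 0.60)
    dwtw: TraitSpec = field(
        default_factory=lambda: TraitSpec(
            name="dw_tw",
            units="g g^-1",
            species_means={"FAGUS": 0.37, "ILEX": 0.43},
            treatment_means={"BROWSED": 0.39, "UNBROWSED": 0.41},
            sd={"FAGUS": 0.03, "ILEX": 0.03},
            n_basis=10,
            lo=0.15,
            hi=0.75,
        )
    )
    #: additive year offset on dw_tw (first year drier, lower ratio)
    dwtw_year_offsets: dict[int, float] = field(
        default_factory=lambda: {2018: -0.01, 2019: 0.01}
    )
    turgid_mass_means: dict[str, float] = field(
        default_factory=lambda: {"FAGUS": 0.35, "ILEX": 0.55}
    )
    turgid_mass_cv: float = 0.10
    n_points: tuple[int, int] = (11, 19)
    noise_mass_sd: float = 0.001  # g
    noise_psi_sd: float = 0.02  # MPa


@dataclass
class VesselConfig:
    """Lognormal vessel-diameter populations per species and organ.

    Defaults place the diffuse-porous deciduous species well above the
    evergreen in mean lumen diameter, so theoretical stem conductance keeps
    the observed species ordering for every ring year.
    """

    mu_log: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("FAGUS", "STEM"): float(np.log(38.0)),
            ("ILEX", "STEM"): float(np.log(24.0)),
            ("FAGUS", "ROOT"): float(np.log(55.0)),
        }
    )
    sigma_log: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("FAGUS", "STEM"): 0.22,
            ("ILEX", "STEM"): 0.22,
            ("FAGUS", "ROOT"): 0.25,
        }
    )
    #: vessels per mm^2, converts the vessel count into a sapwood sector area
    density_per_mm2: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("FAGUS", "STEM"): 90.0,
            ("ILEX", "STEM"): 140.0,
            ("FAGUS", "ROOT"): 60.0,
        }
    )
    n_vessels: int = 120
    plant_cv: float = 0.05
    ring_factors: dict[int, float] = field(
        default_factory=lambda: {2017: 0.95, 2018: 1.00, 2019: 1.03}
    )
    ring_years: tuple[int, ...] = (2017, 2018, 2019)


@dataclass
class BiomassConfig:
    """Harvest traits, sampled once per plant at the end of the study.

    Shoot biomass and total leaf area are lognormal (sapling sizes are
    strongly right-skewed); the root-to-shoot ratio is the free latent and
    root biomass is derived from it, so the per-plant ratio statistics match
    the calibration exactly.
    """

    sb_cells: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {
            ("FAGUS", "BROWSED"): (113.2, 119.4),
            ("FAGUS", "UNBROWSED"): (417.6, 574.9),
            ("ILEX", "BROWSED"): (80.0, 48.0),
            ("ILEX", "UNBROWSED"): (240.0, 144.0),
        }
    )
    rs_treatment: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BROWSED": (0.49, 0.134), "UNBROWSED": (0.26, 0.067)}
    )
    rs_floor: float = 0.05
    rd_treatment: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BROWSED": (67.2, 27.7), "UNBROWSED": (69.7, 14.8)}
    )
    rd_floor: float = 10.0
    la_cells: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("FAGUS", "BROWSED"): 4042.0,
            ("FAGUS", "UNBROWSED"): 13960.0,
            ("ILEX", "BROWSED"): 2200.0,
            ("ILEX", "UNBROWSED"): 7596.0,
        }
    )
    la_cv: float = 0.5
    #: stem cross-sectional area to leaf area ratio, cm^2 cm^-2
    sala_cells: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("ILEX", "BROWSED"): 31.1e-4,
            ("ILEX", "UNBROWSED"): 15.8e-4,
            ("FAGUS", "BROWSED"): 6.70e-4,
            ("FAGUS", "UNBROWSED"): 3.40e-4,
        }
    )
    sala_rel_sd: float = 0.20
    subsample_n_leaves: int = 15
    subsample_frac: tuple[float, float] = (0.02, 0.08)
    measurement_rel_noise: float = 0.005


@dataclass
class PlantMetaConfig:
    height_cm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BROWSED": (72.9, 18.0), "UNBROWSED": (153.1, 20.6)}
    )
    diameter_mm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BROWSED": (20.9, 3.8), "UNBROWSED": (28.7, 4.4)}
    )
    age_years: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BROWSED": (21.7, 6.0), "UNBROWSED": (17.6, 5.7)}
    )
    gsf_range: tuple[float, float] = (0.16, 0.28)


@dataclass
class GasExchangeConfig:
    traits: dict[str, TraitSpec] = field(default_factory=dict)
    leaf_area_means: dict[str, float] = field(
        default_factory=lambda: {"FAGUS": 28.0, "ILEX": 14.0}
    )
    leaf_area_cv: float = 0.15
    fs_base: float = 500.0
    fs_cv: float = 0.05
    ppfd: float = 1200.0
    measurement_rel_noise: float = 0.005


@dataclass
class CohortConfig:
    """Full configuration of a synthetic study cohort."""

    species: tuple[str, ...] = SPECIES
    treatments: tuple[str, ...] = TREATMENTS
    n_plants_per_cell: int = 5
    dates: tuple[str, ...] = DEFAULT_DATES
    water_potential: WaterPotentialConfig = field(default_factory=WaterPotentialConfig)
    gas_exchange: GasExchangeConfig = field(default_factory=GasExchangeConfig)
    biochem: dict[str, TraitSpec] = field(default_factory=dict)
    pv: PVConfig = field(default_factory=PVConfig)
    vessels: VesselConfig = field(default_factory=VesselConfig)
    biomass: BiomassConfig = field(default_factory=BiomassConfig)
    plant_meta: PlantMetaConfig = field(default_factory=PlantMetaConfig)

    # ------------------------------------------------------------------ api
    def repeated_trait(self, name: str) -> TraitSpec:
        if name in self.gas_exchange.traits:
            return self.gas_exchange.traits[name]
        if name in self.biochem:
            return self.biochem[name]
        raise KeyError(name)

    @property
    def late_summer_dates(self) -> tuple[str, ...]:
        return tuple(d for d in self.dates if is_late_summer(d))

    def validate(self) -> None:
        if not self.species:
            raise ConfigError("at least one species required")
        for sp in self.species:
            if sp not in SPECIES:
                raise ConfigError(f"unknown species label {sp!r}")
        if len(set(self.dates)) != len(self.dates):
            raise ConfigError("campaign labels must be unique")
        if self.n_plants_per_cell < 1:
            raise ConfigError("n_plants_per_cell must be >= 1")
        lo, hi = self.pv.n_points
        if not (8 <= lo <= hi):
            raise ConfigError("pv n_points range must lie within [8, inf)")
        if not self.late_summer_dates:
            raise ConfigError("at least one late-summer campaign is required")
        for spec in list(self.gas_exchange.traits.values()) + list(self.biochem.values()):
            spec.validate()
        self.pv.dwtw.validate()
        for key, (_, sd) in self.biomass.sb_cells.items():
            if sd <= 0:
                raise ConfigError(f"shoot biomass sd must be > 0 for {key}")

    # ----------------------------------------------------------- yaml round trip
    def to_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {_enc_key(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return enc(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "CohortConfig":
        return _build(cls, data)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError("cohort configuration file is not a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _enc_key(key: Any) -> Any:
    if isinstance(key, tuple):
        return "|".join(str(k) for k in key)
    return key


def _dec_key(key: Any) -> Any:
    if isinstance(key, str) and "|" in key:
        parts = key.split("|")
        return tuple(int(p) if p.lstrip("-").isdigit() else p for p in parts)
    return key


_TUPLE_INT_KEYED = {"ring_factors", "dwtw_year_offsets"}


def _build(cls: type, data: Any) -> Any:
    """Reconstruct nested dataclasses from a plain dict (YAML payload)."""
    if not dataclasses.is_dataclass(cls):
        return data
    kwargs: dict[str, Any] = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for name, value in data.items():
        if name not in hints:
            raise ConfigError(f"unknown configuration key {name!r} for {cls.__name__}")
        f = hints[name]
        target = f.type if isinstance(f.type, type) else None
        # resolve known nested dataclass fields by default-factory type
        default = f.default_factory() if f.default_factory is not dataclasses.MISSING else None  # type: ignore[misc]
        if dataclasses.is_dataclass(default):
            kwargs[name] = _build(type(default), value)
        elif isinstance(default, dict) and value is not None:
            out = {}
            for k, v in value.items():
                k = _dec_key(k)
                if name in _TUPLE_INT_KEYED and isinstance(k, str):
                    k = int(k)
                if isinstance(v, dict):  # dict of TraitSpec
                    out[k] = _build(TraitSpec, v)
                elif isinstance(v, list):
                    out[k] = tuple(v)
                else:
                    out[k] = v
            kwargs[name] = out
        elif isinstance(default, tuple) or (isinstance(value, list) and target is None):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_paper_defaults() -> CohortConfig:
    """The packaged, field-calibrated cohort configuration.

    Marginal means come from the published group statistics of the browsing
    legacy study (species means for traits with strong species structure,
    treatment means where a browsing effect was reported); dispersions are
    reconstructed from the published standard errors.
    """
    gasex = GasExchangeConfig(
        traits={
            "lma": TraitSpec(
                name="lma",
                units="g m^-2",
                species_means={"FAGUS": 42.4, "ILEX": 150.99},
                treatment_means={"BROWSED": 91.4, "UNBROWSED": 102.0},
                sd={"FAGUS": 7.1, "ILEX": 21.2},
                date_profile=LMA_PROFILE,
                lo=5.0,
            ),
            "a_mass": TraitSpec(
                name="a_mass",
                units="nmol g^-1 s^-1",
                species_means={"FAGUS": 210.6, "ILEX": 49.1},
                treatment_means={"BROWSED": 137.4, "UNBROWSED": 122.3},
                sd={"FAGUS": 32.3, "ILEX": 11.5},
                date_profile=MOISTURE_PROFILE,
                lo=1.0,
            ),
            "g_s": TraitSpec(
                name="g_s",
                units="mol m^-2 s^-1",
                species_means={"FAGUS": 0.129, "ILEX": 0.091},
                treatment_means={"BROWSED": 0.12, "UNBROWSED": 0.10},
                sd={"FAGUS": 0.033, "ILEX": 0.027},
                date_profile=MOISTURE_PROFILE,
                lo=0.005,
            ),
            "c_i": TraitSpec(
                name="c_i",
                units="ppm",
                species_means={"FAGUS": 270.0, "ILEX": 255.0},
                sd={"FAGUS": 12.0, "ILEX": 12.0},
                date_profile=CI_PROFILE,
                lo=50.0,
            ),
            "phi_psii": TraitSpec(
                name="phi_psii",
                units="dimensionless",
                species_means={"FAGUS": 0.21, "ILEX": 0.18},
                sd={"FAGUS": 0.025, "ILEX": 0.025},
                date_profile=MOISTURE_PROFILE,
                lo=0.02,
                hi=0.79,
            ),
        }
    )
    biochem = {
        "n_conc": TraitSpec(
            name="n_conc",
            units="mg g^-1",
            species_means={"FAGUS": 22.36, "ILEX": 13.08},
            treatment_means={"BROWSED": 18.79, "UNBROWSED": 16.65},
            sd={"FAGUS": 2.3, "ILEX": 2.6},
            date_profile=N_PROFILE,
            lo=2.0,
        ),
        "c_conc": TraitSpec(
            name="c_conc",
            units="mg g^-1",
            species_means={"FAGUS": 480.0, "ILEX": 480.0},
            sd={"FAGUS": 15.0, "ILEX": 15.0},
            lo=300.0,
        ),
        "d13c": TraitSpec(
            name="d13c",
            units="permil",
            species_means={"FAGUS": -31.43, "ILEX": -30.15},
            sd={"FAGUS": 0.82, "ILEX": 0.71},
            date_profile=(-0.3, 0.0, 0.3, -0.2, 0.0, 0.2),
            date_mode="absolute",
        ),
        "d15n": TraitSpec(
            name="d15n",
            units="permil",
            species_means={"FAGUS": -2.0, "ILEX": -2.0},
            sd={"FAGUS": 1.0, "ILEX": 1.0},
            date_profile=(-0.2, 0.0, 0.2, -0.2, 0.0, 0.2),
            date_mode="absolute",
        ),
    }
    config = CohortConfig(gas_exchange=gasex, biochem=biochem)
    config.validate()
    return config
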