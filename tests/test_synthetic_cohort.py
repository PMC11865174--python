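"""Generator contracts: determinism, structure, calibration convergence."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from pvecophys.config import ConfigError, load_paper_defaults
from pvecophys.gas_exchange import derive_gas_exchange
from pvecophys.pv_analysis import closed_form_tlp
from pvecophys.synthetic_cohort import (
    PVParameterError,
    generate_cohort,
    generate_pv_sequence,
    generate_vessel_set,
)


def _small_config(n=3):
    cfg = load_paper_defaults()
    cfg.n_plants_per_cell = n
    return cfg


def test_seeded_determinism():
    cfg = _small_config()
    a = generate_cohort(cfg, 42)
    b = generate_cohort(cfg, 42)
    for name in a._TABLES:
        pdt.assert_frame_equal(getattr(a, name), getattr(b, name))
    c = generate_cohort(cfg, 43)
    assert not a.gas_exchange["A_area"].equals(c.gas_exchange["A_area"])


def test_single_species_config_yields_no_other_records():
    cfg = _small_config()
    cfg.species = ("ILEX",)
    cohort = generate_cohort(cfg, 1)
    for table in (cohort.plants, cohort.gas_exchange, cohort.vessels, cohort.biomass):
        assert set(table["species"]) == {"ILEX"}
    # the evergreen was never root-excavated
    assert cohort.biomass["root_dry_mass_g"].isna().all()
    assert not (cohort.vessels["organ"] == "ROOT").any()


def test_structural_fidelity(study_cohort):
    wp = study_cohort.water_potential
    assert (wp["psi_pd_MPa"] >= wp["psi_md_MPa"]).all()
    assert (wp["psi_pd_MPa"] <= 0).all()

    bio = study_cohort.biomass
    assert bio.loc[bio["species"] == "ILEX", "root_dry_mass_g"].isna().all()
    assert bio.loc[bio["species"] == "FAGUS", "root_dry_mass_g"].notna().all()
    assert not (study_cohort.vessels.query("species == 'ILEX'")["organ"] == "ROOT").any()

    # dehydration sequences exist only for late-summer campaigns and keep
    # at least five points beyond the turgor-loss point
    assert set(study_cohort.pv_curves["date"]) == {
        "2018_late_summer",
        "2019_late_summer",
    }
    merged = study_cohort.pv_curves.merge(
        study_cohort.pv_latents,
        on=["plant_id", "date"],
        suffixes=("", "_lat"),
    )
    merged["rwc"] = (merged["fresh_mass_g"] - merged["dry_mass_g"]) / (
        merged["turgid_mass_g"] - merged["dry_mass_g"]
    )
    for (_, _), grp in merged.groupby(["plant_id", "date"]):
        rwc_tlp, _ = closed_form_tlp(
            grp["pi_100"].iloc[0], grp["eps"].iloc[0], grp["r_a"].iloc[0]
        )
        assert (grp["rwc"] < rwc_tlp - 1e-3).sum() >= 5
        assert 11 <= len(grp) <= 19


def test_pv_sequence_noise_free_closed_forms():
    seq = generate_pv_sequence(-1.5, 10.0, 0.3, 0.4, 1.0, n_points=14, seed=0)
    rwc = (seq["fresh_mass_g"] - 0.4) / 0.6
    # full-turgor limit: psi -> 0 as RWC -> 1
    assert seq["psi_MPa"].iloc[0] == pytest.approx(0.0, abs=0.12)
    assert rwc.iloc[0] > 0.99
    # the sampling grid pins one observation exactly at the turgor-loss point
    rwc_tlp, pi_0 = closed_form_tlp(-1.5, 10.0, 0.3)
    assert rwc_tlp == pytest.approx(0.895)
    assert pi_0 == pytest.approx(-1.7647, abs=1e-4)
    i_tlp = (rwc - rwc_tlp).abs().idxmin()
    assert rwc.loc[i_tlp] == pytest.approx(rwc_tlp, abs=1e-9)
    assert seq["psi_MPa"].loc[i_tlp] == pytest.approx(pi_0, abs=1e-6)
    # monotone drying
    assert (seq["fresh_mass_g"].diff().dropna() < 0).all()


def test_pv_sequence_seeded_repeatability():
    a = generate_pv_sequence(-1.8, 12.0, 0.25, 0.3, 0.8, 12, 0.001, 0.02, seed=5)
    b = generate_pv_sequence(-1.8, 12.0, 0.25, 0.3, 0.8, 12, 0.001, 0.02, seed=5)
    pdt.assert_frame_equal(a, b)


def test_pv_sequence_rejects_unphysical_parameters():
    with pytest.raises(PVParameterError):
        generate_pv_sequence(-1.5, 1.4, 0.3, 0.4, 1.0)  # eps <= |pi_100|
    with pytest.raises(PVParameterError):
        generate_pv_sequence(-1.5, 10.0, 0.3, 1.0, 0.4)  # dry >= turgid


def test_vessel_set_degenerate_sigma():
    vs = generate_vessel_set(np.log(40.0), 0.0, n=100, sapwood_area_mm2=1.0, seed=0)
    assert len(vs) == 100
    assert np.allclose(vs["diameter_um"], 40.0)
    assert (vs["diameter_um"] > 0).all()


def test_calibration_convergence_large_cohort(big_cohort):
    """Derived browsed-cell LMA converges on the configured marginal mean."""
    cfg = load_paper_defaults()
    target = cfg.gas_exchange.traits["lma"].treatment_marginal("BROWSED")
    derived = derive_gas_exchange(big_cohort.gas_exchange)
    browsed = derived.loc[derived["treatment"] == "BROWSED", "lma"]
    sem = browsed.std() / np.sqrt(len(browsed))
    assert abs(browsed.mean() - target) < 3 * sem + 1e-9


def test_config_yaml_roundtrip(tmp_path):
    cfg = load_paper_defaults()
    path = tmp_path / "cohort.yaml"
    cfg.to_yaml(str(path))
    back = type(cfg).from_yaml(str(path))
    assert back.config_hash() == cfg.config_hash()
    back.validate()


def test_config_validation_errors():
    cfg = load_paper_defaults()
    cfg.n_plants_per_cell = 0
    with pytest.raises(ConfigError):
        cfg.validate()
    cfg = load_paper_defaults()
    cfg.species = ("QUERCUS",)
    with pytest.raises(ConfigError):
        cfg.validate()
    cfg = load_paper_defaults()
    cfg.dates = ("2018_late_spring", "2018_midsummer")  # no late-summer campaign
    with pytest.raises(ConfigError):
        cfg.validate()
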