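"""Outlier screening, backward model selection, Tukey HSD and PCA."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pvecophys.stats_pipeline import (
    ModelSpec,
    fit_lm_oneshot,
    fit_lmm_backward,
    flag_extreme_outliers,
    run_pca,
    screen_trait_table,
    tukey_dates,
)

warnings.filterwarnings("ignore", module="statsmodels")


def _design(rng, n_per_cell=8, n_dates=3, t_eff=0.0, s_eff=0.0, d_eff=None,
            td_eff=None, plant_sd=1.0, resid_sd=1.0):
    """Balanced factorial table with known ground-truth effects."""
    rows = []
    d_eff = d_eff or [0.0] * n_dates
    for sp_i, sp in enumerate(("FAGUS", "ILEX")):
        for tr_i, tr in enumerate(("BROWSED", "UNBROWSED")):
            for i in range(n_per_cell):
                pid = f"{sp[0]}{tr[0]}{i}"
                u = rng.normal(0.0, plant_sd)
                for d in range(n_dates):
                    mu = t_eff * tr_i + s_eff * sp_i + d_eff[d]
                    if td_eff is not None:
                        mu += td_eff * tr_i * (d == n_dates - 1)
                    rows.append((pid, sp, tr, f"d{d}", mu + u + rng.normal(0, resid_sd)))
    return pd.DataFrame(
        rows, columns=["plant_id", "species", "treatment", "date", "value"]
    )


# ------------------------------------------------------------------ outliers

def test_outlier_flagging_hand_example():
    values = list(range(1, 10)) + [25]
    rep = flag_extreme_outliers(values)
    assert rep.extreme.sum() == 1
    assert rep.extreme[-1]
    assert not rep.removal.any()  # 25 is extreme but < 10x the fence
    q1, q3 = np.percentile(values, [25, 75])
    assert rep.upper_fence == pytest.approx(q3 + 3 * (q3 - q1))


def test_outlier_removal_needs_ten_times_fence():
    values = list(range(1, 10)) + [250.0]
    rep = flag_extreme_outliers(values)
    assert rep.extreme[-1] and rep.removal[-1]
    assert rep.removal.sum() == 1


def test_outlier_constant_vector_flags_nothing():
    rep = flag_extreme_outliers([5.0] * 10)
    assert not rep.extreme.any() and not rep.removal.any()


def test_outlier_needs_four_values():
    with pytest.raises(ValueError):
        flag_extreme_outliers([1.0, 2.0, 3.0])


def test_screen_trait_table_groupwise():
    rng = np.random.default_rng(3)
    rows = []
    for sp, scale in (("FAGUS", 5.0), ("ILEX", 25.0)):
        for i in range(8):
            rows.append((f"{sp}{i}", sp, "BROWSED", scale + rng.normal(0, 0.5)))
    table = pd.DataFrame(rows, columns=["plant_id", "species", "treatment", "value"])
    table["trait"] = "x"
    table.loc[0, "value"] = 500.0  # two orders above its own cell
    clean, report = screen_trait_table(table, group_cols=("trait", "species"))
    assert report["removed"].sum() == 1
    assert len(clean) == len(table) - 1
    # the evergreen's larger scale is untouched by the deciduous cell fences
    assert (clean.loc[clean["species"] == "ILEX", "value"] > 20).all()


# ----------------------------------------------------------- model selection

def test_strong_main_effects_retained():
    rng = np.random.default_rng(1)
    table = _design(rng, n_per_cell=30, t_eff=2.0, s_eff=2.0)
    res = fit_lmm_backward(table, ModelSpec(response="x", transform="none"))
    assert "T" in res.retained and "S" in res.retained
    assert "D" not in res.retained
    assert res.pvalues["T"] < 0.05 and res.pvalues["S"] < 0.05


def test_marginality_keeps_parents_of_interactions():
    rng = np.random.default_rng(5)
    table = _design(rng, n_per_cell=30, td_eff=3.0)
    res = fit_lmm_backward(table, ModelSpec(response="x", transform="none"))
    assert "T:D" in res.retained
    assert "T" in res.retained and "D" in res.retained
    # elimination path never dropped a parent of a retained interaction
    for step in res.path:
        assert step["dropped"] not in res.retained


def test_final_model_is_selection_fixed_point():
    rng = np.random.default_rng(21)
    table = _design(rng, n_per_cell=20, t_eff=1.5)
    res = fit_lmm_backward(table, ModelSpec(response="x", transform="none"))
    retained = set(res.retained)
    droppable = [
        t for t in retained
        if not any(set(t.split(":")) < set(o.split(":")) for o in retained)
    ]
    for t in droppable:
        assert res.pvalues[t] < 0.05


def test_log_transform_auto_detected():
    rng = np.random.default_rng(8)
    table = _design(rng, n_per_cell=25, t_eff=1.0, resid_sd=0.3)
    table["value"] = 10.0 ** (table["value"] * 0.5)  # strongly lognormal
    res = fit_lmm_backward(table, ModelSpec(response="x"))
    assert res.transform == "log10"
    assert "T" in res.retained


def test_tukey_refuses_without_date_effect():
    rng = np.random.default_rng(101)
    table = _design(rng, n_per_cell=10, t_eff=2.0)
    res = fit_lmm_backward(table, ModelSpec(response="x", transform="none"))
    assert "D" not in res.retained
    with pytest.raises(ValueError):
        tukey_dates(res, table)


def test_tukey_isolates_shifted_date():
    rng = np.random.default_rng(17)
    table = _design(rng, n_per_cell=15, d_eff=[0.0, 0.0, 5.0])
    res = fit_lmm_backward(table, ModelSpec(response="x", transform="none"))
    assert res.term_significant("D")
    pairs, letters = tukey_dates(res, table)
    assert len(pairs) == 3  # all date pairs
    assert set(letters["d2"]).isdisjoint(set(letters["d0"]))
    assert set(letters["d0"]) & set(letters["d1"])


def test_oneshot_detects_treatment_effect():
    rng = np.random.default_rng(23)
    rows = []
    for tr_i, tr in enumerate(("BROWSED", "UNBROWSED")):
        for i in range(40):
            rows.append((f"F{tr[0]}{i}", "FAGUS", tr, 2.0 * tr_i + rng.normal()))
    table = pd.DataFrame(rows, columns=["plant_id", "species", "treatment", "value"])
    res = fit_lm_oneshot(table, ModelSpec(response="rs", factors=("T",)))
    assert res.retained == ["T"]
    assert res.pvalues["T"] < 0.05


def test_oneshot_rejects_foreign_species_rows():
    table = pd.DataFrame(
        {
            "plant_id": ["a", "b", "c", "d"],
            "species": ["FAGUS", "FAGUS", "ILEX", "ILEX"],
            "treatment": ["BROWSED", "UNBROWSED"] * 2,
            "value": [1.0, 2.0, 3.0, 4.0],
        }
    )
    with pytest.raises(ValueError, match="single-species"):
        fit_lm_oneshot(table, ModelSpec(response="root_shoot", factors=("T",)))


# ------------------------------------------------------------------- PCA

def _pca_table(rng, n_plants=16, n_traits=4, sep=4.0):
    rows = []
    traits = [f"tr{i}" for i in range(n_traits)]
    for i in range(n_plants):
        sp = "FAGUS" if i % 2 == 0 else "ILEX"
        tr = "BROWSED" if (i // 2) % 2 == 0 else "UNBROWSED"
        for j, t in enumerate(traits):
            base = sep * (sp == "FAGUS") if j < n_traits // 2 else 0.0
            rows.append((f"p{i}", sp, tr, pd.NA, t, base + rng.normal()))
    return pd.DataFrame(
        rows, columns=["plant_id", "species", "treatment", "date", "trait", "value"]
    )


def test_pca_variance_fractions_sum_to_one():
    rng = np.random.default_rng(31)
    table = _pca_table(rng)
    res = run_pca(table, traits=("tr0", "tr1", "tr2", "tr3"))
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
    # orientation convention: dominant loading of each component positive
    for c in res.loadings.columns:
        col = res.loadings[c]
        assert col.iloc[int(np.argmax(np.abs(col.to_numpy())))] > 0


def test_pca_duplicated_trait_reported_as_rank_deficient():
    rng = np.random.default_rng(37)
    table = _pca_table(rng)
    dup = table[table["trait"] == "tr0"].assign(trait="tr3")
    table = pd.concat([table[table["trait"] != "tr3"], dup], ignore_index=True)
    res = run_pca(table, traits=("tr0", "tr1", "tr2", "tr3"))
    assert res.rank_deficient


def test_pca_drops_incomplete_plants_and_needs_three():
    rng = np.random.default_rng(41)
    table = _pca_table(rng)
    table = table.drop(table[(table.plant_id == "p0") & (table.trait == "tr1")].index)
    res = run_pca(table, traits=("tr0", "tr1", "tr2", "tr3"))
    assert res.dropped_plants == ["p0"]
    tiny = table[table["plant_id"].isin(["p1", "p2"])]
    with pytest.raises(ValueError):
        run_pca(tiny, traits=("tr0", "tr1", "tr2", "tr3"))


def test_pca_scores_invariant_to_trait_rescaling():
    rng = np.random.default_rng(43)
    table = _pca_table(rng)
    res1 = run_pca(table, traits=("tr0", "tr1", "tr2", "tr3"))
    scaled = table.copy()
    scaled.loc[scaled["trait"] == "tr0", "value"] *= 1e4
    res2 = run_pca(scaled, traits=("tr0", "tr1", "tr2", "tr3"))
    assert np.allclose(
        res1.scores[["PC1", "PC2"]].to_numpy(),
        res2.scores[["PC1", "PC2"]].to_numpy(),
        atol=1e-8,
    )
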