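"""Theoretical xylem hydraulic conductance from vessel anatomy.

The sapwood-area-specific theoretical hydraulic conductance follows the
Hagen-Poiseuille law summed over vessel lumina::

    k_sth = (pi * rho / (128 * eta)) * sum_i D_i^4 / S

with equivalent circular vessel diameters ``D_i`` (measured in um,
converted to m), sapwood cross-sectional area ``S`` (mm^2 -> m^2), water
density ``rho`` (kg m^-3) and dynamic viscosity ``eta`` expressed in MPa s,
so ``k_sth`` comes out in kg m^-1 s^-1 MPa^-1.  Constants default to water
at 20 degC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RHO_WATER", "ETA_WATER", "equivalent_diameter", "ksth", "derive_ksth_table"]

RHO_WATER = 998.2  # kg m^-3 (20 degC)
ETA_WATER = 1.002e-9  # MPa s   (20 degC; 1.002e-3 Pa s)


@dataclass
class HydraulicsResult:
    k_sth: float  # kg m^-1 s^-1 MPa^-1
    rho: float
    eta: float
    n_vessels: int
    organ: str = ""
    ring_year: int | None = None


def equivalent_diameter(lumen_area_um2):
    """Diameter (um) of the circle with the given lumen area (um^2)."""
    area = np.asarray(lumen_area_um2, dtype=float)
    if np.any(area < 0):
        raise ValueError("lumen area must be non-negative")
    out = np.sqrt(4.0 * area / np.pi)
    return float(out) if out.ndim == 0 else out


def ksth(
    diameters_um,
    sapwood_area_mm2: float,
    rho: float = RHO_WATER,
    eta: float = ETA_WATER,
    organ: str = "",
    ring_year: int | None = None,
) -> HydraulicsResult:
    """Sapwood-area-specific theoretical conductance of one vessel set."""
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0 or np.any(d <= 0):
        raise ValueError("need a non-empty set of positive vessel diameters")
    if sapwood_area_mm2 <= 0:
        raise ValueError("sapwood area must be positive")
    d_m = d * 1e-6
    s_m2 = sapwood_area_mm2 * 1e-6
    k = (np.pi * rho / (128.0 * eta)) * np.sum(d_m**4) / s_m2
    return HydraulicsResult(
        k_sth=float(k),
        rho=rho,
        eta=eta,
        n_vessels=int(d.size),
        organ=organ,
        ring_year=ring_year,
    )


def derive_ksth_table(
    vessels: pd.DataFrame,
    rho: float = RHO_WATER,
    eta: float = ETA_WATER,
) -> pd.DataFrame:
    """Per (plant, organ, ring year) conductance from a tidy vessels table.

    Accepts either a ``diameter_um`` column or a ``lumen_area_um2`` column
    (converted through :func:`equivalent_diameter`).
    """
    df = vessels.copy()
    if "diameter_um" not in df.columns:
        if "lumen_area_um2" not in df.columns:
            raise ValueError("vessels table needs diameter_um or lumen_area_um2")
        df["diameter_um"] = equivalent_diameter(df["lumen_area_um2"].to_numpy())
    keys = ["plant_id", "organ", "ring_year"]
    carry = [c for c in ("species", "treatment") if c in df.columns]
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        res = ksth(
            grp["diameter_um"].to_numpy(),
            float(grp["sapwood_area_mm2"].iloc[0]),
            rho=rho,
            eta=eta,
            organ=key[1],
            ring_year=int(key[2]),
        )
        rec = dict(zip(keys, key))
        for c in carry:
            rec[c] = grp[c].iloc[0]
        rec["n_vessels"] = res.n_vessels
        rec["k_sth"] = res.k_sth
        rows.append(rec)
    return pd.DataFrame(rows)
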