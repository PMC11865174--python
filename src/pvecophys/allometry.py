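"""Whole-plant biomass partitioning and architecture indices.

Derives, per harvested plant:

- total leaf area ``LA`` scaled up from a leaf subsample,
- root-to-shoot dry mass ratio ``R/S`` (root-excavated species only),
- the Huber-value proxy ``S_A/L_A`` (basal stem cross-section per unit
  total leaf area),
- a sapwood-area estimate from the stem cross-section via a fixed
  calibration line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "leaf_area_total",
    "sa_la",
    "root_shoot",
    "sapwood_from_cross_section",
    "SAPWOOD_PROXY_SLOPE",
    "SAPWOOD_PROXY_INTERCEPT",
    "derive_allometry",
]

#: sapwood area (cm^2) vs stem cross-sectional area (cm^2) calibration line,
#: fitted once on a subsample of harvested stems; used descriptively to
#: justify the cross-section as a sapwood proxy, never re-fit in derivation.
SAPWOOD_PROXY_SLOPE = 0.94
SAPWOOD_PROXY_INTERCEPT = -0.061


def leaf_area_total(total_leaf_dry_mass_g, subsample_area_cm2, subsample_mass_g):
    """Whole-crown leaf area (cm^2) from the subsample area:mass ratio."""
    mass = np.asarray(total_leaf_dry_mass_g, dtype=float)
    s_area = np.asarray(subsample_area_cm2, dtype=float)
    s_mass = np.asarray(subsample_mass_g, dtype=float)
    if np.any(s_mass <= 0):
        raise ValueError("subsample mass must be positive")
    out = mass * (s_area / s_mass)
    return float(out) if out.ndim == 0 else out


def sa_la(basal_cross_section_cm2, leaf_area_cm2):
    """Stem cross-sectional area to leaf area ratio, cm^2 cm^-2."""
    cs = np.asarray(basal_cross_section_cm2, dtype=float)
    la = np.asarray(leaf_area_cm2, dtype=float)
    if np.any(la <= 0):
        raise ValueError("leaf area must be positive")
    out = cs / la
    return float(out) if out.ndim == 0 else out


def root_shoot(root_dry_mass_g, shoot_dry_mass_g):
    """Root-to-shoot dry biomass ratio, g g^-1."""
    rb = np.asarray(root_dry_mass_g, dtype=float)
    sb = np.asarray(shoot_dry_mass_g, dtype=float)
    if np.any(sb <= 0):
        raise ValueError("shoot biomass must be positive")
    out = rb / sb
    return float(out) if out.ndim == 0 else out


def sapwood_from_cross_section(cross_section_cm2):
    """Sapwood area (cm^2) from the fixed proxy calibration line, floored at 0."""
    cs = np.asarray(cross_section_cm2, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("cross-section must be positive")
    out = np.maximum(0.0, SAPWOOD_PROXY_SLOPE * cs + SAPWOOD_PROXY_INTERCEPT)
    return float(out) if out.ndim == 0 else out


def derive_allometry(biomass: pd.DataFrame) -> pd.DataFrame:
    """Per-plant allometric indices from a tidy biomass harvest table."""
    out = biomass.copy()
    la = leaf_area_total(
        out["total_leaf_dry_mass_g"].to_numpy(),
        out["subsample_leaf_area_cm2"].to_numpy(),
        out["subsample_leaf_dry_mass_g"].to_numpy(),
    )
    out["leaf_area_cm2"] = la
    out["sa_la"] = sa_la(out["basal_cross_section_cm2"].to_numpy(), la)
    out["sa_la_1e4"] = out["sa_la"] * 1e4  # display convention, 1e-4 cm^2 cm^-2
    rb = out["root_dry_mass_g"].to_numpy()
    sb = out["shoot_dry_mass_g"].to_numpy()
    if np.any(sb <= 0):
        raise ValueError("shoot biomass must be positive")
    out["r_s"] = np.where(np.isfinite(rb), rb / sb, np.nan)
    out["sapwood_area_proxy_cm2"] = sapwood_from_cross_section(
        out["basal_cross_section_cm2"].to_numpy()
    )
    return out
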