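"""Derived fluorescence and gas-exchange quantities.

From raw instantaneous records (IRGA photosynthesis and stomatal
conductance, steady-state and light-adapted maximal fluorescence, incident
light, leaf area and dry mass) this module derives:

- the operating quantum yield of photosystem II,
  ``phi_PSII = (Fm' - Fs)/Fm'``,
- the linear electron transport rate
  ``ETR = phi_PSII * PPFD * 0.5 * 0.84`` (equal excitation partitioning
  between photosystems; standard C3 leaf absorbance),
- intrinsic water-use efficiency ``iWUE = A_area / g_s`` (umol mol^-1),
- leaf mass per area ``LMA = dry mass / area`` (g m^-2) and the mass-based
  photosynthetic rate ``A_mass = 1000 * A_area / LMA`` (nmol g^-1 s^-1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["phi_psii", "etr", "iwue", "lma_and_amass", "derive_gas_exchange"]

#: fraction of absorbed quanta reaching photosystem II
PSII_PARTITION = 0.5
#: leaf absorbance assumed for C3 species
LEAF_ABSORBANCE = 0.84


class InvalidRecordError(ValueError):
    """Raised for physically impossible raw gas-exchange readings."""


def phi_psii(f_s, f_m_prime):
    """Operating PSII quantum yield from fluorescence, in (0, 1)."""
    f_s = np.asarray(f_s, dtype=float)
    f_m_prime = np.asarray(f_m_prime, dtype=float)
    if np.any(f_s <= 0) or np.any(f_m_prime <= f_s):
        raise InvalidRecordError("need F_m' > F_s > 0")
    out = (f_m_prime - f_s) / f_m_prime
    return float(out) if out.ndim == 0 else out


def etr(phi, ppfd):
    """Linear electron transport rate, umol m^-2 s^-1."""
    phi = np.asarray(phi, dtype=float)
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(ppfd <= 0):
        raise InvalidRecordError("PPFD must be positive")
    out = phi * ppfd * PSII_PARTITION * LEAF_ABSORBANCE
    return float(out) if out.ndim == 0 else out


def iwue(a_area, g_s):
    """Intrinsic water-use efficiency A/g_s, umol mol^-1."""
    a_area = np.asarray(a_area, dtype=float)
    g_s = np.asarray(g_s, dtype=float)
    if np.any(g_s <= 0):
        raise InvalidRecordError("stomatal conductance must be positive")
    out = a_area / g_s
    return float(out) if out.ndim == 0 else out


def lma_and_amass(a_area, leaf_area_cm2, leaf_dry_mass_g):
    """(LMA in g m^-2, A_mass in nmol g^-1 s^-1) from one leaf's raw data."""
    a_area = np.asarray(a_area, dtype=float)
    area = np.asarray(leaf_area_cm2, dtype=float)
    mass = np.asarray(leaf_dry_mass_g, dtype=float)
    if np.any(area <= 0) or np.any(mass <= 0):
        raise InvalidRecordError("leaf area and dry mass must be positive")
    lma = mass / (area * 1e-4)
    a_mass = 1000.0 * a_area / lma
    if lma.ndim == 0:
        return float(lma), float(a_mass)
    return lma, a_mass


def derive_gas_exchange(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised derivation over a tidy gas_exchange table.

    Expects columns ``A_area, g_s, F_s, F_m_prime, PPFD, leaf_area_cm2,
    leaf_dry_mass_g`` and passes through identifier columns.
    """
    out = records.copy()
    phi = phi_psii(out["F_s"].to_numpy(), out["F_m_prime"].to_numpy())
    out["phi_psii"] = phi
    out["etr"] = etr(phi, out["PPFD"].to_numpy())
    out["iwue"] = iwue(out["A_area"].to_numpy(), out["g_s"].to_numpy())
    lma, a_mass = lma_and_amass(
        out["A_area"].to_numpy(),
        out["leaf_area_cm2"].to_numpy(),
        out["leaf_dry_mass_g"].to_numpy(),
    )
    out["lma"] = lma
    out["a_mass"] = a_mass
    return out
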