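"""Pressure-volume curve analysis.

Extracts leaf water-relations parameters from a bench dehydration sequence
(paired fresh mass and water potential readings plus a final dry mass).
The analysis follows the classical transformed-curve protocol: beyond the
turgor-loss point the reciprocal of water potential is linear in relative
water content, and the fitted line yields the osmotic potential at full
turgor (its value at RWC = 1), the apoplastic water fraction (its root) and
the osmotic potential at the turgor-loss point.  The maximum bulk modulus
of elasticity is the steepest decline of turgor pressure against relative
symplastic water content near full turgor.

Closed-form relations used throughout (and by the test oracles)::

    R_tlp   = 1 + pi_100 / eps          (relative symplastic content at TLP)
    rwc_tlp = R_a + (1 - R_a) * R_tlp
    pi_0    = pi_100 / R_tlp = pi_100 * (1 - R_a) / (rwc_tlp - R_a)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PVCurveRaw",
    "PVParameters",
    "PVExtractionError",
    "estimate_turgid_mass",
    "compute_rwc_series",
    "fit_apoplastic_line",
    "extract_parameters",
    "fit_pv_table",
    "closed_form_tlp",
]


class PVExtractionError(ValueError):
    """Raised when a curve does not support parameter extraction."""


@dataclass
class PVCurveRaw:
    """One leaf's dehydration sequence, in strictly drying order."""

    fresh_mass: np.ndarray  # g
    psi: np.ndarray  # MPa, <= 0
    dry_mass: float  # g
    label: str = ""

    def __post_init__(self) -> None:
        self.fresh_mass = np.asarray(self.fresh_mass, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.fresh_mass.size != self.psi.size:
            raise PVExtractionError(f"{self.label}: mass/psi length mismatch")
        if self.fresh_mass.size < 8:
            raise PVExtractionError(f"{self.label}: need at least 8 points")
        if self.psi[0] > 1e-9 or np.any(self.psi[1:] >= 0):
            raise PVExtractionError(f"{self.label}: psi must be negative while drying")
        if not self.dry_mass < self.fresh_mass.min():
            raise PVExtractionError(f"{self.label}: dry mass exceeds a fresh mass")
        # drying order up to measurement noise
        rises = np.diff(self.fresh_mass)
        tol = 5.0 * max(1e-4, np.median(np.abs(rises)) * 0.5)
        if np.any(rises > tol):
            raise PVExtractionError(f"{self.label}: fresh mass increases while drying")

    @property
    def n_points(self) -> int:
        return int(self.fresh_mass.size)


@dataclass
class PVParameters:
    """Water-relations parameters extracted from one pressure-volume curve."""

    pi_100: float  # MPa, osmotic potential at full turgor
    pi_0: float  # MPa, osmotic potential at turgor loss
    rwc_tlp: float  # relative water content at turgor loss
    r_a: float  # apoplastic water fraction
    r_s: float  # symplastic water fraction (1 - r_a)
    dw_tw: float  # dry-to-turgid mass ratio
    eps_max: float  # MPa, maximum bulk modulus of elasticity
    turgid_mass: float  # g
    diagnostics: dict = field(default_factory=dict)


def closed_form_tlp(pi_100: float, eps: float, r_a: float) -> tuple[float, float]:
    """Forward-model (rwc_tlp, pi_0) for given generating parameters."""
    r_tlp = 1.0 + pi_100 / eps
    return r_a + (1.0 - r_a) * r_tlp, pi_100 / r_tlp


def estimate_turgid_mass(curve: PVCurveRaw, k_wet: int = 4) -> float:
    """Saturated (full-turgor) mass from the wet end of the curve.

    An ordinary least-squares line of fresh mass on water potential over the
    ``k_wet`` wettest points is extrapolated to psi = 0.  The intercept is
    used when the fitted slope is positive and the intercept is at least the
    largest observed mass (a mild oversaturation guard); otherwise the
    maximum observed fresh mass is returned and a warning logged.
    """
    k = min(k_wet, curve.n_points)
    x = curve.psi[:k]
    y = curve.fresh_mass[:k]
    max_mass = float(curve.fresh_mass.max())
    if np.isclose(x[0], 0.0, atol=1e-9):
        return float(y[0])
    if np.ptp(x) < 1e-9:
        logger.warning("%s: constant-psi wet region, using max observed mass", curve.label)
        return max_mass
    slope, intercept = np.polyfit(x, y, 1)
    if slope > 0 and intercept >= max_mass:
        return float(intercept)
    logger.warning(
        "%s: wet-region extrapolation rejected (slope=%.3g), using max observed mass",
        curve.label,
        slope,
    )
    return max_mass


def compute_rwc_series(curve: PVCurveRaw, turgid_mass: float) -> np.ndarray:
    """Relative water content of every point, clipped at saturation."""
    if not turgid_mass > curve.dry_mass:
        raise PVExtractionError(f"{curve.label}: turgid mass must exceed dry mass")
    rwc = (curve.fresh_mass - curve.dry_mass) / (turgid_mass - curve.dry_mass)
    rwc = np.minimum(rwc, 1.0)
    if np.any(rwc < 0):
        raise PVExtractionError(f"{curve.label}: negative relative water content")
    return rwc


def fit_apoplastic_line(
    rwc: np.ndarray,
    psi: np.ndarray,
    min_points: int = 5,
    r2_threshold: float = 0.995,
    residual_gate: float = 2.0,
) -> tuple[float, float, np.ndarray, float]:
    """Fit the post-turgor-loss linear region of the transformed curve.

    Fits ``-1/psi = a + b * RWC`` over a contiguous dry-end region grown one
    point at a time from the ``min_points`` driest observations.  A wetter
    candidate joins while the enlarged fit keeps ``R^2 >= r2_threshold`` and
    the candidate's own residual stays below ``residual_gate`` times the
    current region's residual standard deviation (with a small absolute
    floor so exactly collinear points are never rejected).

    Returns ``(a, b, member_mask, r_squared)`` with ``b > 0``.
    """
    rwc = np.asarray(rwc, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if rwc.size != psi.size:
        raise PVExtractionError("rwc/psi length mismatch")
    if np.any(psi >= 0):
        raise PVExtractionError("transformed fit requires strictly negative psi")
    y = -1.0 / psi
    order = np.argsort(rwc)  # driest first
    n = rwc.size
    if n < min_points:
        raise PVExtractionError(
            f"need at least {min_points} dry points, got {n}"
        )

    def _fit(idx: np.ndarray) -> tuple[float, float, float, np.ndarray]:
        b, a = np.polyfit(rwc[idx], y[idx], 1)
        resid = y[idx] - (a + b * rwc[idx])
        ss_res = float(resid @ resid)
        ss_tot = float(((y[idx] - y[idx].mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        return a, b, r2, resid

    members = list(order[:min_points])
    a, b, r2, resid = _fit(np.array(members))
    scale = float(np.abs(y[members]).mean())
    floor = 1e-6 * max(scale, 1e-12)
    for cand in order[min_points:]:
        resid_sd = float(resid.std(ddof=min(2, resid.size - 1)))
        gate = max(residual_gate * resid_sd, floor)
        cand_resid = abs(y[cand] - (a + b * rwc[cand]))
        trial = members + [int(cand)]
        a_t, b_t, r2_t, resid_t = _fit(np.array(trial))
        if cand_resid < gate and r2_t >= r2_threshold:
            members, a, b, r2, resid = trial, a_t, b_t, r2_t, resid_t
        else:
            break
    if b <= 0:
        raise PVExtractionError("apoplastic line has non-positive slope")
    mask = np.zeros(n, dtype=bool)
    mask[members] = True
    return float(a), float(b), mask, float(r2)


def extract_parameters(
    curve: PVCurveRaw,
    k_wet: int = 4,
    r2_threshold: float = 0.995,
    residual_gate: float = 2.0,
    eps_window: int = 4,
    eps_method: str = "ols",
) -> PVParameters:
    """Run the full extraction pipeline on one curve.

    Pipeline: saturated-mass estimation -> relative water content ->
    post-TLP line fit.  Then

    - ``pi_100 = -1/(a + b)``  (line evaluated at RWC = 1),
    - ``R_a = -a/b``           (RWC where the line predicts infinite psi),
    - the turgor-loss point is the wettest member of the linear region and
      ``pi_0`` is the line's value there,
    - pre-TLP turgor ``P = psi - pi(RWC)`` (osmotic term from the fitted
      line) and ``eps_max`` is the largest pairwise ``|dP/dR_s|`` among the
      ``eps_window`` wettest pre-TLP points, with relative symplastic
      content ``R_s = (RWC - R_a)/(1 - R_a)``.
    """
    turgid = estimate_turgid_mass(curve, k_wet=k_wet)
    rwc = compute_rwc_series(curve, turgid)
    a, b, mask, r2 = fit_apoplastic_line(
        rwc,
        curve.psi,
        r2_threshold=r2_threshold,
        residual_gate=residual_gate,
    )
    pi_100 = -1.0 / (a + b)
    r_a = -a / b
    diagnostics: dict = {"linear_region_size": int(mask.sum()), "r_squared": r2}
    if pi_100 >= 0:
        raise PVExtractionError(f"{curve.label}: non-negative pi_100 from fit")
    if not 0.0 <= r_a <= 0.8:
        diagnostics["r_a_out_of_range"] = True
        warnings.warn(
            f"{curve.label}: apoplastic fraction {r_a:.3f} outside [0, 0.8]",
            stacklevel=2,
        )

    rwc_tlp = float(rwc[mask].max())
    pi_0 = -1.0 / (a + b * rwc_tlp)

    pre = ~mask
    pre &= rwc > rwc_tlp
    if pre.sum() < 2:
        raise PVExtractionError(f"{curve.label}: too few pre-TLP points for eps_max")
    idx = np.where(pre)[0]
    idx = idx[np.argsort(rwc[idx])[::-1][:eps_window]]
    pi_line = -1.0 / (a + b * rwc[idx])
    turgor = curve.psi[idx] - pi_line
    r_s_rel = (rwc[idx] - r_a) / (1.0 - r_a)
    if eps_method == "ols":
        # slope of turgor against relative symplastic content near full
        # turgor; least squares over the window is noise-robust and exact
        # when turgor declines linearly
        if np.ptp(r_s_rel) < 1e-9:
            raise PVExtractionError(f"{curve.label}: degenerate pre-TLP window")
        slope = np.polyfit(r_s_rel, turgor, 1)[0]
        eps_max = abs(float(slope))
        diagnostics["eps_window_points"] = [int(i) for i in idx]
    elif eps_method == "max_pairwise":
        eps_max = 0.0
        eps_pair = (int(idx[0]), int(idx[0]))
        for i in range(idx.size):
            for j in range(i + 1, idx.size):
                dr = r_s_rel[i] - r_s_rel[j]
                if abs(dr) < 1e-9:
                    continue
                slope = abs((turgor[i] - turgor[j]) / dr)
                if slope > eps_max:
                    eps_max = slope
                    eps_pair = (int(idx[i]), int(idx[j]))
        diagnostics["eps_pair"] = eps_pair
    else:
        raise ValueError(f"unknown eps_method {eps_method!r}")

    return PVParameters(
        pi_100=float(pi_100),
        pi_0=float(pi_0),
        rwc_tlp=rwc_tlp,
        r_a=float(r_a),
        r_s=float(1.0 - r_a),
        dw_tw=float(curve.dry_mass / turgid),
        eps_max=float(eps_max),
        turgid_mass=float(turgid),
        diagnostics=diagnostics,
    )


def fit_pv_table(
    pv_curves: pd.DataFrame,
    r2_threshold: float = 0.995,
    **kwargs,
) -> pd.DataFrame:
    """Extract parameters for every curve in a tidy pv_curves table.

    Curves are keyed by ``(plant_id, date)``; required columns are
    ``fresh_mass_g, psi_MPa, dry_mass_g`` plus the keys.  Failing curves are
    reported with an ``error`` column instead of aborting the batch.
    """
    records = []
    carry = [c for c in ("species", "treatment") if c in pv_curves.columns]
    for (plant, date), grp in pv_curves.groupby(["plant_id", "date"], sort=True):
        grp = grp.sort_values("step") if "step" in grp.columns else grp
        rec = {"plant_id": plant, "date": date}
        for c in carry:
            rec[c] = grp[c].iloc[0]
        try:
            curve = PVCurveRaw(
                fresh_mass=grp["fresh_mass_g"].to_numpy(),
                psi=grp["psi_MPa"].to_numpy(),
                dry_mass=float(grp["dry_mass_g"].iloc[0]),
                label=f"{plant}@{date}",
            )
            params = extract_parameters(curve, r2_threshold=r2_threshold, **kwargs)
            rec.update(
                pi_100=params.pi_100,
                pi_0=params.pi_0,
                rwc_tlp=params.rwc_tlp,
                r_a=params.r_a,
                r_s=params.r_s,
                dw_tw=params.dw_tw,
                eps_max=params.eps_max,
                turgid_mass_g=params.turgid_mass,
                linear_region_size=params.diagnostics["linear_region_size"],
                r_squared=params.diagnostics["r_squared"],
                error="",
            )
        except PVExtractionError as exc:
            rec["error"] = str(exc)
        records.append(rec)
    return pd.DataFrame(records)
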