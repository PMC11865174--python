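"""Extraction contracts for pressure-volume curve analysis.

The forward model of the dehydration sequence serves as the independent
oracle: curves generated from known (pi_100, eps, R_a, D_W/T_W) must give
those values back.
"""

import numpy as np
import pytest

from pvecophys.pv_analysis import (
    PVCurveRaw,
    PVExtractionError,
    closed_form_tlp,
    compute_rwc_series,
    estimate_turgid_mass,
    extract_parameters,
    fit_apoplastic_line,
)
from pvecophys.synthetic_cohort import generate_pv_sequence


def _random_params(rng):
    pi = rng.uniform(-2.5, -1.0)
    eps = rng.uniform(-pi + 3.0, 18.0)
    ra = rng.uniform(0.1, 0.5)
    turgid = rng.uniform(0.3, 1.2)
    dry = rng.uniform(0.25, 0.55) * turgid
    n = int(rng.integers(11, 20))
    return pi, eps, ra, dry, turgid, n


def _curve(pi, eps, ra, dry, turgid, n, seed=0, m_sd=0.0, p_sd=0.0):
    seq = generate_pv_sequence(
        pi, eps, ra, dry, turgid, n_points=n, noise_mass_sd=m_sd,
        noise_psi_sd=p_sd, seed=seed,
    )
    return PVCurveRaw(
        seq["fresh_mass_g"].to_numpy(), seq["psi_MPa"].to_numpy(), dry
    )


def test_oracle_equivalence_noise_free():
    """Every extracted parameter within 1% of its generating value."""
    rng = np.random.default_rng(12345)
    for _ in range(100):
        pi, eps, ra, dry, turgid, n = _random_params(rng)
        params = extract_parameters(_curve(pi, eps, ra, dry, turgid, n))
        rwc_tlp, pi_0 = closed_form_tlp(pi, eps, ra)
        assert params.pi_100 == pytest.approx(pi, rel=0.01)
        assert params.pi_0 == pytest.approx(pi_0, rel=0.01)
        assert params.rwc_tlp == pytest.approx(rwc_tlp, rel=0.01)
        assert params.r_a == pytest.approx(ra, rel=0.01, abs=0.004)
        assert params.eps_max == pytest.approx(eps, rel=0.01)
        assert params.dw_tw == pytest.approx(dry / turgid, rel=0.01)
        assert params.r_s == pytest.approx(1.0 - params.r_a, abs=1e-12)


def test_central_example_parameters():
    params = extract_parameters(_curve(-1.5, 10.0, 0.3, 0.4, 1.0, 14))
    assert params.pi_100 == pytest.approx(-1.5, rel=0.01)
    assert params.pi_0 == pytest.approx(-1.7647, rel=0.01)
    assert params.rwc_tlp == pytest.approx(0.895, rel=0.01)
    assert params.r_a == pytest.approx(0.3, rel=0.01)
    assert params.eps_max == pytest.approx(10.0, rel=0.01)
    assert params.dw_tw == pytest.approx(0.4, rel=0.01)
    assert params.diagnostics["r_squared"] > 0.9999


def test_closed_form_consistency():
    """pi_0 = pi_100 (1 - R_a)/(rwc_tlp - R_a) holds for extracted values."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        pi, eps, ra, dry, turgid, n = _random_params(rng)
        p = extract_parameters(_curve(pi, eps, ra, dry, turgid, n, m_sd=5e-4, p_sd=0.01))
        implied = p.pi_100 * (1.0 - p.r_a) / (p.rwc_tlp - p.r_a)
        assert p.pi_0 == pytest.approx(implied, rel=1e-6)
        assert p.pi_0 <= p.pi_100


def test_turgid_mass_recovery_noise_free():
    curve = _curve(-1.8, 12.0, 0.25, 0.35, 0.9, 13)
    assert estimate_turgid_mass(curve) == pytest.approx(0.9, rel=0.005)


def test_turgid_mass_saturated_first_point():
    mass = np.array([1.0, 0.97, 0.94, 0.91, 0.88, 0.85, 0.82, 0.79])
    psi = np.array([0.0, -0.3, -0.6, -0.95, -1.3, -1.75, -2.1, -2.6])
    curve = PVCurveRaw(mass, psi, 0.4)
    assert estimate_turgid_mass(curve) == 1.0


def test_turgid_mass_fallback_on_negative_slope():
    # wet region slope inverted: the regression is rejected and the largest
    # observed mass is used instead
    mass = np.array([0.95, 0.96, 0.97, 0.98, 0.88, 0.85, 0.82, 0.79])
    psi = np.array([-0.05, -0.3, -0.6, -0.95, -1.3, -1.75, -2.1, -2.6])
    curve = PVCurveRaw(mass, psi, 0.4)
    assert estimate_turgid_mass(curve) == pytest.approx(0.98)


def test_rwc_arithmetic():
    mass = np.linspace(1.4, 1.2, 8)
    psi = np.linspace(-0.05, -2.0, 8)
    curve = PVCurveRaw(mass, psi, 0.4)
    rwc = compute_rwc_series(curve, 1.4)
    assert rwc[0] == pytest.approx(1.0)  # fresh = turgid
    assert rwc[-1] == pytest.approx(0.8)  # (1.2 - 0.4)/(1.4 - 0.4)
    with pytest.raises(PVExtractionError):
        compute_rwc_series(curve, 0.3)  # turgid below dry mass


def test_apoplastic_line_closed_form():
    curve = _curve(-1.5, 10.0, 0.3, 0.4, 1.0, 14)
    rwc = compute_rwc_series(curve, estimate_turgid_mass(curve))
    a, b, mask, r2 = fit_apoplastic_line(rwc, curve.psi)
    assert -1.0 / (a + b) == pytest.approx(-1.5, rel=0.01)
    assert -a / b == pytest.approx(0.3, rel=0.01)
    assert r2 > 0.9999
    assert b > 0


def test_apoplastic_line_excludes_wet_outlier():
    # exactly collinear dry tail plus a wet point far off the line
    rwc = np.array([0.95, 0.86, 0.84, 0.82, 0.80, 0.78, 0.76])
    a_true, b_true = -2.0, 3.0
    y = a_true + b_true * rwc
    psi = -1.0 / y
    psi[0] = psi[0] - 1.5  # pre-TLP point, off the line
    a, b, mask, r2 = fit_apoplastic_line(rwc, psi)
    assert not mask[0]
    assert mask[1:].all()
    assert a == pytest.approx(a_true, rel=1e-6)
    assert b == pytest.approx(b_true, rel=1e-6)


def test_apoplastic_line_needs_five_points():
    rwc = np.array([0.9, 0.85, 0.8, 0.75])
    psi = np.array([-1.0, -1.2, -1.4, -1.6])
    with pytest.raises(PVExtractionError):
        fit_apoplastic_line(rwc, psi)


def test_noisy_recovery_monte_carlo():
    """Median recovery error under bench noise: pi_100 < 5%, eps_max < 15%."""
    rng = np.random.default_rng(2024)
    pi_err, eps_err = [], []
    for _ in range(200):
        seed = int(rng.integers(2**31))
        curve = _curve(-1.5, 10.0, 0.3, 0.4, 1.0, 14, seed=seed, m_sd=0.001, p_sd=0.02)
        try:
            p = extract_parameters(curve)
        except PVExtractionError:
            continue
        pi_err.append(abs((p.pi_100 - (-1.5)) / 1.5))
        eps_err.append(abs((p.eps_max - 10.0) / 10.0))
    assert len(pi_err) > 180
    assert np.median(pi_err) < 0.05
    assert np.median(eps_err) < 0.15


def test_eps_invariant_to_mass_rescaling():
    base = _curve(-1.6, 11.0, 0.3, 0.4, 1.0, 14)
    scaled = PVCurveRaw(base.fresh_mass * 7.5, base.psi, 0.4 * 7.5)
    p0 = extract_parameters(base)
    p1 = extract_parameters(scaled)
    assert p1.eps_max == pytest.approx(p0.eps_max, rel=1e-9)
    assert p1.pi_100 == pytest.approx(p0.pi_100, rel=1e-9)
    assert p1.dw_tw == pytest.approx(p0.dw_tw, rel=1e-9)


def test_noise_cannot_improve_linear_region_r2():
    """Mean linear-region R^2 does not increase with psi noise."""
    def mean_r2(p_sd, n_rep=60):
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(n_rep):
            seed = int(rng.integers(2**31))
            curve = _curve(-1.5, 10.0, 0.3, 0.4, 1.0, 14, seed=seed, p_sd=p_sd)
            try:
                vals.append(extract_parameters(curve).diagnostics["r_squared"])
            except PVExtractionError:
                pass
        return np.mean(vals)

    assert mean_r2(0.04) <= mean_r2(0.01) + 1e-6


def test_curve_validation():
    with pytest.raises(PVExtractionError):
        PVCurveRaw(np.linspace(1, 0.8, 6), np.linspace(-0.1, -2, 6), 0.4)  # < 8 pts
    mass = np.linspace(1.0, 0.8, 9)
    with pytest.raises(PVExtractionError):
        PVCurveRaw(mass, np.linspace(0.1, -2.0, 9), 0.4)  # positive psi
    with pytest.raises(PVExtractionError):
        PVCurveRaw(mass, np.linspace(-0.1, -2.0, 9), 0.9)  # dry above fresh
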