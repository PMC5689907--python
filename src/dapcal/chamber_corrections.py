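"""Ionization-chamber correction factors and QA statistics.

Implements the influence-quantity corrections needed before a chamber
charge can enter the DAP_w calibration relation: air density (k_TP), ion
recombination (k_s, via Jaffe-plot extrapolation and via the TRS-398
two-voltage technique for pulsed beams), polarity (k_pol), the
volume-averaging correction for a thimble chamber in a non-flat profile,
a 1/cos(alpha) model of angular response for fields smaller than the
chamber, and linearity/reproducibility statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "T0_CELSIUS",
    "P0_KPA",
    "TWO_VOLTAGE_PULSED",
    "CorrectionSet",
    "JaffeFit",
    "BeamQuality",
    "k_tp",
    "k_s_jaffe",
    "k_s_two_voltage",
    "k_pol",
    "volume_average_correction",
    "apply_output_ratio_correction",
    "angular_response",
    "qa_stats",
    "reproducibility_pct",
]

T0_CELSIUS = 20.0
P0_KPA = 101.325

#: TRS-398 quadratic two-voltage coefficients for PULSED beams,
#: k_s = a0 + a1*(M1/M2) + a2*(M1/M2)**2 with M1 at the higher (normal
#: operating) voltage V1 and V1/V2 the voltage ratio (table key).
TWO_VOLTAGE_PULSED = {
    2.0: (2.337, -3.636, 2.299),
    2.5: (1.474, -1.587, 1.114),
    3.0: (1.198, -0.875, 0.677),
    3.5: (1.080, -0.542, 0.463),
    4.0: (1.022, -0.363, 0.341),
    5.0: (0.975, -0.188, 0.214),
}


@dataclass
class CorrectionSet:
    """The multiplicative correction factors k_i of the calibration relation."""

    k_tp: float = 1.0
    k_s: float = 1.0
    k_pol: float = 1.0
    k_elec: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_tp", "k_s", "k_pol", "k_elec"):
            v = getattr(self, name)
            if not 0.95 <= v <= 1.05:
                raise ValueError(f"{name} = {v} outside sanity bounds [0.95, 1.05]")

    @property
    def product_excluding_tp(self) -> float:
        """k_s * k_pol * k_elec (k_TP is applied to the charge directly)."""
        return self.k_s * self.k_pol * self.k_elec


@dataclass
class JaffeFit:
    """Least-squares line through normalized 1/M vs 1/U."""

    slope: float
    intercept: float
    r2: float
    k_s: float
    n_points: int


@dataclass
class BeamQuality:
    """Photon beam quality: nominal MV, TPR20,10 and the Spencer-Attix
    water/air stopping-power ratio s_w,air at the reference depth."""

    nominal_mv: float
    tpr_20_10: float
    s_w_air: float

    def __post_init__(self) -> None:
        if not 0.5 < self.tpr_20_10 < 0.9:
            raise ValueError("TPR20,10 outside plausible range")
        if not 1.0 < self.s_w_air < 1.2:
            raise ValueError("s_w,air outside plausible range")


def k_tp(temperature: float, pressure: float,
         t0: float = T0_CELSIUS, p0: float = P0_KPA) -> float:
    """Air-density correction for a vented chamber.

    k_TP = ((273.15 + T) / (273.15 + T0)) * (P0 / P), referenced to
    20 deg C and 101.325 kPa.
    """
    if pressure <= 0 or temperature <= -273.15:
        raise ValueError("nonphysical temperature/pressure")
    return (273.15 + temperature) / (273.15 + t0) * (p0 / pressure)


def _corrected_charge_per_mu(reading) -> float:
    return abs(reading.charge) * k_tp(reading.temperature, reading.pressure) / reading.mu


def k_s_jaffe(series, min_voltage: float = 100.0) -> JaffeFit:
    """Saturation correction from a Jaffe plot.

    Normalizes 1/M_cor(U) to 1/M_cor(U_max), fits a least-squares line
    against 1/U restricted to U >= ``min_voltage`` (general
    recombination is linear in 1/U only above ~100 V for this chamber),
    and extrapolates to infinite voltage: k_s = 1 / intercept.
    """
    readings = sorted(series, key=lambda r: r.bias)
    u = np.array([r.bias for r in readings], dtype=float)
    m = np.array([_corrected_charge_per_mu(r) for r in readings])
    u_norm = u.max()
    m_norm = m[np.argmax(u)]
    keep = u >= min_voltage
    if keep.sum() < 3 or len(np.unique(u[keep])) < 3:
        raise ValueError("need >= 3 distinct voltages above the fit threshold")
    y = m_norm / m[keep]  # normalized 1/M
    x = 1.0 / u[keep]
    fit = stats.linregress(x, y)
    if fit.intercept <= 0:
        raise ValueError("non-positive Jaffe intercept")
    return JaffeFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        k_s=1.0 / float(fit.intercept),
        n_points=int(keep.sum()),
    )


def k_s_two_voltage(m_low: float, m_high: float, ratio: float,
                    coeffs_table=None) -> float:
    """TRS-398 two-voltage saturation correction for pulsed beams.

    Parameters
    ----------
    m_low, m_high : float
        Charges collected at the lower (U1 = U2/ratio) and higher
        (normal operating, U2) voltage.
    ratio : float
        Voltage ratio U2/U1 (2, 4 or 5 in routine use).
    coeffs_table : dict, optional
        Override for the quadratic coefficient table.
    """
    if m_low <= 0 or m_high <= 0:
        raise ValueError("charges must be > 0")
    table = TWO_VOLTAGE_PULSED if coeffs_table is None else coeffs_table
    try:
        a0, a1, a2 = table[float(ratio)]
    except KeyError:
        raise ValueError(f"no two-voltage coefficients for ratio {ratio}") from None
    x = m_high / m_low
    return a0 + a1 * x + a2 * x * x


def k_pol(m_plus: float, m_minus: float, m_routine: float) -> float:
    """Polarity correction (TRS-398 convention).

    k_pol = (|M+| + |M-|) / (2 |M_routine|) with the reading at the
    routine operating polarity in the denominator.
    """
    if m_routine == 0:
        raise ValueError("routine reading must be non-zero")
    return (abs(m_plus) + abs(m_minus)) / (2.0 * abs(m_routine))


def volume_average_correction(profile, length: float = 2.4) -> float:
    """Volume-averaging correction for a thimble chamber.

    The chamber under-reads the CAX dose by the mean relative dose over
    its cavity length; the correction is the reciprocal of that mean::

        k_vol = 1 / mean(R(r)), r in [-length/2, +length/2]

    Parameters
    ----------
    profile : RadialProfile or (positions_cm, values) pair
        Relative dose along the chamber's longitudinal axis.  A
        half-profile is mirrored about the CAX.
    length : float
        Cavity length, cm (2.4 cm for an NE2571 Farmer chamber).
    """
    half = length / 2.0
    if hasattr(profile, "r"):
        r, v = profile.r, profile.value
        if r[-1] < half:
            raise ValueError("profile does not cover the averaging window")
        grid = np.linspace(0.0, half, 2001)
        mean = np.trapezoid(np.interp(grid, r, v), grid) / half
    else:
        pos, v = (np.asarray(a, dtype=float) for a in profile)
        order = np.argsort(pos)
        pos, v = pos[order], v[order]
        if pos[0] > -half or pos[-1] < half:
            raise ValueError("profile does not cover the averaging window")
        grid = np.linspace(-half, half, 4001)
        mean = np.trapezoid(np.interp(grid, pos, v), grid) / length
    if mean <= 0:
        raise ValueError("degenerate profile")
    return 1.0 / mean


def apply_output_ratio_correction(or_measured: float, factor: float,
                                  ndigits: int = 3) -> float:
    """Apply a volume-averaging correction to a measured output ratio,
    rounding half-up to the reporting precision."""
    if or_measured <= 0 or factor <= 0:
        raise ValueError("inputs must be > 0")
    from ._rounding import round_half_up

    return round_half_up(or_measured * factor, ndigits)


def angular_response(alpha: float, field: str = "broad",
                     broad_slope: float = 0.05) -> float:
    """Relative chamber response vs angle of beam incidence.

    For broad beams the measured anisotropy is approximately linear,
    ``1 + broad_slope * alpha / 100`` with broad_slope in %/deg (0.05 ==
    0.25% per 5 deg).  For fields smaller than the sensitive area the
    irradiated air volume grows geometrically as 1/cos(alpha), so the
    small-field response is the broad-field response divided by
    cos(alpha).
    """
    if not 0 <= alpha < 90:
        raise ValueError("alpha must be in [0, 90) degrees")
    broad = 1.0 + broad_slope * alpha / 100.0
    if field == "broad":
        return broad
    if field == "small":
        return broad / np.cos(np.radians(alpha))
    raise ValueError("field must be 'broad' or 'small'")


def reproducibility_pct(charges) -> float:
    """Relative standard deviation (%) of repeated readings."""
    c = np.asarray(charges, dtype=float)
    if len(c) < 2:
        raise ValueError("need >= 2 repeats")
    return 100.0 * c.std(ddof=1) / c.mean()


def qa_stats(charges, mu) -> dict:
    """Linearity and reproducibility statistics of charge vs MU.

    Returns ``repro_pct_sd`` (the %SD of the largest group of repeated
    MU settings), ``linearity_r2`` (R^2 of a free-intercept least-squares
    line of charge over MU) and ``max_dev_pct`` (largest relative
    deviation of a reading from the fitted line, %).
    """
    c = np.asarray(charges, dtype=float)
    m = np.asarray(mu, dtype=float)
    if c.shape != m.shape or c.ndim != 1:
        raise ValueError("charges and mu must be matching 1D sequences")
    uniq, counts = np.unique(m, return_counts=True)
    if len(uniq) < 3:
        raise ValueError("degenerate MU values: need >= 3 distinct settings")
    fit = stats.linregress(m, c)
    pred = fit.intercept + fit.slope * m
    max_dev = float(np.max(np.abs(c - pred) / np.abs(pred)) * 100.0)
    repro = 0.0
    if counts.max() >= 2:
        grp = uniq[np.argmax(counts)]
        repro = reproducibility_pct(c[m == grp])
    return {
        "repro_pct_sd": float(repro),
        "linearity_r2": float(fit.rvalue**2),
        "max_dev_pct": max_dev,
    }
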