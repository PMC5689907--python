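"""DAP_w determination and the chamber calibration coefficient.

The calibration relation is

    DAP_w = M_LAC,cor * N_D,w,LAC * k_s * k_pol * k_elec

where M_LAC,cor is the collected charge corrected for air density and
N_D,w,LAC is the dose-area calibration coefficient (mGy cm^-2 nC^-1).
DAP_w itself factorizes into the central-axis dose times the relative
dose integral over the sensitive area,

    DAP_w = D_w,CAX * Int_A R(r) dr.

This module combines those pieces, predicts the energy dependence of
the chamber response from Spencer-Attix stopping-power ratios, and
compares coefficients between calibration conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._rounding import round_half_up
from .chamber_corrections import BeamQuality, CorrectionSet, k_tp
from .dose_integration import DiscIntegral
from .types import ChamberReading

__all__ = [
    "CalibrationResult",
    "compute_dap",
    "calibration_coefficient",
    "apply_calibration",
    "energy_response_prediction",
    "compare_coefficients",
    "calibrate",
]


@dataclass
class CalibrationResult:
    """Outcome of one calibration: DAP_w per MU, the coefficient, and
    (optionally) the combined standard uncertainty in percent."""

    dap_w: float  # mGy cm^2 / MU
    n_d_w_lac: float  # mGy cm^-2 nC^-1
    m_cor: float  # nC, air-density corrected charge
    u_combined_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.dap_w <= 0 or self.n_d_w_lac <= 0:
            raise ValueError("DAP and coefficient must be positive")


def compute_dap(d_cax: float, integral, vol_avg_corr: float = 1.0) -> float:
    """DAP_w per MU from the CAX dose and the relative dose integral.

    Parameters
    ----------
    d_cax : float
        Central-axis dose output, mGy/MU, as measured by the reference
        chamber (before volume-averaging correction).
    integral : float or DiscIntegral
        Relative dose integral over the sensitive area, cm^2.
    vol_avg_corr : float
        Volume-averaging correction for the reference chamber (>= 1 for
        profiles peaked at the centre); applied to d_cax.
    """
    value = integral.value if isinstance(integral, DiscIntegral) else float(integral)
    if d_cax <= 0 or value <= 0 or vol_avg_corr <= 0:
        raise ValueError("inputs must be positive")
    return d_cax * vol_avg_corr * value


def calibration_coefficient(
    dap_per_mu: float,
    mu: float,
    reading_corrected_nc: float,
    corrections: CorrectionSet | None = None,
) -> float:
    """N_D,w,LAC = (DAP_w per MU * MU) / (M_cor * k_s * k_pol * k_elec)."""
    if reading_corrected_nc <= 0:
        raise ValueError("corrected charge must be > 0")
    k = corrections.product_excluding_tp if corrections is not None else 1.0
    return dap_per_mu * mu / (reading_corrected_nc * k)


def apply_calibration(
    reading: ChamberReading,
    corrections: CorrectionSet,
    n: float,
) -> float:
    """Forward direction: measured DAP_w (mGy cm^2) from a raw reading.

    The raw charge is corrected for air density via k_TP computed from
    the reading's temperature and pressure, then multiplied by the
    coefficient and the remaining correction factors.
    """
    if n <= 0:
        raise ValueError("coefficient must be > 0")
    m_cor = abs(reading.charge) * k_tp(reading.temperature, reading.pressure)
    return m_cor * n * corrections.product_excluding_tp


def energy_response_prediction(s_ref: BeamQuality, s_q: BeamQuality) -> float:
    """Predicted % change in chamber response between beam qualities.

    An air-filled chamber's reading per unit water dose scales with
    1/s_w,air, so going from the reference quality to quality Q changes
    the response by ``100 * (s_ref - s_q) / s_ref`` percent (positive
    when the stopping-power ratio drops, i.e. at higher energy).
    """
    return 100.0 * (s_ref.s_w_air - s_q.s_w_air) / s_ref.s_w_air


def compare_coefficients(n_a: float, n_b: float) -> float:
    """Signed percent difference 100 * (n_a / n_b - 1)."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("coefficients must be > 0")
    return 100.0 * (n_a / n_b - 1.0)


def calibrate(
    d_cax: float,
    integral,
    reading: ChamberReading,
    corrections: CorrectionSet,
    vol_avg_corr: float = 1.0,
    u_combined_pct: float = float("nan"),
) -> CalibrationResult:
    """End-to-end calibration from measured pieces.

    Combines the CAX dose (mGy/MU), the relative dose integral (cm^2),
    and a raw chamber reading (its k_TP computed from the recorded
    temperature/pressure) into DAP_w per MU and N_D,w,LAC.
    """
    dap = compute_dap(d_cax, integral, vol_avg_corr)
    m_cor = abs(reading.charge) * k_tp(reading.temperature, reading.pressure)
    n = calibration_coefficient(dap, reading.mu, m_cor, corrections)
    return CalibrationResult(dap_w=dap, n_d_w_lac=n, m_cor=m_cor,
                             u_combined_pct=u_combined_pct)


def report_1dp(x: float) -> float:
    """Round to the 1-decimal report convention (half-up)."""
    return round_half_up(x, 1)
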