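"""Reference commissioning dataset for a PTW 34070-type chamber.

Published commissioning measurements bundled as the package's worked
example and regression baseline: the quantities entering the
determination of N_D,w,LAC on an Elekta Synergy linac (6/10/18 MV), the
corresponding uncertainty budgets, and the beam-quality data used to
predict the chamber's energy dependence.  These are measured *inputs*
to the pipeline -- every derived number (DAP_w, N_D,w,LAC, combined
uncertainties, percent differences) is recomputed by the package.
"""

from __future__ import annotations

from .chamber_corrections import BeamQuality
from .uncertainty_budget import Budget

__all__ = [
    "R_LAC_CM",
    "NOMINAL_SENSITIVE_AREA_CM2",
    "CALIBRATIONS",
    "BEAM_QUALITIES",
    "PROFILE_INTEGRALS_CONE_CM2",
    "VOLUME_AVG_DETERMINATIONS",
    "OUTPUT_RATIO_NE2571_5X5",
    "OUTPUT_RATIO_CC13_5X5",
    "JAFFE_INTERCEPT_6MV",
    "N_CONE_PRINTED",
    "budget_cone",
    "budget_square4",
    "budget_broad",
]

#: Sensitive radius, cm (collecting-electrode diameter 81.6 mm).  The
#: vendor also quotes a sensitive area of 52.25 cm^2, which differs
#: slightly from pi * 4.08**2 = 52.30 cm^2; the radius is primary here.
R_LAC_CM = 4.08
NOMINAL_SENSITIVE_AREA_CM2 = 52.25

#: Measured inputs per calibration condition.  d_cax in mGy/MU (NE2571),
#: integral in cm^2, m_cor in nC (air-density corrected), n_printed in
#: mGy cm^-2 nC^-1 as reported.
CALIBRATIONS = {
    "cone5": dict(
        energy_mv=6, d_cax=7.379, integral=24.96, mu=100.0, m_cor=112.8,
        k_s=1.001, k_pol=0.999, k_elec=1.000, n_printed=163.7, u_pct=1.3,
    ),
    "square4": dict(
        energy_mv=6, d_cax=7.159, integral=20.29, mu=100.0, m_cor=88.97,
        k_s=1.001, k_pol=0.999, k_elec=1.000, n_printed=163.3, u_pct=2.6,
    ),
    "broad_6mv": dict(
        energy_mv=6, d_cax=7.998, integral=52.01, mu=200.0, m_cor=523.6,
        k_s=1.001, k_pol=0.999, k_elec=1.000, n_printed=158.9, u_pct=0.75,
    ),
    "broad_10mv": dict(
        energy_mv=10, d_cax=8.080, integral=52.51, mu=200.0, m_cor=539.0,
        k_s=1.001, k_pol=0.999, k_elec=1.000, n_printed=157.3, u_pct=0.75,
    ),
    "broad_18mv": dict(
        energy_mv=18, d_cax=8.073, integral=51.97, mu=200.0, m_cor=541.8,
        k_s=1.002, k_pol=0.999, k_elec=1.000, n_printed=154.7, u_pct=0.75,
    ),
}

#: TPR20,10 and Spencer-Attix water/air stopping-power ratios at 10 cm.
BEAM_QUALITIES = {
    6: BeamQuality(6, 0.673, 1.120),
    10: BeamQuality(10, 0.734, 1.105),
    18: BeamQuality(18, 0.777, 1.089),
}

#: Relative dose integral of the 5 cm cone field per detector, cm^2.
PROFILE_INTEGRALS_CONE_CM2 = {"EBT3": 25.17, "CC13": 24.83, "EFD": 24.87}

#: NE2571 volume-averaging correction determined from each detector's
#: profile of the 5 cm cone field.
VOLUME_AVG_DETERMINATIONS = {"EBT3": 1.0011, "EFD": 1.0051, "CC13": 1.0032}

OUTPUT_RATIO_NE2571_5X5 = 0.899
OUTPUT_RATIO_CC13_5X5 = 0.902

#: Jaffe-plot intercept (normalized 1/M at 1/U = 0) for 6 MV; k_s is its
#: reciprocal.  The equivalent recombination slope at +400 V is
#: (k_s - 1) * 400 = 0.36 V, the generator default.
JAFFE_INTERCEPT_6MV = 0.9991

N_CONE_PRINTED = 163.7


def _budget(label, rows) -> Budget:
    b = Budget(label=label)
    for name, u, group in rows:
        b.add(name, u, group)
    return b


def budget_cone() -> Budget:
    """Uncertainty budget for the 5 cm cone calibration (k = 1, %)."""
    return _budget("5 cm cone, 6 MV", [
        ("central-axis dose (NE2571)", 0.6, "dap"),
        ("relative dose integral", 1.0, "dap"),
        ("field-size change from reference", 0.2, "dap"),
        ("M_LAC,cor", 0.07, "response"),
        ("k_s", 0.1, "response"),
        ("k_pol", 0.05, "response"),
        ("k_elec", 0.05, "response"),
        ("linac output reproducibility", 0.2, "additional"),
        ("lateral misalignment (1 mm)", 0.05, "additional"),
        ("misalignment at depth (1 mm)", 0.4, "additional"),
        ("tolerance of sensitive radius (0.1 mm)", 0.25, "additional"),
    ])


def budget_square4() -> Budget:
    """Uncertainty budget for the 4 x 4 cm^2 MLC-field calibration."""
    return _budget("4 x 4 cm^2, 6 MV", [
        ("central-axis dose (NE2571)", 0.6, "dap"),
        ("relative dose integral", 2.4, "dap"),
        ("field-size change from reference", 0.2, "dap"),
        ("M_LAC,cor", 0.07, "response"),
        ("k_s", 0.1, "response"),
        ("k_pol", 0.05, "response"),
        ("k_elec", 0.05, "response"),
        ("linac output reproducibility", 0.2, "additional"),
        ("lateral misalignment (1 mm)", 0.05, "additional"),
        ("misalignment at depth (1 mm)", 0.4, "additional"),
        ("tolerance of sensitive radius (0.1 mm)", 0.25, "additional"),
        ("reproducibility of field area", 0.7, "additional"),
    ])


def budget_broad() -> Budget:
    """Uncertainty budget for the 10 x 10 cm^2 broad-field calibrations."""
    return _budget("10 x 10 cm^2", [
        ("central-axis dose (NE2571)", 0.5, "dap"),
        ("relative dose integral", 0.25, "dap"),
        ("M_LAC,cor", 0.07, "response"),
        ("k_s", 0.1, "response"),
        ("k_pol", 0.05, "response"),
        ("k_elec", 0.05, "response"),
        ("lateral misalignment (1 mm)", 0.05, "additional"),
        ("misalignment at depth (1 mm)", 0.4, "additional"),
        ("tolerance of sensitive radius (0.1 mm)", 0.25, "additional"),
    ])
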