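"""Core data containers shared across the DAP_w commissioning pipeline.

Conventions
-----------
* Distances on detector grids are held in mm (pixel pitch) but off-axis
  radii and integration areas are expressed in cm / cm**2, matching how
  chamber radii and dose-area products are quoted in practice.
* 2D grids are indexed ``(row, col)``; the beam-centre ``origin`` is a
  continuous (sub-pixel) ``(row, col)`` coordinate.  Fiducial marks on
  film scans are ``(x, y) = (col, row)`` pairs, the convention used by
  scikit-image geometric transforms.
* Charge is in nC, dose in Gy for film maps and mGy/MU for machine
  output, temperature in deg C, pressure in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc

__all__ = [
    "PV_FULL_SCALE",
    "FieldSpec",
    "DoseMap2D",
    "FilmScan",
    "ODMap",
    "RadialProfile",
    "ChamberReading",
    "VoxelVolume",
    "CalibrationCurve",
]

#: Full scale of the scanner's 16-bit pixel-value range; OD = -log10(PV / 2**16).
PV_FULL_SCALE = 2**16


@dataclass
class FieldSpec:
    """Analytic model of a collimated photon field's relative dose.

    The in-field plateau falls off through an error-function penumbra and
    settles on a low out-of-field plateau (scatter and head leakage), the
    two features that dominate the dose-area product of fields smaller
    than the chamber.  For a cone field::

        R(r) = (1 - tail_frac) * 0.5*erfc((r - a)/(sqrt(2)*sigma))
               + tail_frac * exp(-tail_decay * max(0, r - a))

    with ``a = nominal_size / 2`` (cm) and ``sigma = penumbra_sigma`` (mm).
    Square fields use the product of per-axis erfc edges and the distance
    outside the square for the tail term.

    Parameters
    ----------
    shape : {"cone", "square"}
        Cone (circular) or MLC/jaw (square) collimation.
    nominal_size : float
        Cone diameter or square side length, cm.
    penumbra_sigma : float
        Error-function edge width, mm.
    cax_dose_per_mu : float
        Central-axis dose output, mGy/MU.
    tail_frac : float
        Out-of-field plateau as a fraction of the CAX dose.  Measured
        values for 1x1 cm2 6 MV beams are ~4% at d_max rising to ~8% at
        30 cm depth; 0 disables the tail.
    tail_decay : float
        Exponential decay rate of the tail outside the field edge, 1/mm.
        0 gives a flat plateau.
    """

    shape: str
    nominal_size: float
    penumbra_sigma: float = 3.0
    cax_dose_per_mu: float = 7.379
    tail_frac: float = 0.04
    tail_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("cone", "square"):
            raise ValueError(f"unknown field shape {self.shape!r}")
        if self.nominal_size <= 0:
            raise ValueError("nominal_size must be > 0")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be > 0")
        if not 0 <= self.tail_frac < 0.2:
            raise ValueError("tail_frac must be in [0, 0.2)")

    # -- closed forms (used both by the generator and as test oracles) ----
    def radial(self, r_cm):
        """Relative dose of a cone field at off-axis distance ``r`` (cm)."""
        if self.shape != "cone":
            raise ValueError("radial() is only defined for cone fields")
        r = np.asarray(r_cm, dtype=float)
        a = self.nominal_size / 2.0
        sigma_cm = self.penumbra_sigma / 10.0
        core = 0.5 * erfc((r - a) / (np.sqrt(2.0) * sigma_cm))
        excess_cm = np.maximum(0.0, r - a)
        tail = self.tail_frac * np.exp(-self.tail_decay * 10.0 * excess_cm)
        return (1.0 - self.tail_frac) * core + tail

    def relative_dose(self, x_cm, y_cm):
        """Relative dose at Cartesian off-axis position (cm)."""
        x = np.asarray(x_cm, dtype=float)
        y = np.asarray(y_cm, dtype=float)
        if self.shape == "cone":
            return self.radial(np.hypot(x, y))
        a = self.nominal_size / 2.0
        sigma_cm = self.penumbra_sigma / 10.0
        s2 = np.sqrt(2.0) * sigma_cm
        core = (
            0.5 * erfc((np.abs(x) - a) / s2)
            * 0.5 * erfc((np.abs(y) - a) / s2)
        )
        dx = np.maximum(0.0, np.abs(x) - a)
        dy = np.maximum(0.0, np.abs(y) - a)
        outside = np.hypot(dx, dy)
        tail = self.tail_frac * np.exp(-self.tail_decay * 10.0 * outside)
        return (1.0 - self.tail_frac) * core + tail


@dataclass
class DoseMap2D:
    """Absorbed dose (or relative dose) on a regular 2D grid.

    Attributes
    ----------
    values : ndarray, shape (ny, nx)
        Dose per pixel, Gy (or dimensionless for a CAX-normalized map).
    pitch : float
        Pixel pitch, mm/pixel (square pixels).
    origin : (float, float)
        Continuous ``(row, col)`` coordinate of the beam centre.
    """

    values: np.ndarray
    pitch: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if self.values.min() < -1e-9:
            raise ValueError("dose values must be non-negative")

    @property
    def pixel_area_cm2(self) -> float:
        return (self.pitch / 10.0) ** 2

    def coords_cm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre (y, x) coordinates in cm relative to the origin."""
        ny, nx = self.values.shape
        y = (np.arange(ny) - self.origin[0]) * self.pitch / 10.0
        x = (np.arange(nx) - self.origin[1]) * self.pitch / 10.0
        return y, x

    def radius_cm(self) -> np.ndarray:
        y, x = self.coords_cm()
        return np.hypot(y[:, None], x[None, :])

    def scaled(self, factor: float) -> "DoseMap2D":
        return DoseMap2D(self.values * factor, self.pitch, self.origin)


@dataclass
class FilmScan:
    """A 16-bit grayscale flatbed scan of radiochromic film.

    ``marks`` are fiducial coordinates in ``(x, y)`` pixel order used to
    co-register pre- and post-exposure scans.
    """

    pv: np.ndarray
    dpi: float
    marks: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self) -> None:
        self.pv = np.asarray(self.pv, dtype=float)
        self.marks = np.asarray(self.marks, dtype=float).reshape(-1, 2)
        if self.dpi <= 0:
            raise ValueError("dpi must be > 0")
        if self.pv.min() <= 0 or self.pv.max() > PV_FULL_SCALE:
            raise ValueError("pixel values must be in (0, 2**16]")

    @property
    def pitch(self) -> float:
        """Pixel pitch in mm (25.4 / dpi)."""
        return 25.4 / self.dpi


@dataclass
class ODMap:
    """Optical density (or net-OD) per pixel with its pixel pitch (mm)."""

    od: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical densities must be finite")


@dataclass
class RadialProfile:
    """One half-profile: relative dose vs off-axis distance from the CAX.

    ``r`` is in cm, ascending from 0; values are normalized to 1 at the
    central axis (within 0.5%, the tolerance for scan noise).
    """

    r: np.ndarray
    value: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.r.shape != self.value.shape or self.r.ndim != 1:
            raise ValueError("r and value must be matching 1D arrays")
        if self.r[0] != 0:
            raise ValueError("profile must start at r = 0")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r must be strictly increasing")
        if np.any(self.value < 0):
            raise ValueError("relative doses must be non-negative")
        if abs(self.value[0] - 1.0) >= 0.005:
            raise ValueError("profile must be normalized to 1 at the CAX")


@dataclass
class ChamberReading:
    """One electrometer acquisition from the ionization chamber."""

    charge: float  # nC
    mu: float
    bias: float = 400.0  # V, signed
    polarity: str = "pos"
    temperature: float = 20.0  # deg C
    pressure: float = 101.325  # kPa

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.pressure <= 0:
            raise ValueError("pressure must be > 0")
        if self.polarity not in ("pos", "neg"):
            raise ValueError("polarity must be 'pos' or 'neg'")


@dataclass
class VoxelVolume:
    """Attenuation values on an isotropic 3D grid, axial axis first."""

    values: np.ndarray  # (nz, ny, nx)
    voxel_size: float  # mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")


class CalibrationCurve:
    """Polynomial net-OD -> dose calibration curve, D_w = sum a_i * dOD**i.

    The curve must be strictly increasing over the net-OD interval that
    maps onto ``valid_dose_range`` so that its numerical inverse (used by
    the synthetic film generator) is well defined.

    Parameters
    ----------
    coefficients : array-like
        Polynomial coefficients a0..a_n in ascending order, Gy per
        (net-OD)**i.
    valid_dose_range : (float, float)
        Dose interval (Gy) over which the fit is valid.
    """

    def __init__(self, coefficients, valid_dose_range=(0.0, 2.8)):
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.valid_dose_range = (float(valid_dose_range[0]), float(valid_dose_range[1]))
        if self.valid_dose_range[1] <= self.valid_dose_range[0]:
            raise ValueError("invalid dose range")
        # Bracket the net-OD mapping to the top of the dose range.  High
        # order fits can turn over beyond the fitted data, so the search
        # stops at the curve's first stationary point.
        hi = self.valid_dose_range[1]
        grid = np.linspace(0.0, 1.0, 4097)
        dose_grid = self.dose(grid)
        rising = np.where(np.diff(dose_grid) <= 0)[0]
        cap = grid[rising[0]] if rising.size else 1.0
        if self.dose(cap) < hi:
            raise ValueError("curve never reaches the top of the dose range")
        self.max_net_od = float(brentq(lambda x: self.dose(x) - hi, 0.0, cap))
        grid = np.linspace(0.0, self.max_net_od, 512)
        deriv = np.polynomial.polynomial.polyval(
            grid, np.polynomial.polynomial.polyder(self.coefficients)
        )
        if np.any(deriv <= 0):
            raise ValueError("curve must be strictly increasing on its domain")

    def dose(self, net_od):
        """Evaluate the curve: dose (Gy) at the given net-OD."""
        return np.polynomial.polynomial.polyval(
            np.asarray(net_od, dtype=float), self.coefficients
        )

    def net_od(self, dose):
        """Numerical inverse: net-OD that produces the given dose (Gy)."""
        d = np.asarray(dose, dtype=float)
        lo, hi = self.valid_dose_range
        if np.any(d < lo - 1e-12) or np.any(d > hi + 1e-12):
            raise ValueError("outside calibration range")

        def invert(di):
            if di <= 0:
                return 0.0
            return brentq(lambda x: self.dose(x) - di, 0.0, self.max_net_od, xtol=1e-14)

        return np.vectorize(invert, otypes=[float])(d)
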