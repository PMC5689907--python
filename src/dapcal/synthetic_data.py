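"""Synthetic generators for every input of the DAP_w commissioning pipeline.

No raw commissioning data (film scans, electrometer logs, microCT
volumes) ship with this package; instead, every pipeline stage can be
exercised against synthetic inputs with known ground truth.  All
generators are deterministic given a seed: identical seeds give
bit-identical outputs.

The closed-form field model in :class:`~dapcal.types.FieldSpec` doubles
as the independent oracle for integration tests: quantities computed
from generated grids can be compared against quadrature of the analytic
formula.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .chamber_corrections import k_tp
from .types import (
    PV_FULL_SCALE,
    CalibrationCurve,
    ChamberReading,
    DoseMap2D,
    FieldSpec,
    FilmScan,
    RadialProfile,
    VoxelVolume,
)

__all__ = [
    "make_field",
    "render_film_scan",
    "sample_profiles",
    "simulate_voltage_series",
    "simulate_chamber_reading",
    "lac_scan",
    "make_chamber_volume",
]

#: OD added to a pixel struck by a dust speck (salt noise in PV space).
DUST_OD = 0.6


def make_field(
    spec: FieldSpec,
    extent: float,
    pitch: float,
    dose_scale: float = 1.0,
) -> DoseMap2D:
    """Render a collimated field onto a regular grid.

    Parameters
    ----------
    spec : FieldSpec
        Analytic field model (cone or square).
    extent : float
        Grid side length, cm.  Must cover the nominal field size.
    pitch : float
        Pixel pitch, mm.
    dose_scale : float
        Multiplier applied to the relative dose (e.g. the CAX dose in Gy
        for an absolute map).  1.0 yields a CAX-normalized map.

    Returns
    -------
    DoseMap2D
        Grid of ``dose_scale * R(x, y)`` with the beam centre at the
        grid centre.
    """
    if extent < spec.nominal_size:
        raise ValueError("field exceeds grid")
    n = int(round(extent * 10.0 / pitch))
    origin = ((n - 1) / 2.0, (n - 1) / 2.0)
    idx = np.arange(n, dtype=float)
    y = (idx - origin[0]) * pitch / 10.0
    x = (idx - origin[1]) * pitch / 10.0
    values = dose_scale * spec.relative_dose(x[None, :], y[:, None])
    return DoseMap2D(values, pitch, origin)


def _default_marks(shape: tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    inset = max(5, min(ny, nx) // 20)
    return np.array(
        [
            [inset, inset],
            [nx - 1 - inset, inset],
            [inset, ny - 1 - inset],
        ],
        dtype=float,
    )


def render_film_scan(
    dose: DoseMap2D,
    curve: CalibrationCurve,
    od_pre: float = 0.25,
    noise_sd: float = 0.0,
    dust_density: float = 0.0,
    seed: int | None = None,
) -> tuple[FilmScan, FilmScan]:
    """Invert the film-dosimetry model to produce pre/post scans.

    The post-exposure pixel value follows
    ``PV = 2**16 * 10**-(od_pre + dOD(D) + noise)`` where ``dOD(D)`` is
    the numerical inverse of the calibration polynomial.  Noise is
    additive Gaussian in OD space; dust specks are isolated high-OD
    pixels (salt noise in PV space), the artefact that the 30x30 median
    filter in the analysis pipeline is there to remove.

    Returns ``(pre, post)`` scans at the dose map's pitch, with matching
    corner fiducial marks.
    """
    lo, hi = curve.valid_dose_range
    if dose.values.max() > hi:
        raise ValueError("outside calibration range")
    rng = np.random.default_rng(seed)
    dpi = 25.4 / dose.pitch
    net_od = curve.net_od(dose.values)
    marks = _default_marks(dose.values.shape)

    scans = []
    for od_map in (np.full_like(net_od, od_pre), od_pre + net_od):
        od = od_map.copy()
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=od.shape)
        pv = PV_FULL_SCALE * 10.0 ** (-od)
        if dust_density > 0:
            speck = rng.random(pv.shape) < dust_density
            pv = np.where(speck, pv * 10.0 ** (-DUST_OD), pv)
        scans.append(FilmScan(pv, dpi=dpi, marks=marks.copy()))
    return scans[0], scans[1]


def sample_profiles(
    dose: DoseMap2D,
    n_directions: int = 2,
    step: float = 0.5,
    detector_fwhm: float = 0.0,
) -> list[RadialProfile]:
    """Scan the map through the beam centre in a star pattern.

    Each of the ``n_directions`` scan lines (equally spaced over 180
    degrees) passes through the beam centre and yields two half-profiles
    normalized to 1 at r = 0.  Detector blurring is applied as a 1D
    Gaussian convolution along the scan line before resampling at the
    requested step, emulating the volume of a scanning point detector.

    Parameters
    ----------
    n_directions : int
        Number of scan lines (>= 1); 2 gives in-plane + cross-plane,
        4 adds the diagonals.
    step : float
        Sample spacing along the profile, mm.
    detector_fwhm : float
        FWHM of the detector blur, mm.  0 disables blurring.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    if step <= 0:
        raise ValueError("step must be > 0")
    ny, nx = dose.values.shape
    r0, c0 = dose.origin
    fine = dose.pitch / 2.0
    sigma_mm = detector_fwhm / 2.3548200450309493

    profiles: list[RadialProfile] = []
    for k in range(n_directions):
        theta = np.pi * k / n_directions
        dr, dc = np.sin(theta), np.cos(theta)
        # longest |t| (mm) keeping both ends of the line inside the grid
        tmax = np.inf
        for d, o, nn in ((dr, r0, ny), (dc, c0, nx)):
            if abs(d) > 1e-12:
                tmax = min(tmax, (nn - 1 - o) * dose.pitch / abs(d), o * dose.pitch / abs(d))
        t = np.arange(-tmax, tmax + fine / 2, fine)
        rows = r0 + t / dose.pitch * dr
        cols = c0 + t / dose.pitch * dc
        line = ndimage.map_coordinates(dose.values, [rows, cols], order=1, mode="nearest")
        if sigma_mm > 0:
            line = ndimage.gaussian_filter1d(line, sigma_mm / fine, mode="nearest")
        rmax_mm = tmax - 4.0 * sigma_mm
        r_out = np.arange(0.0, rmax_mm + step / 2, step)
        for sign, tag in ((1.0, "+"), (-1.0, "-")):
            vals = np.interp(sign * r_out, t, line)
            vals = vals / vals[0]
            label = f"theta={np.degrees(theta):.0f}deg{tag}"
            profiles.append(RadialProfile(r_out / 10.0, vals, label=label))
    return profiles


def simulate_voltage_series(
    m_sat: float,
    recomb_slope: float,
    voltages,
    mu: float = 100.0,
    temperature: float = 20.0,
    pressure: float = 101.325,
) -> list[ChamberReading]:
    """Charge vs bias voltage with general-recombination losses.

    The collected charge follows ``M(U) = m_sat / (1 + recomb_slope/U)``
    so that 1/M is exactly linear in 1/U -- the ion-chamber regime that
    a Jaffe plot extrapolates.  The saturation correction at operating
    voltage U is then ``k_s = 1 + recomb_slope/U`` exactly.

    Parameters
    ----------
    m_sat : float
        Saturation charge (infinite-voltage limit), nC.
    recomb_slope : float
        Recombination slope, V (charge lost per unit 1/U).
    voltages : sequence of float
        Positive bias voltages, V.
    """
    voltages = np.asarray(voltages, dtype=float)
    if np.any(voltages <= 0):
        raise ValueError("all voltages must be > 0")
    return [
        ChamberReading(
            charge=m_sat / (1.0 + recomb_slope / u),
            mu=mu,
            bias=u,
            polarity="pos",
            temperature=temperature,
            pressure=pressure,
        )
        for u in voltages
    ]


def simulate_chamber_reading(
    dap_true: float,
    n_true: float,
    temperature: float = 20.0,
    pressure: float = 101.325,
    ks_true: float = 1.0,
    kpol_true: float = 1.0,
    noise_pct: float = 0.0,
    mu: float = 100.0,
    seed: int | None = None,
) -> ChamberReading:
    """Raw chamber reading consistent with a known DAP_w and coefficient.

    Inverts the calibration relation: the air-density-corrected charge
    is ``dap_true / (n_true * ks_true * kpol_true)`` and the raw charge
    is that divided by k_TP at the given temperature/pressure, with
    optional relative Gaussian noise (``noise_pct`` in percent,
    emulating electrometer/linac reproducibility).

    Parameters
    ----------
    dap_true : float
        True dose-area product delivered, mGy cm^2 (total, not per MU).
    n_true : float
        True calibration coefficient, mGy cm^-2 nC^-1.
    """
    if n_true <= 0:
        raise ValueError("n_true must be > 0")
    rng = np.random.default_rng(seed)
    m_cor = dap_true / (n_true * ks_true * kpol_true)
    raw = m_cor / k_tp(temperature, pressure)
    if noise_pct > 0:
        raw *= 1.0 + rng.normal(0.0, noise_pct / 100.0)
    return ChamberReading(
        charge=raw,
        mu=mu,
        bias=400.0,
        polarity="pos",
        temperature=temperature,
        pressure=pressure,
    )


def lac_scan(dose: DoseMap2D, offsets, r_lac: float = 4.08):
    """Scan a large-area chamber laterally across a field.

    The chamber signal at each lateral ``offset`` (cm, along x) is the
    mean dose over its sensitive disc of radius ``r_lac`` (cm) centred at
    that offset, normalized to the on-axis position.  Emulates the
    lateral setup-tolerance measurement for fields smaller than the
    chamber.

    Returns a list of ``(offset, relative signal)`` pairs.
    """
    offsets = np.asarray(offsets, dtype=float)
    y, x = dose.coords_cm()
    signals = []
    for off in np.concatenate(([0.0], offsets)):
        rr = np.hypot(y[:, None], (x - off)[None, :])
        if (
            off - r_lac < x[0] or off + r_lac > x[-1]
            or -r_lac < y[0] or r_lac > y[-1]
        ):
            raise ValueError("disc exits grid")
        signals.append(dose.values[rr <= r_lac].mean())
    ref = signals[0]
    return [(float(o), s / ref) for o, s in zip(offsets, signals[1:])]


def make_chamber_volume(
    body_thickness: float = 12.75,
    gap_thickness: float = 2.0,
    gap_radius: float = 8.0,
    body_value: float = 2200.0,
    noise_sd: float = 0.0,
    voxel_size: float = 0.082,
    lateral_margin: float = 1.5,
    axial_margin: float = 2.0,
    gap_tilt: float = 0.0,
    axial_offset: float = 0.0,
    seed: int | None = None,
) -> VoxelVolume:
    """MicroCT-like volume of a plane-parallel chamber's air gap.

    A uniform slab (the PMMA body, value ``body_value`` attenuation
    units) of ``body_thickness`` mm contains a coaxial air gap of
    ``gap_thickness`` mm within ``gap_radius`` mm of the axis.  Edges are
    anti-aliased by partial-volume weighting so that sub-voxel edge
    positions are recoverable by 50%-threshold interpolation.  Air is 0.

    Parameters
    ----------
    gap_tilt : float
        Axial displacement of the gap mid-plane per mm of lateral x
        offset (mm/mm); non-zero values emulate non-parallel electrodes.
    axial_offset : float
        Sub-voxel shift of the whole slab along the axial direction, mm;
        used to probe recovery bias at arbitrary edge phases.
    noise_sd : float
        SD of additive Gaussian noise, attenuation units.
    """
    if gap_thickness < 0 or gap_thickness > body_thickness:
        raise ValueError("gap must lie inside the body")
    rng = np.random.default_rng(seed)
    nxy = int(round(2 * (gap_radius + lateral_margin) / voxel_size))
    nz = int(round((body_thickness + 2 * axial_margin) / voxel_size))
    zc = (np.arange(nz) + 0.5) * voxel_size
    xy = (np.arange(nxy) + 0.5) * voxel_size - (nxy * voxel_size) / 2.0

    z_lo = axial_margin + axial_offset
    z_hi = z_lo + body_thickness
    z_mid = (z_lo + z_hi) / 2.0

    # fraction of each voxel along z covered by the interval [a, b]
    def frac(a, b):
        lo = np.maximum(zc - voxel_size / 2.0, a)
        hi = np.minimum(zc + voxel_size / 2.0, b)
        return np.clip(hi - lo, 0.0, None) / voxel_size

    body_frac = frac(z_lo, z_hi)  # (nz,)
    rr = np.hypot(xy[:, None], xy[None, :])  # (ny, nx)
    in_gap = rr <= gap_radius

    values = np.empty((nz, nxy, nxy), dtype=float)
    values[:] = body_value * body_frac[:, None, None]
    if gap_thickness > 0:
        # gap interval can tilt with x; compute per x column
        for j, xv in enumerate(xy):
            g_mid = z_mid + gap_tilt * xv
            gap_frac = frac(g_mid - gap_thickness / 2.0, g_mid + gap_thickness / 2.0)
            col = body_value * (body_frac - gap_frac)
            mask = in_gap[:, j]
            values[:, mask, j] = col[:, None]
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    return VoxelVolume(values, voxel_size)
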