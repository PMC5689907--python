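"""Radiochromic-film dosimetry: scans -> calibrated 2D dose maps.

The analysis chain mirrors standard net-optical-density (net-OD) film
protocols for EBT3-type film scanned on a flatbed transmission scanner:

1. median-filter the 16-bit pixel values (30x30 window) to remove dust
   and foreign particles,
2. convert pixel values to optical density, OD = -log10(PV / 2**16),
3. rigidly co-register the pre-exposure scan onto the post-exposure
   scan using fiducial marks and subtract to obtain net-OD,
4. convert net-OD to dose with a polynomial calibration curve,
5. optionally combine a low-MU and a high-MU exposure of the same field
   (the high map divided by the MU ratio; pointwise maximum) so that
   both the in-field and the low out-of-field dose fall within the
   film's dynamic range,
6. normalize to the central axis for a relative dose distribution.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import EuclideanTransform, warp

from .types import PV_FULL_SCALE, CalibrationCurve, DoseMap2D, FilmScan, ODMap

__all__ = [
    "EBT3_CURVE",
    "pixel_to_od",
    "median_filter",
    "register_and_net_od",
    "od_to_dose",
    "combine_exposures",
    "normalize_to_cax",
    "find_beam_center",
    "film_to_dose",
]

#: Net-OD -> dose (Gy) calibration polynomial for the film lot used in
#: the bundled reference dataset (5th-order fit, valid 0 to 2.8 Gy).
EBT3_CURVE = CalibrationCurve(
    [0.0, 5.29081, 62.94971, -295.56757, 908.96498, -981.35406],
    valid_dose_range=(0.0, 2.8),
)


def pixel_to_od(scan: FilmScan) -> ODMap:
    """Convert 16-bit pixel values to optical density.

    OD = -log10(PV / 2**16); a zero pixel value (fully opaque) has no
    finite OD and is rejected.
    """
    if np.any(scan.pv <= 0):
        raise ValueError("saturated/black pixel")
    return ODMap(-np.log10(scan.pv / PV_FULL_SCALE), pitch=scan.pitch)


def median_filter(map_, window: int = 30):
    """Median-filter an OD map, dose map or raw array.

    Uses reflect padding at the edges.  The default 30x30 window is wide
    enough to suppress isolated dust specks without shifting smooth dose
    gradients appreciably.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(map_, ODMap):
        return ODMap(ndimage.median_filter(map_.od, size=window, mode="reflect"), map_.pitch)
    if isinstance(map_, DoseMap2D):
        return DoseMap2D(
            ndimage.median_filter(map_.values, size=window, mode="reflect"),
            map_.pitch,
            map_.origin,
        )
    return ndimage.median_filter(np.asarray(map_, dtype=float), size=window, mode="reflect")


def register_and_net_od(
    pre: ODMap,
    post: ODMap,
    marks_pre: np.ndarray,
    marks_post: np.ndarray,
    order: int = 1,
    clamp_negative: bool = True,
) -> ODMap:
    """Co-register the pre-exposure OD map onto the post-exposure grid
    and subtract: net-OD = OD_post - OD_pre.

    A rigid (translation + rotation) transform is estimated from >= 2
    fiducial mark correspondences given in ``(x, y)`` pixel order.  Film
    in a flatbed scanner cannot change scale, so similarity/affine terms
    are deliberately excluded.  Slightly negative net-OD from noise is
    clamped to zero by default (the calibration curve is undefined below
    zero); the number of clamped pixels is recorded on the returned
    map's ``n_clamped`` attribute.
    """
    marks_pre = np.asarray(marks_pre, dtype=float).reshape(-1, 2)
    marks_post = np.asarray(marks_post, dtype=float).reshape(-1, 2)
    if marks_pre.shape != marks_post.shape or len(marks_pre) < 2:
        raise ValueError("need >= 2 matching fiducial mark pairs")
    if hasattr(EuclideanTransform, "from_estimate"):
        tform = EuclideanTransform.from_estimate(marks_pre, marks_post)
        if not tform:
            raise ValueError("fiducial registration failed")
    else:  # scikit-image < 0.26
        tform = EuclideanTransform()
        if not tform.estimate(marks_pre, marks_post):
            raise ValueError("fiducial registration failed")
    # tform maps pre (x, y) -> post (x, y); warp needs output -> input.
    pre_on_post = warp(
        pre.od, inverse_map=tform.inverse, order=order, mode="edge",
        preserve_range=True,
    )
    net = post.od - pre_on_post
    n_clamped = 0
    if clamp_negative:
        n_clamped = int(np.count_nonzero(net < 0))
        net = np.clip(net, 0.0, None)
    out = ODMap(net, pitch=post.pitch)
    out.n_clamped = n_clamped
    return out


def od_to_dose(net: ODMap, curve: CalibrationCurve = EBT3_CURVE,
               clamp: bool = False) -> DoseMap2D:
    """Convert net-OD to absorbed dose (Gy) through the calibration
    polynomial.

    Net-OD beyond the curve's fitted domain raises (``extrapolation
    refused``) unless ``clamp`` is set, in which case values are clipped
    to the domain.
    """
    od = net.od
    if od.min() < -1e-12 or od.max() > curve.max_net_od + 1e-12:
        if not clamp:
            raise ValueError("extrapolation refused: net-OD outside curve domain")
        od = np.clip(od, 0.0, curve.max_net_od)
    dose = curve.dose(np.clip(od, 0.0, None))
    # origin unknown at this stage; centre of grid as placeholder
    ny, nx = dose.shape
    return DoseMap2D(np.clip(dose, 0.0, None), net.pitch, ((ny - 1) / 2.0, (nx - 1) / 2.0))


def find_beam_center(dose: DoseMap2D, smooth_window: int = 5) -> tuple[float, float]:
    """Beam centre as the intensity centroid of the above-50% region.

    The map is lightly median-filtered first so that dust or noise does
    not bias the 50% threshold; for symmetric fields the centroid
    coincides with the penumbra midpoint.
    """
    sm = ndimage.median_filter(dose.values, size=smooth_window, mode="reflect")
    peak = sm.max()
    if peak <= 0:
        raise ValueError("beam center not found")
    mask = sm >= 0.5 * peak
    w = np.where(mask, sm, 0.0)
    total = w.sum()
    rows = np.arange(dose.values.shape[0])
    cols = np.arange(dose.values.shape[1])
    return (
        float((w.sum(axis=1) * rows).sum() / total),
        float((w.sum(axis=0) * cols).sum() / total),
    )


def combine_exposures(low: DoseMap2D, high: DoseMap2D, mu_ratio: float) -> DoseMap2D:
    """Combine a low-MU and a high-MU exposure of the same field.

    The high-exposure map is divided by ``mu_ratio``, translated so the
    two beam centres coincide, and the pointwise maximum is taken: the
    low exposure provides the (unsaturated) in-field dose, the high
    exposure the out-of-field dose that would otherwise sit below the
    film's sensitivity floor.  Output is on the low map's grid with its
    origin set to the located beam centre.
    """
    if mu_ratio < 1:
        raise ValueError("mu_ratio must be >= 1")
    c_low = find_beam_center(low)
    c_high = find_beam_center(high)
    shift = (c_low[0] - c_high[0], c_low[1] - c_high[1])
    high_aligned = ndimage.shift(high.values / mu_ratio, shift, order=1, mode="nearest")
    combined = np.maximum(low.values, high_aligned)
    return DoseMap2D(combined, low.pitch, c_low)


def normalize_to_cax(dose: DoseMap2D, disc_radius_mm: float = 2.0) -> DoseMap2D:
    """Divide by the mean dose over a small central disc to obtain the
    relative dose distribution R(x, y) with R = 1 on the central axis."""
    center = find_beam_center(dose)
    y = (np.arange(dose.values.shape[0]) - center[0]) * dose.pitch
    x = (np.arange(dose.values.shape[1]) - center[1]) * dose.pitch
    rr = np.hypot(y[:, None], x[None, :])
    disc = rr <= disc_radius_mm
    cax = dose.values[disc].mean()
    if cax <= 0:
        raise ValueError("zero central-axis dose")
    return DoseMap2D(dose.values / cax, dose.pitch, center)


def film_to_dose(
    pre: FilmScan,
    post: FilmScan,
    curve: CalibrationCurve = EBT3_CURVE,
    window: int = 30,
    clamp: bool = False,
) -> DoseMap2D:
    """Full single-exposure pipeline: scans -> dose map (Gy).

    Median filter in pixel-value space, OD conversion, mark-based
    registration, net-OD, calibration curve.
    """
    pre_f = FilmScan(median_filter(pre.pv, window), pre.dpi, pre.marks)
    post_f = FilmScan(median_filter(post.pv, window), post.dpi, post.marks)
    net = register_and_net_od(
        pixel_to_od(pre_f), pixel_to_od(post_f), pre_f.marks, post_f.marks
    )
    return od_to_dose(net, curve, clamp=clamp)
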