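"""Layer-boundary detection, noise estimation, motion correction and registration.

The pipeline needs exactly two surfaces: the internal limiting membrane (ILM),
the bright vitreoretinal interface that serves both as the anatomical reference
for the nerve-fiber-layer slabs and as the polarization reference for corneal
compensation, and the retinal pigment epithelium (RPE), the bright outer-retina
band that anchors the scleral evaluation slab. Full multi-layer retinal
segmentation is deliberately out of scope; the RNFL posterior border in
particular loses contrast at high IOP and is not segmented.

Surfaces are stored in axial *pixels* as floats (subpixel positions), 0-based
and increasing with depth; conversion to micrometres goes through the volume
geometry. Both detectors refine the boundary to the half-rise point of the
local intensity edge, which is unbiased on a partial-volume sampled step edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ReflectivityVolume, VolumeGeometry, median_filter_db, _nanmedian2d
from .errors import ConfigurationError, InvalidInputError, RegistrationError, SegmentationError


def _despike(pos: np.ndarray, size: int, threshold_px: float = 10.0) -> np.ndarray:
    """Replace isolated detection failures by the local 2D median.

    Subpixel positions that deviate from their ``size x size`` neighbourhood
    median by more than ``threshold_px`` are treated as spikes (e.g. an RPE
    candidate jumping ~20 px onto the bright sclera); everything else keeps
    its raw subpixel value, so smooth anatomy — the ONH pit apex, the steep
    pit wall at the canal rim — is preserved. The threshold sits well above
    the surface relief across one window on those slopes and well below the
    layer-confusion distances that actual failures produce.
    """
    med = _nanmedian2d(pos, size)
    spike = np.isfinite(pos) & np.isfinite(med) & (np.abs(pos - med) > threshold_px)
    return np.where(spike, med, pos)


@dataclass
class Surface:
    """Subpixel axial position of a layer boundary per transverse location.

    ``z_position[x, y]`` in pixels, NaN where undetected. ``registered`` is set
    once the surface has been globally aligned to a baseline acquisition.
    """

    z_position: np.ndarray
    geometry: VolumeGeometry
    registered: bool = False

    def __post_init__(self) -> None:
        self.z_position = np.asarray(self.z_position, dtype=float)
        if self.z_position.shape != (self.geometry.n_x, self.geometry.n_y):
            raise InvalidInputError("surface shape must be (n_x, n_y)")
        finite = self.z_position[np.isfinite(self.z_position)]
        if finite.size and (finite.min() < 0 or finite.max() >= self.geometry.n_z):
            raise InvalidInputError("surface positions must lie within [0, n_z)")

    def to_um(self) -> np.ndarray:
        return self.z_position * self.geometry.axial_pitch

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.z_position)))


@dataclass
class NoiseEstimate:
    """Average noise floor of a reflectivity volume, in dB."""

    mean_floor_db: float
    per_bscan_floor_db: np.ndarray = field(default_factory=lambda: np.array([]))
    n_voxels: int = 0


def estimate_noise_floor(
    refl: ReflectivityVolume,
    ilm: Surface | None = None,
    margin_px: int = 5,
    top_rows: int = 10,
) -> NoiseEstimate:
    """Estimate the noise floor from the signal-free vitreous.

    The vitreous produces no backscatter, so samples above the ILM (ending
    ``margin_px`` above it, to stay clear of the edge) measure the system noise
    floor. Without an ILM the top ``top_rows`` samples of every A-scan are
    used. The floor is the mean of the dB intensity over that region.
    """
    db = refl.db()
    n_z = db.shape[0]
    if ilm is None:
        region = db[: min(top_rows, n_z)]
        mask = np.ones(region.shape, dtype=bool)
    else:
        limit = np.nan_to_num(ilm.z_position - margin_px, nan=0.0)
        z = np.arange(n_z)[:, None, None]
        mask = z < np.maximum(limit, 0)[None, :, :]
        region = db

    vals = region[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        raise ConfigurationError(
            "no usable signal-free region above the ILM to estimate the noise floor"
        )
    if ilm is None:
        per_b = np.nanmean(np.where(np.isfinite(region), region, np.nan), axis=(0, 1))
    else:
        masked = np.where(mask & np.isfinite(db), db, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_b = np.nanmean(masked, axis=(0, 1))
    return NoiseEstimate(float(vals.mean()), np.asarray(per_b), int(vals.size))


def segment_ilm(
    refl: ReflectivityVolume,
    noise: NoiseEstimate,
    k_db: float = 6.0,
    consecutive: int = 3,
    max_nan_fraction: float = 0.5,
    db_filtered: np.ndarray | None = None,
) -> Surface:
    """Detect the ILM as the first sustained rise above the noise floor.

    Per A-scan, the first axial sample where the axially median-filtered dB
    intensity exceeds ``floor + k_db`` for ``consecutive`` samples marks the
    edge; the position is refined to the half-rise point between the local
    floor and the retinal plateau by linear interpolation in linear intensity,
    then median-filtered 5x5 transversely.
    """
    dbf = median_filter_db(refl.db()) if db_filtered is None else db_filtered
    n_z, n_x, n_y = dbf.shape
    thr = noise.mean_floor_db + k_db

    above = dbf >= thr
    run = above.copy()
    for k in range(1, consecutive):
        shifted = np.zeros_like(above)
        shifted[:-k] = above[k:]
        run &= shifted
    found = run.any(axis=0)
    i0 = np.argmax(run, axis=0)

    lin = 10.0 ** (dbf / 10.0)
    floor_lin = 10.0 ** (noise.mean_floor_db / 10.0)

    # retinal plateau just below the edge
    offs = np.arange(1, 6)
    idx = np.clip(i0[None] + offs[:, None, None], 0, n_z - 1)
    plateau = np.median(np.take_along_axis(lin, idx, axis=0), axis=0)
    half = 0.5 * (floor_lin + plateau)

    # half-rise crossing within +-2 samples of the threshold crossing
    rel = np.arange(-2, 3)
    widx = np.clip(i0[None] + rel[:, None, None], 0, n_z - 1)
    v = np.take_along_axis(lin, widx, axis=0)
    ge = v >= half[None]
    j = np.argmax(ge, axis=0)
    has_cross = ge.any(axis=0)

    vj = np.take_along_axis(v, j[None], axis=0)[0]
    vprev = np.take_along_axis(v, np.maximum(j - 1, 0)[None], axis=0)[0]
    denom = vj - vprev
    frac = np.where(denom > 0, (half - vprev) / np.where(denom > 0, denom, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    pos = i0 + (j - 2) - 1 + frac
    pos = np.where(j == 0, i0 + rel[0], pos)

    pos = np.where(found & has_cross, pos, np.nan)
    pos = np.clip(pos, 0, n_z - 1)
    pos = _despike(pos, 5)
    pos[~(found & has_cross)] = np.nan

    nan_frac = float(np.mean(~np.isfinite(pos)))
    if nan_frac > max_nan_fraction:
        raise SegmentationError(
            f"ILM undetected on {nan_frac:.0%} of A-scans (limit {max_nan_fraction:.0%})"
        )
    return Surface(pos, refl.geometry)


def segment_rpe(
    refl: ReflectivityVolume,
    ilm: Surface,
    window_px: tuple[int, int] = (50, 150),
    prominence_db: float = 6.0,
    db_filtered: np.ndarray | None = None,
) -> Surface:
    """Detect the RPE as the dominant bright band below the ILM.

    The search window ``[ilm + window_px[0], ilm + window_px[1]]`` must lie
    inside the volume. The brightest sample in the window is accepted only if
    it stands ``prominence_db`` above the window median (A-scans through the
    optic nerve canal have no RPE and give NaN), then refined to the anterior
    half-rise edge of the peak.
    """
    dbf = median_filter_db(refl.db()) if db_filtered is None else db_filtered
    n_z = dbf.shape[0]
    w0, w1 = window_px
    if not (0 <= w0 < w1):
        raise ConfigurationError("invalid RPE search window")
    finite_ilm = ilm.z_position[np.isfinite(ilm.z_position)]
    if finite_ilm.size == 0:
        raise ConfigurationError("ILM surface is empty")
    if int(np.round(np.nanmax(ilm.z_position))) + w1 >= n_z:
        raise ConfigurationError("RPE search window exceeds the volume depth")

    base = np.where(np.isfinite(ilm.z_position), np.round(ilm.z_position), 0).astype(int)
    offs = np.arange(w0, w1 + 1)
    idx = base[None] + offs[:, None, None]
    win = np.take_along_axis(dbf, idx, axis=0)  # [L, x, y]

    i_pk = np.argmax(win, axis=0)
    peak = np.max(win, axis=0)
    bg = np.median(win, axis=0)
    prominent = (peak - bg) >= prominence_db

    lin = 10.0 ** (win / 10.0)
    half = 0.5 * (10.0 ** (bg / 10.0) + 10.0 ** (peak / 10.0))
    ge = (lin >= half[None]) & (offs[:, None, None] - w0 <= i_pk[None])
    j = np.argmax(ge, axis=0)
    has = ge.any(axis=0)

    vj = np.take_along_axis(lin, j[None], axis=0)[0]
    vprev = np.take_along_axis(lin, np.maximum(j - 1, 0)[None], axis=0)[0]
    denom = vj - vprev
    frac = np.where(denom > 0, (half - vprev) / np.where(denom > 0, denom, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    pos = base + w0 + j - 1 + frac
    pos = np.where(j == 0, base + float(w0), pos)

    ok = prominent & has & np.isfinite(ilm.z_position)
    pos = np.where(ok, pos, np.nan)
    pos = _despike(pos, 5)
    pos[~ok] = np.nan
    pos = np.clip(pos, 0, n_z - 1)
    return Surface(pos, refl.geometry)


def axial_align_bscans(
    surface: Surface,
    exclude_center: tuple[float, float] | None = None,
    exclude_radius_um: float | None = None,
) -> tuple[Surface, np.ndarray]:
    """Correct per-B-scan axial motion against a smooth reference.

    Bulk axial motion between successive B-scans appears as a jagged offset of
    the whole B-scan. The per-B-scan offset is the median deviation of the
    surface from a 2nd-order polynomial fitted across the slow axis; offsets
    are subtracted and returned, so the correction is invertible. A constant
    global offset is deliberately preserved (inter-volume alignment is handled
    by :func:`register_to_baseline`).

    When ``exclude_center``/``exclude_radius_um`` are given, pixels within
    that transverse radius are ignored by the offset estimator, so genuine
    IOP-induced ONH deformation is not aliased into per-B-scan "motion".
    """
    z = surface.z_position
    n_y = z.shape[1]
    if n_y < 3:
        raise InvalidInputError("axial alignment needs at least 3 B-scans")
    z_est = z
    if exclude_center is not None and exclude_radius_um is not None:
        g = surface.geometry
        x = np.arange(g.n_x)[:, None] * g.lateral_pitch_x
        yy = np.arange(g.n_y)[None, :] * g.lateral_pitch_y
        r = np.hypot(x - exclude_center[0], yy - exclude_center[1])
        z_est = np.where(r >= exclude_radius_um, z, np.nan)
        if not np.any(np.isfinite(z_est)):
            z_est = z
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = np.nanmedian(z_est, axis=0)  # per-B-scan representative position
    ys = np.arange(n_y, dtype=float)
    ok = np.isfinite(s)
    if ok.sum() < 3:
        raise SegmentationError("too few B-scans with a detected surface")
    coeff = np.polyfit(ys[ok], s[ok], deg=2)
    ref = np.polyval(coeff, ys)
    shifts = s - ref
    # carry shifts over all-NaN B-scans from the nearest valid neighbour
    if not ok.all():
        shifts[~ok] = np.interp(ys[~ok], ys[ok], shifts[ok])
    aligned = z - shifts[None, :]
    out = Surface(np.clip(aligned, 0, surface.geometry.n_z - 1), surface.geometry)
    out.z_position[~np.isfinite(z)] = np.nan
    return out, shifts


def register_to_baseline(current: Surface, baseline: Surface, exclusion) -> Surface:
    """Align a follow-up surface to the baseline by one global axial shift.

    The shift is the median of (current - baseline) over the periphery outside
    the depression-evaluation annulus, so IOP-induced central deformation does
    not bias it. The returned surface is flagged ``registered``.
    """
    if current.z_position.shape != baseline.z_position.shape:
        raise InvalidInputError("surfaces must share one grid")
    g = current.geometry
    cx, cy = exclusion.center
    x = np.arange(g.n_x)[:, None] * g.lateral_pitch_x
    y = np.arange(g.n_y)[None, :] * g.lateral_pitch_y
    periphery = np.hypot(x - cx, y - cy) >= exclusion.outer_diameter / 2.0

    diff = current.z_position - baseline.z_position
    usable = periphery & np.isfinite(diff)
    if usable.sum() < 0.10 * periphery.sum():
        raise RegistrationError("less than 10% of the periphery overlaps between surfaces")
    shift = float(np.median(diff[usable]))
    out = Surface(
        np.clip(current.z_position - shift, 0, g.n_z - 1), g, registered=True
    )
    out.z_position[~np.isfinite(current.z_position)] = np.nan
    return out


def detect_onh_center(
    ilm: Surface,
    sigma_um: float = 50.0,
    deepest_fraction: float = 0.05,
    min_depth_range_px: float = 5.0,
    override: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Locate the optic nerve head as the centroid of the deepest ILM pixels.

    The ILM is Gaussian-smoothed (sigma in um) and the centroid of its deepest
    ``deepest_fraction`` of pixels is returned in micrometres. Surfaces with no
    discernible pit (depth range below ``min_depth_range_px``) fall back to the
    volume centre with a warning. An explicit ``override`` is returned verbatim.
    """
    if override is not None:
        return (float(override[0]), float(override[1]))
    g = ilm.geometry
    z = ilm.z_position
    filled = np.where(np.isfinite(z), z, np.nanmedian(z))
    sigma_px = (sigma_um / g.lateral_pitch_x, sigma_um / g.lateral_pitch_y)
    smooth = ndimage.gaussian_filter(filled, sigma=sigma_px, mode="nearest")

    depth_range = float(np.nanmax(smooth) - np.nanmin(smooth))
    centre = (g.n_x / 2.0 * g.lateral_pitch_x, g.n_y / 2.0 * g.lateral_pitch_y)
    if depth_range < min_depth_range_px:
        warnings.warn(
            "no ONH pit detected (flat ILM); falling back to the volume centre",
            stacklevel=2,
        )
        return centre
    thr = np.quantile(smooth, 1.0 - deepest_fraction)
    sel = smooth >= thr
    ix, iy = np.nonzero(sel)
    return (
        float(ix.mean() * g.lateral_pitch_x),
        float(iy.mean() * g.lateral_pitch_y),
    )
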