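"""Peripapillary en face metrics: ONH depression, RNFL/retina reflectivity
ratio, RNFL retardation and scleral birefringence.

All four metrics are evaluated in ONH-centred annuli:

* ONH depression — 300 um inner / 700 um outer diameter; the mean posterior
  displacement of the ILM relative to the baseline acquisition, in um.
* RNFL/retina reflectivity ratio — 550/870 um; ratio of mean linear intensity
  in the 20 px slab at the ILM to the slab from ILM+20 px down to the RPE.
* RNFL retardation — 550/870 um; mean compensated retardation in the slab
  [ILM+20 px, ILM+95 px), restricted to voxels more than 3 dB above the noise
  floor.
* Scleral birefringence — 550/870 um; per A-scan OLS slope of compensated
  retardation over depth in the slab [RPE+20 px, RPE+60 px), in deg/um. The
  shallow 40 px slab keeps the cumulative retardation below the 90 deg wrap.

Annulus sizes are *diameters*, exactly as printed in the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import ReflectivityVolume, RetardationVolume, VolumeGeometry
from .errors import ConfigurationError, InvalidInputError
from .segment import NoiseEstimate, Surface

VALID_FRACTION_MIN_DEFAULT = 0.10
SNR_THRESHOLD_DB = 3.0  # voxel validity margin above the noise floor


@dataclass(frozen=True)
class AnnulusSpec:
    """ONH-centred ring; ``center`` in um, diameters in um."""

    center: tuple[float, float]
    inner_diameter: float
    outer_diameter: float

    def __post_init__(self) -> None:
        if not (0 < self.inner_diameter < self.outer_diameter):
            raise ConfigurationError("need 0 < inner_diameter < outer_diameter")


@dataclass(frozen=True)
class SlabSpec:
    """Axial slab relative to a reference surface.

    ``thickness_px=None`` means "down to the RPE" (used for the posterior
    retina slab of the reflectivity ratio).
    """

    reference: Literal["ILM", "RPE"]
    offset_px: int
    thickness_px: int | None

    def __post_init__(self) -> None:
        if self.offset_px < 0:
            raise ConfigurationError("slab offset must be >= 0")
        if self.thickness_px is not None and self.thickness_px < 1:
            raise ConfigurationError("slab thickness must be >= 1 px")

    def thickness_um(self, geometry: VolumeGeometry) -> float:
        if self.thickness_px is None:
            raise ConfigurationError("slab extends to the RPE; thickness is per A-scan")
        return self.thickness_px * geometry.axial_pitch


# protocol defaults
RNFL_REFLECTIVITY_SLAB = SlabSpec("ILM", 0, 20)
RETINA_REFLECTIVITY_SLAB = SlabSpec("ILM", 20, None)
RNFL_RETARDATION_SLAB = SlabSpec("ILM", 20, 75)
SCLERAL_SLAB = SlabSpec("RPE", 20, 40)
DEPRESSION_ANNULUS_DIAMETERS = (300.0, 700.0)
METRIC_ANNULUS_DIAMETERS = (550.0, 870.0)


@dataclass
class EnFaceMap:
    """2D transverse map of a scalar metric; NaN exactly where invalid."""

    values: np.ndarray
    valid_mask: np.ndarray
    geometry: VolumeGeometry
    units: str = ""
    annulus: AnnulusSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool) & np.isfinite(self.values)
        self.values = np.where(self.valid_mask, self.values, np.nan)


@dataclass
class MetricResult:
    mean: float
    sd: float
    n_valid: int
    excluded: bool = False
    exclusion_reason: str = ""


def annulus_mask(spec: AnnulusSpec, geometry: VolumeGeometry) -> np.ndarray:
    """Boolean [n_x, n_y] mask of pixels whose centre lies inside the annulus.

    Pixel centres are at ``(ix * lateral_pitch_x, iy * lateral_pitch_y)``.
    A pixel is included iff ``inner_diameter/2 <= r < outer_diameter/2``.
    """
    cx, cy = spec.center
    r_out = spec.outer_diameter / 2.0
    # reject only annuli with no possible overlap with the field
    max_x = (geometry.n_x - 1) * geometry.lateral_pitch_x
    max_y = (geometry.n_y - 1) * geometry.lateral_pitch_y
    if cx + r_out < 0 or cy + r_out < 0 or cx - r_out > max_x or cy - r_out > max_y:
        raise ConfigurationError("annulus lies entirely outside the field of view")
    x = np.arange(geometry.n_x)[:, None] * geometry.lateral_pitch_x
    y = np.arange(geometry.n_y)[None, :] * geometry.lateral_pitch_y
    r = np.hypot(x - cx, y - cy)
    return (r >= spec.inner_diameter / 2.0) & (r < r_out)


def annulus_average(
    emap: EnFaceMap,
    annulus: AnnulusSpec,
    valid_fraction_min: float = VALID_FRACTION_MIN_DEFAULT,
) -> MetricResult:
    """Mean/SD of the map over valid pixels inside the annulus.

    The result is flagged ``excluded`` when fewer than ``valid_fraction_min``
    of the annulus pixels carry a valid value (mirroring the dataset-exclusion
    rule for retardation maps starved of above-noise pixels).
    """
    mask = annulus_mask(annulus, emap.geometry)
    n_annulus = int(mask.sum())
    if n_annulus == 0:
        raise ConfigurationError("annulus contains no pixels on this grid")
    sel = mask & emap.valid_mask
    n_valid = int(sel.sum())
    if n_valid == 0:
        return MetricResult(np.nan, np.nan, 0, True, "no valid pixels in annulus")
    vals = emap.values[sel]
    excluded = n_valid / n_annulus < valid_fraction_min
    reason = (
        f"only {n_valid}/{n_annulus} annulus pixels valid" if excluded else ""
    )
    sd = float(np.std(vals, ddof=1)) if n_valid > 1 else 0.0
    return MetricResult(float(vals.mean()), sd, n_valid, excluded, reason)


def depression_map(current_ilm: Surface, baseline_ilm: Surface) -> EnFaceMap:
    """Posterior ILM displacement (um) of a registered follow-up vs baseline.

    Positive values mean posterior displacement (ONH cupping). The follow-up
    surface must have been registered to the baseline first.
    """
    if not current_ilm.registered:
        raise InvalidInputError(
            "depression requires the follow-up surface to be registered to baseline"
        )
    if current_ilm.z_position.shape != baseline_ilm.z_position.shape:
        raise InvalidInputError("surfaces must share one grid")
    g = current_ilm.geometry
    diff = (current_ilm.z_position - baseline_ilm.z_position) * g.axial_pitch
    return EnFaceMap(diff, np.isfinite(diff), g, units="um")


def _slab_bounds(ref: Surface, offset_px: int) -> np.ndarray:
    start = np.where(np.isfinite(ref.z_position), np.round(ref.z_position), -1)
    return (start + offset_px).astype(int)


def reflectivity_ratio_map(
    refl: ReflectivityVolume,
    ilm: Surface,
    rpe: Surface,
    rnfl_slab: SlabSpec = RNFL_REFLECTIVITY_SLAB,
    retina_slab: SlabSpec = RETINA_REFLECTIVITY_SLAB,
    min_retina_px: int = 20,
) -> EnFaceMap:
    """Per A-scan ratio of RNFL to posterior-retina mean linear intensity.

    Numerator: mean linear intensity in ``[ilm + offset, +thickness)``;
    denominator: mean from ``ilm + offset`` down to the RPE. A-scans without a
    detected RPE, or whose retina slab is thinner than ``min_retina_px``, give
    NaN. The ratio of linear means makes the metric invariant to global
    intensity rescaling.
    """
    if retina_slab.thickness_px is not None:
        raise ConfigurationError("the posterior-retina slab must extend to the RPE")
    lin = refl.linear_intensity
    n_z = lin.shape[0]
    z = np.arange(n_z)[:, None, None]

    s_num = _slab_bounds(ilm, rnfl_slab.offset_px)
    num_mask = (z >= s_num[None]) & (z < (s_num + rnfl_slab.thickness_px)[None])
    s_den = _slab_bounds(ilm, retina_slab.offset_px)
    e_den = _slab_bounds(rpe, 0)
    den_mask = (z >= s_den[None]) & (z < e_den[None])

    ok = (
        np.isfinite(ilm.z_position)
        & np.isfinite(rpe.z_position)
        & ((e_den - s_den) >= min_retina_px)
        & (s_num >= 0)
        & ((s_num + rnfl_slab.thickness_px) <= n_z)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (lin * num_mask).sum(axis=0) / np.maximum(num_mask.sum(axis=0), 1)
        den = (lin * den_mask).sum(axis=0) / np.maximum(den_mask.sum(axis=0), 1)
        ratio = np.where(ok & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    return EnFaceMap(ratio, np.isfinite(ratio), refl.geometry, units="ratio")


def rnfl_retardation(
    ret: RetardationVolume,
    refl: ReflectivityVolume,
    ilm: Surface,
    noise: NoiseEstimate,
    annulus: AnnulusSpec,
    slab: SlabSpec = RNFL_RETARDATION_SLAB,
    valid_fraction_min: float = VALID_FRACTION_MIN_DEFAULT,
    snr_threshold_db: float = SNR_THRESHOLD_DB,
) -> MetricResult:
    """Mean compensated retardation in the posterior-retina slab.

    Voxel-level average over the slab ``[ilm + offset, + thickness)`` within
    the annulus, restricted to voxels whose intensity exceeds the noise floor
    by ``snr_threshold_db``. The dataset is flagged excluded when fewer than
    ``valid_fraction_min`` of the annulus slab voxels pass the threshold.
    """
    if not ret.compensated:
        raise InvalidInputError("RNFL retardation requires corneal-compensated input")
    if slab.thickness_px is None:
        raise ConfigurationError("retardation slab needs a fixed thickness")
    delta = ret.retardation_deg
    n_z = delta.shape[0]
    z = np.arange(n_z)[:, None, None]
    start = _slab_bounds(ilm, slab.offset_px)
    in_slab = (
        (z >= start[None])
        & (z < (start + slab.thickness_px)[None])
        & (start >= 0)[None]
    )
    amask = annulus_mask(annulus, ret.geometry)
    in_slab &= amask[None]

    db = refl.db()
    valid = in_slab & (db > noise.mean_floor_db + snr_threshold_db) & np.isfinite(delta)
    n_total = int(in_slab.sum())
    n_valid = int(valid.sum())
    if n_total == 0:
        raise ConfigurationError("retardation slab is empty inside the annulus")
    if n_valid == 0:
        return MetricResult(np.nan, np.nan, 0, True, "no voxels above the noise threshold")
    vals = delta[valid]
    excluded = n_valid / n_total < valid_fraction_min
    reason = f"only {n_valid}/{n_total} slab voxels above threshold" if excluded else ""
    return MetricResult(
        float(vals.mean()),
        float(np.std(vals, ddof=1)) if n_valid > 1 else 0.0,
        n_valid,
        excluded,
        reason,
    )


def scleral_birefringence_map(
    ret: RetardationVolume,
    refl: ReflectivityVolume,
    rpe: Surface,
    noise: NoiseEstimate,
    slab: SlabSpec = SCLERAL_SLAB,
    min_valid_px: int = 10,
    snr_threshold_db: float = SNR_THRESHOLD_DB,
) -> EnFaceMap:
    """Effective scleral birefringence per A-scan, in deg/um.

    Assuming retardation rises linearly with depth in the sclera, the
    birefringence is the unweighted OLS slope of compensated retardation vs
    depth over the valid voxels (same 3 dB rule) of the slab
    ``[rpe + offset, + thickness)``, divided by the axial pitch. A-scans with
    fewer than ``min_valid_px`` valid voxels, or whose slab leaves the volume,
    give NaN. No unwrapping is applied (the shallow slab avoids the 90 deg
    wrap) and negative slopes are retained.
    """
    if not ret.compensated:
        raise InvalidInputError("scleral birefringence requires corneal-compensated input")
    if slab.thickness_px is None:
        raise ConfigurationError("scleral slab needs a fixed thickness")
    delta = ret.retardation_deg
    n_z = delta.shape[0]
    t = slab.thickness_px

    start = _slab_bounds(rpe, slab.offset_px)
    ok = np.isfinite(rpe.z_position) & (start >= 0) & (start + t <= n_z)
    start_safe = np.where(ok, start, 0)

    offs = np.arange(t)
    idx = start_safe[None] + offs[:, None, None]
    y = np.take_along_axis(delta, idx, axis=0)  # [t, x, y]
    db = np.take_along_axis(refl.db(), idx, axis=0)
    w = (db > noise.mean_floor_db + snr_threshold_db) & np.isfinite(y) & ok[None]

    k = offs[:, None, None].astype(float)
    n = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sk = np.where(w, k, 0.0).sum(axis=0)
        sy = np.where(w, y, 0.0).sum(axis=0)
        skk = np.where(w, k * k, 0.0).sum(axis=0)
        sky = np.where(w, k * y, 0.0).sum(axis=0)
        denom = n * skk - sk * sk
        slope_px = np.where(denom > 0, (n * sky - sk * sy) / np.where(denom > 0, denom, 1.0), np.nan)
    slope_px = np.where(n >= min_valid_px, slope_px, np.nan)
    values = slope_px / ret.geometry.axial_pitch
    return EnFaceMap(values, np.isfinite(values), ret.geometry, units="deg/um")


def hemifield_split(
    emap: EnFaceMap, annulus: AnnulusSpec, superior_positive_y: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Split valid annulus pixel values into superior and inferior halves.

    Pixels are partitioned by the sign of ``y - center_y``; pixels exactly on
    the dividing line count as superior. By the package's default orientation
    +y is superior (configurable, the acquisition does not fix it).
    """
    g = emap.geometry
    mask = annulus_mask(annulus, g) & emap.valid_mask
    y = np.arange(g.n_y)[None, :] * g.lateral_pitch_y
    dy = np.broadcast_to(y - annulus.center[1], mask.shape)
    sup_side = dy >= 0 if superior_positive_y else dy <= 0
    sup = emap.values[mask & sup_side]
    inf = emap.values[mask & ~sup_side]
    if sup.size == 0 or inf.size == 0:
        raise ConfigurationError("a hemifield of the annulus contains no valid pixels")
    return sup, inf
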