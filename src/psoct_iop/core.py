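"""Reconstruction of reflectivity and phase retardation from dual-channel PS-OCT data.

A polarization-sensitive OCT system splits the backscattered light into a
co-polarized and a cross-polarized detection channel. From the two channel
amplitudes ``A_co`` and ``A_cross`` the tissue reflectivity and the cumulative
single-pass phase retardation are reconstructed per voxel:

    R      = A_co**2 + A_cross**2          (linear intensity, arbitrary units)
    delta  = arctan(A_cross / A_co)        (degrees, unambiguous range 0-90)

The amplitude-ratio form restricts retardation to the unambiguous range
0-90 deg; values accumulated beyond 90 deg fold back (triangular wrap), which
is why quantitative evaluation slabs downstream are chosen shallow enough to
stay below the first wrap.

The anterior segment (mainly the cornea) adds a retardation offset before the
beam reaches the retina. Because the internal limiting membrane (ILM) itself
carries no tissue retardation, the retardation measured at the ILM samples
exactly this offset; :func:`compensate_corneal` subtracts it per A-scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .segment import Surface


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class VolumeGeometry:
    """Sampling geometry of a PS-OCT volume.

    Axial pixel pitch is given *in tissue* (i.e. already divided by the group
    refractive index). The default pitch of 1.9 um/px encodes the instrument
    correspondence 20 px = 38 um.
    """

    n_z: int
    n_x: int
    n_y: int
    axial_pitch: float = 1.9          # um per pixel, in tissue
    lateral_pitch_x: float = 11.71875  # um per pixel (1.5 mm / 128)
    lateral_pitch_y: float = 11.71875
    wavelength: float = 840.0         # nm
    refractive_index: float = 1.35

    def __post_init__(self) -> None:
        if min(self.n_z, self.n_x, self.n_y) < 1:
            raise InvalidInputError("volume dimensions must be >= 1")
        if min(self.axial_pitch, self.lateral_pitch_x, self.lateral_pitch_y) <= 0:
            raise InvalidInputError("pixel pitches must be positive")
        if self.wavelength <= 0:
            raise InvalidInputError("wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_z, self.n_x, self.n_y)

    @property
    def field_x_um(self) -> float:
        return self.n_x * self.lateral_pitch_x

    @property
    def field_y_um(self) -> float:
        return self.n_y * self.lateral_pitch_y

    def px_to_um_axial(self, px):
        return np.asarray(px, dtype=float) * self.axial_pitch


@dataclass
class PSVolume:
    """Dual-channel amplitude volume, axes ``[z, x, y]`` (depth, fast, slow)."""

    amp_co: np.ndarray
    amp_cross: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        self.amp_co = np.asarray(self.amp_co)
        self.amp_cross = np.asarray(self.amp_cross)
        if self.amp_co.shape != self.amp_cross.shape:
            raise InvalidInputError(
                f"channel shape mismatch: {self.amp_co.shape} vs {self.amp_cross.shape}"
            )
        if self.amp_co.shape != self.geometry.shape:
            raise InvalidInputError(
                f"data shape {self.amp_co.shape} does not match geometry {self.geometry.shape}"
            )
        for name, a in (("amp_co", self.amp_co), ("amp_cross", self.amp_cross)):
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise InvalidInputError(f"{name} must be finite and non-negative")


@dataclass
class ReflectivityVolume:
    """Linear-intensity reflectivity, axes ``[z, x, y]``."""

    linear_intensity: np.ndarray
    geometry: VolumeGeometry

    def db(self) -> np.ndarray:
        """10*log10 of linear intensity; -inf where intensity is zero."""
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.linear_intensity)


@dataclass
class RetardationVolume:
    """Phase retardation in degrees, axes ``[z, x, y]``; values in [0, 90] or NaN."""

    retardation_deg: np.ndarray
    geometry: VolumeGeometry
    compensated: bool = False


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #

def compute_reflectivity(vol: PSVolume) -> ReflectivityVolume:
    """Total backscattered intensity: sum of the two channel intensities."""
    intensity = vol.amp_co.astype(np.float64) ** 2 + vol.amp_cross.astype(np.float64) ** 2
    return ReflectivityVolume(intensity, vol.geometry)


def compute_retardation(vol: PSVolume) -> RetardationVolume:
    """Per-voxel retardation ``arctan(A_cross / A_co)`` in degrees.

    Where both amplitudes vanish the retardation is undefined and set to NaN.
    The arctan of two non-negative amplitudes lies in [0, 90] by construction.
    """
    co = vol.amp_co.astype(np.float64)
    cross = vol.amp_cross.astype(np.float64)
    delta = np.degrees(np.arctan2(cross, co))
    delta[(co == 0) & (cross == 0)] = np.nan
    return RetardationVolume(delta, vol.geometry, compensated=False)


def fold_retardation(delta):
    """Triangular fold of retardation (degrees) into the unambiguous range [0, 90].

    ``fold(d) = m if m <= 90 else 180 - m`` with ``m = d mod 180``. Idempotent
    on [0, 90]; NaN passes through.
    """
    d = np.asarray(delta, dtype=float)
    m = np.mod(d, 180.0)
    out = np.where(m > 90.0, 180.0 - m, m)
    if np.ndim(delta) == 0:
        return float(out)
    return out


def average_frames(
    frames: Sequence[PSVolume],
    repeats_per_position: int,
    positions: int,
    register: bool = True,
    max_shift_px: int = 10,
) -> PSVolume:
    """Average repeated B-scan acquisitions in the linear-intensity domain.

    Emulates the instrument's speckle-reduction scheme (e.g. 5 repeats at each
    of 3 positions ~4 um apart = 15 frames). Frames are first registered to the
    first frame by a rigid integer axial shift found by cross-correlating the
    laterally averaged intensity depth profiles; the positions are separated by
    less than the lateral resolution, so no lateral registration is attempted.
    Channel intensities are averaged and the averaged volume is returned with
    amplitude ``sqrt(mean intensity)`` per channel.
    """
    if len(frames) != repeats_per_position * positions:
        raise InvalidInputError(
            f"expected {repeats_per_position * positions} frames, got {len(frames)}"
        )
    ref = frames[0]
    shape = ref.amp_co.shape
    for f in frames[1:]:
        if f.amp_co.shape != shape:
            raise InvalidInputError("all frames must share one shape")

    ref_profile = None
    acc_co = np.zeros(shape, dtype=np.float64)
    acc_cross = np.zeros(shape, dtype=np.float64)
    for f in frames:
        i_co = f.amp_co.astype(np.float64) ** 2
        i_cross = f.amp_cross.astype(np.float64) ** 2
        if register:
            profile = (i_co + i_cross).mean(axis=tuple(range(1, i_co.ndim)))
            if ref_profile is None:
                ref_profile = profile
                shift = 0
            else:
                shift = _axial_shift(profile, ref_profile, max_shift_px)
            if shift:
                i_co = np.roll(i_co, shift, axis=0)
                i_cross = np.roll(i_cross, shift, axis=0)
        acc_co += i_co
        acc_cross += i_cross
    n = float(len(frames))
    return PSVolume(np.sqrt(acc_co / n), np.sqrt(acc_cross / n), ref.geometry)


def _axial_shift(profile: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Integer shift (applied to `profile`) maximizing correlation with `ref`."""
    best, best_score = 0, -np.inf
    p = profile - profile.mean()
    r = ref - ref.mean()
    for s in range(-max_shift, max_shift + 1):
        score = float(np.dot(np.roll(p, s), r))
        if score > best_score:
            best, best_score = s, score
    return best


def compensate_corneal(
    ret: RetardationVolume,
    ilm: "Surface",
    window_px: int = 4,
    smooth: bool = True,
) -> RetardationVolume:
    """Remove the anterior-segment (corneal) retardation offset per A-scan.

    The retardation measured in a short axial window starting at the ILM is
    attributed to the anterior segment. Because the nerve fiber layer begins
    to accumulate retardation immediately below the ILM, the offset is taken
    as the *intercept at the ILM position* of a linear fit over ``window_px``
    samples, which is exact on noiseless input. The offset map is then median
    smoothed transversely (5x5) for robustness to speckle, and
    ``fold(measured - offset)`` is returned. A-scans with undefined ILM give
    NaN throughout.
    """
    if ret.compensated:
        raise InvalidInputError("retardation volume is already compensated")
    delta = ret.retardation_deg
    n_z = delta.shape[0]
    z0f = np.asarray(ilm.z_position, dtype=float)
    valid = np.isfinite(z0f) & (z0f >= 0) & (z0f <= n_z - window_px)
    z0 = np.where(valid, np.round(z0f), 0).astype(int)

    # gather the window [z0, z0 + window_px) per A-scan
    offs = np.arange(window_px)
    win = np.take_along_axis(
        delta, z0[None, :, :] + offs[:, None, None], axis=0
    )  # [window, x, y]

    # per-A-scan linear fit delta(z) ~ a + b*(z - ilm); offset = a
    k = (z0[None] + offs[:, None, None]) - z0f[None]
    kbar = k.mean(axis=0)
    ybar = win.mean(axis=0)
    cov = ((k - kbar) * (win - ybar)).mean(axis=0)
    var = ((k - kbar) ** 2).mean(axis=0)
    slope = cov / np.where(var > 0, var, 1.0)
    offset = ybar - slope * kbar
    offset[~valid] = np.nan

    if smooth:
        offset = _nanmedian2d(offset, 5)
        offset[~valid] = np.nan

    out = fold_retardation(delta - offset[None, :, :])
    out[:, ~valid] = np.nan
    return RetardationVolume(out, ret.geometry, compensated=True)


def _nanmedian2d(a: np.ndarray, size: int) -> np.ndarray:
    """NaN-aware 2D median filter (edge-padded) for small transverse maps."""
    import warnings as _warnings

    pad = size // 2
    padded = np.pad(a, pad, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (size, size))
    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(win, axis=(-2, -1))


def median_filter_db(db_volume: np.ndarray, size_z: int = 3) -> np.ndarray:
    """Axial median filter of a dB volume (speckle spike suppression)."""
    return ndimage.median_filter(db_volume, size=(size_z, 1, 1), mode="nearest")
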