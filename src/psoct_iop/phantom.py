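"""Synthetic dual-channel PS-OCT volumes of the albino-rat posterior eye.

The generator emulates the layered anatomy the analysis assumes — vitreous
noise floor, ILM surface with an ONH pit, a ~30 um nerve fiber layer, inner
retina, a bright RPE band, choroid and a birefringent sclera — together with
the three IOP responses the study quantifies:

* scleral birefringence rises linearly from baseline to a plateau of
  1.16 deg/um at 45 mmHg (slope 2.75e-2 deg/um/mmHg) and stays flat above;
* the RNFL/retina reflectivity ratio declines linearly at -1.0e-2 per mmHg
  from a baseline of 1.5;
* the ONH region displaces posteriorly above 45 mmHg, reaching 15 um at
  105 mmHg.

Signal model (scalar Jones, single-pass): with cumulative retardation delta
and reflectivity R, the noiseless channel amplitudes are
``A_co = sqrt(R)*|cos(delta)|`` and ``A_cross = sqrt(R)*|sin(delta)|``. Fully
developed speckle makes each channel's single-look intensity exponential with
those mean powers; the emitted volume is, by default, the average of 15
independent looks per voxel (the instrument's 5 repeats x 3 positions frame
averaging), drawn as a gamma variate. An additive noise floor is split evenly
between the channels.

Within the sclera the retardation is referenced to the scleral surface
(``delta = corneal_offset + B * depth_into_sclera``) rather than strictly
accumulated through the retina: the analysis only ever uses the within-slab
slope, and re-referencing keeps every evaluation slab inside the unambiguous
0-90 deg range — the same reason the protocol restricts the fit to a shallow
scleral slab.

Every volume is emitted together with a :class:`PhantomTruth` record holding
the ground-truth surfaces and parameter values, the oracle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import PSVolume, VolumeGeometry
from .errors import ConfigurationError
from .quantify import SCLERAL_SLAB, RNFL_REFLECTIVITY_SLAB
from .segment import Surface

#: IOP sampling of the pressure protocol: 5 mmHg steps to 45, then 10 mmHg steps.
DEFAULT_IOP_LEVELS = (14, 20, 25, 30, 35, 40, 45, 55, 65, 75, 85, 95, 105)


def default_geometry(n_z: int = 400, n_x: int = 128, n_y: int = 128) -> VolumeGeometry:
    """Desk-scale sampling of the ~1.5 x 1.5 mm field at 1.9 um axial pitch."""
    return VolumeGeometry(
        n_z=n_z,
        n_x=n_x,
        n_y=n_y,
        axial_pitch=1.9,
        lateral_pitch_x=1500.0 / n_x,
        lateral_pitch_y=1500.0 / n_y,
        wavelength=840.0,
    )


@dataclass(frozen=True)
class LayerTable:
    """Layer thicknesses (um) and mean reflectivities (dB, absolute scale).

    ``retina_thickness_um`` is the full ILM-to-RPE distance (the RNFL is its
    uppermost part). The RNFL reflectivity is not listed: it is solved per
    A-scan so the protocol's 20 px slab ratio equals the configured response.
    The choroid is sized so that the scleral surface sits one slab offset
    (20 px = 38 um) below the RPE surface, matching the scleral slab that
    "excludes the choroid".
    """

    rnfl_thickness_um: float = 30.0
    retina_thickness_um: float = 190.0
    rpe_thickness_um: float = 8.0
    choroid_thickness_um: float = 30.0
    retina_db: float = -40.0
    rpe_db: float = -20.0
    choroid_db: float = -45.0
    sclera_db: float = -25.0


@dataclass(frozen=True)
class ONHConfig:
    """Optic nerve head morphology: Gaussian pit, RPE-free canal."""

    pit_depth_um: float = 60.0
    pit_sigma_um: float = 100.0
    canal_radius_um: float = 75.0


@dataclass(frozen=True)
class ResponseConfig:
    """Parametric IOP responses of the three quantified tissue properties."""

    birefringence_at_14: float = 0.3075          # deg/um (back-derived baseline)
    birefringence_slope: float = 2.75e-2         # deg/um/mmHg, dynamic phase
    birefringence_plateau_iop: float = 45.0      # mmHg
    ratio_at_14: float = 1.5                     # dimensionless baseline
    ratio_slope: float = -1.0e-2                 # per mmHg
    depression_max_um: float = 15.0              # at depression_max_iop
    depression_onset_iop: float = 45.0
    depression_max_iop: float = 105.0
    depression_flat_radius_um: float = 350.0
    depression_taper_radius_um: float = 450.0

    def birefringence(self, iop: float) -> float:
        capped = min(iop, self.birefringence_plateau_iop)
        return self.birefringence_at_14 + self.birefringence_slope * (capped - 14.0)

    def reflectivity_ratio(self, iop: float) -> float:
        return self.ratio_at_14 + self.ratio_slope * (iop - 14.0)

    def depression_um(self, iop: float) -> float:
        if iop <= self.depression_onset_iop:
            return 0.0
        span = self.depression_max_iop - self.depression_onset_iop
        return self.depression_max_um * (iop - self.depression_onset_iop) / span


def response_defaults() -> ResponseConfig:
    """The calibrated default IOP responses (plateau 1.16 deg/um at >= 45 mmHg)."""
    return ResponseConfig()


@dataclass(frozen=True)
class NoiseConfig:
    """Speckle and noise-floor model.

    ``n_looks`` is the number of independent speckle realisations averaged per
    voxel (15 emulates the instrument's frame averaging; 1 gives fully
    developed single-look speckle). ``include_floor`` adds the additive noise
    floor; disabling both speckle and floor yields a strictly noiseless volume.
    """

    speckle: bool = True
    n_looks: int = 15
    include_floor: bool = True
    floor_db: float = -75.0


@dataclass(frozen=True)
class PhantomConfig:
    geometry: VolumeGeometry = field(default_factory=default_geometry)
    layers: LayerTable = field(default_factory=LayerTable)
    onh: ONHConfig = field(default_factory=ONHConfig)
    response: ResponseConfig = field(default_factory=response_defaults)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    ilm_depth_um: float = 190.0
    corneal_offset_deg: float = 3.0
    rnfl_retardation_deg: float = 9.0

    def noiseless(self) -> "PhantomConfig":
        return replace(self, noise=NoiseConfig(speckle=False, include_floor=False))

    def validate(self, max_iop: float = 105.0) -> None:
        g = self.geometry
        L = self.layers
        depth_um = g.n_z * g.axial_pitch
        anatomy = self.ilm_depth_um + L.retina_thickness_um + L.rpe_thickness_um + L.choroid_thickness_um
        if anatomy >= depth_um:
            raise ConfigurationError("layer stack deeper than the volume")
        if L.rnfl_thickness_um >= L.retina_thickness_um:
            raise ConfigurationError("RNFL thicker than the whole retina")
        # unambiguous-range check in the evaluation slabs (single wrap at 90 deg)
        if self.corneal_offset_deg + self.rnfl_retardation_deg >= 90.0:
            raise ConfigurationError("retinal retardation exceeds the unambiguous range")
        b_max = self.response.birefringence(max_iop)
        deepest_um = (SCLERAL_SLAB.thickness_px - 1) * g.axial_pitch
        if self.corneal_offset_deg + b_max * deepest_um >= 90.0:
            raise ConfigurationError(
                "scleral retardation would wrap inside the evaluation slab; "
                "reduce the corneal offset, the birefringence or the slab depth"
            )


@dataclass
class PhantomTruth:
    """Ground truth emitted with each synthetic volume (the acceptance oracle)."""

    ilm_surface: Surface
    rpe_surface: Surface
    scleral_birefringence: float   # deg/um
    rnfl_retardation: float        # deg
    reflectivity_ratio: float      # dimensionless
    depression_um: float
    iop: float


def _bowl_um(r_um: np.ndarray, iop: float, resp: ResponseConfig) -> np.ndarray:
    """IOP-induced posterior displacement profile: flat top, cosine taper edge."""
    d = resp.depression_um(iop)
    if d == 0.0:
        return np.zeros_like(r_um)
    r0, r1 = resp.depression_flat_radius_um, resp.depression_taper_radius_um
    t = np.clip((r_um - r0) / (r1 - r0), 0.0, 1.0)
    return d * 0.5 * (1.0 + np.cos(np.pi * t))


def _coverage(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fraction of the voxel interval [z-0.5, z+0.5] covered by [lo, hi)."""
    return np.clip(np.minimum(z + 0.5, hi) - np.maximum(z - 0.5, lo), 0.0, 1.0)


def generate_volume(
    config: PhantomConfig, iop: float, seed: int | None = 0
) -> tuple[PSVolume, PhantomTruth]:
    """Generate one synthetic dual-channel volume at a given IOP.

    Anatomy (surfaces, layer reflectivities) depends only on the configuration;
    only the three parametric responses vary with IOP, so a series of volumes
    shares its anatomy. Reflectivity uses partial-volume (coverage-weighted)
    sampling at layer boundaries; retardation is sampled at voxel centres.
    """
    config.validate()
    g = config.geometry
    L = config.layers
    resp = config.response
    pitch = g.axial_pitch
    rng = np.random.default_rng(seed)

    # transverse coordinates (um) and ONH-centred radius
    cx = g.n_x / 2.0 * g.lateral_pitch_x
    cy = g.n_y / 2.0 * g.lateral_pitch_y
    x = np.arange(g.n_x)[:, None] * g.lateral_pitch_x
    y = np.arange(g.n_y)[None, :] * g.lateral_pitch_y
    r_um = np.hypot(x - cx, y - cy)

    # layer boundaries in px (float, conformal to the deformed ILM)
    pit_um = config.onh.pit_depth_um * np.exp(-(r_um**2) / (2.0 * config.onh.pit_sigma_um**2))
    ilm = (config.ilm_depth_um + pit_um + _bowl_um(r_um, iop, resp)) / pitch
    b_rnfl = ilm + L.rnfl_thickness_um / pitch
    b_rpe = ilm + L.retina_thickness_um / pitch
    b_rpe_bot = b_rpe + L.rpe_thickness_um / pitch
    b_sclera = b_rpe + (L.rpe_thickness_um + L.choroid_thickness_um) / pitch
    canal = r_um < config.onh.canal_radius_um
    rpe_outside_canal = np.where(canal, np.nan, b_rpe)
    slab_bottom = (
        float(np.nanmax(np.round(rpe_outside_canal)))
        + SCLERAL_SLAB.offset_px
        + SCLERAL_SLAB.thickness_px
    )
    if slab_bottom > g.n_z:
        raise ConfigurationError("sclera too deep: evaluation slab leaves the volume")

    R_ir = 10.0 ** (L.retina_db / 10.0)
    R_rpe = 10.0 ** (L.rpe_db / 10.0)
    R_ch = 10.0 ** (L.choroid_db / 10.0)
    R_sc = 10.0 ** (L.sclera_db / 10.0)

    z = np.arange(g.n_z, dtype=float)[:, None, None]

    # --- RNFL reflectivity calibrated per A-scan so the protocol's slab ratio
    # equals the configured response exactly on noiseless volumes -------------
    target_ratio = resp.reflectivity_ratio(iop)
    s0 = np.round(ilm).astype(int)
    t_num = RNFL_REFLECTIVITY_SLAB.thickness_px
    num_sel = (z >= s0[None]) & (z < (s0 + t_num)[None])
    den_sel = (z >= (s0 + t_num)[None]) & (z < np.round(b_rpe)[None])

    cov_rnfl = _coverage(z, ilm[None], b_rnfl[None])
    cov_ret = _coverage(z, b_rnfl[None], b_rpe[None])
    c_rnfl_num = (cov_rnfl * num_sel).sum(axis=0)
    c_ret_num = (cov_ret * num_sel).sum(axis=0)
    c_ret_den = (cov_ret * den_sel).sum(axis=0)
    n_den = den_sel.sum(axis=0)
    den_mean = c_ret_den * R_ir / np.maximum(n_den, 1)
    R_n = (target_ratio * den_mean * t_num - c_ret_num * R_ir) / np.maximum(c_rnfl_num, 1e-9)
    if np.any(R_n <= 0):
        raise ConfigurationError("reflectivity-ratio response yields a non-positive RNFL reflectivity")

    # --- reflectivity volume (coverage-weighted layer mixture) ---------------
    refl = cov_rnfl * R_n[None] + cov_ret * R_ir
    outside = (
        _coverage(z, b_rpe[None], b_rpe_bot[None]) * R_rpe
        + _coverage(z, b_rpe_bot[None], b_sclera[None]) * R_ch
        + _coverage(z, b_sclera[None], np.full_like(b_sclera, g.n_z)[None]) * R_sc
    )
    # inside the canal the retina-like optic nerve tissue continues downward
    inside = _coverage(z, b_rpe[None], np.full_like(b_rpe, g.n_z)[None]) * R_ir
    refl = refl + np.where(canal[None], inside, outside)

    # --- cumulative single-pass retardation (deg), sampled at voxel centres --
    b_iop = resp.birefringence(iop)
    ramp = np.clip((z - ilm[None]) / ((b_rnfl - ilm)[None]), 0.0, 1.0)
    delta = config.corneal_offset_deg + config.rnfl_retardation_deg * ramp
    # taper the retinal accumulation away across the choroid so the scleral
    # ramp starts continuously at the corneal offset (keeps slabs wrap-free)
    in_choroid = (z >= b_rpe_bot[None]) & (z < b_sclera[None]) & ~canal[None]
    fade = np.clip((b_sclera[None] - z) / (b_sclera - b_rpe_bot)[None], 0.0, 1.0)
    delta = np.where(
        in_choroid, config.corneal_offset_deg + config.rnfl_retardation_deg * fade, delta
    )
    in_sclera = (z >= b_sclera[None]) & ~canal[None]
    delta = np.where(
        in_sclera,
        config.corneal_offset_deg + b_iop * pitch * (z - b_sclera[None]),
        delta,
    )
    delta_rad = np.radians(delta)  # vitreous carries no signal, its delta is moot

    # --- channel powers and speckle ------------------------------------------
    floor_lin = 10.0 ** (config.noise.floor_db / 10.0) if config.noise.include_floor else 0.0
    p_co = refl * np.cos(delta_rad) ** 2 + floor_lin / 2.0
    p_cross = refl * np.sin(delta_rad) ** 2 + floor_lin / 2.0

    if config.noise.speckle:
        n_looks = config.noise.n_looks
        shape = p_co.shape
        i_co = p_co * rng.gamma(n_looks, 1.0 / n_looks, size=shape)
        i_cross = p_cross * rng.gamma(n_looks, 1.0 / n_looks, size=shape)
    else:
        i_co, i_cross = p_co, p_cross

    vol = PSVolume(
        np.sqrt(i_co).astype(np.float32),
        np.sqrt(i_cross).astype(np.float32),
        g,
    )
    rpe_truth = np.where(canal, np.nan, b_rpe)
    truth = PhantomTruth(
        ilm_surface=Surface(ilm.copy(), g),
        rpe_surface=Surface(rpe_truth, g),
        scleral_birefringence=b_iop,
        rnfl_retardation=config.rnfl_retardation_deg,
        reflectivity_ratio=target_ratio,
        depression_um=resp.depression_um(iop),
        iop=float(iop),
    )
    return vol, truth


def generate_iop_series(
    config: PhantomConfig,
    iop_list=None,
    base_seed: int = 0,
) -> list[tuple[PSVolume, PhantomTruth]]:
    """One volume per IOP level with deterministic per-volume seeds.

    Anatomy is constant across the series; only the IOP-driven responses vary.
    Volume ``i`` uses seed ``base_seed + i``, so the series is reproducible.
    """
    levels = DEFAULT_IOP_LEVELS if iop_list is None else tuple(iop_list)
    return [
        generate_volume(config, iop, seed=base_seed + i)
        for i, iop in enumerate(levels)
    ]


def iter_iop_series(config: PhantomConfig, iop_list=None, base_seed: int = 0):
    """Lazy variant of :func:`generate_iop_series` (one volume in memory at a time)."""
    levels = DEFAULT_IOP_LEVELS if iop_list is None else tuple(iop_list)
    for i, iop in enumerate(levels):
        yield generate_volume(config, iop, seed=base_seed + i)
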