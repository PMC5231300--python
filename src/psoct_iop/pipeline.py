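"""End-to-end orchestration: volumes in, per-volume metrics and series
statistics out.

For every volume the pipeline reconstructs reflectivity and retardation,
estimates the noise floor, segments ILM and RPE, compensates the corneal
retardation offset and evaluates the four peripapillary metrics; the
lowest-pressure (first) volume serves as the depression baseline. Metric
series are then tested against IOP with Spearman's rho and OLS over the
configured pressure ranges, the scleral series additionally with a two-phase
(dynamic/plateau) fit, and the superior/inferior scleral hemifields with a
rank-sum test. Excluded or failed volumes are logged and dropped from the
statistics but never fabricated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    PSVolume,
    compensate_corneal,
    compute_reflectivity,
    compute_retardation,
    median_filter_db,
)
from .errors import ConfigurationError, PSOCTError
from .phantom import DEFAULT_IOP_LEVELS, PhantomConfig, iter_iop_series
from .quantify import (
    AnnulusSpec,
    DEPRESSION_ANNULUS_DIAMETERS,
    METRIC_ANNULUS_DIAMETERS,
    MetricResult,
    annulus_average,
    depression_map,
    hemifield_split,
    reflectivity_ratio_map,
    rnfl_retardation,
    scleral_birefringence_map,
)
from .segment import (
    axial_align_bscans,
    detect_onh_center,
    estimate_noise_floor,
    register_to_baseline,
    segment_ilm,
    segment_rpe,
)
from .stats import (
    IOPSeries,
    birefringence_to_dimensionless,
    ols_fit,
    spearman,
    two_phase_summary,
    wilcoxon_ranksum,
)
from . import io as psio

logger = logging.getLogger("psoct_iop")

METRICS = ("scleral_birefringence", "rnfl_retardation", "reflectivity_ratio", "depression")


@dataclass
class ExperimentConfig:
    mode: str = "phantom"                       # "phantom" | "files"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    iop_list: tuple = DEFAULT_IOP_LEVELS
    manifest: str | None = None                 # CSV (iop, stem) next to TIFFs, files mode
    seed: int = 0
    depression_annulus_diameters: tuple[float, float] = DEPRESSION_ANNULUS_DIAMETERS
    metric_annulus_diameters: tuple[float, float] = METRIC_ANNULUS_DIAMETERS
    iop_ranges: tuple = ((14.0, 105.0), (14.0, 45.0))
    valid_fraction_min: float = 0.10
    onh_center_override: tuple[float, float] | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    metrics: pd.DataFrame                 # one row per volume per metric
    statistics: pd.DataFrame              # per metric per IOP range
    two_phase: dict
    hemifield_p: float
    maps: dict                            # (iop, metric) -> EnFaceMap
    failures: list
    provenance: dict


def _iter_volumes(config: ExperimentConfig):
    if config.mode == "phantom":
        if len(config.iop_list) == 0:
            raise ConfigurationError("empty IOP list")
        yield from iter_iop_series(config.phantom, config.iop_list, base_seed=config.seed)
    elif config.mode == "files":
        if not config.manifest:
            raise ConfigurationError("files mode requires a manifest CSV")
        manifest = pd.read_csv(config.manifest)
        if manifest.empty:
            raise ConfigurationError("empty manifest")
        base = Path(config.manifest).parent
        for _, row in manifest.iterrows():
            yield psio.load_volume(base, str(row["stem"])), _FileTruth(float(row["iop"]))
    else:
        raise ConfigurationError(f"unknown mode {config.mode!r}")


@dataclass
class _FileTruth:
    iop: float


def process_volume(
    vol: PSVolume,
    depression_annulus: AnnulusSpec | None,
    metric_annulus: AnnulusSpec | None,
    baseline_ilm=None,
    onh_center_override=None,
    valid_fraction_min: float = 0.10,
    depression_diameters: tuple[float, float] = DEPRESSION_ANNULUS_DIAMETERS,
    metric_diameters: tuple[float, float] = METRIC_ANNULUS_DIAMETERS,
):
    """Run reconstruction, segmentation, compensation and the four metrics on
    one volume. Returns a dict with metric results, maps and the aligned ILM.

    The annuli may be passed in (to reuse the baseline ONH centre across a
    series); otherwise they are centred on this volume's detected ONH.
    """
    refl = compute_reflectivity(vol)
    dbf = median_filter_db(refl.db())
    noise = estimate_noise_floor(refl)            # provisional, top rows
    ilm = segment_ilm(refl, noise, db_filtered=dbf)
    noise = estimate_noise_floor(refl, ilm)       # refined, vitreous above ILM
    rpe = segment_rpe(refl, ilm, db_filtered=dbf)
    ret = compensate_corneal(compute_retardation(vol), ilm)

    if metric_annulus is None or depression_annulus is None:
        center = detect_onh_center(ilm, override=onh_center_override)
        depression_annulus = AnnulusSpec(center, *depression_diameters)
        metric_annulus = AnnulusSpec(center, *metric_diameters)

    # motion estimated on the periphery only, so ONH deformation is preserved
    ilm_aligned, shifts = axial_align_bscans(
        ilm,
        exclude_center=depression_annulus.center,
        exclude_radius_um=0.75 * depression_annulus.outer_diameter,
    )

    out = {
        "noise": noise,
        "ilm": ilm,
        "ilm_aligned": ilm_aligned,
        "bscan_shifts": shifts,
        "rpe": rpe,
        "depression_annulus": depression_annulus,
        "metric_annulus": metric_annulus,
    }

    ratio_map = reflectivity_ratio_map(refl, ilm, rpe)
    out["reflectivity_ratio_map"] = ratio_map
    out["reflectivity_ratio"] = annulus_average(ratio_map, metric_annulus, valid_fraction_min)

    out["rnfl_retardation"] = rnfl_retardation(
        ret, refl, ilm, noise, metric_annulus, valid_fraction_min=valid_fraction_min
    )

    bir_map = scleral_birefringence_map(ret, refl, rpe, noise)
    out["scleral_birefringence_map"] = bir_map
    out["scleral_birefringence"] = annulus_average(bir_map, metric_annulus, valid_fraction_min)
    sup, inf = hemifield_split(bir_map, metric_annulus)
    out["hemifield_means"] = (float(np.mean(sup)), float(np.mean(inf)))

    if baseline_ilm is not None:
        registered = register_to_baseline(ilm_aligned, baseline_ilm, depression_annulus)
        dep_map = depression_map(registered, baseline_ilm)
        out["depression_map"] = dep_map
        out["depression"] = annulus_average(dep_map, depression_annulus, valid_fraction_min)
    return out


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full experiment described by ``config`` deterministically."""
    t0 = time.time()
    rows, failures, maps = [], [], {}
    hemi_sup, hemi_inf = [], []
    baseline_ilm = None
    depression_annulus = metric_annulus = None
    series = {m: [] for m in METRICS}

    n_done = 0
    for vol, truth in _iter_volumes(config):
        iop = float(truth.iop)
        try:
            res = process_volume(
                vol,
                depression_annulus,
                metric_annulus,
                baseline_ilm=baseline_ilm,
                onh_center_override=config.onh_center_override,
                valid_fraction_min=config.valid_fraction_min,
                depression_diameters=config.depression_annulus_diameters,
                metric_diameters=config.metric_annulus_diameters,
            )
        except PSOCTError as exc:
            logger.warning("volume at %.0f mmHg failed: %s", iop, exc)
            failures.append({"iop": iop, "error": str(exc)})
            continue

        if baseline_ilm is None:
            # first (lowest-pressure) volume anchors registration and the annuli
            baseline_ilm = res["ilm_aligned"]
            depression_annulus = res["depression_annulus"]
            metric_annulus = res["metric_annulus"]
            res["depression"] = MetricResult(0.0, 0.0, int(np.sum(~np.isnan(baseline_ilm.z_position))))

        for m in METRICS:
            r: MetricResult = res[m]
            rows.append(
                {
                    "iop_mmHg": iop,
                    "metric": m,
                    "mean": r.mean,
                    "sd": r.sd,
                    "n_valid": r.n_valid,
                    "excluded": r.excluded,
                    "exclusion_reason": r.exclusion_reason,
                }
            )
            if not r.excluded:
                series[m].append((iop, r.mean))
        maps[(iop, "scleral_birefringence")] = res["scleral_birefringence_map"]
        maps[(iop, "reflectivity_ratio")] = res["reflectivity_ratio_map"]
        if "depression_map" in res:
            maps[(iop, "depression")] = res["depression_map"]
        s, i = res["hemifield_means"]
        hemi_sup.append(s)
        hemi_inf.append(i)
        n_done += 1
        logger.info("processed %.0f mmHg (%.1f s elapsed)", iop, time.time() - t0)

    if n_done == 0:
        raise ConfigurationError("all volumes failed; nothing to report")

    stats_rows = []
    for m in METRICS:
        pts = np.array(series[m], dtype=float).reshape(-1, 2)
        full = IOPSeries(pts[:, 0], pts[:, 1])
        for lo, hi in config.iop_ranges:
            sub = full.restrict(lo, hi)
            row = {"metric": m, "iop_lo": lo, "iop_hi": hi, "n": sub.iop.size}
            try:
                corr = spearman(sub)
                row |= {"rho": corr.rho, "p": corr.p_value, "class": corr.strength_class}
            except PSOCTError:
                row |= {"rho": np.nan, "p": np.nan, "class": "n/a"}
            try:
                fit = ols_fit(sub)
                row |= {"slope": fit.slope, "intercept": fit.intercept}
            except PSOCTError:
                row |= {"slope": np.nan, "intercept": np.nan}
            stats_rows.append(row)
    statistics = pd.DataFrame(stats_rows)

    bir_pts = np.array(series["scleral_birefringence"], dtype=float).reshape(-1, 2)
    bir_series = IOPSeries(bir_pts[:, 0], bir_pts[:, 1])
    below, above = (None, None)
    if bir_series.iop.size >= 2:
        below, above = two_phase_summary(bir_series)
    low = bir_series.restrict(14.0, 45.0)
    dn_slope = np.nan
    if low.iop.size >= 2 and np.unique(low.iop).size >= 2:
        dn_slope = birefringence_to_dimensionless(ols_fit(low).slope)
    two_phase = {
        "below": below,
        "above": above,
        "dimensionless_slope_per_mmHg": dn_slope,
    }

    hemifield_p = np.nan
    if len(hemi_sup) >= 3:
        hemifield_p = wilcoxon_ranksum(hemi_sup, hemi_inf)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_volumes": n_done,
        "n_failures": len(failures),
    }
    return ExperimentReport(
        metrics=pd.DataFrame(rows),
        statistics=statistics,
        two_phase=two_phase,
        hemifield_p=hemifield_p,
        maps=maps,
        failures=failures,
        provenance=provenance,
    )


# fixed colour scales for the exported PNGs
_MAP_SCALES = {
    "depression": (-30.0, 30.0, "RdBu_r"),
    "scleral_birefringence": (0.0, 2.0, "viridis"),
    "reflectivity_ratio": (0.0, 2.0, "magma"),
}


def export_report(report: ExperimentReport, outdir: str | Path) -> dict[str, Path]:
    """Write metrics CSV, statistics CSV/JSON, en face maps and a run log."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["metrics"] = outdir / "metrics.csv"
    report.metrics.to_csv(paths["metrics"], index=False, float_format="%.10g")
    paths["statistics_csv"] = outdir / "statistics.csv"
    report.statistics.to_csv(paths["statistics_csv"], index=False, float_format="%.10g")

    def _reg(r):
        return None if r is None else {"slope": r.slope, "intercept": r.intercept, "n": r.n}

    summary = {
        "provenance": report.provenance,
        "hemifield_wilcoxon_p": report.hemifield_p,
        "two_phase": {
            "below": _reg(report.two_phase["below"]),
            "above": _reg(report.two_phase["above"]),
            "dimensionless_slope_per_mmHg": report.two_phase["dimensionless_slope_per_mmHg"],
        },
        "statistics": report.statistics.to_dict(orient="records"),
        "failures": report.failures,
    }
    paths["statistics_json"] = outdir / "statistics.json"
    paths["statistics_json"].write_text(json.dumps(summary, indent=2, default=float))

    for (iop, metric), emap in report.maps.items():
        stem = f"{metric}_{iop:.0f}mmHg"
        psio.save_map(emap, outdir / "maps" / f"{stem}.tif")
        lo, hi, cmap = _MAP_SCALES.get(metric, (None, None, "viridis"))
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(emap.values.T, vmin=lo, vmax=hi, cmap=cmap, origin="lower")
        ax.set_title(f"{metric} @ {iop:.0f} mmHg [{emap.units}]")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(outdir / "maps" / f"{stem}.png", dpi=100)
        plt.close(fig)

    log_lines = [
        f"psoct-iop {report.provenance['version']} run "
        f"(config {report.provenance['config_hash']}, seed {report.provenance['seed']})",
        f"volumes processed: {report.provenance['n_volumes']}, failures: {report.provenance['n_failures']}",
    ]
    excl = report.metrics[report.metrics["excluded"]]
    for _, row in excl.iterrows():
        log_lines.append(
            f"excluded: {row['metric']} at {row['iop_mmHg']:.0f} mmHg ({row['exclusion_reason']})"
        )
    for f in report.failures:
        log_lines.append(f"failed: volume at {f['iop']:.0f} mmHg ({f['error']})")
    paths["log"] = outdir / "run.log"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths
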